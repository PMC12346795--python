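"""Maximum-error comparison against the reference solution, empirical
convergence orders, and the per-experiment error reports.

One "experiment" is one (problem, case) model instance: problem 1 uses the
immunological interaction set, problem 2 the biochemical one; cases are
A (all patients), B (with CVD), C (without CVD).  A report compares the three
solvers' series with the reference on a common grid, mirroring the structure
of the published error tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (AgingModel, AgingSeries, GridSpec, DEFAULT_PROFILE,
                    build_trajectories, exact_series, grid_from_profile,
                    load_trajectories)
from .screen import InteractionSet, fixture_set
from .solvers import METHODS, solve_all

#: classical orders of the implemented schemes, used as table labels
ORDER_LABELS = {"rk4": "O(dt^4)", "ab2": "O(dt^2)", "backward_euler": "O(dt)"}

_TIE_TOL = 1e-15


def max_abs_error(numeric: AgingSeries, exact: AgingSeries) -> float:
    """max_n |exact_n - numeric_n| over all N+1 nodes, endpoints included."""
    if len(numeric) != len(exact):
        raise ValueError(
            f"series length mismatch: {len(numeric)} vs {len(exact)}")
    if numeric.grid != exact.grid:
        raise ValueError("series live on different grids")
    return float(np.max(np.abs(exact.values - numeric.values)))


@dataclass
class ConvergenceResult:
    """Empirical order: least-squares slope of log(max error) vs log(dt)."""

    method: str
    dts: tuple[float, ...]
    errors: tuple[float, ...]
    slope: Optional[float]           # None when the method is exact
    status: str = "estimated"        # "estimated" | "exact"


def empirical_order(
    f: Callable[[float], float],
    antiderivative: Callable[[float], float],
    method: str,
    dts: Sequence[float],
    interval: tuple[float, float] = (0.0, 1.0),
    a0: float = 0.0,
    *,
    exact_tol: float = 1e-14,
) -> ConvergenceResult:
    """Convergence order of one scheme on a closed-form rhs.

    ``antiderivative`` must satisfy F' = f; the truth series is
    a0 + F(t) - F(a).  Each dt must divide the interval exactly.  If every
    error is below ``exact_tol`` the method is reported as exact (no slope:
    rounding noise has no order).
    """
    from .solvers import integrate_function  # local import avoids cycle noise

    if len(dts) < 3:
        raise ValueError("need at least 3 step sizes")
    a, b = interval
    errors = []
    for dt in dts:
        steps = (b - a) / dt
        n = round(steps)
        if abs(steps - n) > 1e-9:
            raise ValueError(f"dt={dt} does not divide [{a}, {b}] exactly")
        grid = GridSpec(dt=dt, dx=0.0, n_steps=n, interval=(a, b))
        series = integrate_function(f, grid, a0, method)
        t = grid.times()
        truth = a0 + np.array([antiderivative(ti) for ti in t]) \
            - antiderivative(a)
        errors.append(float(np.max(np.abs(series.values - truth))))
    if max(errors) < exact_tol:
        return ConvergenceResult(method, tuple(dts), tuple(errors),
                                 slope=None, status="exact")
    slope = float(np.polyfit(np.log(np.asarray(dts)),
                             np.log(np.asarray(errors)), 1)[0])
    return ConvergenceResult(method, tuple(dts), tuple(errors), slope=slope)


@dataclass
class ExperimentConfig:
    """Every switch a report depends on, echoed into the report itself."""

    profile: str = DEFAULT_PROFILE
    increment_rule: str = "unit"
    ab2_start: str = "rk4"
    ab2_variant: str = "standard"
    reference: str = "integral"
    coefficient_mode: str = "signed"      # "signed" | "magnitude"
    a0: float = 0.0
    trajectory_path: Optional[str] = None  # external trajectories (CSV)

    def flags(self) -> dict:
        return asdict(self)


@dataclass
class ErrorReport:
    """Max-error comparison of the three solvers for one (problem, case)."""

    problem: int
    case: str
    grid: GridSpec
    flags: dict
    errors: Dict[str, float]
    ranking: list[str]
    tied: bool

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.errors.values()):
            raise ValueError("errors must be non-negative")
        by_err = sorted(self.errors, key=lambda m: (self.errors[m], m))
        if by_err != self.ranking:
            raise ValueError("ranking inconsistent with stored errors")

    def to_dict(self) -> dict:
        return {
            "problem": self.problem,
            "case": self.case,
            "grid": {"dt": self.grid.dt, "dx": self.grid.dx,
                     "n_steps": self.grid.n_steps,
                     "interval": list(self.grid.interval)},
            "flags": self.flags,
            "errors": self.errors,
            "ranking": self.ranking,
            "tied": self.tied,
        }

    def to_json(self, **kw) -> str:
        kw.setdefault("sort_keys", True)
        kw.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kw)


def build_model(problem: int, case: str,
                config: Optional[ExperimentConfig] = None,
                interaction_set: Optional[InteractionSet] = None) -> AgingModel:
    """Assemble the aging model for one experiment under one configuration."""
    config = config or ExperimentConfig()
    iset = interaction_set if interaction_set is not None \
        else fixture_set(problem, case)
    if config.coefficient_mode == "magnitude":
        iset = iset.with_magnitudes()
    elif config.coefficient_mode != "signed":
        raise ValueError(
            f"unknown coefficient_mode {config.coefficient_mode!r}")
    grid = grid_from_profile(config.profile)
    if config.trajectory_path:
        traj = load_trajectories(config.trajectory_path, grid)
    else:
        traj = build_trajectories(grid, iset.parameter_names(),
                                  config.increment_rule)
    return AgingModel(iset, traj)


def run_experiment(
    problem: int,
    case: str,
    config: Optional[ExperimentConfig] = None,
    interaction_set: Optional[InteractionSet] = None,
) -> ErrorReport:
    """Solve one experiment with all three methods and report max errors.

    Deterministic given the configuration.  ``interaction_set`` overrides the
    shipped fixture (e.g. with a freshly screened set).
    """
    config = config or ExperimentConfig()
    model = build_model(problem, case, config, interaction_set)
    reference = exact_series(model, config.a0, config.reference)
    results = solve_all(model, config.a0, ab2_start=config.ab2_start,
                        ab2_variant=config.ab2_variant)
    errors = {m: max_abs_error(res.series, reference)
              for m, res in results.items()}
    ranking = sorted(errors, key=lambda m: (errors[m], m))
    tied = max(errors.values()) - min(errors.values()) <= _TIE_TOL
    return ErrorReport(problem=problem, case=case, grid=model.grid,
                       flags=config.flags(), errors=errors,
                       ranking=ranking, tied=tied)


def run_all_experiments(
    config: Optional[ExperimentConfig] = None,
    interaction_sets: Optional[Dict[tuple[int, str], InteractionSet]] = None,
) -> Dict[tuple[int, str], ErrorReport]:
    """Reports for all six (problem, case) experiments."""
    out = {}
    for problem in (1, 2):
        for case in ("A", "B", "C"):
            iset = (interaction_sets or {}).get((problem, case))
            out[(problem, case)] = run_experiment(problem, case, config, iset)
    return out


def error_table(reports: Dict[tuple[int, str], ErrorReport]) -> pd.DataFrame:
    """Long-format table shaped like the published comparison tables:
    columns problem, method, order_label, case, max_error."""
    rows = []
    for (problem, case), rep in sorted(reports.items()):
        for method in METHODS:
            rows.append((problem, method, ORDER_LABELS[method], case,
                         rep.errors[method]))
    return pd.DataFrame(
        rows, columns=["problem", "method", "order_label", "case",
                       "max_error"])


def series_frame(model: AgingModel, config: ExperimentConfig) -> pd.DataFrame:
    """Reference and all three numerical series on one grid, for export."""
    reference = exact_series(model, config.a0, config.reference)
    results = solve_all(model, config.a0, ab2_start=config.ab2_start,
                        ab2_variant=config.ab2_variant)
    out = {"n": np.arange(model.grid.n_steps + 1), "t": model.grid.times(),
           "exact": reference.values}
    for m in METHODS:
        out[m] = results[m].series.values
    return pd.DataFrame(out)
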