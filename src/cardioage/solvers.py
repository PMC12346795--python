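"""Three time-stepping schemes for the state-independent aging ODE.

All three advance the scalar aging state A against a right-hand side f that
depends on time only, so each scheme reduces to a quadrature rule:

* classical fourth-order Runge-Kutta (one step = Simpson's rule; with a
  state-independent f the two half-step stages coincide, k2 = k3 exactly);
* two-step Adams-Bashforth, A_{i+1} = A_i + dt*(3/2 f_i - 1/2 f_{i-1}),
  bootstrapped with one RK4 step by default (``start="forward_euler"``
  reproduces a cruder startup);
* backward (implicit) Euler, A_{i+1} = A_i + dt*f_{i+1} -- state-independence
  makes the implicit equation explicit, no iteration needed or performed.

Each solver accepts either an :class:`~cardioage.model.AgingModel` (rhs
tabulated on the grid; RK4 half-step values come from linearly interpolated
trajectories) or, via :func:`integrate_function`, a closed-form rhs callable
(used by the convergence suite, where the theoretical orders 4 / 2 / 1 are
observable).

``solve_ab2(..., variant="shifted")`` evaluates both Adams-Bashforth stencil
points one step late (f_{i+1}, f_i instead of f_i, f_{i-1}).  It is not a
correct integrator; it is shipped because, against a left-Riemann reference,
its maximum error is exactly 3/2 times the backward-Euler error for *any*
rhs -- the signature relation found in the published error tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .model import AgingModel, AgingSeries, GridSpec, rhs_midpoints, rhs_nodes

METHODS = ("rk4", "ab2", "backward_euler")
AB2_STARTS = ("rk4", "forward_euler")
AB2_VARIANTS = ("standard", "shifted")


@dataclass(frozen=True)
class RKStages:
    """Stage slopes of one RK4 step.  For a state-independent rhs, k2 == k3
    exactly: both evaluate the rhs at t_n + h/2."""

    k1: float
    k2: float
    k3: float
    k4: float


@dataclass
class SolverResult:
    series: AgingSeries
    method: str
    stage_log: Optional[List[RKStages]] = None


class _NodeRHS:
    """rhs sampled at grid nodes and half nodes.

    ``nodes[n]`` is f(t_n); ``mids[n]`` is f(t_n + h/2).  The model path
    tabulates both from the trajectory grid; the callable path evaluates
    analytically.
    """

    def __init__(self, nodes: np.ndarray, mids: np.ndarray):
        self.nodes = np.asarray(nodes, dtype=float)
        self.mids = np.asarray(mids, dtype=float)

    @classmethod
    def from_model(cls, model: AgingModel) -> "_NodeRHS":
        return cls(rhs_nodes(model), rhs_midpoints(model))

    @classmethod
    def from_callable(cls, f: Callable[[float], float],
                      grid: GridSpec) -> "_NodeRHS":
        t = grid.times()
        nodes = np.array([f(ti) for ti in t])
        mids = np.array([f(ti + grid.dt / 2.0) for ti in t[:-1]])
        return cls(nodes, mids)


def _check_grid(model: AgingModel, grid: Optional[GridSpec]) -> GridSpec:
    if grid is None:
        return model.grid
    if grid != model.grid:
        raise ValueError(
            "grid does not match the model's trajectory grid "
            f"({grid} vs {model.grid})")
    return grid


def _rk4(f: _NodeRHS, grid: GridSpec, a0: float,
         log_stages: bool) -> tuple[np.ndarray, Optional[List[RKStages]]]:
    n_steps = grid.n_steps
    h = grid.dt
    values = np.empty(n_steps + 1)
    values[0] = a0
    log: Optional[List[RKStages]] = [] if log_stages else None
    for n in range(n_steps):
        k1 = f.nodes[n]
        k2 = f.mids[n]
        k3 = f.mids[n]  # state-independent rhs: identical to k2
        k4 = f.nodes[n + 1]
        values[n + 1] = values[n] + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if log is not None:
            log.append(RKStages(k1, k2, k3, k4))
    return values, log


def _ab2(f: _NodeRHS, grid: GridSpec, a0: float, start: str,
         variant: str) -> np.ndarray:
    if start not in AB2_STARTS:
        raise ValueError(f"unknown ab2 start {start!r}")
    if variant not in AB2_VARIANTS:
        raise ValueError(f"unknown ab2 variant {variant!r}")
    n_steps = grid.n_steps
    dt = grid.dt
    values = np.empty(n_steps + 1)
    values[0] = a0
    if n_steps == 0:
        return values
    if variant == "shifted":
        # the late stencil needs no history: apply it from the first step
        # (this uniformity is what yields the exact 3/2-of-backward-Euler
        # error law against a left-Riemann reference)
        for i in range(n_steps):
            values[i + 1] = values[i] + dt * (1.5 * f.nodes[i + 1]
                                              - 0.5 * f.nodes[i])
        return values
    if start == "rk4":
        values[1] = a0 + dt / 6.0 * (f.nodes[0] + 4 * f.mids[0] + f.nodes[1])
    else:
        values[1] = a0 + dt * f.nodes[0]
    for i in range(1, n_steps):
        values[i + 1] = values[i] + dt * (1.5 * f.nodes[i]
                                          - 0.5 * f.nodes[i - 1])
    return values


def _backward_euler(f: _NodeRHS, grid: GridSpec, a0: float) -> np.ndarray:
    values = np.empty(grid.n_steps + 1)
    values[0] = a0
    values[1:] = a0 + np.cumsum(grid.dt * f.nodes[1:])
    return values


def solve_rk4(model: AgingModel, a0: float = 0.0,
              grid: Optional[GridSpec] = None, *,
              log_stages: bool = False) -> SolverResult:
    """Classical RK4.  Half-step rhs values come from linearly interpolated
    trajectories, so each step is Simpson's rule over [t_n, t_{n+1}]."""
    grid = _check_grid(model, grid)
    values, log = _rk4(_NodeRHS.from_model(model), grid, a0, log_stages)
    return SolverResult(AgingSeries(values, "rk4", grid), "rk4", log)


def solve_ab2(model: AgingModel, a0: float = 0.0,
              grid: Optional[GridSpec] = None, *,
              start: str = "rk4", variant: str = "standard") -> SolverResult:
    """Two-step Adams-Bashforth with a configurable first step."""
    grid = _check_grid(model, grid)
    values = _ab2(_NodeRHS.from_model(model), grid, a0, start, variant)
    return SolverResult(AgingSeries(values, "ab2", grid), "ab2")


def solve_backward_euler(model: AgingModel, a0: float = 0.0,
                         grid: Optional[GridSpec] = None) -> SolverResult:
    """Implicit Euler, solved in closed form (rhs ignores the state)."""
    grid = _check_grid(model, grid)
    values = _backward_euler(_NodeRHS.from_model(model), grid, a0)
    return SolverResult(AgingSeries(values, "backward_euler", grid),
                        "backward_euler")


def integrate_function(f: Callable[[float], float], grid: GridSpec,
                       a0: float = 0.0, method: str = "rk4", *,
                       ab2_start: str = "rk4") -> AgingSeries:
    """Integrate a closed-form rhs f(t) with one of the three schemes.

    Stage values are evaluated analytically (no trajectory interpolation),
    so RK4 exhibits its theoretical fourth order here.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    fr = _NodeRHS.from_callable(f, grid)
    if method == "rk4":
        values, _ = _rk4(fr, grid, a0, log_stages=False)
    elif method == "ab2":
        values = _ab2(fr, grid, a0, ab2_start, "standard")
    else:
        values = _backward_euler(fr, grid, a0)
    return AgingSeries(values, method, grid)


def solve_all(model: AgingModel, a0: float = 0.0, *,
              ab2_start: str = "rk4",
              ab2_variant: str = "standard") -> dict[str, SolverResult]:
    """All three solvers on one model, keyed by method name."""
    return {
        "rk4": solve_rk4(model, a0),
        "ab2": solve_ab2(model, a0, start=ab2_start, variant=ab2_variant),
        "backward_euler": solve_backward_euler(model, a0),
    }
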