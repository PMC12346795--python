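"""Pearson interaction screening between the clinical/social block and a
biomarker block, and the published interaction-coefficient sets.

The aging model is built from k = 6 (social factor, biomarker, r) triples per
experiment; screening selects them from the cross-block Pearson matrix by
coefficient magnitude.  Because the study's cohort is private, the six
published sets (two biomarker blocks x three patient cases) are shipped
verbatim via :func:`fixture_sets` so the numerical pipeline runs without data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import CohortTable

PROBLEM_BLOCKS = {1: "immunological", 2: "biochemical"}
CASES = ("A", "B", "C")  # all patients / with CVD / without CVD


@dataclass
class CorrelationMatrix:
    """Cross-block Pearson matrix: rows = clinical/social, cols = biomarkers.

    Entries for constant columns are NaN ("undefined"), never silently zero,
    and are excluded from pair selection.
    """

    r: pd.DataFrame
    n_used: int

    @property
    def social(self) -> list[str]:
        return list(self.r.index)

    @property
    def biomarkers(self) -> list[str]:
        return list(self.r.columns)

    def defined_entries(self) -> list[tuple[str, str, float]]:
        out = []
        for s in self.r.index:
            for b in self.r.columns:
                val = self.r.loc[s, b]
                if np.isfinite(val):
                    out.append((s, b, float(val)))
        return out

    def to_long(self) -> pd.DataFrame:
        rows = [(s, b, v, self.n_used) for s, b, v in self.defined_entries()]
        return pd.DataFrame(rows, columns=["var1", "var2", "r", "n_used"])


@dataclass(frozen=True)
class InteractionPair:
    """One weighted interaction term a_i * social_i * biomarker_i."""

    social: str
    biomarker: str
    coefficient: float

    @property
    def magnitude(self) -> float:
        return abs(self.coefficient)

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1.0:
            raise ValueError(
                f"|coefficient| > 1 for ({self.social}, {self.biomarker})")


@dataclass
class InteractionSet:
    """The k pairs defining one model instance (one case of one problem)."""

    pairs: tuple[InteractionPair, ...]
    problem: Optional[int] = None   # 1 immunological, 2 biochemical
    case: Optional[str] = None      # A all, B with CVD, C without CVD
    source: str = "screened"

    def __post_init__(self) -> None:
        combos = [(p.social, p.biomarker) for p in self.pairs]
        if len(combos) != len(set(combos)):
            raise ValueError("duplicate (social, biomarker) combination")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([p.coefficient for p in self.pairs])

    def parameter_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.social)
            seen.setdefault(p.biomarker)
        return list(seen)

    def with_magnitudes(self) -> "InteractionSet":
        """Coefficient-mode switch: force all coefficients positive."""
        return InteractionSet(
            tuple(InteractionPair(p.social, p.biomarker, abs(p.coefficient))
                  for p in self.pairs),
            problem=self.problem, case=self.case, source=self.source)

    def to_dict(self) -> dict:
        return {
            "problem": self.problem,
            "case": self.case,
            "source": self.source,
            "pairs": [{"social": p.social, "biomarker": p.biomarker,
                       "r": p.coefficient} for p in self.pairs],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def pearson_matrix(
    cohort: Union[CohortTable, pd.DataFrame],
    social_vars: Sequence[str],
    biomarker_vars: Sequence[str],
) -> CorrelationMatrix:
    """Product-moment correlation of every (social, biomarker) column pair.

    Binary and ordinal columns enter on their integer codes, so entries
    against continuous columns are point-biserial / polyserial-style Pearson
    coefficients -- exactly what a Pearson routine computes on the raw table.
    Constant columns yield NaN rows/columns and a warning.
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    if len(df) < 3:
        raise ValueError(f"need >= 3 records, got {len(df)}")
    if set(social_vars) & set(biomarker_vars):
        raise ValueError("social and biomarker blocks must be disjoint")
    for v in list(social_vars) + list(biomarker_vars):
        if v not in df.columns:
            raise KeyError(f"variable {v!r} not present in the cohort table")

    x = df[list(social_vars)].to_numpy(dtype=float)
    y = df[list(biomarker_vars)].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum(axis=0))
    const_x = sx == 0.0
    const_y = sy == 0.0
    if const_x.any() or const_y.any():
        const = ([v for v, c in zip(social_vars, const_x) if c]
                 + [v for v, c in zip(biomarker_vars, const_y) if c])
        warnings.warn(
            f"constant columns excluded from correlation: {const}",
            stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(sx, sy)
    r[const_x, :] = np.nan
    r[:, const_y] = np.nan
    r = np.clip(r, -1.0, 1.0, out=r)  # guard rounding past the bounds
    frame = pd.DataFrame(r, index=list(social_vars),
                         columns=list(biomarker_vars))
    return CorrelationMatrix(frame, n_used=len(df))


def select_top_pairs(
    matrix: CorrelationMatrix,
    k: int = 6,
    problem: Optional[int] = None,
    case: Optional[str] = None,
) -> InteractionSet:
    """The k interaction pairs of largest |r|, descending, signed r kept.

    Ties in magnitude break lexicographically by (social, biomarker) name.
    """
    entries = matrix.defined_entries()
    if len(entries) < k:
        raise ValueError(
            f"requested k={k} pairs but only {len(entries)} defined entries "
            "are available")
    ranked = sorted(entries, key=lambda e: (-abs(e[2]), e[0], e[1]))
    pairs = tuple(InteractionPair(s, b, r) for s, b, r in ranked[:k])
    return InteractionSet(pairs, problem=problem, case=case, source="screened")


# Published interaction sets: {(problem, case): [(social, biomarker, r)]}.
# The source tables print "II10" and "ICD95" once each; no such variables
# exist elsewhere, so they are read as IL10 and CD95.
_FIXTURES = {
    (1, "A"): [("BMI", "HLA.DR", 0.39), ("PICS", "CD14", 0.37),
               ("BMI", "IPGF", 0.36), ("E", "CD59", 0.32),
               ("BMI", "CD14", 0.29), ("CHD", "CD14", 0.30)],
    (1, "B"): [("BMI", "HLA.DR", 0.50), ("E", "HLA.DR", 0.43),
               ("PICS", "CD14", 0.41), ("E", "CD56", 0.38),
               ("AH", "CD16", 0.38), ("CHD", "IPGF", 0.37)],
    (1, "C"): [("CVD", "IL10", 0.67), ("A", "CD95", 0.43),
               ("BMI", "CD95", 0.43), ("PhA", "CD59", 0.42),
               ("E", "CD59", 0.39), ("PhA", "IPGF", 0.37)],
    (2, "A"): [("CVD", "CTT", 0.43), ("ACVD", "ALB", 0.41),
               ("BMI", "GFR", 0.38), ("CVD", "SOD", 0.33),
               ("AH", "SOD", 0.29), ("ACVD", "GFR", 0.31)],
    (2, "B"): [("PhA", "GFR", 0.47), ("PhA", "ChE", 0.43),
               ("ACVD", "CRP", 0.33), ("AB", "ChE", 0.30),
               ("S", "CTT", 0.24), ("stent", "ChE", 0.24)],
    (2, "C"): [("BMI", "ALB", 0.55), ("BMI", "GFR", 0.48),
               ("E", "SOD", 0.36), ("PhA", "SOD", 0.36),
               ("CVD", "SOD", 0.29), ("A", "CTT", 0.24)],
}


def fixture_sets() -> dict[tuple[int, str], InteractionSet]:
    """The six published model instances, transcribed verbatim.

    Keys are (problem, case): problem 1 = immunological biomarkers,
    problem 2 = biochemical; case A = all patients, B = with CVD,
    C = without CVD.
    """
    return {
        key: InteractionSet(
            tuple(InteractionPair(s, b, r) for s, b, r in triples),
            problem=key[0], case=key[1], source="fixture")
        for key, triples in _FIXTURES.items()
    }


def fixture_set(problem: int, case: str) -> InteractionSet:
    try:
        return fixture_sets()[(problem, case.upper())]
    except (KeyError, AttributeError):
        raise KeyError(
            f"no fixture for problem={problem!r}, case={case!r}; "
            f"available: {sorted(_FIXTURES)}") from None
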