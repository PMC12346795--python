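"""Variable catalog: the immunological, biochemical and clinical/social
variables of the cardiovascular-aging study, with scale, units and (where a
laboratory norm exists) reference ranges.

The catalog is the single source of truth for column names.  Names use the
dotted spellings that appear in the interaction tables (``HLA.DR``,
``NT.proBNP``) so that screened and fixture interaction sets resolve against
generated cohort tables without translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple

ROLES = ("immunological", "biochemical", "clinical_social")
SCALES = ("continuous", "binary", "ordinal")


@dataclass(frozen=True)
class VariableDescriptor:
    """One named variable: its block (role), measurement scale and units.

    ``reference_range`` is the printed laboratory norm where one exists; it is
    used by the cohort generator to centre and bound the synthetic marginal.
    ``n_levels`` applies to ordinal variables only (levels are 0..n_levels-1).
    """

    name: str
    role: str
    scale: str = "continuous"
    units: str = ""
    reference_range: Optional[Tuple[float, float]] = None
    n_levels: int = 3

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r} for {self.name!r}")
        if self.reference_range is not None:
            lo, hi = self.reference_range
            if not lo < hi:
                raise ValueError(
                    f"reference range for {self.name!r} must satisfy low < high"
                )
        if self.scale == "ordinal" and self.n_levels < 2:
            raise ValueError(f"ordinal {self.name!r} needs >= 2 levels")


@dataclass
class VariableCatalog:
    """Ordered collection of descriptors with unique names."""

    descriptors: Tuple[VariableDescriptor, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names in catalog: {dupes}")

    def __iter__(self) -> Iterator[VariableDescriptor]:
        return iter(self.descriptors)

    def __contains__(self, name: str) -> bool:
        return any(d.name == name for d in self.descriptors)

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def get(self, name: str) -> VariableDescriptor:
        for d in self.descriptors:
            if d.name == name:
                return d
        raise KeyError(f"variable {name!r} not in catalog")

    def by_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [d.name for d in self.descriptors if d.role == role]


def default_catalog() -> VariableCatalog:
    """The study's variable set.

    Immunological markers are flow-cytometry readouts reported on a common
    normalised scale (no printed norms); biochemical markers carry the printed
    laboratory reference ranges; clinical/social factors are binary history
    flags or small ordinal scores (education, alcohol, physical activity).
    """
    imm = [
        VariableDescriptor("CD59", "immunological"),
        VariableDescriptor("CD16", "immunological"),
        VariableDescriptor("IL10", "immunological"),
        VariableDescriptor("CD14", "immunological"),
        VariableDescriptor("IPGF", "immunological"),
        VariableDescriptor("CD19", "immunological"),
        VariableDescriptor("TNF", "immunological"),
        VariableDescriptor("VEGF", "immunological"),
        VariableDescriptor("CD56", "immunological"),
        VariableDescriptor("PRF", "immunological"),
        VariableDescriptor("GM.CSF", "immunological"),
        VariableDescriptor("CD8", "immunological"),
        VariableDescriptor("HLA.DR", "immunological"),
        VariableDescriptor("CD95", "immunological"),
        VariableDescriptor("CD4", "immunological"),
    ]
    bio = [
        VariableDescriptor("ALB", "biochemical", units="g/L",
                           reference_range=(38.00, 50.00)),
        VariableDescriptor("CRP", "biochemical", units="mg/L",
                           reference_range=(0.0, 5.0)),
        VariableDescriptor("ChE", "biochemical", units="u/L",
                           reference_range=(4260.00, 11250.00)),
        VariableDescriptor("NT.proBNP", "biochemical", units="pg/mL",
                           reference_range=(0.00, 450.00)),
        VariableDescriptor("CTT", "biochemical", units="mg/L",
                           reference_range=(0.47, 1.09)),
        # printed as a one-sided norm (>60); upper bound is a conventional cap
        VariableDescriptor("GFR", "biochemical", units="mL/min/1.73m2",
                           reference_range=(60.0, 120.0)),
        VariableDescriptor("SOD", "biochemical", units="u/mL",
                           reference_range=(164.00, 240.00)),
    ]
    # conventional adult range for BMI; the study reports none
    clin = [
        VariableDescriptor("S", "clinical_social", scale="binary"),
        VariableDescriptor("A", "clinical_social", scale="ordinal"),
        VariableDescriptor("ACVD", "clinical_social", scale="binary"),
        VariableDescriptor("PhA", "clinical_social", scale="ordinal"),
        VariableDescriptor("E", "clinical_social", scale="ordinal"),
        VariableDescriptor("AB", "clinical_social", scale="binary"),
        VariableDescriptor("AF", "clinical_social", scale="binary"),
        VariableDescriptor("CHD", "clinical_social", scale="binary"),
        VariableDescriptor("BMI", "clinical_social", units="kg/m2",
                           reference_range=(18.5, 40.0)),
        VariableDescriptor("PICS", "clinical_social", scale="binary"),
        VariableDescriptor("stent", "clinical_social", scale="binary"),
        VariableDescriptor("DM", "clinical_social", scale="binary"),
        VariableDescriptor("CHF", "clinical_social", scale="binary"),
        VariableDescriptor("CVD", "clinical_social", scale="binary"),
        VariableDescriptor("AH", "clinical_social", scale="binary"),
    ]
    return VariableCatalog(tuple(imm + bio + clin))
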