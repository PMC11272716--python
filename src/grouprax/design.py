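"""Study-design bookkeeping: substances, dose ladders, time points, treatment groups.

A grouping/read-across omics bridging study exposes each substance at an
ordered ladder of dose levels, samples at a set of time points, and keeps
substance-specific untreated controls.  Every downstream matrix is keyed to
the deterministic treatment-group order defined here so that dendrograms and
support tables are reproducible run to run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

__all__ = [
    "TreatmentGroup",
    "StudyDesign",
    "Exclusion",
    "build_design",
    "apply_exclusions",
    "CONTROL_DOSE",
]

#: Dose-level label reserved for untreated (carrier-solvent) controls.
CONTROL_DOSE = "control"


class TreatmentGroup(NamedTuple):
    """One (substance, dose level, time point) cell of the design.

    ``time_point`` is ``None`` after time points have been collapsed by the
    maximum-perturbation step, in which case the group denotes a
    (substance, dose) pair.
    """

    substance: str
    dose_level: str
    time_point: str | None = None

    def __str__(self) -> str:  # used for matrix column labels / newick leaves
        parts = [self.substance, self.dose_level]
        if self.time_point is not None:
            parts.append(self.time_point)
        return "/".join(parts)


class Exclusion(NamedTuple):
    """A treatment group removed from the study, with the reason recorded."""

    substance: str
    dose_level: str
    time_point: str
    reason: str = ""


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(labels) == 0:
        raise ValueError(f"{what} labels must be non-empty")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels: {list(labels)}")


@dataclass
class StudyDesign:
    """Full-factorial exposure design with an exclusion list.

    Parameters
    ----------
    substances
        Substance labels, e.g. the seven azo dyes of a read-across category.
    dose_levels
        Ordered dose labels (low to high); nominal concentrations, if known,
        in ``nominal_doses`` as ``{substance: {dose_level: conc}}`` and must be
        strictly increasing along ``dose_levels`` for each substance.
    time_points
        Ordered sampling-time labels (e.g. ``["2h", "24h", "48h"]``).
    replicates_per_group
        Intended replicate vessels per treatment group.
    exclusions
        Groups removed from the study (immobilisation losses, QC failures).
    """

    substances: list[str]
    dose_levels: list[str]
    time_points: list[str]
    replicates_per_group: int = 6
    exclusions: list[Exclusion] = field(default_factory=list)
    nominal_doses: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.substances, "substance")
        _check_unique(self.dose_levels, "dose")
        _check_unique(self.time_points, "time")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be positive")
        self.exclusions = [Exclusion(*e) for e in self.exclusions]
        cells = set(self.groups())
        for exc in self.exclusions:
            if TreatmentGroup(exc.substance, exc.dose_level, exc.time_point) not in cells:
                raise ValueError(f"exclusion {exc} does not refer to an existing design cell")
        for sub, ladder in self.nominal_doses.items():
            concs = [ladder[d] for d in self.dose_levels if d in ladder]
            if any(b <= a for a, b in zip(concs, concs[1:])):
                raise ValueError(f"nominal concentrations for {sub} not strictly increasing")

    def groups(self) -> list[TreatmentGroup]:
        """Full-factorial treatment groups in deterministic design order."""
        return build_design(self.substances, self.dose_levels, self.time_points)

    def retained_groups(self) -> list[TreatmentGroup]:
        """Treatment groups remaining after applying the exclusion list."""
        return apply_exclusions(self.groups(), self.exclusions)


def build_design(
    substances: Sequence[str],
    dose_levels: Sequence[str],
    time_points: Sequence[str],
) -> list[TreatmentGroup]:
    """Enumerate the full-factorial treatment groups.

    Order is lexicographic by (substance, dose index, time index) following
    the input label order, so a 7-substance, 3-dose, 3-time study yields 63
    groups in a fixed, reproducible order.
    """
    _check_unique(list(substances), "substance")
    _check_unique(list(dose_levels), "dose")
    _check_unique(list(time_points), "time")
    return [
        TreatmentGroup(s, d, t)
        for s in substances
        for d in dose_levels
        for t in time_points
    ]


def apply_exclusions(
    groups: Sequence[TreatmentGroup],
    exclusions: Sequence[Exclusion | tuple],
) -> list[TreatmentGroup]:
    """Remove excluded treatment groups, preserving order.

    A group missing in any one omics layer must be removed from all layers,
    so exclusion lists from different layers are merged before this call.
    Excluding a group that is not present is a warning, not an error
    (idempotence: re-applying the same list is a no-op).
    """
    excluded = set()
    group_set = set(groups)
    for e in exclusions:
        e = Exclusion(*e)
        g = TreatmentGroup(e.substance, e.dose_level, e.time_point)
        if g not in group_set:
            warnings.warn(f"exclusion of non-existent group {g}", stacklevel=2)
        excluded.add(g)
    return [g for g in groups if g not in excluded]
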