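"""Dose ladders, potency bookkeeping, analogue selection and read-across.

The acute potency of each substance is summarised by its equi-effective
dose: the nominal aqueous concentration inducing 10% immobilisation in the
48-h acute test (lower dose = more potent).  Exposure doses for the omics
bridging study descend from that high dose in half-log10 steps.  Analogue
selection queries the supported clusters of the collapsed multi-omics
dendrogram for the substance whose doses join the target's at the smallest
height; read-across then transfers the source's measured chronic NOEC/LOEC
to the target unchanged, recording whether the conservative worst-case
criterion (source at least as potent as target) holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .bootstrap import BootstrapResult

__all__ = [
    "PotencyRecord",
    "ReadAcrossRecord",
    "AnalogueResult",
    "derive_dose_ladder",
    "resolve_nonresponsive",
    "select_analogue",
    "read_across",
    "read_potency_table",
]


@dataclass(frozen=True)
class PotencyRecord:
    """Acute potency and (optional) measured chronic toxicity of a substance."""

    substance: str
    equi_effective_dose: float | None  # mass/volume; dose causing 10% immobilisation
    responsive: bool = True  # False: no immobilisation at any tested dose
    noec: float | None = None  # measured chronic NOEC
    loec: float | None = None  # measured chronic LOEC

    def __post_init__(self) -> None:
        if self.equi_effective_dose is not None and self.equi_effective_dose <= 0:
            raise ValueError("equi-effective dose must be positive")
        if self.noec is not None and self.loec is not None and not self.noec < self.loec:
            raise ValueError("NOEC must be below LOEC")


@dataclass(frozen=True)
class ReadAcrossRecord:
    """A NOEC/LOEC transfer from source to target substance."""

    source: str
    target: str
    predicted_noec: float
    predicted_loec: float | None
    worst_case_satisfied: bool
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class AnalogueResult:
    """Outcome of analogue selection for a target substance."""

    target: str
    sources: tuple[str, ...]  # empty: no supported analogue; >1: tie, unresolved
    join_height: float | None
    cluster_members: tuple[str, ...]
    au: float | None

    @property
    def source(self) -> str | None:
        return self.sources[0] if len(self.sources) == 1 else None


def derive_dose_ladder(high_dose: float) -> tuple[float, float, float]:
    """(low, medium, high) nominal doses, descending in half-log10 steps.

    medium = high * 10**-0.5, low = high * 10**-1; the ladder spans one
    order of magnitude and is scale-equivariant in the high dose.
    """
    if high_dose <= 0:
        raise ValueError("high dose must be positive")
    return (high_dose * 0.1, high_dose * 10 ** -0.5, high_dose)


def resolve_nonresponsive(potencies: list[PotencyRecord]) -> list[PotencyRecord]:
    """Assign non-responsive substances the highest responsive equi-effective dose.

    A substance that never immobilised the test organisms has no measurable
    equi-effective dose; it is set to the maximum across the responsive
    substances (the least-potent anchor), keeping its responsive flag False.
    Idempotent.
    """
    responsive_doses = [
        p.equi_effective_dose
        for p in potencies
        if p.responsive and p.equi_effective_dose is not None
    ]
    if not responsive_doses:
        raise ValueError("no responsive substance with a measured equi-effective dose")
    anchor = max(responsive_doses)
    return [
        p if p.responsive and p.equi_effective_dose is not None
        else replace(p, equi_effective_dose=anchor)
        for p in potencies
    ]


def select_analogue(
    result: BootstrapResult,
    target: str,
    au_threshold: float = 0.80,
    leaf_substance=lambda leaf: leaf.substance if hasattr(leaf, "substance") else str(leaf).split("/")[0],
) -> AnalogueResult:
    """Pick the read-across source from a supported omics dendrogram.

    Works on the collapsed (substance, dose) dendrogram: candidate sources
    are substances whose complete dose set co-clusters with the target's
    complete dose set inside a cluster whose AU support reaches
    ``au_threshold``; among candidates, the one joining the target at the
    smallest merge height wins.  Ties are returned as a list, not resolved.
    A target with no supported companion yields an empty-source result, not
    an exception.
    """
    dend = result.dendrogram
    substance_of = {leaf: leaf_substance(leaf) for leaf in dend.leaves}
    substances = sorted(set(substance_of.values()))
    full_mask = {
        s: dend.mask_of([leaf for leaf in dend.leaves if substance_of[leaf] == s])
        for s in substances
    }
    if target not in full_mask:
        raise ValueError(f"target {target!r} not among dendrogram substances {substances}")
    target_mask = full_mask[target]

    masks = dend.cluster_masks()
    heights = dend.heights
    au_by_mask = {s.mask: s.au for s in result.supports}

    # join height of each candidate: lowest node containing target + candidate doses
    best: dict[str, float] = {}
    supported_at: dict[str, tuple[int, float]] = {}
    for s in substances:
        if s == target:
            continue
        want = target_mask | full_mask[s]
        for mask, h in zip(masks, heights):
            if mask & want == want:
                best[s] = float(h)
                break
    # candidate must sit with the target inside some AU-supported cluster
    for s, h in best.items():
        want = target_mask | full_mask[s]
        for mask, hh in zip(masks, heights):
            if mask & want == want and au_by_mask.get(mask, 0.0) >= au_threshold:
                supported_at[s] = (mask, float(hh))
                break
    if not supported_at:
        return AnalogueResult(target=target, sources=(), join_height=None,
                              cluster_members=(), au=None)
    h_min = min(best[s] for s in supported_at)
    winners = tuple(sorted(s for s in supported_at if best[s] == h_min))
    mask, _ = supported_at[winners[0]]
    return AnalogueResult(
        target=target,
        sources=winners,
        join_height=h_min,
        cluster_members=tuple(str(m) for m in dend.members(mask)),
        au=au_by_mask.get(mask),
    )


def read_across(
    source: PotencyRecord,
    target: PotencyRecord,
    evidence: tuple[str, ...] = (),
) -> ReadAcrossRecord:
    """Transfer the source's measured chronic NOEC/LOEC to the target.

    Predictions equal the source's measured values bit-exactly (pure
    transfer).  The worst-case flag is True only when the source is at
    least as potent as the target (source equi-effective dose <= target's);
    otherwise the prediction is still emitted, with a warning.
    """
    if source.noec is None:
        raise ValueError(f"source {source.substance} has no measured chronic NOEC")
    if source.equi_effective_dose is None or target.equi_effective_dose is None:
        raise ValueError("both records need equi-effective doses for the worst-case check")
    worst_case = source.equi_effective_dose <= target.equi_effective_dose
    if not worst_case:
        warnings.warn(
            f"worst-case criterion not met: source {source.substance} "
            f"(equi-effective {source.equi_effective_dose}) is less potent than "
            f"target {target.substance} ({target.equi_effective_dose})",
            stacklevel=2,
        )
    return ReadAcrossRecord(
        source=source.substance,
        target=target.substance,
        predicted_noec=source.noec,
        predicted_loec=source.loec,
        worst_case_satisfied=worst_case,
        evidence=evidence,
    )


def read_potency_table(path: str | Path) -> list[PotencyRecord]:
    """Potency CSV: substance, equi_effective_dose, responsive, noec, loec."""
    df = pd.read_csv(path)
    recs = []
    for r in df.itertuples():
        recs.append(
            PotencyRecord(
                substance=r.substance,
                equi_effective_dose=None if _isna(r.equi_effective_dose) else float(r.equi_effective_dose),
                responsive=bool(r.responsive) if hasattr(r, "responsive") else True,
                noec=None if _isna(getattr(r, "noec", None)) else float(r.noec),
                loec=None if _isna(getattr(r, "loec", None)) else float(r.loec),
            )
        )
    return recs


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))
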