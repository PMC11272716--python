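"""Simplified untargeted xenobiotic scan of mass-spectrometry feature matrices.

Three transparent filters reproduce the decision structure of a
parent/biotransformation-product (BTP) detection table:

1. ppm mass match of feature m/z against parent and predicted-BTP neutral
   monoisotopic masses plus adduct offsets (positive-ion, protonated
   molecule by default);
2. treated-vs-control fold-change (hits failing it are kept as
   ``tentative`` annotations);
3. Spearman rank correlation of replicate intensities with nominal exposure
   dose, flagging dose-responsive hits.

All thresholds are explicit configuration, not claims about any particular
instrument workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import FeatureMatrix

__all__ = [
    "PROTON_MASS",
    "MassTarget",
    "XenoHit",
    "match_mz",
    "control_fold_filter",
    "dose_correlation",
    "xeno_scan",
    "read_mass_targets",
    "hits_to_frame",
]

#: Mass of a proton in Da (the [M+H]+ adduct offset).
PROTON_MASS = 1.007276

DEFAULT_ADDUCTS = {"[M+H]+": PROTON_MASS}


@dataclass(frozen=True)
class MassTarget:
    """A parent substance or predicted biotransformation product mass."""

    substance: str
    label: str  # "parent" or a BTP identifier
    neutral_mass: float
    adducts: tuple[tuple[str, float], ...] = tuple(DEFAULT_ADDUCTS.items())

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        if not all(np.isfinite(off) for _, off in self.adducts):
            raise ValueError("adduct offsets must be finite")


@dataclass(frozen=True)
class XenoHit:
    """One (feature, mass target, adduct) match with its evidence trail."""

    feature_id: str
    layer: str
    substance: str
    target_label: str
    adduct: str
    mz_observed: float
    mz_theoretical: float
    ppm_error: float
    fold_change: float | None = None
    tier: str | None = None  # "confirmed" | "tentative"
    dose_corr: float | None = None
    dose_responsive: bool | None = None
    flags: tuple[str, ...] = field(default=())


def match_mz(
    feature_mz: dict[str, float] | pd.Series,
    targets: list[MassTarget],
    ppm_tol: float = 5.0,
    layer: str = "apolar",
) -> list[XenoHit]:
    """All (feature, target, adduct) pairs within the ppm tolerance.

    ppm error = |observed - theoretical| / theoretical * 1e6 with
    theoretical m/z = neutral mass + adduct offset.
    """
    if not targets:
        warnings.warn("empty mass-target list: no hits possible", stacklevel=2)
        return []
    mz = pd.Series(feature_mz, dtype=float)
    if (mz <= 0).any():
        raise ValueError("feature m/z values must be positive")
    hits = []
    for target in targets:
        for adduct, offset in target.adducts:
            theo = target.neutral_mass + offset
            ppm = (mz - theo) / theo * 1e6
            for fid, err in ppm[ppm.abs() <= ppm_tol].items():
                hits.append(
                    XenoHit(
                        feature_id=str(fid),
                        layer=layer,
                        substance=target.substance,
                        target_label=target.label,
                        adduct=adduct,
                        mz_observed=float(mz[fid]),
                        mz_theoretical=theo,
                        ppm_error=float(err),
                    )
                )
    return hits


def _treated_control_means(
    fm: FeatureMatrix, substance: str, feature_id: str
) -> tuple[float, float]:
    col = fm.values[feature_id]
    treated = (fm.meta["substance"] == substance) & ~fm.is_control()
    control = (fm.meta["substance"] == substance) & fm.is_control()
    return float(col[treated.to_numpy()].mean()), float(col[control.to_numpy()].mean())


def control_fold_filter(
    hits: list[XenoHit], fm: FeatureMatrix, min_fc: float = 10.0
) -> list[XenoHit]:
    """Tier hits by treated/control mean fold-change.

    ``confirmed`` when mean treated intensity / mean control intensity is at
    least ``min_fc``; otherwise ``tentative`` (annotation retained, the
    fold-change criterion was not met).  A zero control mean confirms the
    hit with an ``infinite_fc`` flag.
    """
    out = []
    for h in hits:
        treated_mean, control_mean = _treated_control_means(fm, h.substance, h.feature_id)
        if control_mean == 0:
            fc = np.inf
            tier = "confirmed" if treated_mean > 0 else "tentative"
            flags = h.flags + ("infinite_fc",) if treated_mean > 0 else h.flags
        else:
            fc = treated_mean / control_mean
            tier = "confirmed" if fc >= min_fc else "tentative"
            flags = h.flags
        out.append(replace(h, fold_change=float(fc), tier=tier, flags=flags))
    return out


def dose_correlation(
    hits: list[XenoHit],
    fm: FeatureMatrix,
    nominal_doses: dict[str, dict[str, float]],
    threshold: float = 0.8,
    include_controls: bool = True,
) -> list[XenoHit]:
    """Spearman correlation of replicate intensities with nominal dose.

    ``nominal_doses[substance][dose_level]`` gives the nominal exposure
    concentration; controls enter as dose 0 when ``include_controls``.
    Hits whose coefficient reaches ``threshold`` get the dose-responsive
    flag.  Constant intensities leave the coefficient undefined: reported
    as 0 with a ``constant_intensity`` flag.
    """
    out = []
    for h in hits:
        sel = fm.meta["substance"] == h.substance
        if not include_controls:
            sel &= ~fm.is_control()
        meta = fm.meta[sel.to_numpy()]
        doses = np.array(
            [
                0.0 if d == "control" else nominal_doses[h.substance][d]
                for d in meta["dose_level"]
            ]
        )
        intens = fm.values.loc[meta.index, h.feature_id].to_numpy(dtype=float)
        flags = h.flags
        if np.all(intens == intens[0]) or np.all(doses == doses[0]):
            rho = 0.0
            flags = flags + ("constant_intensity",)
        else:
            rho = float(stats.spearmanr(doses, intens).statistic)
        out.append(
            replace(h, dose_corr=rho, dose_responsive=bool(rho >= threshold), flags=flags)
        )
    return out


def xeno_scan(
    fm: FeatureMatrix,
    targets: list[MassTarget],
    feature_mz: dict[str, float] | pd.Series | None = None,
    ppm_tol: float = 5.0,
    min_fc: float = 10.0,
    corr_threshold: float = 0.8,
    nominal_doses: dict[str, dict[str, float]] | None = None,
) -> list[XenoHit]:
    """Full scan: ppm match, fold-change tiering, dose correlation.

    ``feature_mz`` defaults to parsing feature ids as m/z values (the
    convention of direct-infusion feature matrices whose ids are the
    measured m/z).
    """
    if feature_mz is None:
        feature_mz = {fid: float(str(fid).split("_")[-1]) for fid in fm.feature_ids}
    hits = match_mz(feature_mz, targets, ppm_tol=ppm_tol, layer=fm.layer)
    hits = control_fold_filter(hits, fm, min_fc=min_fc)
    if nominal_doses is not None:
        hits = dose_correlation(hits, fm, nominal_doses, threshold=corr_threshold)
    return hits


def read_mass_targets(path: str | Path) -> list[MassTarget]:
    """Targets CSV with columns substance, label, neutral_mass."""
    df = pd.read_csv(path)
    return [
        MassTarget(substance=r.substance, label=r.label, neutral_mass=float(r.neutral_mass))
        for r in df.itertuples()
    ]


def hits_to_frame(hits: list[XenoHit]) -> pd.DataFrame:
    """Flat hits table mirroring a detection-summary layout."""
    return pd.DataFrame(
        [
            {
                "feature_id": h.feature_id,
                "layer": h.layer,
                "substance": h.substance,
                "target": h.target_label,
                "adduct": h.adduct,
                "mz_observed": h.mz_observed,
                "mz_theoretical": h.mz_theoretical,
                "ppm_error": h.ppm_error,
                "fold_change": h.fold_change,
                "tier": h.tier,
                "dose_corr": h.dose_corr,
                "dose_responsive": h.dose_responsive,
                "flags": ";".join(h.flags),
            }
            for h in hits
        ]
    )
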