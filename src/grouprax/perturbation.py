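"""Bioactivity profiles: per-feature t-statistics for treated vs control.

For each treatment group of a layer, an independent two-sample t-test
compares that group's replicates against the substance-specific untreated
controls, feature by feature.  The resulting features x treatment-groups
matrix of t-statistics is the group's bioactivity profile: positive t means
elevated in treated.  Profiles are then optionally collapsed over time
points (maximum-perturbation), vector-normalised per feature, and
concatenated across omics layers before hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import TreatmentGroup
from .matrix import FeatureMatrix


def _group_index(groups) -> pd.Index:
    """Object index of TreatmentGroup keys (not a MultiIndex)."""
    return pd.Index(list(groups), dtype=object, tupleize_cols=False)

__all__ = [
    "TStatProfile",
    "compute_tstats",
    "percent_significant",
    "vector_normalize",
    "max_perturbation_collapse",
    "concatenate_layers",
]


@dataclass
class TStatProfile:
    """Features x treatment-groups matrix of t-statistics for one layer.

    ``t`` columns are :class:`~grouprax.design.TreatmentGroup` keys;
    ``p`` holds the parallel two-sided p-values when available (dropped by
    the maximum-perturbation collapse).  When ``normalised`` is set every
    feature row has unit L2 norm or is exactly all-zero.
    """

    layer: str
    t: pd.DataFrame
    p: pd.DataFrame | None = None
    normalised: bool = False
    flags: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.t.isna().any().any():
            raise ValueError("t-statistic matrix contains missing cells")
        if self.p is not None and not self.t.columns.equals(self.p.columns):
            raise ValueError("t and p column sets differ")

    @property
    def groups(self) -> list[TreatmentGroup]:
        return list(self.t.columns)

    @property
    def n_features(self) -> int:
        return self.t.shape[0]


def compute_tstats(
    fm: FeatureMatrix,
    groups: list[TreatmentGroup] | None = None,
    equal_var: bool = True,
    min_replicates: int = 2,
) -> TStatProfile:
    """Two-sample t-statistics for every treatment group vs its controls.

    Parameters
    ----------
    fm
        Preprocessed layer (normalised counts or transformed intensities).
    groups
        Treatment groups to test; defaults to all non-control groups present
        in the layer, in design order.  Groups with fewer than
        ``min_replicates`` treated or control samples are dropped with a
        warning.
    equal_var
        Pooled-variance Student's t-test (the classical independent
        two-sample t-test) when True; Welch's test when False.

    Notes
    -----
    A feature with zero variance in both groups and equal means gets
    t = 0, p = 1 (flagged).  If the variance is zero but the means differ
    the standard error is floored at the smallest positive standard error
    across features so the statistic stays finite (flagged).
    """
    if groups is None:
        groups = fm.treatment_groups()
    t_cols: dict[TreatmentGroup, np.ndarray] = {}
    p_cols: dict[TreatmentGroup, np.ndarray] = {}
    flag_cols: dict[TreatmentGroup, np.ndarray] = {}
    vals = fm.values
    for g in groups:
        treated_ids = fm.samples_for(g)
        control_ids = fm.control_samples_for(g.substance)
        if len(treated_ids) < min_replicates or len(control_ids) < min_replicates:
            warnings.warn(
                f"group {g} dropped: {len(treated_ids)} treated / "
                f"{len(control_ids)} control replicates",
                stacklevel=2,
            )
            continue
        x = vals.loc[treated_ids].to_numpy(dtype=float)
        y = vals.loc[control_ids].to_numpy(dtype=float)
        t, p, degenerate = _two_sample_t(x, y, equal_var=equal_var)
        t_cols[g], p_cols[g], flag_cols[g] = t, p, degenerate
    if not t_cols:
        raise ValueError("no treatment group with enough replicates")
    idx = vals.columns
    cols = _group_index(t_cols)
    return TStatProfile(
        layer=fm.layer,
        t=pd.DataFrame(np.column_stack(list(t_cols.values())), index=idx, columns=cols),
        p=pd.DataFrame(np.column_stack(list(p_cols.values())), index=idx, columns=cols),
        flags=pd.DataFrame(
            np.column_stack(list(flag_cols.values())), index=idx, columns=cols
        ),
    )


def _two_sample_t(
    x: np.ndarray, y: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-sample t over features (columns); treated minus control."""
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full_like(se, n1 + n2 - 2)
    else:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        with np.errstate(invalid="ignore", divide="ignore"):
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, 1.0)
    degenerate = se == 0
    diff = m1 - m2
    if degenerate.any():
        pos = se[se > 0]
        floor = pos.min() if pos.size else 1.0
        se = np.where(degenerate, floor, se)
    with np.errstate(invalid="ignore"):
        t = diff / se
    p = 2 * stats.t.sf(np.abs(t), df)
    # zero variance and equal means: no evidence either way
    both_const = degenerate & (diff == 0)
    t[both_const] = 0.0
    p[both_const] = 1.0
    return t, p, degenerate


def percent_significant(profile: TStatProfile, alpha: float = 0.05) -> pd.DataFrame:
    """Percent of features with p < alpha, per treatment group.

    Returns a tidy frame with columns ``layer, substance, dose_level,
    time_point, percent`` — the stacked-bar-chart summary of perturbation
    magnitude per assay.
    """
    if profile.p is None:
        raise ValueError("profile has no p-values (collapsed?)")
    rows = []
    for g in profile.groups:
        pct = 100.0 * (profile.p[g] < alpha).mean()
        rows.append(
            {
                "layer": profile.layer,
                "substance": g.substance,
                "dose_level": g.dose_level,
                "time_point": g.time_point,
                "percent": pct,
            }
        )
    return pd.DataFrame(rows)


def vector_normalize(profile: TStatProfile) -> TStatProfile:
    """Scale each feature's row across treatment groups to unit L2 norm.

    All-zero rows are left as zeros (rather than dropped) so feature ids
    stay aligned across analysis modes.  Idempotent.
    """
    t = profile.t.to_numpy(dtype=float)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    out = np.divide(t, norms, out=np.zeros_like(t), where=norms > 0)
    return TStatProfile(
        layer=profile.layer,
        t=pd.DataFrame(out, index=profile.t.index, columns=profile.t.columns),
        p=profile.p,
        normalised=True,
        flags=profile.flags,
    )


def max_perturbation_collapse(profile: TStatProfile) -> TStatProfile:
    """Collapse time points, keeping per feature the t of largest magnitude.

    For every feature and (substance, dose) the signed t-statistic whose
    absolute value is maximal over the available time points is retained;
    output columns are (substance, dose) treatment groups.  p-values are
    dropped (the collapsed profile feeds clustering, not significance
    calls).
    """
    by_pair: dict[TreatmentGroup, list[TreatmentGroup]] = {}
    for g in profile.groups:
        pair = TreatmentGroup(g.substance, g.dose_level, None)
        by_pair.setdefault(pair, []).append(g)
    cols = {}
    for pair, members in by_pair.items():
        pos = profile.t.columns.get_indexer(members)
        block = profile.t.iloc[:, pos].to_numpy(dtype=float)
        if block.shape[1] == 0:
            raise ValueError(f"no available time points for {pair}")
        pick = np.argmax(np.abs(block), axis=1)
        cols[pair] = block[np.arange(block.shape[0]), pick]
    # insertion order preserves the design's (substance, dose) ordering
    t = pd.DataFrame(
        np.column_stack(list(cols.values())),
        index=profile.t.index,
        columns=_group_index(cols),
    )
    return TStatProfile(layer=profile.layer, t=t, p=None, normalised=profile.normalised)


def concatenate_layers(profiles: list[TStatProfile]) -> TStatProfile:
    """Stack layer profiles feature-wise into one combined profile.

    All profiles must cover the identical treatment-group set (enforce this
    upstream by removing a group missing in any layer from all layers).
    Feature ids are prefixed by layer to stay unique.
    """
    if not profiles:
        raise ValueError("no profiles to concatenate")
    if len(profiles) == 1:
        return profiles[0]
    ref = set(profiles[0].groups)
    for pr in profiles[1:]:
        diff = ref.symmetric_difference(pr.groups)
        if diff:
            raise ValueError(
                f"treatment-group sets differ between layers: {sorted(map(str, diff))}"
            )
    order = profiles[0].t.columns
    parts = []
    for pr in profiles:
        block = pr.t.iloc[:, pr.t.columns.get_indexer(order)].copy()
        block.index = [f"{pr.layer}:{f}" for f in block.index]
        parts.append(block)
    t = pd.concat(parts, axis=0)
    return TStatProfile(
        layer="combined",
        t=t,
        p=None,
        normalised=all(pr.normalised for pr in profiles),
    )
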