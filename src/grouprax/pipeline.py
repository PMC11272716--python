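"""End-to-end orchestration: matrices in, supported grouping out.

The canonical run, per layer: preprocess (count filtering and
median-of-ratios normalisation for the transcript layer, log transformation
for intensity layers, PCA outlier removal for all), two-sample t-statistics
per treatment group vs substance-specific controls; then globally: remove
any treatment group unavailable in one layer from all layers, optionally
collapse time points by maximum perturbation, vector-normalise feature
rows, concatenate layers, and cluster with Ward.D2 plus multiscale
bootstrap.  Pipeline order (t -> collapse -> normalise -> cluster) is fixed
and regression-tested; normalising after the collapse makes every feature's
profile comparable across exactly the groups being clustered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .bootstrap import DEFAULT_SCALES, BootstrapResult, multiscale_bootstrap
from .design import StudyDesign, TreatmentGroup
from .matrix import FeatureMatrix
from .perturbation import (
    TStatProfile,
    compute_tstats,
    concatenate_layers,
    max_perturbation_collapse,
    percent_significant,
    vector_normalize,
)
from .preprocess import (
    OutlierReport,
    filter_low_counts,
    log_transform,
    normalize_median_ratio,
    pca_outlier_removal,
)

__all__ = ["GroupingRun", "preprocess_layer", "omics_grouping"]

log = logging.getLogger(__name__)

COUNT_LAYERS = ("transcriptomics",)


@dataclass
class GroupingRun:
    """Everything an omics grouping run produced."""

    profiles: dict[str, TStatProfile]          # per layer, uncollapsed, with p-values
    combined: TStatProfile                     # clustered profile (possibly collapsed)
    result: BootstrapResult
    outlier_reports: dict[str, list[OutlierReport]] = field(default_factory=dict)
    percent_significant: dict[str, object] = field(default_factory=dict)


def preprocess_layer(
    fm: FeatureMatrix,
    min_total: int = 10,
    outlier_conf: float = 0.95,
    transform: bool = True,
) -> tuple[FeatureMatrix, list[OutlierReport]]:
    """Layer-appropriate preprocessing; returns the matrix ready for t-tests.

    Count layers: low-count filter, median-of-ratios normalisation, then
    (``transform=True``) log2.  Intensity layers: log2 with half-minimum
    offset.  Finally a single PCA outlier-removal pass per substance.
    """
    if fm.layer in COUNT_LAYERS:
        fm = filter_low_counts(fm, min_total=min_total)
        fm = normalize_median_ratio(fm)
    if transform:
        fm = log_transform(fm)
    return pca_outlier_removal(fm, conf=outlier_conf)


def omics_grouping(
    layers: dict[str, FeatureMatrix],
    design: StudyDesign,
    collapse: bool = True,
    normalise: bool = True,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    outlier_conf: float = 0.95,
    min_total: int = 10,
    transform: bool = True,
    keep_archive: bool = False,
    preprocess: bool = True,
) -> GroupingRun:
    """Run the full multi-omics grouping workflow over one or more layers.

    A treatment group with omics data missing in any single layer is
    removed from all layers before profiles are built, so every layer's
    t-statistic matrix covers the identical group set.
    """
    reports: dict[str, list[OutlierReport]] = {}
    prepped: dict[str, FeatureMatrix] = {}
    for name, fm in layers.items():
        if preprocess:
            fm, rep = preprocess_layer(
                fm, min_total=min_total, outlier_conf=outlier_conf, transform=transform
            )
            reports[name] = rep
        prepped[name] = fm

    # global exclusion: keep groups with >= 2 treated replicates in every layer
    shared: list[TreatmentGroup] = []
    for g in design.retained_groups():
        if all(
            len(fm.samples_for(g)) >= 2 and len(fm.control_samples_for(g.substance)) >= 2
            for fm in prepped.values()
        ):
            shared.append(g)
    if not shared:
        raise ValueError("no treatment group is available in every layer")
    dropped = set(design.retained_groups()) - set(shared)
    if dropped:
        log.info("groups removed from all layers (missing in one): %s",
                 sorted(map(str, dropped)))

    profiles = {
        name: compute_tstats(fm, groups=shared) for name, fm in prepped.items()
    }
    pct = {name: percent_significant(pr, alpha=alpha) for name, pr in profiles.items()}

    staged = []
    for name, pr in profiles.items():
        out = max_perturbation_collapse(pr) if collapse else pr
        if normalise:
            out = vector_normalize(out)
        staged.append(out)
    combined = concatenate_layers(staged)
    result = multiscale_bootstrap(
        combined, scales=scales, n_boot=n_boot, seed=seed, keep_archive=keep_archive
    )
    return GroupingRun(
        profiles=profiles,
        combined=combined,
        result=result,
        outlier_reports=reports,
        percent_significant=pct,
    )
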