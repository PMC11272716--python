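"""Multiscale bootstrap support for hierarchical clusters (AU / BP / SI).

For a features x objects profile, features are resampled with replacement at
a grid of relative sample sizes r (the "scales").  Each pseudo-replicate is
re-clustered (Ward.D2 on the configured metric) and, for every cluster of
the observed dendrogram, the fraction of replicates recovering exactly that
member set is recorded per scale (the scale-wise bootstrap probability
BP_r).  Shimodaira's multiscale-bootstrap theory models

    probit(1 - BP_r) = v * sqrt(r) + c / sqrt(r)

where v is the signed distance of the data from the cluster-hypothesis
boundary and c its curvature.  A weighted least-squares fit of (v, c) with
binomial-variance weights yields

    AU = 1 - Phi(v - c)        approximately unbiased support
    BP = 1 - Phi(v + c)        fitted plain bootstrap probability
    SI = 1 - Phi(v - c)/Phi(-v - c)   selective-inference support
                                      (clipped to [0, 1])

SI conditions on the cluster having been selected by appearing in the
observed tree, so SI <= AU for supported clusters.

Per-feature squared-difference (Euclidean) or concordance (binary)
accumulators make each replicate's distance matrix a single matrix product,
so the default 10,000 replicates per scale stay fast.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClusterMixin

from .hca import Dendrogram, ward_d2_linkage

__all__ = [
    "ClusterSupport",
    "BootstrapResult",
    "BootstrapArchive",
    "multiscale_bootstrap",
    "fit_au",
    "cluster_frequency",
    "MultiscaleBootstrapClustering",
    "DEFAULT_SCALES",
]

#: The established multiscale default: ten scales, 0.5 to 1.4 in steps of 0.1.
DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


@dataclass
class ClusterSupport:
    """Support values for one cluster of the observed dendrogram.

    ``counts[r]`` is the number of pseudo-replicates at scale r whose
    dendrogram contains exactly this member set; ``n_boot[r]`` the number of
    replicates run at that scale.  ``v`` and ``c`` are the fitted signed
    distance and curvature; ``deviance`` the weighted residual sum of
    squares of the probit fit.
    """

    mask: int
    members: list
    counts: dict[float, int]
    n_boot: dict[float, int]
    v: float
    c: float
    au: float
    bp: float
    si: float
    deviance: float
    flags: tuple[str, ...] = ()

    def bp_raw(self, scale: float = 1.0) -> float:
        """Raw recovery fraction at a given scale."""
        return self.counts[scale] / self.n_boot[scale]


@dataclass
class BootstrapArchive:
    """Per-scale counters of every cluster (bitmask) seen across replicates."""

    leaves: list
    counters: dict[float, Counter] = field(default_factory=dict)

    def mask_of(self, members) -> int:
        pos = {leaf: i for i, leaf in enumerate(self.leaves)}
        m = 0
        for x in members:
            m |= 1 << pos[x]
        return m


@dataclass
class BootstrapResult:
    """Observed dendrogram plus per-cluster multiscale-bootstrap supports."""

    dendrogram: Dendrogram
    supports: list[ClusterSupport]
    scales: tuple[float, ...]
    n_boot: int
    archive: BootstrapArchive | None = None

    def support_for(self, members) -> ClusterSupport | None:
        mask = self.dendrogram.mask_of(members)
        for s in self.supports:
            if s.mask == mask:
                return s
        return None

    def support_table(self) -> pd.DataFrame:
        rows = []
        for s in self.supports:
            rows.append(
                {
                    "members": "+".join(str(m) for m in s.members),
                    "size": len(s.members),
                    "v": s.v,
                    "c": s.c,
                    "au": s.au,
                    "bp": s.bp,
                    "si": s.si,
                    "bp_raw_r1": s.bp_raw(1.0) if 1.0 in s.counts else np.nan,
                    "deviance": s.deviance,
                    "flags": ";".join(s.flags),
                }
            )
        return pd.DataFrame(rows)


def _condensed_accumulators(X: np.ndarray, metric: str):
    """Per-feature condensed accumulators so a replicate's distances are w @ D.

    Euclidean: D[f, k] = squared difference of objects i, j on feature f;
    squared distances are the weighted feature sums.  Binary: discordant and
    union indicator accumulators; distance = weighted discordant / weighted
    union (0 where the union is empty).
    """
    n, m = X.shape
    iu, ju = np.triu_indices(m, k=1)
    if metric == "euclidean":
        D = (X[:, iu] - X[:, ju]) ** 2
        return ("euclidean", D)
    if metric == "binary":
        a = X[:, iu] != 0
        b = X[:, ju] != 0
        disc = (a != b).astype(float)
        union = (a | b).astype(float)
        return ("binary", disc, union)
    raise ValueError(f"unsupported resampling metric {metric!r}")


def _replicate_distances(acc, W: np.ndarray) -> np.ndarray:
    if acc[0] == "euclidean":
        d2 = W @ acc[1]
        return np.sqrt(np.maximum(d2, 0.0))
    disc = W @ acc[1]
    union = W @ acc[2]
    return np.where(union > 0, disc / np.maximum(union, 1e-300), 0.0)


def multiscale_bootstrap(
    profile,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot: int = 10000,
    seed: int | None = None,
    metric: str = "euclidean",
    keep_archive: bool = False,
    chunk: int = 256,
) -> BootstrapResult:
    """Cluster a profile and attach multiscale-bootstrap supports.

    Parameters
    ----------
    profile
        :class:`~grouprax.perturbation.TStatProfile`, or a features x objects
        DataFrame (rows are the resampling unit: molecular features, or
        fingerprint bit positions).
    scales
        Relative resample sizes r; at scale r each replicate draws
        ``round(n * r)`` features with replacement.  Scales where that is
        < 2 are skipped with a warning flag.
    n_boot
        Pseudo-replicates per scale.
    seed
        Seed for the replicate stream; one substream per scale, so results
        are reproducible regardless of scale evaluation order.
    metric
        ``"euclidean"`` (profiles) or ``"binary"`` (fingerprints; the
        asymmetric binary distance, 1 - Tanimoto).
    keep_archive
        Retain per-scale counters of all replicate clusters, enabling
        :func:`cluster_frequency` queries for arbitrary member sets.
    """
    t = profile.t if hasattr(profile, "t") else profile
    X = t.to_numpy(dtype=float)
    n, m = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 features to resample, got {n}")
    if any(r <= 0 for r in scales):
        raise ValueError("scales must be positive")

    # observed tree
    if metric == "binary":
        from .structure import binary_distance_matrix

        dist = binary_distance_matrix(pd.DataFrame(X.T, index=t.columns))
    else:
        from .hca import distance_matrix

        dist = distance_matrix(t, metric=metric)
    dend = ward_d2_linkage(dist)
    observed_masks = dend.cluster_masks()
    root_mask = observed_masks[-1]

    acc = _condensed_accumulators(X, metric)
    rng = np.random.default_rng(seed)
    streams = rng.spawn(len(scales))

    counts: dict[float, Counter] = {}
    n_boot_used: dict[float, int] = {}
    archive = BootstrapArchive(leaves=list(t.columns)) if keep_archive else None
    skipped: list[float] = []
    probs = np.full(n, 1.0 / n)
    for r, stream in zip(scales, streams):
        m_r = int(round(n * r))
        if m_r < 2:
            skipped.append(r)
            continue
        counter: Counter = Counter()
        arch_counter: Counter = Counter() if keep_archive else None
        done = 0
        while done < n_boot:
            b = min(chunk, n_boot - done)
            W = stream.multinomial(m_r, probs, size=b).astype(float)
            D = _replicate_distances(acc, W)
            for row in D:
                Z = hierarchy.linkage(row, method="ward")
                mask_set = set(_linkage_masks(Z, m))
                for mk in observed_masks:
                    if mk in mask_set:
                        counter[mk] += 1
                if keep_archive:
                    arch_counter.update(mask_set)
            done += b
        counts[r] = counter
        n_boot_used[r] = n_boot
        if keep_archive:
            archive.counters[r] = arch_counter

    supports = []
    for mk in observed_masks:
        cluster_counts = {r: counts[r].get(mk, 0) for r in counts}
        if mk == root_mask:
            cluster_counts = {r: n_boot_used[r] for r in counts}
        sup = fit_au(cluster_counts, n_boot_used, mask=mk, members=dend.members(mk))
        if mk == root_mask:
            sup.flags = tuple(set(sup.flags) | {"root"})
        if skipped:
            sup.flags = tuple(set(sup.flags) | {f"scales_skipped:{skipped}"})
        supports.append(sup)
    return BootstrapResult(
        dendrogram=dend,
        supports=supports,
        scales=tuple(r for r in scales if r not in skipped),
        n_boot=n_boot,
        archive=archive,
    )


def _linkage_masks(Z: np.ndarray, m: int) -> list[int]:
    masks = [1 << i for i in range(m)]
    out = []
    for left, right in Z[:, :2].astype(int):
        mk = masks[left] | masks[right]
        masks.append(mk)
        out.append(mk)
    return out


def fit_au(
    counts_by_scale: dict[float, int],
    n_boot_by_scale: dict[float, int] | int,
    mask: int = 0,
    members: list | None = None,
) -> ClusterSupport:
    """Fit (v, c) to scale-wise recovery counts and derive AU, BP and SI.

    Scale-wise bootstrap probabilities are clipped to
    ``[1/(B+1), B/(B+1)]`` to keep the probits finite; a cluster whose
    counts sit at the same clip bound on every scale is reported with the
    degenerate limit (AU = 1 or 0) and flagged.
    """
    scales = sorted(counts_by_scale)
    if isinstance(n_boot_by_scale, int):
        n_boot_by_scale = {r: n_boot_by_scale for r in scales}
    members = members if members is not None else []
    flags: set[str] = set()

    r = np.array(scales, dtype=float)
    cnt = np.array([counts_by_scale[s] for s in scales], dtype=float)
    B = np.array([n_boot_by_scale[s] for s in scales], dtype=float)
    bp_raw = cnt / B

    # scales where every replicate (or none) recovered the cluster carry no
    # probit information; fitting them as clipped constants would fake a
    # curvature, so they are excluded from the fit
    usable = (cnt > 0) & (cnt < B)
    if usable.sum() < 2:
        flags.add("degenerate")
        mean_bp = float(bp_raw.mean())
        val = 1.0 if mean_bp >= 0.5 else 0.0
        return ClusterSupport(
            mask, members, dict(counts_by_scale),
            {s: int(n_boot_by_scale[s]) for s in scales},
            v=-np.inf if val else np.inf, c=0.0,
            au=val, bp=val, si=val, deviance=0.0,
            flags=tuple(flags),
        )
    r = r[usable]
    cnt = cnt[usable]
    B = B[usable]
    bp_raw = bp_raw[usable]
    bp = np.clip(bp_raw, 1.0 / (B + 1.0), B / (B + 1.0))
    if (bp != bp_raw).any():
        flags.add("bp_clipped")

    z = norm.ppf(1.0 - bp)
    # delta-method binomial weights: Var(z) = bp(1-bp) / (B * phi(z)^2)
    phi = norm.pdf(z)
    w = B * phi**2 / (bp * (1.0 - bp))
    A = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    Aw = A * w[:, None]
    beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ z, rcond=None)
    v, c = float(beta[0]), float(beta[1])
    resid = z - A @ beta
    deviance = float((w * resid**2).sum())

    au = float(1.0 - norm.cdf(v - c))
    bp_fit = float(1.0 - norm.cdf(v + c))
    denom = norm.cdf(-v - c)
    if denom <= 0:
        si = 0.0 if v > 0 else 1.0
    else:
        si = float(np.clip(1.0 - norm.cdf(v - c) / denom, 0.0, 1.0))
    return ClusterSupport(
        mask, members, dict(counts_by_scale),
        {s: int(n_boot_by_scale[s]) for s in scales},
        v=v, c=c, au=au, bp=bp_fit, si=si, deviance=deviance, flags=tuple(flags),
    )


def cluster_frequency(target, result: BootstrapResult, scale: float = 1.0) -> int:
    """How many replicates at one scale contained exactly this member set.

    ``target`` is a collection of leaf labels or a bitmask.  Requires the
    run to have retained its archive (``keep_archive=True``).
    """
    if result.archive is None:
        raise ValueError(
            "no archive retained: re-run multiscale_bootstrap with keep_archive=True"
        )
    if scale not in result.archive.counters:
        raise ValueError(f"scale {scale} not in archive ({sorted(result.archive.counters)})")
    mask = target if isinstance(target, int) else result.archive.mask_of(target)
    return int(result.archive.counters[scale].get(mask, 0))


class MultiscaleBootstrapClustering(ClusterMixin, BaseEstimator):
    """Ward.D2 hierarchical clustering with multiscale-bootstrap supports.

    scikit-learn estimator interface over :func:`multiscale_bootstrap`:
    ``X`` is objects x features (objects are clustered, features are the
    resampling unit).

    Attributes
    ----------
    dendrogram_ : Dendrogram
    supports_ : list of ClusterSupport
    labels_ : flat labels from cutting the tree into ``n_clusters``.
    """

    def __init__(
        self,
        scales: tuple[float, ...] = DEFAULT_SCALES,
        n_boot: int = 10000,
        metric: str = "euclidean",
        n_clusters: int = 2,
        keep_archive: bool = False,
        random_state: int | None = None,
    ):
        self.scales = scales
        self.n_boot = n_boot
        self.metric = metric
        self.n_clusters = n_clusters
        self.keep_archive = keep_archive
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            df = X.T
        else:
            X = np.asarray(X, dtype=float)
            df = pd.DataFrame(X.T, columns=range(X.shape[0]))
        result = multiscale_bootstrap(
            df,
            scales=tuple(self.scales),
            n_boot=self.n_boot,
            seed=self.random_state,
            metric=self.metric,
            keep_archive=self.keep_archive,
        )
        self.result_ = result
        self.dendrogram_ = result.dendrogram
        self.supports_ = result.supports
        self.labels_ = self.dendrogram_.cut(self.n_clusters) - 1
        return self
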