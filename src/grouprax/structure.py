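"""Structure-based grouping from binary chemotype fingerprints.

Substances are encoded as fixed-length binary fingerprints (by convention
729 bits, the chemotype-style encoding of atom, bond and fragment features).
Pairwise similarity uses the asymmetric binary distance

    d(a, b) = |a XOR b| / |a OR b| = 1 - Tanimoto(a, b)

which ignores jointly-absent bits, so restricting a fingerprint set to its
non-zero bit positions leaves all distances unchanged.  The distance matrix
is clustered with Ward.D2 and multiscale-bootstrap resampling over bit
positions yields AU/SI supports; fragment mapping then reports, for any
grouping of the substances, which non-zero fragments are shared within a
group and which of those are unique to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import DEFAULT_SCALES, BootstrapResult, multiscale_bootstrap

__all__ = [
    "FINGERPRINT_LENGTH",
    "binary_distance",
    "binary_distance_matrix",
    "cluster_fingerprints",
    "FragmentMap",
    "map_fragments",
    "read_fingerprints",
    "write_fingerprints",
]

#: Conventional chemotype fingerprint length.
FINGERPRINT_LENGTH = 729


def _as_frame(fps) -> pd.DataFrame:
    """Coerce substances x bits input to a validated 0/1 DataFrame."""
    df = fps if isinstance(fps, pd.DataFrame) else pd.DataFrame(fps)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("fingerprints must be binary (0/1)")
    if df.columns.duplicated().any():
        raise ValueError("duplicate bit names")
    return df.astype(int)


def binary_distance(a, b) -> float:
    """Asymmetric binary distance between two bit vectors (1 - Tanimoto).

    Discordant bits over the union of set bits; the undefined 0/0 case of
    two all-zero fingerprints is reported as 0 with a warning.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    union = (a | b).sum()
    if union == 0:
        warnings.warn("both fingerprints all-zero; distance defined as 0", stacklevel=2)
        return 0.0
    return float((a != b).sum() / union)


def binary_distance_matrix(fps) -> pd.DataFrame:
    """Pairwise binary-distance matrix over a substances x bits table."""
    df = _as_frame(fps)
    X = df.to_numpy(dtype=bool)
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d[i, j] = d[j, i] = binary_distance(X[i], X[j])
    if (X.sum(axis=1) == 0).any():
        warnings.warn("all-zero fingerprint present; its distances use the 0/0=0 rule",
                      stacklevel=2)
    return pd.DataFrame(d, index=df.index, columns=df.index)


def cluster_fingerprints(
    fps,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot: int = 10000,
    seed: int | None = None,
    si_threshold: float = 0.95,
    restrict_to_nonzero: bool = False,
    keep_archive: bool = False,
) -> BootstrapResult:
    """Ward.D2 grouping of fingerprints with bit-resampling bootstrap supports.

    Resampling draws bit positions with replacement; by default all bits
    (including jointly-zero ones) are resampled, matching resampling of the
    raw encoding.  ``restrict_to_nonzero`` switches to resampling only bits
    set in at least one substance.  Clusters whose SI support reaches
    ``si_threshold`` are flagged ``"strongly_supported"``.
    """
    df = _as_frame(fps)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 substances to cluster")
    if restrict_to_nonzero:
        df = df.loc[:, df.sum(axis=0) > 0]
    if df.to_numpy().std(axis=0).sum() == 0:
        warnings.warn("all fingerprints identical; supports are degenerate", stacklevel=2)
    result = multiscale_bootstrap(
        df.T,  # features (bits) x objects (substances)
        scales=scales,
        n_boot=n_boot,
        seed=seed,
        metric="binary",
        keep_archive=keep_archive,
    )
    for sup in result.supports:
        if sup.si >= si_threshold:
            sup.flags = tuple(set(sup.flags) | {"strongly_supported"})
    return result


@dataclass
class FragmentMap:
    """Shared and unique non-zero fragments per substance group.

    ``shared[g]``: bit names set in all members of group g.
    ``unique[g]``: shared bits additionally absent from every non-member
    (a subset of ``shared[g]``; unique sets of disjoint groups are disjoint).
    """

    grouping: dict[str, list[str]]
    shared: dict[str, list]
    unique: dict[str, list]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, members in self.grouping.items():
            for bit in self.shared[g]:
                rows.append(
                    {
                        "group": g,
                        "members": "+".join(members),
                        "fragment": bit,
                        "unique_to_group": bit in set(self.unique[g]),
                    }
                )
        return pd.DataFrame(rows, columns=["group", "members", "fragment", "unique_to_group"])


def map_fragments(fps, grouping: dict[str, list[str]]) -> FragmentMap:
    """Map shared/unique fragments of a grouping onto the fingerprints.

    ``grouping`` maps group labels to member substance lists and must
    partition (a subset of) the fingerprinted substances; every member must
    have a fingerprint.
    """
    df = _as_frame(fps)
    seen: set[str] = set()
    for g, members in grouping.items():
        missing = [s for s in members if s not in df.index]
        if missing:
            raise ValueError(f"substances without fingerprints in group {g}: {missing}")
        overlap = seen.intersection(members)
        if overlap:
            raise ValueError(f"grouping is not a partition; repeated substances {sorted(overlap)}")
        seen.update(members)
    shared: dict[str, list] = {}
    unique: dict[str, list] = {}
    for g, members in grouping.items():
        inside = df.loc[members]
        outside = df.drop(index=members)
        shared_mask = inside.all(axis=0)
        outside_any = outside.any(axis=0) if len(outside) else pd.Series(False, index=df.columns)
        shared[g] = list(df.columns[shared_mask])
        unique[g] = list(df.columns[shared_mask & ~outside_any])
    return FragmentMap(grouping=grouping, shared=shared, unique=unique)


def read_fingerprints(path: str | Path) -> pd.DataFrame:
    """Read a substances x bit-names fingerprint CSV."""
    return _as_frame(pd.read_csv(path, index_col=0))


def write_fingerprints(fps, path: str | Path) -> None:
    _as_frame(fps).to_csv(path)
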