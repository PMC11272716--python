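"""Feature matrices and sample metadata, with delimited-text readers/writers.

One :class:`FeatureMatrix` holds a single omics layer — transcript counts or
direct-infusion mass-spectrometry feature intensities — as samples x features,
joined to per-sample metadata (substance, dose level, time point, replicate,
batch, control flag).  Controls are modelled as ``dose_level == "control"``
attached to their own substance, matching substance-specific untreated
controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CONTROL_DOSE, TreatmentGroup

__all__ = ["FeatureMatrix", "read_feature_matrix", "write_feature_matrix", "read_sample_meta"]

LAYERS = ("transcriptomics", "polar", "apolar")

#: Columns required in sample metadata tables.
META_COLUMNS = ("substance", "dose_level", "time_point", "replicate", "batch")


@dataclass
class FeatureMatrix:
    """Samples x features matrix for one omics layer, joined to metadata.

    Parameters
    ----------
    layer
        Layer label; conventionally one of ``transcriptomics``, ``polar``,
        ``apolar`` (other labels are allowed, e.g. ``"combined"``).
    values
        DataFrame, rows indexed by sample id, columns by feature id.
        Entries must be finite and non-negative (counts or intensities).
    meta
        DataFrame indexed by sample id with columns
        ``substance, dose_level, time_point, replicate, batch``.
        Control samples carry ``dose_level == "control"``.
    """

    layer: str
    values: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)
    #: raw counts/intensities must be non-negative; transformed data need not be
    raw: bool = True

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids in matrix")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = [
                (str(self.values.index[i]), str(self.values.columns[j]))
                for i, j in zip(*np.where(~np.vectorize(np.isreal)(vals)))
            ]
            raise ValueError(f"non-numeric cells at {bad[:5]}")
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at sample {self.values.index[i]!r}, "
                f"feature {self.values.columns[j]!r}"
            )
        if self.raw and (vals < 0).any():
            raise ValueError("feature values must be non-negative")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        unmatched = self.values.index.difference(self.meta.index)
        if len(unmatched):
            raise ValueError(f"samples absent from metadata: {list(unmatched)}")
        # keep only metadata rows for samples present, in matrix order
        self.meta = self.meta.loc[self.values.index]

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_control(self) -> pd.Series:
        return self.meta["dose_level"] == CONTROL_DOSE

    def samples_for(self, group: TreatmentGroup) -> list[str]:
        """Sample ids belonging to a treatment group (time ignored if None)."""
        m = (self.meta["substance"] == group.substance) & (
            self.meta["dose_level"] == group.dose_level
        )
        if group.time_point is not None:
            m &= self.meta["time_point"] == group.time_point
        return list(self.meta.index[m])

    def control_samples_for(self, substance: str) -> list[str]:
        """Substance-specific untreated control sample ids."""
        m = (self.meta["substance"] == substance) & self.is_control()
        return list(self.meta.index[m])

    def treatment_groups(self) -> list[TreatmentGroup]:
        """Non-control treatment groups present in this layer, design-ordered."""
        treated = self.meta[~self.is_control()]
        seen = {
            TreatmentGroup(r.substance, r.dose_level, r.time_point)
            for r in treated.itertuples()
        }
        return sorted(seen)

    def subset_samples(self, keep: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.layer, self.values.loc[keep], self.meta.loc[keep], raw=self.raw)

    def subset_features(self, keep) -> "FeatureMatrix":
        return FeatureMatrix(self.layer, self.values.loc[:, keep], self.meta, raw=self.raw)


def read_sample_meta(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a sample-metadata table (first column = sample id)."""
    sep = sep or _sniff_sep(path)
    meta = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    return meta


def _sniff_sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_feature_matrix(
    path: str | Path,
    metadata_path: str | Path | pd.DataFrame,
    layer: str,
    orientation: str = "features-by-samples",
    sep: str | None = None,
) -> FeatureMatrix:
    """Read a delimited feature matrix and join it to sample metadata.

    Parameters
    ----------
    orientation
        ``"features-by-samples"`` (rows = features, the common deposition
        layout) or ``"samples-by-features"``.
    """
    if orientation not in ("features-by-samples", "samples-by-features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    non_numeric = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
    if orientation == "features-by-samples":
        df = df.T
    df.index = df.index.astype(str)
    meta = (
        metadata_path
        if isinstance(metadata_path, pd.DataFrame)
        else read_sample_meta(metadata_path)
    )
    return FeatureMatrix(layer, df, meta)


def write_feature_matrix(
    fm: FeatureMatrix,
    path: str | Path,
    orientation: str = "features-by-samples",
    sep: str = ",",
) -> None:
    """Write the matrix as delimited text at full floating-point precision."""
    df = fm.values.T if orientation == "features-by-samples" else fm.values
    df.to_csv(path, sep=sep, float_format="%.17g")
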