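"""The samples x sOTUs feature table and its on-disk formats.

In memory the table is a pandas DataFrame with sample identifiers on the
index and sOTU identifiers (exact sequence tags) on the columns, holding
nonnegative integer read counts.  On disk the conventional amplicon
orientation is the transpose — rows are sOTUs, columns are samples — and
both TSV and BIOM renderings are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import biom
import numpy as np
import pandas as pd

from .errors import FormatError

_DNA = frozenset("ACGTN")


@dataclass
class FeatureTable:
    """Integer read counts, samples x sOTUs, with optional sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes[:5]}")
        if c.columns.duplicated().any():
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sOTU identifiers: {dupes[:5]}")
        arr = c.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise FormatError("counts must be numeric")
            if (arr < 0).any():
                raise FormatError("counts must be nonnegative")
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("counts must be integers")
        self.counts = c.astype(np.int64)

    # ------------------------------------------------------------- accessors
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sotu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sotus(self) -> int:
        return self.counts.shape[1]

    def sample_counts(self, sample_id: str) -> pd.Series:
        return self.counts.loc[sample_id]

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.counts.sort_index(axis=0).sort_index(axis=1).equals(
            other.counts.sort_index(axis=0).sort_index(axis=1)
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        """Write in the conventional orientation: rows = sOTUs, cols = samples."""
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.counts.T.rename_axis("sotu_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        metadata: pd.DataFrame | None = None,
        orientation: str = "auto",
    ) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(_orient(df, metadata, orientation), metadata=metadata)

    def to_biom(self, path: str | Path) -> None:
        table = biom.Table(
            self.counts.T.to_numpy(),
            observation_ids=[str(s) for s in self.sotu_ids],
            sample_ids=[str(s) for s in self.sample_ids],
        )
        with biom.util.biom_open(str(path), "w") as fh:
            table.to_hdf5(fh, generated_by="crosswell")

    @classmethod
    def from_biom(
        cls, path: str | Path, metadata: pd.DataFrame | None = None
    ) -> "FeatureTable":
        table = biom.load_table(str(path))
        df = table.to_dataframe(dense=True).T  # biom is obs x samples
        return cls(df, metadata=metadata)


def _looks_like_tags(ids: pd.Index) -> bool:
    sample = [str(x) for x in ids[: min(len(ids), 25)]]
    return bool(sample) and all(
        len(s) >= 20 and set(s) <= _DNA for s in sample
    )


def _orient(
    df: pd.DataFrame, metadata: pd.DataFrame | None, orientation: str
) -> pd.DataFrame:
    """Return samples x sOTUs.

    ``auto`` prefers the axis overlapping the metadata index; failing that,
    the axis that looks like DNA tags becomes the sOTU axis.
    """
    if orientation == "samples_rows":
        return df
    if orientation == "sotus_rows":
        return df.T
    if orientation != "auto":
        raise FormatError(f"unknown orientation {orientation!r}")
    if metadata is not None:
        rows = len(set(df.index) & set(metadata.index))
        cols = len(set(df.columns) & set(metadata.index))
        if rows > cols:
            return df
        if cols > rows:
            return df.T
    if _looks_like_tags(df.index) and not _looks_like_tags(df.columns):
        return df.T
    if _looks_like_tags(df.columns) and not _looks_like_tags(df.index):
        return df
    # fall back to the conventional on-disk orientation (rows = sOTUs)
    return df.T


def read_feature_table(
    path: str | Path,
    fmt: str = "auto",
    metadata: pd.DataFrame | None = None,
    orientation: str = "auto",
) -> FeatureTable:
    """Read a feature table from TSV or BIOM, auto-detecting by extension."""
    path = Path(path)
    if fmt == "auto":
        fmt = "biom" if path.suffix == ".biom" else "tsv"
    if fmt == "tsv":
        return FeatureTable.from_tsv(path, metadata=metadata, orientation=orientation)
    if fmt == "biom":
        return FeatureTable.from_biom(path, metadata=metadata)
    raise FormatError(f"unknown feature table format {fmt!r}")


def read_metadata(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a sample metadata TSV indexed by its first column.

    ``column_map`` renames caller columns onto the expected vocabulary
    (well_ID, sample_type, extraction_method, extraction_plate, pcr_rep,
    site, expected_label, est_input_cells).
    """
    md = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if md.index.duplicated().any():
        raise FormatError("duplicate sample identifiers in metadata")
    if column_map:
        md = md.rename(columns=column_map)
    return md
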