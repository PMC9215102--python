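"""OTU abundance tables, quality filters and taxonomy-driven block partitions.

The data model is deliberately small: a dense sample x OTU matrix with id
lists (:class:`OtuTable`), per-sample binary disease labels
(:class:`SampleMetadata`), an OTU -> lineage map (:class:`TaxonomyTable`)
and the partition of OTU columns into taxonomic blocks
(:class:`BlockPartition`).  Dense TSV is the canonical on-disk format;
MicrobiomeHD-style deposits ship dense text tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable", "SampleMetadata", "TaxonomyTable", "BlockPartition",
    "FilterReport", "read_otu_table", "filter_table", "to_relative",
    "partition_by_taxonomy", "TAXONOMIC_LEVELS",
]

#: Lineage ranks ordered coarse -> fine.
TAXONOMIC_LEVELS = ("kingdom", "phylum", "class", "order", "family",
                    "genus", "species")


class DataError(ValueError):
    """Raised when an input table violates the data model."""


@dataclass
class OtuTable:
    """Dense sample x OTU abundance matrix.

    Parameters
    ----------
    values
        Non-negative matrix of shape ``(n_samples, n_otus)``; raw counts
        or relative abundances depending on ``scale``.
    sample_ids, otu_ids
        Unique row / column identifiers.
    scale
        ``"counts"`` or ``"relative"``.
    row_totals
        Set by :func:`to_relative`: the per-sample totals of the source
        count table, so counts can be recovered exactly.
    """

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    scale: str = "counts"
    row_totals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(map(str, self.sample_ids))
        self.otu_ids = list(map(str, self.otu_ids))
        if self.values.ndim != 2:
            raise DataError("values must be a 2-d matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.otu_ids) != p:
            raise DataError("id lists do not match matrix dimensions")
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample ids")
        if len(set(self.otu_ids)) != p:
            raise DataError("duplicate OTU ids")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite abundance values")
        if np.any(self.values < 0):
            raise DataError("negative abundance values")
        if self.scale not in ("counts", "relative"):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.scale == "relative":
            sums = self.values.sum(axis=1)
            bad = np.flatnonzero((sums > 0) & (np.abs(sums - 1.0) > 1e-9))
            if bad.size:
                raise DataError(
                    f"relative rows do not sum to 1 (first: {self.sample_ids[bad[0]]})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.otu_ids)


@dataclass
class SampleMetadata:
    """Per-sample binary disease status plus optional covariates."""

    sample_ids: list[str]
    labels: np.ndarray
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise DataError("labels must align with sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in metadata")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise DataError("labels must be 0/1")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            if len(self.covariates) != len(self.sample_ids):
                raise DataError("covariates must align with sample_ids")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_col: str = "sample_id",
                   label_col: str = "label") -> "SampleMetadata":
        extra = [c for c in df.columns if c not in (sample_col, label_col)]
        cov = df[extra].reset_index(drop=True) if extra else None
        return cls(list(df[sample_col]), df[label_col].to_numpy(), cov)

    def aligned_to(self, table: OtuTable) -> "SampleMetadata":
        """Reorder/subset metadata to the sample order of ``table``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in table.sample_ids if s not in pos]
        if missing:
            raise DataError(f"samples without metadata: {missing[:5]}")
        idx = [pos[s] for s in table.sample_ids]
        cov = (self.covariates.iloc[idx].reset_index(drop=True)
               if self.covariates is not None else None)
        return SampleMetadata(list(table.sample_ids), self.labels[idx], cov)


@dataclass
class TaxonomyTable:
    """Map from OTU id to an ordered lineage (kingdom ... species).

    Missing assignments are stored as ``None``.
    """

    lineages: dict[str, dict[str, Optional[str]]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, otu_col: str = "otu_id") -> "TaxonomyTable":
        """Build from a table with one column per rank, or a single
        ``lineage`` column holding RDP-style ``k__...;p__...`` strings."""
        lineages: dict[str, dict[str, Optional[str]]] = {}
        if "lineage" in df.columns:
            for _, row in df.iterrows():
                lineages[str(row[otu_col])] = _parse_rdp(str(row["lineage"]))
        else:
            ranks = [c for c in df.columns if c.lower() in TAXONOMIC_LEVELS]
            if not ranks:
                raise DataError("no recognised rank columns in taxonomy table")
            for _, row in df.iterrows():
                rec: dict[str, Optional[str]] = {}
                for r in ranks:
                    val = row[r]
                    rec[r.lower()] = None if pd.isna(val) or str(val).strip() == "" \
                        else str(val).strip()
                lineages[str(row[otu_col])] = rec
        return cls(lineages)

    def name_at(self, otu_id: str, level: str) -> Optional[str]:
        rec = self.lineages.get(otu_id)
        if rec is None:
            raise DataError(f"OTU {otu_id!r} has no taxonomy record")
        return rec.get(level)


_RDP_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                 "f": "family", "g": "genus", "s": "species"}


def _parse_rdp(lineage: str) -> dict[str, Optional[str]]:
    rec: dict[str, Optional[str]] = {lvl: None for lvl in TAXONOMIC_LEVELS}
    parts = [p.strip() for p in lineage.split(";") if p.strip()]
    for i, part in enumerate(parts):
        if "__" in part:
            prefix, name = part.split("__", 1)
            lvl = _RDP_PREFIXES.get(prefix.strip().lower())
        else:
            lvl = TAXONOMIC_LEVELS[i] if i < len(TAXONOMIC_LEVELS) else None
            name = part
        if lvl is not None:
            rec[lvl] = name.strip() or None
    return rec


@dataclass
class BlockPartition:
    """Disjoint OTU column blocks (one per taxon at a given level)."""

    level: str
    blocks: dict[str, list[int]]
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for bid, idx in self.blocks.items():
            if len(idx) < 1:
                raise DataError(f"empty block {bid!r}")
            if seen & set(idx):
                raise DataError("blocks are not disjoint")
            seen |= set(idx)

    @property
    def sizes(self) -> dict[str, int]:
        return {bid: len(idx) for bid, idx in self.blocks.items()}

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class FilterReport:
    """Counts removed by each stage of :func:`filter_table`."""

    samples_low_reads: int
    otus_low_reads: int
    otus_low_prevalence: int


def read_otu_table(path, orientation: str = "samples_by_otus") -> OtuTable:
    """Read a dense delimited OTU count table.

    The file must have one header row of ids and one leading id column.
    ``orientation="otus_by_samples"`` transposes on read so the returned
    table is always samples x OTUs.
    """
    if orientation not in ("samples_by_otus", "otus_by_samples"):
        raise DataError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if orientation == "otus_by_samples":
        df = df.T
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError):
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise DataError(
                        f"non-numeric cell at sample {df.index[i]!r}, "
                        f"OTU {df.columns[j]!r}") from None
        raise
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise DataError(
            f"negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}")
    return OtuTable(values, list(df.index.astype(str)),
                    list(df.columns.astype(str)), scale="counts")


def filter_table(table: OtuTable, meta: Optional[SampleMetadata] = None,
                 min_sample_reads: int = 100, min_otu_reads: int = 10,
                 min_prevalence: float = 0.01,
                 ) -> tuple[OtuTable, FilterReport]:
    """Apply the standard read-depth and prevalence filters, in order.

    Samples with fewer than ``min_sample_reads`` total reads are removed
    first; then OTUs with fewer than ``min_otu_reads`` total reads; then
    OTUs present in fewer than ``min_prevalence`` of the remaining
    samples.  Prevalence is evaluated on the sample-filtered table, so
    the operation is idempotent.
    """
    if table.scale != "counts":
        raise DataError("filter_table requires a count table")
    row_tot = table.values.sum(axis=1)
    keep_s = row_tot >= min_sample_reads
    if not keep_s.any():
        raise DataError("all samples removed by read-depth filter")
    vals = table.values[keep_s]
    col_tot = vals.sum(axis=0)
    keep_reads = col_tot >= min_otu_reads
    prevalence = (vals > 0).mean(axis=0)
    keep_prev = prevalence >= min_prevalence
    keep_o = keep_reads & keep_prev
    if not keep_o.any():
        raise DataError("all OTUs removed by filters")
    report = FilterReport(
        samples_low_reads=int((~keep_s).sum()),
        otus_low_reads=int((~keep_reads).sum()),
        otus_low_prevalence=int((keep_reads & ~keep_prev).sum()),
    )
    out = OtuTable(
        vals[:, keep_o],
        [s for s, k in zip(table.sample_ids, keep_s) if k],
        [o for o, k in zip(table.otu_ids, keep_o) if k],
        scale="counts",
    )
    return out, report


def to_relative(table: OtuTable) -> OtuTable:
    """Divide each sample's counts by its total reads."""
    if table.scale != "counts":
        raise DataError("table is already on the relative scale")
    totals = table.values.sum(axis=1)
    if np.any(totals <= 0):
        raise DataError("zero-read sample; run filter_table first")
    rel = table.values / totals[:, None]
    return OtuTable(rel, list(table.sample_ids), list(table.otu_ids),
                    scale="relative", row_totals=totals)


def partition_by_taxonomy(table: OtuTable, taxonomy: TaxonomyTable,
                          level: str = "genus") -> BlockPartition:
    """Group OTU columns into blocks by their taxon name at ``level``.

    OTUs with no assignment at ``level`` are excluded from all blocks
    and reported in :attr:`BlockPartition.excluded`.
    """
    if level not in TAXONOMIC_LEVELS:
        raise DataError(f"unknown taxonomic level {level!r}")
    blocks: dict[str, list[int]] = {}
    excluded: list[int] = []
    for j, otu in enumerate(table.otu_ids):
        name = taxonomy.name_at(otu, level)
        if name is None:
            excluded.append(j)
        else:
            blocks.setdefault(name, []).append(j)
    return BlockPartition(level=level, blocks=blocks, excluded=excluded)
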