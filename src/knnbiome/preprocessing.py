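"""Loading and filtering of OTU count tables.

Real cohorts (e.g. HMP body-site tables at the OTU level) enter the
predictor through three filters, applied in this order:

1. drop low-abundance OTUs averaging fewer than one read per sample;
2. drop OTUs with prevalence below 10% of samples (computed on the
   abundance-filtered table);
3. keep a single sample per subject — the first collection — where
   subject metadata exists.

After filtering, rows are normalized to relative abundance to form a
:class:`~knnbiome.cohort.Cohort` identical in kind to simulated ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "RawOtuTable",
    "read_counts_tsv",
    "read_biom_json",
    "filter_low_abundance",
    "filter_low_prevalence",
    "select_first_sample_per_subject",
    "to_cohort",
    "preprocess",
]


@dataclass
class RawOtuTable:
    """Samples x OTUs nonnegative count (or relative-abundance) matrix."""

    counts: pd.DataFrame  # index: sample ids, columns: OTU ids
    subject_ids: pd.Series | None = None  # indexed like counts
    collection_order: pd.Series | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts contain negative entries")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("sample and OTU identifiers must be unique")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]


def read_counts_tsv(path, metadata_path=None, *, name: str = "") -> RawOtuTable:
    """Read a tab-separated count matrix, auto-detecting orientation.

    The table may be samples x OTUs or OTUs x samples; when a metadata
    table (columns ``sample_id``, ``subject_id``, optional ``visit``) is
    given, the orientation whose ids match the metadata sample ids is
    chosen.  Without metadata the matrix is assumed samples x OTUs.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    subject_ids = collection_order = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if "sample_id" not in meta.columns:
            raise ValueError("metadata needs a sample_id column")
        meta = meta.set_index("sample_id")
        row_hits = df.index.isin(meta.index).sum()
        col_hits = df.columns.isin(meta.index).sum()
        if col_hits > row_hits:
            df = df.T
        if "subject_id" in meta.columns:
            subject_ids = meta["subject_id"].reindex(df.index)
        if "visit" in meta.columns:
            collection_order = pd.to_numeric(meta["visit"].reindex(df.index))
    return RawOtuTable(df, subject_ids, collection_order, name=name or str(path))


def read_biom_json(path, *, name: str = "") -> RawOtuTable:
    """Read a BIOM 1.0 (JSON) table, sparse or dense, as samples x OTUs."""
    with open(path) as fh:
        doc = json.load(fh)
    n_otus, n_samples = doc["shape"]
    otu_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    mat = np.zeros((n_otus, n_samples))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    return RawOtuTable(counts, name=name or str(path))


def filter_low_abundance(table: RawOtuTable, min_mean_reads: float = 1.0) -> RawOtuTable:
    """Drop OTUs averaging fewer than ``min_mean_reads`` per sample.

    The boundary is strict: a column mean of exactly 1 read/sample is
    retained.
    """
    keep = table.counts.mean(axis=0) >= min_mean_reads
    return replace(table, counts=table.counts.loc[:, keep])


def filter_low_prevalence(table: RawOtuTable, min_prevalence: float = 0.10) -> RawOtuTable:
    """Drop OTUs present (count > 0) in fewer than ``min_prevalence`` of samples.

    Strict boundary: prevalence exactly at the threshold is retained.
    """
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    return replace(table, counts=table.counts.loc[:, keep])


def select_first_sample_per_subject(table: RawOtuTable) -> RawOtuTable:
    """Keep one row per subject: the earliest collection.

    Ties in collection order resolve to the first row in input order
    (with a warning); missing metadata is an error.
    """
    if table.subject_ids is None or table.collection_order is None:
        raise ValueError("subject_ids and collection_order metadata are required")
    order = pd.DataFrame(
        {
            "subject": table.subject_ids,
            "visit": table.collection_order,
            "pos": np.arange(table.n_samples),
        },
        index=table.counts.index,
    )
    dup_ties = order.duplicated(subset=["subject", "visit"], keep=False) & ~order[
        "subject"
    ].isna()
    first = order.sort_values(["visit", "pos"], kind="stable").groupby("subject").head(1)
    if dup_ties.loc[first.index].any():
        warnings.warn("tied collection orders resolved by input row order", stacklevel=2)
    keep = first.sort_values("pos").index
    return replace(
        table,
        counts=table.counts.loc[keep],
        subject_ids=table.subject_ids.loc[keep],
        collection_order=table.collection_order.loc[keep],
    )


def to_cohort(table: RawOtuTable) -> Cohort:
    """Normalize rows to relative abundance and build a Cohort.

    Zero-sum rows (all reads filtered away) are dropped with a warning.
    """
    counts = table.counts
    sums = counts.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} zero-sum samples after filtering", stacklevel=2
        )
        counts = counts.loc[~zero]
        sums = sums.loc[~zero]
    rel = counts.div(sums, axis=0)
    return Cohort(
        rel.to_numpy(),
        [str(s) for s in rel.index],
        [str(c) for c in rel.columns],
    )


def preprocess(
    table: RawOtuTable,
    *,
    min_mean_reads: float = 1.0,
    min_prevalence: float = 0.10,
    dedupe_subjects: bool | None = None,
) -> Cohort:
    """Full pipeline: abundance filter, prevalence filter, subject dedupe, cohort.

    ``dedupe_subjects`` defaults to whether subject metadata is present.
    """
    table = filter_low_abundance(table, min_mean_reads)
    table = filter_low_prevalence(table, min_prevalence)
    if dedupe_subjects is None:
        dedupe_subjects = (
            table.subject_ids is not None and table.collection_order is not None
        )
    if dedupe_subjects:
        table = select_first_sample_per_subject(table)
    return to_cohort(table)
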