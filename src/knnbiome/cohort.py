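"""Cohort container: a samples x species relative-abundance matrix.

A cohort holds ``m`` samples over a pool of ``N`` species.  Each row of
``abundances`` is one sample's relative-abundance profile (sums to 1 over
its support); ``assemblages`` is the derived binary presence/absence
matrix.  Cohorts are the common currency between the GLV simulator, the
OTU-preprocessing pipeline and the kNN predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Cohort", "read_cohort", "write_cohort"]

_ROW_SUM_TOL = 1e-9


@dataclass
class Cohort:
    """An m x N matrix of relative abundances plus presence/absence view.

    Parameters
    ----------
    abundances
        Nonnegative (m, N) array; every row must sum to 1 within 1e-9.
    sample_ids, species_ids
        Optional identifiers; defaults are generated (``S0..``, ``sp0..``).
    """

    abundances: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    species_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 2:
            raise ValueError("abundances must be a 2-D samples x species matrix")
        m, n = self.abundances.shape
        if np.any(self.abundances < 0):
            raise ValueError("abundances contain negative entries")
        sums = self.abundances.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > _ROW_SUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"rows {bad[:5].tolist()} do not sum to 1 (first sum {sums[bad[0]]!r})"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(m)]
        if not self.species_ids:
            self.species_ids = [f"sp{i}" for i in range(n)]
        if len(self.sample_ids) != m or len(self.species_ids) != n:
            raise ValueError("identifier lengths do not match the matrix shape")

    @property
    def assemblages(self) -> np.ndarray:
        """Binary (m, N) matrix: 1 exactly where abundance is positive."""
        return (self.abundances > 0).astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundances.shape[1]

    @property
    def richness(self) -> np.ndarray:
        """Number of present species per sample."""
        return self.assemblages.sum(axis=1)

    def subset(self, sample_indices) -> "Cohort":
        idx = np.asarray(sample_indices)
        return Cohort(
            self.abundances[idx],
            [self.sample_ids[i] for i in idx],
            list(self.species_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundances, index=self.sample_ids, columns=self.species_ids
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Cohort(m={self.n_samples}, N={self.n_species})"


def write_cohort(cohort: Cohort, path) -> None:
    """Write a tab-separated samples x species table (12 significant digits)."""
    cohort.to_frame().to_csv(path, sep="\t", float_format="%.12g", index_label="sample_id")


def read_cohort(path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Rows are renormalized to absorb the 12-digit rounding of the writer,
    so a write/read round-trip is lossless at that precision.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    sums = values.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("cohort table contains a zero-sum row")
    values = values / sums
    return Cohort(values, [str(s) for s in df.index], [str(c) for c in df.columns])
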