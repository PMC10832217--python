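"""Dissimilarity-overlap curve (DOC) analysis.

The DOC scatters one point per unordered sample pair: x = overlap of the
two assemblages (weighted by abundance), y = rJSD dissimilarity of the
profiles renormalized over the shared species.  A negative slope in the
high-overlap region means similar assemblages imply similar abundance
profiles — exactly the assumption the kNN predictor relies on — so the
fitted slope over the top-20%-overlap points serves as a suitability
diagnostic for kNN prediction on a given cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .glv import CohortSpec, generate_cohort
from .knn import AssemblageKNN
from .metrics import pairwise_overlap_dissimilarity

__all__ = ["DOCResult", "compute_doc", "doc_slope_vs_gain", "fit_top_overlap"]

TOP_OVERLAP_FRACTION = 0.2


@dataclass
class DOCResult:
    """DOC cloud plus the high-overlap linear fit.

    ``slope``/``intercept`` come from ordinary least squares on the
    points with the top 20% overlap values (ties at the threshold kept).
    ``degenerate`` flags a fit on zero-variance overlaps (slope set to 0).
    """

    pair_indices: np.ndarray  # (n_pairs, 2) sample indices
    overlaps: np.ndarray
    dissimilarities: np.ndarray
    slope: float
    intercept: float
    overlap_threshold: float
    n_fit_points: int
    n_excluded_pairs: int
    degenerate: bool = False

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.overlaps, self.dissimilarities])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_a": self.pair_indices[:, 0],
                "sample_b": self.pair_indices[:, 1],
                "overlap": self.overlaps,
                "dissimilarity": self.dissimilarities,
            }
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Dissimilarity-overlap curve",
                "=" * 40,
                f"pairs: {self.overlaps.size} (excluded empty-overlap: {self.n_excluded_pairs})",
                f"top-overlap fit: {self.n_fit_points} points above {self.overlap_threshold:.4f}",
                f"slope = {self.slope:+.4f}   intercept = {self.intercept:.4f}"
                + ("   [degenerate]" if self.degenerate else ""),
            ]
        )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_top_overlap(overlaps: np.ndarray, dissimilarities: np.ndarray) -> dict:
    """OLS line through the top-20%-overlap points (ties at threshold kept).

    Returns slope, intercept, the overlap threshold actually used, the
    number of fitted points, and a degeneracy flag (zero overlap
    variance, slope reported as 0).
    """
    ov = np.asarray(overlaps, dtype=float)
    ds = np.asarray(dissimilarities, dtype=float)
    if ov.size < 2:
        raise ValueError("fewer than 2 DOC points: slope undefined")
    n_top = int(np.ceil(TOP_OVERLAP_FRACTION * ov.size))
    order = np.argsort(-ov, kind="stable")
    threshold = ov[order[n_top - 1]]
    fit_mask = ov >= threshold
    x, y = ov[fit_mask], ds[fit_mask]
    if x.size < 2:
        raise ValueError("fewer than 2 fit points: slope undefined")
    if np.ptp(x) == 0:
        slope, intercept, degenerate = 0.0, float(y.mean()), True
    else:
        slope, intercept = _ols_line(x, y)
        degenerate = False
    return {
        "slope": slope,
        "intercept": intercept,
        "overlap_threshold": float(threshold),
        "n_fit_points": int(fit_mask.sum()),
        "degenerate": degenerate,
    }


def compute_doc(cohort: Cohort, *, log_base: float | None = None) -> DOCResult:
    """Build the DOC cloud for all m(m-1)/2 pairs and fit the top-overlap slope.

    Pairs with an empty shared species set are excluded from both the
    cloud and the percentile computation.  The fit takes the
    ceil(0.2 * n_pairs) highest-overlap points (plus any further points
    tied with the threshold overlap).
    """
    if cohort.n_samples < 3:
        raise ValueError("DOC needs at least 3 samples")
    ii, jj, ov, ds, excluded = pairwise_overlap_dissimilarity(
        cohort.abundances, log_base=log_base
    )
    fit = fit_top_overlap(ov, ds)
    return DOCResult(
        pair_indices=np.column_stack([ii, jj]),
        overlaps=ov,
        dissimilarities=ds,
        slope=fit["slope"],
        intercept=fit["intercept"],
        overlap_threshold=fit["overlap_threshold"],
        n_fit_points=fit["n_fit_points"],
        n_excluded_pairs=excluded,
        degenerate=fit["degenerate"],
    )


def doc_slope_vs_gain(
    cohort_specs,
    n_test_samples: int,
    ks,
    seed=None,
    *,
    log_base: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """DOC slope and kNN gain Delta for a list of cohort settings.

    For each :class:`~knnbiome.glv.CohortSpec`, a cohort of
    ``n_samples + n_test_samples`` steady states is generated; the first
    ``n_samples`` train the kNN and the DOC, the rest are the held-out
    test set.  Returns the per-cohort table (sigma, lambda, slope, Delta,
    k_min) and, when more than one cohort is given, the OLS fit of Delta
    on slope with its R^2.
    """
    rows = []
    for spec in cohort_specs:
        cohort = generate_cohort(
            _replace(spec, n_samples=spec.n_samples + n_test_samples)
        )
        train = cohort.subset(np.arange(spec.n_samples))
        test = cohort.subset(np.arange(spec.n_samples, cohort.n_samples))
        doc = compute_doc(train, log_base=log_base)
        model = AssemblageKNN(train)
        ev = model.evaluate(test, ks, log_base=log_base)
        rows.append(
            {
                "sigma": spec.sigma,
                "universality_lambda": spec.universality_lambda,
                "seed": spec.seed,
                "doc_slope": doc.slope,
                "gain_delta": ev.gain_delta,
                "k_min": ev.k_min,
                "null_error": ev.null_error,
                "min_error": ev.min_error,
            }
        )
    table = pd.DataFrame(rows)
    fit: dict = {}
    if len(table) > 1 and table["doc_slope"].nunique() > 1:
        res = stats.linregress(table["doc_slope"], table["gain_delta"])
        fit = {
            "slope": res.slope,
            "intercept": res.intercept,
            "r_squared": res.rvalue**2,
            "p_value": res.pvalue,
        }
    return table, fit


def write_doc(result: DOCResult, prefix: str) -> None:
    """Write DOC points and the fit summary as tab-separated tables."""
    result.to_frame().to_csv(f"{prefix}_points.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "slope": result.slope,
                "intercept": result.intercept,
                "overlap_threshold": result.overlap_threshold,
                "n_fit_points": result.n_fit_points,
                "n_pairs": result.overlaps.size,
                "n_excluded_pairs": result.n_excluded_pairs,
            }
        ]
    ).to_csv(f"{prefix}_summary.tsv", sep="\t", index=False)
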