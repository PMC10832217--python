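"""Pairwise composition measures.

Four measures between two samples over a shared species pool:

* Jaccard similarity of their assemblages (presence/absence sets);
* overlap — the mean shared relative abundance,
  O(x, y) = sum_{i in S} (x_i + y_i)/2 over the shared set S;
* renormalized dissimilarity — the root Jensen-Shannon divergence (rJSD)
  between the two profiles renormalized over S only, which makes it
  mathematically independent of the overlap;
* prediction error — the same rJSD applied to a prediction/truth pair
  with identical supports.

KL divergences use the natural logarithm by default (rJSD then ranges in
[0, sqrt(ln 2)] ~ [0, 0.8326]); ``log_base=2`` is available.  0*log(0)
terms are taken as 0.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "jaccard_similarity",
    "jaccard_distance_matrix",
    "overlap",
    "renormalized_dissimilarity",
    "prediction_error",
    "rjsd_max",
    "write_distance_matrix",
]


def rjsd_max(log_base: float | None = None) -> float:
    """Upper bound of the rJSD: sqrt(ln 2) in nats, 1 for base-2 logs."""
    if log_base is None:
        return math.sqrt(math.log(2.0))
    return math.sqrt(math.log(2.0) / math.log(log_base))


def _support(v) -> np.ndarray:
    return np.asarray(v) > 0


def jaccard_similarity(a, b) -> float:
    """|A∩B| / |A∪B| on the present-species index sets.

    Accepts binary assemblages or abundance vectors (positive = present).
    Undefined (raises) when both sets are empty.
    """
    sa, sb = _support(a), _support(b)
    if sa.shape != sb.shape:
        raise ValueError("assemblages must have equal length")
    union = np.count_nonzero(sa | sb)
    if union == 0:
        raise ValueError("Jaccard similarity is undefined for two empty assemblages")
    return np.count_nonzero(sa & sb) / union


def jaccard_distance_matrix(assemblages: np.ndarray) -> np.ndarray:
    """Square matrix of Jaccard distances (1 - similarity) between rows."""
    binary = (np.asarray(assemblages) > 0).astype(float)
    inter = binary @ binary.T
    sizes = binary.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), np.nan)
    return 1.0 - sim


def _relative(v) -> np.ndarray:
    x = np.asarray(v, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundance vector has zero sum")
    return x / total


def overlap(x, y) -> float:
    """Mean shared relative abundance, sum_{i in S} (x_i + y_i) / 2.

    Inputs are renormalized to relative abundances first.  Returns 0 when
    no species is shared and 1 when every present species is shared.
    """
    xt, yt = _relative(x), _relative(y)
    shared = (xt > 0) & (yt > 0)
    return float(((xt[shared] + yt[shared]) / 2.0).sum())


def renormalized_dissimilarity(x, y, *, log_base: float | None = None) -> float:
    """rJSD between the profiles renormalized over their shared species.

    With x̂ the restriction of x to S = supp(x) ∩ supp(y) rescaled to sum
    1 (likewise ŷ), returns sqrt([KL(x̂, m) + KL(ŷ, m)] / 2) with
    m = (x̂ + ŷ)/2.  Raises when S is empty (the pair carries no
    comparable abundance information and must be excluded upstream).
    """
    xt, yt = _relative(x), _relative(y)
    shared = (xt > 0) & (yt > 0)
    if not shared.any():
        raise ValueError("dissimilarity undefined: no shared species")
    xs = xt[shared]
    ys = yt[shared]
    xs = xs / xs.sum()
    ys = ys / ys.sum()
    return _rjsd(xs, ys, log_base)


def _rjsd(p: np.ndarray, q: np.ndarray, log_base: float | None) -> float:
    m = (p + q) / 2.0
    # p, q > 0 on the shared set, so m > 0: no 0/0 inside the logs
    kl_pm = float(np.sum(p * np.log(p / m)))
    kl_qm = float(np.sum(q * np.log(q / m)))
    jsd = (kl_pm + kl_qm) / 2.0
    if log_base is not None:
        jsd /= math.log(log_base)
    return math.sqrt(max(jsd, 0.0))


def prediction_error(predicted, actual, *, log_base: float | None = None) -> float:
    """rJSD between a predicted and an actual profile with identical supports.

    The kNN predictor zeroes absent species exactly, so the supports must
    match; a mismatch is a contract violation, not a data condition.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("profiles must have equal length")
    sp, sa = p > 0, a > 0
    if not np.array_equal(sp, sa):
        raise ValueError("prediction/actual supports differ (contract violation)")
    if not sa.any():
        raise ValueError("profiles are empty")
    ps = p[sa] / p[sa].sum()
    qs = a[sa] / a[sa].sum()
    return _rjsd(ps, qs, log_base)


def pairwise_overlap_dissimilarity(
    abundances: np.ndarray, *, log_base: float | None = None
):
    """Overlap and rJSD dissimilarity for every unordered row pair.

    Vectorized over one row against all later rows at a time.  Returns
    ``(i_idx, j_idx, overlaps, dissimilarities, excluded)`` where pairs
    with an empty shared set are reported in ``excluded`` (count) and do
    not appear in the arrays.
    """
    theta = np.asarray(abundances, dtype=float)
    sums = theta.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("every sample needs a positive total abundance")
    rel = theta / sums
    m = rel.shape[0]
    ii, jj, ovs, ds = [], [], [], []
    excluded = 0
    for i in range(m - 1):
        x = rel[i]
        block = rel[i + 1 :]
        shared = (x > 0) & (block > 0)
        xs = np.where(shared, x, 0.0)
        ys = np.where(shared, block, 0.0)
        ov = (xs + ys).sum(axis=1) / 2.0
        xsum = xs.sum(axis=1)
        ysum = ys.sum(axis=1)
        valid = (xsum > 0) & (ysum > 0)
        excluded += int((~valid).sum())
        if not valid.any():
            continue
        xs = xs[valid] / xsum[valid, None]
        ys = ys[valid] / ysum[valid, None]
        mm = (xs + ys) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            kl_x = np.where(xs > 0, xs * np.log(np.where(xs > 0, xs / mm, 1.0)), 0.0)
            kl_y = np.where(ys > 0, ys * np.log(np.where(ys > 0, ys / mm, 1.0)), 0.0)
        jsd = (kl_x.sum(axis=1) + kl_y.sum(axis=1)) / 2.0
        if log_base is not None:
            jsd = jsd / math.log(log_base)
        d = np.sqrt(np.clip(jsd, 0.0, None))
        j_glob = np.arange(i + 1, m)[valid]
        ii.extend([i] * j_glob.size)
        jj.extend(j_glob.tolist())
        ovs.extend(ov[valid].tolist())
        ds.extend(d.tolist())
    return (
        np.array(ii, dtype=int),
        np.array(jj, dtype=int),
        np.array(ovs),
        np.array(ds),
        excluded,
    )


def write_distance_matrix(distances: np.ndarray, ids, path) -> None:
    """Write a square tab-separated distance matrix with identifiers."""
    pd.DataFrame(distances, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.12g", index_label="id"
    )
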