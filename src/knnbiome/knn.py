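"""Model-free kNN prediction of abundance profiles from assemblages.

Given a training cohort (abundance matrix Theta with binary assemblage
view theta) and a test assemblage phi, the predictor:

1. ranks training samples by Jaccard similarity of assemblages,
2. averages the abundance of each present species over the k nearest
   neighbors, counting only neighbors where the species is present
   (divide by p_i, the number of neighbors carrying species i — not k),
3. falls back to the species' cohort-wide present-only mean when none of
   the k neighbors carries it, and to a 1/N pseudo-abundance when the
   species never occurs in training,
4. zeroes absent species exactly and renormalizes to a probability
   vector.

The naive null model predicts every present species by its cohort-wide
mean abundance independently of the rest of the assemblage; it coincides
with the kNN at k = m under the present-only averaging convention.  The
kNN gain Delta = null error - error at the best k measures how much
predictive information the neighborhood structure carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .metrics import prediction_error

__all__ = [
    "AssemblageKNN",
    "KnnPrediction",
    "KNNEvaluation",
    "knn_predict",
    "null_predict",
    "evaluate_split",
    "local_density",
]

NULL_VARIANTS = ("present-only", "over-m")


@dataclass
class KnnPrediction:
    """One kNN prediction: the profile plus its provenance."""

    predicted: np.ndarray
    neighbor_ids: np.ndarray
    neighbor_similarities: np.ndarray
    fallback_species: np.ndarray  # indices resolved by the cohort-wide mean / 1/N


@dataclass
class KNNEvaluation:
    """Results of a repeated random-split evaluation of the kNN.

    Attributes
    ----------
    ks, errors, errors_se
        The k grid, the mean rJSD prediction error per k, its standard
        error over (repetition, test sample) pairs.
    null_error
        Mean error of the null model under the chosen variant.
    k_min
        Smallest k attaining the minimal mean error.
    gain_delta
        null_error - errors[k_min]; positive when neighborhood structure
        beats the cohort-wide average.
    """

    ks: np.ndarray
    errors: np.ndarray
    errors_se: np.ndarray
    null_error: float
    null_variant: str
    n_repetitions: int
    n_test_per_rep: int
    seed: object = None
    per_sample_errors: np.ndarray | None = field(default=None, repr=False)

    @property
    def k_min(self) -> int:
        return int(self.ks[int(np.argmin(self.errors))])

    @property
    def min_error(self) -> float:
        return float(self.errors.min())

    @property
    def gain_delta(self) -> float:
        return self.null_error - self.min_error

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks, "mean_error": self.errors, "se": self.errors_se}
        )

    def summary(self) -> str:
        lines = [
            "kNN evaluation (rJSD prediction error)",
            "=" * 46,
            f"repetitions: {self.n_repetitions}   test samples/rep: {self.n_test_per_rep}",
            f"null model ({self.null_variant}): {self.null_error:.4f}",
            f"k_min = {self.k_min}   error(k_min) = {self.min_error:.4f}",
            f"gain Delta = {self.gain_delta:+.4f}",
            "-" * 46,
            f"{'k':>6} {'mean_error':>12} {'se':>10}",
        ]
        for k, e, s in zip(self.ks, self.errors, self.errors_se):
            lines.append(f"{int(k):>6} {e:>12.4f} {s:>10.4f}")
        return "\n".join(lines)


class AssemblageKNN:
    """kNN abundance predictor bound to a training cohort.

    Parameters
    ----------
    training : Cohort
        The m x N training matrix.
    null_variant : {"present-only", "over-m"}
        How the null model averages: over samples where the species is
        present (equivalent to kNN at k = m; default) or over all m
        samples including zeros.
    """

    def __init__(self, training: Cohort, null_variant: str = "present-only"):
        if null_variant not in NULL_VARIANTS:
            raise ValueError(f"null_variant must be one of {NULL_VARIANTS}")
        self.training = training
        self.null_variant = null_variant
        theta = training.abundances
        binary = theta > 0
        self._binary = binary.astype(float)
        self._sizes = binary.sum(axis=1)
        counts = binary.sum(axis=0)
        sums = theta.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            self._present_mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        self._over_m_mean = sums / training.n_samples
        self._never_present = counts == 0

    # ---- neighbor machinery -------------------------------------------------

    def similarities(self, assemblage: np.ndarray) -> np.ndarray:
        """Jaccard similarity of one assemblage to every training sample."""
        phi = (np.asarray(assemblage) > 0).astype(float)
        if phi.shape != (self.training.n_species,):
            raise ValueError("assemblage length must equal the species pool size")
        if phi.sum() == 0:
            raise ValueError("test assemblage is empty")
        inter = self._binary @ phi
        union = self._sizes + phi.sum() - inter
        return inter / union

    def neighbors(self, assemblage: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices and similarities of the k nearest training samples.

        Ties in similarity break by ascending training index, so the
        neighbor set is deterministic and seed-independent.
        """
        m = self.training.n_samples
        if not (1 <= k <= m):
            raise ValueError(f"k must lie in [1, {m}]")
        sim = self.similarities(assemblage)
        order = np.argsort(-sim, kind="stable")[:k]
        return order, sim[order]

    # ---- prediction ---------------------------------------------------------

    def predict(self, assemblage: np.ndarray, k: int) -> KnnPrediction:
        """Predict the abundance profile of ``assemblage`` from k neighbors."""
        phi = np.asarray(assemblage) > 0
        idx, sims = self.neighbors(assemblage, k)
        theta_r = self.training.abundances[idx]
        p = (theta_r > 0).sum(axis=0)
        sums = theta_r.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_present = np.where(p > 0, sums / np.maximum(p, 1), 0.0)
        profile = np.where(phi, mean_present, 0.0)

        fallback = phi & (p == 0)
        if fallback.any():
            profile[fallback] = self._present_mean[fallback]
            never = fallback & self._never_present
            if never.any():
                warnings.warn(
                    f"{int(never.sum())} species present in the test assemblage never "
                    "occur in training; using 1/N pseudo-abundance",
                    stacklevel=2,
                )
                profile[never] = 1.0 / self.training.n_species
        total = profile.sum()
        if total <= 0:  # pragma: no cover - requires empty-support contract breach
            raise RuntimeError("prediction degenerated to the zero vector")
        profile = profile / total
        return KnnPrediction(profile, idx, sims, np.where(fallback)[0])

    def predict_null(self, assemblage: np.ndarray, variant: str | None = None) -> np.ndarray:
        """Null-model profile: per-species cohort mean on the present set."""
        variant = variant or self.null_variant
        if variant not in NULL_VARIANTS:
            raise ValueError(f"variant must be one of {NULL_VARIANTS}")
        phi = np.asarray(assemblage) > 0
        if phi.shape != (self.training.n_species,) or not phi.any():
            raise ValueError("test assemblage must be non-empty with pool length")
        base = self._present_mean if variant == "present-only" else self._over_m_mean
        profile = np.where(phi, base, 0.0)
        never = phi & (self._never_present)
        if never.any():
            profile[never] = 1.0 / self.training.n_species
        total = profile.sum()
        if total <= 0:
            raise RuntimeError("null prediction degenerated to the zero vector")
        return profile / total

    # ---- evaluation ---------------------------------------------------------

    def score_samples(
        self, test: Cohort, ks, *, log_base: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-(test sample, k) kNN errors and per-sample null errors."""
        ks = np.asarray(list(ks), dtype=int)
        errs = np.empty((test.n_samples, ks.size))
        null_errs = np.empty(test.n_samples)
        for t in range(test.n_samples):
            actual = test.abundances[t]
            phi = actual > 0
            for a, k in enumerate(ks):
                pred = self.predict(phi, int(k)).predicted
                errs[t, a] = prediction_error(pred, actual, log_base=log_base)
            null_errs[t] = prediction_error(
                self.predict_null(phi), actual, log_base=log_base
            )
        return errs, null_errs

    def evaluate(
        self,
        test: Cohort,
        ks,
        *,
        log_base: float | None = None,
        seed=None,
    ) -> KNNEvaluation:
        """Evaluate against an external test cohort (single split)."""
        errs, null_errs = self.score_samples(test, ks, log_base=log_base)
        ks = np.asarray(list(ks), dtype=int)
        return KNNEvaluation(
            ks=ks,
            errors=errs.mean(axis=0),
            errors_se=errs.std(axis=0, ddof=1) / np.sqrt(errs.shape[0])
            if errs.shape[0] > 1
            else np.zeros(ks.size),
            null_error=float(null_errs.mean()),
            null_variant=self.null_variant,
            n_repetitions=1,
            n_test_per_rep=test.n_samples,
            seed=seed,
            per_sample_errors=errs,
        )


def knn_predict(test_assemblage, training: Cohort, k: int) -> KnnPrediction:
    """Functional form of :meth:`AssemblageKNN.predict`."""
    return AssemblageKNN(training).predict(test_assemblage, k)


def null_predict(test_assemblage, training: Cohort, variant: str = "present-only") -> np.ndarray:
    """Functional form of :meth:`AssemblageKNN.predict_null`."""
    return AssemblageKNN(training).predict_null(test_assemblage, variant)


def evaluate_split(
    cohort: Cohort,
    test_fraction: float,
    ks,
    n_repetitions: int,
    seed,
    *,
    null_variant: str = "present-only",
    log_base: float | None = None,
) -> KNNEvaluation:
    """Repeated random train/test split evaluation (e.g. 99%/1%).

    Each repetition holds out ``round(test_fraction * m)`` samples
    (at least 1), predicts them from the rest at every k, and scores with
    the rJSD prediction error.  Reported errors average over all
    (repetition, test sample) pairs; ``k_min`` is the smallest k at the
    minimum and ``gain_delta = null_error - errors[k_min]``.
    """
    m = cohort.n_samples
    n_test = max(1, int(round(test_fraction * m)))
    if n_test >= m:
        raise ValueError("cohort too small for the requested test fraction")
    ks = np.asarray(list(ks), dtype=int)
    if ks.max() > m - n_test:
        raise ValueError("largest k exceeds the training-set size")
    rng = np.random.default_rng(seed)
    all_errs = []
    all_null = []
    for _ in range(n_repetitions):
        perm = rng.permutation(m)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        model = AssemblageKNN(cohort.subset(train_idx), null_variant=null_variant)
        errs, null_errs = model.score_samples(
            cohort.subset(test_idx), ks, log_base=log_base
        )
        all_errs.append(errs)
        all_null.append(null_errs)
    errs = np.vstack(all_errs)
    null_errs = np.concatenate(all_null)
    return KNNEvaluation(
        ks=ks,
        errors=errs.mean(axis=0),
        errors_se=errs.std(axis=0, ddof=1) / np.sqrt(errs.shape[0])
        if errs.shape[0] > 1
        else np.zeros(ks.size),
        null_error=float(null_errs.mean()),
        null_variant=null_variant,
        n_repetitions=n_repetitions,
        n_test_per_rep=n_test,
        seed=seed,
        per_sample_errors=errs,
    )


def local_density(cohort: Cohort, sample_index: int, k_neighbors: int) -> float:
    """Mean Jaccard distance <D_k> from one sample to its k nearest others.

    Small values mark dense neighborhoods of the assemblage space, where
    the kNN has close neighbors to draw on.
    """
    m = cohort.n_samples
    if not (1 <= k_neighbors < m):
        raise ValueError("k_neighbors must lie in [1, m-1]")
    binary = cohort.assemblages.astype(float)
    phi = binary[sample_index]
    inter = binary @ phi
    union = binary.sum(axis=1) + phi.sum() - inter
    dist = 1.0 - inter / union
    dist = np.delete(dist, sample_index)
    dist.sort()
    return float(dist[:k_neighbors].mean())
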