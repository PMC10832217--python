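"""Seeded experiment protocols producing tidy result tables.

Five protocols mirror the validation experiments of the kNN framework:

* ``training_size_sweep`` — prediction error vs number of GLV training
  samples, per k, against the null model (optionally the neural
  baseline);
* ``k_sweep_real`` — error vs k on a preprocessed cohort under repeated
  99%/1% splits, yielding k_min and the gain Delta;
* ``density_stratified_gain`` — per-sample gain at a fixed k stratified
  by local assemblage density <D_k>;
* ``perturbation_protocol`` — before/after paired samples; each
  subject's post-perturbation profile is predicted with the subject's
  own baseline excluded from training (leakage guard);
* ``pcoa_coordinates`` — classical metric scaling of a distance matrix.

Every protocol is a pure function of its inputs and seed; reports embed
all parameters so they can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from . import __version__
from .cohort import Cohort
from .glv import CohortSpec, generate_cohort
from .knn import AssemblageKNN, evaluate_split, local_density
from .neural import NeuralBaselineSpec, baseline_predict_and_score, train_baseline

__all__ = [
    "ExperimentReport",
    "PairedCohort",
    "training_size_sweep",
    "k_sweep_real",
    "density_stratified_gain",
    "perturbation_protocol",
    "pcoa_coordinates",
]


@dataclass
class ExperimentReport:
    """A named result table plus every parameter needed to regenerate it."""

    name: str
    parameters: dict
    table: pd.DataFrame
    extras: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass
class PairedCohort:
    """Before/after samples keyed by subject (one pair per subject)."""

    cohort: Cohort
    subject_ids: list[str]
    phases: list[str]  # "before" (baseline) or "after" per sample

    def __post_init__(self) -> None:
        if not (
            len(self.subject_ids) == len(self.phases) == self.cohort.n_samples
        ):
            raise ValueError("subject_ids/phases must match the cohort rows")
        bad = set(self.phases) - {"before", "after"}
        if bad:
            raise ValueError(f"unknown phases: {bad}")


def _spawn_seeds(seed, n: int) -> list:
    return np.random.SeedSequence(seed).spawn(n)


def training_size_sweep(
    n_species: int,
    sizes,
    ks,
    *,
    n_test: int = 20,
    n_realizations: int = 100,
    sigma: float = 0.6,
    weighting: str = "influence",
    seed=0,
    include_baseline: bool = False,
    baseline_realizations: int | None = None,
    log_base: float | None = None,
) -> ExperimentReport:
    """Prediction error vs training-set size for GLV cohorts.

    Per realization one cohort of ``max(sizes) + n_test`` steady states is
    generated; the last ``n_test`` rows are the test samples and training
    sets are nested prefixes, so size comparisons are paired.  Reports
    mean +/- sd over realizations for the kNN at each k, both null-model
    variants, and (optionally) the neural baseline trained on the same
    training samples and scored on the same test samples.
    """
    sizes = sorted(int(s) for s in sizes)
    ks = [int(k) for k in ks]
    seeds = _spawn_seeds(seed, n_realizations)
    records: dict[tuple, list] = {}
    baseline_errs: dict[int, list] = {s: [] for s in sizes}
    n_baseline = (
        n_realizations if baseline_realizations is None else baseline_realizations
    )
    for r, s_seed in enumerate(seeds):
        child = s_seed.spawn(2)
        full = generate_cohort(
            CohortSpec(
                n_species=n_species,
                n_samples=sizes[-1] + n_test,
                sigma=sigma,
                weighting=weighting,
                seed=int(np.random.default_rng(child[0]).integers(2**31 - 1)),
            )
        )
        test = full.subset(np.arange(sizes[-1], full.n_samples))
        for size in sizes:
            train = full.subset(np.arange(size))
            for variant in ("present-only", "over-m"):
                model = AssemblageKNN(train, null_variant=variant)
                if variant == "present-only":
                    ev = model.evaluate(test, ks, log_base=log_base)
                    for k, err in zip(ev.ks, ev.errors):
                        records.setdefault((size, f"knn_k{k}"), []).append(err)
                    records.setdefault((size, "null_present_only"), []).append(
                        ev.null_error
                    )
                else:
                    errs = [
                        _null_error(model, test, t, log_base)
                        for t in range(test.n_samples)
                    ]
                    records.setdefault((size, "null_over_m"), []).append(
                        float(np.mean(errs))
                    )
            if include_baseline and r < n_baseline:
                nn_spec = NeuralBaselineSpec(
                    n_species=n_species,
                    seed=int(np.random.default_rng(child[1]).integers(2**31 - 1)),
                )
                nn = train_baseline(train, nn_spec)
                baseline_errs[size].append(
                    baseline_predict_and_score(nn, test, log_base=log_base)
                )
    rows = []
    for (size, method), vals in sorted(records.items()):
        vals = np.asarray(vals)
        rows.append(
            {
                "size": size,
                "method": method,
                "mean_error": vals.mean(),
                "sd_error": vals.std(ddof=1) if vals.size > 1 else 0.0,
                "n_realizations": vals.size,
            }
        )
    if include_baseline:
        for size, vals in baseline_errs.items():
            if vals:
                arr = np.asarray(vals)
                rows.append(
                    {
                        "size": size,
                        "method": "neural_baseline",
                        "mean_error": arr.mean(),
                        "sd_error": arr.std(ddof=1) if arr.size > 1 else 0.0,
                        "n_realizations": arr.size,
                    }
                )
    return ExperimentReport(
        name="training_size_sweep",
        parameters={
            "n_species": n_species,
            "sizes": sizes,
            "ks": ks,
            "n_test": n_test,
            "n_realizations": n_realizations,
            "sigma": sigma,
            "weighting": weighting,
            "seed": seed,
            "include_baseline": include_baseline,
        },
        table=pd.DataFrame(rows),
    )


def _null_error(model: AssemblageKNN, test: Cohort, t: int, log_base):
    from .metrics import prediction_error

    actual = test.abundances[t]
    return prediction_error(
        model.predict_null(actual > 0, model.null_variant), actual, log_base=log_base
    )


def k_sweep_real(
    cohort: Cohort,
    ks,
    reps: int = 100,
    test_fraction: float = 0.01,
    seed=0,
    *,
    null_variant: str = "present-only",
    log_base: float | None = None,
) -> ExperimentReport:
    """Error-vs-k curve with repeated random splits; reports k_min and Delta."""
    ev = evaluate_split(
        cohort,
        test_fraction,
        ks,
        reps,
        seed,
        null_variant=null_variant,
        log_base=log_base,
    )
    table = ev.to_frame()
    table["null_error"] = ev.null_error
    return ExperimentReport(
        name="k_sweep",
        parameters={
            "ks": [int(k) for k in ks],
            "reps": reps,
            "test_fraction": test_fraction,
            "seed": seed,
            "null_variant": null_variant,
        },
        table=table,
        extras={"k_min": ev.k_min, "gain_delta": ev.gain_delta, "evaluation": ev},
    )


def density_stratified_gain(
    cohort: Cohort,
    k_fixed: int = 10,
    d_neighbors: int = 10,
    seed=0,
    *,
    n_strata: int = 4,
    log_base: float | None = None,
) -> ExperimentReport:
    """Per-sample kNN gain at a fixed k vs local assemblage density.

    Each sample is predicted leave-one-out at ``k_fixed``; its gain is
    the null error minus the kNN error.  Samples are stratified into
    ``n_strata`` equal-range bins of <D_{d_neighbors}> and the lowest and
    highest bins are compared with a Mann-Whitney U-test.
    """
    from .metrics import prediction_error

    m = cohort.n_samples
    rows = []
    for i in range(m):
        others = np.concatenate([np.arange(i), np.arange(i + 1, m)])
        model = AssemblageKNN(cohort.subset(others))
        actual = cohort.abundances[i]
        phi = actual > 0
        err_knn = prediction_error(
            model.predict(phi, min(k_fixed, m - 1)).predicted, actual, log_base=log_base
        )
        err_null = prediction_error(model.predict_null(phi), actual, log_base=log_base)
        rows.append(
            {
                "sample": cohort.sample_ids[i],
                "local_density": local_density(cohort, i, d_neighbors),
                "error_knn": err_knn,
                "error_null": err_null,
                "gain": err_null - err_knn,
            }
        )
    table = pd.DataFrame(rows)
    dmin, dmax = table["local_density"].min(), table["local_density"].max()
    if dmax > dmin:
        edges = np.linspace(dmin, dmax, n_strata + 1)
        table["stratum"] = np.clip(
            np.searchsorted(edges, table["local_density"], side="right") - 1,
            0,
            n_strata - 1,
        )
    else:
        table["stratum"] = 0
    extras: dict = {}
    low = table.loc[table["stratum"] == table["stratum"].min(), "gain"]
    high = table.loc[table["stratum"] == table["stratum"].max(), "gain"]
    if len(low) and len(high) and table["stratum"].nunique() > 1:
        u = stats.mannwhitneyu(low, high, alternative="two-sided")
        extras["mannwhitney_u"] = float(u.statistic)
        extras["p_value"] = float(u.pvalue)
    return ExperimentReport(
        name="density_stratified_gain",
        parameters={
            "k_fixed": k_fixed,
            "d_neighbors": d_neighbors,
            "n_strata": n_strata,
            "seed": seed,
        },
        table=table,
        extras=extras,
    )


def perturbation_protocol(
    paired: PairedCohort,
    ks,
    d_neighbors: int = 3,
    seed=0,
    *,
    log_base: float | None = None,
) -> ExperimentReport:
    """Predict each subject's post-perturbation sample, baseline excluded.

    For every subject with exactly one "before" and one "after" sample,
    the training set is all other samples minus that subject's baseline
    (and of course the test sample itself), guarding against leakage of
    the recovery effect.  Reports per-subject gain Delta (null error
    minus best-over-k kNN error), local density <D_{d_neighbors}> in the
    training set, and the Delta-on-<D> linear regression.
    """
    from .metrics import jaccard_similarity, prediction_error

    cohort, subjects, phases = paired.cohort, paired.subject_ids, paired.phases
    by_subject: dict[str, dict[str, list[int]]] = {}
    for i, (s, p) in enumerate(zip(subjects, phases)):
        by_subject.setdefault(s, {"before": [], "after": []})[p].append(i)
    rows = []
    skipped = []
    for subject, idx in by_subject.items():
        if len(idx["before"]) != 1 or len(idx["after"]) != 1:
            skipped.append(subject)
            continue
        test_i = idx["after"][0]
        baseline_i = idx["before"][0]
        train_idx = [
            j for j in range(cohort.n_samples) if j not in (test_i, baseline_i)
        ]
        assert baseline_i not in train_idx and test_i not in train_idx
        train = cohort.subset(train_idx)
        model = AssemblageKNN(train)
        actual = cohort.abundances[test_i]
        phi = actual > 0
        errs = [
            prediction_error(model.predict(phi, int(k)).predicted, actual, log_base=log_base)
            for k in ks
            if k <= train.n_samples
        ]
        err_null = prediction_error(model.predict_null(phi), actual, log_base=log_base)
        sims = sorted(
            (1.0 - jaccard_similarity(phi, train.assemblages[j]) for j in range(train.n_samples))
        )
        rows.append(
            {
                "subject": subject,
                "gain": err_null - min(errs),
                "local_density": float(np.mean(sims[:d_neighbors])),
                "error_null": err_null,
                "error_knn_best": min(errs),
            }
        )
    if skipped:
        import warnings

        warnings.warn(f"skipped unpaired subjects: {skipped}", stacklevel=2)
    table = pd.DataFrame(rows)
    extras: dict = {"skipped_subjects": skipped}
    if len(table) > 1 and table["local_density"].nunique() > 1:
        res = stats.linregress(table["local_density"], table["gain"])
        extras.update(
            regression_slope=res.slope,
            regression_intercept=res.intercept,
            pearson_r=res.rvalue,
            p_value=res.pvalue,
        )
    return ExperimentReport(
        name="perturbation_protocol",
        parameters={"ks": [int(k) for k in ks], "d_neighbors": d_neighbors, "seed": seed},
        table=table,
        extras=extras,
    )


def pcoa_coordinates(distance_matrix: np.ndarray, ids=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling (PCoA) of a square symmetric distance matrix.

    Returns the full coordinate table (columns ``PC1..``) and the
    eigenvalues of the double-centered squared-distance matrix.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if ids is None:
        ids = [str(i) for i in range(d.shape[0])]
    dm = DistanceMatrix(d, ids=[str(i) for i in ids])
    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    coords = res.samples.copy()
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return coords, res.eigvals.to_numpy()
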