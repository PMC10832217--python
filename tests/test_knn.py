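"""kNN predictor tests: Eq-style averaging, null model, evaluation."""

import numpy as np
import pytest

from knnbiome.cohort import Cohort
from knnbiome.knn import (
    AssemblageKNN,
    evaluate_split,
    knn_predict,
    local_density,
    null_predict,
)
from knnbiome.metrics import jaccard_similarity


def make_cohort(rows):
    rows = np.asarray(rows, dtype=float)
    return Cohort(rows / rows.sum(axis=1, keepdims=True))


@pytest.fixture
def random_cohort():
    rng = np.random.default_rng(314)
    rows = np.where(rng.random((40, 12)) < 0.5, rng.random((40, 12)), 0.0)
    rows[rows.sum(axis=1) == 0, 0] = 1.0
    return make_cohort(rows)


# ---- prediction mechanics ---------------------------------------------------


def test_exact_assemblage_match_with_k1_returns_training_row():
    cohort = make_cohort([[0.5, 0.5, 0.0], [0.0, 0.3, 0.7], [0.2, 0.2, 0.6]])
    pred = knn_predict([1, 1, 0], cohort, k=1)
    assert pred.neighbor_ids[0] == 0
    assert pred.predicted == pytest.approx(cohort.abundances[0], abs=1e-12)


def test_present_only_divisor_not_k():
    """A neighbor lacking species i does not dilute its average (divide by p_i)."""
    cohort = make_cohort(
        [
            [0.4, 0.6, 0.0, 0.0],
            [0.0, 0.5, 0.5, 0.0],
        ]
    )
    pred = knn_predict([1, 1, 1, 0], cohort, k=2)
    # species 0 present in one neighbor with relative abundance 0.4:
    # its pre-normalization average is 0.4 (p_0 = 1), not 0.2
    vec = pred.predicted
    # reconstruct pre-normalization values: species1 avg = (0.6+0.5)/2
    expected = np.array([0.4, 0.55, 0.5, 0.0])
    assert vec == pytest.approx(expected / expected.sum(), abs=1e-12)


def test_k_equals_m_matches_present_only_null(random_cohort):
    model = AssemblageKNN(random_cohort)
    phi = random_cohort.assemblages[3]
    knn_full = model.predict(phi, k=random_cohort.n_samples).predicted
    null = model.predict_null(phi, "present-only")
    assert knn_full == pytest.approx(null, abs=1e-12)


def test_support_exactness(random_cohort):
    model = AssemblageKNN(random_cohort)
    rng = np.random.default_rng(9)
    for _ in range(20):
        phi = rng.random(12) < 0.4
        if not phi.any():
            continue
        pred = model.predict(phi, k=5).predicted
        assert np.array_equal(pred > 0, phi)
        assert pred.sum() == pytest.approx(1.0, abs=1e-12)


def test_equation_divisor_invariance():
    """Adding a neighbor lacking species i leaves its average unchanged."""
    base_rows = [
        [0.5, 0.5, 0.0],
        [0.3, 0.7, 0.0],
        [0.0, 0.4, 0.6],  # lacks species 0
    ]
    two = make_cohort(base_rows[:2])
    pred2 = knn_predict([1, 1, 0], two, k=2).predicted
    three = make_cohort(base_rows)
    pred3 = knn_predict([1, 1, 0], three, k=3).predicted
    # species 0 average over neighbors carrying it: (0.5 + 0.3)/2 both times;
    # species 1 average changes, so compare the species-0:species-1 structure
    p2 = 0.4 / (0.4 + 0.6)  # avg0 / (avg0 + avg1) with avg1 = 0.6
    avg1_3 = (0.5 + 0.7 + 0.4) / 3
    p3 = 0.4 / (0.4 + avg1_3)
    assert pred2[0] == pytest.approx(p2, abs=1e-12)
    assert pred3[0] == pytest.approx(p3, abs=1e-12)


def test_fallback_to_cohort_mean_when_neighbors_lack_species():
    cohort = make_cohort(
        [
            [0.5, 0.5, 0.0],
            [0.6, 0.4, 0.0],
            [0.0, 0.2, 0.8],
        ]
    )
    # nearest neighbors of {0,1} are rows 0 and 1; species 2 absent there
    pred = knn_predict([1, 0, 1], cohort, k=2)
    assert 2 in pred.fallback_species
    # species 2 falls back to its cohort-wide present-only mean (0.8)
    expected = np.array([0.55, 0.0, 0.8])
    assert pred.predicted == pytest.approx(expected / expected.sum(), abs=1e-12)


def test_species_never_in_training_gets_uniform_pseudoabundance():
    cohort = make_cohort([[0.5, 0.5, 0.0], [0.4, 0.6, 0.0]])
    with pytest.warns(UserWarning):
        pred = knn_predict([1, 0, 1], cohort, k=1)
    # neighbor (row 0) carries species 0 at 0.5; species 2 never occurs in
    # training and falls back to the 1/N pseudo-abundance before renormalizing
    expected = np.array([0.5, 0.0, 1.0 / 3.0])
    assert 2 in pred.fallback_species
    assert pred.predicted == pytest.approx(expected / expected.sum(), abs=1e-12)


def test_neighbor_sets_match_brute_force(random_cohort):
    model = AssemblageKNN(random_cohort)
    rng = np.random.default_rng(123)
    binary = random_cohort.assemblages
    for _ in range(100):
        phi = rng.random(12) < 0.5
        if not phi.any():
            continue
        k = int(rng.integers(1, random_cohort.n_samples + 1))
        idx, sims = model.neighbors(phi, k)
        brute = sorted(
            range(random_cohort.n_samples),
            key=lambda j: (-jaccard_similarity(phi, binary[j]), j),
        )[:k]
        assert list(idx) == brute
        assert np.all(np.diff(sims) <= 1e-12)


def test_k_out_of_range_rejected(random_cohort):
    model = AssemblageKNN(random_cohort)
    with pytest.raises(ValueError):
        model.predict(random_cohort.assemblages[0], k=0)
    with pytest.raises(ValueError):
        model.predict(random_cohort.assemblages[0], k=random_cohort.n_samples + 1)


# ---- null model -------------------------------------------------------------


def test_null_variants_disagree_by_prevalence_factor():
    # species 0 present in 2 of 4 samples with abundance 0.2 there
    cohort = Cohort(
        np.array(
            [
                [0.2, 0.8, 0.0],
                [0.2, 0.0, 0.8],
                [0.0, 0.5, 0.5],
                [0.0, 0.6, 0.4],
            ]
        )
    )
    model = AssemblageKNN(cohort)
    phi = np.array([1, 1, 1])
    present = model.predict_null(phi, "present-only")
    over_m = model.predict_null(phi, "over-m")
    # pre-normalization means: present-only (0.2, 0.475, 0.567), over-m halves
    # species 0 relative to the others' prevalence-weighted means
    exp_present = np.array([0.2, (0.8 + 0.5 + 0.6) / 4 * 4 / 3, (0.8 + 0.5 + 0.4) / 3])
    assert present == pytest.approx(exp_present / exp_present.sum(), abs=1e-12)
    exp_over = np.array([0.1, (0.8 + 0.5 + 0.6) / 4, (0.8 + 0.5 + 0.4) / 4])
    assert over_m == pytest.approx(exp_over / exp_over.sum(), abs=1e-12)


def test_null_agrees_across_variants_for_ubiquitous_species():
    cohort = make_cohort([[0.3, 0.7], [0.6, 0.4], [0.5, 0.5]])
    model = AssemblageKNN(cohort)
    phi = np.array([1, 1])
    a = model.predict_null(phi, "present-only")
    b = model.predict_null(phi, "over-m")
    assert a == pytest.approx(b, abs=1e-12)


def test_null_independent_of_neighbors(random_cohort):
    phi = random_cohort.assemblages[0]
    direct = null_predict(phi, random_cohort)
    shuffled = null_predict(phi, random_cohort.subset(np.arange(39, -1, -1)))
    assert direct == pytest.approx(shuffled, abs=1e-12)


# ---- evaluation -------------------------------------------------------------


def test_degenerate_identical_cohort_has_zero_errors():
    cohort = make_cohort([[0.3, 0.7, 0.0]] * 10)
    ev = evaluate_split(cohort, 0.1, [1, 2, 5], n_repetitions=3, seed=0)
    # the sqrt in the rJSD turns float rounding of the mean into ~1e-8 noise
    assert np.all(ev.errors <= 1e-7)
    assert ev.null_error <= 1e-7
    assert abs(ev.gain_delta) <= 1e-7


def test_error_at_k_train_size_equals_null(random_cohort):
    ev = evaluate_split(
        random_cohort, 0.1, [1, 5, 36], n_repetitions=4, seed=7
    )  # 36 = training size after the 10% split
    assert ev.errors[-1] == pytest.approx(ev.null_error, abs=1e-12)


def test_gain_identity_and_k_min_tiebreak(random_cohort):
    ev = evaluate_split(random_cohort, 0.1, [1, 2, 5, 10], n_repetitions=5, seed=3)
    k_idx = list(ev.ks).index(ev.k_min)
    assert ev.gain_delta == ev.null_error - ev.errors[k_idx]
    assert ev.errors[k_idx] == ev.errors.min()
    # smallest k on ties
    ties = np.where(ev.errors == ev.errors.min())[0]
    assert ev.k_min == ev.ks[ties[0]]


def test_self_neighbor_recovery(random_cohort):
    """A test sample present in training is recovered exactly at k=1."""
    model = AssemblageKNN(random_cohort)
    errs, _ = model.score_samples(random_cohort.subset([4]), [1])
    assert errs[0, 0] == 0.0


def test_evaluate_split_input_validation(random_cohort):
    with pytest.raises(ValueError):
        evaluate_split(random_cohort, 0.99, [1], 1, seed=0)
    with pytest.raises(ValueError):
        evaluate_split(random_cohort, 0.1, [37], 1, seed=0)


def test_summary_mentions_key_quantities(random_cohort):
    ev = evaluate_split(random_cohort, 0.1, [1, 2], n_repetitions=2, seed=1)
    text = ev.summary()
    assert "k_min" in text and "Delta" in text and "null model" in text


# ---- local density ----------------------------------------------------------


def test_local_density_monotone_in_k(random_cohort):
    vals = [local_density(random_cohort, 0, k) for k in range(1, 20)]
    assert np.all(np.diff(vals) >= -1e-12)


def test_local_density_with_duplicates_includes_zero_terms():
    cohort = make_cohort([[0.5, 0.5, 0.0]] * 3 + [[0.0, 0.5, 0.5]])
    assert local_density(cohort, 0, 2) == 0.0
    assert local_density(cohort, 0, 3) > 0.0


def test_local_density_bounds():
    cohort = make_cohort([[1, 0], [0, 1], [1, 1]])
    with pytest.raises(ValueError):
        local_density(cohort, 0, 3)
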