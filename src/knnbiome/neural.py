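"""Fully connected neural-network comparison model.

Maps a binary species assemblage to a relative-abundance profile with a
2 x 50 fully connected network (tanh hidden layers, linear output)
trained on mean-squared error.  Training uses a 70/20/10
train/validation/test split and a quasi-Newton optimizer (L-BFGS, the
closest available analog of Levenberg-Marquardt backpropagation) run in
short segments with early stopping on the validation MSE; the weights
at the best validation score are kept.  Predictions are post-processed
exactly like the kNN's: clipped to nonnegative, zeroed on absent
species, renormalized, and scored with the same rJSD prediction error,
so the two methods are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .cohort import Cohort
from .metrics import prediction_error

__all__ = [
    "NeuralBaselineSpec",
    "NeuralBaseline",
    "train_baseline",
    "baseline_predict_and_score",
]


@dataclass(frozen=True)
class NeuralBaselineSpec:
    """Training configuration for the baseline network.

    ``max_epochs`` counts optimizer segments of ``iters_per_epoch``
    L-BFGS iterations each (or single passes for first-order solvers);
    training stops early after ``patience`` segments without validation
    improvement, mirroring the classic max-validation-failures rule.
    """

    n_species: int
    hidden_layers: tuple[int, int] = (50, 50)
    split_fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    max_epochs: int = 80
    iters_per_epoch: int = 10
    patience: int = 6
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer_name: str = "lbfgs"

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.optimizer_name not in ("lbfgs", "adam", "sgd"):
            raise ValueError("optimizer_name must be lbfgs, adam or sgd")


@dataclass
class NeuralBaseline:
    """A trained baseline network plus its split bookkeeping."""

    spec: NeuralBaselineSpec
    net: MLPRegressor
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    history: dict = field(default_factory=dict)

    def predict_profiles(self, assemblages: np.ndarray) -> np.ndarray:
        """Predicted relative-abundance profiles for binary assemblages.

        Raw network outputs are clipped at 0, zeroed outside the input
        assemblage, and renormalized; a degenerate all-zero output falls
        back to uniform on the present species.
        """
        phi = (np.asarray(assemblages) > 0).astype(float)
        raw = self.net.predict(phi)
        # tiny floor keeps the support exactly equal to the assemblage even
        # when clipping sends a present species to 0, so the rJSD scorer's
        # support contract holds for the network as it does for the kNN
        raw = (np.clip(raw, 0.0, None) + 1e-12) * phi
        sums = raw.sum(axis=1, keepdims=True)
        uniform = phi / np.maximum(phi.sum(axis=1, keepdims=True), 1.0)
        return np.where(sums > 0, raw / np.where(sums > 0, sums, 1.0), uniform)


def train_baseline(cohort: Cohort, spec: NeuralBaselineSpec) -> NeuralBaseline:
    """Train the 2x50 network on a cohort; deterministic given spec.seed."""
    m = cohort.n_samples
    if m < 10:
        raise ValueError("cohort too small to train the baseline (need m >= 10)")
    if spec.n_species != cohort.n_species:
        raise ValueError("spec.n_species must match the cohort")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(m)
    f_train, f_val, _ = spec.split_fractions
    n_train = max(1, int(round(f_train * m)))
    n_val = max(1, int(round(f_val * m)))
    n_train = min(n_train, m - n_val - 1)
    train_idx = perm[:n_train]
    val_idx = perm[n_train : n_train + n_val]
    test_idx = perm[n_train + n_val :]

    x = cohort.assemblages.astype(float)
    y = cohort.abundances
    kwargs = dict(
        hidden_layer_sizes=spec.hidden_layers,
        activation="tanh",
        solver=spec.optimizer_name,
        random_state=int(np.random.default_rng(spec.seed).integers(2**31 - 1)),
        alpha=0.0,
        warm_start=True,
    )
    if spec.optimizer_name == "lbfgs":
        kwargs["max_iter"] = spec.iters_per_epoch
    else:
        kwargs["max_iter"] = 1
        kwargs["learning_rate_init"] = spec.learning_rate
        kwargs["batch_size"] = min(32, n_train)
    net = MLPRegressor(**kwargs)

    best_val = np.inf
    best_weights = None
    stall = 0
    history = {"train_mse": [], "val_mse": []}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(spec.max_epochs):
            if spec.optimizer_name == "lbfgs":
                net.fit(x[train_idx], y[train_idx])
            else:
                net.partial_fit(x[train_idx], y[train_idx])
            train_mse = float(np.mean((net.predict(x[train_idx]) - y[train_idx]) ** 2))
            val_mse = float(np.mean((net.predict(x[val_idx]) - y[val_idx]) ** 2))
            history["train_mse"].append(train_mse)
            history["val_mse"].append(val_mse)
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_weights = (
                    [c.copy() for c in net.coefs_],
                    [b.copy() for b in net.intercepts_],
                )
                stall = 0
            else:
                stall += 1
                if stall >= spec.patience:
                    break
    if best_weights is not None:
        net.coefs_, net.intercepts_ = best_weights
    return NeuralBaseline(spec, net, train_idx, val_idx, test_idx, history)


def baseline_predict_and_score(
    model: NeuralBaseline,
    test_samples: Cohort,
    *,
    log_base: float | None = None,
) -> float:
    """Mean rJSD prediction error of the baseline on a test cohort."""
    preds = model.predict_profiles(test_samples.assemblages)
    errors = [
        prediction_error(p, a, log_base=log_base)
        for p, a in zip(preds, test_samples.abundances)
    ]
    return float(np.mean(errors))
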