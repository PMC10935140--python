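"""Cost-sensitive fall/ADL classifiers.

Fall corpora are heavily imbalanced (a few percent of fall windows), so the
training loss of both learners scales each sample's contribution by a class
weight ω.  With n samples and n_c of class c, the inverse-class-frequency
scheme sets

    ω_c = n / (2 · n_c),

normalized so a balanced set yields ω = 1 for both classes; the minority
(fall) class always receives the strictly larger weight, and the weight
ratio equals the inverse count ratio exactly.  (The literal class-frequency
scheme ω_c = n_c / n — which up-weights the majority class — is kept behind
``scheme="class_frequency"`` for comparison.)

Learners:

* weighted soft-margin SVM — the per-sample slack penalty is C · ω_{y(i)};
  delegated to scikit-learn's SVC via per-class weights, behind an internal
  feature standardizer.
* weighted single-hidden-layer ANN — tanh hidden layer, sigmoid output,
  trained by full-batch gradient descent on the class-weighted mean squared
  error  J = (1/2n) Σ ω_{y(i)} (ŷ_i − y_i)²,  with seeded initialization
  and early stopping on a validation split.  Authored here because the
  weighted-MSE objective is the point.
* acceleration-magnitude threshold baseline — a window is a fall iff its
  peak acceleration norm reaches the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

WEIGHT_SCHEMES = ("inverse_frequency", "class_frequency")


@dataclass(frozen=True)
class ClassWeights:
    """Per-class training weights ω for labels {0 (ADL), 1 (fall)}.

    Weights computed from label counts are exact rationals
    (:class:`fractions.Fraction`), so the weight ratio equals the inverse
    count ratio exactly, with no float rounding.
    """

    weights: dict[int, float | Fraction]

    def __post_init__(self) -> None:
        if set(self.weights) != {0, 1}:
            raise ValueError("need weights for exactly the classes {0, 1}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("class weights must be positive")

    @property
    def ratio(self):
        """ω_fall / ω_ADL (exact when the weights are rationals)."""
        return self.weights[1] / self.weights[0]

    def as_floats(self) -> dict[int, float]:
        return {c: float(w) for c, w in self.weights.items()}

    def per_sample(self, y: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(y) == 1, float(self.weights[1]),
                        float(self.weights[0]))


def compute_class_weights(labels,
                          scheme: str = "inverse_frequency") -> ClassWeights:
    """Class weights from a label vector; both classes must be present."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    y = np.asarray(labels)
    n = y.size
    counts = {c: int(np.count_nonzero(y == c)) for c in (0, 1)}
    if min(counts.values()) == 0 or set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    if scheme == "inverse_frequency":
        weights = {c: Fraction(n, 2 * counts[c]) for c in (0, 1)}
    else:
        weights = {c: Fraction(counts[c], n) for c in (0, 1)}
    return ClassWeights(weights=weights)


@dataclass
class TrainedModel:
    """A fitted detector: continuous scores plus consistent hard labels.

    ``predict`` is exactly the thresholded score for every sample:
    score > 0 for the SVM margin, score >= 0.5 for the ANN sigmoid output.
    """

    kind: str
    feature_names: list[str] | None
    score_fn: Callable[[np.ndarray], np.ndarray]
    label_rule: Callable[[np.ndarray], np.ndarray]
    metadata: dict = field(default_factory=dict)

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.feature_names is not None:
                X = X[list(self.feature_names)]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if (self.feature_names is not None
                and X.shape[1] != len(self.feature_names)):
            raise ValueError(
                f"expected {len(self.feature_names)} features, "
                f"got {X.shape[1]}")
        return X

    def decision_scores(self, X) -> np.ndarray:
        return self.score_fn(self._matrix(X))

    def predict(self, X) -> np.ndarray:
        return self.label_rule(self.decision_scores(X)).astype(int)


def _as_matrix(X, feature_names) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        names = list(feature_names) if feature_names is not None \
            else list(X.columns)
        return X[names].to_numpy(dtype=float), names
    return (np.asarray(X, dtype=float),
            list(feature_names) if feature_names is not None else None)


# ---------------------------------------------------------------------------
# weighted SVM
# ---------------------------------------------------------------------------

def train_weighted_svm(X, y, weights: ClassWeights | None = None,
                       C: float = 1.0, kernel: str = "rbf",
                       gamma: str | float = "scale", seed: int = 0,
                       feature_names=None,
                       standardize: bool = True) -> TrainedModel:
    """Soft-margin SVM with per-class slack penalty C · ω_c.

    Scores are the signed margin (decision function); a window is called a
    fall when its score is strictly positive.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    Xm, names = _as_matrix(X, feature_names)
    y = np.asarray(y).astype(int)
    if weights is None:
        weights = compute_class_weights(y)
    svc = SVC(C=C, kernel=kernel, gamma=gamma,
              class_weight=weights.as_floats(), random_state=seed)
    clf = make_pipeline(StandardScaler(), svc) if standardize else svc
    clf.fit(Xm, y)
    return TrainedModel(
        kind="svm", feature_names=names,
        score_fn=clf.decision_function,
        label_rule=lambda s: s > 0,
        metadata={"C": C, "kernel": kernel, "gamma": gamma, "seed": seed,
                  "class_weights": weights.as_floats()})


# ---------------------------------------------------------------------------
# weighted ANN
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _AnnNet:
    """Parameters and forward pass of the single-hidden-layer network."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, hidden))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), hidden)
        self.b2 = 0.0

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.tanh(X @ self.W1 + self.b1)
        return h, _sigmoid(h @ self.w2 + self.b2)

    def params(self) -> list[np.ndarray]:
        return [self.W1.copy(), self.b1.copy(), self.w2.copy(),
                np.array(self.b2)]

    def set_params(self, params: list[np.ndarray]) -> None:
        self.W1, self.b1, self.w2 = (params[0].copy(), params[1].copy(),
                                     params[2].copy())
        self.b2 = float(params[3])


def _weighted_mse(y_hat: np.ndarray, y: np.ndarray,
                  omega: np.ndarray) -> float:
    return float(np.sum(omega * (y_hat - y) ** 2) / (2 * y.size))


def train_weighted_ann(X, y, weights: ClassWeights | None = None,
                       hidden_units: int = 64, epochs: int = 600,
                       learning_rate: float = 0.5, momentum: float = 0.9,
                       seed: int = 0, validation_fraction: float = 0.15,
                       patience: int = 60, feature_names=None,
                       standardize: bool = True) -> TrainedModel:
    """Single-hidden-layer network minimizing the class-weighted MSE.

    Full-batch gradient descent (optional momentum) with seeded
    initialization; when ``validation_fraction`` > 0 a stratified split is
    held out and the best-validation parameters are restored (early
    stopping after ``patience`` epochs without improvement).  Scores are
    the sigmoid output in [0, 1]; label rule: score >= 0.5 -> fall.  The
    training-loss history is kept in ``metadata["loss_history"]``.
    """
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    Xm, names = _as_matrix(X, feature_names)
    y = np.asarray(y).astype(float)
    if weights is None:
        weights = compute_class_weights(y.astype(int))
    rng = np.random.default_rng(seed)

    mu = Xm.mean(axis=0) if standardize else np.zeros(Xm.shape[1])
    sd = Xm.std(axis=0) if standardize else np.ones(Xm.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xm - mu) / sd

    if 0 < validation_fraction < 1 and np.unique(y).size == 2:
        idx0 = np.flatnonzero(y == 0)
        idx1 = np.flatnonzero(y == 1)
        rng.shuffle(idx0)
        rng.shuffle(idx1)
        n_val0 = max(1, int(round(validation_fraction * idx0.size)))
        n_val1 = max(1, int(round(validation_fraction * idx1.size)))
        val = np.concatenate([idx0[:n_val0], idx1[:n_val1]])
        tr = np.concatenate([idx0[n_val0:], idx1[n_val1:]])
    else:
        tr = np.arange(y.size)
        val = np.array([], dtype=int)

    Xtr, ytr = Xs[tr], y[tr]
    omega_tr = weights.per_sample(ytr)
    net = _AnnNet(Xs.shape[1], hidden_units, rng)
    velocity = [np.zeros_like(p) for p in net.params()]
    best_val = np.inf
    best_params = net.params()
    since_best = 0
    loss_history = []
    n = ytr.size
    for _ in range(epochs):
        h, y_hat = net.forward(Xtr)
        loss_history.append(_weighted_mse(y_hat, ytr, omega_tr))
        # dJ/dz_out = (1/n) ω (ŷ − y) ŷ (1 − ŷ)
        delta = omega_tr * (y_hat - ytr) * y_hat * (1 - y_hat) / n
        grad_w2 = h.T @ delta
        grad_b2 = delta.sum()
        delta_h = np.outer(delta, net.w2) * (1 - h ** 2)
        grad_W1 = Xtr.T @ delta_h
        grad_b1 = delta_h.sum(axis=0)
        grads = [grad_W1, grad_b1, grad_w2, np.array(grad_b2)]
        params = net.params()
        for i in range(4):
            velocity[i] = momentum * velocity[i] - learning_rate * grads[i]
            params[i] = params[i] + velocity[i]
        net.set_params(params)
        if val.size:
            _, yv = net.forward(Xs[val])
            vloss = _weighted_mse(yv, y[val], weights.per_sample(y[val]))
            if vloss < best_val - 1e-12:
                best_val = vloss
                best_params = net.params()
                since_best = 0
            else:
                since_best += 1
                if since_best > patience:
                    break
    if val.size:
        net.set_params(best_params)

    def score_fn(Xq: np.ndarray) -> np.ndarray:
        return net.forward((Xq - mu) / sd)[1]

    return TrainedModel(
        kind="ann", feature_names=names, score_fn=score_fn,
        label_rule=lambda s: s >= 0.5,
        metadata={"hidden_units": hidden_units, "epochs": epochs,
                  "learning_rate": learning_rate, "momentum": momentum,
                  "seed": seed, "loss_history": loss_history,
                  "class_weights": weights.as_floats()})


# ---------------------------------------------------------------------------
# threshold baseline
# ---------------------------------------------------------------------------

def threshold_baseline(peak_norms, threshold: float) -> np.ndarray:
    """Label a window fall iff its peak acceleration norm >= threshold (g).

    ``peak_norms`` is the per-window max of sqrt(ax² + ay² + az²) on raw
    (unnormalized) acceleration, e.g. from
    :func:`wristfall.features.acc_norm_peaks`.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    peaks = np.asarray(peak_norms, dtype=float)
    return (peaks >= threshold).astype(int)
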