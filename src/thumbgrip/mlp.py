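"""Supervised validation arm: a small feed-forward classifier.

A one-hidden-layer network (default 20 tanh units, 4-way output) is trained
on 30% of the labeled feature vectors with 35% validation and 35% testing,
mirroring the classical supervised benchmark for myoelectric pattern
recognition.  Two objectives are offered:

* ``cross-entropy`` — softmax outputs trained by full-batch Adam;
* ``mse`` — linear outputs against one-hot targets, trained by damped
  least-squares (Levenberg-Marquardt) steps when the parameter count permits,
  otherwise plain gradient descent.

Both use early stopping on the validation objective with a patience counter,
restoring the best parameters seen.  Reports carry, per split: sample count,
total cross-entropy, % error, accuracy/misclassification and the confusion
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable, SplitSpec, split as _split
from .sofm import confusion as _confusion

__all__ = [
    "MlpSpec",
    "MlpModel",
    "SplitMetrics",
    "TrainingReport",
    "split_three_way",
    "train_classifier",
    "evaluate",
]

_LM_MAX_PARAMS = 20_000


@dataclass(frozen=True)
class MlpSpec:
    hidden_units: int = 20
    objective: str = "cross-entropy"  # or "mse"
    max_epochs: int = 500
    patience: int = 10
    learning_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.objective not in ("cross-entropy", "mse"):
            raise ValueError("objective must be 'cross-entropy' or 'mse'")


@dataclass
class MlpModel:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    classes: tuple[str, ...]
    objective: str

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W1 + self.b1)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._hidden(np.asarray(X, float)) @ self.W2 + self.b2

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.classes[i] for i in self.decision(X).argmax(axis=1)])


def split_three_way(
    table: FeatureTable, seed: int, fractions: tuple[float, float, float] = (0.30, 0.35, 0.35)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified, seeded 30/35/35 train/validation/test row partition."""
    train, val, test = _split(table, SplitSpec(fractions=tuple(fractions), seed=seed))
    return train, val, test


def _one_hot(y: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    t = np.zeros((len(y), len(classes)))
    t[np.arange(len(y)), [idx[v] for v in y]] = 1.0
    return t


def _check_finite(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    return X


def _ce_objective(model: MlpModel, X: np.ndarray, T: np.ndarray) -> float:
    p = model.predict_proba(X)
    return float(-(T * np.log(np.clip(p, 1e-12, None))).sum() / len(X))


def _mse_objective(model: MlpModel, X: np.ndarray, T: np.ndarray) -> float:
    return float(((model.decision(X) - T) ** 2).mean())


def _params_to_vec(m: MlpModel) -> np.ndarray:
    return np.concatenate([m.W1.ravel(), m.b1, m.W2.ravel(), m.b2])


def _vec_to_params(m: MlpModel, v: np.ndarray) -> None:
    pos = 0
    for arr in (m.W1, m.b1, m.W2, m.b2):
        arr[...] = v[pos : pos + arr.size].reshape(arr.shape)
        pos += arr.size


def _jacobian(m: MlpModel, X: np.ndarray) -> np.ndarray:
    """Jacobian of the linear outputs w.r.t. all parameters: (n*k, p)."""
    n, d = X.shape
    h = m.W1.shape[1]
    k = m.W2.shape[1]
    A = m._hidden(X)  # (n, h)
    dA = 1.0 - A**2  # tanh'
    p = d * h + h + h * k + k
    J = np.zeros((n, k, p))
    # dW1: dy_nk/dW1_ij = W2_jk * dA_nj * x_ni
    G = dA[:, None, :] * m.W2.T[None, :, :]  # (n, k, h)
    J[:, :, : d * h] = (G[:, :, None, :] * X[:, None, :, None]).reshape(n, k, d * h)
    J[:, :, d * h : d * h + h] = G
    off = d * h + h
    # dW2 block: dy_nk/dW2_jk = A_nj, zero for other output columns;
    # parameter order W2.ravel() = (h, k) row-major
    for j in range(h):
        for kk in range(k):
            J[:, kk, off + j * k + kk] = A[:, j]
    off2 = off + h * k
    for kk in range(k):
        J[:, kk, off2 + kk] = 1.0
    return J.reshape(n * k, p)


def _train_adam_ce(
    model: MlpModel,
    X: np.ndarray,
    T: np.ndarray,
    Xv: np.ndarray,
    Tv: np.ndarray,
    spec: MlpSpec,
) -> None:
    lr = spec.learning_rate
    params = [model.W1, model.b1, model.W2, model.b2]
    ms = [np.zeros_like(p) for p in params]
    vs = [np.zeros_like(p) for p in params]
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    best_val = _ce_objective(model, Xv, Tv)
    best = [p.copy() for p in params]
    wait = 0
    n = len(X)
    for t in range(1, spec.max_epochs + 1):
        A = model._hidden(X)
        P = model.predict_proba(X)
        delta_out = (P - T) / n  # (n, k)
        gW2 = A.T @ delta_out
        gb2 = delta_out.sum(axis=0)
        delta_h = (delta_out @ model.W2.T) * (1.0 - A**2)
        gW1 = X.T @ delta_h
        gb1 = delta_h.sum(axis=0)
        grads = [gW1, gb1, gW2, gb2]
        for p, g, mo, vo in zip(params, grads, ms, vs):
            mo[...] = b1m * mo + (1 - b1m) * g
            vo[...] = b2m * vo + (1 - b2m) * g**2
            mhat = mo / (1 - b1m**t)
            vhat = vo / (1 - b2m**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        val = _ce_objective(model, Xv, Tv)
        if val < best_val - 1e-9:
            best_val = val
            best = [p.copy() for p in params]
            wait = 0
        else:
            wait += 1
            if wait >= spec.patience:
                break
    for p, b in zip(params, best):
        p[...] = b


def _train_lm_mse(
    model: MlpModel,
    X: np.ndarray,
    T: np.ndarray,
    Xv: np.ndarray,
    Tv: np.ndarray,
    spec: MlpSpec,
) -> None:
    lam = 1e-2
    theta = _params_to_vec(model)
    n_out = T.size
    best_val = _mse_objective(model, Xv, Tv)
    best = theta.copy()
    wait = 0
    loss = _mse_objective(model, X, T)
    for _ in range(spec.max_epochs):
        r = (model.decision(X) - T).ravel()
        J = _jacobian(model, X)
        g = J.T @ r
        H = J.T @ J
        accepted = False
        for _attempt in range(8):
            try:
                step = np.linalg.solve(H + lam * np.eye(H.shape[0]), g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            cand = theta - step
            _vec_to_params(model, cand)
            new_loss = _mse_objective(model, X, T)
            if new_loss < loss:
                theta = cand
                loss = new_loss
                lam = max(lam / 3.0, 1e-10)
                accepted = True
                break
            lam *= 4.0
            _vec_to_params(model, theta)
        if not accepted:
            break
        val = _mse_objective(model, Xv, Tv)
        if val < best_val - 1e-12:
            best_val = val
            best = theta.copy()
            wait = 0
        else:
            wait += 1
            if wait >= spec.patience:
                break
    _vec_to_params(model, best)


def _train_gd_mse(
    model: MlpModel,
    X: np.ndarray,
    T: np.ndarray,
    Xv: np.ndarray,
    Tv: np.ndarray,
    spec: MlpSpec,
) -> None:
    lr = spec.learning_rate
    params = [model.W1, model.b1, model.W2, model.b2]
    best_val = _mse_objective(model, Xv, Tv)
    best = [p.copy() for p in params]
    wait = 0
    n = len(X)
    k = T.shape[1]
    for _ in range(spec.max_epochs):
        A = model._hidden(X)
        Y = A @ model.W2 + model.b2
        delta_out = 2.0 * (Y - T) / (n * k)
        gW2 = A.T @ delta_out
        gb2 = delta_out.sum(axis=0)
        delta_h = (delta_out @ model.W2.T) * (1.0 - A**2)
        gW1 = X.T @ delta_h
        gb1 = delta_h.sum(axis=0)
        for p, g in zip(params, (gW1, gb1, gW2, gb2)):
            p -= lr * g
        val = _mse_objective(model, Xv, Tv)
        if val < best_val - 1e-12:
            best_val = val
            best = [p.copy() for p in params]
            wait = 0
        else:
            wait += 1
            if wait >= spec.patience:
                break
    for p, b in zip(params, best):
        p[...] = b


def train_classifier(
    spec: MlpSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    classes: tuple[str, ...] | None = None,
) -> MlpModel:
    """Train the network with early stopping on the validation objective.

    Deterministic given ``spec.seed``.  The returned model's validation
    objective never exceeds its value at initialization (best-so-far
    parameters are restored).
    """
    X_train = _check_finite(X_train)
    X_val = _check_finite(X_val)
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if classes is None:
        classes = tuple(sorted(set(y_train.tolist()) | set(y_val.tolist())))
    d = X_train.shape[1]
    h = spec.hidden_units
    k = len(classes)
    rng = np.random.default_rng(spec.seed)
    lim1 = np.sqrt(6.0 / (d + h))
    lim2 = np.sqrt(6.0 / (h + k))
    model = MlpModel(
        W1=rng.uniform(-lim1, lim1, size=(d, h)),
        b1=np.zeros(h),
        W2=rng.uniform(-lim2, lim2, size=(h, k)),
        b2=np.zeros(k),
        classes=classes,
        objective=spec.objective,
    )
    T = _one_hot(y_train, classes)
    Tv = _one_hot(y_val, classes)
    if spec.objective == "cross-entropy":
        _train_adam_ce(model, X_train, T, X_val, Tv, spec)
    else:
        n_params = d * h + h + h * k + k
        if n_params <= _LM_MAX_PARAMS:
            _train_lm_mse(model, X_train, T, X_val, Tv, spec)
        else:
            _train_gd_mse(model, X_train, T, X_val, Tv, spec)
    return model


@dataclass(frozen=True)
class SplitMetrics:
    """Per-split performance: counts, total cross-entropy, % error."""

    n: int
    cross_entropy: float  # total: -sum log p(true class)
    error_pct: float
    accuracy_pct: float
    misclassification_pct: float
    confusion: pd.DataFrame = field(repr=False)


def evaluate(model: MlpModel, X: np.ndarray, y: np.ndarray) -> SplitMetrics:
    """Metrics of one data split under a fitted model."""
    X = _check_finite(X)
    if len(X) == 0:
        raise ValueError("cannot evaluate an empty split")
    y = np.asarray(y)
    proba = model.predict_proba(X)
    idx = {c: i for i, c in enumerate(model.classes)}
    p_true = proba[np.arange(len(y)), [idx[v] for v in y]]
    ce_total = float(-np.log(np.clip(p_true, 1e-12, None)).sum())
    preds = model.predict(X)
    mat, acc = _confusion(preds, y, classes=model.classes)
    err = 100.0 * float((preds != y).mean())
    return SplitMetrics(
        n=len(y),
        cross_entropy=ce_total,
        error_pct=err,
        accuracy_pct=100.0 * acc,
        misclassification_pct=100.0 - 100.0 * acc,
        confusion=mat,
    )


@dataclass(frozen=True)
class TrainingReport:
    """Supervised-arm report: metrics for each of the three splits."""

    train: SplitMetrics
    validation: SplitMetrics
    test: SplitMetrics

    @property
    def total_samples(self) -> int:
        return self.train.n + self.validation.n + self.test.n
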