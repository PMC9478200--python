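"""Three-layer back-propagation network fed by PLS scores.

Architecture: input layer (PLS score vector, 14 by default) -> hidden
layer with logistic-sigmoid units -> single linear output.  Inputs and
targets are min-max scaled to [-1, 1] on the calibration data (the
toolbox convention this mirrors).  Training is Møller's scaled conjugate
gradient (SCG) with the stopping rule: goal MSE on scaled targets or a
maximum epoch count.  An optional plain gradient-descent trainer retains
the fixed learning rate, which SCG itself does not use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MinMaxScaler",
    "ANNModel",
    "TrainConfig",
    "fit_scaler",
    "init_ann",
    "forward",
    "predict",
    "mse_loss_and_gradient",
    "train_scg",
    "train_gd",
    "full_cv",
    "screen_hidden_nodes",
    "select_hidden_nodes",
    "HiddenNodeReport",
]


@dataclass(frozen=True)
class MinMaxScaler:
    """Per-feature affine map onto [-1, 1] fitted on calibration data.

    Values outside the calibration range map outside [-1, 1]; there is
    deliberately no clipping, so extrapolation is visible downstream.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 2.0 * (x - self.minimum) / (self.maximum - self.minimum) - 1.0

    def invert(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return (z + 1.0) / 2.0 * (self.maximum - self.minimum) + self.minimum


def fit_scaler(data: np.ndarray) -> MinMaxScaler:
    """Fit the [-1, 1] min-max map; a constant feature is an error."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    if np.any(hi - lo <= 0):
        j = int(np.nonzero(hi - lo <= 0)[0][0])
        raise ValueError(f"degenerate scaling range for feature {j} "
                         f"(min == max == {lo[j]})")
    if data.shape[1] == 1:
        return MinMaxScaler(lo[0], hi[0])
    return MinMaxScaler(lo, hi)


@dataclass
class ANNModel:
    """Weights of the 3-layer net plus the input/output scalers."""

    W1: np.ndarray  # (h, d)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (1, h)
    b2: float
    x_scaler: MinMaxScaler | None = None
    y_scaler: MinMaxScaler | None = None
    seed: int | None = None

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    @property
    def input_size(self) -> int:
        return self.W1.shape[1]

    def pack(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1,
                               self.W2.ravel(), [self.b2]])

    def unpack(self, theta: np.ndarray) -> "ANNModel":
        h, d = self.W1.shape
        i = 0
        W1 = theta[i:i + h * d].reshape(h, d); i += h * d
        b1 = theta[i:i + h]; i += h
        W2 = theta[i:i + h].reshape(1, h); i += h
        b2 = float(theta[i])
        return replace(self, W1=W1, b1=b1, W2=W2, b2=b2)


@dataclass(frozen=True)
class TrainConfig:
    """SCG stopping/training parameters (toolbox-style defaults)."""

    max_epochs: int = 1000
    goal_mse: float = 0.001   # on [-1, 1]-scaled targets
    learning_rate: float = 0.1  # used only by the gradient-descent trainer
    restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 0 or self.goal_mse <= 0 or self.learning_rate <= 0:
            raise ValueError("training parameters must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def init_ann(input_size: int, hidden_size: int,
             rng: np.random.Generator) -> ANNModel:
    """Nguyen–Widrow-style initialization, seed-controlled.

    Hidden weights are drawn uniformly, row-normalized, and scaled by
    0.7 * h^(1/d) so the active regions of the sigmoids tile the input
    cube; biases spread the units across [-1, 1].
    """
    h, d = hidden_size, input_size
    W1 = rng.uniform(-1.0, 1.0, size=(h, d))
    norms = np.linalg.norm(W1, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    scale = 0.7 * h ** (1.0 / d)
    W1 = scale * W1 / norms
    if h > 1:
        b1 = scale * np.linspace(-1.0, 1.0, h) * np.sign(W1[:, 0])
    else:
        b1 = np.zeros(1)
    W2 = rng.uniform(-0.5, 0.5, size=(1, h))
    b2 = float(rng.uniform(-0.5, 0.5))
    return ANNModel(W1, b1, W2, b2)


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def forward(model: ANNModel, Z: np.ndarray) -> np.ndarray:
    """Network output in scaled units: W2·sigma(W1·z + b1) + b2 per row."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != model.input_size:
        raise ValueError(
            f"input width {Z.shape[1]} != model input size {model.input_size}")
    H = _sigmoid(Z @ model.W1.T + model.b1)
    return (H @ model.W2.T).ravel() + model.b2


def predict(model: ANNModel, scores: np.ndarray) -> np.ndarray:
    """End-to-end prediction in mg/g: scale scores, run the net, invert
    the target scaling."""
    if model.x_scaler is None or model.y_scaler is None:
        raise ValueError("model has no fitted scalers")
    z = model.x_scaler.apply(scores)
    return np.asarray(model.y_scaler.invert(forward(model, z)), dtype=float)


def mse_loss_and_gradient(model: ANNModel, Z: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean-squared error on scaled targets and its gradient (packed in
    the same order as :meth:`ANNModel.pack`), by back-propagation."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    A1 = Z @ model.W1.T + model.b1
    H = _sigmoid(A1)
    yhat = (H @ model.W2.T).ravel() + model.b2
    resid = yhat - y
    loss = float(resid @ resid) / n
    d_yhat = 2.0 * resid / n                    # (n,)
    gW2 = d_yhat @ H                            # (h,)
    gb2 = float(d_yhat.sum())
    dH = np.outer(d_yhat, model.W2.ravel())     # (n, h)
    dA1 = dH * H * (1.0 - H)
    gW1 = dA1.T @ Z                             # (h, d)
    gb1 = dA1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), [gb2]])
    return loss, grad


def train_scg(model: ANNModel, Z: np.ndarray, y: np.ndarray,
              config: TrainConfig) -> tuple[ANNModel, list[float]]:
    """Scaled conjugate gradient (Møller 1993) on the packed weights.

    Stops when the scaled-target MSE reaches ``config.goal_mse`` or after
    ``config.max_epochs`` iterations.  The returned trace holds the loss
    after every epoch; the loss at accepted steps never increases.
    ``max_epochs == 0`` returns the initial model untouched.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    theta = model.pack()
    n_par = theta.size

    def evaluate(t: np.ndarray) -> tuple[float, np.ndarray]:
        return mse_loss_and_gradient(model.unpack(t), Z, y)

    loss, grad = evaluate(theta)
    trace: list[float] = []
    if config.max_epochs == 0 or loss <= config.goal_mse:
        return model.unpack(theta), [loss]

    sigma0 = 1e-4
    lam, lam_bar = 1e-6, 0.0
    r = -grad
    p = r.copy()
    success = True
    delta = 0.0
    for epoch in range(config.max_epochs):
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss; aborting")
        p_norm2 = float(p @ p)
        if p_norm2 < 1e-300:
            trace.append(loss)
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            _, grad_sig = evaluate(theta + sigma * p)
            s = (grad_sig - grad) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        loss_new, grad_new = evaluate(theta + alpha * p)
        comparison = 2.0 * delta * (loss - loss_new) / mu ** 2
        if comparison >= 0:
            theta = theta + alpha * p
            loss, grad = loss_new, grad_new
            r_new = -grad
            lam_bar = 0.0
            success = True
            if (epoch + 1) % n_par == 0:
                p = r_new.copy()  # periodic restart along steepest descent
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / p_norm2
        trace.append(loss)
        if loss <= config.goal_mse or float(r @ r) < 1e-24:
            break
    return model.unpack(theta), trace


def train_gd(model: ANNModel, Z: np.ndarray, y: np.ndarray,
             config: TrainConfig) -> tuple[ANNModel, list[float]]:
    """Plain gradient descent with the fixed learning rate; kept as the
    rule the fixed ``learning_rate`` parameter actually belongs to."""
    theta = model.pack()
    trace: list[float] = []
    for _ in range(config.max_epochs):
        loss, grad = mse_loss_and_gradient(model.unpack(theta), Z, y)
        trace.append(loss)
        if loss <= config.goal_mse:
            break
        theta = theta - config.learning_rate * grad
    return model.unpack(theta), trace


def _fold_rng(seed: int, *branch: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *branch])


def fit_ann(scores: np.ndarray, y: np.ndarray, hidden_size: int,
            config: TrainConfig, *, rng_branch: tuple = ()) -> ANNModel:
    """Fit scalers and train the net, keeping the best restart by final
    calibration loss.  Deterministic given ``config.seed`` and branch."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    x_scaler = fit_scaler(scores)
    y_scaler = fit_scaler(y)
    Z = x_scaler.apply(scores)
    t = y_scaler.apply(y)
    best: ANNModel | None = None
    best_loss = np.inf
    for restart in range(config.restarts):
        rng = _fold_rng(config.seed, *rng_branch, restart)
        model = init_ann(scores.shape[1], hidden_size, rng)
        trained, trace = train_scg(model, Z, t, config)
        if trace[-1] < best_loss:
            best_loss = trace[-1]
            best = trained
    assert best is not None
    best.x_scaler = x_scaler
    best.y_scaler = y_scaler
    best.seed = config.seed
    return best


def full_cv(scores: np.ndarray, y: np.ndarray, hidden_size: int,
            config: TrainConfig, folds: int | None = None
            ) -> tuple[float, float, np.ndarray]:
    """Cross-validation of the net on the calibration set (Full-CV).

    ``folds=None`` means leave-one-out.  Scalers and weights are refitted
    per fold from a fold-derived seed; pooled held-out predictions give
    RMSEP_c (mg/g) and R²_c (%).

    Returns (rmsep_c, r2_c, pooled held-out predictions).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("cross-validation needs at least 3 samples")
    k = n if folds is None else min(folds, n)
    assignments = np.arange(n) % k
    preds = np.zeros(n)
    for fold in range(k):
        test = assignments == fold
        fold_config = replace(config)
        model = fit_ann(scores[~test], y[~test], hidden_size, fold_config,
                        rng_branch=(fold,))
        preds[test] = predict(model, scores[test])
    rmsep = float(np.sqrt(np.mean((preds - y) ** 2)))
    r2 = 100.0 * (1.0 - ((preds - y) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    return rmsep, r2, preds


@dataclass(frozen=True)
class HiddenNodeReport:
    hidden_size: int
    rmsep_cv: float
    r2_cv: float
    rmsep_val: float
    r2_val: float


def screen_hidden_nodes(scores_cal: np.ndarray, y_cal: np.ndarray,
                        scores_val: np.ndarray, y_val: np.ndarray,
                        candidates: Sequence[int] = (2, 3, 4, 6, 8, 10),
                        config: TrainConfig = TrainConfig(),
                        tolerance: float = 0.10
                        ) -> tuple[int, list[HiddenNodeReport]]:
    """Screen the hidden-layer size over ``candidates``.

    For each h, Full-CV on the calibration set gives RMSEP_c and a net
    trained on the full calibration set gives the external-validation
    RMSEP_v.  The winner is the *smallest* h whose RMSEP_c and RMSEP_v
    both lie within ``tolerance`` (relative) of the respective minima —
    parsimony among the near-optimal models.  If no single h is near
    both minima, the h minimizing RMSEP_c + RMSEP_v is returned.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    y_val = np.asarray(y_val, dtype=float).ravel()
    reports: list[HiddenNodeReport] = []
    for h in candidates:
        rmsep_c, r2_c, _ = full_cv(scores_cal, y_cal, h, config)
        model = fit_ann(scores_cal, y_cal, h, config, rng_branch=(10_000 + h,))
        yhat = predict(model, scores_val)
        rmsep_v = float(np.sqrt(np.mean((yhat - y_val) ** 2)))
        r2_v = 100.0 * (1.0 - ((yhat - y_val) ** 2).sum()
                        / ((y_val - y_val.mean()) ** 2).sum())
        reports.append(HiddenNodeReport(h, rmsep_c, r2_c, rmsep_v, r2_v))
    return select_hidden_nodes(reports, tolerance), reports


def select_hidden_nodes(reports: Sequence[HiddenNodeReport],
                        tolerance: float = 0.10) -> int:
    """Parsimony rule: the smallest h whose RMSEP_c and RMSEP_v are both
    within ``tolerance`` (relative) of the respective minima; when no h is
    near both minima, the h minimizing their sum."""
    min_c = min(r.rmsep_cv for r in reports)
    min_v = min(r.rmsep_val for r in reports)
    near = [r for r in reports
            if r.rmsep_cv <= (1 + tolerance) * min_c
            and r.rmsep_val <= (1 + tolerance) * min_v]
    if near:
        return min(near, key=lambda r: r.hidden_size).hidden_size
    return min(reports, key=lambda r: r.rmsep_cv + r.rmsep_val).hidden_size
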