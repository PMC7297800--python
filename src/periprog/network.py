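"""Feed-forward binary classifier trained by scaled conjugate gradients.

A fully connected network (default one hidden layer of 10 tanh units, one
sigmoid output) is fit to the voxel feature vectors by minimizing mean
binary cross-entropy with Moller's scaled conjugate gradient (SCG): batch
conjugate directions with a scalar Hessian-damping term lambda adapted by
the comparison ratio, and no line search.  Early stopping monitors the
validation cross-entropy with a patience counter; the weights at the best
validation loss are returned.

Features are z-scored with training-partition statistics stored on the
model, so prediction applies the same affine map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrainConfig",
    "NetworkModel",
    "init_network",
    "train_network",
    "predict_proba",
    "save_model_json",
    "load_model_json",
]

_SIGMA0 = 5.0e-5
_LAMBDA0 = 5.0e-7


@dataclass
class TrainConfig:
    """Training hyperparameters."""

    hidden_sizes: tuple = (10,)
    max_iter: int = 250
    patience: int = 10  # validation checks without improvement before stopping
    tol_grad: float = 1.0e-8
    seed: int = 0


@dataclass
class NetworkModel:
    """Weights plus the preprocessing and training trace."""

    layer_sizes: tuple  # (n_in, hidden..., 1)
    weights: list  # list of (W, b) per layer
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    trace: dict = field(default_factory=dict)  # loss curves, stop reason

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]


def _flatten(weights):
    return np.concatenate([a.ravel() for W, b in weights for a in (W, b)])


def _unflatten(vec, layer_sizes):
    weights = []
    pos = 0
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        W = vec[pos : pos + n_in * n_out].reshape(n_in, n_out)
        pos += n_in * n_out
        b = vec[pos : pos + n_out]
        pos += n_out
        weights.append((W, b))
    return weights


def _forward(weights, X):
    """Activations per layer; tanh hidden, sigmoid output."""
    acts = [X]
    h = X
    for li, (W, b) in enumerate(weights):
        z = h @ W + b
        if li < len(weights) - 1:
            h = np.tanh(z)
        else:
            h = 1.0 / (1.0 + np.exp(-np.clip(z, -35.0, 35.0)))
        acts.append(h)
    return acts


def _loss_grad(vec, layer_sizes, X, y, want_grad=True):
    """Mean binary cross-entropy and its gradient in flattened coordinates."""
    weights = _unflatten(vec, layer_sizes)
    acts = _forward(weights, X)
    p = acts[-1][:, 0]
    eps = 1.0e-12
    n = X.shape[0]
    loss = -np.mean(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps))
    if not want_grad:
        return loss, None
    # output delta for sigmoid + cross-entropy
    delta = (p - y)[:, None] / n
    grads = [None] * len(weights)
    for li in range(len(weights) - 1, -1, -1):
        W, b = weights[li]
        a_prev = acts[li]
        grads[li] = (a_prev.T @ delta, delta.sum(axis=0))
        if li > 0:
            delta = (delta @ W.T) * (1.0 - acts[li] ** 2)
    return loss, _flatten(grads)


def init_network(n_inputs: int, hidden_sizes=(10,), seed: int = 0) -> list:
    """Seeded Glorot-style initial weights for a (n_in, hidden..., 1) net."""
    rng = np.random.default_rng(seed)
    sizes = (n_inputs, *hidden_sizes, 1)
    weights = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / (n_in + n_out))
        weights.append((scale * rng.standard_normal((n_in, n_out)), np.zeros(n_out)))
    return weights


def _scg_minimize(f, w0, max_iter, tol_grad, callback=None):
    """Moller's scaled conjugate gradient on f(w) -> (loss, grad).

    Returns (w, losses, stop_reason).  `callback(k, w, loss)` may return
    True to request a stop (used for validation patience).
    """
    w = w0.copy()
    N = w.size
    loss, grad = f(w)
    r = -grad
    p = r.copy()
    lam = _LAMBDA0
    lam_bar = 0.0
    success = True
    delta = 1.0
    losses = [loss]
    stop = "max_iter"
    for k in range(1, max_iter + 1):
        p2 = p @ p
        if p2 < 1e-300:
            stop = "converged"
            break
        pnorm = np.sqrt(p2)
        if success:
            sigma = _SIGMA0 / pnorm
            _, grad_s = f(w + sigma * p)
            s = (grad_s - grad) / sigma
            delta = p @ s
        # scale the (approximate) Hessian
        delta = delta + (lam - lam_bar) * p2
        if delta <= 0.0:  # make the Hessian positive definite
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = p @ r
        alpha = mu / delta
        loss_new, grad_new = f(w + alpha * p)
        Delta = 2.0 * delta * (loss - loss_new) / (mu * mu)
        if Delta >= 0.0:  # successful step
            w = w + alpha * p
            loss = loss_new
            grad = grad_new
            r_new = -grad
            lam_bar = 0.0
            success = True
            if k % N == 0:  # restart
                p = r_new.copy()
            else:
                beta = (r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= 0.75:
                lam = 0.25 * lam
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam = lam + delta * (1.0 - Delta) / p2
        losses.append(loss)
        if np.linalg.norm(grad) < tol_grad:
            stop = "gradient"
            break
        if callback is not None and callback(k, w, loss):
            stop = "early_stop"
            break
    return w, losses, stop


def train_network(
    X_train,
    y_train,
    X_val=None,
    y_val=None,
    config: TrainConfig = None,
) -> NetworkModel:
    """Fit the classifier; returns the model at the best validation loss."""
    config = config or TrainConfig()
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64).ravel()
    if not np.all(np.isfinite(X_train)):
        raise ValueError("non-finite features")
    classes = np.unique(y_train)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    if classes.size < 2:
        raise ValueError("training partition must contain both classes")

    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X_train - mean) / std
    has_val = X_val is not None and len(X_val) > 0
    if has_val:
        Xv = (np.asarray(X_val, dtype=np.float64) - mean) / std
        yv = np.asarray(y_val, dtype=np.float64).ravel()

    layer_sizes = (X_train.shape[1], *config.hidden_sizes, 1)
    w0 = _flatten(init_network(X_train.shape[1], config.hidden_sizes, config.seed))

    state = {"best_w": w0.copy(), "best_val": np.inf, "fails": 0, "val_losses": []}

    def callback(k, w, loss):
        if not has_val:
            return False
        val_loss, _ = _loss_grad(w, layer_sizes, Xv, yv, want_grad=False)
        state["val_losses"].append(val_loss)
        if val_loss < state["best_val"] - 1e-12:
            state["best_val"] = val_loss
            state["best_w"] = w.copy()
            state["fails"] = 0
        else:
            state["fails"] += 1
        return state["fails"] >= config.patience

    f = lambda w: _loss_grad(w, layer_sizes, Xs, y_train)
    w_final, losses, stop = _scg_minimize(
        f, w0, config.max_iter, config.tol_grad, callback
    )
    if has_val and np.isfinite(state["best_val"]):
        w_final = state["best_w"]
    return NetworkModel(
        layer_sizes=layer_sizes,
        weights=_unflatten(w_final, layer_sizes),
        scaler_mean=mean,
        scaler_std=std,
        trace={
            "train_loss": losses,
            "val_loss": state["val_losses"],
            "stop_reason": stop,
            "n_iter": len(losses) - 1,
        },
    )


def predict_proba(model: NetworkModel, X) -> np.ndarray:
    """Per-row progression probability in (0, 1)."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model input {model.n_inputs}"
        )
    Xs = (X - model.scaler_mean) / model.scaler_std
    p = _forward(model.weights, Xs)[-1][:, 0]
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return p[0] if single else p


def save_model_json(model: NetworkModel, path):
    """Serialize architecture, scaler and weights as JSON."""
    obj = {
        "layer_sizes": list(model.layer_sizes),
        "weights": [[W.tolist(), b.tolist()] for W, b in model.weights],
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_std": model.scaler_std.tolist(),
        "trace": {
            k: (list(map(float, v)) if isinstance(v, (list, tuple)) else v)
            for k, v in model.trace.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_model_json(path) -> NetworkModel:
    with open(path) as fh:
        obj = json.load(fh)
    return NetworkModel(
        layer_sizes=tuple(obj["layer_sizes"]),
        weights=[(np.array(W), np.array(b)) for W, b in obj["weights"]],
        scaler_mean=np.array(obj["scaler_mean"]),
        scaler_std=np.array(obj["scaler_std"]),
        trace=obj.get("trace", {}),
    )
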