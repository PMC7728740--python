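"""Bayesian-regularized feed-forward networks trained by Levenberg-Marquardt.

The network minimizes F(w) = beta * E_D + alpha * w'w, with E_D the summed
squared error and the weight penalty acting as a Gaussian prior on the
weights. After every accepted LM step the regularization pair (alpha, beta) is
re-estimated from the evidence framework: the effective number of parameters
gamma_eff = k - 2 alpha tr(H^-1) (H = beta * grad2(E_D) + 2 alpha I) measures
how many of the k weights the data actually determine, and
alpha <- gamma_eff / (2 E_W), beta <- (n - gamma_eff) / (2 E_D) with
E_W = 0.5 w'w. A pure-noise target therefore drives gamma_eff toward zero
(heavy smoothing) while informative targets keep weights alive.

Ten named presets (brnn1..brnn10) cover the 1-3 layer x {purelin, logsig,
tansig} grid; the final output unit is always a single linear neuron.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BrnnConfig",
    "TrainedBrnn",
    "BRNN_PRESETS",
    "activation_eval",
    "train_brnn",
    "predict_net",
    "brnn_preset",
]

BRNN_PRESETS: dict[str, list[tuple[int, str]]] = {
    "brnn1": [(1, "purelin")],
    "brnn2": [(1, "logsig")],
    "brnn3": [(1, "tansig")],
    "brnn4": [(2, "purelin"), (1, "purelin")],
    "brnn5": [(2, "logsig"), (1, "logsig")],
    "brnn6": [(2, "tansig"), (1, "tansig")],
    "brnn7": [(2, "tansig"), (1, "purelin")],
    "brnn8": [(2, "logsig"), (1, "purelin")],
    "brnn9": [(2, "tansig"), (2, "logsig"), (1, "purelin")],
    "brnn10": [(2, "logsig"), (2, "tansig"), (1, "purelin")],
}


def activation_eval(kind: str, x):
    """purelin(x) = x; logsig(x) = 1/(1+e^-x); tansig(x) = 2/(1+e^-2x) - 1."""
    x = np.asarray(x, dtype=float)
    if kind == "purelin":
        return x
    if kind == "logsig":
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out
    if kind == "tansig":
        return np.tanh(x)  # tansig(x) = 2/(1+e^-2x)-1 = tanh(x)
    raise ValueError(f"unknown activation {kind!r}")


def _activation_deriv(kind: str, a: np.ndarray) -> np.ndarray:
    """Derivative expressed through the activation value a."""
    if kind == "purelin":
        return np.ones_like(a)
    if kind == "logsig":
        return a * (1.0 - a)
    if kind == "tansig":
        return 1.0 - a**2
    raise ValueError(f"unknown activation {kind!r}")


@dataclass
class BrnnConfig:
    architecture: list[tuple[int, str]]
    alpha: float = 0.01
    beta: float = 1.0
    max_epochs: int = 1000
    lm_damping: float = 1e-2
    seed: int = 0
    input_scaling: bool = True
    weight_cap: int = 20_000  # exact LM is quadratic in the weight count

    def __post_init__(self) -> None:
        if not self.architecture:
            raise ValueError("at least one hidden layer required")
        for units, act in self.architecture:
            if units < 1:
                raise ValueError("layer sizes must be >= 1")
            activation_eval(act, 0.0)  # validates the name


@dataclass
class TrainedBrnn:
    """Weights, scaling constants and the per-epoch evidence trace."""

    config: BrnnConfig
    weights: list[np.ndarray]  # per layer, incl. output; shape (fan_in, units)
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    trace: dict = field(repr=False, default_factory=dict)

    @property
    def n_weights(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict_net(self, X_new)

    def to_json(self) -> str:
        return json.dumps(
            {
                "architecture": self.config.architecture,
                "weights": [w.tolist() for w in self.weights],
                "biases": [b.tolist() for b in self.biases],
                "x_mean": self.x_mean.tolist(),
                "x_std": self.x_std.tolist(),
                "y_mean": self.y_mean,
                "y_std": self.y_std,
            }
        )


def brnn_preset(name: str) -> list[tuple[int, str]]:
    try:
        return list(BRNN_PRESETS[name])
    except KeyError:
        raise ValueError(f"unknown BRNN preset {name!r}") from None


def _init_weights(cfg: BrnnConfig, p: int, rng) -> tuple[list, list]:
    """Nguyen-Widrow-style seeded initialization (rows rescaled to a fan-in norm)."""
    acts = list(cfg.architecture) + [(1, "purelin")]
    weights, biases = [], []
    fan_in = p
    for units, _ in acts:
        W = rng.uniform(-1.0, 1.0, size=(fan_in, units))
        norm = np.sqrt(np.sum(W**2, axis=0, keepdims=True))
        scale = 0.7 * units ** (1.0 / max(fan_in, 1))
        W = scale * W / np.maximum(norm, 1e-12)
        b = rng.uniform(-scale, scale, size=units)
        weights.append(W)
        biases.append(b)
        fan_in = units
    return weights, biases


def _forward(weights, biases, acts, X):
    """Activations per layer (input first); final entry is the linear output."""
    A = [X]
    for (W, b), act in zip(zip(weights, biases), acts):
        A.append(activation_eval(act, A[-1] @ W + b))
    return A


def _jacobian(weights, acts, A):
    """d yhat / d w, vectorized over samples; column order matches _pack."""
    n = A[0].shape[0]
    L = len(weights)
    deltas = [None] * L
    deltas[L - 1] = np.ones((n, 1))
    for l in range(L - 2, -1, -1):
        d_next = deltas[l + 1] * _activation_deriv(acts[l + 1], A[l + 2])
        deltas[l] = d_next @ weights[l + 1].T
    cols = []
    for l in range(L):
        dl = deltas[l] * _activation_deriv(acts[l], A[l + 1])
        cols.append(np.einsum("ni,nj->nij", A[l], dl).reshape(n, -1))
        cols.append(dl)
    return np.concatenate(cols, axis=1)


def _pack(weights, biases):
    return np.concatenate(
        [np.concatenate([W.ravel(), b.ravel()]) for W, b in zip(weights, biases)]
    )


def _unpack(vec, weights, biases):
    out_w, out_b = [], []
    off = 0
    for W, b in zip(weights, biases):
        out_w.append(vec[off : off + W.size].reshape(W.shape))
        off += W.size
        out_b.append(vec[off : off + b.size])
        off += b.size
    return out_w, out_b


def train_brnn(X: np.ndarray, y: np.ndarray, cfg: BrnnConfig) -> TrainedBrnn:
    """Train by LM on the Gauss-Newton approximation with evidence updates."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 training samples")
    rng = np.random.default_rng(cfg.seed)

    if cfg.input_scaling:
        x_mean = X.mean(axis=0)
        x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    else:
        x_mean = np.zeros(p)
        x_std = np.ones(p)
    Xs = (X - x_mean) / x_std
    y_mean = float(y.mean())
    y_std = float(y.std()) or 1.0
    ys = (y - y_mean) / y_std

    acts = [a for _, a in cfg.architecture] + ["purelin"]
    weights, biases = _init_weights(cfg, p, rng)
    k = sum(W.size + b.size for W, b in zip(weights, biases))
    if k > cfg.weight_cap:
        raise ValueError(
            f"{k} weights exceeds the exact-LM cap ({cfg.weight_cap}); "
            "reduce the input dimension (e.g. a marker subset) or raise weight_cap"
        )

    alpha, beta = float(cfg.alpha), float(cfg.beta)
    mu_lm = float(cfg.lm_damping)
    w = _pack(weights, biases)

    def objective(wvec):
        ws, bs = _unpack(wvec, weights, biases)
        A = _forward(ws, bs, acts, Xs)
        r = A[-1].ravel() - ys
        E_D = float(r @ r)
        E_W = 0.5 * float(wvec @ wvec)
        return beta * E_D + 2.0 * alpha * E_W, r, A, ws, bs

    F, r, A, ws, bs = objective(w)
    trace = {"objective": [], "objective_before": [], "E_D": [], "E_W": [],
             "gamma_eff": [], "accepted": []}
    for _ in range(cfg.max_epochs):
        J = _jacobian(ws, acts, A)
        grad = 2.0 * beta * (J.T @ r) + 2.0 * alpha * w
        if not np.isfinite(F) or not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite objective or gradient in BRNN training")
        if np.linalg.norm(grad) < 1e-8:
            break
        JTJ = J.T @ J
        H = 2.0 * beta * JTJ + 2.0 * alpha * np.eye(k)
        # Up to a few accepted LM steps at fixed (alpha, beta), with a
        # trust-region quality test: Gauss-Newton is exact along the
        # weight-rescaling directions of purelin nets but blind to their
        # bilinear curvature, so a plain F_new < F test can accept long
        # near-flat steps and stall. Require actual/predicted reduction
        # >= 0.25 (raising the damping otherwise).
        accepted = False
        F_before = F
        for _ in range(5):
            took_step = False
            for _ in range(40):
                try:
                    step = np.linalg.solve(H + mu_lm * np.eye(k), -grad)
                except np.linalg.LinAlgError:
                    mu_lm *= 10.0
                    continue
                F_new, r_new, A_new, ws_new, bs_new = objective(w + step)
                pred_red = -(grad @ step) - 0.5 * (step @ (H @ step))
                rho = (F - F_new) / max(pred_red, 1e-300)
                if F_new < F and rho > 0.25:
                    w = w + step
                    F, r, A, ws, bs = F_new, r_new, A_new, ws_new, bs_new
                    mu_lm = max(mu_lm / 10.0, 1e-12)
                    accepted = True
                    took_step = True
                    break
                mu_lm *= 10.0
                if mu_lm > 1e10:
                    break
            if not took_step or mu_lm > 1e10:
                break
            J = _jacobian(ws, acts, A)
            grad = 2.0 * beta * (J.T @ r) + 2.0 * alpha * w
            if np.linalg.norm(grad) < 1e-8:
                break
            H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * np.eye(k)

        E_D = float(r @ r)
        E_W = 0.5 * float(w @ w)
        F_after_step = F
        if accepted:
            # evidence update at the new weights
            J = _jacobian(ws, acts, A)
            H_ev = 2.0 * beta * (J.T @ J) + 2.0 * alpha * np.eye(k)
            gamma_eff = k - 2.0 * alpha * float(np.trace(np.linalg.inv(H_ev)))
            alpha = gamma_eff / max(2.0 * E_W, 1e-12)
            alpha = float(np.clip(alpha, 1e-12, 1e10))
            beta = (n - gamma_eff) / max(2.0 * E_D, 1e-12)
            beta = float(np.clip(beta, 1e-12, 1e10))
            F, r, A, ws, bs = objective(w)  # F at the updated (alpha, beta)
        else:
            gamma_eff = trace["gamma_eff"][-1] if trace["gamma_eff"] else float(k)
        trace["objective"].append(F_after_step)
        trace["objective_before"].append(F_before)
        trace["E_D"].append(E_D)
        trace["E_W"].append(E_W)
        trace["gamma_eff"].append(gamma_eff)
        trace["accepted"].append(accepted)
        if not accepted and mu_lm > 1e10:
            break

    return TrainedBrnn(
        config=cfg,
        weights=ws,
        biases=bs,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        trace={kk: np.asarray(v) for kk, v in trace.items()},
    )


def predict_net(net: TrainedBrnn, X_new: np.ndarray) -> np.ndarray:
    """Deterministic forward pass with the training scaling constants."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != net.x_mean.size:
        raise ValueError(
            f"expected {net.x_mean.size} input columns, got {X_new.shape}"
        )
    Xs = (X_new - net.x_mean) / net.x_std
    acts = [a for _, a in net.config.architecture] + ["purelin"]
    A = _forward(net.weights, net.biases, acts, Xs)
    return A[-1].ravel() * net.y_std + net.y_mean
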