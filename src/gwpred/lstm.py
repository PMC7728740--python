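"""LSTM regression on SNP genotypes, in plain NumPy with analytic BPTT.

Each individual's SNP vector is chunked in genome order into a sequence of
``ceil(p / chunk_size)`` steps of ``chunk_size`` features (zero-padded last
chunk); the final hidden state feeds a scalar linear head. The cell follows
the standard gate equations with the learnable input weights W, recurrent
weights R and bias b concatenated over the four components (input gate i,
forget gate f, cell candidate g, output gate o):

    i,f,o = sigmoid(W x_t + R h_{t-1} + b)        (their row blocks)
    g     = act(W x_t + R h_{t-1} + b)
    C_t   = f * C_{t-1} + i * g
    h_t   = o * act(C_t)

``act`` is the state activation: tanh by default, or ReLU (the variant that
also initializes the cell-candidate recurrent block to the identity and all
biases to zero). Training is mini-batch Adam on the mean squared error with
gradient-norm clipping; gradients are hand-derived reverse-mode and are
validated against central finite differences in the test suite.

Presets lstm1..lstm6 span {ReLU, Tanh} x mini-batch {10%, 50%, 100%}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LstmConfig",
    "LstmParameters",
    "TrainedLstm",
    "LSTM_PRESETS",
    "lstm_cell_step",
    "train_lstm",
    "predict_lstm",
    "lstm_preset",
    "loss_and_gradients",
]

LSTM_PRESETS: dict[str, tuple[str, float]] = {
    "lstm1": ("relu", 0.1),
    "lstm2": ("tanh", 0.1),
    "lstm3": ("relu", 0.5),
    "lstm4": ("tanh", 0.5),
    "lstm5": ("relu", 1.0),
    "lstm6": ("tanh", 1.0),
}


def lstm_preset(name: str, **kw) -> "LstmConfig":
    try:
        act, frac = LSTM_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown LSTM preset {name!r}") from None
    return LstmConfig(state_activation=act, minibatch_fraction=frac, **kw)


@dataclass
class LstmConfig:
    hidden_units: int = 32
    state_activation: str = "tanh"  # tanh | relu
    minibatch_fraction: float = 1.0
    chunk_size: int = 100
    epochs: int = 100
    learning_rate: float = 0.005
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if not 0.0 < self.minibatch_fraction <= 1.0:
            raise ValueError("minibatch_fraction must be in (0, 1]")
        if self.state_activation not in ("tanh", "relu"):
            raise ValueError("state_activation must be 'tanh' or 'relu'")


@dataclass
class LstmParameters:
    """Gate-concatenated parameters: rows of W/R/b are blocks (i, f, g, o)."""

    W: np.ndarray  # (4H, F) input weights
    R: np.ndarray  # (4H, H) recurrent weights
    b: np.ndarray  # (4H,)
    w_out: np.ndarray  # (H,)
    b_out: float

    def __post_init__(self) -> None:
        H4, F = self.W.shape
        if H4 % 4:
            raise ValueError("W must have 4*hidden rows")
        H = H4 // 4
        if self.R.shape != (H4, H) or self.b.shape != (H4,) or self.w_out.shape != (H,):
            raise ValueError("inconsistent gate-concatenated parameter shapes")

    @property
    def hidden(self) -> int:
        return self.W.shape[0] // 4

    def copy(self) -> "LstmParameters":
        return LstmParameters(
            self.W.copy(), self.R.copy(), self.b.copy(), self.w_out.copy(), self.b_out
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    neg = ~pos
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[neg])
    out[neg] = ex / (1.0 + ex)
    return out


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(x) if kind == "tanh" else np.maximum(x, 0.0)


def _act_deriv_from_input(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        t = np.tanh(x)
        return 1.0 - t * t
    return (x > 0).astype(float)


def lstm_cell_step(
    params: LstmParameters,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    C_prev: np.ndarray,
    state_activation: str = "tanh",
) -> tuple[np.ndarray, np.ndarray]:
    """One cell update; accepts a single vector or a (batch, features) block."""
    x = np.atleast_2d(np.asarray(x_t, dtype=float))
    h = np.atleast_2d(np.asarray(h_prev, dtype=float))
    C = np.atleast_2d(np.asarray(C_prev, dtype=float))
    H = params.hidden
    if x.shape[1] != params.W.shape[1] or h.shape[1] != H or C.shape[1] != H:
        raise ValueError("dimension mismatch in lstm_cell_step")
    z = x @ params.W.T + h @ params.R.T + params.b
    i = _sigmoid(z[:, 0:H])
    f = _sigmoid(z[:, H : 2 * H])
    g = _act(z[:, 2 * H : 3 * H], state_activation)
    o = _sigmoid(z[:, 3 * H : 4 * H])
    C_t = f * C + i * g
    h_t = o * _act(C_t, state_activation)
    if np.asarray(x_t).ndim == 1:
        return h_t[0], C_t[0]
    return h_t, C_t


def _to_sequence(X: np.ndarray, chunk: int) -> np.ndarray:
    """(n, p) -> (n, T, chunk) with the last chunk zero-padded."""
    n, p = X.shape
    T = -(-p // chunk)
    pad = T * chunk - p
    if pad:
        X = np.concatenate([X, np.zeros((n, pad))], axis=1)
    return X.reshape(n, T, chunk)


def _forward_seq(params: LstmParameters, Xseq: np.ndarray, act: str):
    """Full forward pass; returns predictions and per-step caches for BPTT."""
    n, T, F = Xseq.shape
    H = params.hidden
    h = np.zeros((n, H))
    C = np.zeros((n, H))
    cache = []
    for t in range(T):
        x = Xseq[:, t, :]
        z = x @ params.W.T + h @ params.R.T + params.b
        i = _sigmoid(z[:, 0:H])
        f = _sigmoid(z[:, H : 2 * H])
        zg = z[:, 2 * H : 3 * H]
        g = _act(zg, act)
        o = _sigmoid(z[:, 3 * H : 4 * H])
        C_new = f * C + i * g
        aC = _act(C_new, act)
        h_new = o * aC
        cache.append((x, h, C, i, f, g, o, zg, C_new, aC))
        h, C = h_new, C_new
    yhat = h @ params.w_out + params.b_out
    return yhat, h, cache


def loss_and_gradients(
    params: LstmParameters, Xseq: np.ndarray, y: np.ndarray, act: str
) -> tuple[float, LstmParameters]:
    """Mean-squared-error loss and its analytic gradients (as an LstmParameters)."""
    n, T, F = Xseq.shape
    H = params.hidden
    yhat, h_T, cache = _forward_seq(params, Xseq, act)
    r = yhat - y
    loss = float(np.mean(r**2))
    dyhat = 2.0 * r / n

    gW = np.zeros_like(params.W)
    gR = np.zeros_like(params.R)
    gb = np.zeros_like(params.b)
    g_wout = h_T.T @ dyhat
    g_bout = float(np.sum(dyhat))

    dh = dyhat[:, None] * params.w_out
    dC_next = np.zeros((n, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, C_prev, i, f, g, o, zg, C_new, aC = cache[t]
        do = dh * aC
        dC = dC_next + dh * o * _act_deriv_from_input(C_new, act)
        di = dC * g
        df = dC * C_prev
        dg = dC * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * _act_deriv_from_input(zg, act),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        gW += dz.T @ x
        gR += dz.T @ h_prev
        gb += dz.sum(axis=0)
        dh = dz @ params.R
        dC_next = dC * f
    return loss, LstmParameters(gW, gR, gb, g_wout, g_bout)


def _init_params(cfg: LstmConfig, F: int, rng) -> LstmParameters:
    H = cfg.hidden_units

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, size=shape)

    W = glorot((4 * H, F))
    R = glorot((4 * H, H))
    b = np.zeros(4 * H)
    if cfg.state_activation == "relu":
        # IRNN-style: identity recurrent block for the cell candidate, zero biases
        R[2 * H : 3 * H, :] = np.eye(H)
    else:
        b[H : 2 * H] = 1.0  # forget-gate bias, standard for tanh LSTMs
    w_out = glorot((H, 1)).ravel()
    return LstmParameters(W, R, b, w_out, 0.0)


@dataclass
class TrainedLstm:
    """Trained parameters plus scaling constants and the training trace."""

    config: LstmConfig
    params: LstmParameters
    n_markers: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    loss_trace: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    n_update_steps: int = 0

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict_lstm(self, X_new)

    def to_json(self) -> str:
        p = self.params
        return json.dumps(
            {
                "hidden_units": self.config.hidden_units,
                "state_activation": self.config.state_activation,
                "chunk_size": self.config.chunk_size,
                "W": p.W.tolist(),
                "R": p.R.tolist(),
                "b": p.b.tolist(),
                "w_out": p.w_out.tolist(),
                "b_out": p.b_out,
                "x_mean": self.x_mean.tolist(),
                "x_std": self.x_std.tolist(),
                "y_mean": self.y_mean,
                "y_std": self.y_std,
            }
        )


def train_lstm(X: np.ndarray, y: np.ndarray, cfg: LstmConfig) -> TrainedLstm:
    """Mini-batch Adam training of the LSTM regression head.

    Batches of size ceil(fraction * n) are drawn by partitioning a fresh
    shuffle each epoch, so larger fractions mean fewer update steps per epoch.
    Raises on a non-finite loss (exploding gradients after clipping).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(cfg.seed)

    x_mean = X.mean(axis=0)
    x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Xs = (X - x_mean) / x_std
    y_mean = float(y.mean())
    y_std = float(y.std()) or 1.0
    ys = (y - y_mean) / y_std
    Xseq = _to_sequence(Xs, cfg.chunk_size)

    params = _init_params(cfg, cfg.chunk_size, rng)
    m = params.copy()
    v = params.copy()
    for fld in ("W", "R", "b", "w_out"):
        getattr(m, fld)[:] = 0.0
        getattr(v, fld)[:] = 0.0
    m.b_out = 0.0
    v.b_out = 0.0

    lr, b1, b2, eps = cfg.learning_rate, 0.9, 0.999, 1e-8
    batch = int(np.ceil(cfg.minibatch_fraction * n))
    step = 0
    losses = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            loss, grads = loss_and_gradients(params, Xseq[idx], ys[idx], cfg.state_activation)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite LSTM loss at epoch {epoch + 1} (exploding gradients)"
                )
            gnorm = np.sqrt(
                sum(float(np.sum(getattr(grads, f) ** 2)) for f in ("W", "R", "b", "w_out"))
                + grads.b_out**2
            )
            if cfg.grad_clip and gnorm > cfg.grad_clip:
                scale = cfg.grad_clip / gnorm
                for fld in ("W", "R", "b", "w_out"):
                    getattr(grads, fld)[:] *= scale
                grads.b_out *= scale
            step += 1
            for fld in ("W", "R", "b", "w_out"):
                g = getattr(grads, fld)
                mf, vf = getattr(m, fld), getattr(v, fld)
                mf[:] = b1 * mf + (1 - b1) * g
                vf[:] = b2 * vf + (1 - b2) * g**2
                mhat = mf / (1 - b1**step)
                vhat = vf / (1 - b2**step)
                getattr(params, fld)[:] -= lr * mhat / (np.sqrt(vhat) + eps)
            m.b_out = b1 * m.b_out + (1 - b1) * grads.b_out
            v.b_out = b2 * v.b_out + (1 - b2) * grads.b_out**2
            params.b_out -= lr * (m.b_out / (1 - b1**step)) / (
                np.sqrt(v.b_out / (1 - b2**step)) + eps
            )
            epoch_loss += loss * idx.size
            n_seen += idx.size
        losses.append(epoch_loss / n_seen)

    return TrainedLstm(
        config=cfg,
        params=params,
        n_markers=p,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        loss_trace=np.asarray(losses),
        n_update_steps=step,
    )


def predict_lstm(net: TrainedLstm, X_new: np.ndarray) -> np.ndarray:
    """Deterministic forward pass with the training scaling and chunking."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != net.n_markers:
        raise ValueError(f"expected {net.n_markers} markers, got {X_new.shape}")
    Xs = (X_new - net.x_mean) / net.x_std
    Xseq = _to_sequence(Xs, net.config.chunk_size)
    yhat, _, _ = _forward_seq(net.params, Xseq, net.config.state_activation)
    return yhat * net.y_std + net.y_mean
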