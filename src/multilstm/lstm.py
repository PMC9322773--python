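"""From-scratch LSTM forecaster for one-step-ahead prediction.

A single LSTM layer with input, forget and output gates plus a memory
cell, followed by a scalar linear head on the hidden state:

    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    cbar_t = tanh(W_c x_t + U_c h_{t-1} + b_c)
    c_t = f_t * c_{t-1} + i_t * cbar_t
    h_t = o_t * tanh(c_t)
    yhat_t = w_y . h_t + b_y

Training minimizes mean-squared error over sliding windows of a single
component series, by full-batch backpropagation through time with an
adaptive-moment (Adam) optimizer and global-norm gradient clipping.
Everything is plain numpy; gradients are hand-derived and are verified
against finite differences in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("multilstm")

__all__ = [
    "LSTMParams",
    "LSTMState",
    "TrainingConfig",
    "gate",
    "cell_step",
    "forward",
    "make_windows",
    "loss_and_gradients",
    "train",
    "train_on_windows",
    "forecast",
    "LSTMForecaster",
]

_GATE_NAMES = ("i", "f", "o", "c")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMParams:
    """Gate/cell weight matrices, biases, and the scalar output head.

    Each ``W`` maps the input x_t (dimension D), each ``U`` the previous
    hidden state h_{t-1} (dimension H).
    """

    W: dict[str, np.ndarray]  # name -> (H, D)
    U: dict[str, np.ndarray]  # name -> (H, H)
    b: dict[str, np.ndarray]  # name -> (H,)
    w_y: np.ndarray  # (H,)
    b_y: float
    hidden_size: int
    input_size: int = 1

    def __post_init__(self) -> None:
        H, D = self.hidden_size, self.input_size
        for k in _GATE_NAMES:
            if self.W[k].shape != (H, D) or self.U[k].shape != (H, H) or self.b[k].shape != (H,):
                raise ValueError(f"inconsistent shapes for gate {k!r}")
            for arr in (self.W[k], self.U[k], self.b[k]):
                if not np.all(np.isfinite(arr)):
                    raise ValueError("non-finite parameter values")
        if self.w_y.shape != (H,):
            raise ValueError("output head shape mismatch")

    @classmethod
    def initialize(cls, hidden_size: int, input_size: int = 1, seed: int = 0) -> "LSTMParams":
        """Uniform +-1/sqrt(H) weights, zero biases, forget bias 1."""
        rng = np.random.default_rng(seed)
        H, D = hidden_size, input_size
        s = 1.0 / np.sqrt(H)
        W = {k: rng.uniform(-s, s, size=(H, D)) for k in _GATE_NAMES}
        U = {k: rng.uniform(-s, s, size=(H, H)) for k in _GATE_NAMES}
        b = {k: np.zeros(H) for k in _GATE_NAMES}
        b["f"] = np.ones(H)  # standard forget-gate stabilizer
        w_y = rng.uniform(-s, s, size=H)
        return cls(W=W, U=U, b=b, w_y=w_y, b_y=0.0, hidden_size=H, input_size=D)

    def flatten(self) -> np.ndarray:
        parts = []
        for k in _GATE_NAMES:
            parts += [self.W[k].ravel(), self.U[k].ravel(), self.b[k]]
        parts += [self.w_y, np.array([self.b_y])]
        return np.concatenate(parts)

    def unflatten_into(self, theta: np.ndarray) -> None:
        H, D = self.hidden_size, self.input_size
        pos = 0

        def take(n, shape):
            nonlocal pos
            out = theta[pos:pos + n].reshape(shape)
            pos += n
            return out

        for k in _GATE_NAMES:
            self.W[k] = take(H * D, (H, D)).copy()
            self.U[k] = take(H * H, (H, H)).copy()
            self.b[k] = take(H, (H,)).copy()
        self.w_y = take(H, (H,)).copy()
        self.b_y = float(take(1, (1,))[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "hidden_size": self.hidden_size,
                "input_size": self.input_size,
                "theta": self.flatten().tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LSTMParams":
        d = json.loads(text)
        p = cls.initialize(d["hidden_size"], d["input_size"], seed=0)
        p.unflatten_into(np.asarray(d["theta"], dtype=float))
        return p


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray
    i: np.ndarray
    f: np.ndarray
    o: np.ndarray
    cbar: np.ndarray
    x: np.ndarray


@dataclass
class TrainingConfig:
    """Hyperparameters for per-component training.

    Window length L is short because component series built from
    12-point trajectories are short; the hidden size, learning rate and
    epoch count are modest defaults for full-batch Adam.
    """

    window: int = 3
    hidden_size: int = 32
    learning_rate: float = 1e-2
    epochs: int = 200
    seed: int = 0
    grad_clip: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window length must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def gate(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """sigmoid(W x + b): the generic gate map, values in (0, 1)."""
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if W.shape[1] != x.shape[0] or W.shape[0] != b.shape[0]:
        raise ValueError(
            f"shape mismatch: W {W.shape}, x {x.shape}, b {b.shape}"
        )
    return _sigmoid(W @ x + b)


def cell_step(
    params: LSTMParams, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
) -> LSTMState:
    """One LSTM cell update from (h_{t-1}, c_{t-1}) and input x_t."""
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    for arr in (x_t, h_prev, c_prev):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite cell input")
    i = _sigmoid(params.W["i"] @ x_t + params.U["i"] @ h_prev + params.b["i"])
    f = _sigmoid(params.W["f"] @ x_t + params.U["f"] @ h_prev + params.b["f"])
    o = _sigmoid(params.W["o"] @ x_t + params.U["o"] @ h_prev + params.b["o"])
    cbar = np.tanh(params.W["c"] @ x_t + params.U["c"] @ h_prev + params.b["c"])
    c = f * c_prev + i * cbar
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c, i=i, f=f, o=o, cbar=cbar, x=x_t)


def forward(
    params: LSTMParams, sequence
) -> tuple[list[LSTMState], np.ndarray]:
    """Unroll the cell over a sequence from zero initial state.

    Returns the per-step states and the scalar head prediction at every
    step (``w_y . h_t + b_y``).
    """
    seq = [np.atleast_1d(np.asarray(x, dtype=float)) for x in sequence]
    if len(seq) == 0:
        raise ValueError("empty input sequence")
    H = params.hidden_size
    h = np.zeros(H)
    c = np.zeros(H)
    states: list[LSTMState] = []
    preds = np.empty(len(seq))
    for t, x_t in enumerate(seq):
        st = cell_step(params, x_t, h, c)
        states.append(st)
        h, c = st.h, st.c
        preds[t] = float(params.w_y @ h) + params.b_y
    return states, preds


def make_windows(series, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding (input window, next value) pairs with stride 1.

    Returns ``(X, y)`` with ``X`` of shape (N-L, L) and ``y`` of shape
    (N-L,); window t covers ``series[t:t+L]`` and targets
    ``series[t+L]``.
    """
    s = np.asarray(series, dtype=float).ravel()
    n = s.size
    if n < L + 1:
        raise ValueError(f"series of length {n} too short for window {L}")
    X = np.lib.stride_tricks.sliding_window_view(s, L)[:-1].copy()
    y = s[L:].copy()
    return X, y


# ---------------------------------------------------------------------------
# Batched forward/backward over all windows (scalar inputs).


def _batch_forward(params: LSTMParams, X: np.ndarray):
    """Forward pass over a batch of scalar-input windows.

    X: (B, L).  Returns caches per step and final predictions (B,).
    """
    B, L = X.shape
    H = params.hidden_size
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in range(L):
        x = X[:, t:t + 1]  # (B, 1)
        zi = x @ params.W["i"].T + h @ params.U["i"].T + params.b["i"]
        zf = x @ params.W["f"].T + h @ params.U["f"].T + params.b["f"]
        zo = x @ params.W["o"].T + h @ params.U["o"].T + params.b["o"]
        zc = x @ params.W["c"].T + h @ params.U["c"].T + params.b["c"]
        i_g = _sigmoid(zi)
        f_g = _sigmoid(zf)
        o_g = _sigmoid(zo)
        cbar = np.tanh(zc)
        c_new = f_g * c + i_g * cbar
        tanh_c = np.tanh(c_new)
        h_new = o_g * tanh_c
        cache.append((x, h, c, i_g, f_g, o_g, cbar, tanh_c))
        h, c = h_new, c_new
    yhat = h @ params.w_y + params.b_y
    return cache, h, yhat


def loss_and_gradients(
    params: LSTMParams, X: np.ndarray, y: np.ndarray
) -> tuple[float, dict]:
    """MSE over windows and its analytic gradient w.r.t. all parameters.

    Backpropagation through time over the L unrolled steps; the head
    reads only the final hidden state of each window.
    """
    B, L = X.shape
    H = params.hidden_size
    cache, h_last, yhat = _batch_forward(params, X)
    err = yhat - y
    loss = float(np.mean(err ** 2))

    grads = {
        "W": {k: np.zeros_like(params.W[k]) for k in _GATE_NAMES},
        "U": {k: np.zeros_like(params.U[k]) for k in _GATE_NAMES},
        "b": {k: np.zeros_like(params.b[k]) for k in _GATE_NAMES},
        "w_y": np.zeros_like(params.w_y),
        "b_y": 0.0,
    }
    dyhat = 2.0 * err / B  # (B,)
    grads["w_y"] = h_last.T @ dyhat
    grads["b_y"] = float(np.sum(dyhat))
    dh = np.outer(dyhat, params.w_y)  # (B, H)
    dc = np.zeros((B, H))
    for t in range(L - 1, -1, -1):
        x, h_prev, c_prev, i_g, f_g, o_g, cbar, tanh_c = cache[t]
        do = dh * tanh_c
        dc_total = dc + dh * o_g * (1.0 - tanh_c ** 2)
        di = dc_total * cbar
        df = dc_total * c_prev
        dcbar = dc_total * i_g
        dzi = di * i_g * (1.0 - i_g)
        dzf = df * f_g * (1.0 - f_g)
        dzo = do * o_g * (1.0 - o_g)
        dzc = dcbar * (1.0 - cbar ** 2)
        for k, dz in zip(_GATE_NAMES, (dzi, dzf, dzo, dzc)):
            grads["W"][k] += dz.T @ x
            grads["U"][k] += dz.T @ h_prev
            grads["b"][k] += dz.sum(axis=0)
        dh = (
            dzi @ params.U["i"]
            + dzf @ params.U["f"]
            + dzo @ params.U["o"]
            + dzc @ params.U["c"]
        )
        dc = dc_total * f_g
    return loss, grads


def _grads_flatten(grads, H: int, D: int) -> np.ndarray:
    parts = []
    for k in _GATE_NAMES:
        parts += [grads["W"][k].ravel(), grads["U"][k].ravel(), grads["b"][k]]
    parts += [grads["w_y"], np.array([grads["b_y"]])]
    return np.concatenate(parts)


def train(series, config: TrainingConfig | None = None) -> tuple[LSTMParams, list[float]]:
    """Fit the forecaster to one component series by full-batch Adam.

    Returns the trained parameters and the per-epoch loss history.
    Raises ``RuntimeError`` naming the epoch if the loss turns
    non-finite.
    """
    cfg = config or TrainingConfig()
    X, y = make_windows(series, cfg.window)
    return train_on_windows(X, y, cfg)


def train_on_windows(
    X: np.ndarray, y: np.ndarray, config: TrainingConfig | None = None
) -> tuple[LSTMParams, list[float]]:
    """Fit on precomputed (window, target) pairs; see :func:`train`."""
    cfg = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] < 1:
        raise ValueError("windows and targets do not align")
    params = LSTMParams.initialize(cfg.hidden_size, 1, seed=cfg.seed)
    theta = params.flatten()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    history: list[float] = []
    for epoch in range(1, cfg.epochs + 1):
        params.unflatten_into(theta)
        loss, grads = loss_and_gradients(params, X, y)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        history.append(loss)
        g = _grads_flatten(grads, cfg.hidden_size, 1)
        norm = float(np.linalg.norm(g))
        if cfg.grad_clip > 0 and norm > cfg.grad_clip:
            g = g * (cfg.grad_clip / norm)
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** epoch)
        vhat = v / (1 - beta2 ** epoch)
        theta = theta - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
    params.unflatten_into(theta)
    return params, history


def forecast(
    params: LSTMParams,
    context,
    horizon: int,
    L: int,
    direction: str = "forward",
) -> np.ndarray:
    """Recursive one-step-ahead continuation of a series.

    ``forward`` continues past the end of the context; ``reverse``
    time-reverses the context, forecasts forward, and reverses the
    result — predicting values *before* the context from later ones.
    """
    ctx = np.asarray(context, dtype=float).ravel()
    if ctx.size < L:
        raise ValueError(f"context of length {ctx.size} shorter than window {L}")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "reverse":
        out = forecast(params, ctx[::-1], horizon, L, "forward")
        return out[::-1]
    buf = list(ctx)
    preds = []
    for _ in range(horizon):
        window = np.asarray(buf[-L:])
        _, p = forward(params, window)
        preds.append(float(p[-1]))
        buf.append(preds[-1])
    return np.asarray(preds)


class LSTMForecaster:
    """Trained per-component forecaster with a one-step interface.

    The pipeline trains one of these per decomposition component and
    asks each for the component value one step past a context window.
    """

    def __init__(self, params: LSTMParams, config: TrainingConfig, history: list[float]):
        self.params = params
        self.config = config
        self.history = history

    @classmethod
    def fit(cls, series, config: TrainingConfig) -> "LSTMForecaster":
        params, history = train(series, config)
        return cls(params, config, history)

    @classmethod
    def fit_windows(cls, X, y, config: TrainingConfig) -> "LSTMForecaster":
        params, history = train_on_windows(X, y, config)
        return cls(params, config, history)

    def predict_next(self, context, index: int | None = None) -> float:
        """Predict the value one step after ``context`` (last L used)."""
        out = forecast(self.params, context, 1, self.config.window, "forward")
        return float(out[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": json.loads(self.params.to_json()),
                "config": {
                    "window": self.config.window,
                    "hidden_size": self.config.hidden_size,
                    "learning_rate": self.config.learning_rate,
                    "epochs": self.config.epochs,
                    "seed": self.config.seed,
                    "grad_clip": self.config.grad_clip,
                },
                "history": self.history,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LSTMForecaster":
        d = json.loads(text)
        params = LSTMParams.from_json(json.dumps(d["params"]))
        config = TrainingConfig(**d["config"])
        return cls(params, config, list(d["history"]))
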