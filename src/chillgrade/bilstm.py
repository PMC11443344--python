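"""Bidirectional LSTM classifier over the selected feature vectors.

Each sample (the nine screened gray-image features, in feature order) is fed as
a sequence of scalar time steps to a forward and a backward LSTM cell with the
usual input/forget/output gates and cell state:

    i_t = sigma(W_i [x_t, h_{t-1}] + b_i)        input gate
    f_t = sigma(W_f [x_t, h_{t-1}] + b_f)        forget gate
    g_t = tanh (W_g [x_t, h_{t-1}] + b_g)        candidate cell state
    o_t = sigma(W_o [x_t, h_{t-1}] + b_o)        output gate
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

The last forward hidden state and the last backward hidden state (the two
direction-final summaries) are concatenated and passed through a dense softmax
head over the four severity grades; the fixed combination weights of the two
directions are subsumed by the head.  Training minimizes cross-entropy plus an
L2 weight penalty with full-batch Adam, gradient clipping at global norm 1 and
a single learning-rate drop at mid-training.  The whole stack is plain numpy
with hand-written backpropagation-through-time; gradients are validated against
finite differences in the test suite.

``tune_with_dbo`` wraps the dung-beetle optimizer around the three
hyperparameters the grid is worst at: learning rate, hidden size and the L2
coefficient (rates searched on log10 scale since the ranges span three orders
of magnitude).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .dbo import DBOConfig, optimize

__all__ = ["CLASSES", "BiLSTMConfig", "BiLSTMModel", "build", "train", "predict",
           "tune_with_dbo", "DEFAULT_SEARCH_BOUNDS"]

CLASSES = ("A", "B", "C", "D")

#: DBO search box: log10 learning rate, hidden units, log10 L2 coefficient
DEFAULT_SEARCH_BOUNDS = ((-4.0, -1.0), (5.0, 100.0), (-4.0, -1.0))


@dataclass(frozen=True)
class BiLSTMConfig:
    """Training hyperparameters (baseline values; DBO searches lr/hidden/l2)."""

    hidden_units: int = 200
    learning_rate: float = 0.001
    l2: float = 0.001
    max_epochs: int = 500
    lr_drop_factor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.learning_rate <= 0 or self.l2 < 0:
            raise ValueError("rates must be positive")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


_WEIGHT_KEYS = ("Wx_f", "Wh_f", "Wx_b", "Wh_b", "Wo")
_BIAS_KEYS = ("b_f", "b_b", "bo")


class BiLSTMModel:
    """Forward + backward LSTM cells with a dense softmax head (numpy)."""

    def __init__(self, config: BiLSTMConfig, input_len: int = 9, n_classes: int = 4):
        self.config = config
        self.input_len = int(input_len)
        self.n_classes = int(n_classes)
        self.norm_mean = np.zeros(input_len)
        self.norm_sd = np.ones(input_len)
        rng = np.random.default_rng(config.seed)
        h = config.hidden_units

        def glorot(fan_in, fan_out, shape):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        self.params = {}
        for d in ("f", "b"):
            self.params[f"Wx_{d}"] = glorot(1 + h, 4 * h, (1, 4 * h))
            self.params[f"Wh_{d}"] = glorot(1 + h, 4 * h, (h, 4 * h))
            bias = np.zeros(4 * h)
            bias[h:2 * h] = 1.0          # forget-gate bias opens the cell early
            self.params[f"b_{d}"] = bias
        self.params["Wo"] = glorot(2 * h, n_classes, (2 * h, n_classes))
        self.params["bo"] = np.zeros(n_classes)

    # -- forward / backward -------------------------------------------------
    def _run_direction(self, x_seq, d):
        """x_seq: (n, L) already direction-ordered. Returns last h and caches."""
        n, length = x_seq.shape
        h_dim = self.config.hidden_units
        wx, wh, b = (self.params[f"Wx_{d}"], self.params[f"Wh_{d}"],
                     self.params[f"b_{d}"])
        h = np.zeros((n, h_dim))
        c = np.zeros((n, h_dim))
        caches = []
        for t in range(length):
            x_t = x_seq[:, t:t + 1]
            z = x_t @ wx + h @ wh + b
            i = _sigmoid(z[:, :h_dim])
            f = _sigmoid(z[:, h_dim:2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim:3 * h_dim])
            o = _sigmoid(z[:, 3 * h_dim:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            caches.append((x_t, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        return h, caches

    def _backprop_direction(self, dh_last, caches, d, grads):
        h_dim = self.config.hidden_units
        wh = self.params[f"Wh_{d}"]
        dh, dc = dh_last, np.zeros_like(dh_last)
        for x_t, h_prev, c_prev, i, f, g, o, c_new in reversed(caches):
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c * o * (1 - o)
            dct = dh * o * (1 - tanh_c**2) + dc
            di = dct * g * i * (1 - i)
            df = dct * c_prev * f * (1 - f)
            dg = dct * i * (1 - g**2)
            dc = dct * f
            dz = np.concatenate([di, df, dg, do], axis=1)
            grads[f"Wx_{d}"] += x_t.T @ dz
            grads[f"Wh_{d}"] += h_prev.T @ dz
            grads[f"b_{d}"] += dz.sum(axis=0)
            dh = dz @ wh.T
        return grads

    def _normalize(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.input_len:
            raise ValueError(
                f"expected feature vectors of length {self.input_len}, got {x.shape}")
        return (x - self.norm_mean) / self.norm_sd

    def forward(self, x, raw=False):
        """Class probabilities (n, n_classes); ``raw`` skips normalization."""
        xn = np.asarray(x, dtype=float) if raw else self._normalize(x)
        h_f, _ = self._run_direction(xn, "f")
        h_b, _ = self._run_direction(xn[:, ::-1], "b")
        rep = np.concatenate([h_f, h_b], axis=1)
        return _softmax(rep @ self.params["Wo"] + self.params["bo"])

    def loss_and_grads(self, xn, y_idx):
        """Mean cross-entropy + L2 penalty and gradients for all parameters."""
        n = xn.shape[0]
        h_f, caches_f = self._run_direction(xn, "f")
        h_b, caches_b = self._run_direction(xn[:, ::-1], "b")
        rep = np.concatenate([h_f, h_b], axis=1)
        probs = _softmax(rep @ self.params["Wo"] + self.params["bo"])
        ce = -np.mean(np.log(probs[np.arange(n), y_idx] + 1e-12))
        l2 = self.config.l2
        penalty = 0.5 * l2 * sum(np.sum(self.params[k] ** 2) for k in _WEIGHT_KEYS)

        dlogits = probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wo"] = rep.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        drep = dlogits @ self.params["Wo"].T
        h_dim = self.config.hidden_units
        self._backprop_direction(drep[:, :h_dim], caches_f, "f", grads)
        self._backprop_direction(drep[:, h_dim:], caches_b, "b", grads)
        for k in _WEIGHT_KEYS:
            grads[k] += l2 * self.params[k]
        return ce + penalty, grads


def build(config: BiLSTMConfig, input_len: int = 9) -> BiLSTMModel:
    """Seeded, randomly initialized model over length-``input_len`` sequences."""
    return BiLSTMModel(config, input_len=input_len)


def _labels_to_idx(y):
    lut = {c: k for k, c in enumerate(CLASSES)}
    try:
        return np.array([lut[v] if isinstance(v, str) else int(v) for v in y])
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from None


def train(model: BiLSTMModel, x, y, config: BiLSTMConfig | None = None):
    """Fit the model with full-batch Adam; returns ``(model, loss_history)``.

    The learning rate is multiplied by ``lr_drop_factor`` once at epoch
    ``ceil(max_epochs/2)``.  Feature standardization statistics are fitted here
    and re-applied at prediction time.  All four classes must be present.
    """
    config = config or model.config
    y_idx = _labels_to_idx(y)
    if len(np.unique(y_idx)) < model.n_classes:
        raise ValueError("every class must be present in the training labels")
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 8:
        raise ValueError("need at least 8 training samples")
    model.norm_mean = x.mean(axis=0)
    model.norm_sd = np.where(x.std(axis=0) > 1e-12, x.std(axis=0), 1.0)
    xn = model._normalize(x)

    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    drop_at = int(np.ceil(config.max_epochs / 2))
    history = []
    for epoch in range(1, config.max_epochs + 1):
        if epoch == drop_at + 1:
            lr = config.learning_rate * config.lr_drop_factor
        loss, grads = model.loss_and_grads(xn, y_idx)
        history.append(loss)
        gnorm = np.sqrt(sum(np.sum(g**2) for g in grads.values()))
        if gnorm > 1.0:
            grads = {k: g / gnorm for k, g in grads.items()}
        for k in model.params:
            m_state[k] = beta1 * m_state[k] + (1 - beta1) * grads[k]
            v_state[k] = beta2 * v_state[k] + (1 - beta2) * grads[k] ** 2
            m_hat = m_state[k] / (1 - beta1**epoch)
            v_hat = v_state[k] / (1 - beta2**epoch)
            model.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)
    return model, history


def predict(model: BiLSTMModel, x):
    """Labels and class probabilities; ties break toward the lower class index."""
    probs = model.forward(x)
    labels = [CLASSES[k] for k in probs.argmax(axis=1)]
    return labels, probs


def _stratified_split(y_idx, frac: float, rng: np.random.Generator):
    """Indices (fit, held_out) with ~frac of each class held out."""
    fit_idx, val_idx = [], []
    for c in np.unique(y_idx):
        members = np.flatnonzero(y_idx == c)
        members = members[rng.permutation(len(members))]
        n_val = max(1, int(round(frac * len(members))))
        val_idx.extend(members[:n_val])
        fit_idx.extend(members[n_val:])
    return np.sort(fit_idx), np.sort(val_idx)


def tune_with_dbo(train_x, train_y, eval_x=None, eval_y=None,
                  dbo_config: DBOConfig | None = None,
                  train_config: BiLSTMConfig | None = None,
                  paper_mode: bool = False, val_fraction: float = 0.25):
    """DBO search over (log10 lr, hidden units, log10 L2); returns best config.

    Fitness is the misclassification rate on a stratified validation carve-out
    of the training set (default), or on ``eval_x``/``eval_y`` when
    ``paper_mode`` is set — the latter matches the original tuning protocol
    but leaks the test split into model selection, so it is opt-in.

    Returns ``(BiLSTMConfig, history)`` with history the per-iteration
    best-so-far fitness.
    """
    train_config = train_config or BiLSTMConfig()
    dbo_config = dbo_config or DBOConfig(bounds=DEFAULT_SEARCH_BOUNDS)
    train_x = np.asarray(train_x, dtype=float)
    y_idx = _labels_to_idx(train_y)
    if paper_mode:
        if eval_x is None or eval_y is None:
            raise ValueError("paper_mode requires an explicit evaluation split")
        fit_x, fit_y = train_x, y_idx
        ev_x, ev_y = np.asarray(eval_x, dtype=float), _labels_to_idx(eval_y)
    else:
        rng = np.random.default_rng(dbo_config.seed)
        fit_idx, val_idx = _stratified_split(y_idx, val_fraction, rng)
        fit_x, fit_y = train_x[fit_idx], y_idx[fit_idx]
        ev_x, ev_y = train_x[val_idx], y_idx[val_idx]

    def objective(pos):
        cand = replace(train_config,
                       learning_rate=float(10.0 ** pos[0]),
                       hidden_units=int(round(pos[1])),
                       l2=float(10.0 ** pos[2]))
        model = build(cand, input_len=train_x.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train(model, fit_x, fit_y, cand)
        labels, _ = predict(model, ev_x)
        pred_idx = _labels_to_idx(labels)
        return float(np.mean(pred_idx != ev_y))

    result = optimize(objective, dbo_config)
    best = replace(train_config,
                   learning_rate=float(10.0 ** result.x_best[0]),
                   hidden_units=int(round(result.x_best[1])),
                   l2=float(10.0 ** result.x_best[2]))
    return best, result.history
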