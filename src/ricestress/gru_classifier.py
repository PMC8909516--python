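"""Gated-recurrent-unit sequence classifier, implemented from the cell
equations with an explicit backward pass.

The cell, for a mini-batch row X_t and previous hidden state H_{t-1}:

    R_t = sigmoid(X_t Wxr + H_{t-1} Whr + br)        (reset gate)
    Z_t = sigmoid(X_t Wxz + H_{t-1} Whz + bz)        (update gate)
    Hc_t = tanh(X_t Wxh + (R_t * H_{t-1}) Whh + bh)  (candidate state)
    H_t = Z_t * H_{t-1} + (1 - Z_t) * Hc_t

The reset gate controls how much of the previous hidden state enters the
candidate (R_t -> 0 discards history, capturing short-term structure); the
update gate interpolates convexly between carrying the old state forward and
adopting the candidate, capturing long-term dependencies without the
vanishing-gradient pathology of a plain RNN.

The classification head passes the final hidden state through two dense
layers (tanh on the first) and a softmax. Training minimizes multiclass
cross-entropy by mini-batch Adam; gradients are computed analytically by
backpropagation through time and verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

NODATA = 255

#: Parameter names in the canonical flattening order used by the optimizer
#: and the gradient checks.
PARAM_NAMES = (
    "Wxr", "Wxz", "Wxh", "Whr", "Whz", "Whh", "br", "bz", "bh",
    "W1", "b1", "W2", "b2",
)


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The defaults (input_size 8, hidden_size 256, batch_size 8,
    learning_rate 1e-4) are the published operating point of the model;
    ``fc_size`` (the width of the inner dense layer) defaults to
    hidden_size // 2.
    """

    input_size: int = 8
    hidden_size: int = 256
    batch_size: int = 8
    learning_rate: float = 1e-4
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    n_classes: int = 3
    fc_size: int | None = None

    def validate(self) -> None:
        if min(self.input_size, self.hidden_size, self.batch_size,
               self.max_epochs, self.n_classes) < 1:
            raise ValueError("sizes must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")

    @property
    def inner_size(self) -> int:
        return self.fc_size if self.fc_size is not None else max(self.hidden_size // 2, 1)


@dataclass
class GRUWeights:
    """All trainable parameter blocks of the cell and the dense head."""

    Wxr: np.ndarray
    Wxz: np.ndarray
    Wxh: np.ndarray
    Whr: np.ndarray
    Whz: np.ndarray
    Whh: np.ndarray
    br: np.ndarray
    bz: np.ndarray
    bh: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @classmethod
    def init(cls, d: int, h: int, inner: int, n_classes: int,
             rng: np.random.Generator, scale: float = 0.1) -> "GRUWeights":
        """Small-uniform initialization in [-scale, scale], seed-controlled."""
        u = lambda *shape: rng.uniform(-scale, scale, size=shape)
        return cls(
            Wxr=u(d, h), Wxz=u(d, h), Wxh=u(d, h),
            Whr=u(h, h), Whz=u(h, h), Whh=u(h, h),
            br=np.zeros((1, h)), bz=np.zeros((1, h)), bh=np.zeros((1, h)),
            W1=u(h, inner), b1=np.zeros((1, inner)),
            W2=u(inner, n_classes), b2=np.zeros((1, n_classes)),
        )

    @classmethod
    def zeros(cls, d: int, h: int, inner: int, n_classes: int) -> "GRUWeights":
        z = np.zeros
        return cls(
            Wxr=z((d, h)), Wxz=z((d, h)), Wxh=z((d, h)),
            Whr=z((h, h)), Whz=z((h, h)), Whh=z((h, h)),
            br=z((1, h)), bz=z((1, h)), bh=z((1, h)),
            W1=z((h, inner)), b1=z((1, inner)),
            W2=z((inner, n_classes)), b2=z((1, n_classes)),
        )

    def blocks(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def copy(self) -> "GRUWeights":
        return GRUWeights(**{k: v.copy() for k, v in self.blocks().items()})

    def n_parameters(self) -> int:
        return sum(v.size for v in self.blocks().values())


@dataclass
class GRUModel:
    """A weight set plus the architecture metadata needed to apply it."""

    weights: GRUWeights
    config: TrainConfig

    def predict_proba(self, sequences: np.ndarray) -> np.ndarray:
        return forward(sequences, self)

    def predict(self, sequences: np.ndarray) -> np.ndarray:
        # argmax breaks ties toward the lowest class index
        return np.argmax(self.predict_proba(sequences), axis=1)


@dataclass
class TrainHistory:
    """Per-epoch losses and accuracies (overall and per class)."""

    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    train_class_accuracy: list[np.ndarray] = field(default_factory=list)
    test_class_accuracy: list[np.ndarray] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gru_cell_step(x_t: np.ndarray, h_prev: np.ndarray,
                  w: GRUWeights) -> np.ndarray:
    """One cell update H_{t-1} -> H_t for a batch of input rows."""
    h_t, _ = _cell_forward(x_t, h_prev, w)
    return h_t


def _cell_forward(x_t, h_prev, w):
    r = _sigmoid(x_t @ w.Wxr + h_prev @ w.Whr + w.br)
    z = _sigmoid(x_t @ w.Wxz + h_prev @ w.Whz + w.bz)
    hc = np.tanh(x_t @ w.Wxh + (r * h_prev) @ w.Whh + w.bh)
    h_t = z * h_prev + (1.0 - z) * hc
    return h_t, (x_t, h_prev, r, z, hc)


def _softmax(scores: np.ndarray) -> np.ndarray:
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def forward(sequences: np.ndarray, model: GRUModel) -> np.ndarray:
    """Class probabilities for sequences shaped (n, T, d) or (T, d)."""
    probs, _, _ = _forward_full(_as_batch(sequences), model.weights)
    return probs


def _as_batch(sequences: np.ndarray) -> np.ndarray:
    seq = np.asarray(sequences, dtype=float)
    if seq.ndim == 2:
        seq = seq[None]
    if seq.ndim != 3:
        raise ValueError("sequences must be (n, T, d) or (T, d)")
    if seq.shape[1] == 0:
        raise ValueError("sequence length must be positive")
    return seq


def _forward_full(seq: np.ndarray, w: GRUWeights):
    n, T, d = seq.shape
    h = np.zeros((n, w.Whr.shape[0]))
    caches = []
    for t in range(T):
        h, cache = _cell_forward(seq[:, t, :], h, w)
        caches.append(cache)
    a1 = np.tanh(h @ w.W1 + w.b1)
    scores = a1 @ w.W2 + w.b2
    probs = _softmax(scores)
    return probs, (caches, h, a1), probs


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-300, None)
    return float(-np.mean(np.log(p)))


def loss_and_gradients(seq: np.ndarray, labels: np.ndarray,
                       w: GRUWeights) -> tuple[float, GRUWeights]:
    """Mean cross-entropy and its analytic gradient in every parameter block.

    Backpropagation through time over the full sequence; gradient blocks are
    returned in a GRUWeights container of matching shapes.
    """
    seq = _as_batch(seq)
    n, T, d = seq.shape
    probs, (caches, h_final, a1), _ = _forward_full(seq, w)
    loss = cross_entropy(probs, labels)

    g = GRUWeights.zeros(d, w.Whr.shape[0], w.W1.shape[1], w.W2.shape[1])

    dscores = probs.copy()
    dscores[np.arange(n), labels] -= 1.0
    dscores /= n
    g.W2 += a1.T @ dscores
    g.b2 += dscores.sum(axis=0, keepdims=True)
    da1 = dscores @ w.W2.T
    dz1 = da1 * (1.0 - a1 ** 2)
    g.W1 += h_final.T @ dz1
    g.b1 += dz1.sum(axis=0, keepdims=True)
    dh = dz1 @ w.W1.T

    for t in range(T - 1, -1, -1):
        x_t, h_prev, r, z, hc = caches[t]
        dz = dh * (h_prev - hc)
        dhc = dh * (1.0 - z)
        dh_prev = dh * z

        dah = dhc * (1.0 - hc ** 2)
        g.Wxh += x_t.T @ dah
        g.bh += dah.sum(axis=0, keepdims=True)
        g.Whh += (r * h_prev).T @ dah
        drh = dah @ w.Whh.T
        dr = drh * h_prev
        dh_prev += drh * r

        daz = dz * z * (1.0 - z)
        g.Wxz += x_t.T @ daz
        g.bz += daz.sum(axis=0, keepdims=True)
        g.Whz += h_prev.T @ daz
        dh_prev += daz @ w.Whz.T

        dar = dr * r * (1.0 - r)
        g.Wxr += x_t.T @ dar
        g.br += dar.sum(axis=0, keepdims=True)
        g.Whr += h_prev.T @ dar
        dh_prev += dar @ w.Whr.T

        dh = dh_prev
    return loss, g


class _Adam:
    """Adam optimizer over the named parameter blocks."""

    def __init__(self, w: GRUWeights, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in w.blocks().items()}
        self.v = {k: np.zeros_like(v) for k, v in w.blocks().items()}
        self.t = 0

    def step(self, w: GRUWeights, g: GRUWeights) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, grad in g.blocks().items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grad ** 2
            update = (self.lr * (self.m[k] / b1c)
                      / (np.sqrt(self.v[k] / b2c) + self.eps))
            getattr(w, k)[...] -= update


def _evaluate(seq, labels, w, n_classes, chunk=4096):
    """Loss, overall accuracy and per-class accuracy without training."""
    losses, correct = [], np.zeros(n_classes)
    totals = np.zeros(n_classes)
    for start in range(0, len(seq), chunk):
        sl = slice(start, start + chunk)
        probs, _, _ = _forward_full(seq[sl], w)
        losses.append(cross_entropy(probs, labels[sl]) * len(seq[sl]))
        pred = probs.argmax(axis=1)
        for c in range(n_classes):
            in_c = labels[sl] == c
            totals[c] += in_c.sum()
            correct[c] += (pred[in_c] == c).sum()
    loss = float(np.sum(losses) / len(seq))
    acc = float(correct.sum() / max(totals.sum(), 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        class_acc = np.where(totals > 0, correct / np.maximum(totals, 1), np.nan)
    return loss, acc, class_acc


def train(train_seq: np.ndarray, train_labels: np.ndarray,
          test_seq: np.ndarray, test_labels: np.ndarray,
          config: TrainConfig) -> tuple[GRUModel, TrainHistory]:
    """Fit the classifier by seeded mini-batch Adam on cross-entropy.

    Records per-epoch train/test loss and (overall and per-class) accuracy,
    stops early when the test loss has not improved for ``config.patience``
    epochs, and returns the epoch-best model by test loss. Fully
    deterministic given ``config.seed``. Raises :class:`DivergenceError` on a
    non-finite loss.
    """
    config.validate()
    train_seq = _as_batch(train_seq)
    test_seq = _as_batch(test_seq)
    if len(train_seq) == 0 or len(test_seq) == 0:
        raise ValueError("train and test sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    d = train_seq.shape[2]
    if d != config.input_size:
        raise ValueError(
            f"sequences carry {d} features but config.input_size={config.input_size}"
        )
    w = GRUWeights.init(d, config.hidden_size, config.inner_size,
                        config.n_classes, rng)
    opt = _Adam(w, config.learning_rate)
    history = TrainHistory()
    best_loss, best_w, since_best = np.inf, w.copy(), 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_seq))
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = loss_and_gradients(train_seq[idx], train_labels[idx], w)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            opt.step(w, grads)

        tr_loss, tr_acc, tr_cls = _evaluate(train_seq, train_labels, w, config.n_classes)
        te_loss, te_acc, te_cls = _evaluate(test_seq, test_labels, w, config.n_classes)
        if not (np.isfinite(tr_loss) and np.isfinite(te_loss)):
            raise DivergenceError(epoch)
        history.train_loss.append(tr_loss)
        history.test_loss.append(te_loss)
        history.train_accuracy.append(tr_acc)
        history.test_accuracy.append(te_acc)
        history.train_class_accuracy.append(tr_cls)
        history.test_class_accuracy.append(te_cls)

        if te_loss < best_loss:
            best_loss, best_w, since_best = te_loss, w.copy(), 0
            history.best_epoch = epoch
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    return GRUModel(weights=best_w, config=config), history


def predict_map(model: GRUModel, sequences: np.ndarray, coords: np.ndarray,
                grid_shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel argmax classification raster; excluded pixels get NODATA (255)."""
    seq = _as_batch(sequences)
    if seq.shape[2] != model.config.input_size:
        raise ValueError("feature count does not match the trained model")
    out = np.full(grid_shape, NODATA, dtype=np.uint8)
    if len(seq):
        pred = model.predict(seq)
        out[coords[:, 0], coords[:, 1]] = pred.astype(np.uint8)
    return out


def expected_parameter_count(d: int, h: int, inner: int, n_classes: int) -> int:
    """Closed-form parameter count: 3(dh + h^2 + h) + dense head."""
    return 3 * (d * h + h * h + h) + (h * inner + inner) + (inner * n_classes + n_classes)
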