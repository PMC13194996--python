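"""Plain 1-D convolutional network for binary speech-state classification.

The architecture is deliberately small: a strided convolutional stem
(kernel 15, stride 4, 32 filters), three blocks of [same-padded
convolution -> rectifier -> max-pool (kernel 2, stride 2) -> dropout]
with 64/128/256 filters, global average pooling over time, and a linear
map to a single logit read through a sigmoid. No normalization layers.

Everything — im2col convolutions, backpropagation, Adam with decoupled-
style L2 (added to the gradient, as in the reference optimizer), cosine
learning-rate decay, early stopping — is implemented directly on NumPy
arrays so the model runs identically on any CPU and exposes exact input
gradients for the saliency analysis. Computations are float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Segment


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults are the reference network)."""

    stem_kernel: int = 15
    stem_stride: int = 4
    stem_out: int = 32
    blocks: tuple[tuple[int, int, int], ...] = ((7, 64, 2), (5, 128, 2), (5, 256, 2))
    dropout_rate: float = 0.1


@dataclass
class TrainConfig:
    """Optimization recipe (defaults are the reference setup)."""

    epochs: int = 80
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.005
    batch_size: int = 48
    lr_schedule: str = "cosine"
    dropout: float = 0.1
    early_stopping_patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.early_stopping_patience < 1:
            raise ValueError("early_stopping_patience must be >= 1")
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("invalid training configuration")


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay: 0.5 * lr0 * (1 + cos(pi * e / E))."""
    return 0.5 * base_lr * (1.0 + np.cos(np.pi * epoch / total_epochs))


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    """Minimal layer protocol: forward caches what backward needs."""

    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(_Layer):
    """Same-padded 1-D convolution, arbitrary stride, He-normal init."""

    def __init__(self, c_in, c_out, kernel, stride=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (c_in * kernel))
        self.params = {
            "W": rng.standard_normal((c_out, c_in, kernel)) * std,
            "b": np.zeros(c_out),
        }
        self.kernel, self.stride = kernel, stride

    def _cols(self, x):
        B, C, L = x.shape
        k, s = self.kernel, self.stride
        out_len = -(-L // s)  # ceil(L / s): "same" output length
        pad_total = max((out_len - 1) * s + k - L, 0)
        pl = pad_total // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pad_total - pl)))
        sB, sC, sL = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(B, C, out_len, k), strides=(sB, sC, s * sL, sL))
        return cols, xp.shape, pl, out_len, L

    def forward(self, x, train=False, rng=None):
        cols, xp_shape, pl, out_len, L = self._cols(x)
        self._cache = (cols, xp_shape, pl, out_len, L)
        y = np.einsum("bcok,fck->bfo", cols, self.params["W"], optimize=True)
        return y + self.params["b"][None, :, None]

    def backward(self, gy):
        cols, xp_shape, pl, out_len, L = self._cache
        W = self.params["W"]
        self.grads["W"] = np.einsum("bfo,bcok->fck", gy, cols, optimize=True)
        self.grads["b"] = gy.sum(axis=(0, 2))
        gcols = np.einsum("bfo,fck->bcok", gy, W, optimize=True)
        gxp = np.zeros(xp_shape)
        s = self.stride
        for j in range(self.kernel):
            gxp[:, :, j:j + s * out_len:s] += gcols[:, :, :, j]
        return gxp[:, :, pl:pl + L]


class ReLU(_Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool1d(_Layer):
    """Kernel-2 stride-2 max pooling (a trailing odd sample is dropped)."""

    def forward(self, x, train=False, rng=None):
        B, C, L = x.shape
        out = L // 2
        if out < 1:
            raise ValueError(f"temporal length {L} too short for pooling")
        xt = x[:, :, :2 * out].reshape(B, C, out, 2)
        self._idx = xt.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xt, self._idx[..., None], axis=3)[..., 0]

    def backward(self, gy):
        B, C, L = self._shape
        out = L // 2
        gxt = np.zeros((B, C, out, 2))
        np.put_along_axis(gxt, self._idx[..., None], gy[..., None], axis=3)
        gx = np.zeros((B, C, L))
        gx[:, :, :2 * out] = gxt.reshape(B, C, 2 * out)
        return gx


class Dropout(_Layer):
    def __init__(self, rate):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class GlobalAvgPool(_Layer):
    def forward(self, x, train=False, rng=None):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy):
        return np.repeat(gy[:, :, None], self._L, axis=2) / self._L


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in),
            "b": np.zeros(n_out),
        }

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, gy):
        self.grads["W"] = gy.T @ self._x
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class SpeechStateCNN:
    """The full network; input (B, C, T), output one logit per sample."""

    def __init__(self, n_channels: int, cfg: ModelConfig | None = None,
                 seed: int = 0):
        if n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        self.n_channels = n_channels
        rng = np.random.default_rng(seed)
        layers: list[_Layer] = [
            Conv1d(n_channels, cfg.stem_out, cfg.stem_kernel, cfg.stem_stride,
                   rng=rng),
            ReLU(),
        ]
        c_in = cfg.stem_out
        for kernel, c_out, pool_stride in cfg.blocks:
            if pool_stride != 2:
                raise ValueError("only kernel-2/stride-2 pooling is supported")
            layers += [Conv1d(c_in, c_out, kernel, 1, rng=rng), ReLU(),
                       MaxPool1d(), Dropout(cfg.dropout_rate)]
            c_in = c_out
        layers += [GlobalAvgPool(), Dense(c_in, 1, rng=rng)]
        self.layers = layers

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        """Flat {name: array} view of all trainable parameters."""
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"{i}.{k}"] = v
        return out

    def set_parameters(self, params: dict) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = params[f"{i}.{k}"]

    def parameter_count(self) -> int:
        return sum(v.size for v in self.parameters().values())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != self.n_channels:
            raise ValueError(
                f"expected input (B, {self.n_channels}, T), got {x.shape}")
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x[:, 0]  # logits

    def backward(self, glogit: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(logit); returns d(loss)/d(input)."""
        g = glogit[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def gradients(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads.items():
                out[f"{i}.{k}"] = v
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Speech probability per segment (evaluation mode, dropout off)."""
        x = np.asarray(x, dtype=np.float64)
        probs = np.empty(x.shape[0])
        for i in range(0, x.shape[0], batch_size):
            z = self.forward(x[i:i + batch_size], train=False)
            probs[i:i + batch_size] = _sigmoid(z)
        return probs

    def input_gradient(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-sample gradient of the BCE loss w.r.t. the input (eval mode)."""
        z = self.forward(np.asarray(x, dtype=np.float64), train=False)
        # per-sample loss: dL_i/dz_i = sigma(z_i) - y_i
        return self.backward(_sigmoid(z) - np.asarray(y, dtype=np.float64))


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    grad = (_sigmoid(logits) - y) / logits.size
    return loss, grad


def parameter_count_formula(n_channels: int, cfg: ModelConfig | None = None) -> int:
    """Closed-form parameter count, for cross-checking the built network."""
    cfg = cfg or ModelConfig()
    total = cfg.stem_kernel * n_channels * cfg.stem_out + cfg.stem_out
    c_in = cfg.stem_out
    for kernel, c_out, _ in cfg.blocks:
        total += kernel * c_in * c_out + c_out
        c_in = c_out
    total += c_in + 1  # linear head
    return total


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def segments_to_arrays(segments: list[Segment]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.data for s in segments]).astype(np.float64)
    y = np.array([s.label for s in segments], dtype=np.float64)
    return X, y


def subsample_balanced(segments: list[Segment], seed: int) -> list[Segment]:
    """Subsample the majority class so both labels are equally frequent."""
    rng = np.random.default_rng(seed)
    by_class = {0: [], 1: []}
    for s in segments:
        by_class[s.label].append(s)
    n = min(len(by_class[0]), len(by_class[1]))
    if n == 0:
        raise ValueError("segments must contain both classes")
    out = []
    for label in (0, 1):
        idx = rng.permutation(len(by_class[label]))[:n]
        out.extend(by_class[label][i] for i in idx)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reuse or audit it."""

    model: SpeechStateCNN
    model_config: ModelConfig
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    zscore_stats: object | None = None  # frozen standardization statistics

    @property
    def best_epoch(self) -> int:
        return int(np.argmin([h["val_loss"] for h in self.history]))

    def predict(self, segments_or_array, batch_size: int = 256) -> np.ndarray:
        """Speech probabilities for segments or an (n, C, T) array."""
        if isinstance(segments_or_array, np.ndarray):
            X = segments_or_array
        else:
            X, _ = segments_to_arrays(segments_or_array)
        if X.ndim != 3 or X.shape[1] != self.model.n_channels:
            raise ValueError(
                f"expected (n, {self.model.n_channels}, T) input, got {X.shape}")
        return self.model.predict_proba(X, batch_size=batch_size)


class _Adam:
    def __init__(self, params: dict, cfg: TrainConfig):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.cfg = cfg

    def step(self, params: dict, grads: dict, lr: float) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1 ** self.t
        b2t = 1.0 - c.beta2 ** self.t
        for k, p in params.items():
            g = grads[k] + c.weight_decay * p  # L2 folded into the gradient
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            p -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + 1e-8)


def _evaluate_loss_acc(model: SpeechStateCNN, X, y, batch_size=256):
    losses, correct = [], 0
    for i in range(0, X.shape[0], batch_size):
        z = model.forward(X[i:i + batch_size], train=False)
        loss, _ = bce_with_logits(z, y[i:i + batch_size])
        losses.append(loss * len(z))
        correct += int(((z >= 0).astype(float) == y[i:i + batch_size]).sum())
    return float(np.sum(losses) / X.shape[0]), correct / X.shape[0]


def train(model: SpeechStateCNN, train_segments, val_segments,
          cfg: TrainConfig | None = None) -> TrainedModel:
    """Fit with Adam, cosine learning-rate decay and early stopping.

    Stops when the validation loss has not improved for
    ``early_stopping_patience`` consecutive epochs and returns the
    best-validation-loss checkpoint. Deterministic for a fixed seed.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    Xtr, ytr = (segments_to_arrays(train_segments)
                if not isinstance(train_segments, tuple) else train_segments)
    Xva, yva = (segments_to_arrays(val_segments)
                if not isinstance(val_segments, tuple) else val_segments)
    for name, y in (("training", ytr), ("validation", yva)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} split contains a single class")

    rng = np.random.default_rng(cfg.seed)
    optimizer = _Adam(model.parameters(), cfg)
    history: list[dict] = []
    best_loss, best_params, since_improve = np.inf, None, 0

    for epoch in range(cfg.epochs):
        lr = (cosine_lr(cfg.lr, epoch, cfg.epochs)
              if cfg.lr_schedule == "cosine" else cfg.lr)
        order = rng.permutation(Xtr.shape[0])
        epoch_loss, n_seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            z = model.forward(Xtr[idx], train=True, rng=rng)
            loss, gz = bce_with_logits(z, ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            model.backward(gz)
            optimizer.step(model.parameters(), model.gradients(), lr)
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        val_loss, val_acc = _evaluate_loss_acc(model, Xva, yva)
        history.append({
            "epoch": epoch, "lr": lr, "train_loss": epoch_loss / n_seen,
            "val_loss": val_loss, "val_acc": val_acc,
        })
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in model.parameters().items()}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.early_stopping_patience:
                break

    if best_params is not None:
        model.set_parameters(best_params)
    return TrainedModel(model=model, model_config=model.cfg, train_config=cfg,
                        history=history)
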