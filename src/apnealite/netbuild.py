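"""Executable networks built from ModelSpecs, with a pure-numpy engine.

The analytic route in :mod:`apnealite.complexity` predicts what a model
costs; this module builds the model itself — a small, self-contained
layer stack (1-D standard and depthwise-separable convolutions, batch
normalization, max-pooling, dropout, dense heads) with forward and
backward passes in numpy, Adam optimization, and early stopping.  The
two routes share nothing but the spec, so equality of their parameter
counts is a meaningful cross-check rather than a tautology.

Inputs are arrays of shape ``(n, length, channels)`` (single-signal
models) or a pair of such arrays (fusion models).  All randomness —
initialization, dropout masks, batch shuffling — flows from explicit
seeds, and training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .archspec import LayerSpec, ModelSpec, fuse_specs, infer_shapes

__all__ = [
    "ExecutableModel",
    "TrainConfig",
    "TrainHistory",
    "build",
    "fuse",
    "train",
    "save_weights",
    "load_weights",
]

Array = np.ndarray
BatchInput = Union[Array, Tuple[Array, Array]]


def _relu(x: Array) -> Array:
    return np.maximum(x, 0.0)


def _softmax(z: Array) -> Array:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _same_pad(length: int, kernel: int, stride: int) -> Tuple[int, int]:
    out = -(-length // stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left


class _Layer:
    """Base layer: parameter lists are parallel (params[i] ↔ grads[i])."""

    trainable = True

    def params(self) -> List[Array]:
        return []

    def grads(self) -> List[Array]:
        return []

    def non_trainable_params(self) -> List[Array]:
        return []

    def forward(self, x: Array, training: bool) -> Array:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: Array) -> Array:  # pragma: no cover - abstract
        raise NotImplementedError


class _BatchNorm(_Layer):
    """Per-channel batch normalization over (batch, time).

    Keeps exponential running statistics (non-trainable) for inference;
    gamma/beta are the trainable scale and shift.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(channels, np.float32)
        self.beta = np.zeros(channels, np.float32)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum = momentum
        self.eps = eps
        self.d_gamma = np.zeros_like(self.gamma)
        self.d_beta = np.zeros_like(self.beta)
        self._cache: tuple = ()

    def params(self) -> List[Array]:
        return [self.gamma, self.beta]

    def grads(self) -> List[Array]:
        return [self.d_gamma, self.d_beta]

    def non_trainable_params(self) -> List[Array]:
        return [self.running_mean, self.running_var]

    def forward(self, x: Array, training: bool) -> Array:
        if training and self.trainable:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma * xhat + self.beta

    def backward(self, grad: Array) -> Array:
        xhat, inv = self._cache
        n = grad.shape[0] * grad.shape[1]
        self.d_gamma[...] = (grad * xhat).sum(axis=(0, 1))
        self.d_beta[...] = grad.sum(axis=(0, 1))
        dxhat = grad * self.gamma
        return inv / n * (
            n * dxhat - dxhat.sum(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class _ConvBase(_Layer):
    def __init__(self, spec: LayerSpec, c_in: int):
        self.k = spec.kernel_size
        self.c_in = c_in
        self.c_out = spec.filters
        self.stride = spec.stride
        self.padding = spec.padding
        self.activation = spec.activation
        self._cache: tuple = ()

    def _pad(self, x: Array) -> Tuple[Array, int]:
        if self.padding == "same":
            left, right = _same_pad(x.shape[1], self.k, self.stride)
            if left or right:
                x = np.pad(x, ((0, 0), (left, right), (0, 0)))
            return x, left
        if self.k > x.shape[1]:
            raise ValueError("valid-padding kernel exceeds input length")
        return x, 0

    def _cols(self, x_padded: Array) -> Array:
        # (n, L_out, k, c_in) view of sliding windows
        win = sliding_window_view(x_padded, self.k, axis=1)  # (n, L', c, k)
        return win[:, :: self.stride].transpose(0, 1, 3, 2)

    def _act(self, z: Array) -> Array:
        self._z_mask = z > 0 if self.activation == "relu" else None
        return _relu(z) if self.activation == "relu" else z

    def _act_grad(self, grad: Array) -> Array:
        return grad * self._z_mask if self._z_mask is not None else grad

    def _col2im(self, d_cols: Array, padded_len: int, left: int, orig_len: int) -> Array:
        # scatter-add window gradients back onto the (padded) input
        n = d_cols.shape[0]
        dx = np.zeros((n, padded_len, self.c_in), np.float32)
        l_out = d_cols.shape[1]
        for j in range(self.k):
            idx = np.arange(l_out) * self.stride + j
            np.add.at(dx, (slice(None), idx), d_cols[:, :, j])
        return dx[:, left : left + orig_len]


class _ConvSC(_ConvBase):
    """Standard 1-D convolution with bias."""

    def __init__(self, spec: LayerSpec, c_in: int, rng: np.random.Generator):
        super().__init__(spec, c_in)
        limit = np.sqrt(6.0 / (self.k * c_in + self.k * self.c_out))
        self.w = rng.uniform(-limit, limit, (self.k, c_in, self.c_out)).astype(np.float32)
        self.b = np.zeros(self.c_out, np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self) -> List[Array]:
        return [self.w, self.b]

    def grads(self) -> List[Array]:
        return [self.dw, self.db]

    def forward(self, x: Array, training: bool) -> Array:
        orig_len = x.shape[1]
        xp, left = self._pad(x)
        cols = self._cols(xp)  # (n, L_out, k, c_in)
        n, l_out = cols.shape[:2]
        flat = cols.reshape(n, l_out, self.k * self.c_in)
        z = flat @ self.w.reshape(self.k * self.c_in, self.c_out) + self.b
        self._cache = (flat, xp.shape[1], left, orig_len)
        return self._act(z)

    def backward(self, grad: Array) -> Array:
        grad = self._act_grad(grad)
        flat, padded_len, left, orig_len = self._cache
        n, l_out = grad.shape[:2]
        g2 = grad.reshape(n * l_out, self.c_out)
        f2 = flat.reshape(n * l_out, self.k * self.c_in)
        self.dw[...] = (f2.T @ g2).reshape(self.w.shape)
        self.db[...] = g2.sum(axis=0)
        d_flat = g2 @ self.w.reshape(self.k * self.c_in, self.c_out).T
        d_cols = d_flat.reshape(n, l_out, self.k, self.c_in)
        return self._col2im(d_cols, padded_len, left, orig_len)


class _ConvDSC(_ConvBase):
    """Depthwise-separable 1-D convolution.

    Depthwise stage: one unbiased kernel per input channel.  Pointwise
    stage: 1x1 channel mix with bias.  Matches the parameter convention
    of the analytic counter (k*c_in + c_in*c_out + c_out).
    """

    def __init__(self, spec: LayerSpec, c_in: int, rng: np.random.Generator):
        super().__init__(spec, c_in)
        lim_d = np.sqrt(6.0 / (self.k + self.k))
        lim_p = np.sqrt(6.0 / (c_in + self.c_out))
        self.w_depth = rng.uniform(-lim_d, lim_d, (self.k, c_in)).astype(np.float32)
        self.w_point = rng.uniform(-lim_p, lim_p, (c_in, self.c_out)).astype(np.float32)
        self.b = np.zeros(self.c_out, np.float32)
        self.dw_depth = np.zeros_like(self.w_depth)
        self.dw_point = np.zeros_like(self.w_point)
        self.db = np.zeros_like(self.b)

    def params(self) -> List[Array]:
        return [self.w_depth, self.w_point, self.b]

    def grads(self) -> List[Array]:
        return [self.dw_depth, self.dw_point, self.db]

    def forward(self, x: Array, training: bool) -> Array:
        orig_len = x.shape[1]
        xp, left = self._pad(x)
        cols = self._cols(xp)  # (n, L_out, k, c_in)
        depth = np.einsum("nlkc,kc->nlc", cols, self.w_depth)
        z = depth @ self.w_point + self.b
        self._cache = (cols, depth, xp.shape[1], left, orig_len)
        return self._act(z)

    def backward(self, grad: Array) -> Array:
        grad = self._act_grad(grad)
        cols, depth, padded_len, left, orig_len = self._cache
        n, l_out = grad.shape[:2]
        self.db[...] = grad.sum(axis=(0, 1))
        d2 = depth.reshape(n * l_out, self.c_in)
        g2 = grad.reshape(n * l_out, self.c_out)
        self.dw_point[...] = d2.T @ g2
        d_depth = (g2 @ self.w_point.T).reshape(n, l_out, self.c_in)
        self.dw_depth[...] = np.einsum("nlkc,nlc->kc", cols, d_depth)
        d_cols = d_depth[:, :, None, :] * self.w_depth[None, None]
        return self._col2im(d_cols, padded_len, left, orig_len)


class _MaxPool(_Layer):
    def __init__(self, pool_size: int):
        self.p = pool_size
        self._cache: tuple = ()

    def forward(self, x: Array, training: bool) -> Array:
        p = self.p
        l_out = (x.shape[1] - p) // p + 1
        xt = x[:, : l_out * p].reshape(x.shape[0], l_out, p, x.shape[2])
        arg = xt.argmax(axis=2)
        self._cache = (x.shape, arg)
        return np.take_along_axis(xt, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad: Array) -> Array:
        shape, arg = self._cache
        n, l_out, c = grad.shape
        dxt = np.zeros((n, l_out, self.p, c), np.float32)
        np.put_along_axis(dxt, arg[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(shape, np.float32)
        dx[:, : l_out * self.p] = dxt.reshape(n, l_out * self.p, c)
        return dx


class _Flatten(_Layer):
    def forward(self, x: Array, training: bool) -> Array:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: Array) -> Array:
        return grad.reshape(self._shape)


class _Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask: Optional[Array] = None

    def forward(self, x: Array, training: bool) -> Array:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: Array) -> Array:
        return grad if self._mask is None else grad * self._mask


class _Dense(_Layer):
    def __init__(self, n_in: int, units: int, activation: str, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + units))
        self.w = rng.uniform(-limit, limit, (n_in, units)).astype(np.float32)
        self.b = np.zeros(units, np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.activation = activation
        self._cache: tuple = ()

    def params(self) -> List[Array]:
        return [self.w, self.b]

    def grads(self) -> List[Array]:
        return [self.dw, self.db]

    def forward(self, x: Array, training: bool) -> Array:
        z = x @ self.w + self.b
        if self.activation == "relu":
            out = _relu(z)
            self._cache = (x, z > 0)
        elif self.activation == "softmax":
            out = _softmax(z)
            self._cache = (x, None)
        else:
            out = z
            self._cache = (x, None)
        return out

    def backward(self, grad: Array) -> Array:
        """Expects d(loss)/d(pre-activation) for softmax heads.

        With cross-entropy loss the softmax+loss gradient collapses to
        (probabilities - targets), which the training loop supplies
        directly; relu masks its own gradient here.
        """
        x, mask = self._cache
        if mask is not None:
            grad = grad * mask
        self.dw[...] = x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T


def _build_stack(spec: ModelSpec, rng: np.random.Generator) -> List[_Layer]:
    trace = infer_shapes(spec)
    layers: List[_Layer] = []
    length, channels = spec.input_length, spec.input_channels
    for lspec, (out_len, out_ch) in zip(spec.layers, trace.shapes):
        if lspec.kind == "batchnorm":
            layers.append(_BatchNorm(channels))
        elif lspec.kind == "conv_sc":
            layers.append(_ConvSC(lspec, channels, rng))
        elif lspec.kind == "conv_dsc":
            layers.append(_ConvDSC(lspec, channels, rng))
        elif lspec.kind == "maxpool":
            layers.append(_MaxPool(lspec.pool_size))
        elif lspec.kind == "flatten":
            layers.append(_Flatten())
        elif lspec.kind == "dropout":
            layers.append(_Dropout(lspec.rate, rng))
        elif lspec.kind == "dense":
            layers.append(_Dense(length * channels, lspec.units, lspec.activation, rng))
        length, channels = out_len, out_ch
    return layers


class ExecutableModel:
    """A runnable network: single-branch stack or two-branch fusion."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.Generator(np.random.PCG64(seed))
        if spec.is_fusion:
            a, b = spec.fusion_branches  # type: ignore[misc]
            self.branch_a = _build_stack(a, rng)
            self.branch_b = _build_stack(b, rng)
            width = infer_shapes(a).flatten_width + infer_shapes(b).flatten_width
            self.head: List[_Layer] = []
            for lspec in spec.layers:
                if lspec.kind == "dropout":
                    self.head.append(_Dropout(lspec.rate, rng))
                elif lspec.kind == "dense":
                    self.head.append(_Dense(width, lspec.units, lspec.activation, rng))
                    width = lspec.units
                else:
                    raise ValueError(f"unsupported fusion head layer {lspec.kind}")
            self.layers = self.branch_a + self.branch_b + self.head
        else:
            self.layers = _build_stack(spec, rng)
            self.branch_a = self.branch_b = None  # type: ignore[assignment]
            self.head = self.layers

    # -- parameter bookkeeping -------------------------------------------------

    def parameter_count(self) -> Tuple[int, int, int]:
        """(total, trainable, non_trainable) over actual arrays."""
        trainable = sum(p.size for l in self.layers for p in l.params())
        frozen = sum(p.size for l in self.layers for p in l.non_trainable_params())
        return trainable + frozen, trainable, frozen

    def trainable_parameter_count(self) -> int:
        return sum(p.size for l in self.layers if l.trainable for p in l.params())

    def _trainable_layers(self) -> List[_Layer]:
        return [l for l in self.layers if l.trainable and l.params()]

    def all_weights(self) -> List[Array]:
        out: List[Array] = []
        for l in self.layers:
            out.extend(l.params())
            out.extend(l.non_trainable_params())
        return out

    # -- forward ---------------------------------------------------------------

    @staticmethod
    def _ensure_3d(x: Array) -> Array:
        x = np.asarray(x, np.float32)
        return x[:, :, None] if x.ndim == 2 else x

    def _run(self, layers: Sequence[_Layer], x: Array, training: bool) -> Array:
        for l in layers:
            x = l.forward(x, training)
        return x

    def forward(self, x: BatchInput, training: bool = False) -> Array:
        """Class probabilities of shape (n, 2)."""
        if self.spec.is_fusion:
            if not isinstance(x, tuple) or len(x) != 2:
                raise ValueError("fusion model expects a pair (ecg_batch, spo2_batch)")
            xa, xb = self._ensure_3d(x[0]), self._ensure_3d(x[1])
            self._check_width(xa, self.spec.fusion_branches[0])  # type: ignore[index]
            self._check_width(xb, self.spec.fusion_branches[1])  # type: ignore[index]
            fa = self._run(self.branch_a, xa, training)
            fb = self._run(self.branch_b, xb, training)
            feat = np.concatenate([fa, fb], axis=1)
            self._split = fa.shape[1]
            return self._run(self.head, feat, training)
        xx = self._ensure_3d(x)  # type: ignore[arg-type]
        self._check_width(xx, self.spec)
        return self._run(self.layers, xx, training)

    @staticmethod
    def _check_width(x: Array, spec: ModelSpec) -> None:
        if x.shape[1] != spec.input_length or x.shape[2] != spec.input_channels:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec "
                f"({spec.input_length}, {spec.input_channels}) of {spec.name!r}"
            )

    def predict_proba(self, x: BatchInput) -> Array:
        return self.forward(x, training=False)

    def predict(self, x: BatchInput) -> Array:
        """Hard labels: 1 = apnea (class index 1), 0 = normal."""
        return self.predict_proba(x).argmax(axis=1)

    # -- backward --------------------------------------------------------------

    def backward(self, d_logits: Array) -> None:
        grad = d_logits
        for l in reversed(self.head):
            grad = l.backward(grad)
        if self.spec.is_fusion:
            ga, gb = grad[:, : self._split], grad[:, self._split :]
            if any(l.trainable for l in self.branch_a):
                for l in reversed(self.branch_a):
                    ga = l.backward(ga)
            if any(l.trainable for l in self.branch_b):
                for l in reversed(self.branch_b):
                    gb = l.backward(gb)

    def freeze_branches(self) -> None:
        if not self.spec.is_fusion:
            raise ValueError("only fusion models have branches to freeze")
        for l in self.branch_a + self.branch_b:
            l.trainable = False


def build(spec: ModelSpec, seed: int = 0) -> ExecutableModel:
    """Instantiate a spec with deterministic Glorot-uniform initialization."""
    return ExecutableModel(spec, seed)


def _copy_trunk(dst: List[_Layer], src_model: ExecutableModel) -> None:
    src_trunk = [l for l in src_model.layers if not isinstance(l, _Dense)]
    src_trunk = src_trunk[: len(dst)]
    for d, s in zip(dst, src_trunk):
        for pd, ps in zip(d.params() + d.non_trainable_params(),
                          s.params() + s.non_trainable_params()):
            pd[...] = ps


def fuse(
    pretrained_a: ExecutableModel,
    pretrained_b: ExecutableModel,
    freeze_branches: bool = True,
    seed: int = 0,
    name: Optional[str] = None,
) -> ExecutableModel:
    """Transfer-learning fusion of two trained single-signal models.

    Branch weights (everything up to and including flatten) are copied
    from the pretrained models; a fresh dropout + softmax head is added
    on the concatenated features.  With ``freeze_branches`` only the new
    head trains.
    """
    if pretrained_a.spec.is_fusion or pretrained_b.spec.is_fusion:
        raise ValueError("fuse expects two single-signal models")
    fspec = fuse_specs(pretrained_a.spec, pretrained_b.spec, name=name)
    model = ExecutableModel(fspec, seed)
    _copy_trunk(model.branch_a, pretrained_a)
    _copy_trunk(model.branch_b, pretrained_b)
    if freeze_branches:
        model.freeze_branches()
    return model


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    """Adam training hyperparameters (the defaults are conventional)."""

    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 20
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size and max_epochs must be positive")


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)
    best_epoch: int = 0
    seed: int = 0


class _Adam:
    def __init__(self, layers: Sequence[_Layer], lr: float):
        self.layers = [l for l in layers if l.trainable and l.params()]
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-7
        self.m = [np.zeros_like(p) for l in self.layers for p in l.params()]
        self.v = [np.zeros_like(p) for l in self.layers for p in l.params()]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        i = 0
        for l in self.layers:
            for p, g in zip(l.params(), l.grads()):
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                p -= self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)
                i += 1


def _one_hot(y: Array) -> Array:
    out = np.zeros((y.shape[0], 2), np.float32)
    out[np.arange(y.shape[0]), y.astype(int)] = 1.0
    return out


def _xent(p: Array, y01: Array) -> float:
    eps = 1e-9
    return float(-np.mean(np.log(p[np.arange(len(y01)), y01.astype(int)] + eps)))


def _take(x: BatchInput, idx: Array) -> BatchInput:
    if isinstance(x, tuple):
        return (x[0][idx], x[1][idx])
    return x[idx]


def _n_samples(x: BatchInput) -> int:
    return x[0].shape[0] if isinstance(x, tuple) else x.shape[0]


def _frozen_features(model: ExecutableModel, x: Tuple[Array, Array],
                     batch: int = 256) -> Array:
    """Concatenated flatten features of frozen branches, computed batchwise."""
    xa = ExecutableModel._ensure_3d(x[0])
    xb = ExecutableModel._ensure_3d(x[1])
    chunks = []
    for start in range(0, xa.shape[0], batch):
        fa = model._run(model.branch_a, xa[start : start + batch], training=False)
        fb = model._run(model.branch_b, xb[start : start + batch], training=False)
        chunks.append(np.concatenate([fa, fb], axis=1))
    return np.vstack(chunks)


def train(
    model: ExecutableModel,
    x_train: BatchInput,
    y_train: Array,
    x_val: BatchInput,
    y_val: Array,
    cfg: TrainConfig = TrainConfig(),
) -> Tuple[ExecutableModel, TrainHistory]:
    """Train with Adam and early stopping on validation loss.

    Labels are 0 (normal) / 1 (apnea).  The best-validation weights are
    restored before returning; identical inputs, config and seed give an
    identical history and final weights.  When every branch layer of a
    fusion model is frozen, branch features are precomputed once and
    only the head is iterated.
    """
    head_only = (
        model.spec.is_fusion
        and not any(l.trainable for l in model.branch_a + model.branch_b)
    )
    if head_only:
        x_train = _frozen_features(model, x_train)  # type: ignore[arg-type]
        x_val = _frozen_features(model, x_val)  # type: ignore[arg-type]
        forward = lambda x, training: model._run(model.head, x, training)  # noqa: E731

        def backward(d_logits: Array) -> None:
            grad = d_logits
            for l in reversed(model.head):
                grad = l.backward(grad)

    else:
        forward = model.forward
        backward = model.backward
    n = _n_samples(x_train)
    if n == 0 or _n_samples(x_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if y_train.shape[0] != n:
        raise ValueError("x/y length mismatch")

    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    opt = _Adam(model.layers, cfg.learning_rate)
    hist = TrainHistory(seed=cfg.seed)
    best_loss = np.inf
    best_weights: List[Array] = []
    bad_epochs = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = _take(x_train, idx), y_train[idx]
            probs = forward(xb, training=True)
            losses.append(_xent(probs, yb) * len(idx))
            d_logits = (probs - _one_hot(yb)) / len(idx)
            backward(d_logits)
            opt.step()
        hist.train_loss.append(float(np.sum(losses) / n))

        val_probs = forward(x_val, training=False)
        vl = _xent(val_probs, y_val)
        hist.val_loss.append(vl)
        hist.val_accuracy.append(float((val_probs.argmax(1) == y_val).mean()))

        if vl < best_loss - 1e-6:
            best_loss = vl
            hist.best_epoch = epoch
            best_weights = [w.copy() for w in model.all_weights()]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break

    if best_weights:
        for w, bw in zip(model.all_weights(), best_weights):
            w[...] = bw
    return model, hist


# ---------------------------------------------------------------------------
# Checkpointing (runtime artifacts; numpy archive keyed by position)


def save_weights(model: ExecutableModel, path: str) -> None:
    np.savez(path, *model.all_weights())


def load_weights(model: ExecutableModel, path: str) -> ExecutableModel:
    with np.load(path) as data:
        arrays = [data[k] for k in data.files]
    weights = model.all_weights()
    if len(arrays) != len(weights):
        raise ValueError("checkpoint does not match model architecture")
    for w, a in zip(weights, arrays):
        if w.shape != a.shape:
            raise ValueError("checkpoint does not match model architecture")
        w[...] = a
    return model
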