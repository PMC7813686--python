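"""A 12-layer 1-D convolutional network for 360-sample heartbeat windows.

Architecture (fixed by :func:`default_architecture`): four alternating
conv/average-pool blocks — conv(k=13, 16 filters) -> pool(3,2) ->
conv(15, 32) -> pool -> conv(17, 64) -> pool -> conv(19, 128) -> pool —
then dropout(0.5), dense(35), dense(5) and softmax.  Convolutions are
stride-1 with length-preserving ("same") zero padding; ReLU follows every
convolution (i.e. precedes every pooling layer); pooling is plain
averaging with kernel 3, stride 2, no padding; the two dense layers carry
an L2 penalty (``l2_factor`` times a global base weight decay).

The network is implemented directly in NumPy: convolutions run as
im2col + GEMM in float32, gradients are computed analytically (verified
against numerical differentiation in the test suite), and training uses
Adam with a step-decay learning-rate schedule
``lr(e) = initial_lr * drop_factor ** floor((e - 1) / drop_period)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np


class ShapeMismatchError(AssertionError):
    """Built layer shapes disagree with the architecture's declared chain."""


# ---------------------------------------------------------------------------
# Declarative architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv1d | avgpool1d | dropout | dense | softmax
    kernel_size: int = 0
    stride: int = 1
    n_filters: int = 0
    padding: str = "same"  # conv only: same | valid
    rate: float = 0.0  # dropout
    n_units: int = 0  # dense
    l2_factor: float = 0.0  # dense

    def __post_init__(self) -> None:
        if self.kind in ("conv1d", "avgpool1d") and self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0 <= self.rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass(frozen=True)
class ArchitectureSpec:
    layers: tuple[LayerSpec, ...]
    input_length: int = 360
    n_classes: int = 5
    # declared per-layer output shapes, verified at build time when present:
    # (channels, length) tuples for conv/pool/dropout, (units,) for dense
    expected_shapes: tuple[tuple[int, ...], ...] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_length": self.input_length,
                "n_classes": self.n_classes,
                "layers": [asdict(l) for l in self.layers],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        return cls(
            layers=tuple(LayerSpec(**l) for l in d["layers"]),
            input_length=d["input_length"],
            n_classes=d["n_classes"],
        )


def default_architecture() -> ArchitectureSpec:
    """The fixed 12-layer network, with its declared output-shape chain."""
    return ArchitectureSpec(
        layers=(
            LayerSpec("conv1d", kernel_size=13, n_filters=16),
            LayerSpec("avgpool1d", kernel_size=3, stride=2),
            LayerSpec("conv1d", kernel_size=15, n_filters=32),
            LayerSpec("avgpool1d", kernel_size=3, stride=2),
            LayerSpec("conv1d", kernel_size=17, n_filters=64),
            LayerSpec("avgpool1d", kernel_size=3, stride=2),
            LayerSpec("conv1d", kernel_size=19, n_filters=128),
            LayerSpec("avgpool1d", kernel_size=3, stride=2),
            LayerSpec("dropout", rate=0.5),
            LayerSpec("dense", n_units=35, l2_factor=5.0),
            LayerSpec("dense", n_units=5, l2_factor=5.0),
            LayerSpec("softmax"),
        ),
        expected_shapes=(
            (16, 360), (16, 179), (32, 179), (32, 89), (64, 89), (64, 44),
            (128, 44), (128, 21), (128, 21), (35,), (5,), (5,),
        ),
    )


def conv_out_len(n_in: int, kernel: int, stride: int, padding: str) -> int:
    """Output length of a 1-D convolution."""
    if n_in < 1:
        raise ValueError("n_in must be >= 1")
    if padding == "same":
        return math.ceil(n_in / stride)
    if padding == "valid":
        if kernel > n_in:
            raise ValueError(f"valid conv: kernel {kernel} > input {n_in}")
        return (n_in - kernel) // stride + 1
    raise ValueError(f"unknown padding {padding!r}")


def pool_out_len(n_in: int, kernel: int = 3, stride: int = 2) -> int:
    """Output length of an unpadded pooling layer (floor mode)."""
    if n_in < kernel:
        raise ValueError(f"pool: input {n_in} shorter than kernel {kernel}")
    return (n_in - kernel) // stride + 1


def shape_chain(arch: ArchitectureSpec) -> list[tuple[int, ...]]:
    """Per-layer output shapes ((channels, length) or (units,))."""
    channels, length = 1, arch.input_length
    flat: int | None = None
    shapes: list[tuple[int, ...]] = []
    for spec in arch.layers:
        if spec.kind == "conv1d":
            length = conv_out_len(length, spec.kernel_size, spec.stride, spec.padding)
            channels = spec.n_filters
            shapes.append((channels, length))
        elif spec.kind == "avgpool1d":
            length = pool_out_len(length, spec.kernel_size, spec.stride)
            shapes.append((channels, length))
        elif spec.kind == "dropout":
            shapes.append((channels, length) if flat is None else (flat,))
        elif spec.kind == "dense":
            flat = spec.n_units
            shapes.append((flat,))
        elif spec.kind == "softmax":
            shapes.append((flat,) if flat is not None else (channels, length))
        else:
            raise ValueError(f"unknown layer kind {spec.kind!r}")
    return shapes


# ---------------------------------------------------------------------------
# Layers (forward + analytic backward)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, s: int, L_out: int) -> np.ndarray:
    """(B, Lp, C) -> (B*L_out, k*C); row layout j*C+c (contiguous copies)."""
    B, _, C = xp.shape
    col = np.empty((B, L_out, k, C), dtype=xp.dtype)
    for j in range(k):
        col[:, :, j, :] = xp[:, j : j + (L_out - 1) * s + 1 : s, :]
    return col.reshape(B * L_out, k * C)


class _Conv1D:
    """Channels-last 1-D convolution: activations are (batch, length, channels)."""

    def __init__(self, spec: LayerSpec, c_in: int, rng: np.random.Generator, dtype,
                 needs_input_grad: bool = True):
        self.spec = spec
        self.c_in = c_in
        self.needs_input_grad = needs_input_grad  # False for the input layer
        k, f = spec.kernel_size, spec.n_filters
        limit = math.sqrt(6.0 / (c_in * k + f))  # Glorot uniform
        # row index j*C + c (tap-major to match _im2col)
        self.W = rng.uniform(-limit, limit, size=(k * c_in, f)).astype(dtype)
        self.b = np.zeros(f, dtype=dtype)
        self.l2_factor = 0.0

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k, s = self.spec.kernel_size, self.spec.stride
        B, L, C = x.shape
        if self.spec.padding == "same":
            L_out = math.ceil(L / s)
            pad_total = max((L_out - 1) * s + k - L, 0)
            pl, pr = pad_total // 2, pad_total - pad_total // 2
        else:
            L_out = (L - k) // s + 1
            pl = pr = 0
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        col = _im2col(xp, k, s, L_out)
        y = col @ self.W + self.b
        self._cache = (col, x.shape, (pl, pr), L_out)
        return y.reshape(B, L_out, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, (B, L, C), (pl, pr), L_out = self._cache
        k, s = self.spec.kernel_size, self.spec.stride
        F = self.W.shape[1]
        dyf = dy.reshape(B * L_out, F)
        self.dW = col.T @ dyf
        self.db = dyf.sum(axis=0)
        if not self.needs_input_grad:
            return None
        if s == 1:
            # input gradient = correlation of dy with the flipped kernel,
            # accumulated tap by tap as batched GEMMs (no col2im scatter)
            w_taps = self.W.reshape(k, C, F)
            dyp = np.pad(dy, ((0, 0), (k - 1 - pl, k - 1 - pr), (0, 0)))
            dx = np.zeros((B, L, C), dtype=dy.dtype)
            for j in range(k):
                dx += dyp[:, k - 1 - j : k - 1 - j + L, :] @ w_taps[j].T
            return dx
        dcol = (dyf @ self.W.T).reshape(B, L_out, k, C)
        dxp = np.zeros((B, L + pl + pr, C), dtype=dy.dtype)
        for j in range(k):
            dxp[:, j : j + (L_out - 1) * s + 1 : s, :] += dcol[:, :, j, :]
        return dxp[:, pl : pl + L, :]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _AvgPool1D:
    """Channels-last unpadded average pooling over the length axis."""

    def __init__(self, spec: LayerSpec):
        self.k, self.s = spec.kernel_size, spec.stride

    def forward(self, x, training):
        self._in_shape = x.shape
        L_out = (x.shape[1] - self.k) // self.s + 1
        acc = x[:, 0 : (L_out - 1) * self.s + 1 : self.s, :].copy()
        for j in range(1, self.k):
            acc += x[:, j : j + (L_out - 1) * self.s + 1 : self.s, :]
        acc /= self.k
        return acc

    def backward(self, dy):
        B, L, C = self._in_shape
        L_out = dy.shape[1]
        dx = np.zeros((B, L, C), dtype=dy.dtype)
        g = dy / self.k
        for j in range(self.k):
            dx[:, j : j + (L_out - 1) * self.s + 1 : self.s, :] += g
        return dx

    def params(self):
        return []


class _Dropout:
    def __init__(self, spec: LayerSpec):
        self.rate = spec.rate
        self.rng = np.random.default_rng(0)  # reseeded by train()

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class _Flatten:
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, spec: LayerSpec, n_in: int, rng: np.random.Generator, dtype):
        limit = math.sqrt(6.0 / (n_in + spec.n_units))
        self.W = rng.uniform(-limit, limit, size=(n_in, spec.n_units)).astype(dtype)
        self.b = np.zeros(spec.n_units, dtype=dtype)
        self.l2_factor = spec.l2_factor

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class Model:
    """The built network: an ordered list of layers ending in softmax."""

    def __init__(self, arch: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        self.arch = arch
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.layers: list = []
        channels, length = 1, arch.input_length
        flat: int | None = None
        built_shapes: list[tuple[int, ...]] = []
        for spec in arch.layers:
            if spec.kind == "conv1d":
                self.layers.append(
                    _Conv1D(spec, channels, rng, dtype, needs_input_grad=bool(self.layers))
                )
                length = conv_out_len(length, spec.kernel_size, spec.stride, spec.padding)
                channels = spec.n_filters
                self.layers.append(_ReLU())  # ReLU after conv, before pooling
                built_shapes.append((channels, length))
            elif spec.kind == "avgpool1d":
                self.layers.append(_AvgPool1D(spec))
                length = pool_out_len(length, spec.kernel_size, spec.stride)
                built_shapes.append((channels, length))
            elif spec.kind == "dropout":
                self.layers.append(_Dropout(spec))
                built_shapes.append((channels, length) if flat is None else (flat,))
            elif spec.kind == "dense":
                if flat is None:
                    self.layers.append(_Flatten())
                    flat = channels * length
                self.layers.append(_Dense(spec, flat, rng, dtype))
                flat = spec.n_units
                built_shapes.append((flat,))
            elif spec.kind == "softmax":
                built_shapes.append((flat,) if flat is not None else (channels, length))
            else:
                raise ValueError(f"unknown layer kind {spec.kind!r}")
        if arch.expected_shapes is not None and tuple(built_shapes) != tuple(arch.expected_shapes):
            raise ShapeMismatchError(
                f"built shape chain {built_shapes} != declared {list(arch.expected_shapes)}"
            )
        self.output_shapes = built_shapes

    # -- forward / backward -------------------------------------------------

    def logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        h = np.asarray(X, dtype=self.dtype)
        if h.ndim == 2:
            h = h[:, :, None]  # channels-last: (batch, length, 1 channel)
        if h.shape[1] != self.arch.input_length:
            raise ValueError(
                f"segments must have length {self.arch.input_length}, got {h.shape[1]}"
            )
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def forward_proba(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        return _softmax(self.logits(X, training))

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, base_l2: float = 1e-4, training: bool = True
    ) -> float:
        """Cross-entropy + L2 loss; leaves dW/db on each parametric layer."""
        probs = self.forward_proba(X, training=training)
        n = len(y)
        eps = np.finfo(self.dtype).tiny
        ce = -float(np.mean(np.log(probs[np.arange(n), y] + eps)))
        reg = 0.0
        dlogits = probs.astype(self.dtype)
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        for layer in self.layers:
            lam = getattr(layer, "l2_factor", 0.0) * base_l2
            if lam > 0:
                reg += 0.5 * lam * float(np.sum(layer.W.astype(np.float64) ** 2))
                layer.dW += (lam * layer.W).astype(layer.dW.dtype)
        return ce + reg

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, value, gname in layer.params():
                yield (li, name, layer, value, gname)


def build_model(arch: ArchitectureSpec | None = None, seed: int = 0, dtype=np.float32) -> Model:
    """Construct the (seeded) network; shape chain is asserted at build time."""
    return Model(arch if arch is not None else default_architecture(), seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 36
    optimizer: str = "adam"
    initial_lr: float = 1e-3
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 20  # epochs
    base_l2: float = 1e-4  # multiplied by each dense layer's l2_factor
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.lr_drop_period) < 1:
            raise ValueError("epochs, batch_size and lr_drop_period must be >= 1")
        if not 0 < self.lr_drop_factor <= 1:
            raise ValueError("lr_drop_factor must be in (0, 1]")


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """Step-decay schedule; ``epoch`` is 1-based."""
    return cfg.initial_lr * cfg.lr_drop_factor ** ((epoch - 1) // cfg.lr_drop_period)


@dataclass
class FitResult:
    model: Model
    loss_trace: list[float] = field(default_factory=list)  # mean batch loss per epoch


class NonFiniteLossError(RuntimeError):
    pass


def train(model: Model, X: np.ndarray, y: np.ndarray, cfg: TrainConfig = TrainConfig()) -> FitResult:
    """Mini-batch Adam training with per-epoch reshuffling and LR decay."""
    X = np.asarray(X, dtype=model.dtype)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training set")
    if cfg.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")

    rng = np.random.default_rng(cfg.seed)
    for layer in model.layers:
        if isinstance(layer, _Dropout):
            layer.rng = np.random.default_rng(rng.integers(2**31))

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
    step = 0
    trace: list[float] = []
    for epoch in range(1, cfg.epochs + 1):
        lr = learning_rate(cfg, epoch)
        order = rng.permutation(len(X)) if cfg.shuffle else np.arange(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss = model.loss_and_grads(X[idx], y[idx], base_l2=cfg.base_l2)
            if not np.isfinite(loss):
                raise NonFiniteLossError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}"
                )
            losses.append(loss)
            step += 1
            if lr == 0.0:
                continue
            bc1 = 1 - beta1**step
            bc2 = 1 - beta2**step
            for li, name, layer, value, gname in model.parameters():
                g = getattr(layer, gname)
                key = (li, name)
                if key not in state:
                    state[key] = (np.zeros_like(value), np.zeros_like(value))
                m, v = state[key]
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                value -= (lr * (m / bc1) / (np.sqrt(v / bc2) + eps)).astype(value.dtype)
        trace.append(float(np.mean(losses)))
    return FitResult(model=model, loss_trace=trace)


def predict(
    model: Model, X: np.ndarray, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic inference (dropout off): argmax labels + probabilities."""
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[None, :]
    probs = np.vstack(
        [model.forward_proba(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
    )
    return probs.argmax(axis=1), probs
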