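"""Dilated fully-convolutional network for dense two-class prediction.

The architecture is eight convolutional layers: seven 3x3 layers (each
followed by batch normalization and ReLU) with dilation factors
1, 1, 2, 4, 8, 16, 1 and 32 channels throughout, then a final 1x1 layer
to 2 output channels.  Dilation spaces the kernel taps d pixels apart,
so the receptive field grows exponentially through the stack
(1 + sum_i d_i * (k_i - 1) = 67 pixels for the default) while "same"
zero padding keeps the output at the input resolution — no pooling, no
downsampling, dense per-pixel logits.

Everything here is plain NumPy: forward and backward passes are
hand-written (per-tap BLAS matmuls for the convolutions, standard batch
normalization and ReLU gradients), which keeps the whole pipeline
dependency-light and bit-deterministic on CPU.

:func:`dilated_conv2d` is the literal d-dilated convolution operator
(f *_d r)(p) = sum_{s + d t = p} f(s) r(t) on a single 2D image; the
network layers use the framework-standard cross-correlation form, which
is equivalent up to a kernel flip (the weights are learned either way).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import Heatmap, ImageVolume

# ---------------------------------------------------------------------------
# The d-dilated convolution operator


@dataclass
class Kernel:
    """A discrete filter r on the support [-k, k]^2 with dilation factor d."""

    r: np.ndarray
    d: int = 1

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("kernel must be square 2D")
        if self.r.shape[0] % 2 != 1:
            raise ValueError("kernel spatial extent must be odd (2k+1)")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("kernel weights must be finite")
        if self.d < 1:
            raise ValueError("dilation factor must be >= 1")

    @property
    def k(self) -> int:
        return self.r.shape[0] // 2


def dilated_conv2d(f: np.ndarray, kernel: Kernel) -> np.ndarray:
    """d-dilated convolution of a 2D image with a kernel, zero-padded to
    the input size: out(p) = sum_t f(p - d*t) r(t) over t in [-k, k]^2.

    With d = 1 this is the ordinary discrete convolution.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("input must be a 2D image")
    k, d = kernel.k, kernel.d
    H, W = f.shape
    out = np.zeros((H, W), dtype=np.float64)
    for ti in range(-k, k + 1):
        a = d * ti
        i0, i1 = max(0, a), min(H, H + a)
        if i0 >= i1:
            continue
        for tj in range(-k, k + 1):
            w = kernel.r[ti + k, tj + k]
            if w == 0.0:
                continue
            b = d * tj
            j0, j1 = max(0, b), min(W, W + b)
            if j0 >= j1:
                continue
            out[i0:i1, j0:j1] += w * f[i0 - a : i1 - a, j0 - b : j1 - b]
    return out


# ---------------------------------------------------------------------------
# Architecture specification


@dataclass
class LayerSpec:
    kernel_size: int
    in_channels: int
    out_channels: int
    dilation: int = 1
    batchnorm: bool = True
    relu: bool = True

    def validate(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd >= 1")
        if self.dilation not in (1, 2, 4, 8, 16):
            raise ValueError("dilation must be one of 1, 2, 4, 8, 16 for this architecture")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")


@dataclass
class ArchitectureSpec:
    layers: list[LayerSpec] = field(default_factory=list)

    def validate(self) -> None:
        if not self.layers:
            raise ValueError("architecture must contain at least one layer")
        for i, layer in enumerate(self.layers):
            layer.validate()
            if i > 0 and layer.in_channels != self.layers[i - 1].out_channels:
                raise ValueError(
                    f"channel mismatch: layer {i} expects {layer.in_channels} input "
                    f"channels, previous layer emits {self.layers[i - 1].out_channels}"
                )
        if self.layers[-1].out_channels != 2:
            raise ValueError("final layer must emit 2 channels (two-class dense prediction)")

    def to_dict(self) -> dict:
        return {"layers": [vars(l) for l in self.layers]}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(layers=[LayerSpec(**l) for l in d["layers"]])


def default_architecture(
    hidden_channels: int = 32,
    dilations: tuple[int, ...] = (1, 1, 2, 4, 8, 16, 1),
    kernel_size: int = 3,
    out_channels: int = 2,
) -> ArchitectureSpec:
    """The default stack: 3x3 conv+BN+ReLU layers at the given dilations,
    then a 1x1 linear layer to the two class channels."""
    layers = []
    in_ch = 1
    for d in dilations:
        layers.append(LayerSpec(kernel_size, in_ch, hidden_channels, d, True, True))
        in_ch = hidden_channels
    layers.append(LayerSpec(1, in_ch, out_channels, 1, False, False))
    spec = ArchitectureSpec(layers)
    spec.validate()
    return spec


def receptive_field(spec: ArchitectureSpec) -> tuple[int, int]:
    """Analytic receptive field of one output pixel: 1 + sum_i d_i*(k_i-1)."""
    spec.validate()
    rf = 1 + sum(l.dilation * (l.kernel_size - 1) for l in spec.layers)
    return (rf, rf)


# ---------------------------------------------------------------------------
# Layers (NumPy forward/backward)


class _ConvLayer:
    """2D convolution (cross-correlation), 'same' zero padding of d*(k//2).

    Activations flow through the model in channels-leading ``(C, N, H, W)``
    layout: the im2col buffer then flattens to a contiguous
    ``(k*k*C, N*H*W)`` matrix with no transposes, so forward, weight
    gradient and input gradient are each a single BLAS GEMM.
    """

    def __init__(self, spec: LayerSpec, rng: np.random.Generator):
        k, cin, cout = spec.kernel_size, spec.in_channels, spec.out_channels
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.d = k, spec.dilation
        self.pad = spec.dilation * (k // 2)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        # persistent scratch, reallocated only when the input shape changes
        # (repeated large allocations cost more in page faults than the GEMMs)
        self._buf_shape: tuple[int, ...] | None = None
        self._xp = self._cols = self._dcols = self._dxp = None
        self._have_cache = False

    def _wmat(self) -> np.ndarray:
        # (O, C, k, k) -> (O, k*k*C) matching the im2col row order (ti, tj, c)
        return np.ascontiguousarray(self.W.transpose(0, 2, 3, 1)).reshape(self.W.shape[0], -1)

    def _ensure_buffers(self, shape: tuple[int, int, int, int]) -> None:
        if self._buf_shape == shape:
            return
        C, N, H, W = shape
        k, p = self.k, self.pad
        if p:
            self._xp = np.zeros((C, N, H + 2 * p, W + 2 * p), dtype=np.float32)
            self._dxp = np.empty_like(self._xp)
        if k > 1:
            self._cols = np.empty((k, k, C, N, H, W), dtype=np.float32)
            self._dcols = np.empty((k * k * C, N * H * W), dtype=np.float32)
        self._buf_shape = shape

    def _fill_cols(self, x: np.ndarray, xp: np.ndarray, cols: np.ndarray) -> np.ndarray:
        C, N, H, W = x.shape
        p, k, d = self.pad, self.k, self.d
        xp[:, :, p : p + H, p : p + W] = x
        for ti in range(k):
            for tj in range(k):
                cols[ti, tj] = xp[:, :, ti * d : ti * d + H, tj * d : tj * d + W]
        return cols.reshape(k * k * C, N * H * W)

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        C, N, H, W = x.shape
        if self.k == 1:
            cols = x.reshape(C, N * H * W)
            if cache:
                self._last_input_k1 = cols
        elif cache:
            # training path: persistent scratch, reused across steps
            self._ensure_buffers(x.shape)
            cols = self._fill_cols(x, self._xp, self._cols)
        else:
            # inference path: transient scratch, freed on return
            p, k = self.pad, self.k
            xp = np.zeros((C, N, H + 2 * p, W + 2 * p), dtype=np.float32)
            cols = self._fill_cols(x, xp, np.empty((k, k, C, N, H, W), dtype=np.float32))
        out = self._wmat() @ cols  # (O, N*H*W)
        out += self.b[:, None]
        self._have_cache = cache
        if cache:
            self._in_shape = (C, N, H, W)
        return out.reshape(-1, N, H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._have_cache, "forward(cache=True) required before backward"
        C, N, H, W = self._in_shape
        O = self.W.shape[0]
        k, d, p = self.k, self.d, self.pad
        dmat = dout.reshape(O, N * H * W)
        self.db = dmat.sum(axis=1)
        if k == 1:
            cols = self._last_input_k1
            self.dW = (dmat @ cols.T).reshape(self.W.shape)
            return (self._wmat().T @ dmat).reshape(C, N, H, W)
        cols2d = self._cols.reshape(k * k * C, N * H * W)
        dw_flat = dmat @ cols2d.T  # (O, k*k*C)
        self.dW = np.ascontiguousarray(dw_flat.reshape(O, k, k, C).transpose(0, 3, 1, 2))
        np.matmul(self._wmat().T, dmat, out=self._dcols)
        dcols = self._dcols.reshape(k, k, C, N, H, W)
        self._have_cache = False
        dxp = self._dxp
        dxp.fill(0.0)
        for ti in range(k):
            for tj in range(k):
                dxp[:, :, ti * d : ti * d + H, tj * d : tj * d + W] += dcols[ti, tj]
        return dxp[:, :, p:-p, p:-p] if p else dxp.copy()

    def params(self):
        return [(self, "W"), (self, "b")]


class _BatchNorm:
    """Per-channel batch normalization; activations are (C, N, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps, self.momentum = eps, momentum
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool, cache: bool) -> np.ndarray:
        c = self.gamma.shape[0]
        if train:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = x  # normalize in place; the conv output is not reused
        xhat -= mean.astype(np.float32).reshape(c, 1, 1, 1)
        xhat *= inv_std.reshape(c, 1, 1, 1)
        if cache:
            self._cache = (xhat, inv_std, train)
        out = xhat * self.gamma.reshape(c, 1, 1, 1)
        out += self.beta.reshape(c, 1, 1, 1)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, was_train = self._cache
        self._cache = None
        c = self.gamma.shape[0]
        self.dgamma = (dout * xhat).sum(axis=(1, 2, 3))
        self.dbeta = dout.sum(axis=(1, 2, 3))
        g = (self.gamma * inv_std).reshape(c, 1, 1, 1)
        if not was_train:
            # frozen statistics: the transform is a per-channel affine map
            return dout * g
        n = dout.shape[1] * dout.shape[2] * dout.shape[3]
        return g * (
            dout
            - (self.dbeta.reshape(c, 1, 1, 1) + xhat * self.dgamma.reshape(c, 1, 1, 1)) / n
        )

    def params(self):
        return [(self, "gamma"), (self, "beta")]


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        if cache:
            self._mask = x > 0
        return np.maximum(x, 0.0, out=x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        dout *= mask
        return dout

    def params(self):
        return []


# ---------------------------------------------------------------------------
# The model


class DilatedFCN:
    """Dense-prediction model: (N, 1, H, W) -> logits (N, 2, H, W)."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.blocks: list = []
        for layer in spec.layers:
            self.blocks.append(_ConvLayer(layer, rng))
            if layer.batchnorm:
                self.blocks.append(_BatchNorm(layer.out_channels))
            if layer.relu:
                self.blocks.append(_ReLU())

    def forward(self, x: np.ndarray, train: bool = False, cache: bool | None = None) -> np.ndarray:
        """Map (N, C_in, H, W) inputs to (N, 2, H, W) logits."""
        if cache is None:
            cache = train
        x = np.ascontiguousarray(
            np.asarray(x, dtype=np.float32).transpose(1, 0, 2, 3)
        )  # internal layout (C, N, H, W)
        for block in self.blocks:
            if isinstance(block, _BatchNorm):
                x = block.forward(x, train=train, cache=cache)
            else:
                x = block.forward(x, cache=cache)
        return np.ascontiguousarray(x.transpose(1, 0, 2, 3))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = np.ascontiguousarray(
            np.asarray(dlogits, dtype=np.float32).transpose(1, 0, 2, 3)
        )
        for block in reversed(self.blocks):
            d = block.backward(d)
        return np.ascontiguousarray(d.transpose(1, 0, 2, 3))

    def parameters(self) -> list[tuple[object, str]]:
        out = []
        for block in self.blocks:
            out.extend(block.params())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, block in enumerate(self.blocks):
            for name in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(block, name):
                    arrays[f"block{i}.{name}"] = getattr(block, name)
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for key, value in arrays.items():
            idx, name = key.split(".", 1)
            setattr(self.blocks[int(idx[5:])], name, value.astype(np.float32))


def build_network(spec: ArchitectureSpec | None = None, seed: int = 0) -> DilatedFCN:
    """Build a model from an architecture spec with seed-deterministic init."""
    return DilatedFCN(spec if spec is not None else default_architecture(), seed)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of (N, C, H, W) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_heatmap(model: DilatedFCN, vol: ImageVolume, slice_batch: int = 8) -> Heatmap:
    """Per-slice forward pass; returns the mass-class probability volume."""
    n_s, n_r, n_c = vol.shape
    probs = np.empty((n_s, n_r, n_c), dtype=np.float64)
    vox = vol.voxels.astype(np.float32)
    for start in range(0, n_s, slice_batch):
        chunk = vox[start : start + slice_batch][:, None, :, :]
        logits = model.forward(chunk, train=False, cache=False)
        probs[start : start + slice_batch] = softmax_channels(logits)[:, 1].astype(np.float64)
    return Heatmap(np.clip(probs, 0.0, 1.0), vol.pixel_spacing_mm, vol.slice_spacing_mm)


def save_model(model: DilatedFCN, path: str | Path) -> Path:
    """Save weights (.npz) plus a JSON sidecar with the architecture and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_arrays())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"seed": model.seed, "spec": model.spec.to_dict()}, indent=2))
    return path


def load_model(path: str | Path) -> DilatedFCN:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = DilatedFCN(ArchitectureSpec.from_dict(meta["spec"]), seed=meta["seed"])
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_arrays(dict(data))
    return model
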