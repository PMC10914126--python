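"""Minimal deterministic forward-only FCN executor.

The point of this engine is not speed parity with a deep-learning
framework but *bitwise reproducibility*: every operation accumulates in a
fixed per-output-pixel order that does not depend on the image size.  That
property is what lets tiled inference be compared with a single whole-image
pass down to the last bit, so any seam error that appears is attributable
to the tiling configuration and never to floating-point reordering.

Concretely, convolutions accumulate ``bias + sum over (dy, dx, c_in)`` in a
fixed loop order with purely element-wise numpy arithmetic (no BLAS/FFT
reductions, whose blocking may depend on operand shape).  All arithmetic is
float64.

Images are plain ``numpy`` arrays in row-major ``(H, W, C)`` layout; a 2-D
array is accepted as single-channel.  There is no batch dimension — the
engine processes one tile at a time, matching the out-of-core contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureSpec, compute_F
from .errors import ConstraintError, StructureError

__all__ = [
    "DTYPE",
    "WeightSet",
    "as_tensor_image",
    "conv2d",
    "maxpool2",
    "avgpool2",
    "upconv2",
    "batchnorm_inference",
    "relu",
    "softmax",
    "argmax_mask",
    "forward",
    "seeded_weights",
    "save_weights",
    "load_weights",
]

DTYPE = np.float64

MODES = ("softmax", "logits", "linear")


def as_tensor_image(x: np.ndarray) -> np.ndarray:
    """Validate and normalise an image to float64 ``(H, W, C)`` layout."""
    x = np.asarray(x)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ConstraintError(f"expected a (H, W) or (H, W, C) array, got shape {x.shape}")
    if x.shape[0] < 1 or x.shape[1] < 1:
        raise ConstraintError(f"image must be at least 1x1 pixels, got shape {x.shape}")
    x = np.ascontiguousarray(x, dtype=DTYPE)
    if not np.all(np.isfinite(x)):
        raise ConstraintError("image contains non-finite values")
    return x


def conv2d(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray,
           padding: str = "SAME") -> np.ndarray:
    """2-D convolution (cross-correlation) with fixed accumulation order.

    ``kernel`` has shape ``(k, k, C_in, C_out)``; ``bias`` shape ``(C_out,)``.
    SAME zero-pads by ``k // 2`` on each side and preserves the spatial
    size; VALID shrinks each dimension by ``2 * (k // 2)``.  Each output
    pixel is computed as ``bias`` plus contributions in ``(dy, dx, c_in)``
    order, independent of the image size — the property tiled/whole-image
    bit-equality rests on.
    """
    x = as_tensor_image(x)
    kernel = np.asarray(kernel, dtype=DTYPE)
    bias = np.asarray(bias, dtype=DTYPE)
    if kernel.ndim != 4 or kernel.shape[0] != kernel.shape[1]:
        raise ConstraintError(f"kernel must be (k, k, C_in, C_out), got {kernel.shape}")
    k, _, c_in, c_out = kernel.shape
    if x.shape[2] != c_in:
        raise ConstraintError(
            f"input has {x.shape[2]} channels but kernel expects {c_in}"
        )
    if bias.shape != (c_out,):
        raise ConstraintError(f"bias must have shape ({c_out},), got {bias.shape}")
    r = k // 2
    h, w = x.shape[:2]
    if padding == "SAME":
        xp = np.pad(x, ((r, r), (r, r), (0, 0))) if r else x
        ho, wo = h, w
    elif padding == "VALID":
        xp = x
        ho, wo = h - 2 * r, w - 2 * r
        if ho < 1 or wo < 1:
            raise ConstraintError(
                f"VALID conv with kernel {k} collapses a {h}x{w} input"
            )
    else:
        raise ConstraintError(f"padding must be SAME or VALID, got {padding!r}")
    out = np.empty((ho, wo, c_out), dtype=DTYPE)
    out[:] = bias
    for dy in range(k):
        for dx in range(k):
            win = xp[dy:dy + ho, dx:dx + wo]
            for ci in range(c_in):
                out += win[:, :, ci, None] * kernel[dy, dx, ci]
    return out


def maxpool2(x: np.ndarray) -> np.ndarray:
    """2×2 max-pool, stride 2.  Requires even spatial dims (pad to a
    multiple of F first)."""
    x = as_tensor_image(x)
    h, w, c = x.shape
    if h % 2 or w % 2:
        raise ConstraintError(
            f"maxpool2 requires even spatial dims, got {h}x{w}; pad the image "
            "to a multiple of F first"
        )
    xr = x.reshape(h // 2, 2, w // 2, 2, c)
    return np.maximum(np.maximum(xr[:, 0, :, 0], xr[:, 0, :, 1]),
                      np.maximum(xr[:, 1, :, 0], xr[:, 1, :, 1]))


def avgpool2(x: np.ndarray) -> np.ndarray:
    """2×2 average pool, stride 2 — the linear-mode stand-in for
    :func:`maxpool2` (same spatial footprint, genuinely linear)."""
    x = as_tensor_image(x)
    h, w, c = x.shape
    if h % 2 or w % 2:
        raise ConstraintError(f"avgpool2 requires even spatial dims, got {h}x{w}")
    xr = x.reshape(h // 2, 2, w // 2, 2, c)
    # fixed summation order per output pixel
    return (((xr[:, 0, :, 0] + xr[:, 0, :, 1]) + xr[:, 1, :, 0]) + xr[:, 1, :, 1]) * 0.25


def upconv2(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Transposed convolution with stride 2 (fractional stride 1/2): doubles
    the spatial size.

    Defined as the adjoint of a stride-2 SAME convolution with the same
    kernel: output pixel ``q`` accumulates ``x[p] * w[d]`` over all
    ``(p, d)`` with ``q = 2 p + d - (k - 1) // 2``.  For the U-Net 2×2
    kernel the contributions tile the output exactly (a learned
    nearest-neighbour upsample); for 3×3 kernels neighbouring input pixels
    overlap.  Accumulation order is ``bias + (dy, dx, c_in)``, fixed.
    """
    x = as_tensor_image(x)
    kernel = np.asarray(kernel, dtype=DTYPE)
    bias = np.asarray(bias, dtype=DTYPE)
    if kernel.ndim != 4 or kernel.shape[0] != kernel.shape[1]:
        raise ConstraintError(f"kernel must be (k, k, C_in, C_out), got {kernel.shape}")
    k, _, c_in, c_out = kernel.shape
    if x.shape[2] != c_in:
        raise ConstraintError(f"input has {x.shape[2]} channels but kernel expects {c_in}")
    h, w = x.shape[:2]
    ho, wo = 2 * h, 2 * w
    off = (k - 1) // 2
    out = np.empty((ho, wo, c_out), dtype=DTYPE)
    out[:] = bias
    for dy in range(k):
        ty0 = dy - off             # target row for p_y = 0
        y0 = 0 if ty0 >= 0 else (-(ty0) + 1) // 2
        t0 = 2 * y0 + ty0
        ny = min(h - y0, (ho - t0 + 1) // 2)
        if ny <= 0:
            continue
        for dx in range(k):
            tx0 = dx - off
            x0_ = 0 if tx0 >= 0 else (-(tx0) + 1) // 2
            s0 = 2 * x0_ + tx0
            nx = min(w - x0_, (wo - s0 + 1) // 2)
            if nx <= 0:
                continue
            for ci in range(c_in):
                out[t0:t0 + 2 * ny:2, s0:s0 + 2 * nx:2] += (
                    x[y0:y0 + ny, x0_:x0_ + nx, ci, None] * kernel[dy, dx, ci]
                )
    return out


def batchnorm_inference(x: np.ndarray, stats: "BNStats") -> np.ndarray:
    """Frozen-statistics batch normalisation:
    ``(x - mean) / sqrt(var + eps) * scale + shift`` per channel."""
    x = as_tensor_image(x)
    if stats.mean.shape[0] != x.shape[2]:
        raise ConstraintError(
            f"batch-norm stats are for {stats.mean.shape[0]} channels, image has {x.shape[2]}"
        )
    inv = 1.0 / np.sqrt(stats.var + stats.eps)
    return (x - stats.mean) * (inv * stats.scale) + stats.shift


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(x: np.ndarray) -> np.ndarray:
    """Numerically stable per-pixel softmax over the channel axis."""
    m = x.max(axis=-1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=-1, keepdims=True)


def argmax_mask(softmax_or_logits: np.ndarray) -> np.ndarray:
    """Per-pixel class labels; ties break toward the lowest class index."""
    return np.argmax(softmax_or_logits, axis=-1).astype(np.int32)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BNStats:
    """Frozen batch-norm statistics for one layer (per-channel vectors)."""

    mean: np.ndarray
    var: np.ndarray
    scale: np.ndarray
    shift: np.ndarray
    eps: float = 1e-5

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.var) < 0):
            raise ConstraintError("batch-norm variance must be non-negative")


@dataclass
class WeightSet:
    """All parameters of one architecture, keyed by layer index.

    ``conv[i] = (kernel, bias)`` for conv and up-conv layers;
    ``bn[i] = BNStats`` for batch-norm layers.
    """

    arch_name: str
    conv: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    bn: dict[int, BNStats] = field(default_factory=dict)
    seed: int | None = None


def _channel_trace(arch: ArchitectureSpec) -> list[int]:
    """Channel count of the tensor *entering* each layer."""
    out: list[int] = []
    ch = arch.in_channels
    produced: dict[int, int] = {}
    for i, layer in enumerate(arch.layers):
        out.append(ch)
        if layer.kind in ("conv", "upconv2"):
            ch = layer.out_channels
        elif layer.kind == "concat_skip":
            ch += produced[layer.ref]
        produced[i] = ch
    return out


def seeded_weights(arch: ArchitectureSpec, seed: int) -> WeightSet:
    """Reproducible random (untrained) weights.

    Uses ``numpy.random.Generator(PCG64(seed))`` with a fixed draw order,
    so the same seed yields bit-identical weights on every platform.
    Kernels are zero-mean Gaussian with variance ``2 / fan_in`` (He
    scaling, keeping activations non-degenerate through deep ReLU stacks);
    biases are zero and batch-norm statistics are the identity
    (mean 0, var 1, scale 1, shift 0).
    """
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    ws = WeightSet(arch_name=arch.name, seed=int(seed))
    entering = _channel_trace(arch)
    for i, layer in enumerate(arch.layers):
        c_in = entering[i]
        if layer.kind in ("conv", "upconv2"):
            k = layer.kernel
            fan_in = k * k * c_in
            kernel = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                size=(k, k, c_in, layer.out_channels))
            bias = np.zeros(layer.out_channels, dtype=DTYPE)
            ws.conv[i] = (kernel.astype(DTYPE), bias)
        elif layer.kind == "batchnorm":
            ws.bn[i] = BNStats(
                mean=np.zeros(c_in, dtype=DTYPE),
                var=np.ones(c_in, dtype=DTYPE),
                scale=np.ones(c_in, dtype=DTYPE),
                shift=np.zeros(c_in, dtype=DTYPE),
            )
    return ws


def _validate_weights(arch: ArchitectureSpec, weights: WeightSet) -> None:
    entering = _channel_trace(arch)
    for i, layer in enumerate(arch.layers):
        if layer.kind in ("conv", "upconv2"):
            if i not in weights.conv:
                raise StructureError(f"weights missing kernel for layer {i} ({layer.kind})")
            kernel, bias = weights.conv[i]
            expect = (layer.kernel, layer.kernel, entering[i], layer.out_channels)
            if tuple(kernel.shape) != expect:
                raise StructureError(
                    f"layer {i}: kernel shape {tuple(kernel.shape)} != expected {expect}"
                )
            if bias.shape != (layer.out_channels,):
                raise StructureError(f"layer {i}: bad bias shape {bias.shape}")
        elif layer.kind == "batchnorm":
            if i not in weights.bn:
                raise StructureError(f"weights missing batch-norm stats for layer {i}")
            if weights.bn[i].mean.shape != (entering[i],):
                raise StructureError(f"layer {i}: batch-norm stats have wrong channel count")


def save_weights(weights: WeightSet, path) -> None:
    """Store a :class:`WeightSet` as a compressed ``.npz`` archive with a
    small manifest (architecture name, seed)."""
    arrays: dict[str, np.ndarray] = {}
    for i, (kernel, bias) in weights.conv.items():
        arrays[f"conv{i}_kernel"] = kernel
        arrays[f"conv{i}_bias"] = bias
    for i, st in weights.bn.items():
        arrays[f"bn{i}_mean"] = st.mean
        arrays[f"bn{i}_var"] = st.var
        arrays[f"bn{i}_scale"] = st.scale
        arrays[f"bn{i}_shift"] = st.shift
        arrays[f"bn{i}_eps"] = np.asarray(st.eps)
    arrays["manifest_name"] = np.asarray(weights.arch_name)
    arrays["manifest_seed"] = np.asarray(-1 if weights.seed is None else weights.seed)
    np.savez_compressed(path, **arrays)


def load_weights(path, arch: ArchitectureSpec | None = None) -> WeightSet:
    """Load a weight archive written by :func:`save_weights`; if ``arch``
    is given, validate the shapes against it."""
    with np.load(path, allow_pickle=False) as data:
        seed = int(data["manifest_seed"])
        ws = WeightSet(arch_name=str(data["manifest_name"]),
                       seed=None if seed < 0 else seed)
        indices = {int(k[4:].split("_")[0]) for k in data.files if k.startswith("conv")}
        for i in sorted(indices):
            ws.conv[i] = (data[f"conv{i}_kernel"], data[f"conv{i}_bias"])
        bn_indices = {int(k[2:].split("_")[0]) for k in data.files if k.startswith("bn")}
        for i in sorted(bn_indices):
            ws.bn[i] = BNStats(
                mean=data[f"bn{i}_mean"], var=data[f"bn{i}_var"],
                scale=data[f"bn{i}_scale"], shift=data[f"bn{i}_shift"],
                eps=float(data[f"bn{i}_eps"]),
            )
    if arch is not None:
        _validate_weights(arch, ws)
    return ws


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def forward(arch: ArchitectureSpec, weights: WeightSet, x: np.ndarray,
            mode: str = "softmax") -> np.ndarray:
    """Run one forward pass over a single image/tile.

    Parameters
    ----------
    arch, weights
        Architecture and matching parameters (shapes are validated).
    x
        ``(H, W)`` or ``(H, W, C_in)`` array; H and W must be multiples of
        the architecture's F so skip concatenations line up.
    mode
        ``"softmax"`` (default): ReLU activations, per-pixel softmax class
        map of the same H×W as the input.
        ``"logits"``: ReLU activations, raw pre-softmax output.
        ``"linear"``: identity activations, average pooling in place of
        max pooling, no softmax — makes the map exactly affine in the
        input, which receptive-field probing relies on.

    Returns
    -------
    ``(H, W, num_classes)`` array; in softmax mode every pixel's channel
    values sum to 1.
    """
    if mode not in MODES:
        raise ConstraintError(f"mode must be one of {MODES}, got {mode!r}")
    x = as_tensor_image(x)
    F = compute_F(arch)
    h, w = x.shape[:2]
    if h % F or w % F:
        raise ConstraintError(
            f"input size {h}x{w} is not a multiple of F={F}; pad the image "
            "(e.g. tiler.pad_to_multiple) before calling forward"
        )
    if x.shape[2] != arch.in_channels:
        raise ConstraintError(
            f"architecture expects {arch.in_channels} input channels, got {x.shape[2]}"
        )
    _validate_weights(arch, weights)
    linear = mode == "linear"
    # only outputs that a later concat_skip references are kept alive
    needed = {l.ref for l in arch.layers if l.kind == "concat_skip"}
    saved: dict[int, np.ndarray] = {}
    cur = x
    for i, layer in enumerate(arch.layers):
        if layer.kind == "conv":
            kernel, bias = weights.conv[i]
            cur = conv2d(cur, kernel, bias, padding=layer.padding)
        elif layer.kind == "maxpool2":
            cur = avgpool2(cur) if linear else maxpool2(cur)
        elif layer.kind == "upconv2":
            kernel, bias = weights.conv[i]
            cur = upconv2(cur, kernel, bias)
        elif layer.kind == "concat_skip":
            skip = saved[layer.ref]
            if skip.shape[:2] != cur.shape[:2]:
                raise ConstraintError(
                    f"concat_skip at layer {i}: shapes {skip.shape} vs {cur.shape} differ"
                )
            cur = np.concatenate([skip, cur], axis=2)
        elif layer.kind == "activation":
            if not linear:
                cur = relu(cur)
        elif layer.kind == "batchnorm":
            cur = batchnorm_inference(cur, weights.bn[i])
        elif layer.kind == "softmax":
            if mode == "softmax":
                cur = softmax(cur)
        if i in needed:
            saved[i] = cur
    return cur


def make_model(arch: ArchitectureSpec, weights: WeightSet,
               mode: str = "softmax"):
    """Bind ``forward`` into a plain ``tile -> output`` callable for the tiler."""
    def model(tile: np.ndarray) -> np.ndarray:
        return forward(arch, weights, tile, mode=mode)

    model.arch = arch  # type: ignore[attr-defined]
    return model
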