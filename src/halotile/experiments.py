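"""Verification experiments: error metrics, halo sweep, stride-offset
sensitivity, and receptive-field probing.

The metrics compare a reference single-pass output ``R`` against a tiled
output ``T`` over ``K`` images of ``m x n`` pixels:

RMSE
    ``(1/K) * sum_k sqrt( sum_ij (R_ij - T_ij)^2 / (m n) )`` over all
    softmax channels.

ME (misclassification error)
    mean over the K images of the per-image count of pixels whose argmax
    class labels disagree; reported with the sample standard deviation
    across images.

MER
    ME normalised by the pixel count, ``ME / (m n)`` (multiply by 100 for
    the percentage of pixels changed by tiling).

ME is the decisive one: ME = 0 means the segmentation is identical
whether or not the image was tiled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .architecture import (
    ArchitectureSpec,
    adjust_to_multiple,
    compute_F,
    compute_halo,
    exact_halo,
    tiling_params,
)
from .engine import WeightSet, argmax_mask, as_tensor_image, forward
from .errors import ConstraintError, InconclusiveProbeError
from .tiler import make_tile_plan, pad_to_multiple, run_tiled_inference

__all__ = [
    "MetricsRow",
    "rmse",
    "misclassification_error",
    "mer",
    "reference_forward",
    "halo_sweep",
    "rows_to_frame",
    "stride_offset_experiment",
    "support_radius_oracle",
    "estimate_erf_halo",
]


def _as_list(images) -> list[np.ndarray]:
    if isinstance(images, np.ndarray):
        return [images]
    return list(images)


def rmse(refs, tiled) -> float:
    """Per-image RMSE of (softmax) outputs, averaged over the K images."""
    refs, tiled = _as_list(refs), _as_list(tiled)
    if len(refs) != len(tiled) or not refs:
        raise ConstraintError("need equally many (>= 1) reference and tiled outputs")
    total = 0.0
    for r, t in zip(refs, tiled):
        r, t = np.asarray(r, dtype=float), np.asarray(t, dtype=float)
        if r.shape != t.shape:
            raise ConstraintError(f"shape mismatch {r.shape} vs {t.shape}")
        m, n = r.shape[:2]
        total += np.sqrt(np.sum((r - t) ** 2) / (m * n))
    return total / len(refs)


def misclassification_error(refs_masks, tiled_masks) -> tuple[float, float]:
    """Mean and sample standard deviation of per-image disagreement counts.

    Masks are integer class labels (argmax of the softmax output with
    ties broken toward the lowest class index).  With a single image the
    standard deviation is reported as 0.0.
    """
    refs, tiled = _as_list(refs_masks), _as_list(tiled_masks)
    if len(refs) != len(tiled) or not refs:
        raise ConstraintError("need equally many (>= 1) reference and tiled masks")
    counts = []
    for r, t in zip(refs, tiled):
        r, t = np.asarray(r), np.asarray(t)
        if r.shape != t.shape:
            raise ConstraintError(f"shape mismatch {r.shape} vs {t.shape}")
        counts.append(int(np.count_nonzero(r != t)))
    counts = np.asarray(counts, dtype=float)
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return float(counts.mean()), sd


def mer(refs_masks, tiled_masks) -> float:
    """Misclassification error rate: ME normalised by the pixel count."""
    refs = _as_list(refs_masks)
    me, _ = misclassification_error(refs_masks, tiled_masks)
    m, n = np.asarray(refs[0]).shape[:2]
    return me / (m * n)


@dataclass(frozen=True)
class MetricsRow:
    """One halo-sweep configuration and its K-averaged error metrics."""

    tile_size: int
    zor: int
    halo: int
    rmse: float
    me: float
    me_sd: float
    mer: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mer <= 1.0) or self.rmse < 0 or self.me < 0:
            raise ConstraintError("metrics out of range")


def rows_to_frame(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    """Metrics rows as a DataFrame with the conventional column set."""
    return pd.DataFrame(
        [
            {"TileSize": r.tile_size, "ZoR": r.zor, "Halo": r.halo,
             "RMSE": r.rmse, "ME": r.me, "sd(ME)": r.me_sd, "MER": r.mer}
            for r in rows
        ]
    )


def reference_forward(arch: ArchitectureSpec, weights: WeightSet,
                      x: np.ndarray, mode: str = "softmax") -> np.ndarray:
    """Single whole-image forward pass (the tiling-free reference):
    reflection-pad to a multiple of F, run once, crop the padding off."""
    x = as_tensor_image(x)
    xp, (ph, pw) = pad_to_multiple(x, compute_F(arch))
    out = forward(arch, weights, xp, mode=mode)
    h, w = x.shape[:2]
    return out[:h, :w]


def halo_sweep(
    arch: ArchitectureSpec,
    weights: WeightSet,
    images: Iterable[np.ndarray],
    tile_size: int,
    halos: Sequence[int],
) -> list[MetricsRow]:
    """Tile with each halo in ``halos`` and measure the error against the
    single-pass reference, averaged over the images.

    Every halo must be a multiple of F (deliberately *undersized* halos are
    how tiling error is demonstrated; *invalid* ones are rejected), and
    ``tile_size`` must leave a ZoR of at least F for the largest halo.
    """
    F = compute_F(arch)
    for h in halos:
        if h % F or h < 0:
            raise ConstraintError(f"halo {h} is not a non-negative multiple of F={F}")
    images = [as_tensor_image(im) for im in _as_list(images)]
    if not images:
        raise ConstraintError("need at least one image")

    refs = [reference_forward(arch, weights, im) for im in images]
    ref_masks = [argmax_mask(r) for r in refs]

    def model(tile: np.ndarray) -> np.ndarray:
        return forward(arch, weights, tile)

    rows: list[MetricsRow] = []
    for halo in halos:
        params = tiling_params(arch, tile_size, halo=halo)
        tiled, tiled_masks = [], []
        for im in images:
            xp_shape = (adjust_to_multiple(im.shape[0], F),
                        adjust_to_multiple(im.shape[1], F))
            plan = make_tile_plan(*xp_shape, params.input_tile, params,
                                  original_size=im.shape[:2])
            out = run_tiled_inference(model, im, plan)
            tiled.append(out)
            tiled_masks.append(argmax_mask(out))
        me, sd = misclassification_error(ref_masks, tiled_masks)
        m, n = images[0].shape[:2]
        rows.append(MetricsRow(
            tile_size=tile_size, zor=params.zor, halo=halo,
            rmse=rmse(refs, tiled), me=me, me_sd=sd, mer=me / (m * n),
        ))
    return rows


def stride_offset_experiment(
    arch: ArchitectureSpec,
    weights: WeightSet,
    image: np.ndarray,
    offsets: Sequence[int] = tuple(range(32)),
    window: int = 256,
    halo: int | None = None,
) -> list[tuple[int, float]]:
    """RMSE between forward passes over windows offset by 0..max pixels.

    Overlapping ``window``-sized subregions of ``image`` are taken, each
    shifted horizontally by its offset; the softmax outputs are compared
    against the offset-0 run over the region common to all windows, inset
    by the halo so no window's border effects reach it.  The outputs agree
    exactly only at offsets that are multiples of F — any other stride
    builds the downsampled feature maps from differently aligned pixel
    blocks.
    """
    image = as_tensor_image(image)
    F = compute_F(arch)
    if halo is None:
        halo = exact_halo(arch)
    if window % F:
        raise ConstraintError(f"window {window} must be a multiple of F={F}")
    offsets = list(offsets)
    max_off = max(offsets)
    if image.shape[0] < window or image.shape[1] < window + max_off:
        raise ConstraintError(
            f"image {image.shape[:2]} too small for window {window} plus offset {max_off}"
        )
    # common region, in image coordinates
    x_lo, x_hi = max_off + halo, window - halo
    y_lo, y_hi = halo, window - halo
    if x_hi <= x_lo or y_hi <= y_lo:
        raise ConstraintError(
            f"no common region: window {window} too small for halo {halo} "
            f"and max offset {max_off}"
        )
    ref = forward(arch, weights, image[0:window, 0:window])
    ref_region = ref[y_lo:y_hi, x_lo:x_hi]
    results = []
    for off in offsets:
        if off == 0:
            results.append((0, 0.0))
            continue
        out = forward(arch, weights, image[0:window, off:off + window])
        region = out[y_lo:y_hi, x_lo - off:x_hi - off]
        results.append((off, rmse(ref_region, region)))
    return results


# ---------------------------------------------------------------------------
# Receptive-field probing
# ---------------------------------------------------------------------------
#
# The operational quantity a halo must cover is *not* the Chebyshev radius
# of one pixel's receptive field (which is phase-asymmetric: a pixel on an
# odd pooling phase reaches further one way than the other) but the
# maximum reach of any pixel of an F-aligned output block beyond the
# block's edges — ZoR boundaries are F-aligned by construction.  The
# probes below therefore measure sensitivity of the F x F aligned block
# around the probe centre and report the worst reach past its edges.

def _probe_center(arch: ArchitectureSpec, probe_size: int) -> int:
    F = compute_F(arch)
    if probe_size % F:
        raise ConstraintError(f"probe_size {probe_size} must be a multiple of F={F}")
    return (probe_size // 2 // F) * F  # F-aligned block origin near the centre


def _block_sensitivity_linear(arch: ArchitectureSpec, weights: WeightSet,
                              probe_size: int) -> np.ndarray:
    """Exact influence of every input pixel on the central F x F aligned
    output block, in linear mode: ``(probe, probe, F, F)`` array of
    max-abs channel deltas.

    In linear mode the network is affine, so the response to a unit
    impulse at pixel ``p`` minus the zero-input response isolates that
    pixel's contribution exactly; outside the receptive field the two
    forward passes perform identical arithmetic and the difference is a
    bitwise zero.  One forward pass per probe position.
    """
    F = compute_F(arch)
    c = _probe_center(arch, probe_size)
    block = np.s_[c:c + F, c:c + F]
    zero = np.zeros((probe_size, probe_size, arch.in_channels))
    base = forward(arch, weights, zero, mode="linear")[block]
    sens = np.zeros((probe_size, probe_size, F, F))
    img = zero
    for y in range(probe_size):
        for x in range(probe_size):
            img[y, x, :] = 1.0
            delta = forward(arch, weights, img, mode="linear")[block] - base
            img[y, x, :] = 0.0
            sens[y, x] = np.max(np.abs(delta), axis=-1)
    return sens


def _block_reach(active: np.ndarray, arch: ArchitectureSpec,
                 probe_size: int) -> int:
    """Worst reach of the active input pixels beyond the aligned block's
    edges (the block spans ``[c, c+F)`` in both axes); raises if the
    support touches the probe border (the probe would only lower-bound the
    true reach) or is empty."""
    F = compute_F(arch)
    c = _probe_center(arch, probe_size)
    ys, xs = np.nonzero(np.any(active, axis=(2, 3)))
    if len(ys) == 0:
        raise InconclusiveProbeError("sensitivity map is all zero (degenerate probe)")
    if (ys.min() == 0 or xs.min() == 0
            or ys.max() == probe_size - 1 or xs.max() == probe_size - 1):
        raise InconclusiveProbeError(
            f"support touches the probe border; probe_size {probe_size} is too "
            "small to bound the receptive field"
        )
    lead = max(c - int(ys.min()), c - int(xs.min()))
    trail = max(int(ys.max()), int(xs.max())) - (c + F - 1)
    return max(lead, trail, 0)


def support_radius_oracle(arch: ArchitectureSpec, weights: WeightSet,
                          probe_size: int) -> int:
    """Measured halo: worst perturbation reach beyond an aligned ZoR edge.

    For every input pixel, a unit perturbation is applied and the change
    of the central F x F aligned output block recorded; the result is the
    maximum distance from an influencing input pixel to the edge of the
    block it influences — exactly the context a tile must include per ZoR
    pixel block, i.e. the quantity
    :func:`halotile.architecture.receptive_margins` computes arithmetically.

    Runs the engine in linear mode (identity activations, average pooling)
    so no perturbation can be masked by a dead ReLU or an unselected max.
    Brute force: one forward pass per input pixel, practical for toy
    architectures (halo ≲ 32).  Matches ``max(receptive_margins(arch))``;
    equals the per-conv sum ``compute_halo(arch)`` whenever pooling phase
    effects vanish (e.g. the depth-2 U-Net).
    """
    sens = _block_sensitivity_linear(arch, weights, probe_size)
    return _block_reach(sens != 0.0, arch, probe_size)


def estimate_erf_halo(
    arch: ArchitectureSpec,
    weights: WeightSet,
    probe_size: int,
    threshold_fraction: float = 1e-4,
    mode: str = "relu",
    n_images: int = 2,
    step: float = 1e-3,
    seed: int = 0,
) -> int:
    """Halo estimate from the *effective* receptive field.

    The effective receptive field is the empirically influential subset of
    the theoretical one: the sensitivity of the aligned output block to
    each input pixel.  With ``mode="relu"`` the sensitivity is measured by
    central finite differences (step ``step``) of the pre-softmax logits
    on standard-normal noise inputs, averaged over ``n_images`` of them;
    with ``mode="linear"`` the exact impulse response is used (and
    ``threshold_fraction=0`` reproduces :func:`support_radius_oracle`).
    Input pixels with sensitivity above ``threshold_fraction`` of the peak
    define the support, whose worst reach beyond the block edge is rounded
    up to a multiple of F.

    Because kernels (learned or random) can only ignore information, never
    extend their size, the estimate never exceeds the exact halo
    (:func:`halotile.architecture.exact_halo`).
    """
    if threshold_fraction < 0:
        raise ConstraintError("threshold_fraction must be >= 0")
    F = compute_F(arch)
    if mode == "linear":
        sens = _block_sensitivity_linear(arch, weights, probe_size)
    elif mode == "relu":
        c = _probe_center(arch, probe_size)
        block = np.s_[c:c + F, c:c + F]
        rng = np.random.Generator(np.random.PCG64(int(seed)))
        sens = np.zeros((probe_size, probe_size, F, F))
        for _ in range(max(1, int(n_images))):
            x0 = rng.standard_normal((probe_size, probe_size, arch.in_channels))
            img = x0.copy()
            for y in range(probe_size):
                for x in range(probe_size):
                    img[y, x, :] = x0[y, x, :] + step
                    hi = forward(arch, weights, img, mode="logits")[block]
                    img[y, x, :] = x0[y, x, :] - step
                    lo = forward(arch, weights, img, mode="logits")[block]
                    img[y, x, :] = x0[y, x, :]
                    sens[y, x] += np.max(np.abs((hi - lo) / (2.0 * step)), axis=-1)
        sens /= max(1, int(n_images))
    else:
        raise ConstraintError(f"mode must be 'relu' or 'linear', got {mode!r}")
    peak = float(sens.max())
    if peak == 0.0:
        raise InconclusiveProbeError("all-zero sensitivity map; cannot estimate the ERF")
    reach = _block_reach(sens > threshold_fraction * peak, arch, probe_size)
    return adjust_to_multiple(reach, F)
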