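"""Exact out-of-core tiling: padding, tile planning, stitching.

The scheme: reflection-pad the image so both dimensions are multiples of
F, partition the padded canvas into non-overlapping Zones of
Responsibility (ZoRs) with a stride equal to the ZoR edge, expand each ZoR
by the halo on every side (clipped at the image bounds — beyond the image
there is no true context to supply), run the network on each expanded
tile, crop every prediction back to its ZoR, write it into the output
canvas, and finally crop the canvas back to the original image size.

With a halo of at least half the network receptive field (rounded up to a
multiple of F) every ZoR pixel sees exactly the context it would see in a
single whole-image pass, so the stitched output is identical — bitwise,
under the deterministic engine in :mod:`halotile.engine`.

Coordinates are 0-based with half-open rectangles ``[y0, y1) x [x0, x1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .architecture import TilingParams, adjust_to_multiple
from .engine import as_tensor_image
from .errors import ConstraintError, ContractError, SizeError

__all__ = [
    "Rect",
    "Tile",
    "TilePlan",
    "pad_to_multiple",
    "make_tile_plan",
    "crop_zor",
    "run_tiled_inference",
]


class Rect(NamedTuple):
    """Half-open rectangle ``[y0, y1) x [x0, x1)`` in padded-image pixels."""

    y0: int
    x0: int
    y1: int
    x1: int

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    def contains(self, other: "Rect") -> bool:
        return (self.y0 <= other.y0 and self.x0 <= other.x0
                and other.y1 <= self.y1 and other.x1 <= self.x1)


@dataclass(frozen=True)
class Tile:
    """One planned tile: its ZoR and the halo-expanded input rectangle.

    ``crop_offset`` is the (dy, dx) position of the ZoR inside the tile's
    output — equal to the ZoR origin minus the input-rectangle origin.
    """

    zor_rect: Rect
    input_rect: Rect
    crop_offset: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.input_rect.contains(self.zor_rect):
            raise ConstraintError(f"ZoR {self.zor_rect} not inside input {self.input_rect}")
        dy = self.zor_rect.y0 - self.input_rect.y0
        dx = self.zor_rect.x0 - self.input_rect.x0
        if (dy, dx) != tuple(self.crop_offset):
            raise ConstraintError("crop_offset inconsistent with rectangles")


@dataclass(frozen=True)
class TilePlan:
    """Partition of a padded image into ZoRs plus halo-expanded inputs."""

    original_size: tuple[int, int]
    padded_size: tuple[int, int]
    pads: tuple[int, int]          # bottom, right reflection pad amounts
    params: TilingParams
    tiles: tuple[Tile, ...]

    @property
    def grid_shape(self) -> tuple[int, int]:
        zor = self.params.zor
        h, w = self.padded_size
        return (-(-h // zor), -(-w // zor))

    def __len__(self) -> int:
        return len(self.tiles)


def pad_to_multiple(x: np.ndarray, F: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflection-pad bottom/right so both spatial dims are multiples of F.

    Reflection (mirror, edge pixel not repeated) preserves local image
    statistics, unlike zero padding.  Returns the padded image and the
    ``(pad_h, pad_w)`` amounts to crop off again after stitching.
    """
    if F < 1:
        raise ConstraintError(f"F must be >= 1, got {F}")
    x = as_tensor_image(x)
    h, w = x.shape[:2]
    ph = adjust_to_multiple(h, F) - h
    pw = adjust_to_multiple(w, F) - w
    if ph == 0 and pw == 0:
        return x, (0, 0)
    if ph > h - 1 or pw > w - 1:
        raise SizeError(
            f"image {h}x{w} too small to reflection-pad by ({ph}, {pw}); "
            "reflection needs at least pad+1 pixels per dimension"
        )
    return np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect"), (ph, pw)


def _axis_zors(extent: int, zor: int) -> list[tuple[int, int]]:
    """Half-open ZoR intervals along one axis: full strides plus a shorter
    remainder (itself a multiple of F because extent and zor are)."""
    out = []
    pos = 0
    while pos < extent:
        out.append((pos, min(pos + zor, extent)))
        pos += zor
    return out


def make_tile_plan(
    H: int,
    W: int,
    max_input_tile: int,
    params: TilingParams,
    original_size: tuple[int, int] | None = None,
) -> TilePlan:
    """Plan the row-major ZoR grid for a padded ``H x W`` image.

    ``H`` and ``W`` must already be multiples of ``params.F`` (use
    :func:`pad_to_multiple` first); ``max_input_tile`` must equal
    ``params.input_tile``.  The stride between ZoR origins is the ZoR
    edge; the last row/column hold the (multiple-of-F) remainders.  Input
    rectangles are the ZoRs expanded by the halo and clipped to the image
    bounds — edge tiles take no halo beyond the border, where no true
    context exists.

    ``original_size`` records the pre-padding image size so the stitched
    output can be cropped back; it defaults to ``(H, W)``.
    """
    F, halo, zor = params.F, params.halo, params.zor
    if H % F or W % F:
        raise ConstraintError(f"padded size {H}x{W} must be a multiple of F={F}")
    if max_input_tile != params.input_tile:
        raise ConstraintError(
            f"max_input_tile {max_input_tile} != params.input_tile {params.input_tile} "
            f"(= zor {zor} + 2*halo {halo})"
        )
    if max_input_tile <= 2 * halo:
        raise ConstraintError(
            f"tile too small for halo: input tile {max_input_tile} <= 2*halo {2 * halo}"
        )
    if original_size is None:
        original_size = (H, W)
    h0, w0 = original_size
    if not (0 < h0 <= H and 0 < w0 <= W):
        raise ConstraintError(f"original size {original_size} outside padded {H}x{W}")
    pads = (H - h0, W - w0)

    tiles = []
    for y0, y1 in _axis_zors(H, zor):
        for x0, x1 in _axis_zors(W, zor):
            zr = Rect(y0, x0, y1, x1)
            ir = Rect(max(0, y0 - halo), max(0, x0 - halo),
                      min(H, y1 + halo), min(W, x1 + halo))
            tiles.append(Tile(zor_rect=zr, input_rect=ir,
                              crop_offset=(y0 - ir.y0, x0 - ir.x0)))
    return TilePlan(original_size=(h0, w0), padded_size=(H, W), pads=pads,
                    params=params, tiles=tuple(tiles))


def crop_zor(tile_output: np.ndarray, tile: Tile) -> np.ndarray:
    """Extract the ZoR region from a tile's full prediction."""
    if tile_output.shape[0] != tile.input_rect.height or \
            tile_output.shape[1] != tile.input_rect.width:
        raise ContractError(
            f"tile output shape {tile_output.shape[:2]} does not match the planned "
            f"input rectangle {tile.input_rect.height}x{tile.input_rect.width}"
        )
    dy, dx = tile.crop_offset
    return tile_output[dy:dy + tile.zor_rect.height, dx:dx + tile.zor_rect.width]


def run_tiled_inference(
    model: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    plan: TilePlan,
    progress: Callable[[int, int], None] | None = None,
) -> np.ndarray:
    """Run ``model`` tile by tile and stitch the ZoRs into one output.

    ``model`` must map an ``(h, w, C_in)`` tile to an ``(h, w, C_out)``
    prediction (spatial size preserved).  ``x`` is the *original* image;
    it is reflection-padded here according to the plan.  The stitched
    result is cropped back to the original height and width, every output
    pixel having been written exactly once.  Peak working set is one input
    tile plus the output canvas.
    """
    x = as_tensor_image(x)
    if x.shape[:2] != plan.original_size:
        raise ConstraintError(
            f"image size {x.shape[:2]} does not match plan original {plan.original_size}"
        )
    xp, pads = pad_to_multiple(x, plan.params.F)
    # the plan's padded size must agree (same F → same rounding)
    if xp.shape[:2] != plan.padded_size:
        raise ConstraintError(
            f"padded size {xp.shape[:2]} does not match plan {plan.padded_size}"
        )
    canvas: np.ndarray | None = None
    for i, tile in enumerate(plan.tiles):
        ir = tile.input_rect
        out = model(xp[ir.y0:ir.y1, ir.x0:ir.x1])
        out = np.asarray(out)
        if out.ndim == 2:
            out = out[:, :, None]
        if out.shape[:2] != (ir.height, ir.width):
            raise ContractError(
                f"model changed the tile spatial size: {out.shape[:2]} != "
                f"{(ir.height, ir.width)}"
            )
        if canvas is None:
            canvas = np.empty(plan.padded_size + (out.shape[2],), dtype=out.dtype)
        zr = tile.zor_rect
        canvas[zr.y0:zr.y1, zr.x0:zr.x1] = crop_zor(out, tile)
        if progress is not None:
            progress(i + 1, len(plan.tiles))
    assert canvas is not None  # plans always contain at least one tile
    h0, w0 = plan.original_size
    return canvas[:h0, :w0]
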