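"""Declarative FCN architecture model and receptive-field (halo) arithmetic.

A fully convolutional encoder–decoder network is described as the ordered
sequence of layers along its longest input→output path.  Skip connections
are recorded as ``concat_skip`` markers that reference the earlier layer
whose output is concatenated; they carry no kernel and therefore contribute
nothing to the receptive field.

The central quantities computed here are:

``halo``
    Half of the network's theoretical receptive field,

    .. math:: \\mathrm{Halo} = \\sum_{c=0}^{N-1} 2^{l_c} \\lfloor k_c / 2 \\rfloor

    summed over the convolutional layers along the longest path, where
    ``l_c`` is the pyramid level of conv ``c`` (number of 2×2 max-pools
    minus number of 2× up-convolutions encountered before it) and ``k_c``
    its square kernel edge.  Each max-pool doubles the effective stride of
    subsequent kernels across the input image, hence the ``2^l`` factor.

``F``
    The ratio between the input image size and the smallest feature map,
    ``2^{max level}`` for these encoder–decoder forms.  Input sizes,
    tile strides and halos must all be multiples of ``F`` for tiled
    inference to reproduce the single-pass result exactly.

Up-convolutions (2× transposed convolutions) contribute zero to the halo
sum: each of their output pixels depends on at most ``ceil(k/2)`` input
pixels and that reach is absorbed by the surrounding convolution terms.
Only with this convention does the sum reproduce the known values for both
U-Net (92) and FC-DenseNet-56 (377).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ConstraintError, SizeError, StructureError

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "TilingParams",
    "assign_levels",
    "level_trace",
    "compute_halo",
    "compute_F",
    "adjust_to_multiple",
    "receptive_margins",
    "exact_halo",
    "valid_output_size",
    "tiling_params",
    "describe",
    "build_unet",
    "build_fc_densenet",
    "build_toy_densenet",
    "arch_from_config",
    "arch_to_config",
    "load_architecture",
    "save_architecture",
    "get_builtin",
    "BUILTIN_NAMES",
]

LAYER_KINDS = frozenset(
    {"conv", "maxpool2", "upconv2", "concat_skip", "activation", "batchnorm", "softmax"}
)

#: layer kinds whose receptive field depends on runtime content; the
#: declarative schema rejects them outright.
FORBIDDEN_KINDS = frozenset(
    {"attention", "self_attention", "deformable_conv", "non_local", "dilated_conv",
     "squeeze_excitation"}
)


@dataclass(frozen=True)
class LayerSpec:
    """One layer along the longest input→output path.

    Parameters
    ----------
    kind
        One of ``conv``, ``maxpool2``, ``upconv2``, ``concat_skip``,
        ``activation``, ``batchnorm``, ``softmax``.
    kernel
        Square kernel edge; required for ``conv`` and ``upconv2``.
    padding
        ``"SAME"`` or ``"VALID"``; convs only.  SAME preserves the spatial
        size, VALID shrinks each dimension by ``2 * (kernel // 2)``.
    out_channels
        Output channel count; convs and up-convs only.
    ref
        For ``concat_skip``: index of the earlier layer whose output is
        concatenated with the current tensor.
    """

    kind: str
    kernel: int | None = None
    padding: str | None = None
    out_channels: int | None = None
    ref: int | None = None

    def __post_init__(self) -> None:
        if self.kind in FORBIDDEN_KINDS:
            raise StructureError(
                f"layer kind {self.kind!r} has a dynamic receptive field and is not supported"
            )
        if self.kind not in LAYER_KINDS:
            raise StructureError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "upconv2"):
            if self.kernel is None or self.kernel < 1:
                raise StructureError(f"{self.kind} requires kernel >= 1, got {self.kernel}")
            if self.out_channels is None or self.out_channels < 1:
                raise StructureError(f"{self.kind} requires out_channels >= 1")
        if self.kind == "conv" and self.padding not in ("SAME", "VALID"):
            raise StructureError(f"conv padding must be SAME or VALID, got {self.padding!r}")
        if self.kind == "concat_skip" and (self.ref is None or self.ref < 0):
            raise StructureError("concat_skip requires a non-negative ref layer index")


@dataclass(frozen=True)
class ArchitectureSpec:
    """An FCN as an ordered layer sequence along its longest path."""

    name: str
    layers: tuple[LayerSpec, ...]
    in_channels: int = 1
    num_classes: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.in_channels < 1 or self.num_classes < 1:
            raise StructureError("in_channels and num_classes must be >= 1")
        for i, layer in enumerate(self.layers):
            if layer.kind == "concat_skip" and layer.ref >= i:
                raise StructureError(
                    f"concat_skip at index {i} references a non-earlier layer {layer.ref}"
                )
        # raises StructureError on malformed pool/up-conv sequences
        level_trace(self)

    @property
    def conv_layers(self) -> tuple[tuple[int, LayerSpec], ...]:
        """(index, layer) pairs for the convolutional layers, in order."""
        return tuple((i, l) for i, l in enumerate(self.layers) if l.kind == "conv")

    @property
    def n_convs(self) -> int:
        """Number of convolutions N along the longest path (up-convs excluded)."""
        return sum(1 for l in self.layers if l.kind == "conv")

    @property
    def has_batchnorm(self) -> bool:
        return any(l.kind == "batchnorm" for l in self.layers)


def level_trace(arch: ArchitectureSpec) -> list[int]:
    """Level of the tensor *entering* each layer, one entry per layer.

    The level starts at 0 at the input, each ``maxpool2`` raises it by one
    and each ``upconv2`` lowers it by one.  Raises
    :class:`~halotile.errors.StructureError` if the level would drop below
    zero (an up-conv with no matching earlier max-pool), if a skip
    concatenation joins tensors of different levels, or if the network does
    not return to level 0 at the output.
    """
    levels: list[int] = []
    level = 0
    for i, layer in enumerate(arch.layers):
        levels.append(level)
        if layer.kind == "maxpool2":
            level += 1
        elif layer.kind == "upconv2":
            level -= 1
            if level < 0:
                raise StructureError(
                    f"upconv2 at index {i} has more up-convs than preceding max-pools"
                )
        elif layer.kind == "concat_skip":
            # up-conv precedes the concat, so compare against the incoming level
            ref_out_level = _output_level(arch, levels, layer.ref)
            if ref_out_level != level:
                raise StructureError(
                    f"concat_skip at index {i} joins level {level} with level "
                    f"{ref_out_level} (layer {layer.ref}); skip branches must rejoin "
                    "at equal level"
                )
    if level != 0:
        raise StructureError(
            f"network ends at level {level}; encoder and decoder are not symmetric"
        )
    return levels


def _output_level(arch: ArchitectureSpec, entry_levels: list[int], index: int) -> int:
    """Level of the tensor *produced* by layer ``index``."""
    layer = arch.layers[index]
    lvl = entry_levels[index]
    if layer.kind == "maxpool2":
        return lvl + 1
    if layer.kind == "upconv2":
        return lvl - 1
    return lvl


def assign_levels(arch: ArchitectureSpec) -> list[int]:
    """Level ``l_c`` of every convolutional layer along the longest path.

    Examples
    --------
    >>> assign_levels(build_unet(depth=2))
    [0, 0, 1, 1, 0, 0, 0]
    """
    trace = level_trace(arch)
    return [trace[i] for i, _ in arch.conv_layers]


def compute_halo(arch: ArchitectureSpec) -> int:
    """Theoretical halo: half the network receptive field, in pixels.

    Sum over the convolutions along the longest path of
    ``2**level * (kernel // 2)``.  1×1 convolutions contribute zero
    (``1 // 2 == 0``), as do up-convolutions and skip concatenations.

    >>> compute_halo(build_unet(depth=5))
    92
    """
    levels = assign_levels(arch)
    return sum(
        (2 ** lvl) * (layer.kernel // 2)
        for lvl, (_, layer) in zip(levels, arch.conv_layers)
    )


def compute_F(arch: ArchitectureSpec) -> int:
    """Downsampling ratio F between the input size and the smallest feature map.

    For encoder–decoder networks this is ``2**max(level)``.  Every input
    size, tile stride and halo must be a multiple of F.

    >>> compute_F(build_unet(depth=5))
    16
    """
    return 2 ** max(level_trace(arch), default=0)


def adjust_to_multiple(value: int, F: int) -> int:
    """Round ``value`` up to the closest multiple of ``F``.

    >>> adjust_to_multiple(92, 16)
    96
    """
    if F < 1:
        raise ConstraintError(f"F must be a positive integer, got {F}")
    if value < 0:
        raise ConstraintError(f"value must be non-negative, got {value}")
    return F * math.ceil(value / F)


def valid_output_size(arch: ArchitectureSpec, input_size: int) -> int:
    """Output edge length if every conv used VALID padding.

    Walks the layer sequence shrinking by ``2 * (k // 2)`` per conv, halving
    at max-pools and doubling at up-convs.  For symmetric encoder–decoder
    builds the result equals ``input_size - 2 * compute_halo(arch)`` — the
    classical 572 → 388 shrinkage of the original valid-padded U-Net.

    Raises
    ------
    SizeError
        If a feature map collapses to a non-positive size, or a max-pool
        receives an odd size (the walk would no longer be exact).
    """
    size = int(input_size)
    for i, layer in enumerate(arch.layers):
        if layer.kind == "conv":
            size -= 2 * (layer.kernel // 2)
            if size <= 0:
                raise SizeError(
                    f"feature map collapses to {size} px at conv layer index {i} "
                    f"(kernel {layer.kernel}) for input {input_size}"
                )
        elif layer.kind == "maxpool2":
            if size % 2:
                raise SizeError(
                    f"odd size {size} px reaches maxpool2 at layer index {i}; "
                    f"choose a larger input than {input_size}"
                )
            size //= 2
            if size <= 0:  # pragma: no cover - unreachable after the odd check
                raise SizeError(f"feature map collapses at maxpool2 index {i}")
        elif layer.kind == "upconv2":
            size *= 2
    return size


def receptive_margins(arch: ArchitectureSpec) -> tuple[int, int]:
    """Exact one-sided context requirements beyond an F-aligned block edge.

    ``compute_halo`` (the per-conv sum) is the classical receptive-field
    half-width, but the context a tile really needs is slightly larger: it
    is the maximum, over the F output phases of an aligned block, of how
    far a pixel's receptive field reaches past the block's leading
    (top/left) and trailing (bottom/right) edges.  Two effects push this
    past the per-conv sum:

    * pooling phase round-up — a pooled cell is shared by F-phase
      siblings, so a pixel inherits the reach of its widest sibling
      through every pool/up-conv round trip (a few pixels for U-Net:
      94 vs 92 at depth 5);
    * stride-2 transposed convs with kernel ≥ 3 — each output pixel on an
      odd phase depends on one *extra* coarse cell on the trailing side,
      adding ``2^level`` pixels per up-conv (FC-DenseNet-56: trailing
      reach 413 vs the per-conv sum 377).

    Computed by walking the layer sequence backward with exact integer
    interval arithmetic for each phase; brute-force perturbation probes
    (:func:`halotile.experiments.support_radius_oracle`) confirm the walk.
    Returns ``(lead, trail)`` in input pixels.
    """
    F = compute_F(arch)
    base = 8 * F  # any aligned anchor comfortably away from 0
    lead = trail = 0
    for phase in range(F):
        lo = hi = base + phase
        for layer in reversed(arch.layers):
            if layer.kind == "conv":
                r = layer.kernel // 2
                lo -= r
                hi += r
            elif layer.kind == "maxpool2":
                # reversed: one coarse cell covers two fine pixels
                lo, hi = 2 * lo, 2 * hi + 1
            elif layer.kind == "upconv2":
                # reversed: fine pixel q depends on coarse p with
                # 2p + d - off = q, d in [0, k)
                k, off = layer.kernel, (layer.kernel - 1) // 2
                lo = -((-(lo + off - k + 1)) // 2)
                hi = (hi + off) // 2
        lead = max(lead, base - lo)
        trail = max(trail, hi - (base + F - 1))
    return lead, trail


def exact_halo(arch: ArchitectureSpec) -> int:
    """Smallest multiple-of-F halo guaranteeing bitwise tiled/whole-image
    equality under the deterministic engine.

    ``adjust_to_multiple(max(receptive_margins(arch)), F)``.  For the
    published U-Net this coincides with the F-rounded per-conv halo
    (96); for networks with 3×3 transposed convs it is one alignment unit
    larger than that rounding.
    """
    F = compute_F(arch)
    return adjust_to_multiple(max(receptive_margins(arch)), F)


# ---------------------------------------------------------------------------
# Tiling parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TilingParams:
    """Pixel bookkeeping for one architecture / input-tile-size pair.

    ``halo_raw`` is the theoretical halo; ``halo`` the value actually used
    for planning (the raw halo rounded up to a multiple of F, unless
    deliberately overridden for error experiments); ``zor`` the Zone of
    Responsibility edge (= output stride); ``input_tile = zor + 2 * halo``.
    """

    halo_raw: int
    halo: int
    zor: int
    F: int

    def __post_init__(self) -> None:
        if self.F < 1:
            raise ConstraintError(f"F must be >= 1, got {self.F}")
        if self.halo < 0 or self.halo % self.F:
            raise ConstraintError(
                f"halo must be a non-negative multiple of F={self.F}, got {self.halo}; "
                "round it with adjust_to_multiple first (raw halos are rejected, not "
                "silently rounded)"
            )
        if self.zor < self.F or self.zor % self.F:
            raise ConstraintError(
                f"ZoR must be a positive multiple of F={self.F} (>= F), got {self.zor}"
            )

    @property
    def input_tile(self) -> int:
        return self.zor + 2 * self.halo


def tiling_params(
    arch: ArchitectureSpec,
    tile_size: int,
    halo: int | None = None,
) -> TilingParams:
    """Tiling parameters for running ``arch`` with square input tiles.

    Parameters
    ----------
    arch
        The architecture to tile.
    tile_size
        Edge of the (maximum) square input tile fed to the network,
        typically chosen from the accelerator memory budget.  Must be a
        multiple of F and large enough to leave ``zor >= F``.
    halo
        Override for the halo actually used (must be a multiple of F).
        Defaults to :func:`exact_halo`, which guarantees bitwise
        tiled/whole-image equality; smaller values are only useful to
        *demonstrate* tiling error.
    """
    F = compute_F(arch)
    halo_raw = compute_halo(arch)
    if halo is None:
        halo = exact_halo(arch)
    if tile_size % F:
        raise ConstraintError(f"tile_size {tile_size} is not a multiple of F={F}")
    zor = tile_size - 2 * halo
    if zor < F:
        raise ConstraintError(
            f"tile_size {tile_size} too small for halo {halo}: ZoR would be {zor} < F={F}"
        )
    return TilingParams(halo_raw=halo_raw, halo=halo, zor=zor, F=F)


def describe(arch: ArchitectureSpec) -> dict:
    """Summary dictionary: name, N, per-conv levels, halo_raw, halo
    (F-rounded), halo_exact (planning default), F."""
    F = compute_F(arch)
    halo_raw = compute_halo(arch)
    return {
        "name": arch.name,
        "n_convs": arch.n_convs,
        "levels": assign_levels(arch),
        "halo_raw": halo_raw,
        "halo": adjust_to_multiple(halo_raw, F),
        "halo_exact": exact_halo(arch),
        "F": F,
    }


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

class _Builder:
    """Incremental layer-list builder tracking indices and channel widths."""

    def __init__(self, in_channels: int) -> None:
        self.layers: list[LayerSpec] = []
        self.channels = in_channels
        self._saved_channels: dict[int, int] = {}

    def add(self, layer: LayerSpec) -> int:
        idx = len(self.layers)
        self.layers.append(layer)
        if layer.kind in ("conv", "upconv2"):
            self.channels = layer.out_channels
        elif layer.kind == "concat_skip":
            self.channels += self._saved_channels[layer.ref]
        self._saved_channels[idx] = self.channels
        return idx

    def conv(self, kernel: int, out_channels: int, padding: str = "SAME") -> int:
        return self.add(LayerSpec("conv", kernel=kernel, padding=padding,
                                  out_channels=out_channels))

    def conv_block(self, kernel: int, out_channels: int, batchnorm: bool = True) -> int:
        """conv → activation → (batchnorm); returns the index of the last layer."""
        self.conv(kernel, out_channels)
        idx = self.add(LayerSpec("activation"))
        if batchnorm:
            idx = self.add(LayerSpec("batchnorm"))
        return idx


def build_unet(
    depth: int = 5,
    base_channels: int = 64,
    num_classes: int = 2,
    in_channels: int = 1,
    batchnorm: bool = True,
) -> ArchitectureSpec:
    """U-Net encoder–decoder with SAME convolutions and frozen batch-norm.

    ``depth`` counts the encoder levels including the bottleneck; the
    published topology is ``depth=5`` (two 3×3 convs per level, 2×2
    max-pools, 2×2 up-convs, skip concatenations, final 1×1 conv), with a
    theoretical halo of 92 and F = 16.  Smaller depths give toy networks
    whose halos stay small enough for brute-force receptive-field probing.
    """
    if depth < 2:
        raise StructureError(f"build_unet requires depth >= 2, got {depth}")
    b = _Builder(in_channels)
    skips: dict[int, int] = {}
    for d in range(depth):
        ch = base_channels * 2 ** d
        b.conv_block(3, ch, batchnorm)
        skips[d] = b.conv_block(3, ch, batchnorm)
        if d < depth - 1:
            b.add(LayerSpec("maxpool2"))
    for d in range(depth - 2, -1, -1):
        ch = base_channels * 2 ** d
        b.add(LayerSpec("upconv2", kernel=2, out_channels=ch))
        b.add(LayerSpec("concat_skip", ref=skips[d]))
        b.conv_block(3, ch, batchnorm)
        b.conv_block(3, ch, batchnorm)
    b.conv(1, num_classes)
    b.add(LayerSpec("softmax"))
    return ArchitectureSpec(
        name=f"unet-d{depth}" if depth != 5 else "unet",
        layers=tuple(b.layers),
        in_channels=in_channels,
        num_classes=num_classes,
    )


def _densenet(
    name: str,
    down_blocks: Sequence[int],
    bottleneck: int,
    up_blocks: Sequence[int],
    growth: int,
    initial_channels: int,
    num_classes: int,
    in_channels: int,
) -> ArchitectureSpec:
    """Fully convolutional DenseNet (Tiramisu-style) layer sequence.

    Each dense block of ``n`` layers chains ``n`` 3×3 convs, every conv
    consuming the concatenation of the block input and all previous conv
    outputs (modelled as conv → concat-with-previous pairs); transitions
    down are a 1×1 conv plus 2×2 max-pool, transitions up a 3×3 transposed
    conv (stride 2) followed by a skip concatenation with the matching
    down-path block output.  The longest path traverses every 3×3 conv of
    every dense block, so each block contributes ``n * 2**level`` pixels of
    halo.
    """
    if len(down_blocks) != len(up_blocks):
        raise StructureError("down and up paths must have the same number of dense blocks")
    b = _Builder(in_channels)
    b.conv_block(3, initial_channels)

    def dense_block(n_layers: int) -> int:
        for _ in range(n_layers):
            entry = len(b.layers) - 1  # tensor entering this conv
            b.conv_block(3, growth)
            b.add(LayerSpec("concat_skip", ref=entry))
        return len(b.layers) - 1

    skips: list[int] = []
    for n in down_blocks:
        skips.append(dense_block(n))
        b.conv_block(1, b.channels)  # transition down: 1x1 conv, then pool
        b.add(LayerSpec("maxpool2"))
    dense_block(bottleneck)
    for n, skip in zip(up_blocks, reversed(skips)):
        b.add(LayerSpec("upconv2", kernel=3, out_channels=b.channels))
        b.add(LayerSpec("concat_skip", ref=skip))
        dense_block(n)
    b.conv(1, num_classes)
    b.add(LayerSpec("softmax"))
    return ArchitectureSpec(name=name, layers=tuple(b.layers),
                            in_channels=in_channels, num_classes=num_classes)


#: dense-block layer counts (down path | bottleneck | up path) and growth rate
_DENSENET_CONFIGS = {
    56: ([4] * 5, 4, [4] * 5, 12),
    67: ([5] * 5, 5, [5] * 5, 16),
    103: ([4, 5, 7, 10, 12], 15, [12, 10, 7, 5, 4], 16),
}


def build_fc_densenet(
    variant: int = 56,
    num_classes: int = 2,
    in_channels: int = 1,
) -> ArchitectureSpec:
    """FC-DenseNet-56/67/103 for semantic segmentation.

    Five pooling stages give F = 32; the theoretical halos are 377 (56),
    471 (67) and 1109 (103), adjusting to 384 / 480 / 1120.
    """
    try:
        down, bottleneck, up, growth = _DENSENET_CONFIGS[int(variant)]
    except (KeyError, ValueError):
        raise StructureError(
            f"unknown FC-DenseNet variant {variant!r}; choose one of 56, 67, 103"
        ) from None
    return _densenet(f"fc-densenet-{variant}", down, bottleneck, up, growth,
                     initial_channels=48, num_classes=num_classes,
                     in_channels=in_channels)


def build_toy_densenet(
    n_pool: int = 2,
    layers_per_block: int = 2,
    growth: int = 4,
    initial_channels: int = 4,
    num_classes: int = 2,
    in_channels: int = 1,
) -> ArchitectureSpec:
    """Growth-rate-reduced FC-DenseNet replica small enough for brute-force
    receptive-field probing and fast exactness tests."""
    if n_pool < 1 or layers_per_block < 1:
        raise StructureError("n_pool and layers_per_block must be >= 1")
    blocks = [layers_per_block] * n_pool
    return _densenet(
        f"toy-densenet-p{n_pool}l{layers_per_block}g{growth}",
        blocks, layers_per_block, blocks, growth,
        initial_channels=initial_channels, num_classes=num_classes,
        in_channels=in_channels,
    )


BUILTIN_NAMES = (
    "unet", "unet-d2", "unet-d3",
    "fc-densenet-56", "fc-densenet-67", "fc-densenet-103",
    "toy-densenet",
)


def get_builtin(name: str, num_classes: int = 2, in_channels: int = 1,
                base_channels: int = 64) -> ArchitectureSpec:
    """Look up a built-in architecture by name (see :data:`BUILTIN_NAMES`)."""
    key = name.lower().replace("_", "-")
    if key.startswith("unet"):
        depth = 5 if key == "unet" else int(key.split("-d")[1])
        return build_unet(depth=depth, base_channels=base_channels,
                          num_classes=num_classes, in_channels=in_channels)
    if key.startswith("fc-densenet-"):
        return build_fc_densenet(int(key.rsplit("-", 1)[1]),
                                 num_classes=num_classes, in_channels=in_channels)
    if key == "toy-densenet":
        return build_toy_densenet(num_classes=num_classes, in_channels=in_channels)
    raise StructureError(f"unknown architecture {name!r}; built-ins: {BUILTIN_NAMES}")


# ---------------------------------------------------------------------------
# Declarative config round-trip
# ---------------------------------------------------------------------------

def arch_to_config(arch: ArchitectureSpec) -> dict:
    """Flat declarative form of an architecture (YAML/JSON friendly)."""
    layers = []
    for layer in arch.layers:
        entry: dict = {"kind": layer.kind}
        if layer.kernel is not None:
            entry["kernel"] = layer.kernel
        if layer.padding is not None:
            entry["padding"] = layer.padding
        if layer.out_channels is not None:
            entry["channels"] = layer.out_channels
        if layer.ref is not None:
            entry["ref"] = layer.ref
        layers.append(entry)
    return {
        "name": arch.name,
        "in_channels": arch.in_channels,
        "num_classes": arch.num_classes,
        "layers": layers,
    }


def arch_from_config(config: dict) -> ArchitectureSpec:
    """Build an :class:`ArchitectureSpec` from its declarative form.

    Unknown or dynamic-receptive-field layer kinds are rejected by the
    :class:`LayerSpec` validator.
    """
    try:
        raw_layers = config["layers"]
    except KeyError:
        raise StructureError("architecture config must contain a 'layers' list") from None
    layers = [
        LayerSpec(
            kind=entry["kind"],
            kernel=entry.get("kernel"),
            padding=entry.get("padding"),
            out_channels=entry.get("channels"),
            ref=entry.get("ref"),
        )
        for entry in raw_layers
    ]
    return ArchitectureSpec(
        name=str(config.get("name", "custom")),
        layers=tuple(layers),
        in_channels=int(config.get("in_channels", 1)),
        num_classes=int(config.get("num_classes", 2)),
    )


def save_architecture(arch: ArchitectureSpec, path) -> None:
    """Write the declarative config as YAML."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(arch_to_config(arch), fh, sort_keys=False)


def load_architecture(path) -> ArchitectureSpec:
    """Read a declarative YAML config written by :func:`save_architecture`."""
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh)
    return arch_from_config(config)
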