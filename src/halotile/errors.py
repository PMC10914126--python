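"""Exception hierarchy for halotile.

All errors derive from :class:`HalotileError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
malformed architectures, size/constraint violations and probe failures.
"""


class HalotileError(Exception):
    """Base class for all halotile errors."""


class StructureError(HalotileError, ValueError):
    """The layer sequence is not a valid encoder–decoder network
    (e.g. an up-convolution with no preceding max-pool)."""


class SizeError(HalotileError, ValueError):
    """A spatial size became invalid while walking the layer sequence
    (feature map collapsed to a non-positive or odd size)."""


class ConstraintError(HalotileError, ValueError):
    """A tiling constraint was violated (size not a multiple of F,
    halo not a multiple of F, tile too small for the halo, ...)."""


class ContractError(HalotileError, ValueError):
    """A callable handed to the tiler broke its contract
    (e.g. the model changed the spatial size of a tile)."""


class InconclusiveProbeError(HalotileError, RuntimeError):
    """A receptive-field probe could not produce a definite answer
    (support touched the probe border, or the sensitivity map was all zero)."""
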