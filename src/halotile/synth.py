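"""Synthetic fixtures: seeded noise fields and colony-like blob images.

The noise generator reproduces the verification setting this package is
validated under: standard-normal pixels (mean 0, sd 1) fed to seeded,
untrained networks.  Tiling exactness is a property of the architecture
and the arithmetic, not of the weights or the image content, so noise plus
random weights exercises it fully.  The blob generator exists for visually
meaningful demos (soft-edged elliptical foreground objects on a noisy
background, loosely imitating phase-contrast stem-cell colonies) and comes
with its ground-truth mask.
"""

from __future__ import annotations

import numpy as np

from .errors import ConstraintError

__all__ = ["generate_noise_image", "generate_blob_image"]


def generate_noise_image(h: int, w: int, seed: int, channels: int = 1) -> np.ndarray:
    """Seeded standard-normal noise image of shape ``(h, w, channels)``."""
    if h < 1 or w < 1 or channels < 1:
        raise ConstraintError("image dimensions must be positive")
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    return rng.standard_normal((h, w, channels))


def generate_blob_image(
    h: int,
    w: int,
    n_blobs: int,
    seed: int,
    mean_radius: float | None = None,
    amplitude: float = 3.0,
    noise_sd: float = 1.0,
    edge_softness: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-edged elliptical foreground blobs on Gaussian background noise.

    Returns ``(image, mask)`` where ``image`` is ``(h, w, 1)`` float and
    ``mask`` the uint8 ground truth (1 inside a blob).  Blob centres,
    radii (uniform in ``[mean_radius/2, 3*mean_radius/2]``) and
    orientations are drawn from the seeded generator; edges fall off over
    ``edge_softness`` pixels so foreground intensity blends into the
    background the way out-of-focus colony borders do.
    """
    if n_blobs < 0:
        raise ConstraintError("n_blobs must be >= 0")
    if mean_radius is None:
        mean_radius = min(h, w) / 8.0
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    image = rng.normal(0.0, noise_sd, (h, w))
    soft_total = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = rng.uniform(0.5, 1.5) * mean_radius
        rx = rng.uniform(0.5, 1.5) * mean_radius
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        # signed "distance" from the ellipse boundary, ~pixels near the edge
        d = (np.sqrt((u / rx) ** 2 + (v / ry) ** 2) - 1.0) * min(rx, ry)
        soft = 1.0 / (1.0 + np.exp(np.clip(d / edge_softness, -50, 50)))
        soft_total = np.maximum(soft_total, soft)
    image = image + amplitude * soft_total
    mask = (soft_total > 0.5).astype(np.uint8)
    return image[:, :, None], mask
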