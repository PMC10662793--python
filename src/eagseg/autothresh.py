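"""Automatic local thresholding around the primary tumor.

After a first growth pass, a disk (2D) or sphere (3D) target region is
built around the tumor's intensity-weighted centroid ("color-intensity
center"): its radius is the maximum distance from that center to any
boundary point of the primary tumor, plus a margin (default 5 pixels).
The working threshold is then recomputed as a fraction (default 20%) of
the Otsu grey level inside this region -- which, in a locally bright
tumor neighborhood, shifts toward 1 relative to the global grey level --
and growth is re-run from the original user seed with the new threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .growth import GrowthConfig, GrowthResult, grow_region, otsu_level
from .io import as_image

__all__ = [
    "LocalTargetRegion",
    "intensity_center",
    "build_target_region",
    "regrow_with_local_threshold",
]

DEFAULT_MARGIN = 5.0
DEFAULT_FRACTION = 0.20


@dataclass
class LocalTargetRegion:
    """Disk/sphere around the tumor's color-intensity center."""

    center: tuple[float, ...]
    radius: float
    mask: np.ndarray


def intensity_center(img, mask) -> tuple[float, ...]:
    """Intensity-weighted centroid of ``mask`` (center of color intensity).

    Each point contributes its coordinates weighted by its intensity:
    ``c_axis = sum_i I(p_i) * coord_axis(p_i) / sum_i I(p_i)``.
    """
    image = as_image(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape differs from image shape")
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        raise ValueError("intensity_center: empty mask")
    w = image.data[idx]
    total = float(w.sum())
    if total <= 0:
        raise ValueError("intensity_center: total intensity is not positive")
    return tuple(float((w * coords).sum() / total) for coords in idx)


def _distance_grid(shape, center) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    sq = np.zeros(shape, dtype=float)
    for g, c in zip(grids, center):
        sq += (g - c) ** 2
    return np.sqrt(sq)


def build_target_region(img, primary: GrowthResult, margin: float = DEFAULT_MARGIN) -> LocalTargetRegion:
    """Target region = disk/sphere of radius (max boundary distance + margin).

    The center is the intensity-weighted centroid of the primary mask and
    the radius is measured to the farthest primary boundary point; the
    region is clipped to the image bounds and always contains the primary
    mask.
    """
    image = as_image(img)
    mask = np.asarray(primary.mask, dtype=bool)
    center = intensity_center(image, mask)
    boundary = np.asarray(primary.boundary, dtype=float)
    if boundary.size == 0:
        raise ValueError("build_target_region: primary result has no boundary")
    dist = np.sqrt(((boundary - np.asarray(center)) ** 2).sum(axis=1))
    radius = float(dist.max()) + float(margin)
    region = _distance_grid(image.shape, center) <= radius
    return LocalTargetRegion(center=center, radius=radius, mask=region)


def regrow_with_local_threshold(
    img,
    seed,
    primary: GrowthResult,
    config: GrowthConfig,
    fraction: float = DEFAULT_FRACTION,
    margin: float = DEFAULT_MARGIN,
) -> GrowthResult:
    """Re-run growth from the user seed with the local working threshold.

    The local Otsu level is computed over the raw target region (the lung
    mask is *not* applied there), but the regrowth itself keeps all
    constraints of ``config``, including the lung mask.
    """
    image = as_image(img)
    region = build_target_region(image, primary, margin=margin)
    level = otsu_level(image.data[region.mask])
    new_threshold = fraction * level
    return grow_region(image, seed, replace(config, threshold=new_threshold))
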