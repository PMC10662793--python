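"""Contrast augmentation and lung-area appointment.

Both steps precede growth. Contrast augmentation is a saturating
quantile stretch (the classic ``imadjust`` behavior, applied over the
whole volume in 3D). Lung appointment separates the dark lung fields
from background air and the bright thorax by a global Otsu split,
discards border-connected dark components (background air), keeps
lung-scale dark components, and then closes + hole-fills so that bright
structures inside the lung (tumor, vessels) belong to the mask. The
resulting mask is used to keep growth from leaking into the chest wall
when a tumor is attached to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, disk

from .growth import otsu_level
from .io import IntensityImage, as_image

__all__ = ["LungMask", "augment_contrast", "segment_lung_mask"]


@dataclass
class LungMask:
    mask: np.ndarray
    component_count: int


def augment_contrast(
    img, low_frac: float = 0.01, high_frac: float = 0.99
) -> IntensityImage:
    """Saturating linear stretch between two intensity quantiles.

    Values at/below the ``low_frac`` quantile map to 0, at/above the
    ``high_frac`` quantile to 1, linear in between. For volumes the
    quantiles are computed over the whole volume. Defaults saturate 1%
    at each tail. A constant image is returned unchanged with a warning.
    """
    if not (0 <= low_frac < high_frac <= 1):
        raise ValueError("need 0 <= low_frac < high_frac <= 1")
    image = as_image(img)
    data = image.data
    lo, hi = np.quantile(data, [low_frac, high_frac])
    if hi <= lo:
        warnings.warn("augment_contrast: constant image, returned unchanged")
        return IntensityImage(data.copy(), image.spacing)
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return IntensityImage(out, image.spacing)


def _border_labels(labels: np.ndarray) -> np.ndarray:
    faces = []
    for ax in range(labels.ndim):
        sl = [slice(None)] * labels.ndim
        sl[ax] = 0
        faces.append(labels[tuple(sl)].ravel())
        sl[ax] = -1
        faces.append(labels[tuple(sl)].ravel())
    vals = np.unique(np.concatenate(faces))
    return vals[vals > 0]


def segment_lung_mask(
    img, min_component_frac: float = 0.005, closing_radius: int = 3
) -> LungMask:
    """Appoint the lung area of a normalized chest image.

    Steps: (1) global Otsu split into dark (air-like) vs bright (body);
    (2) drop dark components connected to the image border (background
    air); (3) keep interior dark components covering at least
    ``min_component_frac`` of the image (the lungs; vessel-scale specks
    are rejected); (4) morphological closing followed by hole filling so
    tumors enclosed by lung are inside the mask. The returned mask never
    intersects the border-connected background, and the pre-closing mask
    is always a subset of it.
    """
    image = as_image(img)
    data = image.data
    nd = data.ndim
    structure = np.ones((3,) * nd, dtype=bool)

    level = otsu_level(data)
    dark = data < level
    empty = LungMask(np.zeros(data.shape, dtype=bool), 0)
    if not dark.any():
        warnings.warn("segment_lung_mask: no dark region found; empty lung mask")
        return empty

    labels, _ = ndimage.label(dark, structure=structure)
    border = _border_labels(labels)
    background = np.isin(labels, border)

    sizes = np.bincount(labels.ravel())
    min_size = min_component_frac * data.size
    keep = [
        lab
        for lab in range(1, sizes.size)
        if lab not in set(border.tolist()) and sizes[lab] >= min_size
    ]
    if not keep:
        warnings.warn(
            "segment_lung_mask: no interior dark component survived; empty lung mask"
        )
        return empty
    lungs = np.isin(labels, keep)

    footprint = disk(closing_radius) if nd == 2 else ball(closing_radius)
    closed = ndimage.binary_closing(lungs, structure=footprint) | lungs
    filled = ndimage.binary_fill_holes(closed)
    filled &= ~background
    filled |= lungs

    count = int(ndimage.label(filled, structure=structure)[1])
    return LungMask(mask=filled, component_count=count)
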