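"""Parametric chest-CT-like phantoms with exact ground truth.

A phantom emulates the structures the segmentation pipeline cares about:
a bright thorax (soft tissue) on a dark background (air), two dark lung
fields, a brighter tumor blob inside one lung -- optionally tangent to
the lung wall, optionally with a dimmer protruding lobe, optionally
fragmented -- plus a few vessel-scale bright dots and additive Gaussian
noise. Edges are softened with a small Gaussian kernel, which is the
hard case the local-threshold and edge-refinement stages exist for.
Truth masks (tumor and lungs) are exact by construction.

These phantoms are geometric, not anatomic: no airways, no HU physics,
no texture. What passing tests on them shows is that the algorithm
recovers a bright, mostly-star-shaped blob in a dark field under noise
and soft edges; they say nothing about pathology variety in real CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import IntensityImage

__all__ = ["PhantomSpec", "PhantomSpecError", "generate_phantom"]


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically impossible."""


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic chest image.

    Intensities are means in [0, 1]. The tumor must be brighter than the
    lung field (as in CT, where solid tumor is soft tissue and lung is
    mostly air). ``wall_attached`` places the tumor ``wall_gap`` pixels
    short of the lateral lung wall and joins it to the wall with a
    narrow stalk of tumor tissue (a pleural tail) ``stalk_halfwidth``
    pixels wide, which merges with the thorax intensity at the pleura.
    ``fragments=2`` produces a second, detached blob (the known failure
    mode of single-seed growth).
    """

    shape: tuple[int, ...] = (128, 128)
    background_intensity: float = 0.05
    thorax_intensity: float = 0.85
    lung_intensity: float = 0.15
    tumor_intensity: float = 0.65
    noise_sd: float = 0.03
    smoothing_sigma: float = 1.0
    tumor_center: tuple[float, ...] | None = None
    tumor_radius: float = 12.0
    wall_attached: bool = False
    wall_gap: float = 4.0
    stalk_halfwidth: float = 1.5
    lobe: bool = False
    lobe_radius: float = 5.0
    lobe_intensity: float | None = None
    fragments: int = 1
    vessel_count: int = 6
    vessel_radius: float = 1.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) not in (2, 3):
            raise PhantomSpecError("shape must be 2D or 3D")
        if not (self.tumor_intensity > self.lung_intensity):
            raise PhantomSpecError("tumor must be brighter than the lung field")
        if self.fragments not in (1, 2):
            raise PhantomSpecError("fragments must be 1 or 2")


def _ellipse_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    q = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        q += ((g - c) / a) ** 2
    return q <= 1.0


def _ball_mask(shape, center, radius) -> np.ndarray:
    return _ellipse_mask(shape, center, (radius,) * len(shape))


def _geometry(shape):
    """Thorax / lung ellipse parameters for a given image shape."""
    nd = len(shape)
    c = tuple((s - 1) / 2.0 for s in shape)
    if nd == 2:
        H, W = shape
        thorax = (c, (0.44 * H, 0.46 * W))
        lung_semi = (0.30 * H, 0.16 * W)
        left = ((c[0], c[1] - 0.22 * W), lung_semi)
        right = ((c[0], c[1] + 0.22 * W), lung_semi)
    else:
        Z, Y, X = shape
        # the chest continues beyond the imaged stack: the thorax ellipsoid
        # clips at the z faces, as in a real CT acquisition
        thorax = (c, (0.75 * Z, 0.44 * Y, 0.46 * X))
        lung_semi = (0.32 * Z, 0.30 * Y, 0.16 * X)
        left = ((c[0], c[1], c[2] - 0.22 * X), lung_semi)
        right = ((c[0], c[1], c[2] + 0.22 * X), lung_semi)
    return thorax, left, right


def _default_tumor_center(spec: PhantomSpec, right_lung):
    (lc, semi) = right_lung
    if not spec.wall_attached:
        return lc
    # Lateral placement, `wall_gap` pixels short of the lung wall along +x;
    # the stalk painted later bridges that gap.
    center = list(lc)
    center[-1] = lc[-1] + semi[-1] - spec.tumor_radius - spec.wall_gap
    return tuple(center)


def _stalk_mask(spec: PhantomSpec, shape, tumor_center, lung_truth) -> np.ndarray:
    """Pleural tail: a narrow band from the blob center to just past the wall."""
    grids = np.indices(shape, dtype=float)
    across = np.zeros(shape, dtype=bool)
    along = grids[-1] - tumor_center[-1]
    perp = np.zeros(shape, dtype=float)
    for ax in range(len(shape) - 1):
        perp += (grids[ax] - tumor_center[ax]) ** 2
    perp = np.sqrt(perp)
    reach = spec.tumor_radius + spec.wall_gap + 3.0
    across = (perp <= spec.stalk_halfwidth) & (along >= 0) & (along <= reach)
    return across


def generate_phantom(spec: PhantomSpec):
    """Render a phantom.

    Returns ``(image, tumor_truth, lung_truth)`` where the image is an
    :class:`IntensityImage` in [0, 1] and both truths are boolean masks.
    Identical specs (including ``rng_seed``) render bit-identical
    outputs.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.shape
    nd = len(shape)

    thorax_par, left_par, right_par = _geometry(shape)
    thorax = _ellipse_mask(shape, *thorax_par)
    left = _ellipse_mask(shape, *left_par)
    right = _ellipse_mask(shape, *right_par)
    lung_truth = left | right

    tumor_center = spec.tumor_center or _default_tumor_center(spec, right_par)
    if len(tumor_center) != nd:
        raise PhantomSpecError("tumor_center rank does not match shape")

    lobe_val = (
        spec.lobe_intensity if spec.lobe_intensity is not None else spec.tumor_intensity
    )
    blobs = [(_ball_mask(shape, tumor_center, spec.tumor_radius), spec.tumor_intensity)]
    if spec.lobe:
        lobe_center = list(tumor_center)
        lobe_center[-2] = tumor_center[-2] - (spec.tumor_radius + spec.lobe_radius - 2.0)
        blobs.append((_ball_mask(shape, tuple(lobe_center), spec.lobe_radius), lobe_val))
    if spec.fragments == 2:
        frag_center = list(tumor_center)
        frag_center[-2] = tumor_center[-2] + 2.4 * spec.tumor_radius
        frag = _ball_mask(shape, tuple(frag_center), 0.6 * spec.tumor_radius)
        if not (frag & lung_truth).any():
            raise PhantomSpecError("fragment falls outside the lungs")
        blobs.append((frag, spec.tumor_intensity))

    if spec.wall_attached:
        stalk = _stalk_mask(spec, shape, tumor_center, lung_truth)
        blobs.append((stalk & lung_truth, spec.tumor_intensity))

    tumor_truth = np.zeros(shape, dtype=bool)
    for b, _ in blobs:
        tumor_truth |= b

    if not spec.wall_attached and not np.all(~tumor_truth | lung_truth):
        raise PhantomSpecError(
            "tumor extends outside the lung ellipse; set wall_attached=True "
            "or move/shrink it"
        )
    # Tumor tissue only exists inside the thorax.
    tumor_truth &= thorax

    img = np.full(shape, spec.background_intensity, dtype=float)
    img[thorax] = spec.thorax_intensity
    img[lung_truth] = spec.lung_intensity

    # Vessel dots: small bright disks in the lung, away from the tumor.
    if spec.vessel_count > 0:
        clearance = ndimage.binary_dilation(
            tumor_truth, iterations=max(int(round(spec.tumor_radius / 3)), 2)
        )
        candidates = np.argwhere(lung_truth & ~clearance)
        if candidates.shape[0]:
            picks = rng.choice(
                candidates.shape[0], size=min(spec.vessel_count, candidates.shape[0]),
                replace=False,
            )
            for k in picks:
                dot = _ball_mask(shape, tuple(candidates[k]), spec.vessel_radius)
                img[dot & lung_truth & ~tumor_truth] = spec.thorax_intensity

    for b, val in blobs:
        # Where a wall-attached blob pokes into the wall it merges with the
        # wall: the brighter thorax value is kept there, so only the part
        # inside the lung is painted at the blob's own intensity.
        img[b & lung_truth] = val

    if spec.smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.smoothing_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)

    return IntensityImage(img), tumor_truth, lung_truth
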