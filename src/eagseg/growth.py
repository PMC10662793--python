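"""Braided (level-synchronous) region growth.

This is the kernel shared by the primary and enhanced segmentation
pipelines. Growth starts from a user seed and expands in rings
("braids"): at each level every not-yet-visited neighbor of the current
ring is tested against the acceptance band

    |I(p) - compare_value| <= threshold

plus, optionally, a lung-mask constraint and a Euclidean radius
constraint about the seed. The comparison value starts at the seed
intensity and, in the enhanced algorithm, is re-estimated after every
complete level as the mean or median of all points accepted so far.
Updating once per level (rather than per pixel) makes the result
independent of visit order within a level.

The working threshold is a fraction (default 20%) of the grey-level
(Otsu) threshold of the image or of a local target region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import IntensityImage, as_image

__all__ = [
    "GrowthConfig",
    "GrowthResult",
    "otsu_level",
    "compute_threshold",
    "update_comparison_value",
    "grow_region",
    "boundary_points",
]

DEFAULT_THRESHOLD_FRACTION = 0.20


@dataclass
class GrowthConfig:
    """Tunables of one growth run.

    threshold:
        Acceptance half-width in normalized intensity units (``threshval``).
    max_radius:
        User-supplied maximum tumor radius in pixels, or None for no
        radius constraint.
    radius_factor:
        Accepted points must lie within ``radius_factor * max_radius`` of
        the seed. Default 2 ("no more than twice as large as the maximum
        radius"); set to 1 to confine growth to the stated radius itself.
    lung_mask:
        Optional boolean mask; accepted points must lie inside it.
    compare_update:
        "none" keeps the seed intensity as the comparison value (primary
        algorithm); "mean"/"median" re-estimate it after each level over
        all accepted points (enhanced algorithm).
    use_spacing:
        If True, the radius constraint is measured in physical units using
        the image spacing; default is plain pixel units.
    """

    threshold: float
    max_radius: float | None = None
    radius_factor: float = 2.0
    lung_mask: np.ndarray | None = None
    compare_update: str = "none"
    use_spacing: bool = False

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.max_radius is not None and self.max_radius <= 0:
            raise ValueError("max_radius must be > 0 when set")
        if self.compare_update not in ("none", "mean", "median"):
            raise ValueError(f"unknown compare_update: {self.compare_update!r}")


@dataclass
class GrowthResult:
    """Outcome of one braided growth run.

    ``trace_frontier[k]`` is the number of points newly accepted at level
    k (the braid ring size); it always ends at 0 when growth exhausts.
    ``trace_cumulative`` is the running total of accepted points and is
    non-decreasing by construction. ``boundary`` holds the accepted
    points that have at least one neighbor outside the mask (the image
    edge counts as outside).
    """

    mask: np.ndarray
    boundary: np.ndarray
    trace_frontier: list[int]
    trace_cumulative: list[int]
    final_compare_value: float
    threshold: float = float("nan")
    seed: tuple[int, ...] | None = None

    @property
    def size(self) -> int:
        return int(self.trace_cumulative[-1]) if self.trace_cumulative else 0

    def trace_rows(self) -> list[tuple[int, int, int]]:
        """(level, frontier, cumulative) rows, e.g. for CSV export."""
        return [
            (lvl, f, c)
            for lvl, (f, c) in enumerate(
                zip(self.trace_frontier, self.trace_cumulative)
            )
        ]


def otsu_level(values) -> float:
    """Grey-level (Otsu) threshold of a collection of intensities.

    Uses a 256-bin histogram over the data range. A constant collection
    returns its single value (the class split is degenerate).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("otsu_level: empty collection")
    if not np.all(np.isfinite(v)):
        raise ValueError("otsu_level: non-finite values")
    if v.min() == v.max():
        return float(v.flat[0])
    return float(threshold_otsu(v, nbins=256))


def compute_threshold(values_or_level, fraction: float = DEFAULT_THRESHOLD_FRACTION) -> float:
    """Working threshold = fraction x grey-level threshold.

    Accepts either a collection of intensities (the Otsu level is computed
    first) or an already-computed grey level as a scalar. The default 20%
    fraction reproduces e.g. a grey level of 0.48 -> 0.096 and 0.64 ->
    0.128.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    arr = np.asarray(values_or_level, dtype=float)
    if arr.ndim == 0:
        level = float(arr)
    else:
        level = otsu_level(arr)
    return fraction * level


def update_comparison_value(tumor_values, mode: str) -> float:
    """Mean or median intensity of all points accepted so far."""
    v = np.asarray(tumor_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("update_comparison_value: empty collection")
    if mode == "mean":
        return float(v.mean())
    if mode == "median":
        return float(np.median(v))
    raise ValueError(f"unknown comparison mode: {mode!r}")


def _neighbor_offsets(ndim: int) -> np.ndarray:
    offs = [o for o in product((-1, 0, 1), repeat=ndim) if any(o)]
    return np.array(offs, dtype=np.intp)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Mask points with >= 1 neighbor outside the mask (full connectivity).

    Points on the image edge count as boundary. Returns an (n, ndim)
    integer array.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, mask.ndim), dtype=np.intp)
    interior = ndimage.binary_erosion(
        mask, structure=np.ones((3,) * mask.ndim, bool), border_value=0
    )
    return np.argwhere(mask & ~interior)


def grow_region(img, seed, config: GrowthConfig) -> GrowthResult:
    """Level-synchronous braided growth from ``seed``.

    Level 0 is the seed alone. At each subsequent level every unvisited
    neighbor (8-connectivity in 2D, 26 in 3D) of the current braid is
    accepted iff its intensity lies within ``threshold`` of the current
    comparison value, it is inside the lung mask (when set), and its
    Euclidean distance from the seed does not exceed
    ``radius_factor * max_radius`` (when set). Every candidate is
    evaluated exactly once. Growth terminates when a level accepts
    nothing.
    """
    image = as_image(img)
    data = image.data
    shape = data.shape
    nd = data.ndim

    seed = tuple(int(round(c)) for c in np.atleast_1d(np.asarray(seed)).ravel())
    if len(seed) != nd:
        raise ValueError(f"seed has {len(seed)} coordinates for a {nd}D image")
    if any(c < 0 or c >= s for c, s in zip(seed, shape)):
        raise ValueError(f"seed {seed} outside image of shape {shape}")
    if config.lung_mask is not None:
        lung = np.asarray(config.lung_mask, dtype=bool)
        if lung.shape != shape:
            raise ValueError("lung_mask shape differs from image shape")
        if not lung[seed]:
            raise ValueError(f"seed {seed} outside the lung mask")
        lung_flat = lung.ravel()
    else:
        lung_flat = None

    seed_val = float(data[seed])
    if np.isnan(seed_val):
        raise ValueError(f"seed {seed} has NaN intensity")

    thr = float(config.threshold)
    spacing = np.asarray(
        image.spacing if config.use_spacing else (1.0,) * nd, dtype=float
    )
    rmax = (
        config.radius_factor * config.max_radius
        if config.max_radius is not None
        else None
    )

    offsets = _neighbor_offsets(nd)
    flat_data = data.ravel()
    visited = np.zeros(data.size, dtype=bool)
    accepted = np.zeros(data.size, dtype=bool)
    seed_flat = int(np.ravel_multi_index(seed, shape))
    visited[seed_flat] = True
    accepted[seed_flat] = True

    accepted_vals = [np.array([seed_val])]
    compare = seed_val
    if config.compare_update != "none":
        compare = update_comparison_value(accepted_vals[0], config.compare_update)

    seed_arr = np.asarray(seed, dtype=np.intp)
    frontier = seed_arr[None, :]
    trace_frontier = [1]
    trace_cumulative = [1]
    total = 1

    while frontier.shape[0] > 0:
        cand = (frontier[:, None, :] + offsets[None, :, :]).reshape(-1, nd)
        inb = np.all((cand >= 0) & (cand < np.asarray(shape)), axis=1)
        cand = cand[inb]
        flat = np.ravel_multi_index(tuple(cand.T), shape)
        flat = np.unique(flat)
        flat = flat[~visited[flat]]
        visited[flat] = True

        if flat.size:
            vals = flat_data[flat]
            ok = np.abs(vals - compare) <= thr
            ok &= np.isfinite(vals)
            if lung_flat is not None:
                ok &= lung_flat[flat]
            if rmax is not None:
                coords = np.column_stack(np.unravel_index(flat, shape))
                dist = np.sqrt((((coords - seed_arr) * spacing) ** 2).sum(axis=1))
                ok &= dist <= rmax + 1e-9
            new_flat = flat[ok]
        else:
            new_flat = flat

        accepted[new_flat] = True
        total += int(new_flat.size)
        trace_frontier.append(int(new_flat.size))
        trace_cumulative.append(total)

        if new_flat.size == 0:
            break
        accepted_vals.append(flat_data[new_flat])
        if config.compare_update != "none":
            compare = update_comparison_value(
                np.concatenate(accepted_vals), config.compare_update
            )
        frontier = np.column_stack(np.unravel_index(new_flat, shape))

    mask = accepted.reshape(shape)
    return GrowthResult(
        mask=mask,
        boundary=boundary_points(mask),
        trace_frontier=trace_frontier,
        trace_cumulative=trace_cumulative,
        final_compare_value=float(compare),
        threshold=thr,
        seed=seed,
    )
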