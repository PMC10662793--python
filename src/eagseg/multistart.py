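"""Multi-seed growth and boundary interpolation.

The enhanced algorithm does not trust a single start point: the tumor
found so far is split into 4 quadrants (2D) or 8 octants (3D) about its
geometric center, one point is drawn at random from each non-empty
sector, and the whole grow + local-threshold-regrow sequence is repeated
independently from the center and each sampled point (5 starts in 2D, 9
in 3D). The per-start masks are then combined into a single boundary by
radial shape averaging about the shared geometric center of their union
(default), or alternatively by pixelwise majority vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .growth import GrowthConfig, GrowthResult

__all__ = [
    "SectorSample",
    "geometric_center",
    "nearest_mask_point",
    "sample_sector_points",
    "multi_start_growth",
    "interpolate_boundaries",
]


@dataclass
class SectorSample:
    center: tuple[int, ...]
    sector_count: int
    points: list[tuple[int, ...]]


def geometric_center(mask) -> tuple[float, ...]:
    """Per-axis mean coordinate of the mask members."""
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("geometric_center: empty mask")
    return tuple(float(c) for c in coords.mean(axis=0))


def nearest_mask_point(mask, point) -> tuple[int, ...]:
    """Closest mask member to a (possibly fractional) point."""
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("nearest_mask_point: empty mask")
    d2 = ((coords - np.asarray(point, dtype=float)) ** 2).sum(axis=1)
    return tuple(int(c) for c in coords[int(np.argmin(d2))])


def sample_sector_points(mask, center, rng) -> SectorSample:
    """Draw one mask point uniformly at random per non-empty sector.

    Sectors are the quadrants/octants of the coordinate frame anchored at
    ``center`` (a coordinate equal to the center's goes to the positive
    side). Empty sectors simply contribute no point.
    """
    mask = np.asarray(mask, dtype=bool)
    nd = mask.ndim
    center = tuple(int(round(c)) for c in np.asarray(center).ravel())
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("sample_sector_points: empty mask")
    rel = coords - np.asarray(center)
    bits = (rel >= 0).astype(int)
    sector_id = np.zeros(coords.shape[0], dtype=int)
    for ax in range(nd):
        sector_id = sector_id * 2 + bits[:, ax]
    points: list[tuple[int, ...]] = []
    for sec in range(2**nd):
        members = coords[sector_id == sec]
        if members.shape[0] == 0:
            warnings.warn(f"sample_sector_points: sector {sec} is empty")
            continue
        pick = members[int(rng.integers(members.shape[0]))]
        points.append(tuple(int(c) for c in pick))
    return SectorSample(center=center, sector_count=2**nd, points=points)


def multi_start_growth(img, seed_list, config: GrowthConfig, per_seed_pipeline) -> list[GrowthResult]:
    """Run ``per_seed_pipeline`` independently from each seed.

    A seed whose growth fails is dropped with a warning; at least one
    result is required.
    """
    results: list[GrowthResult] = []
    for seed in seed_list:
        try:
            results.append(per_seed_pipeline(seed))
        except Exception as exc:
            warnings.warn(f"multi_start_growth: seed {tuple(seed)} failed: {exc}")
    if not results:
        raise RuntimeError("multi_start_growth: every seed failed")
    return results


def _unit_directions_2d(n: int) -> tuple[np.ndarray, float]:
    step = 2 * np.pi / n
    ang = np.arange(n) * step
    return np.column_stack([np.sin(ang), np.cos(ang)]), step


def _unit_directions_3d(n_az: int, n_el: int):
    step_az = 2 * np.pi / n_az
    step_el = np.pi / n_el
    az = -np.pi + (np.arange(n_az) + 0.5) * step_az
    el = -np.pi / 2 + (np.arange(n_el) + 0.5) * step_el
    AZ, EL = np.meshgrid(az, el, indexing="ij")
    dirs = np.column_stack(
        [
            np.sin(EL).ravel(),
            (np.cos(EL) * np.sin(AZ)).ravel(),
            (np.cos(EL) * np.cos(AZ)).ravel(),
        ]
    )
    return dirs, step_az, step_el


def _max_radius_along_rays(mask: np.ndarray, center, dirs: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Farthest sampled radius still inside ``mask`` per direction (-1 if none)."""
    shape = np.asarray(mask.shape)
    pts = np.asarray(center, dtype=float)[None, None, :] + dirs[:, None, :] * radii[None, :, None]
    idx = np.round(pts).astype(np.intp)
    valid = np.all((idx >= 0) & (idx < shape), axis=2)
    idx_clipped = np.clip(idx, 0, shape - 1)
    inside = valid & mask[tuple(np.moveaxis(idx_clipped, 2, 0))]
    return np.max(np.where(inside, radii[None, :], -1.0), axis=1)


def interpolate_boundaries(masks, center, angular_bins: int = 360, method: str = "radial") -> np.ndarray:
    """Combine per-start masks into one boundary.

    radial (default):
        For each direction from ``center`` every mask contributes the
        radius of its farthest member along the ray; the combined radius
        is the mean over contributing masks, and the output is the filled
        star-shaped region of those (angle, radius) samples. In 3D the
        directions form an azimuth x elevation grid
        (``angular_bins x angular_bins/2``).
    majority:
        Pixels present in at least ceil(k/2) of the k input masks.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise ValueError("interpolate_boundaries: need at least one mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("interpolate_boundaries: masks differ in shape")
    nd = masks[0].ndim
    center = tuple(float(c) for c in np.asarray(center).ravel())
    ci = tuple(int(round(c)) for c in center)
    in_bounds = all(0 <= c < s for c, s in zip(ci, shape))
    if not in_bounds or not any(m[ci] for m in masks):
        raise ValueError("interpolate_boundaries: center lies outside every mask")

    if method == "majority":
        counts = np.sum(masks, axis=0)
        need = int(np.ceil(len(masks) / 2))
        return counts >= need
    if method != "radial":
        raise ValueError(f"unknown interpolation method: {method!r}")

    corners = np.array(list(np.ndindex(*(2,) * nd))) * (np.asarray(shape) - 1)
    rmax = float(np.sqrt(((corners - np.asarray(center)) ** 2).sum(axis=1)).max())
    radii = np.arange(0.0, rmax + 0.5, 0.5)

    if nd == 2:
        dirs, step = _unit_directions_2d(angular_bins)
    else:
        n_el = max(angular_bins // 2, 4)
        dirs, step_az, step_el = _unit_directions_3d(angular_bins, n_el)

    per_mask = np.stack([_max_radius_along_rays(m, center, dirs, radii) for m in masks])
    contributing = per_mask >= 0
    sums = np.where(contributing, per_mask, 0.0).sum(axis=0)
    counts = contributing.sum(axis=0)
    interp_r = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    grids = np.indices(shape, dtype=float)
    rel = [g - c for g, c in zip(grids, center)]
    r = np.sqrt(sum(x**2 for x in rel))
    if nd == 2:
        theta = np.arctan2(rel[0], rel[1]) % (2 * np.pi)
        bins = np.round(theta / step).astype(int) % angular_bins
        out = r <= interp_r[bins] + 0.5
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            el = np.arcsin(np.clip(np.where(r > 0, rel[0] / np.maximum(r, 1e-12), 0.0), -1, 1))
        az = np.arctan2(rel[1], rel[2])
        i_az = np.floor((az + np.pi) / step_az).astype(int) % angular_bins
        i_el = np.clip(np.floor((el + np.pi / 2) / step_el).astype(int), 0, n_el - 1)
        out = r <= interp_r.reshape(angular_bins, n_el)[i_az, i_el] + 0.5
    out[ci] = True
    return out
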