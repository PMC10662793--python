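"""Rule-gated edge refinement.

The last stage probes tissue just outside the boundary found so far:
rays are cast from the tumor center at fixed angles (8 in 2D; 16 in 3D
from the azimuth x elevation grid {-180,-90,0,90} x {-90,-45,0,45}
degrees), each ray's last in-mask point is pushed ``offset`` pixels
outward (default 3), and a fresh growth is started at every such
candidate with a tighter working threshold (default 10% of the local
Otsu level instead of 20%). A candidate subsection joins the tumor only
if it is not darker than the tumor minus ``median_sigma`` standard
deviations (median rule) and it is small relative to the tumor (area
ratio below ``area_ratio_max``). Refinement can only add pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .autothresh import DEFAULT_MARGIN, build_target_region, intensity_center
from .growth import GrowthConfig, GrowthResult, boundary_points, grow_region, otsu_level
from .io import as_image

__all__ = [
    "RefineRule",
    "RefinementResult",
    "standard_directions",
    "ray_edge_points",
    "refine_edges",
]


@dataclass
class RefineRule:
    """Constants of the two join rules and the refinement threshold.

    A subsection S joins the primary tumor P iff
    ``median(I[S]) > median(I[P]) - median_sigma * std(I[P])`` and
    ``|S| / |P| < area_ratio_max``.
    """

    median_sigma: float = 3.0
    area_ratio_max: float = 0.2
    threshold_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.area_ratio_max <= 0:
            raise ValueError("area_ratio_max must be > 0")
        if not (0 < self.threshold_fraction <= 0.2):
            raise ValueError("threshold_fraction must be in (0, 0.2]")


@dataclass
class RefinementResult:
    """Refined mask plus per-candidate diagnostics."""

    mask: np.ndarray
    candidates: list[dict] = field(default_factory=list)

    @property
    def joined_count(self) -> int:
        return sum(1 for c in self.candidates if c.get("joined"))


def standard_directions(ndim: int) -> np.ndarray:
    """Unit ray directions: 8 at 45-degree steps in 2D, 16 in 3D."""
    if ndim == 2:
        ang = np.deg2rad(np.arange(0, 360, 45))
        return np.column_stack([np.sin(ang), np.cos(ang)])
    if ndim == 3:
        az = np.deg2rad([-180.0, -90.0, 0.0, 90.0])
        el = np.deg2rad([-90.0, -45.0, 0.0, 45.0])
        AZ, EL = np.meshgrid(az, el, indexing="ij")
        return np.column_stack(
            [
                np.sin(EL).ravel(),
                (np.cos(EL) * np.sin(AZ)).ravel(),
                (np.cos(EL) * np.cos(AZ)).ravel(),
            ]
        )
    raise ValueError("ndim must be 2 or 3")


def ray_edge_points(mask, center, angles, offset: float = 3.0) -> list[tuple[int, ...]]:
    """March rays from ``center``; return points ``offset`` px past the mask.

    ``angles`` is a list of unit direction vectors (use
    :func:`standard_directions` for the canonical sets). For each
    direction the last mask pixel along the ray is found and the returned
    point lies ``offset`` pixels beyond it, clipped to the image bounds.
    Directions along which no mask pixel is met are skipped with a
    warning.
    """
    mask = np.asarray(mask, dtype=bool)
    nd = mask.ndim
    shape = np.asarray(mask.shape)
    center = np.asarray(center, dtype=float).ravel()
    ci = tuple(int(round(c)) for c in center)
    if not all(0 <= c < s for c, s in zip(ci, mask.shape)) or not mask[ci]:
        raise ValueError(f"ray_edge_points: center {ci} not inside the mask")

    corners = np.array(list(np.ndindex(*(2,) * nd))) * (shape - 1)
    rmax = float(np.sqrt(((corners - center) ** 2).sum(axis=1)).max())
    radii = np.arange(0.0, rmax + 0.5, 0.5)

    points: list[tuple[int, ...]] = []
    for d in np.atleast_2d(np.asarray(angles, dtype=float)):
        d = d / np.linalg.norm(d)
        pts = center[None, :] + radii[:, None] * d[None, :]
        idx = np.round(pts).astype(np.intp)
        valid = np.all((idx >= 0) & (idx < shape), axis=1)
        inside = valid & mask[tuple(np.clip(idx, 0, shape - 1).T)]
        if not inside.any():
            warnings.warn(f"ray_edge_points: no mask pixel along direction {d}")
            continue
        # boundary intersection = the last in-mask pixel center on the ray
        last = idx[np.nonzero(inside)[0][-1]]
        r_edge = float(np.linalg.norm(last - center))
        target = center + (r_edge + offset) * d
        target = np.clip(np.round(target).astype(int), 0, shape - 1)
        points.append(tuple(int(c) for c in target))
    return points


def refine_edges(
    img,
    primary_mask,
    points,
    rule: RefineRule,
    config: GrowthConfig,
    margin: float = DEFAULT_MARGIN,
) -> RefinementResult:
    """Grow a candidate subsection at each point and join the passing ones.

    Every candidate growth uses a working threshold of
    ``rule.threshold_fraction`` x the Otsu level of the same local target
    region used for automatic thresholding. The returned mask is the
    primary mask union all joined subsections; per-candidate diagnostics
    (size, ratio, medians, join decision) are kept for inspection.
    """
    image = as_image(img)
    primary_mask = np.asarray(primary_mask, dtype=bool)
    if not primary_mask.any():
        raise ValueError("refine_edges: empty primary mask")

    # Local threshold over the same disk/sphere target area as autothresh.
    pseudo = GrowthResult(
        mask=primary_mask,
        boundary=boundary_points(primary_mask),
        trace_frontier=[],
        trace_cumulative=[int(primary_mask.sum())],
        final_compare_value=float("nan"),
    )
    region = build_target_region(image, pseudo, margin=margin)
    local_level = otsu_level(image.data[region.mask])
    thr = rule.threshold_fraction * local_level
    grow_cfg = replace(config, threshold=thr)

    prim_vals = image.data[primary_mask]
    med_p = float(np.median(prim_vals))
    std_p = float(prim_vals.std())
    floor = med_p - rule.median_sigma * std_p
    prim_size = int(primary_mask.sum())

    out = primary_mask.copy()
    records: list[dict] = []
    for p in points:
        p = tuple(int(c) for c in p)
        rec: dict = {"point": p, "joined": False}
        try:
            sub = grow_region(image, p, grow_cfg)
        except ValueError as exc:
            warnings.warn(f"refine_edges: candidate {p} skipped: {exc}")
            rec["skipped"] = str(exc)
            records.append(rec)
            continue
        sub_mask = sub.mask
        size = int(sub_mask.sum())
        ratio = size / prim_size
        med_s = float(np.median(image.data[sub_mask]))
        passes_median = med_s > floor
        passes_ratio = ratio < rule.area_ratio_max
        rec.update(
            size=size,
            area_ratio=ratio,
            median=med_s,
            median_floor=floor,
            passes_median=passes_median,
            passes_ratio=passes_ratio,
            joined=bool(passes_median and passes_ratio),
        )
        if rec["joined"]:
            out |= sub_mask
        records.append(rec)
    return RefinementResult(mask=out, candidates=records)
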