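"""Orchestration of the primary and enhanced area-growth algorithms.

``primary_segment`` is the baseline: normalize, optionally appoint the
lung area, then a single braided growth with a global working threshold
(20% of the image's Otsu level) and a fixed comparison value.

``eag_segment`` runs the full enhanced sequence:

  i    contrast augmentation (quantile stretch)
  ii   lung-area appointment (seed must lie inside it)
  iii  user-supplied maximum tumor radius
  iv   global working threshold (20% of the whole-image Otsu level)
  v-vii braided growth with a per-level median comparison update
  viii-ix local target region around the intensity center and regrowth
        with the local working threshold
  x    geometric center, sector sampling (4 quadrants / 8 octants),
        independent growth from each start, radial boundary interpolation
  xi   ray-cast edge candidates (8 / 16 directions, offset 3 px) grown at
        a 10% threshold and joined under the median and area-ratio rules

Every stage is individually toggleable; each enabled stage contributes
exactly one entry to the report's ``stage_log``. Randomness is governed
by one master seed: each stochastic stage draws from its own named
substream, so toggling one stage never shifts another stage's draws.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .autothresh import regrow_with_local_threshold
from .edge_refine import RefineRule, refine_edges, ray_edge_points, standard_directions
from .growth import GrowthConfig, GrowthResult, compute_threshold, grow_region
from .io import IntensityImage, as_image, normalize_intensity
from .multistart import (
    geometric_center,
    interpolate_boundaries,
    multi_start_growth,
    nearest_mask_point,
    sample_sector_points,
)
from .preprocess import augment_contrast, segment_lung_mask

__all__ = ["EAGConfig", "SegmentationReport", "primary_segment", "eag_segment"]


@dataclass
class EAGConfig:
    """All pipeline tunables with their defaults."""

    contrast_enabled: bool = True
    contrast_low_frac: float = 0.01
    contrast_high_frac: float = 0.99

    lung_enabled: bool = True
    lung_min_component_frac: float = 0.005
    lung_closing_radius: int = 3

    threshold_fraction: float = 0.20
    radius_factor: float = 2.0
    compare_update: str = "median"
    use_spacing: bool = False

    autothresh_enabled: bool = True
    autothresh_fraction: float = 0.20
    autothresh_margin: float = 5.0

    multistart_enabled: bool = True
    interpolation: str = "radial"
    angular_bins: int | None = None  # default: 360 in 2D, 64 in 3D

    refine_enabled: bool = True
    refine_threshold_fraction: float = 0.10
    refine_median_sigma: float = 3.0
    refine_area_ratio_max: float = 0.2
    refine_offset: float = 3.0

    strict: bool = False

    # nested-key <-> attribute mapping used by config files and --show-config
    _KEYMAP = {
        ("contrast", "enabled"): "contrast_enabled",
        ("contrast", "low_frac"): "contrast_low_frac",
        ("contrast", "high_frac"): "contrast_high_frac",
        ("lung", "enabled"): "lung_enabled",
        ("lung", "min_component_frac"): "lung_min_component_frac",
        ("lung", "closing_radius"): "lung_closing_radius",
        ("growth", "threshold_fraction"): "threshold_fraction",
        ("growth", "radius_factor"): "radius_factor",
        ("growth", "compare_update"): "compare_update",
        ("growth", "use_spacing"): "use_spacing",
        ("autothresh", "enabled"): "autothresh_enabled",
        ("autothresh", "fraction"): "autothresh_fraction",
        ("autothresh", "margin"): "autothresh_margin",
        ("multistart", "enabled"): "multistart_enabled",
        ("multistart", "interpolation"): "interpolation",
        ("multistart", "angular_bins"): "angular_bins",
        ("refine", "enabled"): "refine_enabled",
        ("refine", "threshold_fraction"): "refine_threshold_fraction",
        ("refine", "median_sigma"): "refine_median_sigma",
        ("refine", "area_ratio_max"): "refine_area_ratio_max",
        ("refine", "offset"): "refine_offset",
        ("pipeline", "strict"): "strict",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "EAGConfig":
        """Build a config from a nested mapping (e.g. parsed YAML/JSON)."""
        kwargs = {}
        for section, sub in d.items():
            if not isinstance(sub, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            for key, value in sub.items():
                attr = cls._KEYMAP.get((section, key))
                if attr is None:
                    raise ValueError(f"unknown config key: {section}.{key}")
                kwargs[attr] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "EAGConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out: dict = {}
        for (section, key), attr in self._KEYMAP.items():
            out.setdefault(section, {})[key] = getattr(self, attr)
        return out


@dataclass
class SegmentationReport:
    """Everything one pipeline run produced."""

    final_mask: np.ndarray
    primary_mask: np.ndarray
    lung_mask: np.ndarray | None
    per_seed_results: list[GrowthResult]
    stage_log: list[dict] = field(default_factory=list)
    rng_seed: int | None = None

    def stages(self) -> list[str]:
        return [entry["stage"] for entry in self.stage_log]

    def log_json(self) -> list[dict]:
        """stage_log with numpy scalars coerced to plain Python types."""

        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return clean(self.stage_log)


def _stage_rng(master: int | None, stage: str) -> np.random.Generator:
    """Named substream: independent of the order/enabling of other stages."""
    master = 0 if master is None else int(master)
    code = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master & 0x7FFFFFFF, code]))


def _appoint_lung(image: IntensityImage, cfg: EAGConfig, log: list[dict]):
    lm = segment_lung_mask(
        image,
        min_component_frac=cfg.lung_min_component_frac,
        closing_radius=cfg.lung_closing_radius,
    )
    lung = lm.mask if lm.mask.any() else None
    if lung is None:
        if cfg.strict:
            raise RuntimeError("lung mask is empty (strict mode)")
        warnings.warn("lung mask empty; growth proceeds unconstrained")
    log.append(
        {
            "stage": "lung_area",
            "params": {
                "min_component_frac": cfg.lung_min_component_frac,
                "closing_radius": cfg.lung_closing_radius,
            },
            "summary": {
                "component_count": lm.component_count,
                "size": int(lm.mask.sum()),
            },
        }
    )
    return lung


def primary_segment(img, seed, config: EAGConfig | None = None, max_radius: float | None = None) -> SegmentationReport:
    """Baseline single-start growth with the global 20% working threshold."""
    cfg = config or EAGConfig()
    image = normalize_intensity(as_image(img))
    log: list[dict] = []

    lung = _appoint_lung(image, cfg, log) if cfg.lung_enabled else None

    threshold = compute_threshold(image.data.ravel(), cfg.threshold_fraction)
    log.append(
        {
            "stage": "global_threshold",
            "params": {"fraction": cfg.threshold_fraction},
            "summary": {"threshold": threshold},
        }
    )

    gcfg = GrowthConfig(
        threshold=threshold,
        max_radius=max_radius,
        radius_factor=cfg.radius_factor,
        lung_mask=lung,
        compare_update="none",
        use_spacing=cfg.use_spacing,
    )
    result = grow_region(image, seed, gcfg)
    log.append(
        {
            "stage": "primary_growth",
            "params": {"seed": tuple(int(c) for c in result.seed)},
            "summary": {
                "size": result.size,
                "levels": len(result.trace_frontier),
                "final_compare_value": result.final_compare_value,
            },
        }
    )
    return SegmentationReport(
        final_mask=result.mask,
        primary_mask=result.mask,
        lung_mask=lung,
        per_seed_results=[result],
        stage_log=log,
        rng_seed=None,
    )


def eag_segment(img, seed, max_radius: float | None, config: EAGConfig | None = None, rng: int | None = 0) -> SegmentationReport:
    """Full enhanced area-growth segmentation (stages i-xi)."""
    cfg = config or EAGConfig()
    image = normalize_intensity(as_image(img))
    nd = image.dims
    log: list[dict] = []

    if cfg.contrast_enabled:
        image = augment_contrast(image, cfg.contrast_low_frac, cfg.contrast_high_frac)
        log.append(
            {
                "stage": "contrast_augmentation",
                "params": {
                    "low_frac": cfg.contrast_low_frac,
                    "high_frac": cfg.contrast_high_frac,
                },
                "summary": {},
            }
        )

    lung = _appoint_lung(image, cfg, log) if cfg.lung_enabled else None

    log.append(
        {
            "stage": "max_radius",
            "params": {"max_radius": max_radius, "radius_factor": cfg.radius_factor},
            "summary": {},
        }
    )

    threshold = compute_threshold(image.data.ravel(), cfg.threshold_fraction)
    log.append(
        {
            "stage": "global_threshold",
            "params": {"fraction": cfg.threshold_fraction},
            "summary": {"threshold": threshold},
        }
    )

    gcfg = GrowthConfig(
        threshold=threshold,
        max_radius=max_radius,
        radius_factor=cfg.radius_factor,
        lung_mask=lung,
        compare_update=cfg.compare_update,
        use_spacing=cfg.use_spacing,
    )

    def run_from(start) -> GrowthResult:
        res = grow_region(image, start, gcfg)
        if cfg.autothresh_enabled:
            res = regrow_with_local_threshold(
                image,
                start,
                res,
                gcfg,
                fraction=cfg.autothresh_fraction,
                margin=cfg.autothresh_margin,
            )
        return res

    primary = grow_region(image, seed, gcfg)
    log.append(
        {
            "stage": "braided_growth",
            "params": {
                "seed": tuple(int(c) for c in primary.seed),
                "compare_update": cfg.compare_update,
            },
            "summary": {
                "size": primary.size,
                "levels": len(primary.trace_frontier),
                "final_compare_value": primary.final_compare_value,
            },
        }
    )

    current = primary
    if cfg.autothresh_enabled:
        current = regrow_with_local_threshold(
            image,
            seed,
            primary,
            gcfg,
            fraction=cfg.autothresh_fraction,
            margin=cfg.autothresh_margin,
        )
        log.append(
            {
                "stage": "auto_threshold",
                "params": {
                    "fraction": cfg.autothresh_fraction,
                    "margin": cfg.autothresh_margin,
                },
                "summary": {
                    "local_threshold": current.threshold,
                    "size": current.size,
                },
            }
        )

    per_seed_results = [current]
    work_mask = current.mask

    if cfg.multistart_enabled:
        center = nearest_mask_point(work_mask, geometric_center(work_mask))
        sample = sample_sector_points(work_mask, center, _stage_rng(rng, "sector"))
        seeds = [center]
        for p in sample.points:
            if p not in seeds:
                seeds.append(p)
        results = multi_start_growth(image, seeds, gcfg, run_from)
        per_seed_results = results

        union = np.zeros(work_mask.shape, dtype=bool)
        for r in results:
            union |= r.mask
        bins = cfg.angular_bins or (360 if nd == 2 else 64)
        ucenter = geometric_center(union)
        if not union[tuple(int(round(c)) for c in ucenter)]:
            # non-star-shaped union: anchor the rays at the nearest member
            ucenter = nearest_mask_point(union, ucenter)
        interp = interpolate_boundaries(
            [r.mask for r in results],
            ucenter,
            angular_bins=bins,
            method=cfg.interpolation,
        )
        if lung is not None:
            interp &= lung
        if not interp.any():
            interp = union
        work_mask = interp
        log.append(
            {
                "stage": "multi_start",
                "params": {
                    "sector_count": sample.sector_count,
                    "seeds": [tuple(int(c) for c in s) for s in seeds],
                    "interpolation": cfg.interpolation,
                    "angular_bins": bins,
                },
                "summary": {"n_results": len(results), "size": int(work_mask.sum())},
            }
        )

    final = work_mask
    if cfg.refine_enabled:
        rcenter = nearest_mask_point(work_mask, geometric_center(work_mask))
        dirs = standard_directions(nd)
        points = ray_edge_points(work_mask, rcenter, dirs, offset=cfg.refine_offset)
        if nd == 2:
            # the center itself is the ninth candidate in 2D
            points = [rcenter] + points
        rule = RefineRule(
            median_sigma=cfg.refine_median_sigma,
            area_ratio_max=cfg.refine_area_ratio_max,
            threshold_fraction=cfg.refine_threshold_fraction,
        )
        refined = refine_edges(
            image, work_mask, points, rule, gcfg, margin=cfg.autothresh_margin
        )
        final = refined.mask
        if lung is not None:
            final &= lung
        log.append(
            {
                "stage": "edge_refinement",
                "params": {
                    "offset": cfg.refine_offset,
                    "threshold_fraction": cfg.refine_threshold_fraction,
                    "median_sigma": cfg.refine_median_sigma,
                    "area_ratio_max": cfg.refine_area_ratio_max,
                },
                "summary": {
                    "n_candidates": len(refined.candidates),
                    "n_joined": refined.joined_count,
                    "size": int(final.sum()),
                    "candidates": refined.candidates,
                },
            }
        )

    return SegmentationReport(
        final_mask=final,
        primary_mask=primary.mask,
        lung_mask=lung,
        per_seed_results=per_seed_results,
        stage_log=log,
        rng_seed=rng,
    )
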