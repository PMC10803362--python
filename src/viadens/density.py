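"""Whole-slide viable tumor cell density: tile, count, Sum/Area.

The slide-level quantity is cells per mm² of annotated tumor area, pooled
over all slides of a case: density = (Σ_i Σ_k a_ik) / (Σ_i S_i), where
a_ik is the detected count in patch k of slide i and S_i the polygon area
of slide i in mm². Pooling sums counts and areas first — it is NOT the
mean of per-slide densities.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Sequence

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box

__all__ = [
    "TumorRegion",
    "PatchGrid",
    "SlideDensityResult",
    "tile_region",
    "area_mm2",
    "count_in_region",
    "slide_density",
    "planted_detector",
]


@dataclasses.dataclass(frozen=True)
class TumorRegion:
    """Pathologist-annotated tumor border(s) with pixel calibration.

    ``polygons`` are simple closed rings in pixel coordinates (x = column,
    y = row, origin top-left); ``mpp`` is the isotropic microns-per-pixel
    calibration of the raster. Points exactly on a border count as inside.
    """

    polygons: tuple[Polygon, ...]
    mpp: float

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        polys = tuple(
            p if isinstance(p, Polygon) else Polygon(p) for p in self.polygons
        )
        for p in polys:
            if not p.is_valid:
                raise ValueError(f"self-intersecting or invalid ring: {shapely.is_valid_reason(p)}")
        if sum(p.area for p in polys) <= 0:
            raise ValueError("region must have positive area")
        object.__setattr__(self, "polygons", polys)

    @classmethod
    def from_vertices(cls, rings: Sequence[Sequence], mpp: float) -> "TumorRegion":
        return cls(polygons=tuple(Polygon(r) for r in rings), mpp=mpp)

    def covers(self, x: float, y: float) -> bool:
        pt = Point(x, y)
        return any(p.covers(pt) for p in self.polygons)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        bs = np.array([p.bounds for p in self.polygons])
        return (bs[:, 0].min(), bs[:, 1].min(), bs[:, 2].max(), bs[:, 3].max())


@dataclasses.dataclass(frozen=True)
class PatchGrid:
    """Axis-aligned non-overlapping grid patches intersecting a region.

    Each patch is a half-open pixel rectangle [x0, x1) × [y0, y1) on the
    regular grid anchored at the raster origin (stride = patch size).
    """

    patch_size_px: int
    patches: tuple[tuple[int, int, int, int], ...]


@dataclasses.dataclass(frozen=True)
class SlideDensityResult:
    per_patch_counts: tuple[int, ...]
    sum_cells: int
    area_mm2: float
    density_per_mm2: float


def area_mm2(region: TumorRegion) -> float:
    """Polygon (shoelace) area of the region in mm², outer rings minus holes."""
    area_px2 = sum(p.area for p in region.polygons)
    return float(area_px2) * (region.mpp / 1000.0) ** 2


def tile_region(
    region: TumorRegion,
    raster_shape: tuple[int, int],
    patch_size: int = 1024,
) -> PatchGrid:
    """Grid patches (anchored at the origin) that overlap the region.

    A patch is included iff its rectangle intersects any region polygon
    with positive area; touching only along an edge does not count.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    h, w = raster_shape[:2]
    minx, miny, maxx, maxy = region.bounds
    if minx < 0 or miny < 0 or maxx > w or maxy > h:
        raise ValueError(
            f"region bounds {region.bounds} fall outside the {w}x{h} raster"
        )
    patches = []
    for iy in range(int(miny) // patch_size, int(np.ceil(maxy / patch_size))):
        for ix in range(int(minx) // patch_size, int(np.ceil(maxx / patch_size))):
            x0, y0 = ix * patch_size, iy * patch_size
            rect = box(x0, y0, min(x0 + patch_size, w), min(y0 + patch_size, h))
            if any(p.intersection(rect).area > 0 for p in region.polygons):
                patches.append((x0, y0, x0 + patch_size, y0 + patch_size))
    return PatchGrid(patch_size_px=patch_size, patches=tuple(patches))


def count_in_region(
    detect_fn: Callable[[np.ndarray], np.ndarray],
    raster: np.ndarray,
    region: TumorRegion,
    grid: PatchGrid,
    min_distance: float = 20.0,
) -> list[int]:
    """Detect per patch, keep points inside the region, dedupe seams.

    ``detect_fn(patch_image) -> (n, 2) points`` in patch-local (x, y)
    coordinates, optionally ``(points, scores)``. Detections are mapped to
    slide coordinates, filtered by point-in-polygon (boundary counts as
    inside), then deduplicated across patch seams with the same greedy
    suppression radius used in peak extraction (stronger detection wins).
    Returns the per-patch counts a_ik, aligned with ``grid.patches``.
    """
    h, w = raster.shape[:2]
    all_pts: list[tuple[float, float, float, int]] = []  # x, y, score, patch idx
    for k, (x0, y0, x1, y1) in enumerate(grid.patches):
        patch = raster[y0:min(y1, h), x0:min(x1, w)]
        if patch.shape[0] < grid.patch_size_px or patch.shape[1] < grid.patch_size_px:
            pad = [(0, grid.patch_size_px - patch.shape[0]), (0, grid.patch_size_px - patch.shape[1])]
            if patch.ndim == 3:
                pad.append((0, 0))
            patch = np.pad(patch, pad, mode="edge")
        if getattr(detect_fn, "needs_bounds", False):
            out = detect_fn(patch, (x0, y0, x1, y1))
        else:
            out = detect_fn(patch)
        pts, scores = out if isinstance(out, tuple) else (out, None)
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if scores is None:
            scores = np.ones(len(pts))
        for (px, py), s in zip(pts, scores):
            sx, sy = px + x0, py + y0
            if sx < x1 and sy < y1 and region.covers(sx, sy):
                all_pts.append((sx, sy, float(s), k))

    # greedy cross-seam suppression, strongest first, ties by (y, x)
    all_pts.sort(key=lambda t: (-t[2], t[1], t[0]))
    kept: list[tuple[float, float, float, int]] = []
    for cand in all_pts:
        if all(
            (cand[0] - kx) ** 2 + (cand[1] - ky) ** 2 > min_distance**2
            for kx, ky, _, _ in kept
        ):
            kept.append(cand)
    counts = [0] * len(grid.patches)
    for _, _, _, k in kept:
        counts[k] += 1
    return counts


def slide_density(
    counts_per_slide: Sequence[Sequence[int]],
    regions_per_slide: Sequence[TumorRegion],
) -> SlideDensityResult:
    """Pool counts and areas over all slides of a case: density = Sum/Area."""
    if len(counts_per_slide) != len(regions_per_slide):
        raise ValueError("need one region per slide")
    flat = [int(c) for counts in counts_per_slide for c in counts]
    if any(c < 0 for c in flat):
        raise ValueError("counts must be non-negative")
    total = sum(flat)
    area = sum(area_mm2(r) for r in regions_per_slide)
    if area <= 0:
        raise ValueError("total annotated area is zero")
    return SlideDensityResult(
        per_patch_counts=tuple(flat),
        sum_cells=total,
        area_mm2=area,
        density_per_mm2=total / area,
    )


def planted_detector(slide) -> Callable[..., np.ndarray]:
    """Oracle detector: returns the slide's planted ground-truth points.

    For use with :func:`count_in_region`; returns the planted points that
    fall inside the half-open bounds of the requested patch, in patch-local
    coordinates. Exact by construction — useful to separate counting or
    geometry errors from detection errors.
    """
    planted = np.asarray(slide.planted_points, dtype=float).reshape(-1, 2)

    def oracle(patch: np.ndarray, bounds: tuple[int, int, int, int]) -> np.ndarray:
        x0, y0, x1, y1 = bounds
        inside = (
            (planted[:, 0] >= x0)
            & (planted[:, 0] < x1)
            & (planted[:, 1] >= y0)
            & (planted[:, 1] < y1)
        )
        return planted[inside] - np.array([x0, y0], dtype=float)

    oracle.needs_bounds = True
    return oracle
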