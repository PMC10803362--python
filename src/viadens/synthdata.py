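"""Seeded synthetic histology patches, pseudo-slides, and survival cohorts.

Every downstream stage (detection, density, survival) is testable against
known ground truth generated here. Patches mimic the salient contrast of
H&E at high power: viable tumor nuclei are dense basophilic (dark purple)
elliptical blobs, distractors are pale, fragmented, low-saturation clusters
standing in for necrotic debris and stroma. The generator makes no claim of
photorealism — it provides a learnable but nontrivial detection task whose
ground truth is exact.

All three generators are deterministic: the same spec (including its seed)
produces bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import ellipse

from .density import TumorRegion, area_mm2

__all__ = [
    "PatchSpec",
    "RenderedPatch",
    "SyntheticSlide",
    "CohortSpec",
    "PlacementError",
    "render_patch",
    "render_slide",
    "generate_cohort",
    "rectangle_region",
    "blob_region",
]

BACKGROUND_RGB = (231.0, 208.0, 223.0)  # pale eosin
VIABLE_RGB = (94.0, 58.0, 148.0)  # hematoxylin-dark purple
DISTRACTOR_RGB = (204.0, 186.0, 199.0)  # washed-out debris


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place the requested points."""


@dataclasses.dataclass(frozen=True)
class PatchSpec:
    """Parameters of one synthetic patch.

    ``nucleus_radius_px`` defaults to 20 px, the approximate viable-nucleus
    radius at the reference magnification; ``min_separation_px`` keeps
    blobs disjoint so ground truth is unambiguous.
    """

    width_px: int = 256
    height_px: int = 256
    n_viable: int = 10
    n_distractor: int = 6
    nucleus_radius_px: float = 20.0
    min_separation_px: float = 45.0
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("patch dimensions must be positive")
        if self.n_viable < 0 or self.n_distractor < 0:
            raise ValueError("counts must be non-negative")
        if self.nucleus_radius_px <= 0 or self.min_separation_px < 0:
            raise ValueError("nucleus_radius_px > 0 and min_separation_px >= 0 required")
        if not 0.0 <= self.noise_sd <= 1.0:
            raise ValueError("noise_sd must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class RenderedPatch:
    image: np.ndarray  # uint8 (h, w, 3)
    viable_points: np.ndarray  # (n, 2) float (x, y)
    distractor_points: np.ndarray


@dataclasses.dataclass(frozen=True)
class SyntheticSlide:
    image: np.ndarray  # uint8 tiled raster
    region: TumorRegion
    planted_points: np.ndarray  # (n, 2) float (x, y), all inside region
    mpp: float

    @property
    def planted_density_per_mm2(self) -> float:
        """Exact ground-truth density, recoverable with no rendering loss."""
        return len(self.planted_points) / area_mm2(self.region)


def _place_points(
    rng: np.random.Generator,
    n: int,
    lo: tuple[float, float],
    hi: tuple[float, float],
    min_sep: float,
    existing: list[np.ndarray],
    max_retries: int = 1000,
    inside=None,
    what: str = "points",
) -> np.ndarray:
    """Rejection-sample ``n`` points with pairwise separation ``min_sep``."""
    placed = [p for p in existing]
    new: list[np.ndarray] = []
    sep2 = min_sep**2
    for i in range(n):
        for _attempt in range(max_retries):
            cand = rng.uniform(lo, hi)
            if inside is not None and not inside(cand):
                continue
            if all(np.sum((cand - p) ** 2) > sep2 for p in placed):
                placed.append(cand)
                new.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place {what} {i + 1}/{n} at separation "
                f"{min_sep} px after {max_retries} retries; spec too dense"
            )
    return np.array(new).reshape(-1, 2)


def _place_distractors(
    rng: np.random.Generator,
    n: int,
    lo,
    hi,
    nucleus_radius: float,
    viable: np.ndarray,
    max_retries: int = 1000,
) -> np.ndarray:
    """Distractor centers: clear of viable blobs, free to cluster together.

    Debris clusters only need to stay off the viable nuclei (2r + 2 px so
    blobs never merge with ground truth); among themselves a loose r
    spacing suffices.
    """
    keep_off_viable2 = (2.0 * nucleus_radius + 2.0) ** 2
    self_sep2 = nucleus_radius**2
    placed: list[np.ndarray] = []
    for i in range(n):
        for _attempt in range(max_retries):
            cand = rng.uniform(lo, hi)
            if len(viable) and np.min(np.sum((viable - cand) ** 2, axis=1)) <= keep_off_viable2:
                continue
            if all(np.sum((cand - p) ** 2) > self_sep2 for p in placed):
                placed.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place distractor {i + 1}/{n} after {max_retries} retries"
            )
    return np.array(placed).reshape(-1, 2)


def _draw_nucleus(img, rng, x, y, radius, color, color_jitter=14.0):
    """Filled rotated ellipse with eccentricity 0.6-1.0 and color jitter."""
    a = radius * rng.uniform(0.85, 1.0)
    b = a * rng.uniform(0.6, 1.0)
    rot = rng.uniform(0.0, math.pi)
    col = np.clip(np.asarray(color) + rng.normal(0.0, color_jitter, 3), 0, 255)
    rr, cc = ellipse(y, x, b, a, shape=img.shape[:2], rotation=rot)
    img[rr, cc] = col


def _draw_distractor(img, rng, x, y, radius):
    """Pale fragmented cluster: several small offset chips."""
    n_frag = rng.integers(3, 7)
    for _ in range(n_frag):
        off = rng.uniform(-radius, radius, 2)
        frag_r = rng.uniform(radius / 6.0, radius / 2.5)
        col = np.clip(np.asarray(DISTRACTOR_RGB) + rng.normal(0.0, 8.0, 3), 0, 255)
        rr, cc = ellipse(
            y + off[1], x + off[0], frag_r, frag_r * rng.uniform(0.5, 1.0),
            shape=img.shape[:2], rotation=rng.uniform(0, math.pi),
        )
        img[rr, cc] = col


def render_patch(spec: PatchSpec) -> RenderedPatch:
    """Render one patch; ground-truth points are the viable blob centers."""
    rng = np.random.default_rng(spec.seed)
    w, h, r = spec.width_px, spec.height_px, spec.nucleus_radius_px
    margin = r + 2.0
    if spec.n_viable > 0 and (w <= 2 * margin or h <= 2 * margin):
        raise PlacementError(
            f"patch {w}x{h} too small for nuclei of radius {r}"
        )
    lo, hi = (margin, margin), (w - margin, h - margin)
    viable = _place_points(
        rng, spec.n_viable, lo, hi, spec.min_separation_px, [], what="viable nuclei"
    )
    distractors = _place_distractors(rng, spec.n_distractor, lo, hi, r, viable)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    for x, y in distractors:
        _draw_distractor(img, rng, x, y, r)
    for x, y in viable:
        _draw_nucleus(img, rng, x, y, r, VIABLE_RGB)
    img = ndimage.gaussian_filter(img, sigma=(1.2, 1.2, 0.0))
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd * 255.0, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return RenderedPatch(image=img, viable_points=viable, distractor_points=distractors)


def rectangle_region(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def blob_region(
    cx: float, cy: float, mean_radius: float, seed: int = 0, n_vertices: int = 24,
    irregularity: float = 0.25,
) -> Polygon:
    """Irregular star-convex polygon, a stand-in for a tumor border."""
    rng = np.random.default_rng(seed)
    angles = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    radii = mean_radius * (1.0 + rng.uniform(-irregularity, irregularity, n_vertices))
    pts = np.stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)], axis=1)
    return Polygon(pts)


def render_slide(
    n_patches_x: int,
    n_patches_y: int,
    per_patch: PatchSpec,
    region_shape: Polygon,
    mpp: float,
    n_points: int | None = None,
) -> SyntheticSlide:
    """Tiled pseudo-slide with a known number of nuclei planted in a region.

    By default the planted count matches the patch spec's areal density
    applied to the region: ``n_viable × region_area / patch_area``; pass
    ``n_points`` to plant an exact count instead. Distractors are scattered
    over the whole raster at the analogous density. The planted density is
    exactly ``len(planted_points) / area_mm2(region)``.
    """
    w = n_patches_x * per_patch.width_px
    h = n_patches_y * per_patch.height_px
    region = TumorRegion(polygons=(region_shape,), mpp=mpp)
    minx, miny, maxx, maxy = region.bounds
    margin = per_patch.nucleus_radius_px + 2.0
    if minx < 0 or miny < 0 or maxx > w or maxy > h:
        raise ValueError(f"region bounds {region.bounds} outside the {w}x{h} raster")

    rng = np.random.default_rng(per_patch.seed)
    poly = region_shape
    patch_area = per_patch.width_px * per_patch.height_px
    if n_points is None:
        n_viable = int(round(per_patch.n_viable * poly.area / patch_area))
    else:
        n_viable = int(n_points)
    n_distr = int(round(per_patch.n_distractor * w * h / patch_area))

    viable = _place_points(
        rng,
        n_viable,
        (minx, miny),
        (maxx, maxy),
        per_patch.min_separation_px,
        [],
        inside=lambda p: poly.covers(shapely_point(p)),
        what="planted nuclei",
    )
    distractors = _place_distractors(
        rng,
        n_distr,
        (margin, margin),
        (w - margin, h - margin),
        per_patch.nucleus_radius_px,
        viable,
    )

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    for x, y in distractors:
        _draw_distractor(img, rng, x, y, per_patch.nucleus_radius_px)
    for x, y in viable:
        _draw_nucleus(img, rng, x, y, per_patch.nucleus_radius_px, VIABLE_RGB)
    img = ndimage.gaussian_filter(img, sigma=(1.2, 1.2, 0.0))
    if per_patch.noise_sd > 0:
        img = img + rng.normal(0.0, per_patch.noise_sd * 255.0, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticSlide(image=img, region=region, planted_points=viable, mpp=mpp)


def shapely_point(p):
    from shapely.geometry import Point

    return Point(p[0], p[1])


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Generating model for a synthetic survival cohort.

    Densities come from a two-component Gaussian mixture straddling
    ``true_cutoff``; patients at or above the cutoff form the high-density
    group whose event hazard is multiplied by ``hazard_ratio_high``. The
    default mixture is symmetric about the cutoff (equal weights and
    spreads), which makes the planted cutoff the population median — the
    only kind of cutoff the balance-based selection rule can identify;
    asymmetric cohorts are expressible but their planted cutoff need not
    be recoverable by that rule. Event
    and censoring times are exponential (rates per month); one censoring
    time per patient, truncated at ``max_followup_months``, applies to both
    endpoints. Necrosis response links stochastically to the density group
    so discordant cases exist.
    """

    n_patients: int = 48
    density_low_mean: float = 150.0
    density_high_mean: float = 650.0
    density_low_sd: float = 100.0
    density_high_sd: float = 100.0
    mixing_weight_low: float = 0.5
    true_cutoff: float = 400.0
    hazard_ratio_high: float = 4.5
    baseline_rate: float = 0.008  # events per month, low-density group
    censor_rate: float = 0.004  # per month; 0 disables random censoring
    max_followup_months: float = 240.0
    #: P(necrosis >= 90% | density group)
    p_good_necrosis_low: float = 0.4
    p_good_necrosis_high: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.hazard_ratio_high <= 0 or self.baseline_rate <= 0:
            raise ValueError("hazard_ratio_high and baseline_rate must be positive")
        if self.censor_rate < 0 or self.max_followup_months <= 0:
            raise ValueError("censor_rate >= 0 and max_followup_months > 0 required")
        if not (self.density_low_mean < self.true_cutoff < self.density_high_mean):
            raise ValueError("mixture means must straddle true_cutoff")
        if not 0.0 <= self.mixing_weight_low <= 1.0:
            raise ValueError("mixing_weight_low must lie in [0, 1]")


COHORT_COLUMNS = [
    "patient_id",
    "density_per_mm2",
    "necrosis_rate_pct",
    "dss_months",
    "dss_event",
    "mfs_months",
    "mfs_event",
    "site",
    "size_cm",
]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table under a two-group proportional-hazards model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    # fixed component sizes (round(w*n) low), as in designed simulation
    # cohorts; iid membership would let binomial noise move the cohort's
    # balance point away from the planted cutoff
    n_low = int(round(spec.mixing_weight_low * n))
    is_low = np.zeros(n, dtype=bool)
    is_low[rng.permutation(n)[:n_low]] = True
    density = np.where(
        is_low,
        rng.normal(spec.density_low_mean, spec.density_low_sd, n),
        rng.normal(spec.density_high_mean, spec.density_high_sd, n),
    )
    density = np.clip(density, 0.0, None)
    high = density >= spec.true_cutoff

    rate = spec.baseline_rate * np.where(high, spec.hazard_ratio_high, 1.0)
    t_dss = rng.exponential(1.0 / rate)
    t_mfs = rng.exponential(1.0 / rate)
    if spec.censor_rate > 0:
        censor = np.minimum(
            rng.exponential(1.0 / spec.censor_rate, n), spec.max_followup_months
        )
    else:
        censor = np.full(n, spec.max_followup_months)

    p_good = np.where(high, spec.p_good_necrosis_high, spec.p_good_necrosis_low)
    good = rng.random(n) < p_good
    necrosis = np.where(good, rng.uniform(90.0, 100.0, n), rng.uniform(10.0, 89.0, n))

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "density_per_mm2": density,
            "necrosis_rate_pct": necrosis,
            "dss_months": np.minimum(t_dss, censor),
            "dss_event": t_dss <= censor,
            "mfs_months": np.minimum(t_mfs, censor),
            "mfs_event": t_mfs <= censor,
            "site": np.where(rng.random(n) < 0.646, "proximal", "distal"),
            "size_cm": np.round(rng.lognormal(math.log(9.0), 0.4, n), 1),
        },
        columns=COHORT_COLUMNS,
    )
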