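"""Region tiling, polygon area, in-region counting, pooled density."""

import numpy as np
import pytest
from matplotlib.path import Path as MplPath
from shapely import affinity
from shapely.geometry import Polygon

from viadens.density import (
    TumorRegion,
    area_mm2,
    count_in_region,
    planted_detector,
    slide_density,
    tile_region,
)
from viadens.synthdata import PatchSpec, blob_region, rectangle_region, render_slide


def random_simple_polygon(rng, n_vertices=20, scale=400.0):
    """Star-shaped polygon: simple by construction."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.3, 1.0, n_vertices) * scale
    cx, cy = rng.uniform(scale, 2 * scale, 2)
    return Polygon(
        np.stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)], axis=1)
    )


def raster_area_px2(poly: Polygon) -> float:
    """Pixel-counting oracle: pixels whose centers fall inside."""
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(int(minx) - 1, int(maxx) + 2) + 0.5
    ys = np.arange(int(miny) - 1, int(maxy) + 2) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    path = MplPath(np.asarray(poly.exterior.coords))
    return float(path.contains_points(pts).sum())


class TestAreaMm2:
    def test_square_millimetre(self):
        region = TumorRegion.from_vertices(
            [[(0, 0), (1000, 0), (1000, 1000), (0, 1000)]], mpp=1.0
        )
        assert area_mm2(region) == pytest.approx(1.0)

    def test_rotation_invariance(self):
        square = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        rotated = affinity.rotate(square, 30, origin="centroid")
        region = TumorRegion(polygons=(rotated,), mpp=1.0)
        assert area_mm2(region) == pytest.approx(1.0)

    def test_mpp_scaling_is_quadratic(self):
        ring = [(0, 0), (500, 0), (500, 700), (0, 700)]
        a1 = area_mm2(TumorRegion.from_vertices([ring], mpp=0.25))
        a2 = area_mm2(TumorRegion.from_vertices([ring], mpp=0.5))
        assert a2 == pytest.approx(4 * a1)

    def test_hole_subtracted(self):
        outer = Polygon(
            [(0, 0), (1000, 0), (1000, 1000), (0, 1000)],
            holes=[[(200, 200), (400, 200), (400, 400), (200, 400)]],
        )
        region = TumorRegion(polygons=(outer,), mpp=1.0)
        assert area_mm2(region) == pytest.approx(1.0 - 0.04)

    def test_self_intersecting_ring_rejected(self):
        with pytest.raises(ValueError, match="[Ss]elf-intersect"):
            TumorRegion.from_vertices([[(0, 0), (10, 10), (10, 0), (0, 10)]], mpp=1.0)

    def test_matches_rasterization_oracle(self, rng):
        for _ in range(25):
            poly = random_simple_polygon(rng)
            region = TumorRegion(polygons=(poly,), mpp=1.0)
            shoelace = area_mm2(region) * 1e6  # back to px²
            assert shoelace == pytest.approx(raster_area_px2(poly), rel=0.005)


class TestTileRegion:
    def test_exact_four_patch_cover(self):
        region = TumorRegion.from_vertices(
            [[(0, 0), (2048, 0), (2048, 2048), (0, 2048)]], mpp=1.0
        )
        grid = tile_region(region, (2048, 2048), patch_size=1024)
        assert len(grid.patches) == 4

    def test_region_inside_one_patch(self):
        region = TumorRegion.from_vertices(
            [[(100, 100), (400, 100), (400, 400), (100, 400)]], mpp=1.0
        )
        grid = tile_region(region, (2048, 2048), patch_size=1024)
        assert grid.patches == ((0, 0, 1024, 1024),)

    def test_matches_rasterization_oracle(self, rng):
        for _ in range(10):
            poly = random_simple_polygon(rng, scale=300.0)
            region = TumorRegion(polygons=(poly,), mpp=1.0)
            grid = tile_region(region, (1024, 1024), patch_size=128)
            # oracle: patches containing at least one inside-pixel center
            path = MplPath(np.asarray(poly.exterior.coords))
            expected = set()
            minx, miny, maxx, maxy = poly.bounds
            xs = np.arange(int(minx) - 1, int(maxx) + 2) + 0.5
            ys = np.arange(int(miny) - 1, int(maxy) + 2) + 0.5
            gx, gy = np.meshgrid(xs, ys)
            pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
            inside = pts[path.contains_points(pts)]
            for x, y in inside:
                expected.add((int(x // 128) * 128, int(y // 128) * 128))
            got = {(x0, y0) for x0, y0, _, _ in grid.patches}
            # rasterization misses patches touched only by slivers thinner
            # than one pixel; the oracle set must be contained in ours
            assert expected <= got
            assert len(got - expected) <= max(2, len(expected) // 10)

    def test_region_outside_raster_rejected(self):
        region = TumorRegion.from_vertices(
            [[(0, 0), (600, 0), (600, 600), (0, 600)]], mpp=1.0
        )
        with pytest.raises(ValueError, match="outside"):
            tile_region(region, (512, 512), patch_size=128)


@pytest.fixture(scope="module")
def planted_slide():
    return render_slide(
        4, 4, PatchSpec(seed=11), rectangle_region(12, 12, 1012, 1012),
        mpp=1.0, n_points=96,
    )


class TestCountInRegion:
    def test_oracle_on_empty_slide(self):
        slide = render_slide(
            2, 2, PatchSpec(n_viable=0, n_distractor=0, seed=0),
            rectangle_region(40, 40, 470, 470), mpp=1.0,
        )
        grid = tile_region(slide.region, slide.image.shape[:2], 256)
        counts = count_in_region(planted_detector(slide), slide.image, slide.region, grid)
        assert sum(counts) == 0

    def test_oracle_recovers_planted_count_exactly(self, planted_slide):
        grid = tile_region(planted_slide.region, planted_slide.image.shape[:2], 256)
        counts = count_in_region(
            planted_detector(planted_slide), planted_slide.image,
            planted_slide.region, grid,
        )
        assert sum(counts) == len(planted_slide.planted_points)
        assert len(counts) == len(grid.patches)

    def test_points_outside_region_never_counted(self):
        poly = blob_region(350, 350, 230, seed=5)
        slide = render_slide(3, 3, PatchSpec(n_viable=6, seed=6), poly, mpp=1.0)
        grid = tile_region(slide.region, slide.image.shape[:2], 256)

        # detector that also reports off-region junk at patch corners
        base = planted_detector(slide)

        def noisy(patch, bounds):
            pts = base(patch, bounds)
            return np.vstack([pts, [[1.0, 1.0]]])

        noisy.needs_bounds = True
        counts = count_in_region(noisy, slide.image, slide.region, grid)
        path = MplPath(np.asarray(poly.exterior.coords))
        n_inside_corner = 0
        for x0, y0, _, _ in grid.patches:
            if path.contains_point((x0 + 1.0, y0 + 1.0), radius=1e-9):
                n_inside_corner += 1
        assert sum(counts) <= len(slide.planted_points) + n_inside_corner
        # junk at corners outside the polygon must be filtered
        assert sum(counts) >= len(slide.planted_points)

    def test_seam_duplicates_suppressed(self, planted_slide):
        grid = tile_region(planted_slide.region, planted_slide.image.shape[:2], 256)
        base = planted_detector(planted_slide)

        def duplicating(patch, bounds):
            pts = base(patch, bounds)
            return np.vstack([pts, pts + 0.5])  # near-duplicates 0.7 px away

        duplicating.needs_bounds = True
        counts = count_in_region(
            duplicating, planted_slide.image, planted_slide.region, grid,
            min_distance=20.0,
        )
        assert sum(counts) == len(planted_slide.planted_points)


class TestSlideDensity:
    def test_simple_arithmetic(self):
        region = TumorRegion.from_vertices(
            [[(0, 0), (1000, 0), (1000, 10000), (0, 10000)]], mpp=1.0
        )  # 10 mm²
        res = slide_density([[790]], [region])
        assert res.density_per_mm2 == pytest.approx(79.0)
        assert res.sum_cells == 790

    def test_pooled_ratio_not_mean_of_densities(self):
        ring = [(0, 0), (1000, 0), (1000, 2000), (0, 2000)]  # 2 mm² each
        regions = [TumorRegion.from_vertices([ring], mpp=1.0) for _ in range(2)]
        res = slide_density([[100], [300]], regions)
        assert res.density_per_mm2 == pytest.approx(100.0)  # 400/4, not 125

    def test_pooled_density_between_per_slide_extremes(self, rng):
        ring = [(0, 0), (1000, 0), (1000, 1000), (0, 1000)]
        for _ in range(20):
            counts = [[int(rng.integers(0, 500))] for _ in range(3)]
            areas = rng.uniform(0.5, 3.0, 3)
            regions = [
                TumorRegion.from_vertices(
                    [[(0, 0), (1000 * a, 0), (1000 * a, 1000), (0, 1000)]], mpp=1.0
                )
                for a in areas
            ]
            res = slide_density(counts, regions)
            per_slide = [
                c[0] / area_mm2(r) for c, r in zip(counts, regions)
            ]
            assert min(per_slide) - 1e-9 <= res.density_per_mm2 <= max(per_slide) + 1e-9

    def test_planted_truth_three_slide_case(self):
        slides = [
            render_slide(2, 2, PatchSpec(n_viable=5, seed=20 + i),
                         rectangle_region(30, 30, 480, 480), mpp=1.0)
            for i in range(3)
        ]
        counts, regions = [], []
        for s in slides:
            grid = tile_region(s.region, s.image.shape[:2], 256)
            counts.append(count_in_region(planted_detector(s), s.image, s.region, grid))
            regions.append(s.region)
        res = slide_density(counts, regions)
        planted_sum = sum(len(s.planted_points) for s in slides)
        planted_area = sum(area_mm2(s.region) for s in slides)
        assert res.sum_cells == planted_sum
        assert res.density_per_mm2 == pytest.approx(planted_sum / planted_area)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            slide_density([[1]], [])
        ring = [(0, 0), (10, 0), (10, 10), (0, 10)]
        region = TumorRegion.from_vertices([ring], mpp=1.0)
        with pytest.raises(ValueError, match="region"):
            slide_density([[1], [2]], [region])

    def test_negative_counts_rejected(self):
        ring = [(0, 0), (1000, 0), (1000, 1000), (0, 1000)]
        region = TumorRegion.from_vertices([ring], mpp=1.0)
        with pytest.raises(ValueError):
            slide_density([[-1]], [region])
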