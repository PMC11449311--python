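import numpy as np
import pytest
import shapely

import lionhab as lh
from lionhab import landscape as ls
from lionhab.raster import RasterGrid


def _template(n=20, cs=100.0):
    return RasterGrid(np.zeros((n, n)), origin_x=0.0, origin_y=n * cs, cell_size=cs)


# ---------------------------------------------------------------------------
# percent cover
# ---------------------------------------------------------------------------

class TestPercentCover:
    def test_all_ones_gives_100(self):
        grid = _template(20, 10.0).copy_with(np.ones((20, 20)))
        out = lh.percent_cover(grid, radius=50.0)
        np.testing.assert_allclose(out.values, 100.0)

    def test_checkerboard_is_half(self):
        vals = np.indices((30, 30)).sum(axis=0) % 2
        grid = _template(30, 10.0).copy_with(vals)
        out = lh.percent_cover(grid, radius=55.0)
        # interior cells: 50% up to the disc's exact parity imbalance
        dx, dy = np.meshgrid(np.arange(-5, 6), np.arange(-5, 6))
        disc = (dx**2 + dy**2) * 100 <= 55.0**2
        imbalance = abs(int(((-1.0) ** (dx + dy))[disc].sum()))
        tol = 100.0 * imbalance / (2 * disc.sum())
        interior = out.values[8:-8, 8:-8]
        assert np.all(np.abs(interior - 50.0) <= tol + 1e-9)

    def test_matches_bruteforce_disc_count(self):
        rng = np.random.default_rng(4)
        vals = (rng.uniform(size=(25, 25)) < 0.4).astype(float)
        grid = _template(25, 10.0).copy_with(vals)
        radius = 35.0
        out = lh.percent_cover(grid, radius)
        r, c = 12, 7
        cx, cy = grid.rowcol_to_xy(r, c)
        X, Y = grid.cell_centers()
        inside = (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2 + 1e-9
        expected = 100.0 * vals[inside].sum() / inside.sum()
        assert out.values[r, c] == pytest.approx(expected)

    def test_range_and_monotonicity_under_added_pixels(self):
        rng = np.random.default_rng(9)
        vals = (rng.uniform(size=(25, 25)) < 0.3).astype(float)
        grid = _template(25, 10.0).copy_with(vals)
        out1 = lh.percent_cover(grid, 40.0)
        assert np.all((out1.values >= 0) & (out1.values <= 100))
        more = vals.copy()
        zeros = np.argwhere(more == 0)
        for r, c in zeros[:30]:
            more[r, c] = 1.0
        out2 = lh.percent_cover(grid.copy_with(more), 40.0)
        assert np.all(out2.values >= out1.values - 1e-9)

    def test_radius_below_cell_size_rejected(self):
        grid = _template(20, 10.0).copy_with(np.ones((20, 20)))
        with pytest.raises(ValueError, match="radius"):
            lh.percent_cover(grid, radius=5.0)


# ---------------------------------------------------------------------------
# TRI
# ---------------------------------------------------------------------------

class TestTRI:
    def test_flat_dem_is_zero(self):
        out = lh.terrain_ruggedness_index(_template(10).copy_with(np.full((10, 10), 42.0)))
        np.testing.assert_allclose(out.values, 0.0)

    def test_single_peak(self):
        dem = np.zeros((5, 5))
        dem[2, 2] = 1.0
        out = lh.terrain_ruggedness_index(_template(5).copy_with(dem))
        assert out.values[2, 2] == pytest.approx(np.sqrt(8.0))

    def test_matches_hand_enumeration(self):
        rng = np.random.default_rng(1)
        dem = rng.normal(0, 10, (8, 8))
        out = lh.terrain_ruggedness_index(_template(8).copy_with(dem))
        r, c = 4, 5
        acc = sum(
            (dem[r + dr, c + dc] - dem[r, c]) ** 2
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        )
        assert out.values[r, c] == pytest.approx(np.sqrt(acc))
        # corner cell uses its three in-bounds neighbors only
        corner = sum((dem[dr, dc] - dem[0, 0]) ** 2 for dr, dc in [(0, 1), (1, 0), (1, 1)])
        assert out.values[0, 0] == pytest.approx(np.sqrt(corner))


# ---------------------------------------------------------------------------
# distance / density rasters
# ---------------------------------------------------------------------------

class TestPointRasters:
    def test_distance_zero_at_point_and_geometry(self):
        template = _template(10, 300.0)
        cx, cy = template.rowcol_to_xy(5, 2)
        pts = lh.PointSet(np.array([[cx, cy]]), "boma")
        out = lh.distance_raster(pts, template)
        assert out.values[5, 2] == 0.0
        assert out.values[5, 5] == pytest.approx(900.0)

    def test_distance_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        template = _template(20, 100.0)
        pts = lh.PointSet(rng.uniform(0, 2000, (50, 2)), "boma")
        out = lh.distance_raster(pts, template)
        X, Y = template.cell_centers()
        for _ in range(20):
            r, c = rng.integers(0, 20, 2)
            d = np.hypot(pts.points[:, 0] - X[r, c], pts.points[:, 1] - Y[r, c]).min()
            assert out.values[r, c] == pytest.approx(d)

    def test_distance_triangle_inequality(self):
        rng = np.random.default_rng(8)
        template = _template(15, 100.0)
        pts = lh.PointSet(rng.uniform(0, 1500, (30, 2)), "boma")
        out = lh.distance_raster(pts, template)
        X, Y = template.cell_centers()
        for _ in range(50):
            r1, c1, r2, c2 = rng.integers(0, 15, 4)
            sep = np.hypot(X[r1, c1] - X[r2, c2], Y[r1, c1] - Y[r2, c2])
            assert abs(out.values[r1, c1] - out.values[r2, c2]) <= sep + 1e-9

    def test_empty_point_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lh.distance_raster(lh.PointSet(np.empty((0, 2)), "boma"), _template(10))

    def test_density_counts_and_closed_disc(self):
        template = _template(10, 100.0)
        cx, cy = template.rowcol_to_xy(4, 4)
        pts = lh.PointSet(np.array([[cx, cy], [cx + 250.0, cy], [cx + 500.0, cy]]), "boma")
        out = lh.density_raster(pts, template, radius=250.0)
        assert out.values[4, 4] == 2.0  # boundary point included (closed disc)
        far = template.rowcol_to_xy(9, 0)
        assert out.values[9, 0] == 0.0

    def test_density_sum_at_least_point_count(self):
        rng = np.random.default_rng(2)
        template = _template(12, 100.0)
        pts = lh.PointSet(rng.uniform(50, 1150, (40, 2)), "boma")
        out = lh.density_raster(pts, template, radius=150.0)  # > cell diagonal
        assert out.values.sum() >= len(pts)


# ---------------------------------------------------------------------------
# scaling and extraction
# ---------------------------------------------------------------------------

class TestScaling:
    def test_scaled_layers_have_mean0_sd1(self, stack):
        for name, grid in stack.layers.items():
            vals = grid.values[~grid.is_nodata()]
            assert abs(vals.mean()) < 1e-6, name
            assert abs(vals.std() - 1.0) < 1e-6, name

    def test_constant_layer_rejected_by_name(self):
        template = _template(10)
        raw = ls.CovariateStack(layers={"flat": template.copy_with(np.full((10, 10), 3.0))})
        with pytest.raises(ValueError, match="flat"):
            lh.scale_covariates(raw)

    def test_unscale_roundtrip(self, bundle, stack):
        raw = bundle[0]
        name = "cover"
        scaled = stack.layers[name].values
        np.testing.assert_allclose(ls.unscale(stack, name, scaled), raw.layers[name].values, atol=1e-10)

    def test_extraction_at_cell_center_matches_layer(self, stack):
        grid = stack.layers["cover"]
        x, y = grid.rowcol_to_xy(10, 20)
        out = lh.extract_covariates(stack, x, y, "wet", names=["cover"])
        assert out["cover"] == grid.values[10, 20]

    def test_wet_dry_extraction_differs_only_in_seasonal_layers(self, stack):
        x, y = stack.template.rowcol_to_xy(30, 40)
        wet = lh.extract_covariates(stack, x, y, "wet")
        dry = lh.extract_covariates(stack, x, y, "dry")
        assert wet["cover"] == dry["cover"]
        assert wet["tri"] == dry["tri"]
        assert wet["evi"] != dry["evi"]

    def test_matrix_extraction_matches_per_layer_lookups(self, stack):
        rng = np.random.default_rng(12)
        xs = rng.uniform(1000, 19000, 100)
        ys = rng.uniform(1000, 19000, 100)
        seasons = np.where(rng.uniform(size=100) < 0.5, "wet", "dry")
        names = ["cover", "evi", "dist_human"]
        mat = ls.extract_matrix(stack, xs, ys, seasons, names)
        for i in range(100):
            for j, n in enumerate(names):
                assert mat[i, j] == stack.resolve(n, seasons[i]).sample(xs[i], ys[i])


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

class TestGenerator:
    def test_seeded_determinism(self):
        a, *_ = lh.generate_synthetic_landscape(seed=5, extent=(12_000, 12_000), cell_size=200.0)
        b, *_ = lh.generate_synthetic_landscape(seed=5, extent=(12_000, 12_000), cell_size=200.0)
        for name in a.layers:
            np.testing.assert_array_equal(a.layers[name].values, b.layers[name].values)

    def test_physical_ranges(self, bundle):
        raw = bundle[0]
        cover = raw.layers["cover"].values
        assert cover.min() >= 0.0 and cover.max() <= 100.0
        assert raw.layers["tri"].values.min() >= 0.0
        assert raw.layers["evi_wet"].values.mean() > raw.layers["evi_dry"].values.mean()

    def test_wet_season_bomas_vacate_subregion(self, bundle):
        _, points, _, vacate = bundle
        dry_in = shapely.contains(vacate, shapely.points(points["bomas_dry"].points)).sum()
        wet_in = shapely.contains(vacate, shapely.points(points["bomas_wet"].points)).sum()
        assert wet_in < dry_in

    def test_zero_bomas_flags_nodata_distance_layer(self):
        params = lh.LandscapeParams(n_bomas_dry=0)
        raw, *_ = lh.generate_synthetic_landscape(seed=1, extent=(12_000, 12_000), cell_size=200.0, params=params)
        assert raw.layers["dist_human_dry"].is_nodata().all()
        assert any("all_nodata" in f for f in raw.flags)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lh.generate_synthetic_landscape(seed=1, extent=(2_000, 2_000), cell_size=200.0)

    def test_water_and_human_distance_layers_exist(self, bundle):
        raw = bundle[0]
        assert "dist_water" in raw.layers  # kept for the correlation check, not modelled


class TestPlaceBomas:
    def _region(self):
        return shapely.box(0, 0, 10_000, 10_000), shapely.box(0, 0, 4_000, 10_000)

    def test_fraction_zero_keeps_all(self):
        region, vacate = self._region()
        dry, wet = lh.place_bomas_seasonal(region, 100, vacate, 0.0, seed=3)
        assert len(wet) == len(dry)

    def test_fraction_one_empties_polygon(self):
        region, vacate = self._region()
        dry, wet = lh.place_bomas_seasonal(region, 100, vacate, 1.0, seed=3)
        assert shapely.contains(vacate, shapely.points(wet.points)).sum() == 0

    def test_half_fraction_removes_about_half(self):
        region, vacate = self._region()
        dry, wet = lh.place_bomas_seasonal(region, 400, vacate, 0.5, seed=3)
        n_in_dry = shapely.contains(vacate, shapely.points(dry.points)).sum()
        n_in_wet = shapely.contains(vacate, shapely.points(wet.points)).sum()
        removed = n_in_dry - n_in_wet
        # binomial(n_in_dry, 0.5): within 4 sd of half
        assert abs(removed - 0.5 * n_in_dry) <= 4 * np.sqrt(0.25 * n_in_dry)

    def test_zero_dry_count_rejected(self):
        region, vacate = self._region()
        with pytest.raises(ValueError):
            lh.place_bomas_seasonal(region, 0, vacate, 0.5, seed=1)
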