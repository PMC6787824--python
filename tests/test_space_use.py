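"""Kernel space use: analytic Gaussian oracles, contours, overlap, catalog."""

import numpy as np
import pytest

from seaseg import space_use as su


def gaussian_cloud(n, sigma_km, center=(10.0, -25.0), seed=42):
    rng = np.random.default_rng(seed)
    dx = rng.normal(0, sigma_km, n)
    dy = rng.normal(0, sigma_km, n)
    lon = center[0] + dx / (111.195 * np.cos(np.radians(center[1])))
    lat = center[1] + dy / 111.195
    return lon, lat


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert su.great_circle_km(12.3, -45.6, 12.3, -45.6) == 0.0

    def test_equator_to_pole_quarter_circumference(self):
        assert su.great_circle_km(0, 0, 0, 90) == pytest.approx(10007.5, abs=0.1)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.uniform([-180, -89], [180, 89])
            b = rng.uniform([-180, -89], [180, 89])
            assert su.great_circle_km(*a, *b) == pytest.approx(
                su.great_circle_km(*b, *a), rel=1e-12)


class TestProjection:
    def test_roundtrip(self):
        rng = np.random.default_rng(2)
        lon = rng.uniform(-40, 40, 50)
        lat = rng.uniform(-50, 50, 50)
        x, y = su.laea_project(lon, lat, 5.0, -10.0)
        lon2, lat2 = su.laea_inverse(x, y, 5.0, -10.0)
        assert np.allclose(lon, lon2, atol=1e-9)
        assert np.allclose(lat, lat2, atol=1e-9)

    def test_local_distances_preserved(self):
        # near the projection centre distances are ~ great-circle exact
        x, y = su.laea_project([10.0, 12.0], [-25.0, -25.0], 11.0, -25.0)
        proj_d = float(np.hypot(np.diff(x), np.diff(y))[0])
        gc_d = su.great_circle_km(10.0, -25.0, 12.0, -25.0)
        assert proj_d == pytest.approx(gc_d, rel=1e-3)


class TestKernelUD:
    def test_gaussian_cloud_matches_analytic_area(self):
        lon, lat = gaussian_cloud(5000, 100.0)
        k = su.kernel_ud(lon, lat, bandwidth_km=186.0, cell_km=25.0)
        analytic = 2 * np.pi * np.log(2) * (100.0**2 + 186.0**2)
        assert k.contour_area_km2(50) == pytest.approx(analytic, rel=0.05)

    def test_identical_positions_kernel_only_area(self):
        k = su.kernel_ud(np.full(10, 3.0), np.full(10, 12.0), 186.0, 25.0)
        analytic = 2 * np.pi * np.log(2) * 186.0**2
        assert k.contour_area_km2(50) == pytest.approx(analytic, rel=0.05)

    def test_too_few_positions_raises(self):
        with pytest.raises(su.InsufficientPositionsError):
            su.kernel_ud([0, 1, 2], [0, 1, 2])

    def test_density_normalised_and_contours_nested(self):
        for seed in (1, 2, 3):
            lon, lat = gaussian_cloud(300, 250.0, seed=seed)
            k = su.kernel_ud(lon, lat)
            assert k.density.sum() * k.cell_km**2 == pytest.approx(1.0, abs=1e-6)
            m50, m95 = k.contour_mask(50), k.contour_mask(95)
            assert m50.sum() < m95.sum()
            assert np.all(m95[m50])  # 50% cells are a subset of 95% cells


class TestSummarize:
    def test_unimodal_centroid_near_sample_mean(self):
        lon, lat = gaussian_cloud(2000, 150.0)
        k = su.kernel_ud(lon, lat)
        a50, a95, (clon, clat), counts = su.summarize_ud(k)
        assert a50 < a95
        assert len(counts) == 1
        d = su.great_circle_km(clon, clat, np.mean(lon), np.mean(lat))
        assert d <= 25.0 * np.sqrt(2)

    def test_bimodal_centroid_in_heavier_mode(self):
        lon1, lat1 = gaussian_cloud(700, 120.0, center=(0.0, 0.0), seed=5)
        lon2, lat2 = gaussian_cloud(300, 120.0, center=(0.0, 27.0), seed=6)
        k = su.kernel_ud(np.r_[lon1, lon2], np.r_[lat1, lat2])
        _, _, (clon, clat), counts = su.summarize_ud(k)
        assert len(counts) == 2
        assert abs(clat) < 10.0  # inside the 70% mode near the equator


class TestOverlap:
    def test_identical_sets_full_overlap(self):
        lon, lat = gaussian_cloud(500, 150.0)
        ka = su.kernel_ud(lon, lat)
        kb = su.kernel_ud(lon, lat)
        ov = su.hr_overlap(ka, kb, 50)
        assert ov.overlap_ab == pytest.approx(1.0, abs=0.01)
        assert ov.overlap_ba == pytest.approx(1.0, abs=0.01)

    def test_distant_clouds_zero_overlap(self):
        la, ta = gaussian_cloud(300, 100.0, center=(0.0, 0.0), seed=7)
        lb, tb = gaussian_cloud(300, 100.0, center=(45.0, 0.0), seed=8)
        ov = su.hr_overlap(su.kernel_ud(la, ta), su.kernel_ud(lb, tb), 95)
        assert ov.overlap_ab == 0.0 and ov.overlap_ba == 0.0

    def test_nested_clouds_asymmetric(self):
        la, ta = gaussian_cloud(2000, 60.0, seed=9)
        lb, tb = gaussian_cloud(2000, 500.0, seed=10)
        ov = su.hr_overlap(su.kernel_ud(la, ta), su.kernel_ud(lb, tb), 95)
        assert ov.overlap_ab > 0.97
        assert ov.overlap_ba < ov.overlap_ab

    def test_relabel_swaps_fields(self):
        la, ta = gaussian_cloud(400, 200.0, seed=11)
        lb, tb = gaussian_cloud(300, 150.0, center=(13.0, -27.0), seed=12)
        ka, kb = su.kernel_ud(la, ta), su.kernel_ud(lb, tb)
        ab = su.hr_overlap(ka, kb, 50)
        ba = su.hr_overlap(kb, ka, 50)
        assert ab.overlap_ab == pytest.approx(ba.overlap_ba, abs=1e-12)
        assert ab.overlap_ba == pytest.approx(ba.overlap_ab, abs=1e-12)


class TestAreaCatalog:
    def test_containment(self):
        assert su.assign_area((-18.0, 24.0)) == "Canary Current"
        assert su.assign_area((10.0, -25.0)) == "Benguela Current"

    def test_boundary_tie_breaks_by_catalog_order(self):
        # (-20, 12) lies on the shared edge of Canary and Guinea Currents;
        # Canary comes first in the bundled catalog
        assert su.assign_area((-20.0, 12.0)) == "Canary Current"

    def test_gap_falls_back_to_nearest_with_warning(self):
        with pytest.warns(UserWarning):
            label = su.assign_area((-30.0, -20.0))
        assert label in {"South Atlantic", "Brazil Current", "Benguela Current",
                         "Guinea Current"}

    def test_empty_catalog_raises(self):
        with pytest.raises(su.EmptyCatalogError):
            su.assign_area((0.0, 0.0), catalog=[])


class TestGeoJSON:
    def test_contours_export_as_closed_polygons(self):
        lon, lat = gaussian_cloud(500, 150.0, seed=13)
        k = su.kernel_ud(lon, lat)
        gj = su.contour_geojson(k)
        assert gj["type"] == "FeatureCollection"
        assert len(gj["features"]) >= 2
        for f in gj["features"]:
            ring = f["geometry"]["coordinates"][0]
            assert ring[0] == ring[-1]
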