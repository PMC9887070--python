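import numpy as np
import pytest

from apcmap import spatial
from apcmap.core_tables import AreaGeometry, ValidationError
from apcmap.spatial import (Variogram, classify_values, empirical_variogram,
                            estimate_tau2, fit_variogram, krige, make_grid,
                            shrink_to_null)
from apcmap.synthetic import generate_spatial_field


class TestShrinkage:
    def test_tau2_zero_when_everything_is_null(self):
        assert estimate_tau2([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], null=1.0) == 0.0

    def test_tau2_equals_empirical_variance_when_noise_free(self):
        v = np.array([0.8, 1.0, 1.4, 1.2])
        tau2 = estimate_tau2(v, np.zeros(4), null=1.0)
        assert tau2 == pytest.approx(np.mean((v - 1.0) ** 2))

    def test_tau2_recovery_from_simulation(self, rng):
        true_tau2, n = 0.04, 300
        s2 = rng.uniform(0.005, 0.03, n)
        v = 1.0 + rng.normal(0, np.sqrt(true_tau2), n) + rng.normal(0, np.sqrt(s2))
        est = estimate_tau2(v, s2, null=1.0)
        assert est == pytest.approx(true_tau2, rel=0.25)

    def test_limits(self):
        assert shrink_to_null(2.0, 0.0, 0.5, 1.0).stabilized == 2.0
        assert shrink_to_null(2.0, 0.5, 0.0, 1.0).stabilized == 1.0
        assert shrink_to_null(2.0, 0.3, 0.3, 1.0).stabilized == pytest.approx(1.5)

    def test_degenerate_flag(self):
        sv = shrink_to_null(2.0, 0.0, 0.0, 1.0)
        assert sv.degenerate and sv.stabilized == 1.0

    def test_shrinkage_strictly_decreasing_in_variance(self):
        """For a fixed departure from the null, |z - m0| shrinks as the
        sampling variance grows."""
        sigmas = np.linspace(0.01, 2.0, 50)
        dev = [abs(shrink_to_null(1.7, s2, 0.05, 1.0).stabilized - 1.0)
               for s2 in sigmas]
        assert all(a > b for a, b in zip(dev, dev[1:]))


class TestEmpiricalVariogram:
    def test_two_points_definition(self):
        out = empirical_variogram([[0.0, 0.0], [1.0, 0.0]], [0.0, 3.0],
                                  n_bins=2, max_dist=2.0)
        assert len(out) == 1
        assert out["gamma"].iloc[0] == pytest.approx(9.0 / 2.0)

    def test_constant_field_is_flat_zero(self, rng):
        pts = rng.uniform(0, 10, (40, 2))
        out = empirical_variogram(pts, np.full(40, 5.0))
        assert np.allclose(out["gamma"], 0.0)

    def test_white_noise_is_flat_at_its_variance(self, rng):
        pts = np.column_stack([np.repeat(np.arange(25), 25),
                               np.tile(np.arange(25), 25)]).astype(float)
        s2 = 0.5
        z = rng.normal(0, np.sqrt(s2), len(pts))
        out = empirical_variogram(pts, z, n_bins=8)
        # Matheron estimator has variance ~ 2 gamma^2 / N_k per bin
        mc_sd = np.sqrt(2.0 * s2 ** 2 / out["n_pairs"])
        assert (np.abs(out["gamma"] - s2) < 3 * mc_sd + 0.02).all()

    def test_coincident_points_rejected(self):
        with pytest.raises(ValidationError):
            empirical_variogram([[0, 0], [0, 0]], [1.0, 2.0])


class TestFitVariogram:
    def test_exponential_recovery(self):
        pts = np.column_stack([np.repeat(np.arange(20), 20),
                               np.tile(np.arange(20), 20)]) * 10.0
        u = generate_spatial_field(pts, 0.01, 0.09, 30.0,
                                   np.random.default_rng(1))
        fit = fit_variogram(empirical_variogram(pts, u, n_bins=14))
        assert fit.partial_sill == pytest.approx(0.09, rel=0.30)
        assert fit.range_ == pytest.approx(30.0, rel=0.30)
        assert fit.nugget < 0.03

    def test_pure_nugget_field_has_no_structure(self, rng):
        pts = rng.uniform(0, 100, (300, 2))
        z = rng.normal(0, 0.3, 300)
        fit = fit_variogram(empirical_variogram(pts, z, n_bins=10))
        assert fit.partial_sill < 0.25 * (fit.nugget + fit.partial_sill) + 1e-6

    def test_too_few_bins_rejected(self):
        import pandas as pd
        binned = pd.DataFrame({"h": [1, 2], "gamma": [0.1, 0.2],
                               "n_pairs": [5, 5]})
        with pytest.raises(ValidationError):
            fit_variogram(binned)


class TestKriging:
    @pytest.fixture()
    def system(self, rng):
        pts = rng.uniform(0, 10, (5, 2))
        z = rng.normal(1.0, 0.4, 5)
        v = Variogram("exponential", nugget=0.0, partial_sill=0.1, range_=3.0)
        return pts, z, v

    def test_exact_interpolation_with_zero_nugget(self, system):
        pts, z, v = system
        surf = krige(pts, z, np.zeros(5), v, pts)
        assert np.abs(surf.values - z).max() < 1e-10

    def test_constant_field_reproduced_everywhere(self, system, rng):
        pts, _, v = system
        surf = krige(pts, np.full(5, 2.5), np.zeros(5), v,
                     rng.uniform(0, 10, (30, 2)))
        assert np.abs(surf.values - 2.5).max() < 1e-10

    def test_weights_sum_to_one(self, system, rng):
        pts, z, v = system
        _, weights = krige(pts, z, np.full(5, 0.05), v,
                           rng.uniform(0, 10, (40, 2)), return_weights=True)
        assert np.abs(weights.sum(axis=1) - 1.0).max() < 1e-10

    def test_matches_direct_linear_system_oracle(self, rng):
        """For small n the prediction equals an independent dense solve of
        the augmented ordinary-kriging system."""
        from scipy.spatial.distance import cdist
        for n in (3, 4, 6):
            pts = rng.uniform(0, 8, (n, 2))
            z = rng.normal(0, 1, n)
            e2 = rng.uniform(0, 0.05, n)
            v = Variogram("exponential", nugget=0.02, partial_sill=0.3,
                          range_=2.5)
            tgt = rng.uniform(0, 8, (3, 2))
            surf = krige(pts, z, e2, v, tgt)
            for j in range(3):
                A = np.zeros((n + 1, n + 1))
                A[:n, :n] = v.covariance(cdist(pts, pts))
                A[np.diag_indices(n)[0][:n], np.diag_indices(n)[1][:n]] = v.sill + e2
                A[n, :n] = A[:n, n] = 1.0
                b = np.concatenate([v.covariance(cdist(tgt[j:j + 1], pts))[0], [1.0]])
                lam = np.linalg.solve(A, b)
                assert surf.values[j] == pytest.approx(lam[:n] @ z, abs=1e-10)

    def test_measurement_error_smooths_instead_of_interpolating(self, rng):
        """With e^2 > 0 everywhere, the surface at a data centroid lies
        strictly between the local value and the field mean."""
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]], float)
        z = np.array([0.8, 1.1, 0.9, 1.2, 2.0])
        v = Variogram("exponential", nugget=0.0, partial_sill=0.2, range_=1.0)
        surf = krige(pts, z, np.full(5, 0.1), v, pts[4:5])
        assert z.mean() < surf.values[0] < z[4]

    def test_coincident_centroids_rejected(self):
        v = Variogram("exponential", nugget=0.0, partial_sill=0.1, range_=1.0)
        with pytest.raises(ValidationError, match="coincident"):
            krige([[0, 0], [0, 0], [1, 1]], [1, 2, 3], None, v, [[0.5, 0.5]])


class TestClassifyAndRender:
    def test_classification_rules(self):
        assert classify_values([1.0], 1.0, 0.1)[0] == "near"
        assert classify_values([1.2], 1.0, 0.1)[0] == "above"
        assert classify_values([0.5], 1.0, 0.1)[0] == "below"
        # zero tolerance: strict sign classification
        out = classify_values([0.999, 1.001], 1.0, 0.0)
        assert list(out) == ["below", "above"]
        # additive scale for AAPC about 0
        out = classify_values([-3.0, 0.2, 3.0], 0.0, 1.0, scale="additive")
        assert list(out) == ["below", "near", "above"]

    def test_render_is_deterministic_and_validates(self, tmp_path, rng):
        from shapely.geometry import box
        geoms = [AreaGeometry(f"g{i}{j}", box(i, j, i + 1, j + 1))
                 for i in range(4) for j in range(4)]
        pts = make_grid(geoms, resolution=0.5)
        assert len(pts) == 64  # 8x8 interior points of the 4x4 union
        v = Variogram("exponential", nugget=0.0, partial_sill=0.1, range_=1.5)
        coords = np.array([(g.centroid.x, g.centroid.y) for g in geoms])
        z = rng.normal(1.0, 0.3, len(geoms))
        surf = krige(coords, z, np.full(len(z), 0.02), v, pts)
        spatial.classify_surface(surf, null=1.0, tolerance=0.05)
        p1, p2 = tmp_path / "m1.png", tmp_path / "m2.png"
        spatial.render_map(surf, geoms, p1, contour_levels=[0.9, 1.0, 1.1])
        spatial.render_map(surf, geoms, p2, contour_levels=[0.9, 1.0, 1.1])
        assert p1.read_bytes() == p2.read_bytes()
        with pytest.raises(ValidationError, match="empty geometry"):
            spatial.render_map(surf, [], tmp_path / "m3.png")

    def test_constant_surface_single_class(self, tmp_path):
        from shapely.geometry import box
        geoms = [AreaGeometry("g", box(0, 0, 3, 3))]
        from apcmap.spatial import KrigedSurface
        pts = make_grid(geoms, resolution=0.5)
        surf = KrigedSurface(x=pts[:, 0], y=pts[:, 1],
                             values=np.full(len(pts), 1.0),
                             variances=np.zeros(len(pts)))
        spatial.classify_surface(surf, null=1.0, tolerance=0.05)
        assert set(surf.classes) == {"near"}
        spatial.render_map(surf, geoms, tmp_path / "const.png",
                           contour_levels=[0.8, 1.2])
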