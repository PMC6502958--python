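"""Tests for the copula simulation, Doornik-Hansen test and ellipse geometry."""

import numpy as np
import pandas as pd
import pytest

import pupilrqa as pq
from pupilrqa.exceptions import DegenerateInputError, DomainError
from pupilrqa.population_stats import nearest_psd


@pytest.fixture(scope="module")
def observed():
    return pq.load_observed_cohort()


@pytest.fixture(scope="module")
def simulated():
    return pq.load_simulated_cohort()


@pytest.fixture(scope="module")
def sim_points(simulated):
    return np.column_stack([simulated["entropy"],
                            simulated["det_pct"] / 100.0])


class TestCorrelation:
    def test_symmetric_unit_diagonal(self, observed):
        C = pq.correlation_matrix(observed)
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert (C.abs() <= 1.0 + 1e-12).all().all()

    def test_perfect_linearity(self):
        df = pd.DataFrame({
            "age": [20, 30, 40, 50], "ess": [1, 3, 5, 7],
            "entropy": [0.8, 0.9, 1.0, 1.1], "det_pct": [30, 40, 50, 60],
            "pct_change": [0.1, 0.2, 0.3, 0.4]})
        C = pq.correlation_matrix(df)
        # every column here is a perfect affine image of every other
        np.testing.assert_allclose(C.to_numpy(), 1.0, atol=1e-12)

    def test_zero_variance_column_fails(self, observed):
        df = observed.copy()
        df["ess"] = 5
        with pytest.raises(DegenerateInputError):
            pq.correlation_matrix(df)


class TestCopula:
    def test_seed_reproducibility(self, observed):
        a = pq.gaussian_copula_sample(observed, 50, seed=7)
        b = pq.gaussian_copula_sample(observed, 50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_large_sample_preserves_ent_det_correlation(self, observed):
        sim = pq.gaussian_copula_sample(observed, 2000, seed=1)
        r_obs = observed["entropy"].corr(observed["det_pct"])
        r_sim = sim["entropy"].corr(sim["det_pct"])
        assert abs(r_sim - r_obs) < 0.10

    def test_margins_within_observed_range(self, observed):
        sim = pq.gaussian_copula_sample(observed, 500, seed=2)
        for col in ("entropy", "det_pct", "pct_change"):
            assert sim[col].min() >= observed[col].min() - 1e-12
            assert sim[col].max() <= observed[col].max() + 1e-12

    def test_integer_margins_rounded(self, observed):
        sim = pq.gaussian_copula_sample(observed, 100, seed=3)
        assert sim["age"].dtype.kind == "i"
        assert sim["ess"].dtype.kind == "i"

    def test_quantile_convergence(self, observed):
        """Simulated column quantiles converge to observed quantiles."""
        sim = pq.gaussian_copula_sample(observed, 20000, seed=4)
        for q in (0.25, 0.5, 0.75):
            assert sim["entropy"].quantile(q) == pytest.approx(
                observed["entropy"].quantile(q), abs=0.03)

    def test_nearest_psd_repair(self):
        C = np.array([[1.0, 0.99, -0.99],
                      [0.99, 1.0, 0.99],
                      [-0.99, 0.99, 1.0]])  # indefinite
        fixed = nearest_psd(C)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0)


class TestDoornikHansen:
    def test_degrees_of_freedom_definition(self):
        # bivariate input -> chi-square with 4 df: the statistic of an
        # enormous normal sample has survival probability ~ chi2(4)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4000, 2))
        stat, p = pq.doornik_hansen(X)
        from scipy import stats as ss
        assert p == pytest.approx(ss.chi2.sf(stat, 4))

    def test_affine_invariance(self, sim_points):
        stat1, _ = pq.doornik_hansen(sim_points)
        rescaled = sim_points * np.array([3.0, 100.0]) + np.array([-1.0, 5.0])
        stat2, _ = pq.doornik_hansen(rescaled)
        assert stat1 == pytest.approx(stat2, rel=1e-9)

    def test_rejects_gross_nonnormality(self, rng):
        X = rng.exponential(size=(200, 2)) ** 2
        stat, p = pq.doornik_hansen(X)
        assert p < 0.001

    def test_type_i_error_calibration(self):
        """~5% rejections at alpha = 0.05 for bivariate normal samples."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            X = rng.normal(size=(100, 2))
            _, p = pq.doornik_hansen(X)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_too_few_rows_fails(self):
        with pytest.raises(DegenerateInputError):
            pq.doornik_hansen(np.random.default_rng(0).normal(size=(6, 2)))


class TestPredictionEllipse:
    def test_isotropic_covariance_gives_circle(self, rng):
        # rotationally symmetric cloud: lambda1 ~ lambda2
        X = rng.normal(size=(20000, 2))
        ell = pq.prediction_ellipse(X)
        assert ell.eccentricity < 0.25

    def test_shift_equivariance(self, sim_points):
        e0 = pq.prediction_ellipse(sim_points)
        e1 = pq.prediction_ellipse(sim_points + np.array([2.0, -1.0]))
        assert e1.center[0] == pytest.approx(e0.center[0] + 2.0)
        assert e1.center[1] == pytest.approx(e0.center[1] - 1.0)
        assert e1.a_x == pytest.approx(e0.a_x)
        assert e1.a_y == pytest.approx(e0.a_y)
        assert e1.theta == pytest.approx(e0.theta)

    def test_column_swap_reflects_orientation(self, sim_points):
        e0 = pq.prediction_ellipse(sim_points)
        e1 = pq.prediction_ellipse(sim_points[:, ::-1])
        assert e1.a_x == pytest.approx(e0.a_x)
        assert e1.a_y == pytest.approx(e0.a_y)
        # swapping axes maps theta -> pi/2 - theta
        assert e1.theta == pytest.approx(np.pi / 2 - e0.theta, abs=1e-9)

    def test_coverage_simulation(self, sim_points, rng):
        """~95% of draws from the fitted normal fall inside the ellipse."""
        ell = pq.prediction_ellipse(sim_points, alpha=0.05)
        mean = sim_points.mean(axis=0)
        cov = np.cov(sim_points.T)
        draws = rng.multivariate_normal(mean, cov, size=10000)
        frac = np.mean(pq.contains(ell, draws))
        assert abs(frac - 0.95) < 0.01

    def test_degenerate_covariance_fails(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateInputError):
            pq.prediction_ellipse(X)


@pytest.fixture(scope="module")
def ellipse():
    return pq.PredictionEllipse(center=(0.9, 0.44), a_x=0.53, a_y=0.2,
                                theta=0.69, alpha=0.05)


class TestContourAndContains:

    def test_t_zero_point(self, ellipse):
        pt = pq.ellipse_contour(ellipse, np.array([0.0]))[0]
        sx = ellipse.a_x / 2
        assert pt[0] == pytest.approx(0.9 + sx * np.cos(0.69))
        assert pt[1] == pytest.approx(0.44 + sx * np.sin(0.69))

    def test_contour_satisfies_quadratic_form(self, ellipse):
        pts = pq.ellipse_contour(ellipse)
        c, s = np.cos(ellipse.theta), np.sin(ellipse.theta)
        u = (pts[:, 0] - 0.9) * c + (pts[:, 1] - 0.44) * s
        v = -(pts[:, 0] - 0.9) * s + (pts[:, 1] - 0.44) * c
        q = (u / (ellipse.a_x / 2)) ** 2 + (v / (ellipse.a_y / 2)) ** 2
        np.testing.assert_allclose(q, 1.0, atol=1e-10)

    def test_antipodal_symmetry(self, ellipse):
        t = np.array([0.3, 0.3 + np.pi])
        pts = pq.ellipse_contour(ellipse, t)
        mid = pts.mean(axis=0)
        np.testing.assert_allclose(mid, [0.9, 0.44], atol=1e-12)

    def test_center_inside_contour_on_boundary_far_point_outside(self,
                                                                 ellipse):
        assert pq.contains(ellipse, np.array([0.9, 0.44]))
        boundary = pq.ellipse_contour(ellipse, np.array([1.2345]))[0]
        assert pq.contains(ellipse, boundary)
        far = np.array([0.9 + 10 * ellipse.a_x * np.cos(0.69),
                        0.44 + 10 * ellipse.a_x * np.sin(0.69)])
        assert not pq.contains(ellipse, far)

    def test_eccentricity_and_area(self, ellipse):
        assert ellipse.eccentricity == pytest.approx(
            np.sqrt(1 - (0.2 / 0.53) ** 2))
        assert ellipse.area == pytest.approx(np.pi * 0.265 * 0.1)


class TestNormativeIntervals:
    def test_tangent_bin_is_degenerate(self, sim_points):
        ell = pq.prediction_ellipse(sim_points)
        contour = pq.ellipse_contour(ell, np.linspace(0, 2 * np.pi, 400001))
        x_max = contour[:, 0].max()
        # a narrow bin hugging the rightmost x gives a collapsed interval
        tab = pq.normative_intervals(ell, ent_bin_width=1e-4)
        last = tab.iloc[-1]
        assert last["ent_hi"] >= x_max - 1e-4
        assert last["det_max"] - last["det_min"] <= 3

    def test_bins_outside_extent_omitted(self, sim_points):
        ell = pq.prediction_ellipse(sim_points)
        tab = pq.normative_intervals(ell, 0.05)
        contour = pq.ellipse_contour(ell)
        assert tab["ent_hi"].iloc[0] >= contour[:, 0].min()
        assert tab["ent_lo"].iloc[-1] <= contour[:, 0].max()
        assert (tab["det_max"] >= tab["det_min"]).all()
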