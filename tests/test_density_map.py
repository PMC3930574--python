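import numpy as np
import pytest

from dysphonia import (
    LABEL_CO,
    LABEL_PD,
    density,
    fit_kde,
    log_density,
    pd_posterior,
    posterior,
    select_bandwidth,
)
from dysphonia.density_map import KDEModel, posterior_batch
from scipy.special import logsumexp


def _two_cluster(seed=0, n=40, sep=4.0):
    rng = np.random.default_rng(seed)
    z = np.vstack([rng.normal(0, 1, (n // 2, 2)), rng.normal(sep, 1, (n - n // 2, 2))])
    labels = np.array([LABEL_CO] * (n // 2) + [LABEL_PD] * (n - n // 2))
    return z, labels


def _single_center_model(center_co, center_pd, var=(1.0, 2.0), h=0.5,
                         priors=(0.5, 0.5)):
    return KDEModel(
        class_centers={LABEL_CO: np.atleast_2d(center_co),
                       LABEL_PD: np.atleast_2d(center_pd)},
        variances=np.array(var), h=h,
        priors={LABEL_CO: priors[0], LABEL_PD: priors[1]})


class TestDensity:
    def test_peak_closed_form(self):
        h, s1, s2 = 0.5, 1.0, 2.0
        model = _single_center_model([0.0, 0.0], [10.0, 10.0], var=(s1**2, s2**2), h=h)
        got = density(model, LABEL_CO, np.array([0.0, 0.0]))
        assert got == pytest.approx(1.0 / (2 * np.pi * h * s1 * s2))

    def test_quadrature_normalization(self):
        z, labels = _two_cluster(1)
        model = fit_kde(z, labels, h=0.3)
        sig = np.sqrt(model.h * model.variances)
        for lab in (LABEL_CO, LABEL_PD):
            centers = model.class_centers[lab]
            lo = centers.min(axis=0) - 8 * sig
            hi = centers.max(axis=0) + 8 * sig
            gx = np.linspace(lo[0], hi[0], 400)
            gy = np.linspace(lo[1], hi[1], 400)
            GX, GY = np.meshgrid(gx, gy, indexing="ij")
            vals = density(model, lab, np.column_stack([GX.ravel(), GY.ravel()]))
            integral = np.trapezoid(np.trapezoid(vals.reshape(400, 400), gy, axis=1), gx)
            assert integral == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_point_between_two_centers(self):
        model = KDEModel(
            class_centers={LABEL_CO: np.array([[-1.0, 0.0], [1.0, 0.0]]),
                           LABEL_PD: np.array([[50.0, 50.0]])},
            variances=np.array([1.0, 1.0]), h=0.5,
            priors={LABEL_CO: 0.5, LABEL_PD: 0.5})
        # on the axis of symmetry the mixture equals either single-center bump
        single = _single_center_model([-1.0, 0.0], [50.0, 50.0], var=(1.0, 1.0), h=0.5)
        z = np.array([0.0, 3.0])
        assert density(model, LABEL_CO, z) == pytest.approx(
            density(single, LABEL_CO, z), rel=1e-12)

    def test_strictly_positive_far_away(self):
        z, labels = _two_cluster(2)
        model = fit_kde(z, labels, h=0.2)
        assert np.isfinite(log_density(model, LABEL_PD, np.array([100.0, -100.0])))


class TestFitKDE:
    def test_empirical_priors_from_imbalanced_classes(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(195, 2))
        labels = np.array([LABEL_CO] * 48 + [LABEL_PD] * 147)
        model = fit_kde(z, labels, h=0.5, priors="empirical")
        assert model.priors[LABEL_PD] == pytest.approx(147 / 195)

    def test_equal_priors(self):
        z, labels = _two_cluster(4)
        model = fit_kde(z, labels, h=0.5, priors="equal")
        assert model.priors == {LABEL_CO: 0.5, LABEL_PD: 0.5}

    def test_covariance_monotone_in_h(self):
        z, labels = _two_cluster(5)
        det_lo = np.linalg.det(fit_kde(z, labels, h=0.01).covariance)
        det_hi = np.linalg.det(fit_kde(z, labels, h=1.0).covariance)
        assert det_lo < det_hi

    def test_zero_variance_component_errors(self):
        z = np.column_stack([np.arange(10.0), np.ones(10)])
        labels = np.array([LABEL_CO] * 5 + [LABEL_PD] * 5)
        with pytest.raises(ValueError):
            fit_kde(z, labels, h=0.5)

    def test_h_out_of_range(self):
        z, labels = _two_cluster(6)
        with pytest.raises(ValueError):
            fit_kde(z, labels, h=1.5)


class TestPosterior:
    def test_equidistant_tie_goes_to_pd(self):
        model = _single_center_model([-1.0, 0.0], [1.0, 0.0], var=(1.0, 1.0))
        res = posterior(model, np.array([0.0, 0.0]))
        assert res.posteriors[LABEL_PD] == pytest.approx(0.5, abs=1e-12)
        assert res.predicted == LABEL_PD

    def test_degenerate_prior(self):
        model = _single_center_model([-1.0, 0.0], [1.0, 0.0], priors=(1e-300, 1.0 - 1e-300))
        res = posterior(model, np.array([-5.0, 0.0]))
        assert res.posteriors[LABEL_PD] == pytest.approx(1.0, abs=1e-6)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(7)
        z, labels = _two_cluster(7, n=30)
        model = fit_kde(z, labels, h=0.4)
        for pt in rng.normal(0, 5, size=(20, 2)):
            res = posterior(model, pt)
            assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_prior(self):
        z, labels = _two_cluster(8)
        pt = np.array([1.0, 1.0])
        posts = []
        for p_pd in (0.1, 0.3, 0.5, 0.7, 0.9):
            model = fit_kde(z, labels, h=0.5, priors={LABEL_CO: 1 - p_pd, LABEL_PD: p_pd})
            posts.append(posterior(model, pt).posteriors[LABEL_PD])
        assert all(b > a for a, b in zip(posts, posts[1:]))

    def test_underflow_falls_back_to_priors(self):
        model = _single_center_model([0.0, 0.0], [1.0, 0.0], var=(1e-6, 1e-6), h=0.01,
                                     priors=(0.25, 0.75))
        res = posterior(model, np.array([1e200, 1e200]))
        assert res.underflow
        assert res.predicted == LABEL_PD
        assert res.posteriors[LABEL_PD] == pytest.approx(0.75)

    def test_map_decision_boundary_balances_weighted_densities(self):
        """Along random rays, the bisection-found boundary satisfies
        p(z|PD)P(PD) = p(z|CO)P(CO)."""
        z, labels = _two_cluster(9)
        model = fit_kde(z, labels, h=0.3)
        rng = np.random.default_rng(10)
        a = np.array([0.0, 0.0])  # inside CO cluster
        b = np.array([4.0, 4.0])  # inside PD cluster

        def g(t):
            pt = a + t * (b - a) + offset
            return pd_posterior(model, pt[None, :])[0] - 0.5

        found = 0
        for _ in range(5):
            offset = rng.normal(0, 0.3, 2)
            lo, hi = 0.0, 1.0
            if g(lo) * g(hi) > 0:
                continue
            for _ in range(60):
                mid = (lo + hi) / 2
                (lo, hi) = (mid, hi) if g(lo) * g(mid) > 0 else (lo, mid)
            pt = a + lo * (b - a) + offset
            lhs = density(model, LABEL_PD, pt) * model.priors[LABEL_PD]
            rhs = density(model, LABEL_CO, pt) * model.priors[LABEL_CO]
            assert lhs == pytest.approx(rhs, rel=1e-6)
            found += 1
        assert found >= 3


class TestBandwidthSelection:
    def test_singleton_grid(self):
        z, labels = _two_cluster(11)
        res = select_bandwidth(z, labels, grid=np.array([0.37]))
        assert res.h == 0.37
        assert len(res.trace) == 1

    def test_trace_length_matches_grid(self):
        z, labels = _two_cluster(12)
        grid = np.arange(0.1, 1.01, 0.1)
        res = select_bandwidth(z, labels, grid=grid)
        assert len(res.trace) == len(grid)

    def test_tight_clusters_prefer_small_h(self):
        rng = np.random.default_rng(13)
        z = np.vstack([rng.normal(0, 0.05, (30, 2)), rng.normal(5, 0.05, (30, 2))])
        labels = np.array([LABEL_CO] * 30 + [LABEL_PD] * 30)
        res = select_bandwidth(z, labels)
        assert res.h < 1.0  # strictly below the grid maximum

    def test_matches_naive_loo_oracle(self):
        """Brute-force leave-one-out loop reproduces the vectorized criterion."""
        z, labels = _two_cluster(14, n=16)
        grid = np.array([0.2, 0.5, 0.9])
        res = select_bandwidth(z, labels, grid=grid)
        variances = z.var(axis=0, ddof=1)
        oracle = []
        for h in grid:
            var = h * variances
            ll = 0.0
            for lab in (LABEL_CO, LABEL_PD):
                Zw = z[labels == lab]
                for i in range(len(Zw)):
                    rest = np.delete(Zw, i, axis=0)
                    d2 = ((Zw[i] - rest) ** 2 / var).sum(axis=1)
                    ll += logsumexp(-0.5 * d2) - np.log(len(rest)) \
                        - np.log(2 * np.pi) - 0.5 * np.log(var).sum()
            oracle.append(ll)
        for (h, got), want in zip(res.trace, oracle):
            assert got == pytest.approx(want, rel=1e-10)
        assert res.h == grid[int(np.argmax(oracle))]

    def test_invalid_grid(self):
        z, labels = _two_cluster(15)
        with pytest.raises(ValueError):
            select_bandwidth(z, labels, grid=np.array([]))
        with pytest.raises(ValueError):
            select_bandwidth(z, labels, grid=np.array([0.0, 0.5]))
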