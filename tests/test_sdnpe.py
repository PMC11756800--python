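"""SD-NPE: regressor, lattice arithmetic, and the conjugate Bayes oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from patternfit.sdnpe import (LINREG_LATTICE, TURING_LATTICE,
                              NaturalGradientBoostingMVN, ParameterLattice,
                              RegressorSpec, SamplePosterior,
                              analytic_linreg_posterior, estimate_prior,
                              generalization_error, hpd_region_contains,
                              integrate_posteriors, lattice_kl,
                              predict_sample_posterior, simulate_linreg,
                              train_regressor)

FAST_SPEC = RegressorSpec(n_estimators=40)


@pytest.fixture(scope="module")
def noisy_identity_regressor():
    """Features that perfectly encode the labels, up to tiny noise."""
    rng = np.random.default_rng(0)
    y = rng.uniform(0.6, 1.0, size=(800, 2))
    X = y + rng.normal(0, 1e-2, size=y.shape)
    reg = train_regressor(X[:700], y[:700], spec=RegressorSpec(), seed=0)
    return reg, X, y


class TestRegressor:
    def test_near_noiseless_recovery(self, noisy_identity_regressor):
        reg, X, y = noisy_identity_regressor
        posts = reg.predict_posteriors(X[700:])
        mu = np.array([p.mean for p in posts])
        rmse = float(np.sqrt(np.mean((mu - y[700:]) ** 2)))
        assert rmse < 0.02  # close to the 0.01 feature noise floor

    def test_constant_labels_with_jitter(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2))
        y = 0.8 + rng.normal(0, 1e-3, size=(200, 2))
        reg = train_regressor(X[:150], y[:150], spec=FAST_SPEC, seed=0)
        mu = np.array([p.mean for p in reg.predict_posteriors(X[150:])])
        assert np.max(np.abs(mu - 0.8)) < 0.01

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 2))
        y = X + rng.normal(0, 0.1, size=X.shape)
        r1 = train_regressor(X, y, spec=FAST_SPEC, seed=5)
        r2 = train_regressor(X, y, spec=FAST_SPEC, seed=5)
        assert np.array_equal(r1.predict_theta(X), r2.predict_theta(X))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            train_regressor(np.zeros((10, 2)), np.zeros((10, 2)))

    def test_degenerate_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(100, 2))
        y = np.column_stack([np.ones(100), X[:, 0]])
        with pytest.raises(ValueError):
            train_regressor(X, y)

    def test_covariances_spd(self, noisy_identity_regressor):
        reg, X, _ = noisy_identity_regressor
        for p in reg.predict_posteriors(X[:20]):
            np.linalg.cholesky(p.cov)  # raises if not SPD


class TestSamplePosterior:
    def test_density_integrates_to_one(self):
        p = SamplePosterior([0.8, 0.8], 0.0004 * np.eye(2))
        mass = p.density_on(TURING_LATTICE).sum() * TURING_LATTICE.cell_area
        assert mass == pytest.approx(1.0, abs=0.02)

    def test_density_max_at_mean_cell(self):
        p = SamplePosterior([0.77, 0.93], np.diag([4e-4, 9e-4]))
        dens = p.density_on(TURING_LATTICE)
        i, j = np.unravel_index(np.argmax(dens), dens.shape)
        ax0, ax1 = TURING_LATTICE.axes
        assert abs(ax0[i] - 0.77) <= TURING_LATTICE.cell
        assert abs(ax1[j] - 0.93) <= TURING_LATTICE.cell

    def test_half_cell_origin_shift_robust(self):
        p = SamplePosterior([0.8, 0.8], 0.0004 * np.eye(2))
        shifted = ParameterLattice(origin=(0.55 + 0.0025, 0.55 + 0.0025),
                                   n=(100, 100), cell=0.005)
        m1 = p.density_on(TURING_LATTICE).max()
        m2 = p.density_on(shifted).max()
        assert abs(m1 - m2) / m1 < 0.05

    def test_non_spd_repaired(self):
        bad = np.array([[1e-4, 5e-4], [5e-4, 1e-4]])  # indefinite
        p = SamplePosterior([0.8, 0.8], bad)
        np.linalg.cholesky(p.cov)


class TestPrior:
    def test_identical_posteriors_average_to_themselves(self):
        class Fixed:
            def predict_theta(self, X):
                return np.tile([0.8, 0.8, np.log(0.02), np.log(0.02), 0.0],
                               (len(X), 1))
        prior = estimate_prior(Fixed(), np.zeros((7, 2)), TURING_LATTICE)
        single = TURING_LATTICE.normalize(
            SamplePosterior([0.8, 0.8], 4e-4 * np.eye(2)).density_on(
                TURING_LATTICE))
        assert np.max(np.abs(prior - single)) < 1e-9 * single.max()

    def test_two_modes_half_weight(self):
        class TwoModes:
            def predict_theta(self, X):
                t = np.tile([0.7, 0.7, np.log(0.01), np.log(0.01), 0.0],
                            (len(X), 1))
                t[len(X) // 2:, 0] = t[len(X) // 2:, 1] = 0.9
                return t
        prior = estimate_prior(TwoModes(), np.zeros((10, 2)), TURING_LATTICE)
        v1 = TURING_LATTICE.interpolate(prior, (0.7, 0.7))
        v2 = TURING_LATTICE.interpolate(prior, (0.9, 0.9))
        assert v1 == pytest.approx(v2, rel=1e-6)

    def test_uniform_labels_give_near_uniform_prior(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0.6, 1.0, size=(3000, 2))
        X = y + rng.normal(0, 1e-2, size=y.shape)
        reg = train_regressor(X, y, spec=RegressorSpec(n_estimators=80), seed=0)
        prior = estimate_prior(reg, X, TURING_LATTICE)
        box = ParameterLattice(origin=(0.6, 0.6), n=(80, 80), cell=0.005)
        uniform_mass = 1.0 / (0.4 * 0.4)
        # total-variation distance to uniform, on the box interior
        inner = prior[10:90, 10:90]
        tv = 0.5 * np.sum(np.abs(inner - uniform_mass)) \
            * TURING_LATTICE.cell_area
        assert tv < 0.15


def random_posterior(rng, scale=0.03):
    mean = rng.uniform(0.65, 0.95, size=2)
    L = np.array([[rng.uniform(0.5, 1.5) * scale, 0],
                  [rng.uniform(-0.5, 0.5) * scale,
                   rng.uniform(0.5, 1.5) * scale]])
    return SamplePosterior(mean, L @ L.T)


class TestIntegration:
    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(hst.integers(0, 2**31 - 1))
    def test_single_posterior_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = random_posterior(rng)
        uniform = TURING_LATTICE.normalize(np.ones(TURING_LATTICE.shape))
        out = integrate_posteriors([p], uniform, TURING_LATTICE)
        ref = TURING_LATTICE.normalize(p.density_on(TURING_LATTICE))
        assert np.max(np.abs(out - ref)) < 1e-9 * ref.max()

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(hst.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        posts = [random_posterior(rng) for _ in range(4)]
        prior = TURING_LATTICE.normalize(np.ones(TURING_LATTICE.shape))
        a = integrate_posteriors(posts, prior, TURING_LATTICE)
        b = integrate_posteriors(posts[::-1], prior, TURING_LATTICE)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("n", [1, 2, 5, 10])
    def test_matches_gaussian_product_closed_form(self, n):
        # uniform prior + exactly-normal sample posteriors: the integrated
        # posterior is the normalized product of the Gaussians
        rng = np.random.default_rng(n)
        posts = [random_posterior(rng, scale=0.05) for _ in range(n)]
        prior = TURING_LATTICE.normalize(np.ones(TURING_LATTICE.shape))
        out = integrate_posteriors(posts, prior, TURING_LATTICE)
        prec = sum(np.linalg.inv(p.cov) for p in posts)
        cov = np.linalg.inv(prec)
        mean = cov @ sum(np.linalg.inv(p.cov) @ p.mean for p in posts)
        ref = TURING_LATTICE.normalize(
            SamplePosterior(mean, cov).density_on(TURING_LATTICE))
        assert lattice_kl(ref, out, TURING_LATTICE) < 1e-3

    def test_normalization_invariant(self):
        rng = np.random.default_rng(9)
        posts = [random_posterior(rng) for _ in range(6)]
        prior = TURING_LATTICE.normalize(np.ones(TURING_LATTICE.shape))
        out = integrate_posteriors(posts, prior, TURING_LATTICE)
        assert out.sum() * TURING_LATTICE.cell_area == pytest.approx(1.0,
                                                                     abs=1e-9)

    def test_empty_list_rejected(self):
        prior = TURING_LATTICE.normalize(np.ones(TURING_LATTICE.shape))
        with pytest.raises(ValueError):
            integrate_posteriors([], prior, TURING_LATTICE)


class TestGeneralizationError:
    def test_uniform_density_value(self):
        lat = ParameterLattice(origin=(0.0, 0.0), n=(50, 50), cell=0.01)
        uniform = lat.normalize(np.ones(lat.shape))  # area 0.25 -> density 4
        err = generalization_error([uniform, uniform],
                                   [(0.2, 0.3), (0.4, 0.1)], lat)
        assert err == pytest.approx(-np.log(4.0), abs=1e-9)

    def test_sharper_posterior_scores_better(self):
        truth = (0.8, 0.8)
        sharp = TURING_LATTICE.normalize(
            SamplePosterior(truth, 1e-4 * np.eye(2)).density_on(TURING_LATTICE))
        flat = TURING_LATTICE.normalize(
            SamplePosterior(truth, 1e-2 * np.eye(2)).density_on(TURING_LATTICE))
        assert generalization_error([sharp], [truth]) \
            < generalization_error([flat], [truth])

    def test_truth_outside_lattice_rejected(self):
        uniform = TURING_LATTICE.normalize(np.ones(TURING_LATTICE.shape))
        with pytest.raises(ValueError):
            generalization_error([uniform], [(2.0, 2.0)])


class TestHPD:
    def test_mean_inside_tail_outside(self):
        p = SamplePosterior([0.8, 0.8], 1e-4 * np.eye(2))
        dens = TURING_LATTICE.normalize(p.density_on(TURING_LATTICE))
        assert hpd_region_contains(dens, TURING_LATTICE, (0.8, 0.8), 0.95)
        assert not hpd_region_contains(dens, TURING_LATTICE, (0.6, 0.99), 0.95)


class TestAnalyticOracle:
    def test_no_data_returns_prior(self):
        post = analytic_linreg_posterior(np.zeros((0, 2)), np.zeros(0), 0.1,
                                         prior_mean=[0.2, -0.1],
                                         prior_cov=0.3 * np.eye(2))
        assert np.allclose(post.mean, [0.2, -0.1])
        assert np.allclose(post.cov, 0.3 * np.eye(2))

    def test_near_interpolation_limit(self):
        # one observation y = a*x at x=1 with tiny noise pins the weight
        post = analytic_linreg_posterior(np.array([[1.0, 0.0]]),
                                         np.array([0.737]), 1e-4,
                                         prior_mean=[0.0, 0.0],
                                         prior_cov=np.eye(2))
        assert abs(post.mean[0] - 0.737) < 1e-3

    def test_precision_additivity_under_flat_prior(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = X @ np.array([0.5, -0.2]) + rng.normal(0, 0.1, 30)
        once = analytic_linreg_posterior(X, y, 0.1)
        twice = analytic_linreg_posterior(np.vstack([X, X]),
                                          np.concatenate([y, y]), 0.1)
        assert np.allclose(twice.cov, once.cov / 2.0, rtol=1e-6)

    def test_singular_design_flat_prior_rejected(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(np.linalg.LinAlgError):
            analytic_linreg_posterior(X, np.array([1.0, 2.0]), 0.1)


class TestLinregValidationHarness:
    def test_simple_condition_scaled_down(self):
        from patternfit.sdnpe import run_linreg_validation
        res = run_linreg_validation("simple", train_size=4000, seed=0,
                                    n_obs=10, n_cases=8, spec=FAST_SPEC)
        assert res["median_kl"] < 1.5  # scaled-down smoke bound
        assert np.all(np.isfinite(res["kls"]))

    def test_simulated_observations_match_condition(self):
        rng = np.random.default_rng(0)
        feats, labels = simulate_linreg("redundant", 500, rng)
        # y depends on the weights only through their sum
        resid = feats[:, 1] - (labels[:, 0] + labels[:, 1]) * feats[:, 0]
        assert np.std(resid) < 0.12
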