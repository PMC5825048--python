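import numpy as np
import pytest
from scipy.stats import multivariate_normal

from swayblocks.cop_data import Condition
from swayblocks.exceptions import InsufficientDataError, StateError, ValidationError
from swayblocks.gmm_em import (
    GMMModel,
    Responsibilities,
    e_step,
    fit_gmm,
    gaussian_logpdf,
    label_ub_cluster,
    log_likelihood,
    m_step,
    model_from_dict,
    model_to_dict,
)


def random_model(rng, d=3):
    w = rng.uniform(0.2, 0.8)
    means = rng.normal(scale=3, size=(2, d))
    covs = np.empty((2, d, d))
    for i in range(2):
        a = rng.normal(size=(d, d))
        covs[i] = a @ a.T + 0.5 * np.eye(d)
    return GMMModel(weights=[w, 1 - w], means=means, covariances=covs)


def sample_mixture(rng, weights, means, covs, n):
    comp = rng.choice(2, size=n, p=weights)
    Z = np.empty((n, means.shape[1]))
    for i in range(2):
        idx = comp == i
        Z[idx] = rng.multivariate_normal(means[i], covs[i], size=idx.sum())
    return Z


class TestGaussianLogpdf:
    def test_value_at_mean_identity_cov(self):
        val = gaussian_logpdf(np.zeros(3), np.zeros(3), np.eye(3))
        assert val == pytest.approx(-1.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = random_model(rng)
            z = rng.normal(size=(5, 3))
            for i in range(2):
                ref = multivariate_normal.logpdf(z, m.means[i], m.covariances[i])
                np.testing.assert_allclose(
                    gaussian_logpdf(z, m.means[i], m.covariances[i]), ref, atol=1e-10
                )

    def test_symmetric_about_mean(self):
        rng = np.random.default_rng(1)
        m = random_model(rng)
        z = rng.normal(size=3)
        mu, sig = m.means[0], m.covariances[0]
        assert gaussian_logpdf(z, mu, sig) == pytest.approx(
            gaussian_logpdf(2 * mu - z, mu, sig), abs=1e-10
        )

    def test_monte_carlo_normalization(self):
        # importance-sample the density against a wider proposal
        rng = np.random.default_rng(2)
        mu = np.array([0.5, -1.0, 0.2])
        sig = np.diag([1.0, 0.5, 2.0])
        prop_cov = 4 * np.eye(3)
        pts = rng.multivariate_normal(mu, prop_cov, size=200_000)
        log_q = multivariate_normal.logpdf(pts, mu, prop_cov)
        log_p = gaussian_logpdf(pts, mu, sig)
        integral = np.exp(log_p - log_q).mean()
        assert integral == pytest.approx(1.0, rel=0.01)


class TestEStep:
    def test_midpoint_of_equal_components_is_half(self):
        model = GMMModel(
            weights=[0.5, 0.5],
            means=[[-1, 0, 0], [1, 0, 0]],
            covariances=[np.eye(3), np.eye(3)],
        )
        resp = e_step(model, np.zeros((1, 3)))
        np.testing.assert_allclose(resp.p[0], [0.5, 0.5], atol=1e-12)

    def test_identical_components_follow_prior(self):
        eps = 0.01
        model = GMMModel(
            weights=[1 - eps, eps],
            means=[[0, 0, 0], [0, 0, 0]],
            covariances=[np.eye(3), np.eye(3)],
        )
        resp = e_step(model, np.random.default_rng(0).normal(size=(10, 3)))
        np.testing.assert_allclose(resp.p[:, 1], eps, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        model = random_model(rng)
        resp = e_step(model, rng.normal(size=(50, 3)))
        np.testing.assert_allclose(resp.p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((resp.p >= 0) & (resp.p <= 1))

    def test_agrees_with_naive_density_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            model = random_model(rng)
            Z = rng.normal(scale=2, size=(8, 3))
            dens = np.column_stack(
                [
                    model.weights[i]
                    * multivariate_normal.pdf(Z, model.means[i], model.covariances[i])
                    for i in range(2)
                ]
            )
            expected = dens / dens.sum(axis=1, keepdims=True)
            np.testing.assert_allclose(e_step(model, Z).p, expected, atol=1e-8)

    def test_extreme_outlier_does_not_underflow(self):
        model = GMMModel(
            weights=[0.5, 0.5],
            means=[[0, 0, 0], [1, 1, 1]],
            covariances=[np.eye(3), np.eye(3)],
        )
        resp = e_step(model, np.full((1, 3), 1e4))
        np.testing.assert_allclose(resp.p.sum(axis=1), 1.0)
        assert np.all(np.isfinite(resp.p))


class TestMStep:
    def test_hard_responsibilities_recover_cluster_stats(self):
        Z = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 1.0],
                [0.0, 1.0, 2.0],
                [10.0, 10.0, 10.0],
                [11.0, 12.0, 10.0],
                [12.0, 11.0, 13.0],
            ]
        )
        hard = np.zeros((6, 2))
        hard[:3, 0] = 1.0
        hard[3:, 1] = 1.0
        w, mu, cov = m_step(Z, Responsibilities(hard), reg=1e-6)
        np.testing.assert_allclose(w, [0.5, 0.5])
        for i, sel in enumerate((Z[:3], Z[3:])):
            np.testing.assert_allclose(mu[i], sel.mean(axis=0), atol=1e-12)
            expected = np.cov(sel.T, ddof=0) + 1e-6 * np.eye(3)
            np.testing.assert_allclose(cov[i], expected, atol=1e-12)

    def test_uniform_responsibilities_give_global_mean(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(30, 3))
        w, mu, _ = m_step(Z, Responsibilities(np.full((30, 2), 0.5)))
        np.testing.assert_allclose(mu[0], Z.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(mu[1], Z.mean(axis=0), atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-15)

    def test_empty_component_without_rng_raises(self):
        Z = np.random.default_rng(6).normal(size=(10, 3))
        resp = np.zeros((10, 2))
        resp[:, 0] = 1.0
        with pytest.raises(ValidationError):
            m_step(Z, Responsibilities(resp))

    def test_empty_component_reseeded_with_rng(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(10, 3))
        resp = np.zeros((10, 2))
        resp[:, 0] = 1.0
        w, mu, cov = m_step(Z, Responsibilities(resp), rng=rng)
        assert w.sum() == pytest.approx(1.0)
        assert any(np.allclose(mu[1], z) for z in Z)


class TestFitGmm:
    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gmm(np.zeros((5, 3)), seed=0)

    def test_recovers_well_separated_mixture(self):
        rng = np.random.default_rng(8)
        means = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        covs = np.stack([np.eye(3), np.eye(3)])
        weights = np.array([0.65, 0.35])
        Z = sample_mixture(rng, weights, means, covs, 2000)
        model = fit_gmm(Z, seed=1)
        order = np.argsort(model.means[:, 0])
        np.testing.assert_allclose(model.means[order], means, atol=0.1)
        np.testing.assert_allclose(model.weights[order], weights, atol=0.05)
        assert model.converged

    def test_loglik_non_decreasing_every_run(self):
        rng = np.random.default_rng(9)
        Z = sample_mixture(
            rng,
            np.array([0.5, 0.5]),
            np.array([[0, 0, 0], [4, 4, 4]], dtype=float),
            np.stack([np.eye(3), np.eye(3)]),
            400,
        )
        model = fit_gmm(Z, n_init=5, seed=2, track_history=True)
        for history in model.ll_histories:
            assert np.all(np.diff(history) >= -1e-10)

    def test_duplicating_every_point_doubles_loglik_only(self):
        rng = np.random.default_rng(10)
        Z = sample_mixture(
            rng,
            np.array([0.5, 0.5]),
            np.array([[0, 0, 0], [8, 8, 8]], dtype=float),
            np.stack([np.eye(3), np.eye(3)]),
            300,
        )
        m1 = fit_gmm(Z, seed=3)
        m2 = fit_gmm(np.vstack([Z, Z]), seed=3)
        order1 = np.argsort(m1.means[:, 0])
        order2 = np.argsort(m2.means[:, 0])
        np.testing.assert_allclose(
            m1.means[order1], m2.means[order2], atol=1e-3
        )
        np.testing.assert_allclose(m1.weights[order1], m2.weights[order2], atol=1e-3)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(11)
        Z = rng.normal(size=(100, 3))
        a = fit_gmm(Z, n_init=3, seed=5)
        b = fit_gmm(Z, n_init=3, seed=5)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.train_loglik == b.train_loglik


class TestLogLikelihood:
    def test_degenerate_mixture_equals_component_logpdf(self):
        mu = np.array([1.0, 2.0, 3.0])
        model = GMMModel(
            weights=[1 - 1e-15, 1e-15],
            means=[mu, mu + 100],
            covariances=[np.eye(3), np.eye(3)],
        )
        z = mu + 0.5
        assert log_likelihood(model, z[None, :]) == pytest.approx(
            gaussian_logpdf(z, mu, np.eye(3)), abs=1e-9
        )

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(12)
        m = random_model(rng)
        swapped = GMMModel(
            weights=m.weights[::-1].copy(),
            means=m.means[::-1].copy(),
            covariances=m.covariances[::-1].copy(),
        )
        Z = rng.normal(size=(40, 3))
        assert log_likelihood(m, Z) == pytest.approx(
            log_likelihood(swapped, Z), abs=1e-10
        )

    def test_matches_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(13)
        for _ in range(20):
            Z = rng.normal(size=(200, 3)) * rng.uniform(0.5, 2, size=3)
            gm = sklearn.GaussianMixture(
                n_components=2, covariance_type="full", random_state=0, reg_covar=1e-6
            ).fit(Z)
            model = GMMModel(
                weights=gm.weights_, means=gm.means_, covariances=gm.covariances_
            )
            ours = log_likelihood(model, Z)
            theirs = gm.score(Z) * len(Z)
            assert ours == pytest.approx(theirs, abs=1e-6 * abs(theirs))


class TestLabelUbCluster:
    def _model(self):
        return GMMModel(
            weights=[0.5, 0.5],
            means=[[0.0, 0.0, 0.0], [3.0, 3.0, 3.0]],
            covariances=[np.eye(3), np.eye(3)],
        )

    def test_faller_mean_at_component_forces_designation(self):
        model = label_ub_cluster(self._model(), np.array([[3.0, 3.0, 3.0]]))
        assert model.ub_index == 1
        model = label_ub_cluster(self._model(), np.array([[0.0, 0.0, 0.0]]))
        assert model.ub_index == 0

    def test_tie_broken_toward_larger_velocity_mean(self):
        model = GMMModel(
            weights=[0.5, 0.5],
            means=[[0.0, 2.0, 0.0], [0.0, -2.0, 0.0]],
            covariances=[np.eye(3), np.eye(3)],
        )
        labeled = label_ub_cluster(model, np.zeros((1, 3)))
        assert labeled.ub_index == 0  # equidistant -> larger v_mean coordinate

    def test_no_faller_descriptors_raises(self):
        with pytest.raises(StateError):
            label_ub_cluster(self._model(), np.empty((0, 3)))

    def test_ub_component_has_larger_means_on_planted_mixtures(self):
        # sway descriptors form a tight quiet cluster and a broad, displaced
        # unquiet cluster; the designated component should sit at the larger
        # mean in >= 95% of runs
        rng = np.random.default_rng(14)
        hits = 0
        n_runs = 40
        for _ in range(n_runs):
            qb = rng.normal(0.0, 0.5, size=(300, 3))
            ub = rng.normal(3.5, 1.5, size=(80, 3))
            Z = np.vstack([qb, ub])
            model = fit_gmm(Z, n_init=5, seed=int(rng.integers(2**31)))
            # faller-derived blocks: a mix enriched in UB
            faller = np.vstack([qb[:60], ub[:40]])
            model = label_ub_cluster(model, faller)
            if np.all(model.means[model.ub_index] > model.means[model.qb_index]):
                hits += 1
        assert hits >= 0.95 * n_runs


class TestSerialization:
    def test_round_trip_exact(self):
        rng = np.random.default_rng(15)
        model = random_model(rng)
        model = label_ub_cluster(model, rng.normal(size=(5, 3)))
        model.condition = Condition.EC
        back = model_from_dict(model_to_dict(model))
        np.testing.assert_array_equal(back.weights, model.weights)
        np.testing.assert_array_equal(back.means, model.means)
        np.testing.assert_array_equal(back.covariances, model.covariances)
        assert back.ub_index == model.ub_index
        assert back.condition is Condition.EC
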