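"""Trajectory mixture: likelihood, EM, posteriors, entropy, alignment."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import norm

from lcsmix.lcsm import fiml_loglik
from lcsmix.mixture import (
    EMConfig,
    MixtureParams,
    _em_iterate,
    align_labels,
    em_fit,
    information_criteria,
    mixture_loglik,
    n_free_params,
    observed_information_se,
    permute_classes,
    posterior_probs,
    relative_entropy,
)
from lcsmix.simulate import GeneratorConfig, generate_cohort

from conftest import make_panel


def _params(pi, means, theta_val, structure="class"):
    means = np.asarray(means, dtype=float)
    K, T = means.shape
    return MixtureParams.from_wave_means(
        np.asarray(pi), means, np.full((K, T), theta_val), structure
    )


class TestMixtureLoglik:
    def test_k1_reduces_to_independent_normals(self):
        rng = np.random.default_rng(1)
        y = rng.normal(5, 2, (15, 9))
        obs = rng.random((15, 9)) < 0.7
        obs[:, 0] = True
        data = make_panel(np.where(obs, y, np.nan), observed=obs)
        p = _params([1.0], [np.full(9, 5.0)], 4.0)
        expected = norm(5.0, 2.0).logpdf(y[obs]).sum()
        assert mixture_loglik(p, data) == pytest.approx(expected, rel=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        data = make_panel(rng.normal(5, 3, (40, 9)))
        means = rng.normal(5, 3, (3, 9))
        p = _params([0.5, 0.3, 0.2], means, 2.0)
        perm = np.array([2, 0, 1])
        p2 = MixtureParams(p.pi[perm], p.eta1[perm], p.deltas[perm], p.theta[perm])
        ll1, ll2 = mixture_loglik(p, data), mixture_loglik(p2, data)
        assert ll1 == pytest.approx(ll2, rel=1e-12)
        ic1 = information_criteria(ll1, n_free_params(p), 40)
        ic2 = information_criteria(ll2, n_free_params(p2), 40)
        assert ic1 == pytest.approx(ic2)
        e1 = relative_entropy(posterior_probs(p, data))
        e2 = relative_entropy(posterior_probs(p2, data))
        assert e1 == pytest.approx(e2, rel=1e-10)

    def test_two_subject_hand_oracle(self):
        # subject 1 sees waves (1,2); subject 2 sees wave 1 only
        y = np.array([[3.0, 4.0] + [np.nan] * 7, [10.0] + [np.nan] * 8])
        data = make_panel(y)
        mu = np.zeros((2, 9))
        mu[0, :2] = (3.0, 5.0)
        mu[1, :2] = (9.0, 9.0)
        p = _params([0.6, 0.4], mu, 4.0)
        d = norm(0, 2).pdf
        s1 = 0.6 * d(3.0 - 3.0) * d(4.0 - 5.0) + 0.4 * d(3.0 - 9.0) * d(4.0 - 9.0)
        s2 = 0.6 * d(10.0 - 3.0) + 0.4 * d(10.0 - 9.0)
        assert mixture_loglik(p, data) == pytest.approx(np.log(s1) + np.log(s2), rel=1e-12)

    def test_k1_agrees_with_fiml_diagonal(self):
        rng = np.random.default_rng(4)
        y = rng.normal(6, 2, (25, 9))
        obs = rng.random((25, 9)) < 0.6
        obs[:, 0] = True
        data = make_panel(np.where(obs, y, np.nan), observed=obs)
        mu = np.linspace(4, 8, 9)
        p = _params([1.0], [mu], 3.0)
        assert mixture_loglik(p, data) == pytest.approx(
            fiml_loglik(mu, np.eye(9) * 3.0, data), rel=1e-12
        )


class TestPosterior:
    def test_identical_classes_uniform(self):
        data = make_panel(np.full((6, 9), 5.0))
        p = _params([0.5, 0.5], np.full((2, 9), 5.0), 2.0)
        np.testing.assert_allclose(posterior_probs(p, data), 0.5)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        data = make_panel(rng.normal(5, 4, (100, 9)))
        p = _params([0.2, 0.3, 0.5], rng.normal(5, 4, (3, 9)), 2.0)
        post = posterior_probs(p, data)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_single_subject_bayes_oracle(self):
        y = np.array([[4.0] + [np.nan] * 8])
        data = make_panel(y)
        mu = np.zeros((2, 9))
        mu[0, 0], mu[1, 0] = 3.0, 6.0
        p = _params([0.7, 0.3], mu, 1.0)
        num0 = 0.7 * norm(3, 1).pdf(4.0)
        num1 = 0.3 * norm(6, 1).pdf(4.0)
        np.testing.assert_allclose(
            posterior_probs(p, data)[0], [num0 / (num0 + num1), num1 / (num0 + num1)],
            atol=1e-12,
        )


class TestEntropy:
    def test_one_hot_gives_one(self):
        post = np.eye(4)[np.array([0, 1, 2, 3, 0, 1])]
        assert relative_entropy(post) == pytest.approx(1.0)

    def test_uniform_gives_zero(self):
        assert relative_entropy(np.full((10, 5), 0.2)) == pytest.approx(0.0, abs=1e-12)

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            relative_entropy(np.ones((5, 1)))


def test_information_criteria_arithmetic():
    ics = information_criteria(-100.0, 10, 100)
    assert ics["aic"] == pytest.approx(220.0)
    assert ics["bic"] == pytest.approx(200 + 10 * np.log(100))
    assert ics["abic"] == pytest.approx(200 + 10 * np.log(102 / 24))


class TestEmFit:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(7)
        y = rng.normal(6, 3, (80, 9))
        obs = rng.random((80, 9)) < 0.75
        obs[:, 0] = True
        data = make_panel(np.where(obs, y, np.nan), observed=obs)
        fit = em_fit(data, 1, EMConfig(seed=0))
        wave_mean = np.array(
            [y[obs[:, t], t].mean() for t in range(9)]
        )
        np.testing.assert_allclose(fit.params.wave_means[0], wave_mean, atol=1e-8)
        pooled = np.mean(
            np.concatenate([(y[obs[:, t], t] - wave_mean[t]) ** 2 for t in range(9)])
        )
        assert fit.params.theta[0, 0] == pytest.approx(pooled, abs=1e-8)

    def test_ll_monotone_every_iteration(self):
        rng = np.random.default_rng(9)
        data, _ = generate_cohort(GeneratorConfig(n=400, seed=9))
        for trial in range(3):
            means0 = rng.normal(6, 4, (3, 9))
            trace = []
            _em_iterate(
                np.full(3, 1 / 3), means0, np.full((3, 9), 10.0),
                data.y, data.observed, "class", 1e-10, 200, ll_trace=trace,
            )
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-7 * np.maximum(1, np.abs(trace[:-1])))

    def test_recovers_well_separated_classes(self):
        cfg = replace(
            GeneratorConfig(),
            n=800,
            residual_sd=1.5,
            retention_schedule=(1.0,) * 9,
            seed=15,
        )
        data, truth = generate_cohort(cfg)
        fit = em_fit(data, 5, EMConfig(n_starts=20, refine_top=5, seed=16))
        ref = MixtureParams.from_wave_means(
            np.asarray(cfg.class_proportions), cfg.trajectory_means(), np.full((5, 9), 1.0)
        )
        fit = permute_classes(fit, align_labels(fit.params, ref))
        # oracle: the realized truth-conditional frequencies and sample
        # means of this cohort (classes are near-perfectly separated here)
        labels = truth["true_class"].to_numpy()
        freq = np.bincount(labels, minlength=5) / cfg.n
        np.testing.assert_allclose(fit.params.pi, freq, atol=0.01)
        for c in range(5):
            np.testing.assert_allclose(
                fit.params.wave_means[c], data.y[labels == c].mean(axis=0), atol=0.2
            )
        assert fit.ll_replicated

    def test_loglik_field_consistent(self):
        data, _ = generate_cohort(GeneratorConfig(n=300, seed=19))
        fit = em_fit(data, 2, EMConfig(n_starts=8, refine_top=3, seed=20))
        assert fit.loglik == pytest.approx(mixture_loglik(fit.params, data), rel=1e-10)

    def test_invalid_k(self):
        data, _ = generate_cohort(GeneratorConfig(n=10, seed=1))
        with pytest.raises(ValueError):
            em_fit(data, 0)
        with pytest.raises(ValueError):
            em_fit(data, 11)


class TestAlignLabels:
    def _ref(self):
        cfg = GeneratorConfig()
        return MixtureParams.from_wave_means(
            np.asarray(cfg.class_proportions), cfg.trajectory_means(), np.full((5, 9), 1.0)
        )

    def test_identity(self):
        ref = self._ref()
        np.testing.assert_array_equal(align_labels(ref, ref), np.arange(5))

    def test_recovers_applied_permutation(self):
        ref = self._ref()
        rng = np.random.default_rng(3)
        for _ in range(5):
            perm = rng.permutation(5)
            shuffled = MixtureParams(
                ref.pi[perm], ref.eta1[perm], ref.deltas[perm], ref.theta[perm]
            )
            recovered = align_labels(shuffled, ref)
            np.testing.assert_array_equal(shuffled.wave_means[recovered], ref.wave_means)

    def test_noisy_estimates_still_aligned(self):
        # moderate estimation noise never flips the optimal assignment for
        # these well-separated reference curves
        ref = self._ref()
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(100):
            perm = rng.permutation(5)
            noisy = MixtureParams(
                ref.pi[perm],
                ref.eta1[perm] + rng.normal(0, 0.3, 5),
                ref.deltas[perm] + rng.normal(0, 0.3, (5, 8)),
                ref.theta[perm],
            )
            recovered = align_labels(noisy, ref)
            hits += int(np.array_equal(recovered, np.argsort(perm)))
        assert hits >= 99

    def test_dimension_mismatch(self):
        ref = self._ref()
        small = MixtureParams(
            np.array([0.5, 0.5]), np.zeros(2), np.zeros((2, 8)), np.full((2, 9), 1.0)
        )
        with pytest.raises(ValueError):
            align_labels(small, ref)


def test_observed_information_se_magnitude():
    # SEs from the observed information should be positive and of the
    # sampling-noise order for a small well-separated fit
    cfg = replace(GeneratorConfig(), n=500, residual_sd=1.5, seed=23)
    data, _ = generate_cohort(cfg)
    fit = em_fit(data, 2, EMConfig(n_starts=10, refine_top=3, seed=24))
    se = observed_information_se(fit.params, data)
    assert np.all(se["eta1"] > 0) and np.all(se["deltas"] > 0)
    assert np.all(se["eta1"] < 2.0) and np.all(se["deltas"] < 2.0)
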