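"""EM correctness: closed forms, invariants, recovery, and an independent
reference implementation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpseg.gmm_core import (
    MixtureParams,
    assign_cp,
    cp_component,
    default_init,
    em_fit,
    log_likelihood,
    responsibilities,
)


def sample_mixture(rng, n, params):
    comp = rng.choice(params.k, size=n, p=params.weights)
    return rng.normal(params.means[comp], params.sds[comp])


class TestDefaultInit:
    def test_published_values(self):
        p = default_init()
        assert p.k == 3
        assert p.means.tolist() == [0.15, 1.5, 4.0]
        assert p.sds.tolist() == [0.02, 0.1, 1.5]
        assert p.weights.tolist() == [0.45, 0.5, 0.05]
        assert p.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestMixtureParams:
    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams([0, 1], [1, 1], [0.5, 0.6])

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams([0, 1], [1, 0], [0.5, 0.5])


class TestEmFit:
    def test_single_component_equals_closed_form_mle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(1.0, 0.1, size=2000)
        init = MixtureParams([0.5], [1.0], [1.0])
        fit = em_fit(x, init=init)
        assert fit.params.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert fit.params.sds[0] == pytest.approx(x.std(), abs=1e-6)
        assert fit.params.weights[0] == 1.0

    def test_parameter_recovery_at_published_truth(self):
        rng = np.random.default_rng(2024)
        truth = default_init()
        x = sample_mixture(rng, 30_000, truth)
        fit = em_fit(x)
        assert fit.converged
        assert np.all(np.abs(fit.params.means - truth.means) < 0.1)
        assert np.all(np.abs(fit.params.weights - truth.weights) < 0.03)

    def test_degenerate_duplicate_samples_engage_floor(self):
        x = np.array([1.0, 1.0, 1.0])
        init = MixtureParams([0.5, 1.5], [0.5, 0.5], [0.5, 0.5])
        fit = em_fit(x, init=init, max_iter=50)
        assert fit.params.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(fit.params.sds >= 1e-4)
        assert fit.floor_engaged

    def test_fewer_samples_than_components_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            em_fit(np.array([1.0, 2.0]))

    def test_loglik_trace_non_decreasing(self):
        rng = np.random.default_rng(5)
        x = sample_mixture(rng, 2000, default_init())
        fit = em_fit(x)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_loglik_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 1.0, size=400)  # arbitrary non-Gaussian data
        fit = em_fit(x, max_iter=60)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
        assert fit.params.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        x = sample_mixture(rng, 3000, default_init())
        fit_a = em_fit(x)
        fit_b = em_fit(rng.permutation(x))
        assert np.allclose(fit_a.params.means, fit_b.params.means, atol=1e-12)
        assert np.allclose(fit_a.params.sds, fit_b.params.sds, atol=1e-12)
        assert np.allclose(fit_a.params.weights, fit_b.params.weights, atol=1e-12)

    def test_deterministic_rerun(self):
        rng = np.random.default_rng(7)
        x = sample_mixture(rng, 1000, default_init())
        a, b = em_fit(x), em_fit(x)
        assert np.array_equal(a.loglik_trace, b.loglik_trace)
        assert np.array_equal(a.params.means, b.params.means)

    def test_agrees_with_reference_em(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(8)
        x = sample_mixture(rng, 5000, default_init())
        fit = em_fit(x, tol=1e-10, max_iter=1000)
        init = default_init()
        gm = sklearn.GaussianMixture(
            n_components=3,
            weights_init=init.weights,
            means_init=init.means[:, None],
            precisions_init=(1.0 / init.sds ** 2)[:, None, None],
            tol=1e-10, reg_covar=1e-12, max_iter=1000,
        ).fit(x[:, None])
        mine = log_likelihood(x, fit.params) / x.size
        assert mine == pytest.approx(gm.score(x[:, None]), abs=1e-6)
        assert np.allclose(np.sort(fit.params.means),
                           np.sort(gm.means_.ravel()), atol=1e-3)


class TestResponsibilities:
    def test_single_component_posterior_is_one(self):
        p = MixtureParams([2.0], [0.5], [1.0])
        r = responsibilities(np.array([0.0, 2.0, 10.0]), p)
        assert np.all(r == 1.0)

    def test_symmetric_mixture_midpoint(self):
        p = MixtureParams([-1.0, 1.0], [0.5, 0.5], [0.5, 0.5])
        r = responsibilities(np.array([0.0]), p)
        assert np.allclose(r, [[0.5, 0.5]], atol=1e-12)

    def test_sample_at_bright_mean_under_default_init(self):
        r = responsibilities(np.array([4.0]), default_init())
        assert r[0, 2] > 0.99

    def test_rows_sum_to_one_even_for_outliers(self):
        x = np.array([-1e3, 0.0, 1e3])
        r = responsibilities(x, default_init())
        assert np.allclose(r.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.isfinite(r))


class TestAssignCp:
    def test_bright_samples_assigned(self):
        assert np.all(assign_cp(np.full(10, 4.0), default_init()))

    def test_dark_samples_not_assigned(self):
        assert not np.any(assign_cp(np.full(10, 0.15), default_init()))

    def test_empty_input(self):
        out = assign_cp(np.array([]), default_init())
        assert out.shape == (0,) and out.dtype == bool

    def test_cp_role_follows_fitted_means_not_index(self):
        # highest mean sits at index 0
        p = MixtureParams([5.0, 1.0, 0.1], [1.0, 0.5, 0.05], [0.2, 0.4, 0.4])
        assert cp_component(p) == 0
        assert np.all(assign_cp(np.array([5.0, 6.0]), p))

    def test_mean_tie_broken_by_weight(self):
        p = MixtureParams([2.0, 2.0, 0.1], [1.0, 1.0, 0.05], [0.1, 0.6, 0.3])
        assert cp_component(p) == 1
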