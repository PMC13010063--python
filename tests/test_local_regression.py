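"""Kernel weighting, per-patient WLS, and the likelihood-ratio loss."""

import numpy as np
import pytest
from scipy.optimize import minimize

from latloc import (KernelSpec, adaptive_bandwidth, fit_all_local,
                    fit_local_null, fit_local_wls, kernel_weights,
                    pairwise_distances, prediction_loss)
from latloc.local_regression import local_fit, neg_log_likelihood_ratio


def test_pairwise_distances_345_and_diagonal():
    Z = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 1.0]])
    D = pairwise_distances(Z)
    assert D[0, 1] == pytest.approx(5.0)
    assert np.all(np.diag(D) == 0)
    assert np.allclose(D, D.T)


def test_pairwise_distances_row_permutation_equivariance(rng):
    Z = rng.standard_normal((8, 3))
    D = pairwise_distances(Z)
    perm = rng.permutation(8)
    assert np.allclose(pairwise_distances(Z[perm]), D[np.ix_(perm, perm)])


def test_pairwise_distances_rejects_nonfinite():
    with pytest.raises(ValueError, match="finite"):
        pairwise_distances(np.array([[0.0], [np.nan]]))


def test_adaptive_bandwidth_hand_enumeration():
    # 1-D latents {0, 1, 3}: nearest-neighbour distances are (1, 1, 2)
    D = pairwise_distances(np.array([[0.0], [1.0], [3.0]]))
    assert np.allclose(adaptive_bandwidth(D, k=1), [1.0, 1.0, 2.0])
    # k = n-1 gives the maximum distance from each point
    assert np.allclose(adaptive_bandwidth(D, k=2), [3.0, 2.0, 3.0])


def test_adaptive_bandwidth_duplicate_points_error():
    D = pairwise_distances(np.array([[1.0], [1.0], [5.0]]))
    with pytest.raises(ValueError, match="raise k or jitter"):
        adaptive_bandwidth(D, k=1)


def test_adaptive_bandwidth_k_range_checked():
    D = pairwise_distances(np.array([[0.0], [1.0]]))
    with pytest.raises(ValueError, match="k must"):
        adaptive_bandwidth(D, k=2)


def test_gaussian_weight_at_kth_neighbour_is_exp_half():
    # a point exactly at the adaptive bandwidth has scaled distance u = 1
    Z = np.array([[0.0], [1.0], [2.5]])
    D = pairwise_distances(Z)
    dk = adaptive_bandwidth(D, k=1)
    lw = kernel_weights(D, dk, KernelSpec(sigma=1.0))
    assert lw.W[0, 1] == pytest.approx(np.exp(-0.5))
    assert np.all(np.diag(lw.W) == 1.0)


def test_huge_sigma_reduces_local_fit_to_global_ols(rng):
    Z = rng.standard_normal((50, 3))
    y = Z @ [1.0, -0.5, 2.0] + rng.normal(0, 0.2, 50)
    fits = fit_all_local(Z, y, KernelSpec(sigma=1e6), ridge_eps=0.0)
    A = np.column_stack([np.ones(50), Z])
    beta_ols = np.linalg.lstsq(A, y, rcond=None)[0]
    assert np.max(np.abs(fits.beta - beta_ols)) < 1e-4


def test_tricube_weights_vanish_outside_bandwidth():
    Z = np.array([[0.0], [0.5], [3.0]])
    D = pairwise_distances(Z)
    dk = adaptive_bandwidth(D, k=1)
    lw = kernel_weights(D, dk, KernelSpec(family="tricube", k=1))
    assert lw.W[0, 2] == 0.0           # far point: u > 1
    assert np.all(np.diag(lw.W) == 1.0)


# ---------------------------------------------------------------------------
# weighted least squares


def test_wls_with_uniform_weights_equals_ols(rng):
    Z = rng.standard_normal((25, 3))
    y = rng.standard_normal(25)
    beta = fit_local_wls(Z, y, np.ones(25), ridge_eps=0.0)
    A = np.column_stack([np.ones(25), Z])
    assert np.allclose(beta, np.linalg.lstsq(A, y, rcond=None)[0], atol=1e-8)


def test_wls_constant_response_gives_intercept_only(rng):
    Z = rng.standard_normal((15, 2))
    beta = fit_local_wls(Z, np.full(15, 3.25), rng.random(15) + 0.1,
                         ridge_eps=0.0)
    assert np.allclose(beta, [3.25, 0.0, 0.0], atol=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_wls_matches_numerical_minimizer_of_weighted_sse(seed):
    # brute-force optimizer oracle on the weighted objective
    rng = np.random.default_rng(seed)
    n, d = 20, 2
    Z = rng.standard_normal((n, d))
    y = rng.standard_normal(n)
    w = rng.random(n) + 0.05
    A = np.column_stack([np.ones(n), Z])

    def sse(beta):
        return float(np.sum(w * (y - A @ beta) ** 2))

    def grad(beta):
        return -2.0 * A.T @ (w * (y - A @ beta))

    res = minimize(sse, np.zeros(d + 1), jac=grad, method="BFGS",
                   options={"gtol": 1e-12})
    beta = fit_local_wls(Z, y, w, ridge_eps=0.0)
    assert np.allclose(beta, res.x, atol=1e-6)


def test_wls_singular_design_raises_and_ridge_fixes():
    Z = np.ones((10, 2))  # collinear with intercept
    y = np.arange(10.0)
    with pytest.raises(np.linalg.LinAlgError, match="ridge_eps"):
        fit_local_wls(Z, y, np.ones(10), ridge_eps=0.0)
    beta = fit_local_wls(Z, y, np.ones(10), ridge_eps=1e-6)
    assert np.all(np.isfinite(beta))


def test_local_null_is_weighted_mean():
    assert fit_local_null(np.array([0.0, 0.0, 3.0]),
                          np.array([1.0, 1.0, 2.0])) == pytest.approx(1.5)
    y = np.array([5.0, -1.0, 2.0])
    assert fit_local_null(y, np.ones(3)) == pytest.approx(y.mean())
    w = np.array([1.0, 1e-12, 1e-12])
    assert fit_local_null(y, w) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# likelihood-ratio term


def _direct_loglik_difference(w, e_full, e_null):
    # independent oracle: weighted Gaussian log-likelihoods with plug-in
    # variances, evaluated term by term
    def loglik(e):
        s2 = np.sum(w * e ** 2) / np.sum(w)
        return np.sum(w * (-0.5 * np.log(2 * np.pi * s2) - e ** 2 / (2 * s2)))

    return loglik(e_null) - loglik(e_full)


@pytest.mark.parametrize("seed", range(4))
def test_neg_log_ratio_matches_direct_likelihood_evaluation(seed):
    rng = np.random.default_rng(seed)
    n = 15
    Z = rng.standard_normal((n, 2))
    y = Z @ [1.0, -1.0] + rng.normal(0, 0.5, n)
    w = rng.random(n) + 0.05
    fit = local_fit(Z, y, w, ridge_eps=0.0)
    A = np.column_stack([np.ones(n), Z])
    e_full = y - A @ fit.beta
    e_null = y - fit.beta_null
    direct = _direct_loglik_difference(w, e_full, e_null)
    assert fit.neg_log_ratio == pytest.approx(direct, abs=1e-8)
    assert fit.neg_log_ratio <= 0.0
    assert fit.sigma2_full <= fit.sigma2_null + 1e-12


def test_neg_log_ratio_zero_when_outcome_locally_constant():
    w = np.ones(5)
    with pytest.warns(UserWarning, match="locally constant"):
        val = neg_log_likelihood_ratio(w, np.zeros(5), np.zeros(5))
    assert val == 0.0


def test_nesting_invariant_across_cohort(small_dataset):
    ds, X, y, _ = small_dataset
    Z = ds.latent_true
    fits = fit_all_local(Z, y, KernelSpec())
    assert np.all(fits.sigma2_full <= fits.sigma2_null + 1e-10)
    assert np.all(fits.neg_log_ratio <= 1e-12)


def test_prediction_loss_negative_and_scale_invariant(rng):
    Z = rng.standard_normal((30, 2))
    y = Z @ [1.0, 0.5] + rng.normal(0, 0.3, 30)
    spec = KernelSpec()
    loss = prediction_loss(Z, y, spec)
    assert loss < 0
    # variance-ratio form: rescaling the outcome leaves the loss unchanged
    assert prediction_loss(Z, 7.3 * y, spec) == pytest.approx(loss, abs=1e-9)


def test_prediction_loss_weaker_for_unrelated_outcome(rng):
    Z = rng.standard_normal((60, 2))
    y_signal = Z @ [1.0, 1.0] + rng.normal(0, 0.2, 60)
    y_noise = rng.standard_normal(60)
    spec = KernelSpec()
    assert abs(prediction_loss(Z, y_noise, spec)) < abs(
        prediction_loss(Z, y_signal, spec))


def test_prediction_loss_rejects_duplicated_cohort(rng):
    z = rng.standard_normal((1, 2))
    Z = np.repeat(z, 10, axis=0)
    with pytest.raises(ValueError, match="raise k or jitter"):
        prediction_loss(Z, rng.standard_normal(10), KernelSpec(k=3))
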