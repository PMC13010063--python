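"""Global fit, deviation flags, subgroups, characterization, projection."""

import numpy as np
import pytest

from latloc import (KernelSpec, SyntheticConfig, cluster_predictors,
                    deviation_profile, fit_all_local, fit_global,
                    form_subgroups, generate, interaction_analysis,
                    latent_correlation, project_test, rmse_contrast,
                    standardize, zscore_profile)
from latloc.diagnostics import GlobalFit


def _manual_ols_with_ci(Z, y, level=0.95):
    # independent closed-form oracle for OLS coefficients and t-based CIs
    from scipy import stats
    A = np.column_stack([np.ones(len(y)), Z])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    resid = y - A @ beta
    dof = len(y) - A.shape[1]
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    half = stats.t.ppf(0.5 + level / 2, dof) * np.sqrt(np.diag(cov))
    return beta, beta - half, beta + half


def test_fit_global_matches_closed_form_ols(rng):
    Z = rng.standard_normal((40, 3))
    y = Z @ [1.0, -2.0, 0.5] + rng.normal(0, 0.7, 40)
    fit = fit_global(Z, y)
    beta, lo, hi = _manual_ols_with_ci(Z, y)
    assert np.allclose(fit.coefficients, beta, atol=1e-8)
    assert np.allclose(fit.ci_lower, lo, atol=1e-8)
    assert np.allclose(fit.ci_upper, hi, atol=1e-8)
    assert np.all(fit.ci_lower <= fit.coefficients)
    assert np.all(fit.coefficients <= fit.ci_upper)


def test_fit_global_noiseless_and_noise_only():
    rng = np.random.default_rng(1)
    Z = rng.standard_normal((100, 2))
    fit = fit_global(Z, 2.0 * Z[:, 0])
    assert fit.coefficients[1] == pytest.approx(2.0)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.ci_upper[1] - fit.ci_lower[1] < 1e-8
    big = np.random.default_rng(2).standard_normal((2000, 2))
    noise_fit = fit_global(big, np.random.default_rng(3).standard_normal(2000))
    assert noise_fit.r_squared < 0.05


def test_fit_global_rejects_rank_deficiency():
    Z = np.ones((30, 2))
    with pytest.raises(ValueError, match="rank"):
        fit_global(Z, np.arange(30.0))


# ---------------------------------------------------------------------------
# deviation profile and flags


def _toy_global():
    return GlobalFit(coefficients=np.array([0.0, 1.0, 2.0]),
                     ci_lower=np.array([-0.1, 0.8, 1.7]),
                     ci_upper=np.array([0.1, 1.2, 2.3]),
                     r_squared=0.5, residual_sd=1.0, fitted=np.zeros(3))


def test_deviation_profile_flags_strictly_outside():
    gfit = _toy_global()
    beta_local = np.array([
        [0.0, 1.0, 2.0],    # identical to global: no flags
        [0.0, 1.2, 2.0],    # exactly on the boundary: not flagged
        [0.0, 0.5, 2.5],    # outside on both dims
    ])
    prof = deviation_profile(beta_local, gfit)
    assert not prof[prof["patient"] == 0]["flag"].any()
    assert not prof[prof["patient"] == 1]["flag"].any()
    flags = prof[prof["patient"] == 2]
    assert flags["flag"].all()
    assert np.allclose(prof["diff"],
                       (beta_local[:, 1:] - [1.0, 2.0]).T.ravel())


def test_flag_count_monotone_in_ci_level(rng):
    Z = rng.standard_normal((80, 2))
    y = Z @ [1.0, 1.0] + rng.normal(0, 0.5, 80)
    fits = fit_all_local(Z, y, KernelSpec())
    n95 = deviation_profile(fits.beta, fit_global(Z, y, 0.95))["flag"].sum()
    n99 = deviation_profile(fits.beta, fit_global(Z, y, 0.99))["flag"].sum()
    assert n99 <= n95


def test_flag_rate_higher_for_planted_subgroup_on_oracle_latent():
    """With the true manifold coordinates, the CI rule flags planted-subgroup
    members on the planted dimension far more often than the background."""
    rates = []
    for seed in range(3):
        ds = generate(SyntheticConfig(seed=seed))
        y = (ds.y_raw - ds.y_raw.mean()) / ds.y_raw.std()
        Z = ds.latent_true
        fits = fit_all_local(Z, y, KernelSpec())
        prof = deviation_profile(fits.beta, fit_global(Z, y))
        sub = prof[prof["dim"] == 2]
        m = ds.subgroup_labels == 1
        member_rate = sub["flag"].to_numpy()[m].mean()
        bg_rate = sub["flag"].to_numpy()[~m].mean()
        rates.append((member_rate, bg_rate))
    assert all(mr > br for mr, br in rates)
    assert np.mean([mr for mr, _ in rates]) > 0.5


def test_form_subgroups_rules():
    gfit = _toy_global()
    beta = np.tile([0.0, 1.0, 2.0], (40, 1))
    beta[:12, 1] = 2.0   # 12 patients deviate positive on dim 1
    beta[12:15, 2] = 0.0  # 3 patients deviate negative on dim 2
    prof = deviation_profile(beta, gfit)
    subs = form_subgroups(prof, min_size=5)
    assert len(subs) == 1
    assert subs[0].dim == 1 and subs[0].sign == 1 and subs[0].size == 12
    assert np.array_equal(subs[0].members, np.arange(12))
    # every member satisfies the flag rule on the subgroup's (dim, sign)
    for sg in subs:
        rows = prof[(prof["dim"] == sg.dim)
                    & prof["patient"].isin(sg.members)]
        assert rows["flag"].all() and (rows["sign"] == sg.sign).all()
    assert form_subgroups(prof.assign(flag=False)) == []


# ---------------------------------------------------------------------------
# characterization


def test_latent_correlation_identity_and_sign_flip(rng):
    X = rng.standard_normal((300, 6))
    Z = np.column_stack([X[:, 3], rng.standard_normal(300)])
    lc = latent_correlation(Z, X)
    assert lc.corr[0, 3] == pytest.approx(1.0)
    assert lc.top[0][0] == 3
    flipped = latent_correlation(np.column_stack([-Z[:, 0], Z[:, 1]]), X)
    assert np.allclose(flipped.corr[0], -lc.corr[0])


def test_latent_correlation_near_zero_for_independent_columns(rng):
    Z = rng.standard_normal((2000, 2))
    X = rng.standard_normal((2000, 4))
    assert np.max(np.abs(latent_correlation(Z, X).corr)) < 0.1


def test_zscore_profile_centering_and_single_member(small_dataset):
    _, X, _, _ = small_dataset
    full = zscore_profile(X, np.arange(X.shape[0]))
    assert np.max(np.abs(full)) < 1e-10
    one = zscore_profile(X, np.array([4]))
    assert np.allclose(one, X[4])
    with pytest.raises(ValueError, match="empty"):
        zscore_profile(X, np.array([], dtype=int))


def test_zscore_profile_detects_shifted_predictor():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((2000, 8))
    members = np.arange(60)
    X[members, 5] += 1.0
    X = (X - X.mean(0)) / X.std(0)
    prof = zscore_profile(X, members)
    assert abs(prof[5] - 1.0) < 0.2
    assert np.all(np.abs(np.delete(prof, 5)) < 0.4)


def test_cluster_predictors_recovers_blocks(rng):
    # four blocks of correlated predictors
    n, per = 500, 4
    base = rng.standard_normal((n, 4))
    X = np.hstack([base[:, [b]] + 0.1 * rng.standard_normal((n, per))
                   for b in range(4)])
    labels = cluster_predictors(X, n_clusters=4)
    for b in range(4):
        block = labels[b * per:(b + 1) * per]
        assert len(set(block)) == 1
    assert len(set(labels)) == 4


def test_cluster_predictors_singletons_and_duplicates(rng):
    X = rng.standard_normal((100, 5))
    assert len(set(cluster_predictors(X, n_clusters=5))) == 5
    X2 = np.column_stack([X, X[:, 0] * 2.0])  # perfectly correlated pair
    labels = cluster_predictors(X2, n_clusters=4)
    assert labels[0] == labels[5]


def test_interaction_analysis_recovers_planted_interaction(rng):
    n = 200
    x = rng.standard_normal(n)
    g = np.zeros(n)
    members = rng.choice(n, 60, replace=False)
    g[members] = 1.0
    y = x + 1.5 * x * g + rng.normal(0, 0.3, n)
    X = np.column_stack([x, rng.standard_normal(n)])
    res = interaction_analysis(X, y, members, [0, 1])
    row = res[res["predictor"] == 0].iloc[0]
    assert row["coef"] == pytest.approx(1.5, abs=0.2)
    assert row["p_value"] < 0.01
    null_row = res[res["predictor"] == 1].iloc[0]
    assert null_row["p_value"] > row["p_value"]
    assert "p_bh" in res.columns


def test_interaction_analysis_skips_degenerate_indicator(rng):
    X = rng.standard_normal((50, 2))
    y = rng.standard_normal(50)
    with pytest.warns(UserWarning, match="collinear"):
        res = interaction_analysis(X, y, np.arange(50), [0])
    assert len(res) == 0


def test_rmse_contrast_identities(rng):
    y = rng.standard_normal(30)
    fitted = y + rng.normal(0, 0.5, 30)
    members = np.arange(10)
    same = rmse_contrast(y, fitted, fitted, members)
    assert same.improvement_inside == 0.0
    assert same.improvement_outside == 0.0
    perfect = rmse_contrast(y, fitted, y, members)
    assert perfect.rmse_local_inside == 0.0
    assert perfect.improvement_inside == pytest.approx(
        perfect.rmse_global_inside)
    with pytest.raises(ValueError, match="strict"):
        rmse_contrast(y, fitted, fitted, np.arange(30))


# ---------------------------------------------------------------------------
# test-set projection


def test_project_test_duplicate_row_and_empty(quick_train_config):
    from latloc import train
    ds = generate(SyntheticConfig(seed=31))
    X, y, _ = standardize(ds.X_raw, ds.y_raw)
    res = train(X, y, quick_train_config)
    gfit = fit_global(res.Z, y)
    spec = quick_train_config.kernel
    prof, assign = project_test(X[:3], res.params, res.Z, y, gfit, spec)
    fits = fit_all_local(res.Z, y, spec)
    # a duplicated training row gets a nearly identical local model
    for i in range(3):
        got = prof[prof["patient"] == i].sort_values("dim")["beta_local"].to_numpy()
        assert np.allclose(got, fits.beta[i, 1:], atol=0.05)
    empty_prof, empty_assign = project_test(
        np.empty((0, X.shape[1])), res.params, res.Z, y, gfit, spec)
    assert len(empty_prof) == 0 and empty_assign == {}


def test_project_test_assigns_matching_subgroup():
    gfit = _toy_global()
    # build directly on latent coordinates via a trivial identity encoder
    from latloc.autoencoder import MLPSpec, AutoencoderParams
    params = AutoencoderParams(
        spec=MLPSpec(layer_widths=(2, 2)),
        enc_weights=[np.eye(2)], enc_biases=[np.zeros(2)],
        dec_weights=[np.eye(2)], dec_biases=[np.zeros(2)])
    rng = np.random.default_rng(0)
    Z_train = rng.standard_normal((60, 2))
    y_train = Z_train @ [1.0, 2.0]
    from latloc.diagnostics import Subgroup
    sg = Subgroup(id="dim1_pos", dim=1, sign=1,
                  members=np.arange(5), size=5)
    # test patient whose neighbourhood slope exceeds the dim-1 CI: craft by
    # amplifying the outcome locally is complex; instead just check the
    # assignment plumbing on whatever flags arise
    prof, assign = project_test(Z_train[:4], params, Z_train, y_train, gfit,
                                KernelSpec(), subgroups=[sg])
    for i, hits in assign.items():
        rows = prof[(prof["patient"] == i) & (prof["dim"] == 1)]
        flagged = bool(rows["flag"].iloc[0]) and int(rows["sign"].iloc[0]) == 1
        assert ("dim1_pos" in hits) == flagged
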