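"""Latent-outcome augmentation and block-missing imputation laws."""

import dataclasses
import math

import numpy as np
import pytest

from mrfomics import (Hyperparameters, McmcConfig, MultiOmicsDataset,
                      OutcomeSpec, SimulationConfig, generate_full_data,
                      inject_missingness, run_mcmc, _kernels)
from mrfomics.augmentation import (augment_binary, augment_survival,
                                   truncated_normal)
from mrfomics.state import ModelState


def _survival_ds(small_sim):
    ds, _ = small_sim
    rng = np.random.default_rng(9)
    t = np.exp(ds.Y.y / ds.Y.y.std())
    c = rng.exponential(np.median(t) * 2, t.size) + 1e-6
    y = np.minimum(t, c)
    ev = (t <= c).astype(int)
    return MultiOmicsDataset(list(ds.sample_ids), OutcomeSpec("survival", y, ev),
                            ds.C, ds.E, ds.M, ds.U_E, ds.U_M, ds.probe_map,
                            ds.network, list(ds.covariate_names)), ev


def test_binary_augmentation_sign_constraint(small_sim):
    ds, _ = small_sim
    ybin = (ds.Y.y > np.median(ds.Y.y)).astype(float)
    dsb = MultiOmicsDataset(list(ds.sample_ids), OutcomeSpec("binary", ybin),
                            ds.C, ds.E, ds.M, ds.U_E, ds.U_M, ds.probe_map,
                            ds.network, list(ds.covariate_names))
    state = ModelState(dsb, Hyperparameters(), np.random.default_rng(0))
    rng = np.random.default_rng(1)
    for _ in range(50):
        augment_binary(state, rng)
        assert np.all(state.Ystar[ybin == 1] > 0)
        assert np.all(state.Ystar[ybin == 0] <= 0)


def test_binary_halfnormal_moment():
    """mu = 0, y = 1: draws are half-normal with mean sqrt(2/pi) ~ 0.7979."""
    rng = np.random.default_rng(4)
    draws = truncated_normal(np.zeros(200_000), 1.0, 0.0, np.inf, rng)
    assert np.mean(draws) == pytest.approx(math.sqrt(2 / math.pi), abs=5e-3)


def test_truncation_inactive_in_far_limit():
    """y=0 with mu far below 0: truncation at 0 is inactive, draws ~ N(mu,1)."""
    rng = np.random.default_rng(4)
    mu = -8.0
    draws = truncated_normal(np.full(50_000, mu), 1.0, -np.inf, 0.0, rng)
    assert np.mean(draws) == pytest.approx(mu, abs=0.02)
    assert np.std(draws) == pytest.approx(1.0, abs=0.02)


def test_survival_event_records_are_exact_log_times(small_sim):
    ds, ev = _survival_ds(small_sim)
    state = ModelState(ds, Hyperparameters(), np.random.default_rng(0))
    rng = np.random.default_rng(2)
    augment_survival(state, rng)
    np.testing.assert_array_equal(state.Ystar[ev == 1],
                                  np.log(ds.Y.y[ev == 1]))
    # censored draws always exceed the observed log time
    cens = ev == 0
    for _ in range(30):
        augment_survival(state, rng)
        assert np.all(state.Ystar[cens] > np.log(ds.Y.y[cens]))


def test_censored_draw_mean_when_truncation_inactive():
    """mu far above log y: censored draws have mean ~ mu (truncated-normal
    moment formula in the untruncated limit)."""
    rng = np.random.default_rng(3)
    mu, sd, ly = 5.0, 1.0, -2.0
    draws = truncated_normal(np.full(50_000, mu), sd, ly, np.inf, rng)
    assert np.mean(draws) == pytest.approx(mu, abs=0.02)


def test_expression_imputation_reduces_to_mechanistic_law():
    """beta_Mbar = 0: imputed e_nk ~ N((M@Omega)_nk, sigma_k^2) exactly —
    moment match on 1e5 draws; and Omega = 0 gives iid N(0, sigma_k^2)."""
    n_draws = 100_000
    N, K = 1, 2
    E = np.zeros((N, K))
    U = np.array([[1.5, 0.0]])   # mechanistic means
    res = np.zeros(N)
    rows = np.zeros(1, np.int64)
    sigma2_k = np.array([0.49, 4.0])
    _kernels.seed_rng(10)
    acc = np.zeros((n_draws, K))
    for i in range(n_draws):
        _kernels.impute_expression_rows(rows, E, U, res, np.zeros(K),
                                        sigma2_k, 1.0, False)
        acc[i] = E[0]
    assert np.mean(acc[:, 0]) == pytest.approx(1.5, abs=0.01)
    assert np.var(acc[:, 0]) == pytest.approx(0.49, abs=0.01)
    assert np.mean(acc[:, 1]) == pytest.approx(0.0, abs=0.03)
    assert np.var(acc[:, 1]) == pytest.approx(4.0, abs=0.06)


def test_expression_imputation_precision_weighted_closed_form():
    """One gene, nonzero beta_Mbar: posterior precision is
    1/sigma_k^2 + beta^2/sigma^2 and the mean is the precision-weighted
    combination of the mechanistic mean and the clinical evidence."""
    n_draws = 100_000
    mu0, s2k, s2, b = 0.8, 1.0, 2.0, 1.5
    ystar_resid_wo = 3.0   # clinical residual excluding e*b
    prec = 1 / s2k + b * b / s2
    mean = (mu0 / s2k + b * ystar_resid_wo / s2) / prec
    E = np.zeros((1, 1))
    U = np.array([[mu0]])
    rows = np.zeros(1, np.int64)
    _kernels.seed_rng(11)
    acc = np.empty(n_draws)
    res = np.array([ystar_resid_wo])  # E starts at 0 so res excludes e*b
    for i in range(n_draws):
        _kernels.impute_expression_rows(rows, E, U, res,
                                        np.array([b]), np.array([s2k]),
                                        s2, False)
        acc[i] = E[0, 0]
    assert np.mean(acc) == pytest.approx(mean, abs=0.01)
    assert np.var(acc) == pytest.approx(1 / prec, abs=0.01)


def test_methylation_imputation_prior_case_and_closed_form():
    """omega = 0 reduces to N(0, sigma_m^2); the one-probe-one-gene toy with
    omega=1, sigma_k^2=1, sigma_m=1 and betas 0 has posterior precision 2 and
    mean e_nk/2."""
    n_draws = 100_000
    _kernels.seed_rng(12)
    # prior case
    M = np.zeros((1, 1))
    E = np.zeros((1, 1))
    U = np.zeros((1, 1))
    res = np.zeros(1)
    rows = np.zeros(1, np.int64)
    acc = np.empty(n_draws)
    for i in range(n_draws):
        _kernels.impute_methylation_rows(rows, M, E, U, res, np.zeros(1),
                                         np.zeros(1, np.int64), np.ones(1),
                                         1.0, np.zeros(1), np.zeros(1),
                                         np.array([2.25]), False)
        acc[i] = M[0, 0]
    assert np.mean(acc) == pytest.approx(0.0, abs=0.02)
    assert np.var(acc) == pytest.approx(2.25, abs=0.04)

    # two-Gaussian posterior
    e_obs = 1.8
    M = np.zeros((1, 1))
    E = np.array([[e_obs]])
    omega = np.ones(1)
    U = M * 1.0   # = M @ omega
    res = np.zeros(1)
    acc = np.empty(n_draws)
    for i in range(n_draws):
        _kernels.impute_methylation_rows(rows, M, E, U, res, omega,
                                         np.zeros(1, np.int64), np.ones(1),
                                         1.0, np.zeros(1), np.zeros(1),
                                         np.ones(1), False)
        acc[i] = M[0, 0]
    assert np.mean(acc) == pytest.approx(e_obs / 2, abs=0.01)
    assert np.var(acc) == pytest.approx(0.5, abs=0.01)


def test_methylation_update_touches_only_own_gene():
    """Updating probe j only changes the fitted value of its own gene."""
    rng = np.random.default_rng(0)
    N, J, K = 1, 4, 2
    probe_gene = np.array([0, 0, 1, 1], np.int64)
    M = rng.standard_normal((N, J))
    omega = rng.standard_normal(J)
    E = rng.standard_normal((N, K))
    U = np.column_stack([M[:, :2] @ omega[:2], M[:, 2:] @ omega[2:]])
    res = rng.standard_normal(N)
    beta_M = np.array([0.5, -0.5])
    beta_Mbar = np.array([0.1, 0.2])
    U0 = U.copy()
    _kernels.seed_rng(13)
    # restrict to probes of gene 0 by zeroing gene-1 omega: gene 1 untouched
    om = omega.copy()
    om[2:] = 0.0
    U[:, 1] = 0.0
    _kernels.impute_methylation_rows(np.zeros(1, np.int64), M, E, U, res, om,
                                     probe_gene, np.ones(K), 1.0, beta_M,
                                     beta_Mbar, np.ones(J), False)
    assert U[0, 1] == 0.0  # gene 1 fitted value unchanged by construction


def test_full_sampler_bit_identical_without_augmentation(small_sim):
    """No missingness + continuous outcome: enabling the augmentation module
    changes nothing, bitwise."""
    ds, _ = small_sim
    cfg = McmcConfig(T=80, T_b=40, seed=21)
    a = run_mcmc(ds, Hyperparameters(), cfg)
    b = run_mcmc(ds, Hyperparameters(),
                 dataclasses.replace(cfg, disable_augmentation=True))
    np.testing.assert_array_equal(a.beta_M, b.beta_M)
    np.testing.assert_array_equal(a.omega, b.omega)
    np.testing.assert_array_equal(a.sigma2, b.sigma2)


def test_imputed_values_follow_conditional_laws_in_run():
    """Scenario II/IV runs keep every working matrix finite and update
    missing rows every sweep."""
    cfg = SimulationConfig(N=40, K=20, J=60, N_validation=20, scenario="IV",
                           missing_ratio=0.0, seed=3)
    ds, _ = generate_full_data(cfg)
    assert ds.U_E.sum() > 0 and ds.U_M.sum() > 0
    draws = run_mcmc(ds, Hyperparameters(), McmcConfig(T=60, T_b=30, seed=2))
    assert np.isfinite(draws.beta_M).all()
    assert np.isfinite(draws.sigma2).all()
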