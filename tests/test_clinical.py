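"""Clinical layer: MRF prior arithmetic and the four-way gene-effect update,
checked against exhaustive enumeration with betas integrated analytically."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mrfomics import GeneNetwork, _kernels
from mrfomics.clinical import (mrf_conditional_logit,
                               mrf_conditional_probability,
                               mrf_joint_log_prior)


def _net(K, edges=()):
    A = np.zeros((K, K), np.int8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return GeneNetwork(A)


def test_isolated_node_prior_probability():
    """No neighbours: inclusion probability is exp(d)/(1+exp(d)) — about
    0.05 at d=-3 and 0.02 at d=-4."""
    net = _net(3)
    p3 = mrf_conditional_probability(0, np.zeros(3), net, -3.0, 0.5)
    assert p3 == pytest.approx(math.exp(-3) / (1 + math.exp(-3)))
    assert round(p3, 2) == 0.05
    p4 = mrf_conditional_probability(0, np.zeros(3), net, -4.0, 0.5)
    assert round(p4, 2) == 0.02


def test_f_zero_reduces_to_bernoulli():
    net = _net(4, [(0, 1), (1, 2), (2, 3)])
    gamma = np.array([1, 1, 1, 1])
    for k in range(4):
        p = mrf_conditional_probability(k, gamma, net, -2.0, 0.0)
        assert p == pytest.approx(math.exp(-2) / (1 + math.exp(-2)))


def test_two_active_neighbours_logit():
    """d=-3, f=0.5 with two included neighbours: logit -2, probability
    1/(1+e^2) ~ 0.1192."""
    net = _net(3, [(0, 1), (0, 2)])
    gamma = np.array([0, 1, 1])
    assert mrf_conditional_logit(0, gamma, net, -3.0, 0.5) == pytest.approx(-2.0)
    assert mrf_conditional_probability(0, gamma, net, -3.0, 0.5) == \
        pytest.approx(1 / (1 + math.e ** 2), rel=1e-6)


def test_joint_prior_trivia():
    net = _net(5, [(0, 1)])
    assert mrf_joint_log_prior(np.zeros(5), net, -3.0, 0.5) == 0.0
    # flipping an isolated gene changes the joint by exactly d
    g = np.zeros(5)
    g[4] = 1
    assert mrf_joint_log_prior(g, net, -3.0, 0.5) == pytest.approx(-3.0)


@pytest.mark.parametrize("K,edges", [
    (4, [(0, 1), (1, 2)]),
    (6, [(0, 1), (0, 2), (3, 4), (4, 5), (2, 3)]),
])
def test_conditional_consistent_with_joint_ratios(K, edges):
    """The logistic MRF conditionals must equal the ratio of joint prior
    values over all 2^K states."""
    net = _net(K, edges)
    d, f = -2.5, 0.7
    for state in itertools.product([0, 1], repeat=K):
        g = np.array(state, float)
        for k in range(K):
            g1, g0 = g.copy(), g.copy()
            g1[k], g0[k] = 1, 0
            ratio = mrf_joint_log_prior(g1, net, d, f) - \
                mrf_joint_log_prior(g0, net, d, f)
            assert ratio == pytest.approx(
                mrf_conditional_logit(k, g, net, d, f), abs=1e-10)


# ---------------------------------------------------------------------------
# enumeration oracle for the gene-effect update
# ---------------------------------------------------------------------------

def _clinical_posterior_oracle(y, U, W, net, d, f, tau, sigma2, alloc):
    """Exact posterior over all (gamma_M, gamma_Mbar) configurations for K
    genes, active betas integrated analytically:
    y | config ~ N(0, sigma2 (I + D D'/tau)) with D the active columns."""
    K = U.shape[1]
    N = y.size
    configs = list(itertools.product([0, 1], repeat=2 * K))
    logw = np.empty(len(configs))
    la = np.log(alloc)
    for i, cfg in enumerate(configs):
        gM = np.array(cfg[:K])
        gMb = np.array(cfg[K:])
        gor = (gM | gMb).astype(float)
        lp = mrf_joint_log_prior(gor, net, d, f)
        for k in range(K):
            if gor[k]:
                lp += la[gM[k] * 1 + gMb[k] * 2 - 1]  # 10 -> 0, 01 -> 1, 11 -> 2
        cols = [U[:, k] for k in range(K) if gM[k]] + \
               [W[:, k] for k in range(K) if gMb[k]]
        if cols:
            D = np.column_stack(cols)
            cov = sigma2 * (np.eye(N) + D @ D.T / tau)
        else:
            cov = sigma2 * np.eye(N)
        lp += stats.multivariate_normal.logpdf(y, np.zeros(N), cov)
        logw[i] = lp
    w = np.exp(logw - logw.max())
    return {c: wi for c, wi in zip(configs, w / w.sum())}


@pytest.mark.parametrize("f,edges", [(0.0, []), (0.8, [(0, 1)])])
def test_gene_effect_gibbs_matches_enumeration(f, edges):
    """Long-run frequencies of the four-way gene-effect Gibbs update match
    exhaustive enumeration (K=2, N=8, TV < 0.02), without and with the MRF
    edge coupling the two genes."""
    rng = np.random.default_rng(7)
    N, K = 8, 2
    U = rng.standard_normal((N, K))
    W = rng.standard_normal((N, K))
    y = 1.2 * U[:, 0] - 1.0 * W[:, 1] + 0.6 * rng.standard_normal(N)
    d, tau, sigma2 = -1.5, 1.0, 0.36
    net = _net(K, edges)
    alloc = (1 / 3, 1 / 3, 1 / 3)
    exact = _clinical_posterior_oracle(y, U, W, net, d, f, tau, sigma2, alloc)

    E = U + W  # kernel sees E and U; W = E - U
    beta_M = np.zeros(K)
    beta_Mbar = np.zeros(K)
    gamma_M = np.zeros(K, np.int8)
    gamma_Mbar = np.zeros(K, np.int8)
    nbr_idx = np.concatenate([np.where(net.adjacency[k])[0]
                              for k in range(K)]).astype(np.int64) \
        if net.adjacency.any() else np.empty(0, np.int64)
    nbr_off = np.concatenate(
        ([0], np.cumsum(net.adjacency.sum(1)))).astype(np.int64)
    res = y.copy()
    la = math.log(1 / 3)
    _kernels.seed_rng(123)
    counts: dict = {}
    n_sweeps = 50_000
    for _ in range(n_sweeps):
        for k in range(K):
            _kernels.clin_gene_update(k, E, U, res, beta_M, beta_Mbar,
                                      gamma_M, gamma_Mbar, nbr_idx, nbr_off,
                                      d, f, tau, sigma2, la, la, la)
        key = tuple(gamma_M) + tuple(gamma_Mbar)
        counts[key] = counts.get(key, 0) + 1
    tv = 0.5 * sum(abs(counts.get(c, 0) / n_sweeps - p)
                   for c, p in exact.items())
    assert tv < 0.02, tv


def test_prior_dominated_limit_empties_model():
    """Zero-signal data with very negative d: both indicators end up 0 with
    probability near 1, and the coefficients are exactly 0."""
    rng = np.random.default_rng(1)
    N = 30
    U = rng.standard_normal((N, 1))
    W = rng.standard_normal((N, 1))
    y = rng.standard_normal(N)
    E = U + W
    beta_M = np.zeros(1)
    beta_Mbar = np.zeros(1)
    gamma_M = np.ones(1, np.int8)
    gamma_Mbar = np.ones(1, np.int8)
    res = y - U[:, 0] * 0 - W[:, 0] * 0
    _kernels.seed_rng(3)
    la = math.log(1 / 3)
    on = 0
    for _ in range(2000):
        _kernels.clin_gene_update(0, E, U, res, beta_M, beta_Mbar, gamma_M,
                                  gamma_Mbar, np.empty(0, np.int64),
                                  np.zeros(2, np.int64), -12.0, 0.5, 1.0, 1.0,
                                  la, la, la)
        on += int(gamma_M[0] or gamma_Mbar[0])
    assert on / 2000 < 0.01
    assert beta_M[0] == 0.0 and beta_Mbar[0] == 0.0


def test_or_consistency_in_draws(fitted_small):
    """gamma stored per draw is the elementwise OR of the two indicators —
    and beta support matches indicators in every draw."""
    _, _, draws = fitted_small
    on = (draws.gamma_M == 1) | (draws.gamma_Mbar == 1)
    sizes = draws.gamma_M.sum(1) + draws.gamma_Mbar.sum(1)
    np.testing.assert_array_equal(sizes, draws.model_size)
    assert np.all((draws.beta_M != 0) == (draws.gamma_M == 1))
    assert np.all((draws.beta_Mbar != 0) == (draws.gamma_Mbar == 1))
    assert on.dtype == bool


def test_beta_c_posterior_mean_is_ridge_shrunk_ls(small_sim):
    """With no active genes and a centred latent outcome, the beta_C draw
    centres on the ridge-shrunk least-squares solution."""
    from mrfomics import Hyperparameters
    from mrfomics.clinical import update_beta_C_and_sigma2
    from mrfomics.state import ModelState
    ds, _ = small_sim
    h = Hyperparameters(tau_c=0.01)
    state = ModelState(ds, h, np.random.default_rng(0))
    C = ds.C
    target = np.linalg.solve(C.T @ C + h.tau_c * np.eye(C.shape[1]),
                             C.T @ state.Ystar)
    rng = np.random.default_rng(5)
    acc = np.zeros(C.shape[1])
    n = 3000
    for _ in range(n):
        # reset residual so each draw sees the same conditional
        state.res = state.Ystar - C @ state.beta_C
        update_beta_C_and_sigma2(state, rng, update_sigma2=False)
        acc += state.beta_C
    np.testing.assert_allclose(acc / n, target, atol=0.05)


def test_binary_outcome_fixes_sigma2(small_sim):
    """Probit identifiability: sigma2 is exactly 1 in every stored draw."""
    import dataclasses
    from mrfomics import (Hyperparameters, McmcConfig, OutcomeSpec,
                          MultiOmicsDataset, run_mcmc)
    ds, _ = small_sim
    ybin = (ds.Y.y > np.median(ds.Y.y)).astype(float)
    dsb = MultiOmicsDataset(list(ds.sample_ids), OutcomeSpec("binary", ybin),
                            ds.C, ds.E, ds.M, ds.U_E, ds.U_M, ds.probe_map,
                            ds.network, list(ds.covariate_names))
    draws = run_mcmc(dsb, Hyperparameters(), McmcConfig(T=60, T_b=30, seed=1))
    assert np.all(draws.sigma2 == 1.0)
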