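"""Mechanistic layer: expression decomposition and probe-indicator Gibbs
updates, checked against independent closed-form / enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mrfomics import _kernels, mechanistic


def _marginal_logpdf_oracle(Ek, r, X, active, s2k, s2, bk, tau_k):
    """Independent oracle: log p(E_k, r | active set) with omega integrated
    out, evaluated as one multivariate normal density of the stacked data
    vector.  Slab variance is s2k / tau_k (it scales with sigma_k^2)."""
    N = Ek.size
    XS = X[:, np.asarray(active, bool)]
    c = s2k / tau_k
    G = XS @ XS.T
    top = np.hstack([s2k * np.eye(N) + c * G, bk * c * G])
    bot = np.hstack([bk * c * G, s2 * np.eye(N) + bk * bk * c * G])
    cov = np.vstack([top, bot])
    return stats.multivariate_normal.logpdf(np.concatenate([Ek, r]),
                                            mean=np.zeros(2 * N), cov=cov)


def _config_posterior_oracle(Ek, r, X, s2k, s2, bk, tau_k, pi):
    """Exact posterior over all 2^p active-set configurations."""
    p = X.shape[1]
    logw = []
    for cfg in itertools.product([0, 1], repeat=p):
        act = np.array(cfg, bool)
        lp = act.sum() * np.log(pi) + (p - act.sum()) * np.log(1 - pi)
        lp += _marginal_logpdf_oracle(Ek, r, X, act, s2k, s2, bk, tau_k)
        logw.append(lp)
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def test_decompose_identity_and_zero_case(small_sim):
    ds, truth = small_sim
    J, K = ds.n_probes, ds.n_genes
    Om = np.zeros((J, K))
    E_M, E_Mbar = mechanistic.decompose_expression(ds.E, ds.M, Om)
    assert not E_M.any()
    np.testing.assert_array_equal(E_Mbar, ds.E)
    # identity design: single nonzero entry picks out one methylation column
    M = np.eye(2)
    Om2 = np.zeros((2, 2))
    Om2[0, 0] = 0.5
    E_M2, _ = mechanistic.decompose_expression(np.ones((2, 2)), M, Om2)
    np.testing.assert_allclose(E_M2[:, 0], [0.5, 0.0])


def test_decompose_conservation_exact(fitted_small):
    ds, _, draws = fitted_small
    # rebuild E^M from a stored draw; conservation must hold bitwise
    om = draws.omega[-1]
    Om = np.zeros((ds.n_probes, ds.n_genes))
    Om[np.arange(ds.n_probes), ds.probe_map.probe_gene] = om
    E_M, E_Mbar = mechanistic.decompose_expression(ds.E, ds.M, Om)
    assert np.max(np.abs(ds.E - E_M - E_Mbar)) == 0.0


def test_marginal_likelihood_matches_mvn_oracle():
    """The collapsed marginal used by the z update equals the stacked
    multivariate-normal density up to configuration-independent constants."""
    rng = np.random.default_rng(3)
    N, p = 6, 3
    X = rng.standard_normal((N, p))
    Ek = rng.standard_normal(N)
    r = rng.standard_normal(N)
    s2k, s2, bk, tau_k = 0.8, 1.3, 0.6, 1.0
    Gk = X.T @ X
    xe, xr = X.T @ Ek, X.T @ r
    configs = list(itertools.product([0, 1], repeat=p))
    mine = np.array([
        _kernels._logml_subset(Gk, xe, xr, np.array(c, bool), s2k, s2, bk, tau_k)
        for c in configs])
    oracle = np.array([
        _marginal_logpdf_oracle(Ek, r, X, c, s2k, s2, bk, tau_k)
        for c in configs])
    # differences relative to the empty configuration must agree exactly
    np.testing.assert_allclose(mine - mine[0], oracle - oracle[0],
                               rtol=1e-9, atol=1e-9)


@pytest.mark.parametrize("bk", [0.0, 0.7])
def test_gibbs_z_matches_enumeration_oracle(bk):
    """Long-run single-site Gibbs frequencies over z-configurations match the
    exhaustive-enumeration posterior (TV < 0.02), with and without the
    clinical-likelihood coupling."""
    rng = np.random.default_rng(42)
    N, p = 6, 3
    X = rng.standard_normal((N, p))
    w_true = np.array([1.0, 0.0, -0.8])
    Ek = X @ w_true + 0.5 * rng.standard_normal(N)
    Ystar = bk * (X @ w_true) + rng.standard_normal(N)
    s2k, s2, tau_k, pi = 0.5, 1.0, 1.0, 0.4

    M = X.copy()
    E = Ek[:, None].copy()
    U = np.zeros((N, 1))
    z = np.zeros(1 * p, np.int8)
    omega = np.zeros(p)
    pi_k = np.array([pi])
    sigma2_k = np.array([s2k])
    beta_M = np.array([bk])
    beta_Mbar = np.array([0.0])
    gene_probes = np.arange(p, dtype=np.int64)
    gene_off = np.array([0, p], np.int64)
    res = Ystar.copy()   # U=0, beta_C absent

    _kernels.seed_rng(99)
    n_sweeps = 50_000
    counts = np.zeros(2 ** p)
    for _ in range(n_sweeps):
        _kernels.mech_gene_update(
            0, M, E, U, res, z, omega, pi_k, sigma2_k, beta_M, beta_Mbar,
            1.0, gene_probes, gene_off, tau_k, 0.2, 0.8, 0.001, 0.001,
            True, True, False, False)
        counts[int(z[0]) * 4 + int(z[1]) * 2 + int(z[2])] += 1
    freq = counts / n_sweeps

    exact = _config_posterior_oracle(Ek, Ystar, X, s2k, 1.0, bk, tau_k, pi)
    tv = 0.5 * np.abs(freq - exact).sum()
    assert tv < 0.02, (freq, exact)


def test_strong_signal_single_probe_inclusion():
    """One probe, |corr(E_k, M_j)| near 1 at N=100: posterior inclusion
    probability of z must exceed 0.99 (closed-form Bernoulli odds)."""
    rng = np.random.default_rng(0)
    N = 100
    x = rng.standard_normal(N)
    Ek = 1.0 * x + 0.05 * rng.standard_normal(N)
    X = x[:, None]
    post = _config_posterior_oracle(Ek, np.zeros(N), X, 0.05 ** 2, 1.0,
                                    0.0, 1.0, 0.5)
    assert post[1] > 0.99
    # and the kernel agrees: Gibbs inclusion frequency also > 0.99
    _kernels.seed_rng(1)
    z = np.zeros(1, np.int8)
    omega = np.zeros(1)
    incl = 0
    E = Ek[:, None].copy()
    U = np.zeros((N, 1))
    res = np.zeros(N)
    for _ in range(500):
        _kernels.mech_gene_update(
            0, X.copy(), E, U, res, z, omega, np.array([0.5]),
            np.array([0.05 ** 2]), np.zeros(1), np.zeros(1), 1.0,
            np.zeros(1, np.int64), np.array([0, 1], np.int64),
            1.0, 0.2, 0.8, 0.001, 0.001, True, True, False, False)
        incl += int(z[0])
    assert incl / 500 > 0.99


def test_pi_limit_forces_empty_model():
    """pi_k -> 0 drives all z to 0 and omega exactly to 0 (Dirac spike)."""
    rng = np.random.default_rng(2)
    N, p = 20, 3
    X = rng.standard_normal((N, p))
    Ek = X @ np.array([1.0, 1.0, 1.0])
    _kernels.seed_rng(5)
    z = np.ones(p, np.int8)
    omega = rng.standard_normal(p)
    E = Ek[:, None].copy()
    U = (X @ omega)[:, None]
    res = np.zeros(N)
    _kernels.mech_gene_update(
        0, X, E, U, res, z, omega, np.array([1e-12]), np.array([1.0]),
        np.zeros(1), np.zeros(1), 1.0, np.arange(p, dtype=np.int64),
        np.array([0, p], np.int64), 1.0, 0.2, 0.8, 0.001, 0.001,
        True, True, False, False)
    assert z.sum() == 0
    assert np.all(omega == 0.0)


def test_update_pi_conjugate_counting(fitted_small):
    """pi_k ~ Beta(a + sum z, b + |J_k| - sum z): long-run mean of draws
    matches the Beta mean for a frozen z configuration."""
    ds, _, _ = fitted_small
    from mrfomics.state import ModelState
    from mrfomics import Hyperparameters
    state = ModelState(ds, Hyperparameters(a=0.2, b=0.8),
                       np.random.default_rng(0))
    k = 0
    jidx = state.gene_probes[state.gene_off[k]:state.gene_off[k + 1]]
    state.z[jidx[0]] = 1
    s, p = 1, jidx.size
    np.random.seed(11)
    draws = []
    for _ in range(4000):
        mechanistic.update_pi(state, k)
        draws.append(state.pi_k[k])
    expect = (0.2 + s) / (0.2 + 0.8 + p)
    se = np.std(draws) / np.sqrt(len(draws))
    assert abs(np.mean(draws) - expect) < 4 * se + 1e-3


def test_update_sigma2k_conjugate_moments(fitted_small):
    """With Omega = 0 and E_k = 0 the sigma_k^2 conditional is
    InvGamma(delta1 + N/2, delta2); check the long-run mean."""
    ds, _, _ = fitted_small
    from mrfomics.state import ModelState
    from mrfomics import Hyperparameters
    h = Hyperparameters(delta1=3.0, delta2=2.0)
    state = ModelState(ds, h, np.random.default_rng(0))
    state.E[:, 0] = 0.0
    state.omega[:] = 0.0
    state.U[:, 0] = 0.0
    np.random.seed(12)
    vals = [
        (mechanistic.update_sigma2_k(state, 0), state.sigma2_k[0])[1]
        for _ in range(4000)
    ]
    shape, rate = 3.0 + state.N / 2, 2.0
    expect = rate / (shape - 1)
    se = np.std(vals) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - expect) < 4 * se + 1e-3


def test_dirac_exactness_after_full_run(fitted_small):
    """Bitwise zero coefficients wherever the indicator is off, in every
    stored draw."""
    _, _, draws = fitted_small
    assert np.all(draws.omega[draws.z == 0] == 0.0)
    assert np.all(draws.beta_M[draws.gamma_M == 0] == 0.0)
    assert np.all(draws.beta_Mbar[draws.gamma_Mbar == 0] == 0.0)
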