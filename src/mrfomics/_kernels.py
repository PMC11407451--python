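"""Compiled Gibbs-sweep kernels.

These are the hot loops of the sampler: single-site updates of the probe
indicators z_jk with the coefficient vector integrated out, the four-way
enumeration of the gene-effect indicator pair (gamma_M, gamma_Mbar), and the
per-cell imputation of block-missing omics rows.  Everything operates on flat
numpy arrays; the Python-facing state objects live in the sibling modules.

Randomness comes from numba's internal np.random stream — call ``seed_rng``
once per run for bit-reproducibility.

The residual convention used throughout: ``res = Ystar - F`` where
``F = C @ beta_C + E @ beta_Mbar + U @ (beta_M - beta_Mbar)`` and
``U = M @ Omega`` is the methylation-regulated expression part (so that
E^M = U and E^Mbar = E - U).  Every kernel keeps ``res`` and ``U`` exactly in
sync with the state it mutates.
"""

import numpy as np
from numba import njit

_EXP_CLIP = 50.0


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _logml_subset(Gk, xe, xr, act, s2k, s2, bk, tau_k):
    """Log marginal likelihood of (E_k, clinical residual) for the active
    probe subset ``act``, with omega integrated out analytically.

    Both the mechanistic Gaussian likelihood (variance s2k) and the clinical
    one (variance s2, coefficient bk = beta_M - beta_Mbar) share the Gram
    matrix Gk = X'X, so the posterior precision is
    A = (1/s2k + bk^2/s2) * Gk_S + (tau_k/s2k) * I.
    Terms constant across subsets are dropped.
    """
    p = act.shape[0]
    q = 0
    for t in range(p):
        if act[t]:
            q += 1
    if q == 0:
        return 0.0
    idx = np.empty(q, np.int64)
    c = 0
    for t in range(p):
        if act[t]:
            idx[c] = t
            c += 1
    cc = 1.0 / s2k + bk * bk / s2
    lam = tau_k / s2k
    A = np.empty((q, q))
    v = np.empty(q)
    for a in range(q):
        ia = idx[a]
        v[a] = xe[ia] / s2k + bk * xr[ia] / s2
        for b in range(q):
            A[a, b] = cc * Gk[ia, idx[b]]
        A[a, a] += lam
    L = np.linalg.cholesky(A)
    logdet = 0.0
    for a in range(q):
        logdet += 2.0 * np.log(L[a, a])
    m = np.linalg.solve(A, v)
    quad = 0.0
    for a in range(q):
        quad += v[a] * m[a]
    return 0.5 * q * np.log(lam) - 0.5 * logdet + 0.5 * quad


@njit(cache=True)
def mech_gene_update(k, M, E, U, res, z, omega, pi_k, sigma2_k,
                     beta_M, beta_Mbar, sigma2,
                     gene_probes, gene_off, tau_k, a_pi, b_pi,
                     delta1, delta2, coupled,
                     update_z, update_pi, update_var):
    """Gibbs update of gene k's mechanistic block: (z_.k, omega_.k, pi_k,
    sigma_k^2).  Single-site z moves with omega integrated out; active omega
    redrawn from its conjugate multivariate normal; inactive entries exactly 0
    (Dirac spike).  ``coupled`` includes the clinical likelihood term (the
    outcome depends on M@Omega through beta_M - beta_Mbar)."""
    N = M.shape[0]
    lo, hi = gene_off[k], gene_off[k + 1]
    p = hi - lo
    jidx = gene_probes[lo:hi]
    X = np.empty((N, p))
    for t in range(p):
        jj = jidx[t]
        for n in range(N):
            X[n, t] = M[n, jj]
    Gk = X.T @ X
    Ek = np.empty(N)
    for n in range(N):
        Ek[n] = E[n, k]
    xe = X.T @ Ek
    bk = (beta_M[k] - beta_Mbar[k]) if coupled else 0.0
    u = np.empty(N)
    r = np.empty(N)
    for n in range(N):
        u[n] = U[n, k]
        r[n] = res[n] + bk * u[n]
    xr = X.T @ r
    s2k = sigma2_k[k]
    pik = pi_k[k]

    act = np.empty(p, np.bool_)
    for t in range(p):
        act[t] = z[jidx[t]] == 1

    if update_z:
        lpi = np.log(pik)
        lqi = np.log(1.0 - pik)
        for t in range(p):
            act[t] = True
            l1 = _logml_subset(Gk, xe, xr, act, s2k, sigma2, bk, tau_k) + lpi
            act[t] = False
            l0 = _logml_subset(Gk, xe, xr, act, s2k, sigma2, bk, tau_k) + lqi
            diff = l0 - l1
            if diff > _EXP_CLIP:
                pr1 = 0.0
            elif diff < -_EXP_CLIP:
                pr1 = 1.0
            else:
                pr1 = 1.0 / (1.0 + np.exp(diff))
            act[t] = np.random.random() < pr1
        for t in range(p):
            z[jidx[t]] = 1 if act[t] else 0

    # redraw omega on the active set from its conjugate normal full conditional
    q = 0
    for t in range(p):
        if act[t]:
            q += 1
    w_full = np.zeros(p)
    if q > 0:
        idx = np.empty(q, np.int64)
        c = 0
        for t in range(p):
            if act[t]:
                idx[c] = t
                c += 1
        cc = 1.0 / s2k + bk * bk / sigma2
        lam = tau_k / s2k
        A = np.empty((q, q))
        v = np.empty(q)
        for a in range(q):
            ia = idx[a]
            v[a] = xe[ia] / s2k + bk * xr[ia] / sigma2
            for b in range(q):
                A[a, b] = cc * Gk[ia, idx[b]]
            A[a, a] += lam
        L = np.linalg.cholesky(A)
        mpost = np.linalg.solve(A, v)
        zdraw = np.random.standard_normal(q)
        pert = np.linalg.solve(L.T, zdraw)
        for a in range(q):
            w_full[idx[a]] = mpost[a] + pert[a]
    for t in range(p):
        omega[jidx[t]] = w_full[t]

    u_new = X @ w_full
    for n in range(N):
        res[n] += bk * (u[n] - u_new[n])
        U[n, k] = u_new[n]

    if update_pi:
        pi_k[k] = np.random.beta(a_pi + q, b_pi + p - q)

    if update_var:
        rss = 0.0
        for n in range(N):
            d = Ek[n] - u_new[n]
            rss += d * d
        w2 = 0.0
        for t in range(p):
            w2 += w_full[t] * w_full[t]
        shape = delta1 + 0.5 * (N + q)
        rate = delta2 + 0.5 * rss + 0.5 * tau_k * w2
        sigma2_k[k] = rate / np.random.gamma(shape, 1.0)


@njit(cache=True)
def mech_sweep(M, E, U, res, z, omega, pi_k, sigma2_k, beta_M, beta_Mbar,
               sigma2, gene_probes, gene_off, tau_k, a_pi, b_pi,
               delta1, delta2, coupled, update_z, update_pi, update_var):
    K = gene_off.shape[0] - 1
    for k in range(K):
        mech_gene_update(k, M, E, U, res, z, omega, pi_k, sigma2_k,
                         beta_M, beta_Mbar, sigma2, gene_probes, gene_off,
                         tau_k, a_pi, b_pi, delta1, delta2, coupled,
                         update_z, update_pi, update_var)


@njit(cache=True)
def mrf_log_odds(k, gamma_M, gamma_Mbar, nbr_idx, nbr_off, d, f):
    """Log-odds of gene-level inclusion gamma_k = gamma_M[k] OR gamma_Mbar[k]
    under the MRF conditional: d + f * (number of included neighbours)."""
    s = 0
    for t in range(nbr_off[k], nbr_off[k + 1]):
        k2 = nbr_idx[t]
        if gamma_M[k2] == 1 or gamma_Mbar[k2] == 1:
            s += 1
    return d + f * s


@njit(cache=True)
def clin_gene_update(k, E, U, res, beta_M, beta_Mbar, gamma_M, gamma_Mbar,
                     nbr_idx, nbr_off, d, f, tau, sigma2,
                     la10, la01, la11):
    """Gibbs update of gene k's clinical block by enumerating the four
    (gamma_M, gamma_Mbar) configurations with the active betas integrated out.

    Prior weights: the MRF conditional acts on the OR of the pair; the three
    active configurations share the gene-in-model probability with
    log-allocation weights la10/la01/la11."""
    N = E.shape[0]
    u = np.empty(N)
    w = np.empty(N)
    s = np.empty(N)
    bM = beta_M[k]
    bMb = beta_Mbar[k]
    uu = 0.0
    ww = 0.0
    uw = 0.0
    us = 0.0
    ws = 0.0
    for n in range(N):
        un = U[n, k]
        wn = E[n, k] - un
        sn = res[n] + un * bM + wn * bMb
        u[n] = un
        w[n] = wn
        s[n] = sn
        uu += un * un
        ww += wn * wn
        uw += un * wn
        us += un * sn
        ws += wn * sn

    eta = mrf_log_odds(k, gamma_M, gamma_Mbar, nbr_idx, nbr_off, d, f)
    if eta > _EXP_CLIP:
        lp1, lp0 = 0.0, -eta
    elif eta < -_EXP_CLIP:
        lp1, lp0 = eta, 0.0
    else:
        lse = np.log1p(np.exp(-np.abs(eta)))
        lp1 = -lse if eta > 0 else eta - lse
        lp0 = -eta - lse if eta > 0 else -lse

    A1 = uu + tau
    A2 = ww + tau
    det = A1 * A2 - uw * uw
    lm10 = 0.5 * np.log(tau) - 0.5 * np.log(A1) + us * us / (2.0 * sigma2 * A1)
    lm01 = 0.5 * np.log(tau) - 0.5 * np.log(A2) + ws * ws / (2.0 * sigma2 * A2)
    quad11 = (A2 * us * us - 2.0 * uw * us * ws + A1 * ws * ws) / det
    lm11 = np.log(tau) - 0.5 * np.log(det) + quad11 / (2.0 * sigma2)

    logw = np.empty(4)
    logw[0] = lp0
    logw[1] = lp1 + la10 + lm10
    logw[2] = lp1 + la01 + lm01
    logw[3] = lp1 + la11 + lm11
    mx = logw[0]
    for c in range(1, 4):
        if logw[c] > mx:
            mx = logw[c]
    tot = 0.0
    for c in range(4):
        logw[c] = np.exp(logw[c] - mx)
        tot += logw[c]
    udraw = np.random.random() * tot
    cum = 0.0
    cfg = 3
    for c in range(4):
        cum += logw[c]
        if udraw < cum:
            cfg = c
            break

    new_bM = 0.0
    new_bMb = 0.0
    if cfg == 1:
        new_bM = us / A1 + np.sqrt(sigma2 / A1) * np.random.standard_normal()
        gamma_M[k], gamma_Mbar[k] = 1, 0
    elif cfg == 2:
        new_bMb = ws / A2 + np.sqrt(sigma2 / A2) * np.random.standard_normal()
        gamma_M[k], gamma_Mbar[k] = 0, 1
    elif cfg == 3:
        m1 = (A2 * us - uw * ws) / det
        m2 = (A1 * ws - uw * us) / det
        # covariance sigma2 * A^{-1}; 2x2 Cholesky by hand
        S11 = sigma2 * A2 / det
        S12 = -sigma2 * uw / det
        S22 = sigma2 * A1 / det
        l11 = np.sqrt(S11)
        l21 = S12 / l11
        l22 = np.sqrt(max(S22 - l21 * l21, 1e-300))
        z1 = np.random.standard_normal()
        z2 = np.random.standard_normal()
        new_bM = m1 + l11 * z1
        new_bMb = m2 + l21 * z1 + l22 * z2
        gamma_M[k], gamma_Mbar[k] = 1, 1
    else:
        gamma_M[k], gamma_Mbar[k] = 0, 0
    beta_M[k] = new_bM
    beta_Mbar[k] = new_bMb
    for n in range(N):
        res[n] = s[n] - u[n] * new_bM - w[n] * new_bMb


@njit(cache=True)
def clin_sweep(E, U, res, beta_M, beta_Mbar, gamma_M, gamma_Mbar,
               nbr_idx, nbr_off, d, f, tau, sigma2, la10, la01, la11):
    K = E.shape[1]
    for k in range(K):
        clin_gene_update(k, E, U, res, beta_M, beta_Mbar, gamma_M, gamma_Mbar,
                         nbr_idx, nbr_off, d, f, tau, sigma2, la10, la01, la11)


@njit(cache=True)
def impute_expression_rows(rows, E, U, res, beta_Mbar, sigma2_k, sigma2,
                           modular):
    """Impute block-missing expression rows cell by cell.

    The full conditional of e_nk combines the mechanistic mean (M@Omega)_nk
    (variance sigma_k^2) with the clinical likelihood through beta_Mbar[k];
    with ``modular`` (or beta_Mbar[k] = 0) it reduces exactly to the
    mechanistic law.  Genes are updated sequentially per subject because all
    of a subject's expression values share one clinical observation."""
    K = E.shape[1]
    for i in range(rows.shape[0]):
        n = rows[i]
        for k in range(K):
            mu0 = U[n, k]
            s2k = sigma2_k[k]
            bmb = beta_Mbar[k]
            beff = 0.0 if modular else bmb
            e_old = E[n, k]
            rres = res[n] + e_old * bmb
            prec = 1.0 / s2k + beff * beff / sigma2
            mean = (mu0 / s2k + beff * (rres if not modular else 0.0) / sigma2) / prec
            e_new = mean + np.random.standard_normal() / np.sqrt(prec)
            E[n, k] = e_new
            res[n] = rres - e_new * bmb


@njit(cache=True)
def impute_methylation_rows(rows, M, E, U, res, omega, probe_gene,
                            sigma2_k, sigma2, beta_M, beta_Mbar, sigma_m2,
                            modular):
    """Impute block-missing methylation rows probe by probe.

    The full conditional of m_nj combines the N(0, sigma_m_j^2) prior, the
    mechanistic likelihood of the observed expression of the probe's gene
    (coefficient omega_j), and the clinical likelihood (coefficient
    omega_j * (beta_M - beta_Mbar)).  With ``modular`` or omega_j = 0 it
    reduces to the prior.  Since probes map many-to-one, probe j only touches
    gene probe_gene[j]'s residual."""
    J = M.shape[1]
    for i in range(rows.shape[0]):
        n = rows[i]
        for j in range(J):
            k = probe_gene[j]
            wj = omega[j]
            bk = beta_M[k] - beta_Mbar[k]
            m_old = M[n, j]
            if modular:
                prec = 1.0 / sigma_m2[j]
                lin = 0.0
            else:
                e_res = E[n, k] - U[n, k] + m_old * wj
                rres = res[n] + m_old * wj * bk
                cb = wj * bk
                prec = 1.0 / sigma_m2[j] + wj * wj / sigma2_k[k] + cb * cb / sigma2
                lin = wj * e_res / sigma2_k[k] + cb * rres / sigma2
            m_new = lin / prec + np.random.standard_normal() / np.sqrt(prec)
            dm = m_new - m_old
            M[n, j] = m_new
            U[n, k] += dm * wj
            res[n] -= dm * wj * bk
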