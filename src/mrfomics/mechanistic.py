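"""First model layer: spike-and-slab regression of each gene's expression on
its promoter methylation probes.

Expression decomposes as E = E^M + E^Mbar with E^M = M @ Omega.  Each
candidate probe effect omega_jk carries a Dirac spike-and-slab prior

    omega_jk | z_jk, sigma_k^2 ~ (1 - z_jk) * delta_0 + z_jk * N(0, sigma_k^2 / tau_k),

so inactive coefficients are exactly zero.  Indicators are updated by
single-site Gibbs with the coefficient vector integrated out analytically;
because the outcome depends on M@Omega (through beta_M - beta_Mbar), the
marginal likelihood includes both the mechanistic and the clinical Gaussian
terms unless the two-stage ``modular_mechanistic`` mode is requested.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .state import ModelState

__all__ = ["decompose_expression", "update_probe_indicators", "update_pi",
           "update_sigma2_k", "probe_marginal_loglik"]


def decompose_expression(E: np.ndarray, M: np.ndarray, Omega: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Split expression into the methylation-regulated part and the rest.

    Returns ``(E_M, E_Mbar)`` with ``E_M = M @ Omega`` and
    ``E_Mbar = E - E_M``; the identity ``E_M + E_Mbar == E`` holds exactly.
    """
    E = np.asarray(E, float)
    M = np.asarray(M, float)
    Omega = np.asarray(Omega, float)
    if M.shape[1] != Omega.shape[0] or Omega.shape[1] != E.shape[1] \
            or M.shape[0] != E.shape[0]:
        raise ValueError("dimension mismatch between E, M and Omega")
    E_M = M @ Omega
    return E_M, E - E_M


def probe_marginal_loglik(state: ModelState, k: int, active: np.ndarray,
                          coupled: bool = True) -> float:
    """Log marginal likelihood (up to config-independent constants) of gene
    k's data for a given active-probe configuration, omega integrated out.

    Exposed for oracle tests; the single-site update uses the same kernel.
    """
    lo, hi = state.gene_off[k], state.gene_off[k + 1]
    jidx = state.gene_probes[lo:hi]
    X = state.M[:, jidx]
    Gk = X.T @ X
    Ek = state.E[:, k]
    bk = (state.beta_M[k] - state.beta_Mbar[k]) if coupled else 0.0
    r = state.res + bk * state.U[:, k]
    return float(_kernels._logml_subset(
        Gk, X.T @ Ek, X.T @ r, np.asarray(active, bool),
        state.sigma2_k[k], state.sigma2, bk, state.hyper.tau_k))


def update_probe_indicators(state: ModelState, k: int,
                            coupled: bool = True) -> None:
    """Resample z_.k single-site and redraw omega_.k from its conjugate
    normal full conditional (inactive entries set exactly to 0)."""
    h = state.hyper
    _kernels.mech_gene_update(
        k, state.M, state.E, state.U, state.res, state.z, state.omega,
        state.pi_k, state.sigma2_k, state.beta_M, state.beta_Mbar,
        state.sigma2, state.gene_probes, state.gene_off,
        h.tau_k, h.a, h.b, h.delta1, h.delta2, coupled,
        True, False, False)


def update_pi(state: ModelState, k: int) -> None:
    """Conjugate Beta draw: pi_k ~ Beta(a + sum z, b + |J_k| - sum z)."""
    h = state.hyper
    lo, hi = state.gene_off[k], state.gene_off[k + 1]
    s = int(state.z[state.gene_probes[lo:hi]].sum())
    p = hi - lo
    state.pi_k[k] = np.random.beta(h.a + s, h.b + p - s)


def update_sigma2_k(state: ModelState, k: int) -> None:
    """Inverse-gamma full conditional for the mechanistic noise variance.

    Shape delta1 + (N + q_k)/2 and rate delta2 + ||E_k - M w_k||^2/2
    + tau_k ||w_k||^2 / 2, since the slab variance scales with sigma_k^2.
    """
    h = state.hyper
    lo, hi = state.gene_off[k], state.gene_off[k + 1]
    jidx = state.gene_probes[lo:hi]
    w = state.omega[jidx]
    q = int(state.z[jidx].sum())
    rss = float(np.sum((state.E[:, k] - state.U[:, k]) ** 2))
    shape = h.delta1 + 0.5 * (state.N + q)
    rate = h.delta2 + 0.5 * rss + 0.5 * h.tau_k * float(w @ w)
    state.sigma2_k[k] = rate / np.random.gamma(shape, 1.0)
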