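"""Second model layer: outcome regression on clinical covariates and the two
expression components, with an MRF network prior on gene inclusion.

    Ystar = C beta_C + E^M beta_M + E^Mbar beta_Mbar + eps,  eps ~ N(0, sigma2 I)

Gene effects carry Dirac spike-and-slab priors whose indicators
(gamma_M, gamma_Mbar) are coupled through the Markov-random-field prior on
the gene-level OR, gamma_k = gamma_M_k OR gamma_Mbar_k:

    p(gamma_k | gamma_-k) = logistic(d + f * sum_{k' in N_k} gamma_k').

d < 0 encourages sparsity; f >= 0 rewards selecting network neighbours
jointly.  The joint prior is defined (up to its intractable normalizing
constant) so that these conditionals are exactly its full conditionals.
Keep f small: large values of the smoothness parameter can cross the MRF
phase transition and flood the model.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .datasets import GeneNetwork
from .state import ModelState

__all__ = ["mrf_conditional_logit", "mrf_conditional_probability",
           "mrf_joint_log_prior", "update_gene_effects",
           "update_beta_C_and_sigma2"]


def mrf_conditional_logit(k: int, gamma: np.ndarray, net: GeneNetwork,
                          d: float, f: float) -> float:
    """Log-odds of including gene k given the other indicators:
    d + f * (number of included neighbours).  Position k of ``gamma`` is
    ignored."""
    nbrs = net.neighbors(k)
    return float(d + f * np.sum(np.asarray(gamma)[nbrs]))


def mrf_conditional_probability(k: int, gamma: np.ndarray, net: GeneNetwork,
                                d: float, f: float) -> float:
    """Conditional prior inclusion probability: the logistic transform of the
    conditional log-odds.  For an isolated node this is exp(d)/(1+exp(d))."""
    eta = mrf_conditional_logit(k, gamma, net, d, f)
    return float(1.0 / (1.0 + np.exp(-eta)))


def mrf_joint_log_prior(gamma: np.ndarray, net: GeneNetwork,
                        d: float, f: float) -> float:
    """Unnormalized joint log prior d * sum(gamma) + f * (edges within the
    included set), i.e. each undirected edge counted once, so that the
    conditional log-odds of flipping one gene is exactly
    ``mrf_conditional_logit``.  Only differences are ever used."""
    g = np.asarray(gamma, float)
    A = net.adjacency.astype(float)
    return float(d * g.sum() + 0.5 * f * g @ A @ g)


def update_gene_effects(state: ModelState, k: int) -> None:
    """Resample (gamma_M, gamma_Mbar, beta_M, beta_Mbar) for gene k by
    enumerating the four indicator configurations with the active betas
    integrated out; active betas are then redrawn from their conditional
    normal, inactive set exactly to 0."""
    h = state.hyper
    la = np.log(np.maximum(h.alloc, 1e-300))
    _kernels.clin_gene_update(
        k, state.E, state.U, state.res, state.beta_M, state.beta_Mbar,
        state.gamma_M, state.gamma_Mbar, state.nbr_idx, state.nbr_off,
        h.d, h.f, h.tau, state.sigma2, la[0], la[1], la[2])


def update_beta_C_and_sigma2(state: ModelState, rng: np.random.Generator,
                             update_sigma2: bool = True) -> None:
    """Joint conjugate normal draw of beta_C, then the inverse-gamma draw of
    sigma2 (skipped for binary outcomes, where sigma2 is fixed at 1).

    The sigma2 conditional has shape delta1 + (N + q)/2 with q counting every
    coefficient whose slab scales with sigma2 (active betas plus beta_C) and
    rate delta2 + RSS/2 + (tau * ||beta_active||^2 + tau_c * ||beta_C||^2)/2.
    """
    h = state.hyper
    C = state.ds.C
    partial = state.res + C @ state.beta_C      # Ystar minus the omics part
    A = C.T @ C + h.tau_c * np.eye(C.shape[1])
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, C.T @ partial)
    pert = np.linalg.solve(L.T, rng.standard_normal(C.shape[1]))
    state.beta_C = mean + np.sqrt(state.sigma2) * pert
    state.res = partial - C @ state.beta_C

    if not update_sigma2:
        return
    q = C.shape[1] + int(state.gamma_M.sum() + state.gamma_Mbar.sum())
    quad = (h.tau * float(state.beta_M @ state.beta_M
                          + state.beta_Mbar @ state.beta_Mbar)
            + h.tau_c * float(state.beta_C @ state.beta_C))
    shape = h.delta1 + 0.5 * (state.N + q)
    rate = h.delta2 + 0.5 * float(state.res @ state.res) + 0.5 * quad
    state.sigma2 = float(rate / rng.gamma(shape, 1.0))
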