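"""Data augmentation: block-missing omics rows and latent outcomes.

Block-missing rows of E and M are imputed each sweep from their full
conditionals (see `_kernels`); binary outcomes get a probit latent variable
(Y_n = 1 iff Y*_n > 0, with sigma2 fixed at 1 for identifiability) and
right-censored survival outcomes follow an accelerated-failure-time scheme on
the log-time scale: Y*_n = log y_n exactly for events, and a draw from
N(mu_n, sigma2) truncated to (log y_n, inf) for censored records.

Truncated-normal draws use scipy's inverse-CDF implementation, which is
numerically robust far into the tails.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import _kernels
from .state import ModelState

__all__ = ["impute_missing_expression", "impute_missing_methylation",
           "augment_binary", "augment_survival", "truncated_normal"]


def truncated_normal(mu, sd, lower, upper, rng: np.random.Generator) -> np.ndarray:
    """Vectorized draw from N(mu, sd^2) truncated to (lower, upper)."""
    mu = np.asarray(mu, float)
    a = (np.asarray(lower, float) - mu) / sd
    b = (np.asarray(upper, float) - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)


def impute_missing_expression(state: ModelState, modular: bool = False) -> None:
    """Redraw every expression cell of rows with U_E = 1.

    The conditional mean precision-weights the mechanistic prediction
    (M@Omega)_nk (precision 1/sigma_k^2) against the clinical evidence through
    beta_Mbar_k (precision beta_Mbar_k^2 / sigma2).  With ``modular`` (or a
    zero coefficient) the draw is exactly N((M@Omega)_nk, sigma_k^2)."""
    if state.rows_E_mis.size == 0:
        return
    _kernels.impute_expression_rows(
        state.rows_E_mis, state.E, state.U, state.res, state.beta_Mbar,
        state.sigma2_k, state.sigma2, modular)


def impute_missing_methylation(state: ModelState, modular: bool = False) -> None:
    """Redraw every methylation cell of rows with U_M = 1.

    Combines the N(0, sigma_m_j^2) prior with the mechanistic likelihood of
    the observed expression of the probe's gene and the clinical likelihood;
    probes with omega_j = 0 (or ``modular``) reduce to the prior."""
    if state.rows_M_mis.size == 0:
        return
    _kernels.impute_methylation_rows(
        state.rows_M_mis, state.M, state.E, state.U, state.res, state.omega,
        state.probe_gene, state.sigma2_k, state.sigma2, state.beta_M,
        state.beta_Mbar, state.sigma_m2, modular)


def augment_binary(state: ModelState, rng: np.random.Generator) -> None:
    """Probit latent draw: Y*_n ~ N(mu_n, 1) truncated to (0, inf) when
    y_n = 1 and to (-inf, 0] when y_n = 0."""
    y = state.ds.Y.y
    mu = state.Ystar - state.res
    lower = np.where(y == 1, 0.0, -np.inf)
    upper = np.where(y == 1, np.inf, 0.0)
    new = truncated_normal(mu, 1.0, lower, upper, rng)
    state.res += new - state.Ystar
    state.Ystar = new


def augment_survival(state: ModelState, rng: np.random.Generator) -> None:
    """AFT latent draw on the log-time scale: events are deterministic
    (Y* = log y); censored records are drawn from N(mu_n, sigma2) truncated
    below at log y_n."""
    yspec = state.ds.Y
    cens = np.where(yspec.event == 0)[0]
    if cens.size == 0:
        return
    mu = (state.Ystar - state.res)[cens]
    sd = float(np.sqrt(state.sigma2))
    new = truncated_normal(mu, sd, np.log(yspec.y[cens]), np.inf, rng)
    state.res[cens] += new - state.Ystar[cens]
    state.Ystar[cens] = new
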