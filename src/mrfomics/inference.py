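"""Posterior summarization, feature selection, BMA prediction and metrics.

PPI (posterior probability of inclusion) is the fraction of kept MCMC draws
in which an indicator equals one.  The default selection rule is the median
probability model (PPI strictly greater than 0.5); alternatively a cutoff
controlling the Bayesian false discovery rate can be derived from the PPIs.
Predictions are Bayesian model averages of the per-iteration predictor

    yhat_i = C_new beta_C_i + (M_new Omega_i) beta_M_i
             + (E_new - M_new Omega_i) beta_Mbar_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines.utils import concordance_index
from scipy.special import ndtr
from sklearn.metrics import average_precision_score, roc_auc_score

from .datasets import OutcomeSpec
from .sampler import PosteriorDraws

__all__ = ["PosteriorSummary", "compute_ppi", "select_features",
           "bayesian_fdr_threshold", "predict_bma", "pmse",
           "feature_selection_auc", "c_index"]


@dataclass
class PosteriorSummary:
    """Posterior means, PPIs and selection flags for one fitted model."""

    gene_ids: list[str]
    probe_ids: list[str]
    probe_gene: np.ndarray
    covariate_names: list[str]
    threshold: float
    ppi_gamma_M: np.ndarray
    ppi_gamma_Mbar: np.ndarray
    ppi_z: np.ndarray
    beta_C_mean: np.ndarray
    beta_M_mean: np.ndarray
    beta_Mbar_mean: np.ndarray
    omega_mean: np.ndarray
    selected_M: np.ndarray
    selected_Mbar: np.ndarray
    predictions: np.ndarray | None = None
    metrics: dict = field(default_factory=dict)

    @property
    def ppi_gamma(self) -> np.ndarray:
        """PPI of the gene-level OR indicator is not the max of the two
        marginals in general; it is computed from the draws in compute_ppi
        and stored in metrics; this property returns the stored value."""
        return np.asarray(self.metrics["ppi_gamma_or"])


def compute_ppi(draws: PosteriorDraws, threshold: float = 0.5) -> PosteriorSummary:
    """Summarize kept draws: PPIs (indicator means across draws), posterior
    mean coefficients, and selection flags at ``threshold``."""
    if draws.n_kept == 0:
        raise ValueError("zero kept draws")
    ppi_M = draws.gamma_M.mean(axis=0)
    ppi_Mb = draws.gamma_Mbar.mean(axis=0)
    meta = draws.meta
    summary = PosteriorSummary(
        gene_ids=list(meta.get("gene_ids", map(str, range(ppi_M.size)))),
        probe_ids=list(meta.get("probe_ids", map(str, range(draws.z.shape[1])))),
        probe_gene=np.asarray(meta.get("probe_gene",
                                       np.zeros(draws.z.shape[1], int))),
        covariate_names=list(meta.get("covariate_names",
                                      map(str, range(draws.beta_C.shape[1])))),
        threshold=threshold,
        ppi_gamma_M=ppi_M,
        ppi_gamma_Mbar=ppi_Mb,
        ppi_z=draws.z.mean(axis=0),
        beta_C_mean=draws.beta_C.mean(axis=0),
        beta_M_mean=draws.beta_M.mean(axis=0),
        beta_Mbar_mean=draws.beta_Mbar.mean(axis=0),
        omega_mean=(draws.omega.mean(axis=0) if draws.omega is not None
                    else np.zeros(draws.z.shape[1])),
        selected_M=ppi_M > threshold,
        selected_Mbar=ppi_Mb > threshold,
    )
    summary.metrics["ppi_gamma_or"] = (draws.gamma_M | draws.gamma_Mbar
                                       ).mean(axis=0).tolist()
    summary.metrics["threshold"] = threshold
    return summary


def select_features(summary: PosteriorSummary, threshold: float = 0.5,
                    inclusive: bool = False) -> dict[str, list[str]]:
    """Gene selection sets at a PPI threshold.

    Default rule is strict (PPI > threshold), the median probability model at
    0.5.  ``inclusive`` switches to >=, the convention of the Bayesian-FDR
    cutoff.  Returns the only-M, only-Mbar and both-effects sets plus the
    selected probes.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    cmp = (lambda p: p >= threshold) if inclusive else (lambda p: p > threshold)
    selM = cmp(summary.ppi_gamma_M)
    selMb = cmp(summary.ppi_gamma_Mbar)
    genes = np.asarray(summary.gene_ids)
    probes = np.asarray(summary.probe_ids)
    return {
        "only_M": genes[selM & ~selMb].tolist(),
        "only_Mbar": genes[selMb & ~selM].tolist(),
        "both": genes[selM & selMb].tolist(),
        "probes": probes[cmp(summary.ppi_z)].tolist(),
    }


def bayesian_fdr_threshold(ppi: np.ndarray, alpha: float) -> float:
    """Smallest PPI cutoff t with estimated Bayesian FDR at most alpha.

    The estimator (Newton et al. 2004) for cutoff t is
    sum_k (1 - p_k) 1{p_k >= t} / #{p_k >= t}; selection at the returned
    cutoff is inclusive (p >= t).  Returns 1.0 when no cutoff qualifies
    (select nothing).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(ppi, float)
    best = 1.0
    for t in np.unique(p)[::-1]:
        sel = p >= t
        fdr = float(np.sum((1 - p)[sel]) / sel.sum())
        if fdr <= alpha:
            best = float(t)
        else:
            break
    return best


def predict_bma(draws: PosteriorDraws, C_new: np.ndarray, E_new: np.ndarray,
                M_new: np.ndarray, return_per_iteration: bool = False):
    """Bayesian-model-average prediction for complete new samples.

    Per kept draw i the prediction uses the identity
    yhat = C beta_C + E beta_Mbar + M (omega * (beta_M - beta_Mbar))_probe;
    the final prediction is the average across kept draws.  For binary
    outcomes the result is on the latent probit scale (apply a normal CDF for
    probabilities); for survival it is a predicted mean log-time.
    """
    if draws.omega is None:
        raise ValueError("omega draws were not stored; rerun with store_omega")
    C_new = np.atleast_2d(np.asarray(C_new, float))
    E_new = np.atleast_2d(np.asarray(E_new, float))
    M_new = np.atleast_2d(np.asarray(M_new, float))
    if np.isnan(E_new).any() or np.isnan(M_new).any():
        raise ValueError("new samples must have both omics blocks observed")
    probe_gene = np.asarray(draws.meta["probe_gene"], int)
    D = draws.n_kept
    per_iter = np.empty((D, C_new.shape[0]))
    for i in range(D):
        b = draws.beta_M[i] - draws.beta_Mbar[i]
        w = draws.omega[i] * b[probe_gene]
        per_iter[i] = (C_new @ draws.beta_C[i] + E_new @ draws.beta_Mbar[i]
                       + M_new @ w)
    yhat = per_iter.mean(axis=0)
    if return_per_iteration:
        return yhat, per_iter
    return yhat


def predict_probability(yhat: np.ndarray) -> np.ndarray:
    """Probit transform of latent-scale predictions for binary outcomes."""
    return ndtr(np.asarray(yhat, float))


def pmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-squared prediction error sqrt(sum (y - yhat)^2 / N_v)."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def feature_selection_auc(ppi: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based ROC AUC of PPI scores against a binary ground truth."""
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    return float(roc_auc_score(truth, np.asarray(ppi, float)))


def feature_selection_aucpr(ppi: np.ndarray, truth: np.ndarray) -> float:
    """Area under the precision-recall curve of PPI scores."""
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    return float(average_precision_score(truth, np.asarray(ppi, float)))


def c_index(y: OutcomeSpec, predicted_logtime: np.ndarray) -> float:
    """Harrell concordance over admissible pairs.

    Predictions are on the log-time scale: a larger predicted value means
    longer expected survival (lower risk); ties count one half.
    """
    if y.kind != "survival":
        raise ValueError("c_index requires a survival outcome")
    return float(concordance_index(y.y, np.asarray(predicted_logtime, float),
                                   y.event))
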