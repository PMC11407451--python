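"""Penalized-regression comparators and the five-fold decision scheme for
including incomplete subjects.

The *mimic* methods are two-stage analogues of the hierarchical model: stage
one fits each gene's expression on its own promoter probes by lasso or
elastic net (penalty by five-fold CV), giving Ehat^M = M @ What and
Ehat^Mbar = E - Ehat^M; stage two fits the outcome on
[C, Ehat^M, Ehat^Mbar] by the same penalized family.  The *vanilla* methods
regress the outcome on the concatenation [C, E, M] in one stage.

``fit_with_cv_arm_choice`` decides between fitting on all subjects (imputing
missing blocks) and fitting on complete cases only, by five-fold CV
stratified to preserve the missing ratio, scoring PMSE on complete-data
validation subjects only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.linear_model import ElasticNetCV, LassoCV

from .datasets import Hyperparameters, MultiOmicsDataset
from .inference import compute_ppi, pmse, predict_bma
from .sampler import McmcConfig, run_mcmc

logger = logging.getLogger("mrfomics")

__all__ = ["PenalizedFit", "fit_mimic_penalized", "fit_vanilla_penalized",
           "fit_with_cv_arm_choice"]

_ENET_L1_GRID = (0.1, 0.5, 0.7, 0.9, 0.95, 1.0)


def _make_cv_estimator(variant: str, seed: int):
    if variant == "lasso":
        return LassoCV(cv=5, alphas=50, random_state=seed, max_iter=5000)
    if variant == "enet":
        return ElasticNetCV(cv=5, alphas=50, l1_ratio=list(_ENET_L1_GRID),
                            random_state=seed, max_iter=5000)
    raise ValueError("variant must be 'lasso' or 'enet'")


@dataclass
class PenalizedFit:
    """Fitted two-stage (or one-stage) penalized predictor."""

    variant: str
    stage1_coef: np.ndarray | None   # (J,) per-probe weights, mimic only
    stage1_intercept: np.ndarray | None
    stage2_model: object
    probe_gene: np.ndarray | None
    mimic: bool

    def _decompose(self, E: np.ndarray, M: np.ndarray):
        EhatM = M @ self._omega_matrix(E.shape[1]) + self.stage1_intercept
        return EhatM, E - EhatM

    def _omega_matrix(self, K: int) -> np.ndarray:
        W = np.zeros((self.stage1_coef.size, K))
        W[np.arange(self.stage1_coef.size), self.probe_gene] = self.stage1_coef
        return W

    def predict(self, C: np.ndarray, E: np.ndarray, M: np.ndarray) -> np.ndarray:
        """Predict outcomes for complete new samples (C without the intercept
        column is accepted; an intercept is handled by the estimator)."""
        Cc = C[:, 1:] if np.allclose(C[:, 0], 1.0) else C
        if self.mimic:
            EhatM, EhatMbar = self._decompose(E, M)
            X = np.column_stack([Cc, EhatM, EhatMbar])
        else:
            X = np.column_stack([Cc, E, M])
        return self.stage2_model.predict(X)


def _training_response(ds: MultiOmicsDataset) -> np.ndarray:
    if ds.Y.kind == "survival":
        return np.log(ds.Y.y)   # crude AFT response for the comparators
    return ds.Y.y


def fit_mimic_penalized(ds: MultiOmicsDataset, variant: str = "enet",
                        seed: int = 0) -> PenalizedFit:
    """Two-stage penalized fit on complete-case rows."""
    cc = ds.complete_cases()
    y = _training_response(cc)
    J, K = cc.n_probes, cc.n_genes
    coef = np.zeros(J)
    intercepts = np.zeros(K)
    for k in range(K):
        cols = cc.probe_map.probes_of(k)
        X = cc.M[:, cols]
        if np.allclose(X.std(axis=0), 0):
            logger.info("gene %d: zero-variance probes, stage-1 coef 0", k)
            intercepts[k] = cc.E[:, k].mean()
            continue
        est = _make_cv_estimator(variant, seed)
        est.fit(X, cc.E[:, k])
        coef[cols] = est.coef_
        intercepts[k] = est.intercept_
    fit = PenalizedFit(variant, coef, intercepts, None,
                       cc.probe_map.probe_gene, mimic=True)
    EhatM, EhatMbar = fit._decompose(cc.E, cc.M)
    X2 = np.column_stack([cc.C[:, 1:], EhatM, EhatMbar])
    stage2 = _make_cv_estimator(variant, seed)
    stage2.fit(X2, y)
    fit.stage2_model = stage2
    return fit


def fit_vanilla_penalized(ds: MultiOmicsDataset, variant: str = "enet",
                          seed: int = 0) -> PenalizedFit:
    """One-stage penalized regression of the outcome on [C, E, M]."""
    cc = ds.complete_cases()
    X = np.column_stack([cc.C[:, 1:], cc.E, cc.M])
    est = _make_cv_estimator(variant, seed)
    est.fit(X, _training_response(cc))
    return PenalizedFit(variant, None, None, est, None, mimic=False)


def _stratified_missing_folds(ds: MultiOmicsDataset, n_folds: int,
                              rng: np.random.Generator) -> list[np.ndarray]:
    """Partition subjects into folds preserving the per-platform missing
    pattern counts as evenly as possible."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for group_mask in ((ds.U_E == 1), (ds.U_M == 1),
                       (ds.U_E == 0) & (ds.U_M == 0)):
        idx = np.where(group_mask)[0]
        idx = idx[rng.permutation(idx.size)]
        for i, n in enumerate(idx):
            folds[i % n_folds].append(int(n))
    return [np.sort(np.array(f, int)) for f in folds]


def fit_with_cv_arm_choice(ds: MultiOmicsDataset, hyper: Hyperparameters | None = None,
              cfg: McmcConfig | None = None, n_folds: int = 5,
              cv_T: int | None = None) -> dict:
    """Decide by five-fold CV whether incomplete subjects help, then refit.

    Per fold the model is trained on all remaining subjects (full arm) and on
    the complete-case remainder (CC arm); fold PMSE is computed on the
    fold's complete-data subjects only.  The arm with the smaller mean PMSE
    is refit on the full training data (ties prefer the full-data arm).
    Fold MCMC chains run at ``cv_T`` iterations (default T/2) to bound cost.
    """
    hyper = hyper or Hyperparameters()
    cfg = cfg or McmcConfig()
    if cv_T is None:
        cv_T = max(cfg.T // 2, 20)
    fold_cfg = replace(cfg, T=cv_T, T_b=cv_T // 2)
    rng = np.random.default_rng(cfg.seed)
    folds = _stratified_missing_folds(ds, n_folds, rng)
    all_rows = np.arange(ds.n_samples)

    fold_pmse = {"full": [], "cc": []}
    for f, val_rows in enumerate(folds):
        complete_val = val_rows[(ds.U_E[val_rows] == 0)
                                & (ds.U_M[val_rows] == 0)]
        if complete_val.size == 0:
            raise RuntimeError(
                f"fold {f} has no complete validation subjects; "
                f"fold sizes {[len(x) for x in folds]}, "
                f"missing E {int(ds.U_E.sum())}, M {int(ds.U_M.sum())}")
        train_rows = np.setdiff1d(all_rows, val_rows)
        train_full = ds.subset(train_rows)
        train_cc = train_full.complete_cases()
        val = ds.subset(complete_val)
        y_val = _training_response(val)
        for arm, tds in (("full", train_full), ("cc", train_cc)):
            draws = run_mcmc(tds, hyper, replace(fold_cfg, seed=cfg.seed + f))
            yhat = predict_bma(draws, val.C, val.E, val.M)
            fold_pmse[arm].append(pmse(y_val, yhat))

    mean_full = float(np.mean(fold_pmse["full"]))
    mean_cc = float(np.mean(fold_pmse["cc"]))
    chosen = "full" if mean_full <= mean_cc else "cc"
    if mean_full == mean_cc:
        logger.info("CV tie; preferring the full-data arm")
    final_ds = ds if chosen == "full" else ds.complete_cases()
    final_draws = run_mcmc(final_ds, hyper, cfg)
    return {
        "chosen": chosen,
        "fold_pmse": fold_pmse,
        "mean_pmse": {"full": mean_full, "cc": mean_cc},
        "draws": final_draws,
        "summary": compute_ppi(final_draws),
        "cv_T": cv_T,
    }
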