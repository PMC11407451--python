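"""Mutable MCMC model state shared by the two model layers.

Holds working copies of the omics matrices (block-missing rows are filled in
place by the imputation sweep), the latent outcome Y*, the current parameter
vectors, and the maintained quantities

* ``U = M @ Omega`` — the methylation-regulated expression component E^M,
* ``res = Ystar - (C@beta_C + E@beta_Mbar + U@(beta_M - beta_Mbar))``,

which every update keeps exactly in sync.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Hyperparameters, MultiOmicsDataset


@dataclass
class MechanisticState:
    """First-layer snapshot: probe effects and per-gene noise.

    ``omega``/``z`` are flat length-J vectors (each probe maps to exactly one
    gene, so the J×K matrix Omega has one structurally allowed entry per row);
    ``Omega`` materializes the matrix view.
    """

    omega: np.ndarray     # (J,)
    z: np.ndarray         # (J,) int8
    sigma2_k: np.ndarray  # (K,)
    pi_k: np.ndarray      # (K,)
    probe_gene: np.ndarray

    @property
    def Omega(self) -> np.ndarray:
        J = self.omega.shape[0]
        K = self.sigma2_k.shape[0]
        Om = np.zeros((J, K))
        Om[np.arange(J), self.probe_gene] = self.omega
        return Om


@dataclass
class ClinicalState:
    """Second-layer snapshot: clinical effects and selection indicators."""

    beta_C: np.ndarray
    beta_M: np.ndarray
    beta_Mbar: np.ndarray
    gamma_M: np.ndarray
    gamma_Mbar: np.ndarray
    sigma2: float

    @property
    def gamma(self) -> np.ndarray:
        """Gene-level inclusion: the elementwise OR of the two indicators."""
        return ((self.gamma_M == 1) | (self.gamma_Mbar == 1)).astype(np.int8)


class ModelState:
    """Full sampler state bound to one dataset + hyperparameter set."""

    def __init__(self, ds: MultiOmicsDataset, hyper: Hyperparameters,
                 rng: np.random.Generator):
        self.ds = ds
        self.hyper = hyper
        N, K, J = ds.n_samples, ds.n_genes, ds.n_probes
        self.N, self.K, self.J = N, K, J

        # probe map packed CSR-style: probe indices grouped by gene
        order = np.argsort(ds.probe_map.probe_gene, kind="stable")
        self.gene_probes = order.astype(np.int64)
        counts = np.bincount(ds.probe_map.probe_gene, minlength=K)
        self.gene_off = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        self.probe_gene = ds.probe_map.probe_gene.astype(np.int64)

        # network packed as neighbour lists
        A = ds.network.adjacency
        self.nbr_idx = np.concatenate([np.where(A[k] == 1)[0] for k in range(K)]
                                      ).astype(np.int64) if K else np.empty(0, np.int64)
        self.nbr_off = np.concatenate(([0], np.cumsum(A.sum(axis=1)))).astype(np.int64)

        self.rows_E_mis = np.where(ds.U_E == 1)[0].astype(np.int64)
        self.rows_M_mis = np.where(ds.U_M == 1)[0].astype(np.int64)

        # working data copies; missing rows start from their marginal laws
        self.M = ds.M.copy()
        self.E = ds.E.copy()
        self.sigma_m2 = np.full(J, hyper.sigma_m ** 2)
        if self.rows_M_mis.size:
            self.M[self.rows_M_mis] = rng.normal(
                0.0, hyper.sigma_m, (self.rows_M_mis.size, J))

        # parameters
        self.z = np.zeros(J, np.int8)
        self.omega = np.zeros(J)
        self.pi_k = np.full(K, hyper.a / (hyper.a + hyper.b))
        obs_E = ds.U_E == 0
        self.sigma2_k = np.maximum(np.var(ds.E[obs_E], axis=0), 1e-3) \
            if obs_E.any() else np.ones(K)
        self.beta_M = np.zeros(K)
        self.beta_Mbar = np.zeros(K)
        self.gamma_M = np.zeros(K, np.int8)
        self.gamma_Mbar = np.zeros(K, np.int8)

        # latent outcome
        y = ds.Y.y
        if ds.Y.kind == "continuous":
            self.Ystar = y.copy()
        elif ds.Y.kind == "binary":
            self.Ystar = np.where(y == 1, 1.0, -1.0)
        else:
            self.Ystar = np.log(y)

        # beta_C from least squares on C; sigma2 from its residual variance
        self.beta_C, *_ = np.linalg.lstsq(ds.C, self.Ystar, rcond=None)
        resid = self.Ystar - ds.C @ self.beta_C
        if ds.Y.kind == "binary":
            self.sigma2 = 1.0
        else:
            self.sigma2 = float(max(np.var(resid), 1e-3))

        if self.rows_E_mis.size:
            self.E[self.rows_E_mis] = rng.normal(
                0.0, np.sqrt(self.sigma2_k)[None, :], (self.rows_E_mis.size, K))

        self.U = np.zeros((N, K))   # M @ Omega with Omega = 0 initially
        self.res = self.Ystar - ds.C @ self.beta_C
        self.iteration = 0

    # -- derived views ------------------------------------------------------
    @property
    def mechanistic(self) -> MechanisticState:
        return MechanisticState(self.omega, self.z, self.sigma2_k, self.pi_k,
                                self.probe_gene)

    @property
    def clinical(self) -> ClinicalState:
        return ClinicalState(self.beta_C, self.beta_M, self.beta_Mbar,
                             self.gamma_M, self.gamma_Mbar, self.sigma2)

    @property
    def fitted(self) -> np.ndarray:
        """Linear predictor of the clinical model (Ystar - res)."""
        return self.Ystar - self.res

    def recompute_derived(self) -> None:
        """Rebuild U and res from scratch (consistency check / drift reset)."""
        for k in range(self.K):
            jidx = self.gene_probes[self.gene_off[k]:self.gene_off[k + 1]]
            self.U[:, k] = self.M[:, jidx] @ self.omega[jidx]
        F = (self.ds.C @ self.beta_C + self.E @ self.beta_Mbar
             + self.U @ (self.beta_M - self.beta_Mbar))
        self.res = self.Ystar - F

    def model_size(self) -> int:
        return int(self.gamma_M.sum() + self.gamma_Mbar.sum())
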