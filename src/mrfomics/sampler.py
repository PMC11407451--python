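"""MCMC orchestration: sweep ordering, burn-in/thinning, multi-chain runs,
draw storage and convergence diagnostics.

Each iteration performs, in order: (1) latent-outcome augmentation for
binary/survival responses, (2) imputation of block-missing omics rows,
(3) the mechanistic block per gene (z, omega, pi_k, sigma_k^2), (4) the
clinical block per gene (the four-way (gamma_M, gamma_Mbar) enumeration)
followed by beta_C and sigma2.  Runs are bit-deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
import zipfile
import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _kernels, augmentation, clinical
from .datasets import Hyperparameters, MultiOmicsDataset
from .state import ModelState

logger = logging.getLogger("mrfomics")

__all__ = ["McmcConfig", "PosteriorDraws", "run_mcmc", "run_chains",
           "cross_chain_ppi_correlation", "save_draws", "load_draws",
           "plot_traces"]


@dataclass
class McmcConfig:
    """Sampler settings.

    ``T`` total iterations, ``T_b`` burn-in, ``thin`` keep-every;
    ``modular_mechanistic`` drops the clinical-likelihood term from the
    z/omega updates (two-stage fit); ``modular_imputation`` restores the
    literal prior/mechanistic imputation laws.  The ``update_*`` switches
    freeze blocks for validation experiments.
    """

    T: int = 10000
    T_b: int = 5000
    thin: int = 1
    n_chains: int = 4
    seed: int = 0
    store_omega: bool = True
    modular_mechanistic: bool = False
    modular_imputation: bool = False
    disable_augmentation: bool = False
    update_mechanistic: bool = True
    update_clinical: bool = True
    update_pi: bool = True
    update_variances: bool = True
    update_beta_C: bool = True
    progress_every: int = 0
    recompute_every: int = 500

    def __post_init__(self) -> None:
        if not (0 <= self.T_b < self.T):
            raise ValueError("require 0 <= T_b < T")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return -((self.T - self.T_b) // -self.thin)  # ceil division


@dataclass
class PosteriorDraws:
    """Stored post-burn-in draws (one record per kept iteration)."""

    gamma_M: np.ndarray      # (D, K) int8
    gamma_Mbar: np.ndarray   # (D, K) int8
    z: np.ndarray            # (D, J) int8
    beta_C: np.ndarray       # (D, L)
    beta_M: np.ndarray       # (D, K)
    beta_Mbar: np.ndarray    # (D, K)
    sigma2: np.ndarray       # (D,)
    sigma2_k: np.ndarray     # (D, K)
    pi_k: np.ndarray         # (D, K)
    model_size: np.ndarray   # (D,)
    log_joint: np.ndarray    # (D,)
    omega: np.ndarray | None = None   # (D, J) when store_omega
    meta: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return self.gamma_M.shape[0]


def _log_joint(state: ModelState) -> float:
    h = state.hyper
    resid_E = state.E - state.U
    rss_k = np.sum(resid_E * resid_E, axis=0)
    lj = (-0.5 * state.N * np.log(state.sigma2)
          - 0.5 * float(state.res @ state.res) / state.sigma2
          - 0.5 * state.N * float(np.sum(np.log(state.sigma2_k)))
          - 0.5 * float(np.sum(rss_k / state.sigma2_k)))
    gam = (state.gamma_M | state.gamma_Mbar).astype(float)
    A = state.ds.network.adjacency.astype(float)
    lj += h.d * gam.sum() + 0.5 * h.f * float(gam @ A @ gam)
    return float(lj)


def run_mcmc(ds: MultiOmicsDataset, hyper: Hyperparameters | None = None,
             cfg: McmcConfig | None = None,
             initial_state: ModelState | None = None) -> PosteriorDraws:
    """Run one chain and return the kept draws.

    Deterministic given ``cfg.seed``; raises RuntimeError with a state
    summary on numerical failure (non-positive-definite precision).
    """
    hyper = hyper or Hyperparameters()
    cfg = cfg or McmcConfig()
    ss = np.random.SeedSequence(cfg.seed)
    numba_seed = int(ss.generate_state(1, np.uint32)[0])
    rng = np.random.default_rng(ss.spawn(1)[0])
    _kernels.seed_rng(numba_seed)

    state = initial_state if initial_state is not None \
        else ModelState(ds, hyper, rng)
    kind = ds.Y.kind
    N, K, J, L = state.N, state.K, state.J, ds.C.shape[1]
    D = cfg.n_kept
    draws = PosteriorDraws(
        gamma_M=np.empty((D, K), np.int8),
        gamma_Mbar=np.empty((D, K), np.int8),
        z=np.empty((D, J), np.int8),
        beta_C=np.empty((D, L)),
        beta_M=np.empty((D, K)),
        beta_Mbar=np.empty((D, K)),
        sigma2=np.empty(D),
        sigma2_k=np.empty((D, K)),
        pi_k=np.empty((D, K)),
        model_size=np.empty(D, np.int64),
        log_joint=np.empty(D),
        omega=np.empty((D, J)) if cfg.store_omega else None,
        meta={
            "gene_ids": list(ds.probe_map.gene_ids),
            "probe_ids": list(ds.probe_map.probe_ids),
            "probe_gene": ds.probe_map.probe_gene.tolist(),
            "covariate_names": list(ds.covariate_names),
            "outcome_kind": kind,
            "seed": cfg.seed,
            "T": cfg.T, "T_b": cfg.T_b, "thin": cfg.thin,
            "hyper": asdict(hyper),
        },
    )
    la = np.log(np.maximum(hyper.alloc, 1e-300))
    kept = 0
    try:
        for t in range(cfg.T):
            state.iteration = t
            if not cfg.disable_augmentation:
                if kind == "binary":
                    augmentation.augment_binary(state, rng)
                elif kind == "survival":
                    augmentation.augment_survival(state, rng)
                augmentation.impute_missing_expression(
                    state, cfg.modular_imputation)
                augmentation.impute_missing_methylation(
                    state, cfg.modular_imputation)
            if cfg.update_mechanistic:
                _kernels.mech_sweep(
                    state.M, state.E, state.U, state.res, state.z,
                    state.omega, state.pi_k, state.sigma2_k, state.beta_M,
                    state.beta_Mbar, state.sigma2, state.gene_probes,
                    state.gene_off, hyper.tau_k, hyper.a, hyper.b,
                    hyper.delta1, hyper.delta2,
                    not cfg.modular_mechanistic, True,
                    cfg.update_pi, cfg.update_variances)
            if cfg.update_clinical:
                _kernels.clin_sweep(
                    state.E, state.U, state.res, state.beta_M,
                    state.beta_Mbar, state.gamma_M, state.gamma_Mbar,
                    state.nbr_idx, state.nbr_off, hyper.d, hyper.f,
                    hyper.tau, state.sigma2, la[0], la[1], la[2])
            if cfg.update_beta_C:
                clinical.update_beta_C_and_sigma2(
                    state, rng,
                    update_sigma2=cfg.update_variances and kind != "binary")
            if cfg.recompute_every and (t + 1) % cfg.recompute_every == 0:
                state.recompute_derived()
            if t >= cfg.T_b and (t - cfg.T_b) % cfg.thin == 0:
                draws.gamma_M[kept] = state.gamma_M
                draws.gamma_Mbar[kept] = state.gamma_Mbar
                draws.z[kept] = state.z
                draws.beta_C[kept] = state.beta_C
                draws.beta_M[kept] = state.beta_M
                draws.beta_Mbar[kept] = state.beta_Mbar
                draws.sigma2[kept] = state.sigma2
                draws.sigma2_k[kept] = state.sigma2_k
                draws.pi_k[kept] = state.pi_k
                draws.model_size[kept] = state.model_size()
                draws.log_joint[kept] = _log_joint(state)
                if draws.omega is not None:
                    draws.omega[kept] = state.omega
                kept += 1
            if cfg.progress_every and (t + 1) % cfg.progress_every == 0:
                logger.info("iter %d/%d  model size %d  sigma2 %.3f",
                            t + 1, cfg.T, state.model_size(), state.sigma2)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"numerical failure at iteration {state.iteration}: {exc}; "
            f"model size {state.model_size()}, sigma2 {state.sigma2:.4g}, "
            f"min sigma2_k {state.sigma2_k.min():.4g}") from exc
    assert kept == D
    return draws


def run_chains(ds: MultiOmicsDataset, hyper: Hyperparameters | None = None,
               cfg: McmcConfig | None = None) -> list[PosteriorDraws]:
    """Run ``cfg.n_chains`` independent chains with per-chain seeds derived
    from ``cfg.seed``."""
    from dataclasses import replace
    cfg = cfg or McmcConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_chains,
                                                            np.uint32)
    return [run_mcmc(ds, hyper, replace(cfg, seed=int(s))) for s in seeds]


def cross_chain_ppi_correlation(runs: list[PosteriorDraws]) -> dict:
    """Pairwise Pearson correlations of PPI vectors between chains, for the
    gene-level indicators (the OR of gamma_M, gamma_Mbar) and for the probe
    indicators Z.  A constant PPI vector yields NaN entries."""
    if len(runs) < 2:
        raise ValueError("need at least two chains")

    def corr(vectors: list[np.ndarray]) -> np.ndarray:
        m = len(vectors)
        out = np.full((m, m), np.nan)
        for i in range(m):
            out[i, i] = 1.0
            for j in range(i + 1, m):
                vi, vj = vectors[i], vectors[j]
                if vi.std() == 0 or vj.std() == 0:
                    continue
                out[i, j] = out[j, i] = float(np.corrcoef(vi, vj)[0, 1])
        return out

    gam = [((r.gamma_M | r.gamma_Mbar)).mean(axis=0) for r in runs]
    zz = [r.z.mean(axis=0) for r in runs]
    return {"gamma": corr(gam), "z": corr(zz)}


def save_draws(draws: PosteriorDraws, path: str | Path) -> Path:
    """Store draws as a single compressed archive with a JSON manifest."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    arrays = {k: v for k, v in vars(draws).items()
              if isinstance(v, np.ndarray)}
    np.savez_compressed(path, **arrays)
    with zipfile.ZipFile(path, "a") as zf:
        zf.writestr("manifest.json", json.dumps(draws.meta, indent=2))
    return path


def load_draws(path: str | Path) -> PosteriorDraws:
    valid = {f.name for f in dataclasses.fields(PosteriorDraws)}
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files if k in valid}
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("manifest.json"))
    return PosteriorDraws(meta=meta, **arrays)


def plot_traces(draws: PosteriorDraws, path: str | Path) -> Path:
    """Write trace plots for sigma2, model size and the (unnormalized) log
    joint density — the standard convergence artifact."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(7, 7), sharex=True)
    for ax, (name, series) in zip(axes, [
            ("sigma^2", draws.sigma2),
            ("model size", draws.model_size),
            ("log joint (unnormalized)", draws.log_joint)]):
        ax.plot(series, lw=0.7)
        ax.set_ylabel(name)
    axes[-1].set_xlabel("kept iteration")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
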