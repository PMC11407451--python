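"""Synthetic multi-omics data with known ground truth.

The generator reproduces the simulation design the model is evaluated on:
N = 100 subjects with L = 3 standard-normal clinical covariates, J = 300
methylation probes randomly allocated to K genes (each gene gets at least
one probe; at J = 300, K = 100 the mean is 3 probes/gene), 50% of genes
methylation-regulated with probe indicators z ~ Bern(1/2) and probe effects
|w| ~ Unif(0.5, 1), residual expression E^Mbar ~ N(0, I), and 15
outcome-relevant genes: five with both effect types, five acting only
through the methylation-regulated part, five only through the residual part
(so gamma_M and gamma_Mbar each have exactly 10 ones).  Effective clinical
coefficients have |beta| ~ Unif(1, 1.5); covariate and intercept
coefficients are 1; outcome noise sd sigma is 1, 2 or 3.  The gene network
draws edges among the 15 effective genes iid Bern(0.1) and places the same
number of edges among ineffective genes.  Block missingness is injected
after the fact (scenarios II-IV).

Instead of resampling real 450k probes, methylation is generated as
within-gene blocks of exchangeably correlated Gaussians (default rho = 0.5)
and standardized per probe — a stated deviation that keeps the generator
self-contained; rho = 0 recovers independent probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import (GeneNetwork, MultiOmicsDataset, OutcomeSpec,
                       ProbeGeneMap)

__all__ = ["SimulationConfig", "SimulationTruth", "generate_full_data",
           "generate_network", "inject_missingness"]

N_EFFECTIVE = 15            # genes carrying any clinical effect
N_PER_EFFECT_GROUP = 5      # both / only-M / only-Mbar


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the stated simulation conditions."""

    N: int = 100
    L: int = 3
    K: int = 100
    J: int = 300
    sigma: float = 1.0           # clinical noise sd (1, 2 or 3)
    rho: float = 0.5             # within-gene probe correlation
    scenario: str = "I"          # I complete; II E-missing; III M-missing; IV both
    missing_ratio: float = 0.0   # II/III: fraction of subjects missing a block
    missing_split: float = 0.5   # IV: share of the missing half lacking E
    N_validation: int = 100
    outcome_kind: str = "continuous"
    censor_rate: float = 0.3     # survival only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < self.K:
            raise ValueError("need J >= K so every gene can receive a probe")
        if self.K < N_EFFECTIVE:
            raise ValueError(f"need K >= {N_EFFECTIVE} for the fixed "
                             "effective-gene layout")
        if not (0 <= self.missing_ratio < 1):
            raise ValueError("missing ratio must be in [0, 1)")
        if self.scenario not in ("I", "II", "III", "IV"):
            raise ValueError("scenario must be one of I, II, III, IV")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset (training portion)."""

    z: np.ndarray            # (J,) true probe indicators
    omega: np.ndarray        # (J,) true probe effects
    gamma_M: np.ndarray      # (K,)
    gamma_Mbar: np.ndarray   # (K,)
    beta_C: np.ndarray       # (L+1,) incl. intercept
    beta_M: np.ndarray       # (K,)
    beta_Mbar: np.ndarray    # (K,)
    regulated: np.ndarray    # (K,) 1 = methylation-regulated gene
    E_M: np.ndarray          # (N, K)
    E_Mbar: np.ndarray       # (N, K)
    network: GeneNetwork
    validation: MultiOmicsDataset | None = None
    extras: dict = field(default_factory=dict)

    @property
    def gamma(self) -> np.ndarray:
        return ((self.gamma_M == 1) | (self.gamma_Mbar == 1)).astype(np.int8)


def _signed_uniform(rng: np.random.Generator, low: float, high: float,
                    size: int) -> np.ndarray:
    """Unif(low, high) or Unif(-high, -low), sign by a fair coin."""
    mag = rng.uniform(low, high, size)
    sign = np.where(rng.random(size) < 0.5, 1.0, -1.0)
    return mag * sign


def generate_network(effective: np.ndarray, K: int,
                     rng: np.random.Generator,
                     edge_prob: float = 0.1) -> GeneNetwork:
    """Edges among effective genes iid Bern(edge_prob); then the same number
    of edges placed uniformly at random among ineffective genes (capped at
    capacity)."""
    A = np.zeros((K, K), np.int8)
    eff = np.asarray(effective, int)
    n_eff_edges = 0
    for a in range(len(eff)):
        for b in range(a + 1, len(eff)):
            if rng.random() < edge_prob:
                i, j = eff[a], eff[b]
                A[i, j] = A[j, i] = 1
                n_eff_edges += 1
    ineff = np.setdiff1d(np.arange(K), eff)
    m = len(ineff)
    capacity = m * (m - 1) // 2
    n_add = min(n_eff_edges, capacity)
    if n_add < n_eff_edges:  # pragma: no cover - tiny-K corner
        import logging
        logging.getLogger("mrfomics").warning(
            "ineffective-gene edge count capped at capacity %d", capacity)
    if n_add > 0:
        chosen = rng.choice(capacity, size=n_add, replace=False)
        pairs = [(a, b) for a in range(m) for b in range(a + 1, m)]
        for c in chosen:
            i, j = ineff[pairs[c][0]], ineff[pairs[c][1]]
            A[i, j] = A[j, i] = 1
    return GeneNetwork(A)


def _allocate_probes(K: int, J: int, rng: np.random.Generator) -> np.ndarray:
    """Each gene gets one probe; the rest are allocated uniformly."""
    probe_gene = np.empty(J, np.int64)
    probe_gene[:K] = np.arange(K)
    probe_gene[K:] = rng.integers(0, K, J - K)
    return probe_gene[rng.permutation(J)]


def _correlated_methylation(n: int, probe_gene: np.ndarray, rho: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Within-gene exchangeable-correlation Gaussian blocks, standardized per
    probe (sample mean 0, variance 1)."""
    J = probe_gene.size
    M = np.empty((n, J))
    K = probe_gene.max() + 1
    for k in range(K):
        cols = np.where(probe_gene == k)[0]
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, cols.size))
        M[:, cols] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
    M -= M.mean(axis=0)
    M /= M.std(axis=0)
    return M


def generate_full_data(cfg: SimulationConfig
                       ) -> tuple[MultiOmicsDataset, SimulationTruth]:
    """Simulate a complete training dataset plus ground truth (the complete
    validation dataset of ``cfg.N_validation`` samples from the same law is
    attached as ``truth.validation``); scenario II-IV missingness is then
    injected into the training data."""
    rng = np.random.default_rng(cfg.seed)
    N, K, J, L = cfg.N, cfg.K, cfg.J, cfg.L
    n_tot = N + cfg.N_validation

    probe_gene = _allocate_probes(K, J, rng)
    M = _correlated_methylation(n_tot, probe_gene, cfg.rho, rng)
    C = np.column_stack([np.ones(n_tot), rng.standard_normal((n_tot, L))])

    # effect layout: genes 0-4 both, 5-9 only type-M, 10-14 only type-Mbar
    gamma_M = np.zeros(K, np.int8)
    gamma_Mbar = np.zeros(K, np.int8)
    gamma_M[0:2 * N_PER_EFFECT_GROUP] = 1
    gamma_Mbar[0:N_PER_EFFECT_GROUP] = 1
    gamma_Mbar[2 * N_PER_EFFECT_GROUP:3 * N_PER_EFFECT_GROUP] = 1
    effective = np.arange(N_EFFECTIVE)

    # methylation-regulated genes: the type-M carriers must be regulated,
    # otherwise their effect would be vacuous; fill up to 50% at random
    regulated = np.zeros(K, np.int8)
    must = np.where(gamma_M == 1)[0]
    regulated[must] = 1
    pool = np.setdiff1d(np.arange(K), must)
    n_extra = max(K // 2 - must.size, 0)   # small K: carriers already exceed 50%
    if n_extra:
        extra = rng.choice(pool, size=n_extra, replace=False)
        regulated[extra] = 1

    z = np.zeros(J, np.int8)
    omega = np.zeros(J)
    forced = []
    for k in np.where(regulated == 1)[0]:
        cols = np.where(probe_gene == k)[0]
        zz = (rng.random(cols.size) < 0.5).astype(np.int8)
        if zz.sum() == 0:   # redraw once, else force one active probe
            zz = (rng.random(cols.size) < 0.5).astype(np.int8)
            if zz.sum() == 0:
                zz[rng.integers(0, cols.size)] = 1
                forced.append(int(k))
        z[cols] = zz
    active = np.where(z == 1)[0]
    omega[active] = _signed_uniform(rng, 0.5, 1.0, active.size)

    E_M = np.zeros((n_tot, K))
    for k in range(K):
        cols = np.where(probe_gene == k)[0]
        E_M[:, k] = M[:, cols] @ omega[cols]
    E_Mbar = rng.standard_normal((n_tot, K))   # sigma_k^2 = 1
    E = E_M + E_Mbar

    beta_C = np.ones(L + 1)
    beta_M = np.zeros(K)
    beta_Mbar = np.zeros(K)
    beta_M[gamma_M == 1] = _signed_uniform(rng, 1.0, 1.5, int(gamma_M.sum()))
    beta_Mbar[gamma_Mbar == 1] = _signed_uniform(rng, 1.0, 1.5,
                                                 int(gamma_Mbar.sum()))

    linpred = C @ beta_C + E_M @ beta_M + E_Mbar @ beta_Mbar
    ystar = linpred + cfg.sigma * rng.standard_normal(n_tot)
    if cfg.outcome_kind == "continuous":
        def outcome(rows):
            return OutcomeSpec("continuous", ystar[rows])
    elif cfg.outcome_kind == "binary":
        def outcome(rows):
            return OutcomeSpec("binary", (ystar[rows] > 0).astype(float))
    else:
        t = np.exp(ystar)
        # exponential censoring tuned to the requested marginal censor rate
        scale = np.quantile(t, 1 - cfg.censor_rate) / np.log(2.0)
        c = rng.exponential(scale, n_tot) + 1e-8
        yobs = np.minimum(t, c)
        event = (t <= c).astype(int)

        def outcome(rows):
            return OutcomeSpec("survival", yobs[rows], event[rows])

    network = generate_network(effective, K, rng)
    gene_ids = [f"g{k+1}" for k in range(K)]
    probe_ids = [f"cg{j+1:05d}" for j in range(J)]
    probe_map = ProbeGeneMap(probe_ids, gene_ids, probe_gene)

    def build(rows, tag):
        ids = [f"{tag}{i+1}" for i in range(rows.size)]
        return MultiOmicsDataset(
            ids, outcome(rows), C[rows], E[rows], M[rows],
            np.zeros(rows.size, np.int8), np.zeros(rows.size, np.int8),
            probe_map, network,
            ["intercept"] + [f"c{l+1}" for l in range(L)])

    train = build(np.arange(N), "s")
    validation = build(np.arange(N, n_tot), "v")

    truth = SimulationTruth(
        z=z, omega=omega, gamma_M=gamma_M, gamma_Mbar=gamma_Mbar,
        beta_C=beta_C, beta_M=beta_M, beta_Mbar=beta_Mbar,
        regulated=regulated, E_M=E_M[:N], E_Mbar=E_Mbar[:N],
        network=network, validation=validation,
        extras={"forced_active_probe_genes": forced,
                "linpred": linpred[:N]})

    if cfg.scenario != "I" and cfg.missing_ratio > 0 or cfg.scenario == "IV":
        train = inject_missingness(train, cfg.scenario, cfg.missing_ratio,
                                   cfg.missing_split,
                                   int(rng.integers(0, 2 ** 31)))
    return train, truth


def inject_missingness(ds: MultiOmicsDataset, scenario: str,
                       ratio: float = 0.0, split: float = 0.5,
                       seed: int = 0) -> MultiOmicsDataset:
    """Block-missingness injection.

    II: ``ratio`` of subjects lose their expression block; III: same for
    methylation; IV: half of all subjects lose exactly one block, a fraction
    ``split`` of them the expression block.  No subject ever loses both.
    """
    rng = np.random.default_rng(seed)
    N = ds.n_samples
    U_E = np.zeros(N, np.int8)
    U_M = np.zeros(N, np.int8)
    if scenario == "I":
        pass
    elif scenario in ("II", "III"):
        n_mis = int(round(ratio * N))
        rows = rng.choice(N, size=n_mis, replace=False)
        (U_E if scenario == "II" else U_M)[rows] = 1
    elif scenario == "IV":
        n_mis = N // 2
        rows = rng.choice(N, size=n_mis, replace=False)
        n_e = int(round(split * n_mis))
        U_E[rows[:n_e]] = 1
        U_M[rows[n_e:]] = 1
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if ((U_E == 1) & (U_M == 1)).any():
        raise ValueError("injection would leave a subject with no omics data")
    E = ds.E.copy()
    M = ds.M.copy()
    E[U_E == 1] = 0.0
    M[U_M == 1] = 0.0
    return MultiOmicsDataset(list(ds.sample_ids), ds.Y, ds.C, E, M, U_E, U_M,
                             ds.probe_map, ds.network,
                             list(ds.covariate_names))
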