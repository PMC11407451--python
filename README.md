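# mrfomics

Network-guided Bayesian integration of DNA methylation and gene expression
for biomarker selection and clinical outcome prediction, with support for
block-missing omics data and continuous, binary or right-censored survival
outcomes.

## Who this is for

Biostatisticians and computational biologists who have, for one cohort,
(a) a sample × gene expression matrix, (b) a sample × probe methylation
matrix (M-values) with a many-to-one probe→gene promoter map, (c) clinical
covariates and an outcome, and (d) a gene–gene interaction network (e.g.
pathway-derived), and who want to know *which genes drive the outcome, and
through which route* — while keeping subjects that are missing an entire
omics platform instead of throwing them away.

## The model

A two-layer hierarchical regression. The **mechanistic layer** splits each
gene's expression into a methylation-regulated part and a remainder:

    E = E^M + E^M̄,   E^M = M Ω,
    ω_jk | z_jk, σ_k² ~ (1 − z_jk) δ₀ + z_jk N(0, σ_k²/τ_k),   z_jk ~ Bern(π_k)

with π_k ~ Beta(a, b). The **clinical layer** regresses the (possibly
latent) outcome on covariates and the two expression components:

    Y* = C β^C + E^M β^M + E^M̄ β^M̄ + ε,   ε ~ N(0, σ² I),
    β_k^M | γ_k^M ~ (1 − γ_k^M) δ₀ + γ_k^M N(0, σ²/τ)      (same for M̄)

so a gene can act through methylation-driven expression (a *type M* effect,
β^M), through other regulation (*type M̄*, β^M̄), or both. The Dirac spikes
make unselected coefficients exactly zero. Gene-level inclusion
γ_k = γ_k^M ∨ γ_k^M̄ carries a Markov-random-field prior on the network:

    p(γ_k | γ_−k) = logistic(d + f Σ_{k′∈N_k} γ_{k′})

(d < 0 for sparsity, f ≥ 0 rewards selecting linked genes jointly).
Inference is a collapsed Gibbs sampler; binary outcomes use a probit latent
variable, survival outcomes an accelerated-failure-time latent log-time, and
subjects missing a whole omics block have that block imputed from its full
conditional every sweep (data augmentation). Selection is by posterior
probability of inclusion (PPI > 0.5, or a Bayesian-FDR-derived cutoff);
prediction is a Bayesian model average over kept draws.

## Worked example

`examples/simulate_and_fit.py` generates a synthetic cohort (N=100 samples,
K=100 genes, J=300 promoter probes, 15 outcome-relevant genes split 5/5/5
across effect types) and fits the model:

```
training data: 100 samples, 100 genes, 300 probes, 24 network edges
feature-selection AUC vs ground truth: 1.000 (1.0 = PPIs rank every true effect above every null)
selected at PPI>0.5 — only methylation-driven: ['g6', 'g7', 'g8', 'g9', 'g10'], only other-regulation: ['g11', 'g12', 'g13', 'g15'], both: ['g1', 'g2', 'g3', 'g4', 'g5', 'g14']
held-out PMSE 1.055 against outcome sd 5.182 — the model explains most outcome variance
```

The PPIs rank every truly effective gene above every null gene (AUC 1.0),
the three selection sets recover the generator's 5/5/5 effect layout almost
exactly, and held-out root-mean-square prediction error (1.06) approaches
the irreducible noise sd (1.0). The other examples each cover one
capability:

- `examples/network_prior_effect.py` — analytic MRF prior probabilities
  (isolated gene ≈ 0.05 at d=−3, ≈ 0.02 at d=−4) and the PPI lift the
  network prior gives truly effective genes;
- `examples/block_missing_data.py` — 50% of subjects missing methylation:
  augmented full-data fit vs complete-case fit, plus the five-fold CV rule
  that chooses between them;
- `examples/survival_outcome.py` — censored outcomes, concordance index;
- `examples/files_and_reports.py` — TSV input/output, validation report,
  Bayesian-FDR selection, result tables.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-derives the package's analytic reference quantities (the MRF prior
inclusion probabilities of an isolated gene at the two default sparsity
settings) by evaluating the model's own prior conditional, and writes them
as JSON.

## Layout

| module | contents |
|---|---|
| `mrfomics.datasets` | containers, TSV readers/writers, validation |
| `mrfomics.mechanistic` / `clinical` | the two model layers and their Gibbs updates |
| `mrfomics.augmentation` | latent outcomes and block-missing imputation |
| `mrfomics.sampler` | MCMC orchestration, chains, diagnostics |
| `mrfomics.inference` | PPIs, selection, Bayesian FDR, BMA prediction, metrics |
| `mrfomics.simulate` | synthetic-data generator with ground truth |
| `mrfomics.baselines` | mimic/vanilla lasso & elastic net, CV arm choice |
| `mrfomics.config` / `experiment` | run configs, presets, replicated grids |

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.
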