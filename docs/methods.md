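# Methods

## Model

Data for N subjects: outcome Y (continuous, binary, or right-censored
survival time), clinical covariates C (N×L, first column an all-ones
intercept), gene expression E (N×K), promoter methylation M-values M (N×J)
with a many-to-one probe→gene map (probe sets J_k, every gene has ≥ 1
probe), and a binary symmetric gene network G (zero diagonal).

**Mechanistic layer.** E = E^M + E^M̄ with E^M = MΩ. Each allowed entry
ω_jk (j ∈ J_k) has a Dirac spike-and-slab prior
(1−z_jk)δ₀ + z_jk N(0, σ_k²/τ_k), z_jk ~ Bern(π_k), π_k ~ Beta(a, b),
and gene-level noise E_k − Mω_k ~ N(0, σ_k² I), σ_k⁻² ~ Ga(δ₁, δ₂).
Because each probe maps to exactly one gene, Ω is stored as a length-J
vector.

**Clinical layer.** Y* = Cβ^C + E^M β^M + E^M̄ β^M̄ + ε, ε ~ N(0, σ²I),
with β^C ~ N(0, σ²/τ_c I), σ⁻² ~ Ga(δ₁, δ₂), and Dirac spike-and-slab
priors N(0, σ²/τ) on each β_k^M, β_k^M̄ governed by indicators γ_k^M,
γ_k^M̄. The gene-level indicator γ_k = γ_k^M ∨ γ_k^M̄ has the MRF
conditional p(γ_k|γ_−k) = logistic(d + f Σ_{k′∈N_k} γ_{k′}). The joint
form used is d·Σγ + f·(number of edges inside the included set), i.e.
(f/2)·γᵀGγ for symmetric G — the unique joint whose full conditionals are
exactly the logistic conditional above (a full-G quadratic without the 1/2
would double f in the conditional). Only differences of this unnormalized
joint are ever used.

**Outcome augmentation.** Binary outcomes use a probit latent variable
(y=1 ⇔ Y*>0) with σ² fixed at 1 for identifiability. Survival outcomes use
an accelerated-failure-time form on the log scale: Y* = log y exactly for
events; for censored records Y* is drawn each sweep from N(μ, σ²) truncated
below at log y. σ² stays free in the survival model.

**Block missingness.** A subject may lack the whole E block or the whole M
block (never both; scattered NA cells are rejected). Missing rows are
parameters updated by Gibbs: e_nk combines its mechanistic law
N((Mω)_nk, σ_k²) with the clinical likelihood through β_k^M̄; m_nj combines
its N(0, (σ_j^m)²) prior, the mechanistic likelihood through ω_j, and the
clinical likelihood through ω_j(β_k^M − β_k^M̄). These are the full joint
conditionals — the imputation-model laws alone (obtained with
`modular_imputation=True`) would not leave the stated joint model invariant
when the clinical coupling is nonzero. Imputed values are treated as data by
every other conditional.

## Sampler

Per iteration: (1) outcome augmentation; (2) imputation of missing rows;
(3) per gene, single-site z updates with the whole ω_·k vector integrated
out analytically (the marginal includes both the mechanistic likelihood and
the clinical one, since Y depends on Mω_k through β_k^M − β_k^M̄), then a
conjugate multivariate-normal redraw of the active ω_·k, a Beta draw of
π_k, and an inverse-gamma draw of σ_k²; (4) per gene, exact four-way
enumeration of (γ_k^M, γ_k^M̄) with the active β's integrated out, then
conditional-normal β redraws; finally a joint conjugate draw of β^C and an
inverse-gamma draw of σ². The maintained residual vector and the fitted
E^M matrix are updated incrementally by every move and rebuilt from scratch
every `recompute_every` iterations to cap floating-point drift.

Because the MRF prior only constrains the OR of the indicator pair, the
prior split across the three active configurations {10, 01, 11} is a free
choice; the default gives each one conditional weight 1/3 (configurable
via `Hyperparameters.alloc`). The four-way enumeration handles the
OR-coupling exactly, which sequential single-indicator moves would not
without care.

Hot loops are numba-compiled; numba's RNG stream and the numpy Generator
used for the once-per-iteration draws are both seeded from the run seed, so
runs are bit-reproducible. Truncated-normal draws use scipy's inverse-CDF
implementation, accurate far into the tails. Cholesky factorizations of the
small per-gene precision matrices are guaranteed positive definite for
τ_k, τ > 0; a numerical failure aborts with a state summary.

Initialization: all indicators 0, Ω = 0, β^C from least squares on C,
σ² and σ_k² from data variances, missing blocks from their marginal laws.
On very small, weakly identified instances the all-zero start can linger in
a sparse mode when σ² starts at the full marginal residual variance; at the
intended scales (N ≈ 100, effects |β| ≥ 1) the chain leaves it within a few
sweeps.

## Defaults (and why)

| parameter | default | meaning |
|---|---|---|
| d | −3 (−4 in the `application` preset) | MRF sparsity; isolated-gene prior inclusion ≈ 0.05 (≈ 0.02) |
| f | 0.5 | MRF smoothness; kept small to stay below the MRF phase transition (no automatic guard — keep f ≲ 1) |
| τ, τ_k | 1 | slab precision scales |
| τ_c | 0.01 | weak prior on clinical covariate effects |
| a, b | 0.2, 0.8 | Beta prior on π_k: 20% expected probe inclusion |
| δ₁, δ₂ | 0.001 | vague variance priors |
| σ_j^m | 1 | imputation sd for standardized M-values |
| T, T_b, thin, chains | 10000, 5000, 1, 4 | sampler defaults, overridable |

## Synthetic data

The generator states the world the model is evaluated in: N=100 training
and 100 validation samples, L=3 standard-normal covariates, J=300 probes
allocated at random to K ∈ {100, 200, 500} genes (each gene ≥ 1 probe),
50% of genes methylation-regulated with z ~ Bern(1/2) within their probe
sets and |ω| ~ Unif(0.5, 1) with random sign, residual expression
~ N(0, 1), 15 effective genes (five with both effect types, five only
type M, five only type M̄ — so γ^M and γ^M̄ each have exactly 10 ones),
|β| ~ Unif(1, 1.5) with random sign, covariate/intercept coefficients 1,
outcome noise σ ∈ {1, 2, 3}. Networks draw edges among the 15 effective
genes iid Bern(0.1) and place an equal number uniformly among ineffective
genes. Scenarios II/III remove the E/M block for a stated fraction of
subjects; scenario IV removes exactly one block for half the subjects.

Two generator choices the recipe leaves open: the 10 type-M genes are
forced into the regulated half (a type-M effect through an unregulated gene
would be vacuous), and a regulated gene whose Bern(1/2) probe draw comes up
all-zero is redrawn once, then forced to one active probe. Methylation is
synthesized as within-gene exchangeable-correlation Gaussian blocks
(ρ = 0.5, configurable; ρ = 0 gives independence), standardized per probe —
it does **not** emulate real 450k beta-value distributions, LD-like probe
structure, or batch effects. A green test on this generator therefore
establishes correctness of the algorithm under the stated statistical
structure, not robustness to array artefacts.

## Validation strategy

- Closed-form unit oracles: every conjugate update is checked against an
  independent density/moment computation (stacked multivariate-normal
  marginals for the collapsed z update, enumeration with β integrated for
  the four-way clinical update, Beta/inverse-gamma moments, truncated-normal
  moments).
- Stationarity: on enumerable instances the long-run Gibbs frequencies of
  indicator configurations match exact posteriors (total variation < 0.02
  at 50k sweeps), with the MRF coupling and the clinical–mechanistic
  coupling active.
- Joint-distribution check: a successive-conditional simulator (alternately
  regenerating data given parameters and sweeping parameters given data)
  preserves the prior marginals of seven statistics spanning all blocks,
  within 3 Monte-Carlo SEs (batch-means), using proper priors (δ = 3) so
  the moments exist.
- Reduction identities: with complete data and a continuous outcome the
  augmentation step is a bitwise no-op; with zero clinical coupling the
  imputation laws collapse to their mechanistic/prior forms exactly.

## Known limitations

- Two omics layers only (methylation → expression); no SNP/miRNA layers.
- Missingness must be whole-block-per-subject and missing at random;
  informative missingness and interval censoring are out of scope.
- d and f are fixed hyperparameters, not estimated; no phase-transition
  guard beyond documentation.
- The comparators (mimic/vanilla lasso and elastic net) use complete cases
  only, matching their usual practice.
- MCMC cost grows linearly in K and J per sweep; very large gene panels
  will want longer wall-clock budgets (the compiled sweep handles
  K=100, J=300, T=2000 in seconds).
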