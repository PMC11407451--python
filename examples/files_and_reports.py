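"""Reading TSV inputs, validating them, and writing result tables.

Round-trips a simulated dataset through the on-disk format (samples x
features TSV matrices, two-column probe map and edge list), fits a short
chain, applies the Bayesian-FDR selection rule and writes the standard
output files.
"""

import tempfile
from pathlib import Path

import numpy as np

from mrfomics import (Hyperparameters, McmcConfig, SimulationConfig,
                      bayesian_fdr_threshold, compute_ppi, generate_full_data,
                      read_dataset, run_mcmc, write_dataset, write_results)
from mrfomics.datasets import summarize_dataset

tmp = Path(tempfile.mkdtemp())
ds0, truth = generate_full_data(
    SimulationConfig(N=80, K=20, J=60, N_validation=10, seed=2))
paths = write_dataset(ds0, tmp / "data")
print("wrote", sorted(p.name for p in (tmp / "data").iterdir()))

ds = read_dataset(paths, "continuous")
info = summarize_dataset(ds)
print(f"read back: {info['n_samples']} samples, {info['n_genes']} genes, "
      f"violations: {info['violations'] or 'none'}")

draws = run_mcmc(ds, Hyperparameters(), McmcConfig(T=800, T_b=400, seed=9))
summary = compute_ppi(draws)
ppis = np.concatenate([summary.ppi_gamma_M, summary.ppi_gamma_Mbar])
t = bayesian_fdr_threshold(ppis, alpha=0.05)
print(f"Bayesian-FDR cutoff at alpha=0.05: PPI >= {t:.3f} "
      f"selects {(ppis >= t).sum()} of {ppis.size} candidate effects")

out = write_results(summary, tmp / "results")
print("result files:", sorted(p.name for p in (tmp / "results").iterdir()))
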