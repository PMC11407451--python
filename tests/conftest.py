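import numpy as np
import pytest

from mrfomics import (Hyperparameters, McmcConfig, SimulationConfig,
                      generate_full_data)


@pytest.fixture(scope="session")
def small_sim():
    """Small complete scenario-I dataset with ground truth (session-cached)."""
    cfg = SimulationConfig(N=60, K=20, J=60, sigma=1.0, N_validation=60,
                           seed=20240917)
    ds, truth = generate_full_data(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def fitted_small(small_sim):
    """A short fitted chain on the small dataset, reused across tests."""
    from mrfomics import run_mcmc
    ds, truth = small_sim
    draws = run_mcmc(ds, Hyperparameters(),
                     McmcConfig(T=600, T_b=300, seed=7))
    return ds, truth, draws


@pytest.fixture()
def toy_files(tmp_path):
    """Write a tiny 4-sample dataset to TSV files; sample s3 has no
    methylation row (block-missing M)."""
    rng = np.random.default_rng(5)
    samples = ["s1", "s2", "s3", "s4"]
    genes = ["g1", "g2"]
    probes = ["p1", "p2", "p3"]
    clin = "sample_id\tage\ty\n" + "\n".join(
        f"{s}\t{rng.integers(40, 70)}\t{rng.normal():.6f}" for s in samples)
    expr_rows = [f"{s}\t{rng.normal():.6f}\t{rng.normal():.6f}"
                 for s in samples]
    expr = "sample_id\t" + "\t".join(genes) + "\n" + "\n".join(expr_rows)
    meth_rows = [f"{s}\t" + "\t".join(f"{rng.normal():.6f}" for _ in probes)
                 for s in samples if s != "s3"]
    meth = "sample_id\t" + "\t".join(probes) + "\n" + "\n".join(meth_rows)
    pm = "probe_id\tgene_id\np1\tg1\np2\tg1\np3\tg2\n"
    net = "gene_a\tgene_b\ng1\tg2\n"
    paths = {}
    for name, text in [("clinical", clin), ("expression", expr),
                       ("methylation", meth), ("probe_map", pm),
                       ("network", net)]:
        p = tmp_path / f"{name}.tsv"
        p.write_text(text + ("\n" if not text.endswith("\n") else ""))
        paths[name] = p
    return paths
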