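"""Shared data containers and on-disk formats.

All matrices are tab-separated text with a header row of feature identifiers
and a first column of sample identifiers.  The clinical table is the master
sample list; a sample absent from an omics matrix is *block-missing* for that
platform (its whole row is treated as unobserved and later imputed by the
sampler).  Scattered NA cells inside an observed row are rejected — the model
only supports whole-row missingness per platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeGeneMap",
    "GeneNetwork",
    "OutcomeSpec",
    "Hyperparameters",
    "MultiOmicsDataset",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "write_results",
]


class DataError(ValueError):
    """Raised when an input violates a dataset invariant."""


@dataclass
class ProbeGeneMap:
    """Many-to-one assignment of methylation probes to genes.

    Probes are kept in their original (matrix-column) order; ``probe_gene``
    gives, for each probe index, the index of its gene.  Per-gene probe index
    sets (the sets J_k) are derived and must partition {0..J-1} with every
    gene receiving at least one probe.
    """

    probe_ids: list[str]
    gene_ids: list[str]
    probe_gene: np.ndarray  # (J,) int, gene index per probe

    def __post_init__(self) -> None:
        self.probe_gene = np.asarray(self.probe_gene, dtype=np.int64)
        if self.probe_gene.shape != (len(self.probe_ids),):
            raise DataError("probe_gene must have one entry per probe")
        counts = np.bincount(self.probe_gene, minlength=len(self.gene_ids))
        if (counts == 0).any():
            empty = [self.gene_ids[i] for i in np.where(counts == 0)[0]]
            raise DataError(f"genes without any mapped probe: {empty[:5]}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def probes_of(self, k: int) -> np.ndarray:
        """Indices of the probes mapped to gene ``k`` (the set J_k)."""
        return np.where(self.probe_gene == k)[0]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, probe_ids: Sequence[str],
                   gene_ids: Sequence[str]) -> "ProbeGeneMap":
        """Build from a two-column (probe_id, gene_id) table."""
        mapping = dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))
        gene_index = {g: i for i, g in enumerate(gene_ids)}
        probe_gene = np.empty(len(probe_ids), dtype=np.int64)
        for j, pid in enumerate(probe_ids):
            if pid not in mapping:
                raise DataError(f"probe {pid!r} has no gene mapping")
            g = mapping[pid]
            if g not in gene_index:
                raise DataError(f"probe {pid!r} maps to unknown gene {g!r}")
            probe_gene[j] = gene_index[g]
        return cls(list(map(str, probe_ids)), list(map(str, gene_ids)), probe_gene)


@dataclass
class GeneNetwork:
    """Undirected gene–gene network as a K×K binary symmetric adjacency."""

    adjacency: np.ndarray  # (K, K) {0,1}, zero diagonal

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise DataError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise DataError("network not symmetric")
        if not np.isin(A, (0, 1)).all():
            raise DataError("adjacency entries must be 0/1")
        if np.diagonal(A).any():
            raise DataError("adjacency diagonal must be zero")
        self.adjacency = A.astype(np.int8)

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, k: int) -> np.ndarray:
        return np.where(self.adjacency[k] == 1)[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame, gene_ids: Sequence[str]) -> "GeneNetwork":
        gene_index = {g: i for i, g in enumerate(gene_ids)}
        K = len(gene_ids)
        A = np.zeros((K, K), dtype=np.int8)
        for a, b in zip(edges.iloc[:, 0].astype(str), edges.iloc[:, 1].astype(str)):
            if a not in gene_index or b not in gene_index:
                missing = a if a not in gene_index else b
                raise DataError(f"network gene {missing!r} not among expression genes")
            i, j = gene_index[a], gene_index[b]
            if i == j:
                continue  # self-loops carry no information in the MRF prior
            A[i, j] = A[j, i] = 1
        return cls(A)


OUTCOME_KINDS = ("continuous", "binary", "survival")


@dataclass
class OutcomeSpec:
    """Clinical outcome: continuous y, binary y in {0,1}, or right-censored
    survival (y = min(t, c) > 0 with event indicator delta)."""

    kind: str
    y: np.ndarray
    event: np.ndarray | None = None  # survival only; 1 = event observed

    def __post_init__(self) -> None:
        if self.kind not in OUTCOME_KINDS:
            raise DataError(f"outcome kind must be one of {OUTCOME_KINDS}")
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.kind == "binary" and not np.isin(self.y, (0.0, 1.0)).all():
            raise DataError("binary outcome values must be 0/1")
        if self.kind == "survival":
            if self.event is None:
                raise DataError("survival outcome requires an event indicator")
            self.event = np.asarray(self.event, dtype=np.int8)
            if not np.isin(self.event, (0, 1)).all():
                raise DataError("event indicator must be 0/1")
            if (self.y <= 0).any():
                raise DataError("non-positive survival time")

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class Hyperparameters:
    """Prior hyperparameters.

    d, f control the MRF prior on gene inclusion (d<0 encourages sparsity,
    f>=0 rewards jointly selected network neighbours); tau / tau_k scale the
    Gaussian slab precisions of the clinical and mechanistic coefficients;
    tau_c is the prior precision scale of clinical-covariate effects; (a, b)
    is the Beta prior on the per-gene probe-inclusion probability pi_k;
    (delta1, delta2) the inverse-gamma shape/rate for the noise variances;
    sigma_m the imputation sd for standardized methylation M-values.
    ``alloc`` is the conditional prior weight of the three active
    (gamma_M, gamma_Mbar) configurations {10, 01, 11} given that the gene is
    in the model (the MRF prior only constrains their OR).
    """

    d: float = -3.0
    f: float = 0.5
    tau: float = 1.0
    tau_k: float = 1.0
    tau_c: float = 0.01
    a: float = 0.2
    b: float = 0.8
    delta1: float = 0.001
    delta2: float = 0.001
    sigma_m: float = 1.0
    alloc: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if self.f < 0:
            raise DataError("MRF smoothness f must be >= 0")
        for name in ("tau", "tau_k", "tau_c", "a", "b", "delta1", "delta2", "sigma_m"):
            if getattr(self, name) <= 0:
                raise DataError(f"hyperparameter {name} must be > 0")
        s = float(sum(self.alloc))
        if s <= 0 or any(w < 0 for w in self.alloc):
            raise DataError("alloc weights must be non-negative with positive sum")
        self.alloc = tuple(float(w) / s for w in self.alloc)


@dataclass
class MultiOmicsDataset:
    """Aligned outcome, clinical, expression and methylation data.

    ``C`` carries an all-ones intercept column as its first column (added by
    the readers/generators).  Rows of ``E`` (or ``M``) flagged by ``U_E``
    (``U_M``) are unobserved placeholders — the sampler imputes them.  The
    invariant U_E[n]*U_M[n] != 1 guarantees every sample has at least one
    omics platform observed.
    """

    sample_ids: list[str]
    Y: OutcomeSpec
    C: np.ndarray          # (N, L) incl. intercept column
    E: np.ndarray          # (N, K)
    M: np.ndarray          # (N, J)
    U_E: np.ndarray        # (N,) int8
    U_M: np.ndarray        # (N,) int8
    probe_map: ProbeGeneMap
    network: GeneNetwork
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.C = np.ascontiguousarray(self.C, dtype=np.float64)
        self.E = np.ascontiguousarray(self.E, dtype=np.float64)
        self.M = np.ascontiguousarray(self.M, dtype=np.float64)
        self.U_E = np.asarray(self.U_E, dtype=np.int8)
        self.U_M = np.asarray(self.U_M, dtype=np.int8)
        problems = validate_dataset(self, _raise=False)
        fatal = [p for p in problems if p.startswith("fatal")]
        if fatal:
            raise DataError("; ".join(fatal))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return self.E.shape[1]

    @property
    def n_probes(self) -> int:
        return self.M.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.C.shape[1]

    def complete_cases(self) -> "MultiOmicsDataset":
        """Subset to samples observed on every platform (complete-case view)."""
        keep = np.where((self.U_E == 0) & (self.U_M == 0))[0]
        return self.subset(keep)

    def subset(self, rows: np.ndarray) -> "MultiOmicsDataset":
        rows = np.asarray(rows)
        Y = OutcomeSpec(self.Y.kind, self.Y.y[rows],
                        None if self.Y.event is None else self.Y.event[rows])
        return MultiOmicsDataset(
            [self.sample_ids[i] for i in rows], Y,
            self.C[rows], self.E[rows], self.M[rows],
            self.U_E[rows], self.U_M[rows],
            self.probe_map, self.network, list(self.covariate_names))


def validate_dataset(ds: MultiOmicsDataset, _raise: bool = True) -> list[str]:
    """Report violated invariants (never mutates).

    Violations prefixed "fatal" make the dataset unusable for fitting.
    """
    out: list[str] = []
    N = len(ds.sample_ids)
    for arr, name, width in ((ds.C, "C", None), (ds.E, "E", ds.probe_map.n_genes),
                             (ds.M, "M", ds.probe_map.n_probes)):
        if arr.shape[0] != N:
            out.append(f"fatal: {name} has {arr.shape[0]} rows, expected {N}")
        if width is not None and arr.shape[1] != width:
            out.append(f"fatal: {name} has {arr.shape[1]} columns, expected {width}")
    if ds.network.n_genes != ds.probe_map.n_genes:
        out.append("fatal: network dimension does not match gene count")
    both = (ds.U_E.astype(int) * ds.U_M.astype(int)) == 1
    if both.any():
        bad = [ds.sample_ids[i] for i in np.where(both)[0]]
        out.append("fatal: samples missing both omics blocks "
                   f"(U_E*U_M=1, need at least one platform): {bad[:5]}")
    if ds.Y.n != N:
        out.append(f"fatal: outcome length {ds.Y.n} != {N}")
    if ds.Y.kind == "survival" and (ds.Y.y <= 0).any():
        out.append("non-positive survival time")
    obs_E = ds.U_E == 0
    obs_M = ds.U_M == 0
    if np.isnan(ds.E[obs_E]).any():
        out.append("fatal: NA cells inside observed expression rows "
                   "(only whole-row block missingness is supported)")
    if np.isnan(ds.M[obs_M]).any():
        out.append("fatal: NA cells inside observed methylation rows")
    if np.isnan(ds.C).any():
        out.append("fatal: NA in clinical covariates")
    if not np.allclose(ds.C[:, 0], 1.0):
        out.append("first clinical column is not an intercept column of ones")
    A = ds.network.adjacency
    if not np.array_equal(A, A.T):
        out.append("network not symmetric")
    return out


def summarize_dataset(ds: MultiOmicsDataset) -> dict:
    """Dimension / missingness summary used by the diagnostics report."""
    return {
        "n_samples": ds.n_samples,
        "n_genes": ds.n_genes,
        "n_probes": ds.n_probes,
        "n_covariates": ds.n_covariates,
        "outcome_kind": ds.Y.kind,
        "n_missing_expression": int(ds.U_E.sum()),
        "n_missing_methylation": int(ds.U_M.sum()),
        "n_complete": int(((ds.U_E == 0) & (ds.U_M == 0)).sum()),
        "n_edges": ds.network.n_edges,
        "violations": validate_dataset(ds, _raise=False),
    }


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return df


def read_dataset(paths: Mapping[str, str | Path], outcome_kind: str) -> MultiOmicsDataset:
    """Read a dataset from TSV files.

    ``paths`` must name ``clinical``, ``expression``, ``methylation``,
    ``probe_map`` and ``network`` files.  The clinical table defines the
    master sample list and order; samples absent from an omics matrix get the
    corresponding missingness flag.  The clinical table holds the covariates
    plus outcome columns ``y`` (continuous), ``label`` (binary) or
    ``time``/``event`` (survival).
    """
    paths = {k: Path(v) for k, v in paths.items()}
    for key in ("clinical", "expression", "methylation", "probe_map", "network"):
        if key not in paths:
            raise DataError(f"missing path for {key!r}")
        if not paths[key].exists():
            raise FileNotFoundError(paths[key])

    clin = _read_matrix(paths["clinical"])
    sample_ids = list(clin.index)
    if outcome_kind == "survival":
        outcome_cols = ["time", "event"]
        Y = OutcomeSpec("survival", clin["time"].to_numpy(float),
                        clin["event"].to_numpy(int))
    elif outcome_kind == "binary":
        outcome_cols = ["label"]
        Y = OutcomeSpec("binary", clin["label"].to_numpy(float))
    else:
        outcome_cols = ["y"]
        Y = OutcomeSpec("continuous", clin["y"].to_numpy(float))
    covariates = clin.drop(columns=outcome_cols)
    C = np.column_stack([np.ones(len(clin)), covariates.to_numpy(float)])
    covariate_names = ["intercept"] + list(covariates.columns)

    expr = _read_matrix(paths["expression"])
    meth = _read_matrix(paths["methylation"])
    gene_ids = list(expr.columns)
    probe_ids = list(meth.columns)

    N, K, J = len(sample_ids), len(gene_ids), len(probe_ids)
    E = np.full((N, K), np.nan)
    M = np.full((N, J), np.nan)
    U_E = np.ones(N, dtype=np.int8)
    U_M = np.ones(N, dtype=np.int8)
    for n, sid in enumerate(sample_ids):
        if sid in expr.index:
            E[n] = expr.loc[sid].to_numpy(float)
            U_E[n] = 0
        if sid in meth.index:
            M[n] = meth.loc[sid].to_numpy(float)
            U_M[n] = 0
    E[U_E == 1] = 0.0  # placeholder rows, overwritten by the imputation sweep
    M[U_M == 1] = 0.0

    probe_map = ProbeGeneMap.from_frame(
        pd.read_csv(paths["probe_map"], sep="\t", dtype=str), probe_ids, gene_ids)
    edges = pd.read_csv(paths["network"], sep="\t", dtype=str)
    network = GeneNetwork.from_edge_list(edges, gene_ids)

    return MultiOmicsDataset(sample_ids, Y, C, E, M, U_E, U_M,
                             probe_map, network, covariate_names)


def _fmt_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_dataset(ds: MultiOmicsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset back to the TSV file set (round-trip exact).

    Block-missing rows are written by *omitting* the sample from the matrix,
    matching how missingness is encoded on read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_ids = ds.probe_map.gene_ids
    probe_ids = ds.probe_map.probe_ids
    ids = np.array(ds.sample_ids)

    clin = pd.DataFrame(ds.C[:, 1:], index=ids, columns=ds.covariate_names[1:])
    clin.index.name = "sample_id"
    if ds.Y.kind == "survival":
        clin["time"] = ds.Y.y
        clin["event"] = ds.Y.event
    elif ds.Y.kind == "binary":
        clin["label"] = ds.Y.y.astype(int)
    else:
        clin["y"] = ds.Y.y

    paths = {
        "clinical": out / "clinical.tsv",
        "expression": out / "expression.tsv",
        "methylation": out / "methylation.tsv",
        "probe_map": out / "probe_map.tsv",
        "network": out / "network.tsv",
    }
    _fmt_frame(clin, paths["clinical"])
    expr = pd.DataFrame(ds.E[ds.U_E == 0], index=ids[ds.U_E == 0], columns=gene_ids)
    expr.index.name = "sample_id"
    _fmt_frame(expr, paths["expression"])
    meth = pd.DataFrame(ds.M[ds.U_M == 0], index=ids[ds.U_M == 0], columns=probe_ids)
    meth.index.name = "sample_id"
    _fmt_frame(meth, paths["methylation"])
    pd.DataFrame({"probe_id": probe_ids,
                  "gene_id": [gene_ids[g] for g in ds.probe_map.probe_gene]}
                 ).to_csv(paths["probe_map"], sep="\t", index=False)
    ii, jj = np.where(np.triu(ds.network.adjacency, 1) == 1)
    pd.DataFrame({"gene_a": [gene_ids[i] for i in ii],
                  "gene_b": [gene_ids[j] for j in jj]}
                 ).to_csv(paths["network"], sep="\t", index=False)
    return paths


def write_results(summary, out_dir: str | Path) -> dict[str, Path]:
    """Write the posterior summary as delimited text plus a JSON metrics file.

    Emits a per-gene PPI table with selection flags, a probe-selection table,
    posterior-mean coefficients, a prediction table (when predictions were
    requested) and ``metrics.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_ids = summary.gene_ids
    probe_ids = summary.probe_ids
    paths: dict[str, Path] = {}

    genes = pd.DataFrame({
        "gene": gene_ids,
        "ppi_M": summary.ppi_gamma_M,
        "ppi_Mbar": summary.ppi_gamma_Mbar,
        "selected_M": summary.selected_M.astype(int),
        "selected_Mbar": summary.selected_Mbar.astype(int),
        "beta_M_mean": summary.beta_M_mean,
        "beta_Mbar_mean": summary.beta_Mbar_mean,
    })
    paths["genes"] = out / "ppi_genes.tsv"
    genes.to_csv(paths["genes"], sep="\t", index=False, float_format="%.10g")

    probes = pd.DataFrame({
        "probe": probe_ids,
        "gene": [gene_ids[g] for g in summary.probe_gene],
        "ppi_z": summary.ppi_z,
        "selected": (summary.ppi_z > summary.threshold).astype(int),
        "omega_mean": summary.omega_mean,
    })
    paths["probes"] = out / "ppi_probes.tsv"
    probes.to_csv(paths["probes"], sep="\t", index=False, float_format="%.10g")

    coef = pd.DataFrame({"covariate": summary.covariate_names,
                         "beta_C_mean": summary.beta_C_mean})
    paths["coefficients"] = out / "coefficients.tsv"
    coef.to_csv(paths["coefficients"], sep="\t", index=False, float_format="%.10g")

    sel = genes[genes.selected_M.astype(bool) | genes.selected_Mbar.astype(bool)]
    paths["selected"] = out / "selected_features.tsv"
    sel.to_csv(paths["selected"], sep="\t", index=False, float_format="%.10g")

    if summary.predictions is not None:
        pred = pd.DataFrame({"prediction": summary.predictions})
        paths["predictions"] = out / "predictions.tsv"
        pred.to_csv(paths["predictions"], sep="\t", index=False, float_format="%.10g")

    paths["metrics"] = out / "metrics.json"
    with open(paths["metrics"], "w") as fh:
        json.dump(summary.metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
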