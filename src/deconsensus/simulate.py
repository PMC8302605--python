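"""Negative-binomial RNA-seq count simulation with known DEG truth.

Datasets are generated under a two-group design: every gene gets a baseline
mean and dispersion (either drawn from a parametric log-normal/dispersion-trend
model or resampled from a template count table), a chosen proportion of genes
(``pdeg``) is flagged as truly differentially expressed, and flagged genes have
their treatment-group mean multiplied by 2**(+/- logfc).  Counts are then drawn
independently per sample from a negative binomial with Var = mu + phi * mu^2
(Poisson when phi = 0).  Full parameter grids with per-cell replicates are
supported for benchmarking, with reproducible per-dataset seeds derived by a
splitmix64 mix of (base seed, cell index, replicate index).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CONTROL, TREATMENT, CountMatrix, SampleDesign, normalized_counts


@dataclass
class ParametricBaseline:
    """Log-normal gene means with a 1/mu dispersion trend, bulk-RNA-seq-like.

    mean_log_mu / sd_log_mu are on the natural-log scale; dispersion follows
    phi(mu) = dispersion_a + dispersion_b / mu.
    """

    mean_log_mu: float = 4.0
    sd_log_mu: float = 2.0
    dispersion_a: float = 0.1
    dispersion_b: float = 1.0


@dataclass
class SimParams:
    n_genes: int = 10_000
    reps_per_group: int = 3
    pdeg: float = 0.05
    logfc: float = 1.0
    up_fraction: float = 0.5
    baseline: ParametricBaseline | pd.DataFrame = field(default_factory=ParametricBaseline)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.reps_per_group < 2:
            raise ValueError("reps_per_group must be >= 2")
        if not 0.0 <= self.pdeg <= 1.0:
            raise ValueError("pdeg must be in [0, 1]")
        if self.logfc <= 0:
            raise ValueError("logfc must be > 0")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValueError("up_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Per-gene ground truth: DEG flag and true log2 fold change (0 for non-DEGs)."""

    table: pd.DataFrame  # index gene id, columns is_deg (bool), true_logfc (float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def is_deg(self) -> pd.Series:
        return self.table["is_deg"]

    @property
    def true_logfc(self) -> pd.Series:
        return self.table["true_logfc"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df["is_deg"] = df["is_deg"].astype(bool)
        return cls(df)


def estimate_baseline(template: CountMatrix) -> pd.DataFrame:
    """Per-gene (mean, dispersion) from a template table, method of moments.

    Means are taken on size-factor-normalized counts; the dispersion estimate
    is phi = max(0, (var - mean) / mean^2) and genes with zero mean are dropped.
    """
    if template.shape[1] < 2:
        raise ValueError("template needs at least 2 samples")
    norm = normalized_counts(template)
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    keep = mean > 0
    mean, var = mean[keep], var[keep]
    phi = np.maximum(0.0, (var - mean) / mean**2)
    return pd.DataFrame({"mean": mean, "dispersion": phi})


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) via gamma-Poisson mixing; phi = 0 is exact Poisson."""
    lam = np.array(mean, dtype=float, copy=True)
    over = phi > 0
    if over.any():
        shape = 1.0 / phi[over]
        lam[over] = rng.gamma(shape, mean[over] * phi[over])
    return rng.poisson(lam)


def simulate_dataset(p: SimParams) -> tuple[CountMatrix, SampleDesign, SimTruth]:
    """Simulate one two-group count dataset; deterministic given ``p.seed``."""
    rng = np.random.default_rng(p.seed)

    if isinstance(p.baseline, pd.DataFrame):
        pool = p.baseline[["mean", "dispersion"]].to_numpy(dtype=float)
        idx = rng.integers(0, len(pool), size=p.n_genes)
        mu = pool[idx, 0]
        phi = pool[idx, 1]
    else:
        b = p.baseline
        mu = rng.lognormal(b.mean_log_mu, b.sd_log_mu, size=p.n_genes)
        phi = b.dispersion_a + b.dispersion_b / mu

    n_deg = int(round(p.pdeg * p.n_genes))
    if p.pdeg > 0 and n_deg == 0:
        warnings.warn("pdeg * n_genes rounds to 0: simulating 0 DEGs", stacklevel=2)
    deg_idx = rng.choice(p.n_genes, size=n_deg, replace=False)
    n_up = int(round(p.up_fraction * n_deg))
    true_logfc = np.zeros(p.n_genes)
    true_logfc[deg_idx[:n_up]] = p.logfc
    true_logfc[deg_idx[n_up:]] = -p.logfc

    mu_treat = mu * 2.0**true_logfc
    r = p.reps_per_group
    counts = np.empty((p.n_genes, 2 * r), dtype=np.int64)
    for j in range(r):
        counts[:, j] = _draw_nb(rng, mu, phi)
    for j in range(r):
        counts[:, r + j] = _draw_nb(rng, mu_treat, phi)

    genes = [f"G{i + 1}" for i in range(p.n_genes)]
    samples = [f"CTRL_{j + 1}" for j in range(r)] + [f"TREAT_{j + 1}" for j in range(r)]
    m = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    group = pd.Series([CONTROL] * r + [TREATMENT] * r, index=samples, name="group")
    design = SampleDesign(group=group)
    is_deg = np.zeros(p.n_genes, dtype=bool)
    is_deg[deg_idx] = True
    truth = SimTruth(
        pd.DataFrame({"is_deg": is_deg, "true_logfc": true_logfc}, index=genes)
    )
    return m, design, truth


# ---------------------------------------------------------------------------
# parameter grids


def _splitmix64(x: int) -> int:
    """One splitmix64 step; the standard 64-bit mixing constant sequence."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return z ^ (z >> 31)


def derive_seed(base_seed: int, cell_index: int, replicate_index: int) -> int:
    """Deterministic per-dataset seed; documented so grids reproduce piecewise."""
    z = _splitmix64(_splitmix64(_splitmix64(base_seed) ^ cell_index) ^ replicate_index)
    return int(z % (2**31))


#: defaults mirroring the published simulation settings (10,000 genes,
#: 3 replicates per group, DEG proportions 0.05/0.1, |logFC| 0.5..4)
DEFAULT_GRID: dict[str, list] = {
    "n_genes": [10_000],
    "reps_per_group": [3],
    "pdeg": [0.05, 0.1],
    "logfc": [0.5, 1.0, 2.0, 4.0],
}


def run_grid(grid: dict[str, list], replicates_per_cell: int, base_seed: int,
             baseline: ParametricBaseline | pd.DataFrame | None = None):
    """Yield (label, SimParams, dataset) over the Cartesian grid x replicates.

    ``grid`` maps SimParams field names to candidate values.  Every cell is
    labelled by its parameter settings and replicate index; the total number
    of datasets is |grid| * replicates_per_cell.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty parameter grid")
    keys = list(grid)
    combos = list(itertools.product(*(grid[k] for k in keys)))
    for cell_index, combo in enumerate(combos):
        cell = dict(zip(keys, combo))
        for rep in range(replicates_per_cell):
            seed = derive_seed(base_seed, cell_index, rep)
            kwargs = dict(cell)
            if baseline is not None:
                kwargs["baseline"] = baseline
            params = SimParams(seed=seed, **kwargs)
            label = "_".join(f"{k}-{cell[k]}" for k in keys) + f"_rep-{rep}"
            yield label, params, simulate_dataset(params)
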