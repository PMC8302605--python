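"""Weighted co-expression modules, eigengenes and trait correlation (WGCNA-lite).

The network is unsigned: adjacency a_ij = |Pearson cor(g_i, g_j)|^beta, with
the soft-threshold power beta chosen as the smallest candidate achieving a
signed scale-free topology fit R^2 >= the target (else the best-fitting one).
Gene-gene similarity is the topological overlap measure (TOM), modules come
from average-linkage hierarchical clustering of 1 - TOM with a static height
cut, and each module is summarised by its eigengene — the first principal
component of the standardized member-expression matrix, one value per sample.
Module eigengenes are correlated against sample traits: numeric traits by
Pearson correlation directly, categorical traits through one binary indicator
vector per level.

A planted-module fixture generator is included so recovery can be tested
against a known latent-factor structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import CONTROL, TREATMENT, SampleDesign


@dataclass
class CoexpressionConfig:
    candidate_powers: tuple = tuple(range(1, 21))
    rsq_target: float = 0.8
    min_module_size: int = 30
    cut_height: float = 0.975

    def __post_init__(self) -> None:
        powers = list(self.candidate_powers)
        if not powers or sorted(powers) != powers:
            raise ValueError("candidate_powers must be non-empty and ascending")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValueError("cut_height must be in (0, 1]")


@dataclass
class ModuleSet:
    """Module assignment (0 = unassigned), eigengenes, kME and trait correlations."""

    gene_to_module: pd.Series
    eigengenes: pd.DataFrame        # modules x samples, unit-norm rows
    kme: pd.DataFrame               # genes x modules, Pearson correlations
    trait_table: pd.DataFrame       # module, trait, r, pvalue, significant
    chosen_power: int


def _drop_constant_genes(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=0)
    if (sd == 0).any():
        expr = expr.loc[sd > 0]
        if expr.empty:
            raise ValueError("all genes constant across samples")
    return expr


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with zero diagonal."""
    a = np.abs(np.corrcoef(expr.to_numpy())) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit: (signed R^2, slope).

    Connectivities are binned into ``n_bins`` equal-width bins; log10
    frequency is regressed on log10 mean connectivity per occupied bin, and
    R^2 is negated when the slope is positive (a scale-free degree
    distribution requires a decreasing relationship).
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() > 0 and k[mask].mean() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    rsq = r**2
    return (-rsq if slope > 0 else rsq), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame, cfg: CoexpressionConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power beta and return the per-power fit table."""
    cfg = cfg or CoexpressionConfig()
    expr = _drop_constant_genes(expr)
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 samples for co-expression analysis")
    cor = np.abs(np.corrcoef(expr.to_numpy()))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in cfg.candidate_powers:
        k = (cor**beta).sum(axis=1)
        rsq, slope = scale_free_fit(k)
        rows.append({"power": beta, "rsq": rsq, "slope": slope,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    fit = pd.DataFrame(rows)
    passing = fit[fit["rsq"] >= cfg.rsq_target]
    beta = int(passing["power"].iloc[0]) if len(passing) else int(
        fit.loc[fit["rsq"].idxmax(), "power"]
    )
    return beta, fit


def tom_similarity(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Topological overlap: t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    l_ij = sum_u a_iu * a_uj counts shared neighbours; the diagonal is 1.
    """
    expr = _drop_constant_genes(expr)
    a = adjacency_matrix(expr, beta)
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def detect_modules(tom: pd.DataFrame, cfg: CoexpressionConfig | None = None) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` fall into module 0 (the
    unassigned pool); surviving modules are renumbered 1..K by decreasing size.
    """
    cfg = cfg or CoexpressionConfig()
    t = tom.to_numpy()
    if t.shape[0] != t.shape[1] or not np.allclose(t, t.T, atol=1e-8):
        raise ValueError("TOM must be square and symmetric")
    dist = 1.0 - t
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    flat = hierarchy.fcluster(z, t=cfg.cut_height, criterion="distance")
    sizes = pd.Series(flat).value_counts()
    keep = sizes[sizes >= cfg.min_module_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    assigned = np.array([relabel.get(c, 0) for c in flat])
    return pd.Series(assigned, index=tom.index, name="module")


def module_eigengenes(
    expr: pd.DataFrame, gene_to_module: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-module eigengene (unit-norm first PC of standardized members) and kME.

    Eigengene signs are aligned so each correlates non-negatively with the
    module's mean standardized expression profile; kME is the Pearson
    correlation of every gene with every module eigengene.
    """
    modules = sorted(set(gene_to_module) - {0})
    if not modules:
        raise ValueError("no modules with id > 0")
    z = expr.sub(expr.mean(axis=1), axis=0)
    sd = expr.std(axis=1, ddof=0).replace(0, np.nan)
    z = z.div(sd, axis=0).dropna()
    eig = {}
    for mod in modules:
        members = gene_to_module.index[gene_to_module == mod]
        sub = z.loc[z.index.intersection(members)].to_numpy()
        if sub.shape[0] == 0 or np.allclose(sub.var(axis=1), 0):
            raise ValueError(f"module {mod} has no expression variation")
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        eig[mod] = e / np.linalg.norm(e)
    eigengenes = pd.DataFrame(eig, index=expr.columns).T
    eigengenes.index.name = "module"
    kme = pd.DataFrame(
        {mod: z.apply(lambda g: np.corrcoef(g, eigengenes.loc[mod])[0, 1], axis=1)
         for mod in modules}
    )
    return eigengenes, kme


def correlate_traits(
    eigengenes: pd.DataFrame,
    design: SampleDesign,
    include_group: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate each module eigengene with every sample trait.

    Numeric traits use Pearson correlation with a two-sided t-test (n - 2 df);
    categorical traits are expanded into one binary 0/1 vector per level, each
    correlated separately.  The CONTROL/TREATMENT group is included as a
    categorical trait when ``include_group`` is set.  Rows are flagged
    significant at p < ``alpha``; constant traits get an undefined (NaN) r.
    """
    samples = list(eigengenes.columns)
    if len(samples) < 3:
        raise ValueError("need >= 3 samples for trait correlation")
    vectors: dict[str, pd.Series] = {}
    if include_group:
        group = design.group.reindex(samples)
        for level in (CONTROL, TREATMENT):
            vectors[f"group={level}"] = (group == level).astype(float)
    for col in design.traits.columns:
        t = design.traits[col].reindex(samples)
        if pd.api.types.is_numeric_dtype(t):
            vectors[col] = t.astype(float)
        else:
            for level in sorted(t.dropna().unique()):
                vectors[f"{col}={level}"] = (t == level).astype(float)
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        for name, vec in vectors.items():
            v = vec.to_numpy(dtype=float)
            if np.std(v) == 0 or np.std(e) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(e, v)
            rows.append({
                "module": mod, "trait": name, "r": r, "pvalue": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            })
    return pd.DataFrame(rows)


def coexpression_analysis(
    expr: pd.DataFrame,
    design: SampleDesign,
    cfg: CoexpressionConfig | None = None,
) -> ModuleSet:
    """Full pipeline: power selection, TOM, modules, eigengenes, trait table."""
    cfg = cfg or CoexpressionConfig()
    expr = _drop_constant_genes(expr)
    beta, _ = pick_soft_threshold(expr, cfg)
    tom = tom_similarity(expr, beta)
    assignment = detect_modules(tom, cfg)
    if (assignment > 0).any():
        eigengenes, kme = module_eigengenes(expr, assignment)
        traits = correlate_traits(eigengenes, design)
    else:  # nothing co-expressed strongly enough: empty but well-formed output
        eigengenes = pd.DataFrame(columns=expr.columns)
        kme = pd.DataFrame(index=expr.index)
        traits = pd.DataFrame(
            columns=["module", "trait", "r", "pvalue", "significant"])
    return ModuleSet(
        gene_to_module=assignment, eigengenes=eigengenes, kme=kme,
        trait_table=traits, chosen_power=beta,
    )


# ---------------------------------------------------------------------------
# planted-module fixture generator


def make_planted_modules(
    n_modules: int = 3,
    module_size: int = 60,
    n_noise_genes: int = 60,
    n_samples: int = 12,
    intra_cor: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Latent-factor expression fixture with known module structure.

    Each module m has one standard-normal latent factor f_m per sample; a
    member gene is sqrt(intra_cor) * f_m + sqrt(1 - intra_cor) * noise so any
    two members correlate at ``intra_cor`` in expectation while modules are
    mutually independent.  Noise genes are pure standard normals.  Returns
    (expression table, true module labels, latent factors x samples).
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    factors = rng.standard_normal((n_modules, n_samples))
    rows, labels, names = [], [], []
    a, b = np.sqrt(intra_cor), np.sqrt(1.0 - intra_cor)
    for mod in range(1, n_modules + 1):
        for g in range(module_size):
            rows.append(a * factors[mod - 1] + b * rng.standard_normal(n_samples))
            labels.append(mod)
            names.append(f"M{mod}_G{g + 1}")
    for g in range(n_noise_genes):
        rows.append(rng.standard_normal(n_samples))
        labels.append(0)
        names.append(f"NOISE_G{g + 1}")
    expr = pd.DataFrame(rows, index=names, columns=samples)
    truth = pd.Series(labels, index=names, name="module")
    latent = pd.DataFrame(
        factors, index=[f"factor_{m + 1}" for m in range(n_modules)], columns=samples
    )
    return expr, truth, latent
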