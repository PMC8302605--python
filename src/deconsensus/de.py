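"""Native differential-expression detectors and per-method result handling.

Three simplified but statistically standard detectors cover the main families
of published DE methods:

* ``run_modt`` — a moderated t-test on log2-transformed normalized counts with
  empirical-Bayes variance shrinkage (limma-style);
* ``run_nbwald`` — a negative-binomial Wald test on group means with
  moment-based dispersion shrunk toward the median (DESeq2/edgeR-style);
* ``run_ranksum`` — a two-sided Wilcoxon rank-sum test, exact for small
  tie-free groups (nonparametric stand-in).

Each returns per-gene (logFC, p-value, BH-adjusted FDR) with a shared sign
convention: positive logFC means overexpressed in the treatment group.
Externally computed result tables can be imported through the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_io import CONTROL, TREATMENT, CountMatrix, SampleDesign, normalized_counts

#: pseudo-count added to group means / log2 values so zero counts stay finite
PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    """Per-gene (logFC, p-value, FDR) from one detection method."""

    method_name: str
    table: pd.DataFrame  # index gene id; columns logfc, pvalue, fdr

    def __post_init__(self) -> None:
        missing = {"logfc", "pvalue", "fdr"} - set(self.table.columns)
        if missing:
            raise ValueError(f"DEResult missing column(s): {sorted(missing)}")
        dup = self.table.index[self.table.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate gene id(s) in {self.method_name}: {list(dup)}")
        for col in ("pvalue", "fdr"):
            v = self.table[col].to_numpy()
            if np.any((v < 0) | (v > 1) | ~np.isfinite(v)):
                raise ValueError(f"{col} outside [0, 1] in {self.method_name}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_arrays(norm: pd.DataFrame, d: SampleDesign):
    ctrl = d.samples_in(CONTROL)
    treat = d.samples_in(TREATMENT)
    if len(ctrl) < 2 or len(treat) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (control {len(ctrl)}, treatment {len(treat)})"
        )
    return norm[ctrl].to_numpy(), norm[treat].to_numpy()


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log s^2 to a scaled-F model; returns (prior df d0, s0^2).

    Under s^2 ~ s0^2 * F(df, d0), e = log s^2 - digamma(df/2) + log(df/2)
    has mean log s0^2 - digamma(d0/2) + log(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2); d0 is infinite when the observed spread
    of log s^2 is no larger than the chi-square sampling noise alone.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    return d0, s0_2


def moderated_t_fit(m: CountMatrix, d: SampleDesign, prior_df: float | None = None) -> pd.DataFrame:
    """Per-gene moderated-t statistics on y = log2(normalized count + 0.5).

    ``prior_df`` overrides the estimated prior degrees of freedom d0
    (0 disables moderation, numpy.inf fully trusts the prior variance).
    Returns a frame with logfc, t, pvalue, s2, posterior_var and the shared
    d0 / s0_2 / df values repeated per gene.
    """
    norm = normalized_counts(m)
    y = np.log2(norm + PSEUDOCOUNT)
    yc, yt = _group_arrays(y, d)
    nc, nt = yc.shape[1], yt.shape[1]
    df = nc + nt - 2
    lfc = yt.mean(axis=1) - yc.mean(axis=1)
    s2 = ((nc - 1) * yc.var(axis=1, ddof=1) + (nt - 1) * yt.var(axis=1, ddof=1)) / df

    d0, s0_2 = _fit_f_dist(s2, df)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        post_var = np.full_like(s2, s0_2)
        total_df = np.inf
    else:
        post_var = (d0 * s0_2 + df * s2) / (d0 + df)
        total_df = d0 + df
    se = np.sqrt(post_var * (1.0 / nc + 1.0 / nt))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return pd.DataFrame(
        {
            "logfc": lfc,
            "t": t,
            "pvalue": np.clip(p, 0.0, 1.0),
            "s2": s2,
            "posterior_var": post_var,
            "d0": d0,
            "s0_2": s0_2,
            "df": df,
        },
        index=m.gene_ids,
    )


def run_modt(m: CountMatrix, d: SampleDesign, prior_df: float | None = None) -> DEResult:
    """Empirical-Bayes moderated t-test detector (log-scale linear model)."""
    d.check_matches(m)
    fit = moderated_t_fit(m, d, prior_df=prior_df)
    table = fit[["logfc", "pvalue"]].copy()
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    return DEResult("modt", table)


# ---------------------------------------------------------------------------
# negative-binomial Wald


def run_nbwald(m: CountMatrix, d: SampleDesign, dispersion=None) -> DEResult:
    """NB Wald test on normalized group means with shrunken moment dispersion.

    The per-gene dispersion is a method-of-moments estimate from the pooled
    within-group variance, averaged 50/50 with the across-gene median
    ("common") dispersion; ``dispersion`` overrides it (scalar or per-gene).
    The Wald statistic compares log group means with delta-method variance
    Var(log mu_hat) ~= (1/mu_hat + phi) / n per group.
    """
    d.check_matches(m)
    norm = normalized_counts(m)
    xc, xt = _group_arrays(norm, d)
    nc, nt = xc.shape[1], xt.shape[1]
    mu_c = xc.mean(axis=1)
    mu_t = xt.mean(axis=1)

    if dispersion is None:
        grand = (xc.sum(axis=1) + xt.sum(axis=1)) / (nc + nt)
        s2 = ((nc - 1) * xc.var(axis=1, ddof=1) + (nt - 1) * xt.var(axis=1, ddof=1)) / (
            nc + nt - 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_gene = np.where(grand > 0, (s2 - grand) / np.where(grand > 0, grand, 1.0) ** 2, 0.0)
        phi_gene = np.maximum(phi_gene, 0.0)
        phi = 0.5 * phi_gene + 0.5 * np.median(phi_gene)
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mu_c.shape)

    a_c = mu_c + PSEUDOCOUNT
    a_t = mu_t + PSEUDOCOUNT
    delta = np.log(a_t) - np.log(a_c)
    var = (1.0 / a_t + phi) / nt + (1.0 / a_c + phi) / nc
    z = delta / np.sqrt(var)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 0.0, 1.0)
    table = pd.DataFrame(
        {"logfc": delta / np.log(2.0), "pvalue": p, "fdr": bh_adjust(p)},
        index=m.gene_ids,
    )
    return DEResult("nbwald", table)


# ---------------------------------------------------------------------------
# rank-sum


def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the Mann–Whitney U statistic by dynamic programming."""
    # only invoked for n1 + n2 <= 10, so enumerate all C(n1+n2, n1) subsets
    n = n1 + n2
    pmf = np.zeros(n1 * n2 + 1, dtype=float)
    offset = n1 * (n1 - 1) // 2  # sum of the n1 smallest 0-based ranks
    for subset in combinations(range(n), n1):
        pmf[sum(subset) - offset] += 1.0
    return pmf / pmf.sum()


def _exact_two_sided_p(u: np.ndarray, pmf: np.ndarray) -> np.ndarray:
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(U >= u)
    u = u.astype(int)
    return np.minimum(1.0, 2.0 * np.minimum(cdf[u], sf[u]))


def run_ranksum(m: CountMatrix, d: SampleDesign) -> DEResult:
    """Two-sided Wilcoxon rank-sum detector on normalized counts.

    Exact null distribution when n_T + n_C <= 10 and a gene has no ties;
    otherwise a tie-corrected normal approximation with continuity
    correction.  logFC is the same group-mean ratio as ``run_nbwald``.
    """
    d.check_matches(m)
    norm = normalized_counts(m)
    xc, xt = _group_arrays(norm, d)
    nc, nt = xc.shape[1], xt.shape[1]
    n = nc + nt
    both = np.concatenate([xc, xt], axis=1)
    ranks = stats.rankdata(both, axis=1)
    r_t = ranks[:, nc:].sum(axis=1)
    u = r_t - nt * (nt + 1) / 2.0  # Mann-Whitney U for the treatment group

    # tie-corrected normal approximation (vectorized over genes)
    sorted_vals = np.sort(both, axis=1)
    tie_term = np.zeros(both.shape[0])
    for g in range(both.shape[0]):
        _, counts = np.unique(sorted_vals[g], return_counts=True)
        tie_term[g] = np.sum(counts**3 - counts)
    sigma2 = nc * nt / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mean_u = nc * nt / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mean_u - np.sign(u - mean_u) * 0.5) / np.sqrt(sigma2)
    p = np.where(sigma2 > 0, 2.0 * stats.norm.sf(np.abs(np.where(sigma2 > 0, z, 0.0))), 1.0)
    p = np.clip(p, 0.0, 1.0)

    if n <= 10:
        no_ties = tie_term == 0
        if no_ties.any():
            pmf = _exact_u_pmf(nt, nc)
            p[no_ties] = _exact_two_sided_p(u[no_ties], pmf)

    mu_c = xc.mean(axis=1) + PSEUDOCOUNT
    mu_t = xt.mean(axis=1) + PSEUDOCOUNT
    table = pd.DataFrame(
        {"logfc": np.log2(mu_t / mu_c), "pvalue": p, "fdr": bh_adjust(p)},
        index=m.gene_ids,
    )
    return DEResult("ranksum", table)


# ---------------------------------------------------------------------------
# import path


def import_results(path, method_name: str) -> DEResult:
    """Load an externally produced per-method table (gene, logfc, pvalue[, fdr]).

    A missing fdr column is recomputed from the p-values by BH.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    required = {"gene", "logfc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    df = df.set_index("gene")
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene row(s): {list(dup)}")
    if "fdr" not in df.columns:
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    return DEResult(method_name, df[["logfc", "pvalue", "fdr"]])


def run_all_detectors(m: CountMatrix, d: SampleDesign) -> list[DEResult]:
    """Run the three native detectors on one dataset."""
    return [run_modt(m, d), run_nbwald(m, d), run_ranksum(m, d)]
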