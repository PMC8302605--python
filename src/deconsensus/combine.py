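"""Integration of per-method DE results into consensus calls.

Four combination strategies are provided:

* a minimum-vote system tagging genes PREVALENT (called DE by at least
  ``min_votes`` methods), POSSIBLE (called by at least one but fewer) or
  NOT_DEG, where a method "calls" a gene when FDR < p_cutoff and
  |logFC| >= lfc_cutoff;
* a combined logFC as the arithmetic mean of the per-method estimates;
* a combined FDR via Fisher's method, X^2 = -2 * sum(ln FDR_i) against a
  chi-square with 2k degrees of freedom (applied to FDR values, accepting
  the known conservativeness, for fidelity to the vote criteria);
* a Gaussian Naive Bayes classifier trained on vectors of per-method
  significance evidence from simulated datasets with known DEG labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEResult

PREVALENT = "PREVALENT"
POSSIBLE = "POSSIBLE"
NOT_DEG = "NOT_DEG"

#: floor applied to FDR values before taking logs in Fisher's method
FISHER_CLAMP = 1e-300
#: cap on the -log10(p) evidence features fed to the classifier
FEATURE_CLIP = 300.0


@dataclass
class CombineConfig:
    """Significance thresholds shared by the vote system and combined-FDR call."""

    p_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    min_votes: int = 2

    def __post_init__(self) -> None:
        if self.lfc_cutoff < 0:
            raise ValueError("lfc_cutoff must be >= 0")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")


def _aligned_tables(results: Sequence[DEResult]) -> list[DEResult]:
    if not results:
        raise ValueError("need at least one DEResult")
    base = set(results[0].gene_ids)
    for r in results[1:]:
        diff = base.symmetric_difference(r.gene_ids)
        if diff:
            raise ValueError(
                f"gene sets differ between {results[0].method_name} and "
                f"{r.method_name}: {len(diff)} genes in the symmetric difference"
            )
    order = results[0].table.index
    return [DEResult(r.method_name, r.table.loc[order]) for r in results]


def de_calls(results: Sequence[DEResult], cfg: CombineConfig) -> pd.DataFrame:
    """Boolean gene x method table: FDR < p_cutoff AND |logFC| >= lfc_cutoff."""
    aligned = _aligned_tables(results)
    return pd.DataFrame(
        {
            r.method_name: (r.table["fdr"] < cfg.p_cutoff)
            & (r.table["logfc"].abs() >= cfg.lfc_cutoff)
            for r in aligned
        }
    )


def vote_tag(results: Sequence[DEResult], cfg: CombineConfig) -> pd.DataFrame:
    """Vote counts and PREVALENT/POSSIBLE/NOT_DEG tags per gene."""
    calls = de_calls(results, cfg)
    if cfg.min_votes > calls.shape[1]:
        warnings.warn(
            f"min_votes={cfg.min_votes} exceeds the {calls.shape[1]} supplied "
            "methods; no gene can be PREVALENT",
            stacklevel=2,
        )
    votes = calls.sum(axis=1)
    tag = np.where(
        votes >= cfg.min_votes, PREVALENT, np.where(votes >= 1, POSSIBLE, NOT_DEG)
    )
    return pd.DataFrame({"votes": votes.astype(int), "tag": tag}, index=calls.index)


def fisher_combine(values) -> float:
    """Fisher's method for one gene: chi-square upper tail of -2*sum(ln v), 2k df."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    if np.any(~np.isfinite(v)) or np.any(v > 1) or np.any(v < 0):
        raise ValueError("values must be finite and in [0, 1]")
    v = np.maximum(v, FISHER_CLAMP)
    x2 = -2.0 * np.sum(np.log(v))
    return float(stats.chi2.sf(x2, 2 * v.size))


def fisher_combine_matrix(fdr: pd.DataFrame) -> pd.Series:
    """Row-wise Fisher combination of a gene x method FDR table (vectorized)."""
    v = np.maximum(fdr.to_numpy(dtype=float), FISHER_CLAMP)
    x2 = -2.0 * np.log(v).sum(axis=1)
    return pd.Series(stats.chi2.sf(x2, 2 * fdr.shape[1]), index=fdr.index)


def mean_logfc(values) -> float:
    """Arithmetic mean of per-method logFC estimates for one gene."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    if np.any(~np.isfinite(v)):
        raise ValueError("logFC values must be finite")
    return float(v.mean())


def combine_results(
    results: Sequence[DEResult],
    cfg: CombineConfig,
    nb_model: "NBModel | None" = None,
) -> pd.DataFrame:
    """Full combined table: votes, tag, mean logFC, Fisher FDR, NB posterior.

    The combined-FDR significance call mirrors the vote criteria:
    combined_fdr < p_cutoff AND |combined_logfc| >= lfc_cutoff.
    """
    aligned = _aligned_tables(results)
    out = vote_tag(aligned, cfg)
    lfc = pd.DataFrame({r.method_name: r.table["logfc"] for r in aligned})
    fdr = pd.DataFrame({r.method_name: r.table["fdr"] for r in aligned})
    out["combined_logfc"] = lfc.mean(axis=1)
    out["combined_fdr"] = fisher_combine_matrix(fdr)
    out["combined_call"] = (out["combined_fdr"] < cfg.p_cutoff) & (
        out["combined_logfc"].abs() >= cfg.lfc_cutoff
    )
    if nb_model is not None:
        # classifier evidence is the raw per-method p-value vector
        pvals = pd.DataFrame({r.method_name: r.table["pvalue"] for r in aligned})
        posterior, call = nb_model.predict(pvals)
        out["nb_posterior"] = posterior
        out["nb_call"] = call
    return out


# ---------------------------------------------------------------------------
# Naive Bayes classifier


@dataclass
class NBModel:
    """Gaussian Naive Bayes over per-method significance evidence.

    Features are -log10 of the supplied p-values (adjusted p-values when the
    caller provides them), clipped to [0, 300]; each class gets one Gaussian
    per method and priors follow the training label frequencies.
    """

    method_names: list[str]
    prior_deg: float
    prior_non: float
    mean_deg: np.ndarray
    var_deg: np.ndarray
    mean_non: np.ndarray
    var_non: np.ndarray
    feature_transform: str = "neglog10_clip300"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.var_deg <= 0) or np.any(self.var_non <= 0):
            raise ValueError("class-conditional variances must be positive")
        if not np.isclose(self.prior_deg + self.prior_non, 1.0):
            raise ValueError("class priors must sum to 1")

    # -- persistence (human-readable key-value text) --

    def to_file(self, path) -> None:
        fmt = lambda v: ",".join(f"{float(x):.17g}" for x in np.atleast_1d(v))
        lines = [
            f"feature_transform\t{self.feature_transform}",
            f"methods\t{','.join(self.method_names)}",
            f"prior_deg\t{float(self.prior_deg):.17g}",
            f"prior_non\t{float(self.prior_non):.17g}",
            f"mean_deg\t{fmt(self.mean_deg)}",
            f"var_deg\t{fmt(self.var_deg)}",
            f"mean_non\t{fmt(self.mean_non)}",
            f"var_non\t{fmt(self.var_non)}",
        ]
        for k, v in self.metadata.items():
            lines.append(f"meta_{k}\t{v}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "NBModel":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    k, v = line.rstrip("\n").split("\t", 1)
                    kv[k] = v
        vec = lambda s: np.array([float(x) for x in s.split(",")])
        meta = {k[5:]: v for k, v in kv.items() if k.startswith("meta_")}
        return cls(
            method_names=kv["methods"].split(","),
            prior_deg=float(kv["prior_deg"]),
            prior_non=float(kv["prior_non"]),
            mean_deg=vec(kv["mean_deg"]),
            var_deg=vec(kv["var_deg"]),
            mean_non=vec(kv["mean_non"]),
            var_non=vec(kv["var_non"]),
            feature_transform=kv["feature_transform"],
            metadata=meta,
        )

    # -- prediction --

    def predict(self, p_table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        """Posterior P(DEG | evidence) and the call posterior > 0.5 per gene."""
        given = list(p_table.columns)
        if given != self.method_names:
            raise ValueError(
                f"method mismatch: model expects {self.method_names}, got {given}"
            )
        x = nb_features(p_table.to_numpy(dtype=float))
        log_deg = np.log(self.prior_deg) + _gauss_loglik(x, self.mean_deg, self.var_deg)
        log_non = np.log(self.prior_non) + _gauss_loglik(x, self.mean_non, self.var_non)
        # normalized in log space for numerical stability
        m = np.maximum(log_deg, log_non)
        post = np.exp(log_deg - m) / (np.exp(log_deg - m) + np.exp(log_non - m))
        posterior = pd.Series(post, index=p_table.index, name="nb_posterior")
        return posterior, posterior > 0.5


def nb_features(p: np.ndarray) -> np.ndarray:
    """Evidence transform: -log10(p) clipped to [0, 300]."""
    with np.errstate(divide="ignore"):
        return np.clip(-np.log10(np.maximum(p, 10.0**-FEATURE_CLIP)), 0.0, FEATURE_CLIP)


def _gauss_loglik(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var).sum(axis=1)


def nb_train(
    feature_tables: Sequence[tuple[pd.DataFrame, pd.Series]],
    metadata: dict | None = None,
) -> NBModel:
    """Train the classifier from (gene x method p-value table, is_deg labels) pairs.

    Each pair typically comes from one simulated dataset; at least two are
    expected so the evidence spans several simulation settings.  Training is
    deterministic given the inputs.
    """
    if len(feature_tables) < 2:
        raise ValueError("need >= 2 training datasets")
    methods = list(feature_tables[0][0].columns)
    xs, ys = [], []
    for table, labels in feature_tables:
        if list(table.columns) != methods:
            raise ValueError("inconsistent method columns across training tables")
        xs.append(nb_features(table.to_numpy(dtype=float)))
        ys.append(np.asarray(labels, dtype=bool))
    x = np.vstack(xs)
    y = np.concatenate(ys)
    if y.all() or not y.any():
        raise ValueError("training data must contain both DEG and non-DEG labels")
    var_floor = 1e-9 * max(float(x.var()), 1.0)
    model = NBModel(
        method_names=methods,
        prior_deg=float(y.mean()),
        prior_non=float(1.0 - y.mean()),
        mean_deg=x[y].mean(axis=0),
        var_deg=np.maximum(x[y].var(axis=0), var_floor),
        mean_non=x[~y].mean(axis=0),
        var_non=np.maximum(x[~y].var(axis=0), var_floor),
        metadata=metadata or {},
    )
    return model
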