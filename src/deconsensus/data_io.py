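"""Count-matrix I/O, expression filtering, normalization and sample QC.

The raw input is a gene-by-sample table of read counts plus a sample design
("target") table assigning each sample to the CONTROL or TREATMENT group and
optionally carrying extra numeric or categorical trait columns.  This module
validates those inputs, removes genes with little evidence of expression
(a counts-per-million threshold in a minimum number of samples), computes
median-of-ratios size factors for the downstream detectors, and produces
sample-level quality-control summaries (PCA, sample-sample correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "CONTROL"
TREATMENT = "TREATMENT"

#: accepted spellings in the design file, mapped onto the two group levels
GROUP_ALIASES = {
    "CTRL": CONTROL,
    "CONTROL": CONTROL,
    "C": CONTROL,
    "TREAT": TREATMENT,
    "TREATMENT": TREATMENT,
    "T": TREATMENT,
}


@dataclass
class CountMatrix:
    """Non-negative integer gene-by-sample count table.

    Wraps a pandas DataFrame (genes as rows, samples as columns) and enforces
    unique identifiers, integral non-negative counts and >= 2 samples.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        dup_genes = df.index[df.index.duplicated()].unique()
        if len(dup_genes):
            raise ValueError(f"duplicate gene id(s): {list(map(str, dup_genes))}")
        dup_samples = df.columns[df.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValueError(f"duplicate sample id(s): {list(map(str, dup_samples))}")
        if df.shape[1] < 2:
            raise ValueError(f"need at least 2 samples, got {df.shape[1]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
            raise ValueError(f"non-numeric counts in column(s): {list(bad)}")
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                f"non-integral count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        self.counts = df.astype(np.int64)
        self.counts.index.name = "gene"
        self.counts.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleDesign:
    """Per-sample group labels (CONTROL/TREATMENT) and optional trait columns."""

    group: pd.Series  # index = sample ids, values in {CONTROL, TREATMENT}
    traits: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        bad = set(self.group.unique()) - {CONTROL, TREATMENT}
        if bad:
            raise ValueError(
                f"unknown group label(s) {sorted(bad)}; accepted: "
                f"{sorted(GROUP_ALIASES)} (mapped to CONTROL/TREATMENT)"
            )
        for level in (CONTROL, TREATMENT):
            if (self.group == level).sum() == 0:
                raise ValueError(f"group {level} is empty")
        if self.traits is None or self.traits.empty:
            self.traits = pd.DataFrame(index=self.group.index)
        elif not self.traits.index.equals(self.group.index):
            raise ValueError("trait table index must match the sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group.index)

    def samples_in(self, level: str) -> list[str]:
        return list(self.group.index[self.group == level])

    def check_matches(self, m: CountMatrix) -> None:
        """Require set equality between design samples and count-matrix samples."""
        a, b = set(self.sample_ids), set(m.sample_ids)
        if a != b:
            raise ValueError(
                f"design/count sample mismatch: {sorted(a - b)} only in design, "
                f"{sorted(b - a)} only in counts"
            )


@dataclass
class FilterConfig:
    """Low-expression filter: keep genes with >= min_cpm CPM in >= min_samples samples."""

    min_cpm: float = 2.0
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.min_cpm < 0:
            raise ValueError("min_cpm must be >= 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path) -> CountMatrix:
    """Read a TSV count table (first column gene ids, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(m: CountMatrix, path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="gene")


def read_design(path) -> SampleDesign:
    """Read a TSV target table: sample id, group label, optional trait columns.

    Group labels are mapped through :data:`GROUP_ALIASES`.  A trait column is
    typed numeric when every value parses as a number, categorical otherwise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.shape[1] < 1:
        raise ValueError("design file needs at least a group column")
    raw = df.iloc[:, 0].str.upper()
    unknown = sorted(set(raw) - set(GROUP_ALIASES))
    if unknown:
        raise ValueError(
            f"unknown group label(s) {unknown}; accepted labels: {sorted(GROUP_ALIASES)}"
        )
    group = raw.map(GROUP_ALIASES)
    group.name = "group"
    traits = df.iloc[:, 1:].copy()
    for col in traits.columns:
        as_num = pd.to_numeric(traits[col], errors="coerce")
        if as_num.notna().all():
            traits[col] = as_num
    return SampleDesign(group=group, traits=traits)


def write_design(d: SampleDesign, path) -> None:
    out = pd.DataFrame({"treat": d.group.map({CONTROL: "CTRL", TREATMENT: "TREAT"})})
    for col in d.traits.columns:
        out[col] = d.traits[col]
    out.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# normalization and filtering


def cpm(m: CountMatrix) -> pd.DataFrame:
    """Counts per million: counts scaled so every sample column sums to 1e6."""
    libsize = m.counts.sum(axis=0)
    zero = libsize.index[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero)}")
    return m.counts / libsize * 1e6


def filter_low_expression(m: CountMatrix, cfg: FilterConfig | None = None) -> CountMatrix:
    """Drop genes without >= min_cpm CPM in >= min_samples samples.

    CPM is evaluated on the matrix as given (pre-normalization); the sample
    set is unchanged.  Idempotent up to the CPM recomputation on the reduced
    library sizes only in the sense tested: the kept-gene rule is re-applied
    to the already-filtered matrix and must keep everything.
    """
    cfg = cfg or FilterConfig()
    if cfg.min_samples > m.shape[1]:
        raise ValueError(
            f"min_samples={cfg.min_samples} exceeds sample count {m.shape[1]}"
        )
    keep = (cpm(m) >= cfg.min_cpm).sum(axis=1) >= cfg.min_samples
    return CountMatrix(m.counts.loc[keep])


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors with a library-size fallback.

    For genes with all-positive counts, each sample's factor is the median of
    counts[g, s] / geometric-mean_g(counts).  When no such gene exists the
    factors default to library sizes.  Factors are rescaled to geometric
    mean 1 so that normalized counts stay on the raw-count scale.
    """
    arr = m.counts.to_numpy(dtype=float)
    allzero = np.where(arr.sum(axis=0) == 0)[0]
    if len(allzero):
        raise ValueError(f"all-zero sample(s): {[m.sample_ids[i] for i in allzero]}")
    positive = (arr > 0).all(axis=1)
    if positive.any():
        sub = arr[positive]
        log_geomean = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geomean[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        factors = arr.sum(axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def normalized_counts(m: CountMatrix) -> pd.DataFrame:
    """Counts divided per sample by the median-of-ratios size factor."""
    return m.counts / size_factors(m)


def log_cpm(m: CountMatrix) -> pd.DataFrame:
    """log2(CPM + 1), the transform used for PCA, correlation and co-expression."""
    return np.log2(cpm(m) + 1.0)


# ---------------------------------------------------------------------------
# quality control


def qc_summaries(m: CountMatrix, n_components: int | None = None) -> dict:
    """Sample-level QC on log2(CPM+1): PCA coordinates and Pearson correlation.

    Returns a dict with ``pca_coordinates`` (samples x components),
    ``variance_explained`` (percent per component, non-increasing) and
    ``sample_correlation`` (samples x samples, unit diagonal).
    """
    x = log_cpm(m)
    if float(x.to_numpy().std()) == 0.0:
        raise ValueError("constant expression matrix: correlation undefined")
    per_sample_sd = x.std(axis=0, ddof=0)
    if (per_sample_sd == 0).any():
        raise ValueError(
            f"constant sample(s) {list(per_sample_sd.index[per_sample_sd == 0])}: "
            "correlation undefined"
        )
    corr = x.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)

    k = n_components or min(m.shape[1] - 1, 10)
    centered = (x - x.mean(axis=1).values[:, None]).to_numpy()  # center per gene
    # SVD on samples-as-observations; scores are the PCA coordinates
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    coords = u[:, :k] * s[:k]
    total_var = (s**2).sum()
    var_explained = 100.0 * (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    pcs = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return {
        "pca_coordinates": pd.DataFrame(coords, index=m.sample_ids, columns=pcs),
        "variance_explained": pd.Series(var_explained, index=pcs),
        "sample_correlation": corr,
    }
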