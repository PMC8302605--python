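# Methods

This note documents the models and procedures implemented in `deconsensus`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## Filtering, normalization and QC

Genes are kept when they reach `min_cpm` counts per million in at least
`min_samples` samples (defaults 2 and 2), evaluated on the raw counts before
normalization. The filter is idempotent and monotone in the threshold.

Normalization uses median-of-ratios size factors: for genes with positive
counts in every sample, the factor of sample *s* is the median of
`counts[g,s] / geometric-mean_g`. When no all-positive gene exists the
factors fall back to library sizes. Factors are rescaled to geometric mean 1
so normalized counts stay on the raw-count scale. Detectors consume
`counts / factor`; PCA, sample correlation and co-expression use
`log2(CPM + 1)` (the pseudo-count is a stability choice; the transform for
these steps was otherwise an open design point).

## Detectors

All three detectors share the sign convention logFC > 0 ⇔ overexpressed in
treatment, use pseudo-count 0.5 against zero means, and adjust p-values by
Benjamini–Hochberg (delegated to `statsmodels.multipletests`; a brute-force
step-up oracle backs it in the tests).

**Moderated t (`modt`).** On `y = log2(normalized + 0.5)`: pooled residual
variance `s²_g` with `d = n − 2` df; the prior `(d₀, s₀²)` is estimated by
matching the first two moments of `log s²_g` to a scaled-F model (the
digamma/trigamma construction; the trigamma inverse is solved by Newton
iteration). Posterior variance `s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)`;
moderated t has `d₀ + d` df (normal when `d₀ = ∞`, i.e. when the observed
spread of `log s²` does not exceed chi-square sampling noise). `prior_df`
can be forced to 0 (ordinary pooled t) or ∞ for testing.

**NB Wald (`nbwald`).** Group means `μ̂` of normalized counts; per-gene
moment dispersion `φ̂ = max(0, (s²_within − μ̄)/μ̄²)` shrunk 50/50 toward the
across-gene median; Wald statistic on `ln((μ̂_T+0.5)/(μ̂_C+0.5))` with
delta-method variance `(1/μ̂ + φ)/n` per group, two-sided normal p. The 50/50
shrinkage is a deliberately simple stand-in for the likelihood-based
dispersion shrinkage of the established NB packages.

**Rank-sum (`ranksum`).** Two-sided Wilcoxon rank-sum on normalized counts.
Exact null distribution (by exhaustive subset enumeration) when
`n_T + n_C ≤ 10` and the gene has no ties; otherwise a tie-corrected normal
approximation with continuity correction. At 3 vs 3 the smallest exact
two-sided p is 2/20 = 0.1, so this detector cannot reach FDR < 0.05 at that
depth — kept as honest small-sample behaviour rather than patched.

## Combination strategies

A method **calls** a gene when `fdr < p_cutoff` *and* `|logfc| ≥ lfc_cutoff`
(defaults 0.05 and 1). Vote tags: PREVALENT when votes ≥ `min_votes`,
POSSIBLE when 1 ≤ votes < `min_votes`, NOT_DEG otherwise. PREVALENT sets are
nested across thresholds by construction.

Combined logFC is the arithmetic mean of the per-method estimates. The
combined FDR applies Fisher's method directly to the per-method FDR values
(`X² = −2Σ ln FDRᵢ`, upper-tail χ² with 2k df, inputs floored at 1e-300).
Applying Fisher to already-adjusted values is conservative; it is kept
because it is the integration rule this methodology defines. The combined
significance call mirrors the vote criteria (`combined_fdr < p_cutoff` and
`|combined_logfc| ≥ lfc_cutoff`), and the combined FDR is *not* re-adjusted
across genes afterwards.

### Naive Bayes evidence classifier

Trained on vectors of raw per-method p-values from simulated datasets with
known labels. Features are `−log10 p` clipped to [0, 300]; each class gets
one Gaussian per method (variances floored at `1e-9 × max feature variance`)
and priors follow the training label frequencies; prediction accumulates
log-likelihoods and calls a gene when the posterior exceeds 0.5. Raw
p-values (not FDR) are the evidence, matching the methodology's definition
of the training vectors; the choice is recorded in the model metadata, and
models serialize to a human-readable key-value text file.

Known limitation: the conditional-independence assumption is strongly
violated here because all detectors see the same counts. With three native
detectors at 3 vs 3 replicates the classifier over-calls borderline genes
(precision ≈ 0.6 versus ≈ 0.85 for the vote system at threshold 2) while
achieving the best recall, and it is the clear winner when the true effect
size is at the call cutoff (|log2FC| = 1), where cutoff-based strategies
collapse. Its pooled held-out F-measure sits ≈ 0.05–0.06 below the best
competing strategy on the benchmark grid; alternative feature transforms
(probit z-scores, sqrt-log) were evaluated and do not change this materially,
so the documented transform was kept.

## Simulator

Each gene receives a baseline mean and dispersion either parametrically —
`μ ~ LogNormal(4, 2)` on the natural-log scale with trend
`φ = 0.1 + 1/μ`, chosen to resemble bulk RNA-seq moments — or by resampling
per-gene (mean, dispersion) pairs estimated from a template count table by
method of moments. `round(pdeg × n_genes)` genes are flagged as true DEGs
(exact by construction); a fraction `up_fraction` (default 0.5) get
treatment mean `μ·2^logfc`, the rest `μ·2^−logfc`. Counts are gamma-Poisson
draws, independent per sample, so `φ = 0` is exactly Poisson. Grids iterate
the Cartesian product of parameter lists with per-dataset seeds derived by a
splitmix64 mix of (base seed, cell index, replicate index), making any grid
cell reproducible in isolation.

What the generator does **not** emulate: between-gene correlation (module
structure is produced by the separate planted-module fixture generator),
sample-level library-size variation, batch effects, outlier samples and
isoform structure. A green benchmark therefore establishes correctness of
the statistical machinery under a clean NB world, not robustness to real
data pathologies.

## Evaluation

Confusion counts cover every simulated gene: genes removed by the
expression filter are scored as not-called, so filtered-out true DEGs count
as false negatives (conservative). Precision, recall and F-measure with a
zero denominator are reported as missing, and grouped summaries exclude
them with an exclusion count. AUC is the rank-based (Mann–Whitney)
statistic with average ranks for ties, identical to the trapezoidal ROC
area; detectors and the combined FDR are ranked by FDR with raw p as
tie-break (the ranking statistic was an open point; the choice is recorded
here), vote thresholds get no AUC (binary calls), and the classifier is
ranked by its posterior.

## Co-expression (WGCNA-lite)

Unsigned network: adjacency `|cor|^β` with β the smallest candidate power
whose signed scale-free fit R² (log-log regression of degree frequency on
binned connectivity, 10 bins, negated for positive slopes) reaches 0.8,
else the best-fitting candidate. Topological overlap
`t_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`; modules from
average-linkage clustering of `1 − TOM` cut statically at height 0.975,
clusters under 30 genes pooled into module 0 and survivors renumbered by
size. The static cut replaces the dynamic tree cut because it is fully
specifiable and testable. Eigengenes are the unit-norm first principal
component of the standardized member matrix, sign-aligned to correlate
non-negatively with the module mean profile. Trait correlation: Pearson r
with a two-sided t-test (n − 2 df) for numeric traits; categorical traits
(and the control/treatment grouping itself, included because group status
is the trait of primary interest) are expanded into one 0/1 indicator per
level; rows are flagged at p < 0.05; constant traits yield an undefined r.

The planted-module fixture draws each module's latent factor as a standard
normal per sample and members as `√ρ·factor + √(1−ρ)·noise`, so members
correlate at ρ in expectation and modules are mutually independent. Note
that a small block-structured fixture is not scale-free, so recovery tests
run at a fixed moderate power (8) rather than through the automatic
selector.

## Over-representation analysis

Queries and gene sets are intersected with the background universe first
(default in the pipeline: all genes surviving the expression filter — the
measured universe). `p = P(X ≥ k)` under Hypergeom(N, K, n); BH within the
tested family; per-module enrichment corrects within each module's family.
Sets with zero overlap report p = 1.

## Numerical choices and degenerate inputs

Fisher inputs floored at 1e-300 before logs; NB feature clip at 300 on the
−log10 scale; classifier variance floor `1e-9 × max variance`; constant
genes dropped (with warning) before co-expression; constant expression
matrices, all-zero samples, single-class truth vectors and empty grids are
rejected with descriptive errors. Ranks use average tie-handling
throughout. All stochastic components take explicit integer seeds and are
deterministic given them.
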