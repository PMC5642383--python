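# Methods

`regmut` implements a regional (megabase-scale) analysis of somatic mutation
density against normal-tissue chromatin features, of the kind used to ask
*when* during cancer progression the cell-of-origin chromatin state begins to
shape the mutation landscape. This note records the models, the numerical
choices, and what the synthetic tests do and do not establish.

## Coordinate frame

All quantities live on a tiling of the autosomes into equal-width windows
(default 1 Mbp). Coordinates are 0-based half-open throughout; 1-based
mutation inputs (MAF-like TSV, VCF) are converted on read. Trailing partial
windows are **dropped**, not truncated, so every window has identical width
and densities are comparable without length normalization. Windows are
removed (a) by any-overlap with exclusion regions — centromeres, telomeres,
blacklists, or analysis-specific sets such as differentially-methylated CpG
regions — and (b) when their mappable-coverage fraction falls below a
threshold (default 0.5; the right value depends on the mappability track in
use, so it is configurable and logged). Because windows are a regular grid,
interval overlap reduces to floor division and clipping; no interval-tree
machinery is needed.

## Quantification

Mutation density for a sample group is the summed per-window count over the
group's samples. Counting conserves records exactly: counts plus the logged
number of records falling outside retained windows equal the records
selected. ChIP-seq-style reads are assigned to the window containing the
interval midpoint (one read, one window — no double counting); peak and
replication-timing scores are distributed as score × (overlap length /
interval length), which conserves total score across retained windows. No
depth normalization is applied by default: the downstream forest is
invariant to monotone per-feature scaling. Multi-allelic records expand to
one record per alternate allele.

For matched precancer/cancer pairs, mutation identity is (chrom, pos, ref,
alt) — the sample of origin is ignored, the standard convention for matching
somatic calls — and a pair partitions into precancer-only / common /
cancer-only sets that are disjoint with union equal to the pair's distinct
mutations. The precancer member of a pair is identified by its cohort label
(`precancer_cohort` parameter).

## Sample embedding

Samples are compared by 1 − Pearson correlation of their per-window count
vectors (range [0, 2]; values within 1e-12 of the endpoints are snapped to
them, so perfectly correlated or anticorrelated profiles land exactly on 0
and 2). Classical metric scaling embeds the samples: square the
dissimilarities, Gower double-center, eigendecompose, scale the top-k
eigenvectors by √λ. 1 − r dissimilarities need not be Euclidean, so negative
eigenvalues can occur; they are clamped to zero for the coordinates and
their relative mass is reported, never silently dropped. Axis orientation is
fixed by making the largest-magnitude loading on each axis positive, for
reproducible plots. Per-sample total-count normalization before correlating
is available behind a flag and off by default (raw counts).

## Random-forest feature selection

The response is the per-window group mutation density; the predictors are
the per-window chromatin features. A bootstrap ensemble of regression trees
(default 1000 trees) is evaluated entirely out-of-bag:

* **Variance explained (VE)** is the OOB pseudo-R²,
  `1 − MSE_oob / Var(y)`, with each window's OOB prediction the mean over
  trees whose bootstrap excluded it. VE may be negative. `Var(y) = 0`
  returns VE = 0 with a warning. The bootstrap is re-drawn (fresh sub-seed)
  in the unlikely event some window is in-bag for every tree.
* **Permutation importance** of feature *m* is the mean over trees of the
  per-tree OOB MSE increase when column *m* is permuted within that tree's
  OOB rows. Ranks are by descending importance, ties broken
  lexicographically by feature name.
* **Greedy backward elimination** restricts to the top-20 features by
  importance, then repeatedly refits, records VE, and removes the currently
  least-important member (importances are re-evaluated at each step by
  default — that is what makes the procedure greedy; a flag freezes the
  initial ranks). A feature's selection score is the VE of the step at which
  it was the weakest active member, which makes the per-feature bars
  directly comparable to the all-features reference line.
* **Repeats**: the whole cycle repeats (default 1000×) under independent
  sub-seeds; per-feature scores are summarised as mean/min/max, and the
  **significance line** is the mean full-model VE minus one standard error
  of that mean (SEM = sd/√R). A feature is significant when its mean step VE
  reaches the line **and is positive** — a feature whose model explains no
  variance cannot be called significant regardless of where a (possibly
  negative) threshold sits; without this clause the rule degenerates on null
  data, where the threshold lies just below a full-model VE of ≈ 0.

Forest hyperparameters follow regression-forest convention: F/3 candidate
features per split, minimum leaf size 5, bootstrap size W with replacement —
all configurable. Determinism is a contract: every stochastic step draws
from `SeedSequence(master, spawn_key=(domain, *indices))` with fixed domain
constants (`regmut._seeds`), so an identical master seed reproduces the full
`SelectionSummary` bit-for-bit, and independent re-implementations (the test
suite's brute-force importance loop) can replay the exact streams.

## Category variance partitioning

Features are grouped by tissue/cell type, each category carrying a shared
mark panel (H3K27me3, H3K36me3, H3K4me1, H3K4me3, H3K9me3, ± accessibility).
A category's VE comes from a forest on its columns alone; its null
distribution from repeated random draws of equally many features from the
pool (optionally excluding the category, the stricter comparison). The
empirical p-value uses the add-one estimator `(1 + #{null ≥ obs}) / (1 + n)`
— never exactly zero, with resolution floor `1/(n_iter+1)`; at the default
1000 draws the smallest reportable value is 1/1001 ≈ 0.001, and a claim like
"p < 2.2e-16" is reported as "below the resolution floor". Between-category
correlation concatenates the two categories' tracks in matched-assay order
and takes the Spearman correlation; categories with different assay panels
are a hard error rather than a silent partial match.

## Differential-region prediction

Given the same mark measured in a "source" tissue (the state the cells are
thought to have shifted toward) and a "target" tissue (the tissue of
origin), regress target on source across all windows and select the windows
in the top 5% of residuals (ceiling on the count, ties broken by window
index) that also show target > source — the windows with excess
target-tissue signal. Two OLS models of observed density (one per tissue
track, trained on all windows) are evaluated at the selected windows;
observed-vs-predicted and predicted-vs-predicted differences use a paired
two-sided Wilcoxon signed-rank test (a paired t-test is available behind a
flag; the location-test family is a documented choice — the comparison the
procedure needs is "is one prediction systematically off here"). The
per-region table of (target − source difference, |observed − source-model
error|) and its Spearman correlation quantify whether larger chromatin
differences predict better. An all-zero difference vector (e.g. exactly
equal predictions) yields p = 1 by convention; constant columns make the
correlation undefined and are reported as NaN with a warning.

## Synthetic cohorts

The generator stands in for controlled-access mutation cohorts and external
epigenome panels. Feature tracks are lag-1 autocorrelated Gaussian series
over window index (default autocorrelation 0.5, mimicking megabase-scale
smoothness of chromatin signal), with within-category cross-correlation ρ
(default 0.5) through a shared latent component, affinely mapped to a
nonnegative signal-like range (location 100, scale 20). Mutation counts
follow a log-linear model: λ_i = exp(baseline + Σ β_k z_ik) on standardized
causal features, per-sample counts Poisson(λ·scale) or negative-binomial
(gamma-Poisson) when overdispersion is set. Defaults: 5 causal features with
β = 0.4…0.8, baseline log-rate 0 (≈1 mutation/Mb/sample at the feature
mean, a realistic whole-genome burden), 20 samples.

A note on the VE regime these defaults produce: five effects of 0.4–0.8 on
standardized Gaussian features give sd(log λ) ≈ 1.4 (≈ 2.3 when the causal
features are mutually correlated), so the exponential link produces
heavy-tailed counts whose variance is dominated by a few extreme windows.
An OOB forest cannot extrapolate to those windows, so full-model VE
measures ≈ 0.2–0.55 depending on seed — well below what the same procedure
reports on real regional mutation data (where the dynamic range across
megabase windows is far smaller). The recovery and calibration guarantees
are therefore stated as ratios, ranks and bands, which are stable in this
regime; the absolute VE level on synthetic data is not a claim about real
data.

Paired cohorts draw a precancer catalog, keep each mutation in the matched
cancer sample with probability `shared_fraction`, and add fresh draws from
the cancer rate model; the realized shared fraction is recorded. The
metaplasia scenario plants `n_planted` windows with a +3σ target-track
boost; the log-rate follows the source track plus a mean-corrected lognormal
distortion whose sd shrinks linearly with the realized target − source
difference (1.0 at zero difference, 0 at 1.5×boost), encoding "the larger
the chromatin shift, the more faithfully the source state sets the mutation
rate" — the mechanism behind the difference-vs-accuracy correlation.

What the synthetic tests do **not** show: real chromatin tracks are not
Gaussian, real mutation rates carry sequence-context and replication-timing
structure beyond a log-linear model, and real cohorts have per-sample
burden heterogeneity. Passing tests establish that the *procedures* recover
a known generating structure under their stated conditions, not that any
biological conclusion transfers.

## Problem sizes and profiles

Library defaults match the full-scale procedure (1000 trees, 1000 repeats,
1000 null draws). The test suite and the `run-all` interactive profile use
scaled-down sizes (100 trees, 20–50 repeats, windows in the hundreds) chosen
so the statistical assertions remain sharp; `--paper-scale` restores
1000/1000. The significance rule, seeds and thresholds are identical across
profiles.

## Known limitations

* ChIP read assignment by midpoint ignores reads straddling window edges in
  proportion to read length — negligible at 1 Mbp windows.
* The elimination path refits a forest per step; at full scale (1000 trees ×
  1000 repeats × 20 steps) this is compute-heavy and is the reason the
  scaled profile exists.
* `category_correlation` requires identical assay panels; heterogeneous
  panels must be subset first.
* The CLI's `--threads` flag is reserved; stages currently run serially.
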