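# Methods

## Scope and model assumptions

The package analyses two kinds of experiments on airway epithelium from
two donor groups:

* **bulk transcriptomics of mixed tissue** — each sample's expression is a
  convex mixture of cell-type expression profiles, so the abundance of a
  cell type in a sample is reflected jointly by all of its marker genes;
* **two-color competitive proliferation assays** — two labeled basal-cell
  populations grow exponentially in the same well on an unlabeled feeder
  layer, and their ratio is read out by flow cytometry at two timepoints.

All statistical machinery is chosen for *small cohorts*: exact rank tests
where attainable, and rank-based (distribution-free) screening elsewhere.

## Consensus marker discovery

**Candidate selection** (`RankSumMarkerSelector`, `select_candidates`).
For a cell-labelled count matrix, each gene is tested one-vs-rest
(target cells vs all others) with a two-sided Wilcoxon rank-sum test.
At cell-level group sizes (hundreds per group) the tie-corrected normal
approximation is the appropriate and the only feasible path; the test is
vectorized across genes. P-values are Benjamini–Hochberg adjusted across
genes and a gene is retained iff q < `fdr_threshold` (default 0.01) *and*
its mean expression is higher in the target cells — over-expressed, not
merely different. Cells are library-size normalized (total counts scaled
to the median total) before testing and means: median-of-ratios
normalization is undefined at cell level because virtually no gene is
non-zero in every cell. An optional gene-exclusion filter (driven by a
user-supplied gene→chromosome map) supports removing sex-chromosome genes
before selection so sex imbalance between groups cannot masquerade as
cell-type signal.

**Similarity and clustering** (`similarity_matrix`, `main_cluster`).
Counts are size-factor normalized, and the similarity of two genes is the
Pearson correlation of log2(normalized + 1) across samples (pseudocount 1
handles zeros). Genes with zero variance are flagged and given correlation
0 to all others. Agglomerative clustering runs on distance 1 − r with
*average linkage* and the tree is cut at distance 1 − `min_mean_r`
(default 0.5). Among clusters with ≥ 2 members and mean pairwise r ≥
`min_mean_r`, the *main* cluster is the largest; ties break toward higher
mean correlation, then the lexicographically first member, so results are
deterministic. Linkage and cut are config-exposed because co-expression
module extraction has no single canonical setting; average linkage on
correlation distance is the conventional choice. When no cluster
qualifies, an empty panel with an explicit "no co-correlating cluster"
status is returned rather than an exception, so a cohort-level failure is
diagnosable in the consensus step.

**Consensus** (`ConsensusMarkerFinder`, `consensus_markers`). The main
cluster is extracted per cohort on the candidate genes (candidates missing
from any cohort are dropped with a warning) and the consensus panel is the
set intersection across all cohorts, reported in candidate order. The
result is invariant to cohort order and is always a subset of the
candidates.

## Normalization and composition scoring

**Size factors** (`MedianOfRatiosNormalizer`, `size_factors`). The
median-of-ratios estimator: the reference for each gene is its geometric
mean across samples; genes containing any zero are excluded; a sample's
factor is the median ratio of its counts to the reference. This matches
the default DESeq2 normalization exactly (verified against pydeseq2 in the
test suite). Note a structural property: rescaling one of n samples by c
rescales *all* normalized counts by c^(1/n), because the geometric-mean
reference absorbs c^(1/n). Per-sample depth changes therefore leave all
*between-sample ratios* of normalized values (and of marker scores)
invariant — that scale-free quantity is what the tests assert, to 1e-9.

**Marker score** (`GeometricMarkerScorer`, `marker_score`). A sample's
score for a panel is the geometric mean of (normalized count + ε) over the
panel genes, computed in log space so 1000-gene panels at ~1e6 neither
overflow nor underflow. The pseudocount ε defaults to 0, in which case a
single zero marker zeroes the score; ε is config-exposed and recorded in
output metadata because zero handling is a genuine analysis choice.
Panel genes absent from the matrix are dropped with a logged warning
(panels derived on other platforms routinely miss genes); a panel with no
gene present is an error.

**Group comparison** (`compare_groups`). Exactly two groups; delegates to
the exact Wilcoxon test below and reports per-group medians.

## Exact Wilcoxon rank-sum test

`wilcoxon_exact` computes the Mann–Whitney U of the first group and a
two-sided p-value p = min(1, 2·min(P(U ≤ u), P(U ≥ u))). For tie-free data
with n1 + n2 ≤ `exact_cap` (default 30) the null distribution is built by
the exact counting recurrence f(a,b;u) = f(a−1,b;u−b) + f(a,b−1;u) — the
largest rank joins either group — so small-cohort p-values are exact
rationals on the enumeration lattice (e.g. the minimum attainable
two-sided p for 3 vs 3 is 2/20 = 0.1). With ties, or beyond the cap, the
tie-corrected normal approximation with continuity correction is used;
when the tie-corrected variance is zero (all observations identical) p is
1. The `method` flag in the result records which path ran. Counts up to
C(30,15) ≈ 1.55e8 are exact in float64.

`benjamini_hochberg` validates inputs in (0, 1] and delegates to
statsmodels' step-up implementation; outputs preserve input order, satisfy
q ≥ p and q ≤ 1, and are monotone on sorted inputs.

## Competitive proliferation analysis

Under exponential growth, the fold change of the labeled ratio over X days
is Y = 2^(X(1/td_focal − 1/td_ref)), so

    G_a = (td_focal − td_ref)/td_ref × 100
        = −td_ref·log2(Y) / (X + td_ref·log2(Y)) × 100.

`ratio_change` excludes unlabeled feeder events by renormalizing over
labeled events (algebraically a no-op on the ratio, which is why feeder
contamination at any level < 1 cannot bias Y); a color at 0% is rejected
("population extinct or unlabeled") since Y is undefined, and such wells
are excluded from pair summaries and counted in diagnostics.
`growth_advantage` enforces the domain X + td_ref·log2(Y) > 0 (a positive
implied focal doubling time). Percent inputs are required on the 0–100
scale; inputs that sum to ≤ 1.5 at both timepoints are rejected as likely
0–1 fractions unless `allow_fraction_scale` is set, preventing silent 100×
errors. `summarize_pair` computes per-well G_a against the reference
donor's doubling time, orienting Y by which color the focal donor carries,
and reports means separately per dye-swap orientation plus their average.

`doubling_time` regresses cumulative population doublings
(PD = log2(harvested/seeded) per passage) on cumulative days by least
squares through the origin and returns 1/slope; regression over all
passages is the default because it uses every passage rather than the
endpoints only, and an `endpoint` mode is provided. `viral_titre` is
(%positive/100 × cells plated)/volume, with the percentage explicitly
interpreted on the 0–100 scale; `colony_forming_efficiency` is
colonies/seeded × 100.

## Synthetic data

`simulate_mixture_counts` draws counts with mean
μ[g,s] = depth_s · Σ_c f[c,s]·π[g,c] from a negative binomial with
Var = μ + αμ² (gamma–Poisson mixture; α = 0 is the Poisson limit). This is
the standard bulk RNA-seq noise model and the one the median-of-ratios
normalization assumes. Each sample is drawn from the substream keyed by
(seed, column index), so identical parameters at the same position yield
identical columns regardless of the rest of the design.

`simulate_coculture` computes true population sizes
N_i(t) = N_i(0)·2^(t/td_i), mixes in a feeder fraction of unlabeled
events, and reports percentages either exactly (*analytic mode*,
`events=None`, which makes forward–inverse identities exact and serves as
a deterministic oracle) or by multinomial sampling of `events` flow events
over (A, B, unlabeled). `simulate_doubling_curve` applies mean-one
log-normal noise with a given CV to per-passage harvests.

`make_marker_discovery_scenario` builds the default marker-discovery
study: 3 cohorts × 60 samples, a 10-gene marker block carrying half the
target cell type's expression, 200 decoy genes expressed equally by both
cell types (hence carrying no compositional signal), a mirror block
expressed only by the background type (keeping profiles normalized; not
in the candidate panel, as an over-expression screen would not have
selected it), target fraction ~ U(0.1, 0.6), depth ~ U(5e4, 1.5e5), NB
dispersion 0.05. These defaults were chosen once as realistic bulk
RNA-seq scales for tissue cohorts; with them, same-type marker pairs
correlate at r ≈ 0.8–0.9 and decoys at r ≈ 0.

**What the generators do and do not emulate.** They reproduce the
compositional correlation structure, depth variation, over-dispersion,
feeder contamination and finite flow sampling that the methods rely on.
They do not model batch effects, single-cell dropout, UMI structure,
lag phases, contact inhibition or density-dependent growth — so passing
tests demonstrate correctness of the estimators under the stated models,
not robustness to those real-data phenomena.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] and symmetrized before clustering;
  zero-variance genes get r = 0 off-diagonal and are flagged.
* Geometric means are computed in log space; a zero with ε = 0 short-
  circuits to score 0 rather than exp(−inf) arithmetic.
* Exact-test p-values are never 0; the minimum attainable two-sided p is
  2/C(n1+n2, n1).
* Duplicate gene or sample names, negative counts, non-integer counts
  (without `allow_float`), mismatched MTX sidecars, and percent/fraction
  scale confusion are all rejected with messages naming the offending
  entity.
* Output CSVs are written with 9-significant-digit floats so repeated runs
  are byte-identical; every CLI output carries a JSON manifest with
  config, seed, package versions and input checksums sufficient to re-run
  the stage.

## Problem sizes in the test suite

The suite exercises the pipeline at the study's own scales: 3-vs-3 and
7-vs-8 cohort comparisons, 3 cohorts × 60 samples × 210 candidate genes
for consensus recovery, 2000 genes × 1000 cells × 100 runs for FDR
control under a global null, 500 seeded replicates × 10,000 flow events
for estimator calibration, and 1000 null simulations for the type-I error
of the group comparison.

## Known limitations

* The consensus step is a single-cut hierarchical clustering; it does not
  attempt multi-resolution or network-based module detection.
* Doubling times are external inputs to the growth-advantage calculation
  (as in the assay design), not jointly estimated from the co-culture.
* `select_candidates` treats cells as exchangeable replicates; it does not
  model donor structure within cell labels.
* Median-of-ratios normalization requires at least one gene with non-zero
  counts in every sample; matrices violating this are rejected rather
  than silently rescued.
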