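# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Differential expression

### Proteins

Label-free MS intensities are nonnegative reals with explicit
non-detection; absence is informative (a cell is missing, not zero), so all
statistics run over *detected* values only. For each protein the
fold-change is the ratio of detected-sample means, case over control, on
the linear scale — matching how fold-changes are conventionally reported
for these data. The test is a two-sided Welch *t* on log intensities:
Welch rather than pooled because cohort sizes and variances are routinely
unequal in patient studies (a `equal_var=True` flag restores the pooled
test, and `log_transform=False` tests raw intensities; both choices are
deliberately exposed because either convention appears in practice).
Proteins with zero detections in either cohort are excluded before
testing; proteins with fewer than two detected values in a group cannot be
tested and are reported with p = q = 1 outside the FDR family, rather than
silently dropped. Degenerate zero-variance features get p = 1 when the
group means agree and p = 0 otherwise.

### Transcripts

Counts are normalized with TMM scaling factors: reference sample = the one
whose upper-quartile count fraction is closest to the cohort mean; genes
zero in either member of a pair are dropped pairwise; 30% two-sided trim on
log2 ratios (M) and 5% on average log2 abundance (A); inverse-asymptotic-
variance weighted mean of the surviving M values; factors rescaled to
product 1 so effective library size = raw × factor. The implementation is
cross-checked in the test suite against Bioconductor edgeR's
`calcNormFactors` (agreement ≈ 1e-7 on a 200×6 fixture). FPKM uses these
effective sizes: count / ((length/10³)(effective size/10⁶)).

The test is a conditional exact test with a single common dispersion.
Counts are scaled to the geometric-mean effective library size and group
totals y₁, y₂ formed (rounded to integers; the rounding error is ≪ the
counting noise at the library sizes used). Modelling each group total as
NB with shape r_j = n_j/φ and a shared success parameter, the conditional
distribution of y₁ given t = y₁+y₂ is negative-hypergeometric — free of
the unknown mean — and the two-sided p-value is the total conditional
probability of outcomes no more likely than the observed one. As φ → 0
this reduces exactly to the binomial split test Binomial(t, n₁/(n₁+n₂)),
which the tests verify. φ is estimated by method of moments: the mean over
genes (pooled within-group variance − mean)/mean², using genes with mean
scaled count ≥ 1, floored at 0. Moment estimation is adequate here because
only a single common dispersion is needed; per-gene (tagwise) dispersion,
GLM designs and covariates are out of scope.

Fold-change uses the normalized group means with a 0.5 pseudocount —
applied to the fold-change only, never the test, so the test stays exact
while ratios stay finite. A gene is significant when q ≤ α (default 0.05)
**and** the fold-change is at least `fc_min` (default 2) in either
direction; the threshold is interpreted on the linear scale, symmetric
(≥ 2 or ≤ 0.5). Transcripts with no nonzero count in either cohort are
excluded, mirroring the protein rule. FDR families are per ome: the two
omes are corrected separately because they are separate experiments with
separate detection processes.

Benjamini–Hochberg adjustment is the step-up rule q₍ᵢ₎ = min over j ≥ i of
p₍ⱼ₎·m/j capped at 1; the suite checks it against the brute-force
definition and statsmodels.

## Over-representation

One-sided binomial tails, matching the convention of reference-list ORA
tools: for fold enrichment ≥ 1 the upper tail P(X ≥ k) with
X ~ Binomial(n, K/N), for under-represented sets the lower tail (rows
carry fold_enrichment < 1 so direction is explicit). The binomial model is
an approximation to sampling without replacement; the exact hypergeometric
test is available via `test="hypergeometric"`. `tail="over"` forces the
upper tail for every set — that fixed one-sided version is the calibrated
choice (its p-values are stochastically super-uniform under random lists,
which the acceptance tests verify with 2,000 draws), whereas the
direction-adaptive default is a reporting convention, not a calibrated
p-value. FDR correction is optional because scanning both corrected and
uncorrected lists is a legitimate exploratory workflow.

Redundant GO-style terms (near-identical membership) merge by
single-linkage clustering at Jaccard similarity ≥ 0.5 on reference-
restricted member sets. Single linkage at 0.5 is a reproducible stand-in
for the judgment-based merging such term lists usually receive; the
threshold is a parameter. GO hierarchy traversal is intentionally not
implemented — term relationships enter only through member overlap. A
user-supplied blocklist of regex patterns removes terms irrelevant to the
assayed cell type, with removals logged.

## Concordance and coupling

Detection filter: a feature enters set-level analysis only if detected in
at least `min_detect` (default 5) samples of *each* cohort, boundary
inclusive.

Direction classes use strict cuts: up above 1.1 (a >10% increase), down
below 0.9, exactly-at-boundary = unchanged. For the set-level proportion
test, members instead split at FC > 1 vs FC < 1 (FC exactly 1 counts in
neither arm) and the split (n_up, n_down) is tested with the two-sided
pooled two-proportion z-test with continuity correction — the numerator is
floored at 0 and a degenerate pooled proportion returns p = 1. This equals
the Yates-corrected chi-square on the equivalent 2×2 table and R's
`prop.test`; both equivalences are tested.

Two denominator conventions coexist deliberately: set-level tests compare
n_up vs n_down each out of (n_up + n_down), while whole-ome ("global")
tests compare the significant-up and significant-down counts each out of
the total detected population. The pair of conventions is the one that
reproduces all of the published worked examples the suite checks.

The magnitude test is a two-sided one-sample *t* of all member
fold-changes against 1, on the linear scale because per-set average
fold-changes are reported linearly (log-scale testing is a one-liner on
the caller's side; the linear choice is recorded in the output). Zero
variance or fewer than two members yields NaN — undefined tests propagate
as NA and never silently become 0 or 1, except the documented degenerate
pooled-proportion case.

Coupling: each ome is called up (down) when its proportion test has
p ≤ α and the majority points that way, mixed otherwise, none when
untestable; (down, up) → `discordant_t_down_p_up`, (up, down) →
`discordant_t_up_p_down`, matched calls → `concordant_up`/`concordant_down`,
anything else → `undetermined`.

## Synthetic cohorts

The generator emulates the *structure* of a paired LCL cohort study:

* 20 cases vs 20 controls by default (the transcriptomic cohort size).
* Transcripts: per-gene abundances log-normal(μ=3, σ=1.2); library sizes
  uniform on 100k–160k; counts NB with common dispersion 0.1 (typical for
  biological replicates of a cell line panel); case means multiplied by
  the gene's set-level transcript fold-change.
* Proteins: log intensities normal with per-protein baseline
  N(21, 1.5²) and sample noise SD 0.4 (a ~40% CV, mid-range for label-free
  quantification); case samples shifted by log(protein fold-change);
  detection probability logistic in log intensity (midpoint 19.5, slope 1),
  so dim proteins go missing more often — the missing-not-at-random
  mechanism that makes proteome coverage an order of magnitude sparser
  than the transcriptome. An MCAR model would not reproduce that.
* Set sizes follow the detected-member counts of the study's mitochondrial
  functional groups (44 Complex I transcripts / 26 proteins, 19/12 for
  Complex V, 52/11 for SLC25, …) so synthetic concordance tables have the
  same shape and power as the published ones; planted directions are
  transcript 0.8× / protein 2.0× for complexes I–IV, 0.8×/0.8× for
  Complex V and the ribosome, protein-only gains for TCA and TIMM/TOMM,
  1.5×/1.5× for immune and sphingolipid sets.
* The gene universe is ~2.4k genes (and the null-calibration scenario uses
  500 genes at 10 vs 10 with proportionally shallower libraries): a
  scaled-down universe with per-gene depth in the same regime as a
  mid-expressed gene in the full-size experiment, chosen so the 50-seed
  calibration and recovery studies are routine to run. Percent-scale
  global summaries (21% / 4%) depend on the real data and are validated
  from the printed counts, not from simulation.

What the generator does **not** emulate: read- or spectrum-level noise,
peptide-to-protein inference, batch structure, covariates (age/sex),
gene–gene correlation, and composition effects beyond the planted
fold-changes. Passing recovery tests therefore show the statistics behave
correctly under the assumed model, not that the model captures every
property of real cohorts.

## Numerical conventions

* Exact-test tie handling: outcomes with conditional log-probability
  ≤ observed + 1e-9 count toward the p-value; p capped at 1.
* Exact-test enumeration is chunked at 4M outcome states to bound memory;
  totals in the default scenarios stay ≪ that.
* All TSV output uses a fixed `%.10g` float format and sorted JSON keys,
  making reruns byte-identical.
* Proportion tests validate 0 ≤ x ≤ n and n > 0; the global test
  additionally requires n_up + n_down ≤ n_total.
* Gene sets are intersected with the reference before testing; sets with
  no reference members are skipped with a log notice.

## Known limitations

* The common-dispersion exact test is the closest faithful stand-in for a
  scaling-normalized count analysis whose exact internals (exact test vs
  GLM, dispersion flavor) are not pinned down; all constants sit in
  function signatures.
* The binomial ORA inherits the reference-list tool's model choice; for
  small references the hypergeometric flag is more accurate.
* Coupling calls for tiny sets (e.g. 2 detected proteins) are structurally
  `undetermined` — the proportion test cannot reach α with two members.
* The magnitude test treats member fold-changes as independent;
  co-regulated complexes violate that, so its p-values are optimistic for
  tightly co-expressed sets.
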