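# Methods

## Scope and model

`bindexpr` implements a two-group integrative analysis of transcription-factor
occupancy and gene expression from count data. The statistical core is the
classic negative-binomial (NB) treatment of sequencing counts: feature *i* in
library *j* is modelled as

    k_ij ~ NB(mean = s_j · q_i,g(j),  variance = mean + α_i · mean²)

with library size factors `s_j`, per-group concentrations `q_i,g`, and a
per-feature dispersion `α_i ≥ 0` (`α = 0` recovers Poisson). All genomic
coordinates are 0-based half-open (BED native); GTF-style 1-based inclusive
inputs must be converted on read.

## Binding regions

Peaks from all cell lines are pooled and merged transitively wherever they
overlap or abut. "Abutting" means `end_a == start_b` exactly — a 1-bp gap is
not merged. Support is the set of distinct *cell lines* contributing a peak
(replicate peak lists for a line should be unioned before merging); regions
with support 1 are removed before any counting, since a single-line region
cannot be distinguished from line-specific artifact. Fragment rescoring
counts ≥ 1 bp overlaps; because merged regions are disjoint, a fragment can
hit two regions only by spanning the gap between them, and is then counted
in both. Cross-set comparisons (`overlap_sets`) use the same ≥ 1 bp
convention. Conversion of short reads to fragments (fixed strand-aware
extension) is assumed done upstream; the synthetic generator emits 200-bp
fragments directly.

## Differential testing

*Size factors.* Median-of-ratios: `s_j = median_i k_ij / (Π_v k_iv)^{1/m}`
over features with all-positive counts. An error is raised when no such
feature exists rather than silently switching reference.

*Dispersions.* Within a library set (one group by default), normalized
counts `x_ij = k_ij/s_j` give per-feature mean `q̂_i` and sample variance
`w_i`; the raw method-of-moments dispersion is
`max(0, (w_i − q̂_i · mean_j(1/s_j)) / q̂_i²)` (shot noise subtracted). A
trend `α(q) = a₀ + a₁/q` is fitted by least squares over features with
`q̂ > 0`, with `a₀, a₁` floored at 0 so the trend is non-increasing and
nonnegative. The working per-feature dispersion is the **fitted trend value**
(floored at 1e-8). The conservative alternative `max(raw, fitted)` is
available (`sharing="max"`), but at 4 replicates per group the raw
method-of-moments estimate is so noisy that taking the maximum systematically
inflates dispersions and visibly deflates null p-values (Kolmogorov–Smirnov
distance from uniform 0.04–0.09 versus 0.02–0.05 for the trend rule, whose
residual deviation matches the discreteness floor of the exact test itself).
Trend sharing keeps the realized false-discovery proportion at the nominal
level on planted data; its cost is sensitivity to genuine per-feature
dispersion outliers, which the generator (and the fitted model) do not
include.

*Exact test.* For each feature the group sums `K_A`, `K_B` are modelled as NB
with moment-matched null parameters: pooled concentration
`q₀ = mean_j(k_ij/s_j)`, mean `μ_g = q₀ Σ_{j∈g} s_j` and variance
`Σ_{j∈g} (q₀ s_j + α_i q₀² s_j²)` using each group's dispersion fit. The
two-sided p-value sums the conditional probabilities of all splits
`a + b = K_A + K_B` no more probable than the observed one, normalized by the
total over splits. Underdispersed inputs are clamped to Poisson. For totals
above 10,000 the conditional distribution is replaced by a moment-matched
normal (continuity-corrected, two-sided); the switch point keeps the exact
enumeration at desk-scale runtime while affecting only features where the
discrete and normal tails already agree closely. An all-zero feature has no
evidence and gets p = 1.

*Multiple testing.* Benjamini–Hochberg step-up (via statsmodels), strict
`FDR < q` for significance; q defaults to 0.05. Fold change is
`mean_A / mean_B` of normalized group means, undefined (written `N/A`) when
the denominator is zero — never reported as infinity. Group means are
reported on the normalized scale averaged over libraries, the convention
that reproduces published "read counts" columns.

*Units of replication.* Binding is tested on one pooled column per cell line
(4 vs 4); expression on replicate libraries (8 vs 8 with 2 replicates per
line). Both are just count matrices to `run_differential`; callers can pool
with `CountMatrix.pooled_by_cell_line`.

## Regulatory domains and enrichment

Basal domain: 5 kb upstream / 1 kb downstream of the TSS, strand-aware,
inclusive of the TSS. Extension: up to 1 Mb beyond each basal edge,
truncated at the nearest neighboring gene's basal domain (running extremes
over sorted neighbors, so a long basal domain further away also truncates)
and at chromosome bounds; the extension never shrinks below the gene's own
basal domain, and basal domains may overlap each other. These defaults are
the standard basal-plus-extension association settings and are exposed as
parameters.

Association is whole-region ≥ 1 bp overlap with the *extended* domain; a
region may pair with zero, one, or many genes. TSS-relative positions use
the region midpoint (summits are not recoverable after merging — a
documented divergence from summit-based distances), signed negative
upstream. The enrichment test is region-based binomial: a region hits a term
if its midpoint lies in the union of extended domains of genes carrying the
term; the null hit probability is that union's share of genome bp; the
p-value is the upper binomial tail. The gene-based hypergeometric companion
test is out of scope.

## Integration

Gene/BR pairs are joined with both differential tables and classified
(both-significant / binding-only / expression-only / neither) by strict
FDR < q on each axis. Dually significant pairs fall into four direction
quadrants (binding up in A or B × expression up in A or B). The concordance
statistic compares observed quadrant counts `o` with expected counts
`e = n · (binding marginal) · (expression marginal)` — the marginals are an
explicit input, defaulting to each table's genome-wide significant direction
proportions, because tying them to the 823-pair subset would make the test
partially self-referential. The statistic is `Σ (o−e)²/e` with **df = 3**
(goodness-of-fit against externally supplied marginals, not the 1-df
independence test of an internally estimated 2×2 table). Expected counts are
displayed truncated to integers, as such tables are conventionally printed,
but contributions and the statistic are always computed from the unrounded
values; the table also carries the reader-recomputable `(o − ⌊e⌋)²/⌊e⌋`
column.

On/off genes: significantly differential genes whose minor-group normalized
mean is strictly below 5.

Clustering preparation: `log(x+1)` (natural log; any base differs by a
constant absorbed by the standardization, and +1 handles zeros), per-library
(column) centering and unit sample-variance scaling with zero-variance
columns zero-filled, then per-feature (row) scaling to unit sum of squares
with all-zero rows left at zero. Hierarchical clustering itself is a
visualization choice left to standard tooling.

## Synthetic data

The generator emulates the study design the pipeline targets: 8 cell lines
in two groups of 4, one ChIP library per line and 2 RNA replicates per line,
a 160 Mb four-chromosome genome with 1,600 non-overlapping genes (TSS
spacing ≥ 20 kb) and ~1,260 planted binding regions. Defaults (all
`SimulationConfig` fields):

- baseline concentrations `q_i ~ LogNormal(5, 1.2)` (median ≈ 150 counts);
- dispersion trend `α = 0.05 + 5/μ`, evaluated at each group's mean so the
  mean–variance relationship is identical for differential and
  non-differential features at a given mean;
- library size factors uniform on [0.5, 2];
- differential fractions 0.34 (binding) and 0.075 (expression), with A-up
  shares 0.56 and 0.81 — the observed study-level proportions; planted
  |log₂ fold changes| uniform on [2, 6];
- half of the A-up differential genes are "on/off" (minor-group mean uniform
  on [0.05, 0.8], so observed counts are typically < 5);
- 70% of regions are parked inside a gene's basal promoter window
  (−4 kb … +0.8 kb of the TSS) and half of those specifically at
  differential genes; a region linked to a differential gene becomes
  differential with probability 0.8 and copies the gene's direction with
  probability 0.85 — this linkage is what plants binding–expression
  concordance. The residual differential probability among remaining regions
  is solved so the overall binding differential fraction meets its target;
- occupancy per cell line: 0.9 for shared regions, 0.95/0.5 for the
  up/down group of differential regions, plus 5% singleton regions emitted
  in exactly one line to exercise the support filter; peak edges jittered
  ±20 bp, with ≥ 100 bp clearance between planted regions so jitter can
  never fuse two of them;
- fragments (200 bp) are placed to overlap their region by ≥ 20 bp, exactly
  `k_ij` per region and library, so rescoring recovers the planted counts up
  to edge effects; background fragments are off by default.

Randomness: one seed, with a fixed-key sub-stream per stage
(`SeedSequence(seed).spawn`-style), so outputs are byte-identical across
reruns and insensitive to stage order.

What the generator does **not** emulate: read-level artifacts (mappability,
GC bias, duplicate reads), peak-caller and reproducibility-analysis noise,
per-feature dispersion outliers off the trend, correlated counts between
neighboring regions, and annotation complexity (overlapping genes,
alternative TSSs). Passing tests therefore demonstrate correctness of the
statistical machinery under its stated model, not robustness to those
real-data pathologies.

## Numerical and design notes

- Exact-test tie comparison uses a 1e-9 additive tolerance in log space so
  group relabeling is exactly symmetric.
- Dispersions are floored at 1e-8; expected-count zeros and degenerate
  marginals raise errors rather than producing NaN statistics.
- Problem sizes in the test suite and acceptance script (2,000 features for
  calibration, default generator scale for the end-to-end study) were chosen
  so the whole suite runs in well under ten minutes on one CPU while keeping
  Monte-Carlo error well inside the asserted bounds.
- Known limitation: median-of-ratios normalization is biased when a large,
  direction-skewed fraction of features is differential (the A-group size
  factors absorb part of the signal). At the default study-level fractions
  the realized false-discovery proportion on planted data runs at ~0.06–0.08
  against a nominal 0.05; with heavier planted asymmetry it degrades
  further. This is a property of the normalization scheme itself and is left
  visible rather than corrected post hoc.
- Feature identifiers are treated as opaque and distinct; no gene aliasing
  layer is applied.
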