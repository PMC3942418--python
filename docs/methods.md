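# Methods

## Data model and preprocessing

The central object is a samples × taxa matrix of non-negative integer counts
with a strictly increasing month index per sample. Counts are assumed to be
raw read tallies per OTU; all downstream statistics presume the table has
been rarefied to a common depth, and the pipeline enforces this by rarefying
first.

**Read QC.** A read is kept iff it contains at most one ambiguous base (`N`)
and is at least 150 bp long. Both bounds are inclusive on the keep side
(N-count ≤ 1, length ≥ 150). The filter is idempotent and order-preserving.

**Rarefaction** subsamples each sample's read multiset without replacement
to the target depth — a multivariate hypergeometric draw per sample, all
samples driven by one seeded generator so a seed fully determines the
output. Without-replacement draws are unbiased for relative abundance,
which the test suite verifies by Monte Carlo. A sample shallower than the
depth is an error naming the sample, not a silent drop.

**Richness summaries.** Richness at a rank is the number of rank groups with
count ≥ 1 after collapsing (presence means ≥ 1 read; no relative-abundance
floor). Taxa unclassified at a rank collapse into one explicit
`unclassified` group which counts as one taxon by default
(`include_unclassified=False` drops it). Summary SDs use the **population
convention** (divisor *n*) throughout the package; recomputing the original
survey's printed per-sample genus values gives its printed SD only under
this convention (26.8 vs 28.0 with *n* − 1), so it is applied uniformly to
richness and moving-window statistics.

## Taxa–time relationship

The accumulation curve S(T) is built by **sliding windows** by default:
S(T) is the mean, over all n−T+1 contiguous windows of length T, of the
number of distinct taxa present anywhere in the window. This is the standard
TTR construction in the species–time literature; a **nested** variant
(accumulate from the first sample) is provided for sensitivity analysis
since the original survey does not state its construction. S(1) is then the
mean per-sample richness and S(n) the total distinct taxa observed, and
S(T) is non-decreasing.

The fit is unweighted OLS of log₁₀S on log₁₀T: w is the slope, c = 10^
intercept, r² the coefficient of determination. Any log base yields the same
w. A perfectly constant curve (zero slope, zero residual variance) is
reported as w = 0, r² = 0 with a warning rather than an error, so
time-invariant groups remain comparable.

**Per-phylum TTR** restricts the table to each phylum's member OTUs (full
OTU resolution — phylum-level presence alone could not produce distinct
per-phylum exponents) and refits. Groups present in fewer than two samples
are not scored. Dominant and rare sets are the k groups with highest and
lowest mean relative abundance (mean over samples of the group's proportion
of reads); the two sets must be disjoint, so k is rejected when 2k exceeds
the number of scorable groups. Note that in the original survey's published
per-phylum table the named five "most dominant" phyla are not exactly the
top five by the printed mean abundances (Chloroflexi, 1.9 %, is named ahead
of Firmicutes, 2.5 %); the published group means are reproduced from the
named sets, while this package's ranking is strictly by mean relative
abundance.

## Moving-window change and similarity

Pearson similarity is computed between relative-abundance profiles over the
union of taxa (proportions rather than counts, since samples are
depth-normalized upstream; a zero-variance profile is an error naming the
sample). The percent change between months x−1 and x is 100 · (1 − r); a
negative correlation therefore gives a change above 100 %, which is reported
unclamped (observed change rates in practice sit far below this). Δt is the
mean ± population SD of the n−1 consecutive changes; the SD convention is
recorded in the result object. The Sørensen matrix is the presence/absence
Dice coefficient 2|A∩B|/(|A|+|B|), computed after rarefaction; ordination
(NMDS etc.) of that matrix is left to external tools.

## CCA, forward selection, variance partitioning

Covariates are log₂(x+1)-transformed for standardization (so a {0,1} scale
indicator maps to {0,1}).

CCA is implemented from the chi-square eigen-formulation: with P the count
matrix divided by its grand total, row masses r and column masses c, the
standardized residual matrix is Q̄ᵢⱼ = (Pᵢⱼ − rᵢcⱼ)/√(rᵢcⱼ); total inertia
is ‖Q̄‖²_F, identical to the classical chi-square statistic divided by the
grand total. Covariates are centred under row-mass weighting, scaled by √r,
and Q̄ is projected onto their column space (rank-revealing SVD basis, so
collinear covariates degrade gracefully); the SVD of the projection gives
the constrained eigenvalues (squared singular values), site scores
(site-focused scaling), species scores and biplot scores. Eigenvalues are
invariant to taxon order and to affine rescaling of covariates; the
implementation agrees with an independent CCA implementation to machine
precision in the cross-check test. Partial CCA residualizes the covariates
on the conditioning variables in the same weighted geometry, measuring
inertia explained beyond the condition.

**Forward selection** greedily adds the candidate contributing the largest
additional constrained inertia, testing each addition by a seeded
permutation test: the candidate's residuals given the already-selected
variables are row-shuffled, and p = (b+1)/(m+1) where b counts permuted
statistics ≥ observed (the estimator cannot return 0; the minimal attainable
p at m permutations is 1/(m+1), e.g. 0.002 at 499). Selection stops when no
remaining candidate reaches p < 0.05. The default permutation count is 499.

**Variance partitioning** runs a plain CCA for every non-empty subset of the
three covariate groups (wastewater W, operational O, scale S) and solves the
inclusion–exclusion system for the seven Venn components of explained
inertia; unexplained is 1 minus the all-groups fraction, and the eight
values sum to 1 by construction. Fractions are raw inertia ratios (no
adjusted-R² correction, which matches the CCA-based partitioning tradition
this analysis follows). Shared components can be slightly negative —
a known property of inclusion–exclusion partitions — and are reported as
computed rather than truncated at zero.

## Synthetic community generator

The generator emulates the survey design so that every analysis stage has a
testable ground truth: 12 monthly samples at 13 422 reads, 15 phyla × 200
OTUs, phylum pool masses geometric with ratio 0.8 (the four dominant phyla
carry ≈ 0.77–0.87 of reads, inside the 0.73–0.95 band such communities
show), per-taxon lognormal abundance spread (σ = 1.5), presence following a
two-state Markov chain per taxon, a seasonal temperature sinusoid spanning
16.3–25.1 °C whose standardized value shifts the log-abundance of a random
10 % taxon subset by `env_coupling` (default 1.0), and multinomial read
sampling per month. Wastewater covariates (BOD, TN) are shared between the
two reactors of a pair; DO and SRT are per-reactor; the scale indicator is
0/1. Counts are drawn with replacement (multinomial) even though rarefaction
is without replacement: at depths far above per-taxon counts the distinction
is immaterial and generation stays simple.

Two calibration choices matter:

* **Occupancy by dominance class.** Dominant-phylum taxa are present in a
  month with probability 0.89, rare-phylum taxa 0.27. These occupancies
  place the mean global TTR exponent near 0.37 (within the 0.2–0.7 design
  bracket for such reactors) and make dominant phyla turn over more slowly
  than rare phyla in essentially every seed.
* **Memoryless chains by default.** The defaults set persistence equal to
  colonization, so presence is independent across months at the class
  occupancy and, with `env_coupling = 0`, months are exchangeable. This
  keeps the forward-selection permutation test exactly calibrated on
  null data: with chain memory (persistence > colonization at the same
  occupancy) the community drifts smoothly and genuinely aligns with any
  smooth seasonal covariate, so a row-permutation test over-selects it —
  a real property of autocorrelated time series, not an artifact. Users
  modelling month-to-month memory can raise persistence above colonization
  (occupancy stays col/(col+1−pers)) but should then interpret permutation
  p-values as liberal.

What the generator does **not** emulate: sequence-level error and chimeras
(QC is tested on hand-written FASTA fixtures), within-phylum phylogenetic
structure, interactions between taxa, and reactor upsets. Passing tests
therefore show the statistics behave correctly under the assumed sampling
model, not that the model captures every feature of real activated-sludge
series.

## Problem sizes and numerical conventions

The test suite and acceptance script run the synthetic design at its native
size (12 samples × 3000 taxa per reactor; 24 samples for the stacked
ordination) and use 199 permutations in property tests and 499 in the
pipeline default. Oracle comparisons use tolerances of 1e−10 (chi-square
inertia, exact power-law recovery) and 1e−9 (explained-fraction and VPA
identities). Rank decisions inside CCA use a relative singular-value cutoff
of 1e−9. Ties in forward selection are broken by candidate order after
sorting on the observed statistic (stable sort). Degenerate inputs —
constant accumulation curves, constant covariates, zero-total samples,
samples shallower than the rarefaction depth — either take a documented
convention (w = 0, r² = 0) or raise a validation error naming the offender.

## Known limitations

* The published whole-community exponents of the original survey
  (w = 0.43 / 0.55) cannot be re-derived here: they require the raw
  sequencing data and a retired classifier version, and the survey does not
  state its window construction. The package instead verifies its TTR
  machinery against brute-force enumeration and exact power-law recovery,
  and reproduces every internally consistent published summary from the
  printed per-sample and per-phylum values.
* The published OTU-level richness rows are internally inconsistent (their
  printed averages do not follow from their printed per-sample values) and
  are excluded from checks.
* Raw (unadjusted) inertia fractions in VPA are biased upward with few
  samples and many covariates; comparisons should hold covariate counts
  fixed.
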