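# Methods

This note documents the statistical model behind `morphsym`, the
conventions and tunable parameters, what the synthetic generator does and
does not emulate, and the design decisions taken where the procedure was
genuinely open.

## Object symmetry and the Procrustes decomposition

A structure with internal (object) bilateral symmetry is analyzed by
comparing each landmark configuration with its mirrored, label-swapped
copy.  The pairing scheme declares which landmarks form left/right pairs
and which lie on the symmetry axis; `reflect_relabel` mirrors across the
x-axis and exchanges pair labels (an involution whose fixed points are
the perfectly symmetric configurations).

`gpa_align` implements generalized Procrustes analysis: configurations
are centred, scaled to unit centroid size, and refitted to the
iteratively updated consensus by a proper rotation (determinant +1 —
reflection is never fitted, it is handled only by the explicit
reflect-relabel map) plus an optimal scale factor (the full Procrustes
fit; with scaling the consensus solves the classical complex
eigenproblem, which the tests use as an independent oracle).  Iteration
stops when the consensus moves by less than 1e-10 in Procrustes distance,
with a cap of 100 iterations and a warning on non-convergence.

For the symmetry decomposition the mirrored copies of all `n·r`
configurations join the superimposition (`2·n·r` configurations in
total) and the consensus is symmetrized each iteration.  Because a
symmetric consensus makes alignment commute with reflect-relabel, the
aligned mirrored copy equals the reflect-relabel image of the aligned
original to machine precision, and

* symmetric component  = (aligned original + aligned mirrored)/2 — an
  exact fixed point of reflect-relabel;
* asymmetric component = (aligned original − aligned mirrored)/2 — an
  exact sign-flipper; original = symmetric + asymmetric identically.

The asymmetric component is defined as the *half*-difference so this
conservation holds exactly; software that uses the full difference
differs by a constant factor 2 in all asymmetry magnitudes.

Axis convention: a symmetrized consensus automatically has its midline
landmarks on the x-axis; the configuration is additionally rotated so
the anterior axis-reference landmark sits at positive x.  This fixes the
longitudinal (cephalocaudal) axis used by the asymmetry profile.

Per-specimen components average over digitization replicates; the
replicate-level aligned copies are retained because the ANOVA error term
lives at that level.  Centroid size is reported in the original digitized
units (scaled by the TPS `SCALE` factor when present).

## Procrustes ANOVA

The response is the stack of `2·n·r` aligned copies, flattened to
`2K`-vectors.  Sums of squares are sequential (type I) projections for
three 1-df terms — sex, side, and sex×side — with all remaining
variation (individual shape, individual×side, replicate error) pooled
into the error row.  With 103 specimens, 2 replicates and the symmetry
doubling this leaves 411 − 3 = 408 error df.  Because sex is a
between-specimen factor while side is balanced within every
specimen-replicate, the design columns are mutually orthogonal and the
decomposition is exact (SS parts sum to the total).

The sex main effect tests sexual dimorphism of the symmetric component;
the side effect is directional asymmetry; sex×side is the sex contrast
in the asymmetric component (the row conventionally labelled fluctuating
asymmetry in two-way tables of this design).  F ratios use the pooled
error mean square.

RRPP p-values randomize reduced-model residuals at the exchangeable unit
of each term:

* sex and sex×side — whole-specimen residual blocks are permuted across
  specimens (all `2r` rows of a specimen travel together), because
  specimens, not rows, are exchangeable under those nulls;
* side — the two symmetry copies of each specimen-replicate are swapped
  at random, the natural randomization of left-right labelling.

All permutation p-values use the add-one estimator
`(count + 1)/(B + 1)`.  Default B = 1000; a type-I calibration of the
sex term over 200 null simulations is part of the test suite.

## The left-right triangle-area profile

For each bilateral pair, the axis-aligned right triangle from the
anterior axis-reference landmark to the pair member has area
`A = ½·|x_lm − x_ref|·|y_lm − y_ref|` (legs parallel and perpendicular
to the symmetry axis).  The descriptor is the percentage side contrast
`100·(A_R − A_L)/((A_L + A_R)/2)`, negative when the left-side area is
larger ("skewed to the left").  It is computed on the per-specimen
aligned configuration (symmetric + asymmetric component), is exactly
zero for a bilaterally symmetric specimen, and is invariant to uniform
scaling.  Pairs whose areas both vanish are flagged degenerate and
scored 0.  Profiles are ordered anterior→posterior by the scheme's
longitudinal order; an option removes each sex's mean asymmetric
component first, leaving the fluctuating part.

Conventions chosen here (the construction admits alternatives): the
triangle legs are axis-parallel, which makes "right triangle" true by
construction; values are per specimen (replicate-averaged); the sign
convention is area-based, not displacement-based.

Per-pair inference: a one-sample Z-test of the mean against 0, using the
sample standard deviation as σ by default (a fixed σ can be supplied);
zero-variance pairs are flagged (p = 0 for a nonzero mean, p = 1
otherwise).  Between sexes the samples are unpaired and of unequal size,
so a literally paired test is impossible at specimen level; Welch's
two-sample t is used per pair.

## Mantel correlation of module asymmetries

For a two-module partition, specimen-by-specimen Euclidean distance
matrices are computed from each module's asymmetric coordinates;
Mantel's r is the Pearson correlation of their lower triangles.  The
point test permutes rows/columns of one matrix (999 by default); a
bootstrap over specimens (5000 iterations by default) yields the
distribution of r used for the between-sex comparison, which *is* paired
— by bootstrap iteration index — with degenerate (zero-variance)
differences flagged.

## Covariance-ratio modularity

With coordinate columns grouped by landmark module (both coordinates of
a landmark always travel together), the covariance ratio for two modules
is

    CR = sqrt( Σ s_b² / sqrt( Σ s_w1² · Σ s_w2² ) )

where `Σ s_b²` sums squared between-module covariances (one term per
cross pair of columns) and `Σ s_wm²` sums squared off-diagonal
within-module covariances (trace-of-squared-block convention).  For more
than two modules the mean of all pairwise CRs is used.  CR → 0 indicates
modularity.  Note a finite-size property of this canonical form: with
all off-diagonal covariances equal, CR equals the ratio of between to
within entry counts (≈1.10 for two 6-column modules), approaching 1 only
as modules grow.

`cr_effect_size` builds the null by randomly reassigning landmarks to
modules with module sizes preserved; `Z = (CR_obs − mean_null)/sd_null`
is negative for modular signal.  The reported distribution repeats the
standardization over bootstrap resamples of the null set, giving the
spread summarized by the mean and 95% CI.  Pairwise model comparison
uses `|Ẑ₁₂|` (difference of distribution means) with the overlap
p-value `2·min(P(Z_low ≥ mean Z_high), P(Z_high ≤ mean Z_low))` clipped
to [0, 1] — a symmetrized tail fraction, chosen because "overlap ratio"
admits several formalizations; the choice is isolated in one function.
Letter groups are the maximal cliques of the non-significance graph
(compact letter display), so models share a letter exactly when their
signals are statistically similar at α = 0.05.

### Modularity test against arbitrary partitions

The hypothesized partition's CR (computed on the size-regressed
symmetric-component residuals) is compared with CRs of random partitions
with the same module sizes (default 10,000 rounds).  Shuffling landmarks
*within* modules leaves CR unchanged — an invariance of the statistic —
so the "observed distribution" under that jitter is degenerate at the
point value; the reported observed distribution instead shows the
sampling spread via a bootstrap over specimens, while the p-value is the
proportion of arbitrary CRs at or below the point CR (add-one
corrected).  Using the bootstrap mean instead would import the
bootstrap's small-sample bias into the p-value and make the test
conservative.

Calibration caveat: the random-reassignment null treats landmarks as
exchangeable.  The symmetric component of bilateral data is *not*
landmark-exchangeable — pair members mirror each other almost exactly —
so partitions that keep pairs intact start with lower CR than random
partitions that split them.  The calibration tests therefore run on
landmark-exchangeable block-correlated matrices
(`generate_shape_matrix`), where the test holds its nominal level;
on real symmetric components the p-value should be read as a comparison
against pair-blind partitions.

### Likelihood/AICc covariation-model selection

The landmark correlation matrix uses Tucker's congruence coefficient
between the centred n×2 coordinate blocks of each landmark pair (inner
product of the flattened blocks over their norms, in [−1, 1]).  A
covariation model assigns each unordered landmark pair to a parameter
group (within module m / between modules, shared or separate); the group
correlation estimate is the inverse Fisher-z of the mean Fisher-z of its
members, and the log-likelihood sums normal log-densities of z(r) with
variance 1/(n_eff − 3).  AICc uses k = number of correlation parameters
and sample size N = number of landmark correlations (the convention of
likelihood-based modularity selection; n_eff is available by option);
model weights are exp(−ΔAICc/2), normalized.

`enumerate_covariation_variants` expands each multi-module hypothesis by
crossing {shared, per-module} within-correlation with {pooled, per-pair}
between-correlation and deduplicating variants that induce the same
pair grouping (for two modules the between crossing collapses, leaving
two distinct variants; three modules give four).  The shipped seven
hypotheses — uniform, three bi-modular, three tri-modular anatomical —
expand to 19 distinct covariation models.  The specific variant list is
a reconstruction from the enumeration rule; only the hypothesis count
and the total are pinned by design.

## The synthetic generator

`generate_dataset` emulates the study design the package is built
around: 55 female and 48 male specimens (defaults), two digitization
replicates.  Per specimen it draws

* a symmetric individual shape deviation with exchangeable block
  correlation at the "slot" level (one slot per bilateral pair, one per
  midline landmark; ρ_within = 0.5 and ρ_between = 0.2 by default,
  SD σ_shape = 0.02 in units of the unit-centroid-size template),
  expanded mirror-symmetrically so individuals stay exactly symmetric
  before asymmetry is injected;
* a sex-specific directional asymmetry field added to the left-side
  landmarks (default: outward-normal displacement of +0.012 for females,
  −0.009 for males, giving opposite skews);
* individual fluctuating asymmetry on the left side, equicorrelated
  across coordinates at `asym_module_corr` (default 0.5) so module-wise
  asymmetries correlate — the dial the Mantel analysis tracks —
  with SD σ_fa = 0.01;
* per replicate, digitization noise (σ_digit = 0.004) and a random
  similarity transform (rotation ~ U(0, 2π), log-normal scale around a
  base size of 10 units, translation), so superimposition is genuinely
  exercised: asymmetry is injected in the template frame *before* the
  nuisance transform.

Defaults were chosen once as plausible magnitudes for Procrustes-scale
carapace variation (shape SD a few percent of centroid size, measurement
noise an order of magnitude smaller) and are not tuned per analysis.
Every drawn effect is returned in a truth record for recovery tests.

What the generator does not emulate: realistic carapace geometry (the
template is a schematic symmetric outline), allometric growth (size and
shape are independent, so the size regression estimates a true zero
slope), antisymmetry, landmark-specific digitization error, or
correlation between x and y deviations.  Passing tests demonstrate that
the estimators recover known structure of this form, not that real crabs
have any particular structure.

A second generator, `generate_shape_matrix`, draws landmark-exchangeable
block-correlated (n × 2K) matrices directly; it is the reference input
for calibrating and power-testing the modularity statistics.

Known second-order effect: the Procrustes projection makes the mean
asymmetric component a slightly biased estimate of the injected
directional field (bias O(σ²), independent of n); recovery tests compare
against a noise-free decomposition and allow for it.

## Problem sizes and numerical choices

The test suite runs at reduced sizes chosen for tightness per unit time:
calibration uses 200 null simulations with B = 199 permutations on
12-landmark, 20-specimen datasets; recovery uses 50 seeds (AICc,
n = 100, K = 12) and 20 seeds (modular signal); the acceptance script
runs the full 103-specimen design with 999 ANOVA permutations, 1000
Mantel bootstraps and 2000 modularity rounds.  Library defaults are the
full-scale counts (1000 ANOVA, 5000 Mantel, 999 CR, 10,000 modularity
rounds).  Correlation matrices are clipped to ±0.999999 before Fisher-z;
non-PSD block-correlation requests are shrunk toward the identity just
enough to restore PSD; all stochastic routines take explicit integer
seeds and the pipeline spawns per-stage seeds from one master seed.

## Limitations

2D landmarks only; object symmetry only (no matching symmetry of paired
separate structures); no semilandmark sliding; no phylogenetic
correction of modularity statistics; measurement-error decomposition is
limited to the pooled error term; no plotting — the pipeline emits CSV
tables and plain-text summaries.
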