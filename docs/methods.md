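# Methods

## Model

Differential coexpression of a gene pair is modeled as a change in the
pair's *dependence structure* between two conditions.  By Sklar's theorem a
bivariate joint distribution factors into its marginals and a copula; the
copula carries exactly the dependence.  Since expression marginals are
unknown and heavy-tailed, both conditions' copulas are estimated
nonparametrically: pseudo-observations are average-tie scaled ranks
u_k = rank(x_k)/m, and the empirical copula is the lower-quadrant counting
step function over the points (u_k, v_k).  The pair's score is the
two-sample Kolmogorov–Smirnov distance between the tumor and normal
empirical copulas.

Assumptions worth stating explicitly:

* samples within a condition are exchangeable (the copula ignores the
  matched-pair structure *within* a condition; pairing only aligns the two
  condition matrices over patients);
* dependence is evaluated pairwise — higher-order dependence among three or
  more genes is out of model;
* ranks are informative, i.e. profiles are not dominated by ties.  With
  heavy ties (e.g. zero-inflated counts) the pseudo-observations collapse
  and both the score and its theoretical bounds degrade; the Fréchet
  envelope tests therefore use tie-free data.

## Computing the KS distance

Both empirical copulas are piecewise-constant on the rectangular lattice
spanned by the union of their u-coordinates times the union of their
v-coordinates.  The supremum of |Ĉ₁ − Ĉ₂| over the unit square is therefore
*attained* on that lattice, and the default `pooled_points` mode computes
it exactly with a 2-D histogram and two cumulative-sum passes,
O((m₁+m₂)²) per pair.  Two alternative modes exist:

* `grid`: max over a regular lattice of the open unit square (a
  convergence cross-check; always ≤ the exact sup);
* `copula_values_1d`: the one-dimensional two-sample KS statistic between
  the two vectors of copula CDF values evaluated at each copula's own
  points.

The sup statistic obeys a hard ceiling: every copula lies between the
Fréchet–Hoeffding bounds max(u+v−1, 0) and min(u, v), whose sup-gap is 0.5,
so DC_Copula ≤ 0.5 + O(1/m).  Score thresholds above 0.5 (e.g. the 0.56
and 0.6 figures common in applications of this method) are only attainable
under the 1-d variant, which is unbounded below 1.  For this reason the
recovery experiment (below) defaults to `copula_values_1d`; everything else
defaults to the exact sup.

Scale-invariance holds *exactly* in this implementation: strictly
increasing per-profile transforms leave ranks, hence pseudo-observations,
hence the score bit-identical.  For strictly decreasing transforms applied
identically in both conditions the score can only stay equal or grow; with
equal sample sizes and tie-free data the lattice evaluation makes this
exact as well (tested at tolerance 1e-12).

## Copula density (diagnostic)

A beta-kernel density estimator is provided for visual inspection of a
pair's dependence; it never feeds the score.  At evaluation point (u, v)
the estimate averages products of beta densities with shape parameters
u/h+1, (1−u)/h+1 (Chen's boundary-adapted smoother), which is exactly
unbiased for the independence copula.  Pseudo-observations are rescaled by
m/(m+1) to keep them off the boundary.  The bandwidth h minimizes a plug-in
AMISE of the form A·h² + B/(mh), with the integrated bias/variance
constants computed against a Frank-copula reference fitted by inverting the
sample Kendall tau; the closed-form minimizer (B/2mA)^{1/3} is clipped to
[1/m, m^{−1/5}].

## Preprocessing

The count pipeline mirrors standard UMI practice: keep genes with count
> 2 in ≥ 4 samples (both strict thresholds configurable); scale each
sample to the median total count; rank genes by dispersion (variance/mean)
standardized within 20 equal-occupancy mean-expression bins (median/MAD
centering — robust to outlier bins) and keep the top 2000.  A per-pair
log2 fold change (pseudocount 1) is available as an alternative single-
matrix representation, but scoring consumes the two per-condition matrices
directly, because the score is defined on per-condition profiles.

## Modules, eigengenes, enrichment

The DC matrix converts to the dissimilarity 1 − score; modules come from
average-linkage (UPGMA) clustering, cut either to a requested k or at a
height (default 0.99 × the maximum merge height), with clusters below
`min_size` (default 5) folded into their nearest cluster by average
inter-cluster distance.  A module's eigengene is the first right singular
vector of the members' per-gene standardized expression (unit norm, sign
aligned to the mean member profile); `variance_explained` is the leading
eigenvalue fraction.  Eigengene networks are Pearson correlation matrices
among eigengenes computed separately within each condition; the composite
display puts normal above the diagonal and tumor below, so sign flips
across the diagonal mark condition-dependent module relationships.

Enrichment treats the post-filter scored gene set as the universe.
`pathway_score = n/m` is fold-enrichment with n = overlap/|module| and
m = |set∩universe|/|universe| (the alternative n = overlap/|set| is behind
a flag).  Over-representation uses the upper-tail hypergeometric p-value
with BH-FDR across all (module, set) tests; the CCDF curve uses each
module's *maximum* pathway score.

## Synthetic data

The generator emulates the simulation design used to validate the method:
each gene i.i.d. Gaussian per condition with per-gene means ~ U(2, 12) and
sds ~ U(0.5, 2) (log-scale-like magnitudes), p = 50 genes and m = 51
matched pairs by default.  Selected pairs receive controlled per-condition
Pearson correlations; in `exact` mode the *sample* correlation equals the
target to ~1e-12 via an orthogonalize-then-mix construction.  Noise
injection adds level × N(0, 1); a percent-style noise label maps to
level = percent/100 × pooled sd of the clean matrix.

A pair is "truly differentially coexpressed" when |ρ_normal − ρ_tumor| >
0.5 *and* the signs differ, evaluated on the realized noiseless sample.
At p = 50, m = 51 this rule also captures a handful of background pairs
whose sample correlations fluctuate across ±0.25, so recovery proportions
plateau below 1 even at zero noise — a property of the truth definition,
not a detection failure.

What the generator does *not* emulate: count noise (data are Gaussian, not
negative binomial), library-size effects, batch structure, or ties — so
passing simulation tests demonstrates the statistic's behavior under clean
monotone-transformable signals, not robustness to count-data artifacts.

## The three experiments

* **Concordance** — for every ordered pair of correlations on a grid from
  −1 to +1 (step 0.1, 21 points), draw one exact-correlation pair per
  value and record the copula KS distance, repeated `reps` times.  The
  mean distance tracks the correlation gap (Spearman ≈ 0.98 at n = 100,
  20 reps) and the diagonal sits near zero (median ≈ 0.07).
* **Stability** — score a clean dataset and a noise-injected copy; for each
  threshold report the fraction of clean-selected pairs that survive.  At
  30 genes the mean common fraction falls from 1 (no noise) through ≈ 0.6
  (level 0.5) to ≈ 0.4 (level 1.0), means over 10 seeds.
* **Recovery** — plant 10 exact ±0.9 sign-flipping pairs among 50 genes,
  add noise to the tumor matrix only, detect at DC threshold 0.6 with the
  1-d statistic, and report the matched proportion of the truth set.  The
  planted correlation ±0.9 was fixed at design time so the planted signal
  clears the 0.6 threshold on clean data (±0.8 straddles it at m = 51),
  making the noise-degradation curve informative.

Problem sizes above (n = 100/reps = 20 for concordance; 30–50 genes and 10
seeds for the noise studies) are the package's standard evaluation
settings; they keep the full evaluation in the tens of seconds while
leaving all trends far from their decision margins.

## Numerical notes and limitations

* Ties take average ranks everywhere.
* The empirical-copula CDF at arbitrary (u, v) can sit up to 2/m *below*
  the Fréchet lower bound (one rank-step floor loss per margin); bound
  checks use 2/m slack.
* Pair ordering in extracted lists is descending score with lexicographic
  gene-index tie-breaks; module labels are renumbered by first gene
  appearance — all outputs are deterministic given (data, seed).
* With unequal condition sample sizes the decreasing-transform inequality
  holds only up to O(1/min(m₁, m₂)) marginal-count mismatch.
* All-pairs scoring is O(p² m²); at the preprocessing default of 2000
  genes this is ~2 × 10⁶ pair scores and is best run with a gene subset
  or a compute budget in mind.
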