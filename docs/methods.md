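# Methods

This note documents the models implemented in `nutrigeom`, their
assumptions, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## Diet space and geometry

Diets are points on the macronutrient 2-simplex: percent of total energy
from protein (P), carbohydrate (C) and fat (F), P + C + F = 100. Percent is
the canonical unit everywhere; proportions (0–1) are a derived view used
only inside the Scheffé fits. Compositions are validated at load with
tolerance 1e-6 on the sum and then renormalized exactly, so the simplex
invariant is float-safe downstream. The right-angled mixture triangle (RMT)
plots protein on x and carbohydrate on y, with fat implied as the remainder
— the origin is a pure-fat diet, and fat falls to 0 along x + y = 100.
Prediction grids default to the full triangle; `clip_to_hull` restricts them
to the convex hull of the tested diets when no extrapolation is wanted. Both
are supported because the choice is a genuine design question: surfaces
drawn over the full triangle extrapolate beyond the tested region.

## Scheffé mixture surfaces

Candidate models per response: null (grand mean), linear Scheffé
(y = Σβᵢxᵢ, no intercept), quadratic Scheffé (adds pairwise products), and,
behind a flag, the special-cubic term x_P·x_C·x_F. The quadratic is the
implemented "non-linear" default — it is the standard second-order mixture
model. Fits are ordinary least squares; the AIC uses the Gaussian profile
log-likelihood −(n/2)(log 2πσ̂² + 1) with σ̂² = RSS/n and counts the error
variance as a parameter (k = 2/4/7 for null/linear/quadratic). Only AIC
*differences* within this family matter, so the convention is held fixed
rather than argued over. Selection takes the simplest model (fewest terms)
whose AIC is within 2 points of the minimum, with the boundary inclusive
(a model at exactly min + 2 qualifies). Extrema of a predicted surface are
reported per grid point, ties in lexicographic (protein, carb) order, and a
flat surface is flagged degenerate rather than given an arbitrary optimum.

No inference (standard errors, surface-difference tests) is attempted on
surface coefficients; surfaces are descriptive predictions.

## Differential expression

Genes with fewer than 10 reads in (n − 4) or more samples are removed
(53 of 57 in the reference design). Normalization is trimmed-mean-of-log-
ratios (TMM-style: 30% two-sided trim on M-values, 5% on A-values,
precision weights, factors normalized to geometric mean 1); effective
library size = raw library size × factor.

Each gene is fitted with an NB2 GLM (variance μ + αμ²), log link, offset =
log effective library size, covariates intercept + fat% + carb%. Protein is
omitted because the three percentages are collinear with the intercept.
The significance call is the joint 2-df likelihood-ratio test of the fat
and carb coefficients against χ²₂, with BH FDR < 0.05; per-covariate Wald
p-values are also emitted because the tested contrast is a configuration
question, not something the design itself fixes. IRLS runs Fisher scoring
with step halving, max 50 iterations, deviance tolerance 1e-8, and a 1e-6
ridge applied only when the unpenalized normal equations fail (degenerate
genes), so well-posed fits are exact ML — this is what makes the Poisson
limit agree with a standard GLM implementation to 1e-6.

Dispersion is estimated per gene by maximizing the Cox–Reid adjusted
profile likelihood (loglik − ½ log det X'WX) over log α, then shrunk toward
a lowess trend of log α on log mean (frac 0.5) with fixed weight 0.75 on
the trend. The weight is a moderation default recorded in the run manifest;
on all-null data the trend recovers the common dispersion and the LRT
p-values are uniform (checked by KS test in the suite). This engine is a
deliberately simplified from-scratch implementation: it mirrors the design
(continuous compositional covariates, FDR rule) and makes no attempt at
numerical parity with published count-model packages.

For clustering, significant genes are refitted with the no-intercept
parameterization ~0 + fat% + carb% + protein%. The three columns span the
constant vector (they sum to 100), so the fit is identifiable, but only
coefficient *contrasts* are — a common shift of all three coefficients is
absorbed by the compositional constraint. Row-scaling before clustering
uses exactly the contrast information.

## Differential splicing

Exons with fewer than 10 reads summed over all samples are removed, and
genes left with fewer than 2 exons are dropped from usage testing. Exon
usage is the count fraction count[exon, s] / Σ_gene count[·, s]; samples
with gene total 0 give missing usage, and an exon with (numerically)
constant usage gets zero scaled usage plus a flag. Raw fractions, not
model-fitted usages, feed surfaces and correlations — they are
implementation-independent and match what usage plots show; a configuration
switch is noted for fitted usage.

The test is an exon-versus-rest-of-gene binomial GLM: conditional on the
gene total, the exon count is binomial, and logit P(read on exon) =
β₀ + u_F·fat% + u_C·carb%, with a 2-df LRT on the nutrient terms and BH FDR
over all tested exons. This is the exact conditional form of a two-row
count GLM with per-sample totals as offsets: conditioning on totals
profiles out the 57 per-sample nuisance intercepts instead of estimating
them, which keeps the small-sample LRT calibrated. Two consequences are
documented rather than hidden: (i) the test assumes no extra-binomial
variation in the split beyond the multinomial (adequate for the generator;
real tissue data may be overdispersed, which would make the test
anti-conservative there); (ii) p-values are not exactly invariant to
rescaling a gene's counts in one sample, because the binomial information
grows with the total — usage *estimates* are invariant, and a gene whose
expression responds to diet while its usage does not stays null (verified
by construction in the suite). Usage fold changes are reported between the
design's extreme fat levels, 15% and 60% of energy:
log_fold_change_15_60 = 45 × u_F on the logit scale.

## Nutrient correlation and gene-set scores

Each significant feature is correlated (Pearson, two-sided t-transform
p-values) with its samples' diet fat/carb/protein percent. The BH family is
all features × 3 nutrients within one analysis (expression and splicing
corrected separately); correcting per nutrient instead is a defensible
alternative, and the family choice is therefore explicit configuration.
Because the three nutrient vectors are linearly dependent (they sum to
100), a feature's three correlations satisfy
r_P·sd_P = −(r_F·sd_F + r_C·sd_C) on any design — the Venn partition over
nutrient subsets describes attribution, not independent evidence.
Per-sample nutrient exposure is the diet's design percent; intake-weighted
exposure is out of scope.

Gene-set scores are Σ_g z_g(s) over the set, with z computed per gene
across samples on normalized expression (default log2 CPM + 0.5; the
normalization is configurable). Scores are invariant to affine rescaling
of any member gene.

## Fuzzy c-means clustering

Features are represented by their scaled 3-coefficient vectors. Row-wise
(per-feature) centering/scaling is the default — it removes expression
magnitude so clusters reflect response topology; column-wise scaling is
available since either reading of "centered and scaled" is defensible.
Degenerate features (three equal coefficients) scale to the zero vector
and are dropped with a log entry by default.

Clustering uses the classic Bezdek alternating updates: memberships
u_ij = 1/Σ_l (d_ij/d_lj)^{2/(m−1)} with Euclidean distance, centers as
u^m-weighted means, objective Σ u^m d², iterated to tolerance 1e-9 with a
documented limit convention (a point on a center takes membership 1). The
fuzzifier defaults to m = 2 and k = 5 clusters; k is configurable and a
fuzzy partition coefficient is exposed as a diagnostic because no selection
criterion is prescribed. The updates only find local optima, so fitting
restarts from 10 random center initializations and keeps the lowest final
objective; labels are canonicalized by sorting centers lexicographically so
runs are comparable across seeds. Hard assignments take the maximum
membership, ties to the lowest cluster index (counted and logged).

Cluster surfaces fit the per-sample mean of member features'
centered/scaled values (per-sample, not per-diet, means — the finer
default) with the AIC-selected Scheffé machinery.

## Deconvolution

Signatures are per-type mean expression over the union of marker genes,
ranked per type by fold change of the type mean over the maximum
other-type mean with a minimum fold requirement. DWLS iterates weighted
nonnegative least squares: weights 1/max((S·p)², ε) capped at the 0.95
quantile of the current weights (the dampening; a fixed-quantile cap is a
deliberate simplification of the published dampening-constant search),
starting from the unweighted NNLS solution, until the proportion vector is
stable; the final vector is renormalized to the simplex. Noiseless mixtures
are recovered to machine precision, and estimates are invariant to positive
rescaling of the bulk vector. Cell types above 1% in at least one sample
are retained for gene–proportion correlation (Pearson + BH FDR).

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure of the study design:
ten isocaloric diets covering the simplex with the 6/6/5-replicate pattern
(57 samples); Gaussian phenotypes around Scheffé surfaces; NB gene counts
whose log-means are linear in the diet percentages, with log-normal library
sizes around 2×10⁶ (a desk-scale depth — real experiments run deeper, and
depth is configurable); multinomial exon splits whose usage logits are
linear in the percentages; and bulk profiles as noisy convex combinations
of cell-type signatures. One global seed drives deterministic per-stage
substreams, and the truth manifest (coefficients, flags, labels, seeds)
fully determines the generating distribution — re-simulation from it
reproduces the data byte for byte.

Defaults of the bundled scenario are synthetic conventions, chosen once for
comfortable detectability at n = 57, not study-reported values: ~2,000
genes, half diet-responsive, split evenly over five coefficient topologies
(fat+, fat−, protein+/fat−, carb+/protein−, protein+) with per-percent
log-mean effects ≈ 0.015 (×0.8–1.3 jitter) and NB dispersions log-normal
around 0.05; ~5,000 exons in 1,250 four-exon genes, 20% of genes carrying
one responsive exon with per-percent logit effects ≈ 0.02; 4 cell types
with 60 markers each. In a gene with one responsive exon, the *other*
exons' usages also shift through the multinomial denominator, so
calibration checks use genes with no planted effect anywhere.

Not emulated: read-level artifacts (GC/length bias, mapping error),
batch structure, correlated gene–gene variation beyond the shared diet
covariates, and exon-level overdispersion beyond the multinomial. Passing
tests therefore demonstrate correctness of the estimators under the stated
models, not robustness to those real-data violations.

## Numerical conventions

Scheffé fits use `lstsq`; AIC ties are impossible in practice but selection
is deterministic (fewest terms first). IRLS clips the linear predictor to
±30 to avoid overflow on degenerate genes; non-converged fits are flagged
NA and counted rather than silently reported. BH adjustment is the standard
step-up procedure. All tabular outputs are TSV with headers; identical
config + seed gives byte-identical tables (images exempt).

## Known limitations

- The NB engine promises calibration and design fidelity, not numerical
  parity with any published estimator; quasi-likelihood F-tests, exact
  tests and observation weights are out of scope.
- The splicing test treats exons independently (no per-gene joint model)
  and consumes pre-flattened exon annotation; junction/isoform analysis is
  out of scope.
- Functional enrichment is limited to an optional hypergeometric utility
  against user-supplied sets; it does not reproduce any annotation
  service's results.
- Single-cell reference processing (normalization, label transfer,
  embeddings) is out of scope; the deconvolution consumes a ready signature
  or labeled reference matrix.
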