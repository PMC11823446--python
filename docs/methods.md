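# Methods

This note documents the statistical procedures implemented in `hepapod`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Normalization and sample QC

Raw probe counts are first multiplied by per-probe attenuation factors
(>= 1), restoring attenuated probes to unattenuated-equivalent counts; each
sample is then scaled to reads per million (RPM) of its adjusted total, a
pseudo-count of 1 is added, and values are log2-transformed. Normalization is
scale-equivariant per sample: multiplying one sample's counts by a constant
leaves its normalized values unchanged.

Samples are removed when any of five metrics falls strictly below threshold:
total reads < 300,000; total alignment rate < 40%; unique alignment rate
< 30%; aligned reads < 300,000; fraction of probes with >= 5 reads < 50%.
Alignment rates cannot be derived from a probe-count matrix and must arrive
as metadata (read mapping is upstream of this package); aligned reads and
the expressed-probe fraction are recomputed from counts when absent.

Within each (substance, concentration, run) group of at least three
replicates, each sample's median Pearson correlation with its co-replicates
is compared with the median of the other replicates' medians; the worst
sample is dropped when the absolute difference exceeds 0.05. The rule is
applied in a single pass with at most one removal per group: the criterion
is one-shot, and iterating it could cascade removals through small groups.
Correlations are computed on the post-normalization log2 matrix over all
probes (restricting to expressed probes would make the rule depend on a
second threshold for no clear gain).

## Trend prefilter (mode A)

The trend statistic follows Williams' construction: dose-group means
(control excluded) are isotonized by weighted pool-adjacent-violators, and

    T = (isotonized mean at the top dose - control mean) / SE,
    SE = s_p * sqrt(1/n_top + 1/n_0),

with s_p^2 the pooled within-group variance over all groups. The statistic
is evaluated in both monotone directions and the larger value taken, so
up- and down-regulation are screened symmetrically. Implementation detail:
the isotone fit at the last group equals the extreme suffix weighted mean
(max for isotone, min for antitone), which allows the statistic — and its
permutation distribution — to be computed for thousands of probes as a few
matrix products.

Significance comes from permutation of sample labels (default 2,000
resamples, seeded; fewer than 100 is rejected as unstable), with
p = (1 + #{T_perm >= T_obs}) / (n_perm + 1). Classical critical-value tables
for this test are edition-dependent; a seeded permutation null is exactly
reproducible and calibrates correctly under the constant-variance
assumption, which the type-I-error test verifies to within 3 binomial SEs at
alpha = 0.05. A probe passes with p < 0.05 and a maximal linear-scale
fold-change over control >= 2 (fold-change is 2^|difference of log2 group
means|, maximized over dose groups).

## Curve-fit prefilter (mode B)

Ahead of signature clustering a stricter filter applies: (i) some dose group
must differ from control by a pooled-variance t-test at p < 0.05 — the
lowest such dose is the LOTEL (lowest observed transcriptional effect
level); (ii) the fold-change at the LOTEL must exceed 2; (iii) the better of
a linear and a Hill fit must cross a 3-SD benchmark response within the
tested range. The LOTEL fold-change condition means only responses with an
abrupt onset qualify — a shallow monotone curve that reaches significance
before 2-fold is excluded by design.

## Benchmark-concentration engine

Nine mean functions are fit per probe: Hill a + v d^n/(k^n + d^n); power
a + b d^p; linear and polynomials of degree 2 and 3; exponentials
a e^{bd}, a e^{±(bd)^p}, a(c-(c-1)e^{-bd}), a(c-(c-1)e^{-(bd)^p}).
Errors are Gaussian with constant variance, so maximum likelihood is least
squares; optimization uses bounded trust-region least squares with several
heuristic starts (doses are rescaled by the top dose internally for
conditioning). The Hill cooperativity n and the power/exponent p are
restrained to [1, 18] and [1, 8] to exclude supra-steep degenerate fits —
the conventional restraint in benchmark-dose software; both bounds are
module constants.

The lack-of-fit p-value is a likelihood-ratio test of the model against the
saturated dose-group-means model: LR = n ln(SSE_model/SSE_saturated) on
(number of groups - number of mean parameters) degrees of freedom.

The BMC is the smallest positive dose where |f(d) - f(0)| = BMR * sigma-hat
(sigma-hat the MLE residual SD), located by a geometric scan over
(0, 10 x top dose] plus Brent refinement; for the linear model this
reproduces the closed form BMR * sigma / |b| to 1e-8 relative. Crossings
beyond the top dose are retained at this stage — the explicit filters
remove extrapolations by their own rules. Model selection is lowest AIC
among converged fits with a defined BMC; exact ties go to fewer parameters,
then to a fixed model-name order.

Profile-likelihood bounds exploit a simplification specific to the
constant-variance Gaussian likelihood: pinning the BMC at c determines the
residual SD from the mean parameters (sigma = |f(c) - f(0)| / BMR), so each
profile evaluation is an unconstrained bounded optimization over mean
parameters only. The BMCL/BMCU are where the profile log-likelihood drops
by chi^2_1(0.90)/2 below the optimum — two one-sided 95% bounds — located
by a multiplicative scan plus bisection; a bound that never crosses within
the search range is reported at the range endpoint with a flag. Empirical
two-sided coverage for the linear model is confirmed near 90% by
simulation.

Post-fit filters (strict comparisons, boundary values retained): fit p-value
< 0.001, BMCU/BMCL > 40, BMC below one-tenth of the lowest positive dose,
max fold-change < 2. The fit-p rule removes probes whose best curve still
fits poorly relative to the saturated model — which includes very strong
responders with idiosyncratic shapes. Before clustering, a second filter
removes BMCs above the top tested dose and fits with BMCU/BMCL > 20.

## Injury threshold (BMC105)

The liver-injury threshold is the 105th smallest surviving gene-level BMC
per substance/run — an index adopted as an external constant from a prior
qualifying study, configurable via `threshold_index`. Fewer than 105
surviving BMCs makes the run non-calculable. Classification: calculable in
all runs = SILI, in some = equivocal, in none = non-SILI. The cross-run
summary uses the arithmetic mean over calculable runs (geometric optional).
Percent-dilution and micromolar units interconvert as
uM = %v/v x density x 1e7 / MW, with a default MW of 300 g/mol for mixtures
of unknown composition and density 1 g/mL (an explicit assumption; densities
of dilute aqueous media are close to 1).

## Pathway potency and prioritization

Gene-level BMCs are aggregated — not enrichment-tested — onto gene sets: a
pathway with at least `min_hits` (default 3) member genes holding surviving
BMCs is scored by BMCMedian, the median member BMC (arithmetic mean of the
central pair for even counts). Pathways are ranked by ascending BMCMedian
with ties sharing the mean rank. The prioritization metric FOC/BMC x 100
divides the maximum fold-over-control response among member genes by the
mean BMCMedian and multiplies by 100, reported to 3 significant figures;
it is large for pathways that respond strongly at low concentrations.
Member direction summaries are up/down/mixed; mixed flags nonmonotone or
heterogeneous pathway responses. A config-level "gene-set patch" mechanism
supports documented post hoc curation (adding or removing members of a named
set) without hard-coding any edit.

## Response-similarity signatures

Overlap reports use two labeled semantics, because "shared X of possible Y"
admits several readings: core mode (intersection of all sets over their
union, percentage rounded to the nearest integer) and pairwise Jaccard.

Signatures concretize rank-scoring as follows: per substance/run, select the
union of the top-N lowest-BMC features and top-N highest max-fold-change
features (default N = 100); with K selected, the feature ranked r by
ascending BMC scores K - r + 1, signed + for up- and - for down-regulation;
unselected features are exactly 0 after matrix merge. Run-level signatures
are kept as separate rows rather than averaged, so inter-run agreement is
visible in the tree. Clustering is Ward linkage on Euclidean distance with
the tree cut to k = 5 clusters by default; features and leaf labels are
sorted lexicographically before linkage, making the result invariant to
input order. The dendrogram serializes to Newick.

## Morphology EC10

Tile "altered" probabilities, strictly inside (0,1), are modeled by a
double-index (variable-dispersion) beta regression: logit(mu) = b0 + b1 x,
log(phi) = g0 + g1 x, fit by maximum likelihood (the statsmodels BetaModel
backend) with covariance from the observed information. The dose covariate
is x = log10(concentration), with vehicle wells at a pseudo-dose one decade
below the lowest positive concentration — log spacing matches the half-log
design. Substances with no tile above 0.5 are screened out (no signal to
model). Boundary scores are rejected with guidance to apply the standard
squeeze (y(n-1) + 0.5)/n explicitly; silent data modification is avoided.

EC10 is defined relative to the fitted dynamic range over the tested
interval: the concentration where mu rises 10% of the way from mu(x_min) to
mu(x_max), inverted in closed form through the logit. An absolute variant
(mu = 0.10) is available behind `mode="absolute"`; the relative convention
was chosen because a fixed absolute probability need not be attainable for
weakly responding substances. The CI comes from the delta method on the
log10-concentration scale (numerical gradient of the inversion with respect
to (b0, b1) against the fitted covariance), then exponentiated. The dose
effect is declared non-resolvable when |b1| is smaller than its standard
error. One model is fit per substance per run by default (pooling optional).

## IVIVE potency windows

In vitro pathway BMCs (uM) are compared with in vivo plasma concentrations
at the liver-weight LOEL. Anchors may require (a) dose-proportional
extrapolation, plasma(LOEL dose) = plasma(ref dose) x LOEL/ref — linear
toxicokinetics, the simplest defensible assumption at low doses; (b)
clearance back-scaling, dividing a post-clearance measurement by
(1 - cleared fraction); (c) mg/L to uM conversion via molecular weight.
Concordance is the symmetric fold ratio max(a,b)/min(a,b) against inclusive
windows: <= 2 "within 2-fold", <= 3 "within 3-fold", else discordant.
Ratios are always computed from the inputs rather than transcribed.

## Synthetic-data generator

The generator emulates the screen's statistical structure: 9 half-log
concentration levels (top default 500 uM), 4 technical replicates, 2
independent runs, 8 vehicle wells per substance per run, and a probe panel
defaulting to 3,368 with a planted minority of responders (100 Hill, 25
nonmonotone, 10 linear by default; potencies log-uniform across the tested
range; fold-changes log-uniform in [4, 32]; directions random). Responder
profiles on the log2 scale: Hill with cooperativity h (default 2) and
half-max k solved so the 1-SD crossing equals the requested potency exactly;
linear with slope set by the same 1-SD convention, saturating at the stated
maximal fold-change; nonmonotone as a log-dose Gaussian bump. Noise is
Gaussian on the log2 scale with constant variance across doses (matching
the modeling assumption downstream; default SD 0.2); per-sample library
sizes are lognormal around the mean depth (log-SD 0.15); counts are Poisson
draws of each probe's relative abundance share of the library, divided by
the attenuation factor for the randomly attenuated 10% of probes (factors
log-uniform in [1, 50]). Tile scores come from the same beta model the
morphology stage fits, and gene sets are random possibly-overlapping
subsets of the probe universe.

What it does not emulate: read-level sequencing error, probe
cross-hybridization, batch/plate spatial effects, dose-dependent variance,
cytotoxicity-driven global expression collapse at high doses, and
correlated co-regulation among null probes. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to every artifact of real assay data. One relevant
interaction is worth noting: because normalization is compositional
(per-sample totals), very small probe panels let strong responders distort
null probes' apparent levels; with panels of a few hundred probes or more
the effect is negligible, and test fixtures use panel sizes chosen
accordingly.

## Problem sizes used in the checks

The statistical validation runs at desk scale: type-I-error calibration on
1,000 null probes with 1,000 permutations; planted-Hill recovery through
simulation, normalization and the full model suite over 100 seeded repeats
(400-probe panels); linear-model profile-CI coverage over 120 repeats;
beta-regression recovery and EC10 CI coverage over 200 repeats; the
end-to-end pipeline on a 120-probe, single-substance fixture. These sizes
give Monte-Carlo error small enough for the stated tolerances (3 binomial
SEs throughout).

## Known limitations

- Permutation p-values are tied to the resampling seed; ranking stability
  near the alpha boundary requires the default 2,000 resamples or more.
- The profile-CI search is bounded at [BMC x 1e-6, 10 x top dose]; genuinely
  unbounded profiles (flat likelihoods) report flagged endpoints rather than
  infinite bounds.
- The generic profile optimization is local (started at the MLE); heavily
  multimodal likelihoods could under-cover, though the model suite's bounded
  parameterizations make this rare in practice.
- No model averaging and no nonconstant-variance error models are provided.
- The morphology stage consumes precomputed tile probabilities; image
  handling and CNN inference are out of scope.
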