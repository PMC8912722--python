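# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `parapop`, in the order the pipeline runs them.

## Data model

Genotypes are diploid allele fragment sizes (positive integers) per
individual × locus × 2 copies, with a single missing sentinel; both copies of
a locus are missing together (half-calls are rejected at validation). Allele
sizes are kept exactly as genotyped — no binning to repeat numbers — and all
statistics drop missing slots locus-wise (pairwise-complete), matching the
behavior of the common desktop tools. Species is a property of the
*population*, not the individual: morphologically misassigned individuals are
detected downstream by the admixture classifier, never re-homed during I/O.
GenePop population labels are recovered from shared individual-id prefixes
when possible (the convention the writer emits), otherwise `pop1, pop2, ...`.

## Diversity and differentiation

- **He convention.** Expected heterozygosity is the uncorrected
  1 − Σp² with allele frequencies pooled over the scope (species or
  population), i.e. the GenAlEx default, not Nei's unbiased (2n/(2n−1))
  form. Means over loci use the loci polymorphic in the whole dataset, so a
  locus monomorphic within one species still enters that species's mean;
  SE = SD/√(#loci).
- **F.** 1 − Ho/He per locus; loci with He = 0 are undefined and excluded
  from the mean.
- **Private alleles.** An allele is private to a group if observed in that
  group and in no other. The per-population "private-allele frequency" used
  in the geography regressions is the summed within-population relative
  frequency of allele copies private to the population's species; an
  alternative definition (distinct private alleles / distinct alleles) is
  exposed via `freq_definition` for sensitivity checks.
- **AMOVA.** Distances between allele copies are identity mismatches
  (F_ST-type), not squared size differences (no R_ST variant is used by the
  pipeline's defaults). Sums of squares are computed per locus from
  allele-count tables (algebraically identical to the pairwise-distance
  definition), pushed through the standard nested moment equations with
  unequal-size coefficients; variance components are summed over loci and the
  Φ statistics are ratios of the summed components. Negative components and
  negative pairwise F_ST estimates are truncated at zero (logged). Note the
  among-group component is the *unbiased* random-effects variance — with two
  species it is roughly twice the plug-in G_CT heterozygosity deficit; the
  synthetic-data calibration therefore targets this estimator, not G_ST.
- **Permutations.** Φ_ST permutes individuals among populations; Φ_SC
  permutes individuals among populations within species; Φ_CT permutes whole
  populations among species; p = (#{perm ≥ obs} + 1)/(N + 1), default
  N = 9999 (tests and examples use fewer for speed).
- **Regressions.** One geographic predictor at a time by OLS with a
  two-sided t-test on the slope; exact fits (zero residual variance) report
  t = ∞/p = 0 for a non-zero slope and t = 0/p = 1 for a constant response.

## Admixture model

The Gibbs sampler implements the basic admixture model: cluster allele
frequencies P with independent Dirichlet(λ = 1) priors per cluster × locus
(no correlated-frequencies prior), individual ancestries Q with a fixed
symmetric Dirichlet(α = 1/K) prior (uniform on the simplex; α is not
inferred — adequate for the K = 2 contrast this package targets, and
config-exposed). Updates cycle Z | P,Q → P | Z → Q | Z; posterior means of Q
and P are taken over post-burn-in sweeps. ln P(X|K) is estimated by the
STRUCTURE convention (mean minus half the variance of the post-burn-in
log-likelihood trace) — an approximation, used only for the ΔK ranking.
Desk-scale defaults are a 5×10⁴-sweep chain with 20% burn-in; the test suite
uses shorter chains, which mix fast on the separable K = 2 problems it
checks. Replicates are aligned by the cluster permutation maximizing summed
Q-column correlation (solved as an assignment problem). One consequence of
the α prior worth knowing: with L loci, a fully assigned individual's
posterior mean own-cluster ancestry is (2L + α)/(2L + 1), e.g. ≈ 0.986 at
L = 17 — "pure" individuals never reach exactly 1.

Introgression classes apply ordered thresholds to the ancestry of the other
species's cluster: pure ≤ 0.05, introgressed ≤ 0.5, hybrid ≤ 0.9, else
misassigned. The 0.05 introgression threshold is the field convention; the
0.5/0.9 cuts formalize the narrative hybrid/misidentified categories and are
config-exposed.

## Coalescent simulator

A Gillespie realization of the two-deme structured coalescent, backward in
time, with three epochs: (0, t2) recent sizes, (t2, t1) early sizes, (t1, ∞)
a single ancestral deme. The four scenarios differ only in when migration is
active: SI never, AM in (t2, t1), SC in (0, t2), CM in (0, t1). Migration
rates are backward lineage-movement rates matching the forward direction of
gene flow (m1 = forward cau→mor, so mor-resident lineages jump to cau at
rate m1), the convention of the standard forward-parameterized simulators.
Time is continuous, in generations; conversion to years is a separate
operation (default 5 yr/generation, reflecting a ≥5-year maturation age for
the motivating taxa).

Mutations are dropped on lineages as a Poisson process of rate μ per locus
per generation (default 5×10⁻⁴, config-exposed and placeable under a prior);
each mutation steps the repeat state ±1 with equal probability (strict SMM;
the symmetric walk is direction-reversible, so accumulating steps backward
along lineages is distributionally identical to dropping them forward on the
tree). The ancestral state is 20 repeats; final states below 2 are reflected
at 2 — a boundary correction, exact only when boundary approaches are rare
(they are, except under extreme μ·Ne). Validation: the mean TMRCA of a
panmictic pair matches 2Ne; the equilibrium heterozygosity of a single
population matches the stepwise-mutation closed form
1 − 1/√(1 + 8Neμ) (up to the (1 − 1/n) sampling factor of the plug-in He
estimator); and the TMRCA distribution of the two-deme split model matches
msprime on identical parameters (two-sample KS).

**Summary statistics** (fixed order): per species, means over loci of He,
Ho, allele count, allele-size variance, and M-ratio (alleles per unit of
allele-size span); jointly, between-species F_ST (two-group AMOVA), mean
(δμ)² (squared difference of mean allele sizes), the shared-allele
proportion (|A∩B|/|A∪B| summed over loci), and private-allele counts scaled
by diploid sample size. The exact statistic set used with the original
ABCtoolbox run is unpublished; this set is a standard SSR-ABC choice and is
config-exposed. One exact linear dependence is inherent (allele counts and
private counts satisfy L·(nall_a − nall_b) = n·(priv_a − priv_b)); the
regression machinery tolerates it (see below).

## ABC

Default priors (the originals are unpublished): log-uniform Ne ∈ [10², 10⁶]
for all five sizes, uniform t1 ∈ [10³, 10⁵] generations, t2 | t1 uniform on
(0, t1) (conditional draw enforces t2 < t1), log-uniform m ∈ [10⁻⁶, 10⁻²];
migration parameters are forced to 0 under SI. The reference table is
reproducible and resumable: row i's randomness derives from
SeedSequence(seed, i), so chunked and restarted runs agree bitwise.

Rejection standardizes each statistic by median/MAD over the table (columns
with MAD = 0 are dropped with a warning) and keeps the n_keep smallest
Euclidean distances, ties broken by row order. Model selection: retained-set
frequencies ("rejection") or, by default, a multinomial logistic regression
of the model label on standardized statistics over the retained set,
weighted by the Epanechnikov kernel on distance, evaluated at the observed
vector ("mnlogistic"); a single-hidden-layer classifier ("neuralnet",
unweighted) is available since the R package's method of that name is
architecture-unspecified. PPs are clipped to ≥ 10⁻⁴ and renormalized before
Bayes factors (ratios of PPs, valid under the uniform model prior).

Goodness of fit is the marginal-density formulation: the distance from the
observed standardized vector to the mean simulated vector, compared with the
null distribution of the same distance for the model's own simulations;
p = (#{D_sim > D_obs} + 1)/(n + 1). This is calibrated (p uniform under the
null) by construction and by test.

Parameter estimation follows the rejection + local-linear adjustment recipe:
Epanechnikov weights with bandwidth = the largest retained distance;
weighted linear regression of each parameter (log-transformed when strictly
positive) on the standardized statistics, adjusted to the observed point;
mode = argmax of a weighted Gaussian KDE on the transformed scale; bounds =
weighted empirical 2.5/97.5 percentiles; the mode is clipped into the
interval. The regression uses the minimum-norm least-squares solution, which
handles the exactly collinear statistics noted above (the same linear
constraint holds for the observed vector, so predictions are unaffected);
only a degenerate design (rank < 2) falls back to unadjusted weighted
quantiles with a warning. Adjusted values can leave the prior support —
standard behavior for untruncated regression adjustment, visible mainly when
the posterior is diffuse. The reported "mode" is the marginal weighted-KDE
mode, not a joint mode.

## Decline contrast

r = Ne_t1/Ne_t2 is computed per retained simulation from the
regression-adjusted parameters with propagated weights (non-positive sizes
excluded, counted). Scenario contrasts use a two-sided Mann–Whitney U test
(exact when both samples are ≤ 20 and tie-free, tie-corrected normal
approximation otherwise). Posterior draws are correlated model outputs
rather than independent experimental units; the comparison is implemented as
published, and every report carries an explicit caveat field saying the
rank-test p-value overstates evidence.

## Synthetic-data generator

Fixtures are frequency-model draws, not coalescent runs — deliberately, so
"does the statistic work" is separated from "does the demographic model
fit". Each species's shared-allele profile is a Balding–Nichols Dirichlet
draw around a common base; population profiles are BN draws around their
species profile. The draws are made through frozen uniforms pushed through
the gamma quantile function (common random numbers), making the implied
divergence a smooth monotone function of the two differentiation parameters;
those parameters are calibrated by bisection until the large-sample AMOVA
Φ_CT and the mean within-species pairwise F_ST implied by the profiles (via
expected allele-count tables pushed through the same estimator the
measurement uses) hit the template targets within 0.005. Unattainable
targets raise an error reporting the best attained value.

Each species also carries a private allele block (absent from the other
species); in the first species the private-block weight increases linearly
with population altitude (defaults 0.05 → 0.30), reproducing the
altitude-enrichment pattern. Designated introgressed/hybrid/misassigned
individuals draw each allele copy from the other species's pool with
probability equal to their true ancestry (introgressed ~ U(0.08, 0.45),
hybrid ~ U(0.52, 0.88), misassigned ~ U(0.92, 0.995)), recorded in a truth
table. The default template mirrors the study scale (2 species, 20 + 19
populations, ≈19/15 individuals per population, 17 loci, Φ_CT target 0.478,
2% missing data); a "mini" template (2×3 populations × 10 individuals,
8 loci) keeps test suites fast.

What the generator does *not* emulate: real allele-size distributions and
null-allele artifacts, isolation-by-distance within species, linkage, or any
mechanistic demography — so tests passing on synthetic data demonstrate that
the estimators recover the structure they target, not that the coalescent
model fits any particular real dataset.

## Problem sizes used by the validation suite

The closed-loop ABC checks run on a 2×10⁴-row reference table with 17 loci
and 20 + 20 diploid samples per dataset, 2000 retained for model selection
and 500 for parameter estimation within the SC scenario; scenario recovery
uses 20 pseudo-observed datasets from a strong-migration secondary-contact
draw (m1 = 2×10⁻³), and interval coverage uses 40 prior draws × 5 size
parameters. Admixture recovery runs 1500-sweep chains on 100 individuals ×
17 loci. The simulator equilibrium check uses 2000 loci at Ne = 1000,
μ = 5×10⁻⁴. These sizes are the package's validation defaults; all scale up
by argument.

## Known limitations

- The admixture sampler omits STRUCTURE's correlated-frequency prior and
  α inference; it is built for the separable two-species contrast, not for
  subtle K > 2 structure.
- ln P(X|K) is a trace-based approximation; ΔK inherits its noise.
- The GOF test statistic (distance to the mean simulated vector) is one of
  several possible formulations; it is seeded and config-switchable.
- Regression-adjusted posteriors are not truncated to the prior support.
- AMOVA handles missing data per locus via complete allele copies, which can
  differ marginally from tools that drop whole individuals.
- The coalescent state floor is a reflection applied to final states, not a
  per-event reflecting boundary.
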