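# Methods

`hierqst` implements the statistical core of a common-garden phylogeography
analysis: testing whether quantitative-trait differentiation among and
within phylogeographic regions departs from its neutral molecular
expectation, and whether traits track elevation of origin. This note
documents the models, the estimators, the synthetic-data generator, the
numerical choices, and the limits of what the tests demonstrate.

## The nested random-effects model

Phenotypes measured in a common garden are modelled as

```
y_ijkl = mu + R_i + P_ij + F_ijk + e_ijkl
```

with regions *i*, populations *j(i)*, open-pollinated seed families *k(ij)*
and plants *l(ijk)*; all effects are independent zero-mean Gaussians with
variances σ²_R, σ²_P, σ²_F, σ²_e. Because plants share a uniform garden
environment, among-origin variance is interpreted as genetic.

Two estimators are provided:

- **ANOVA (method of moments).** Sequential nested sums of squares are
  equated to their exact expectations under the random model. For
  unbalanced data the expected-sums-of-squares coefficients are computed
  from the group-size functionals Σn²/n at each level of nesting
  (Henderson Method I style). These coefficients are exact under any
  imbalance and reduce to the familiar `n`, `cn`, `bcn` multipliers for
  balanced data, so the estimator is unbiased before truncation. We chose
  this over unweighted-means approximations because it costs nothing extra
  and removes an approximation error that would otherwise contaminate the
  simulation-recovery checks. Negative solutions are truncated to 0 and
  flagged; truncation induces a small upward bias in the remaining
  component means (visible in the recovery simulations as a few percent on
  the region component, whose sampling distribution with 4 regions is
  widest).
- **REML.** EM on the mixed-model equations, warm-started at the floored
  ANOVA solution. In balanced designs with an interior ANOVA solution, the
  ANOVA estimate *is* the REML optimum and a fixed point of the EM map, so
  the two agree to machine precision by construction. EM approaches a zero
  boundary at a vanishing rate, so a component that falls below 0.1% of the
  trait variance while still shrinking is pinned to the boundary; if EM has
  not met the 1e-8 relative tolerance within 500 sweeps, a bounded
  quasi-Newton (L-BFGS-B) finish on the log-variances maximises the
  restricted likelihood directly, evaluated through the
  mixed-model-equations determinant identity. The trait is internally
  standardised so all tolerances are scale-free; estimates are returned on
  the original scale.

The initial-size covariate (rosette diameter at transplantation) is
handled by pre-residualisation: the trait is replaced by the residuals of
an OLS fit on the covariate plus the trait grand mean. This keeps the
random-model estimators closed-form and testable; the alternative — a
fixed covariate inside the REML fit — differs only at second order when
the covariate is near-orthogonal to the origin structure, which the
randomised garden layout makes plausible. Skewed count traits can be
power-transformed first (exponents 0.656 for leaf counts, 0.620 for flower
counts, 0.331 for biomass are the package defaults for those trait types).

## Q indices

With V_A = k·σ²_F (k = 4 for half-sib families, the default for an
outcrossing, self-incompatible species where open-pollinated maternal
families approximate half-sibs; k = 2 full-sib; k = 1 broad-sense):

```
Q_SR = σ²_P / (σ²_P + 2 V_A)
Q_RT = σ²_R / (σ²_R + 2 (σ²_P + V_A))   (total_within, default)
Q_RT = σ²_R / (σ²_R + 2 V_A)            (pooled)
```

Hierarchical Q formulas are not standardised in the literature, so both
region-level conventions are implemented and the `qst` subcommand reports
them side by side; the default treats everything below the region level as
"within". Residual variance never enters an index. The indices are
undefined (an error, not 0) when their denominator vanishes.

## Hierarchical AMOVA and standardization

Each individual contributes two allele copies per locus; distance is
allele identity (infinite-allele convention, appropriate for the
standardized indices and robust to microsatellite homoplasy assumptions).
Sums of squares are partitioned among regions / among populations within
regions / within populations, and components are solved from the
expected-mean-square equations with per-locus sample-size coefficients, so
missing copies are excluded locus-wise. Components are summed across loci
before forming F_RT, F_SR, F_ST (components-then-ratio, not mean of
ratios). Raw negative components stay in the sums; reported F values are
clamped to [0, 1] with the unclamped value retained. Degenerate levels
collapse gracefully: one region yields a two-level among-population
analysis (σ²_a = 0), and one population per region yields a two-level
among-region analysis (σ²_b = 0).

Standardized indices divide each F by its maximum attainable value given
the observed within-population variation, obtained by recoding alleles so
that groups at the focal level share none and re-running the AMOVA. For
F'_ST and F'_SR the recoding is per population; for F'_RT it is per
region, leaving codes shared between populations of the same region
intact — the region-level scheme is a convention of this package, stated
here because hierarchical standardization is not pinned down in the
literature. When both the raw F and its recoded maximum are zero the
standardized index is reported as 0 (the level carries no
differentiation); a zero maximum with positive raw F is an error.
Hedrick's G'_ST is computed in closed form from multi-locus G_ST and the
unweighted mean within-population gene diversity H_S:
G'_ST = G_ST (s − 1 + H_S) / ((s − 1)(1 − H_S)).

## Jackknife and selection calls

Every index CI comes from the delete-one-population jackknife:
pseudovalues θ*_i = θ̂ + (n−1)(θ̂ − θ₋ᵢ), CI = mean ± z·SE with z = 1.96
(95%, normal approximation; a t-multiplier can be configured), clamped to
[0, 1] for indices defined there. Subsets on which the estimator is
undefined (a region losing its last population) are skipped with n
adjusted; more than 20% failures aborts. Q and F' are jackknifed
independently over their own population sets, since phenotyped and
genotyped population sets need not coincide.

Selection calls use CI non-overlap: Q wholly above F' ⇒ diversifying,
wholly below ⇒ unifying, otherwise neutral; the same rule orders Q_RT
against Q_SR. Non-overlap of two independent 95% intervals is conservative
relative to a formal test of the difference — calls of "neutral"/"equal"
are therefore cautious. This rule reproduces, from the printed intervals
of the worked example shipped with the package, all 14 selection calls and
all 7 level comparisons.

## Auxiliary statistics

Population trait means are two-stage (plants → family means → unweighted
mean of family means), so large families do not dominate. Trait–elevation
association uses Pearson's r with the t-transformation p-value (n−2 df),
and each population subset is its own Holm step-down family across traits
(delegated to `statsmodels.multipletests(method="holm")`, identical to the
explicit max-min step-down formula). Phenology is compared with G tests
(G = 2ΣO·ln(O/E), χ² reference), one among-regions test on the pooled
regions × stages table and one populations × stages test per region;
no Williams correction by default (an option), cells expected-0/observed-0
are dropped, expected-0/observed-positive is an error.

## Synthetic data

The generator reproduces the study design: 4 regions holding 6/5/4/6
populations (21 total), 6 seed families per population, 8 plants per
family split evenly between control and clipped halves, 5 microsatellite
loci — so every estimator is exercised at the sampling depth it was built
for. Defaults for the generating variances are σ² = (2, 1, 1, 4)
(region, population, family, residual), i.e. moderate hierarchical
structure with residual noise dominating, which is typical for
common-garden morphometrics; the covariate slope defaults to 0 so the Q
pipeline is covariate-free unless requested.

Genotypes follow a hierarchical Dirichlet (Balding–Nichols-style) drift
model: ancestral frequencies per locus from a symmetric Dirichlet
(concentration 1, 8 alleles by default, microsatellite-like); region
frequencies Dirichlet-centred on ancestral with concentration
(1−θ_RT)/θ_RT; population frequencies likewise around their region with
(1−θ_SR)/θ_SR; Hardy–Weinberg draws within populations. Because a
Dirichlet with concentration c around its mean has E(F) = 1/(1+c), the
targets θ_RT and θ_SR are the expected fixation indices at each level and
the total expectation is θ_RT + (1−θ_RT)·θ_SR — the closed form the
calibration and coverage tests check against. Defaults θ_RT = 0.1,
θ_SR = 0.3 mirror the weak-among-region / strong-within-region ordering
characteristic of postglacial recolonisation. Phenology is multinomial
per population from region-level stage probabilities.

What the generator does *not* emulate: linkage, selfing (the species is
modelled as fully outcrossing), mutation and migration dynamics, genotyping
error, non-Gaussian trait distributions, and maternal/common-environment
effects inflating family variance. Passing recovery tests therefore show
the estimators are correct under the stated model, not that real data meet
its assumptions.

## Problem sizes and numerical choices

Simulation-based checks use 200 replicates for variance-component and Q
recovery, 500 replicates for jackknife coverage, and 2000 for the G-test
size, balancing Monte-Carlo error (mean SE on the region component is
~6% of its value at 200 replicates, the widest of any check) against
runtime. Exact checks (AMOVA vs brute force, standardization vs explicit
recoding, jackknife of a linear statistic) are asserted at 1e-10–1e-12.
Ties and degenerate inputs: constant traits yield all-zero components
(not an error); constant estimators yield point CIs; monomorphic loci
contribute zero to AMOVA sums; empty stage categories are dropped from G
tests.

## Known limitations

- The jackknife z-interval is mildly anticonservative with 21 populations
  (observed F_ST coverage ≈ 91–92% at nominal 95%); the t-quantile option
  narrows the gap.
- Q_RT with 4 regions rests on 3 degrees of freedom; its point estimate is
  noisy and slightly downward-biased as a ratio (≈ −0.03 at Q_RT = 0.371
  in the recovery simulations), which is inherent to the design, not the
  estimator.
- The covariate enters by pre-residualisation, not joint REML fitting.
- No permutation p-values for AMOVA components, no parametric bootstrap,
  no stepwise-mutation distances, and no dominant/haploid data support.
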