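# hierqst

Hierarchical Q<sub>ST</sub>–F<sub>ST</sub> analysis for common-garden
phylogeography.

Widespread Alpine plants often show strong molecular structure among
phylogeographic regions — the legacy of glacial survival in isolated
refugia — and further structure among populations within regions, shaped
during postglacial recolonisation. Given a common-garden experiment
(regions ⊃ populations ⊃ open-pollinated seed families ⊃ plants) and
codominant marker data (e.g. microsatellites) from the same populations,
this package asks, separately at each hierarchical level, whether
quantitative-trait differentiation exceeds, matches, or falls short of
its neutral molecular expectation — evidence for diversifying selection,
drift alone, or unifying selection.

## What it computes

- **Nested variance components** σ²_region, σ²_population(region),
  σ²_family(population), σ²_residual for each trait, by exact
  method-of-moments ANOVA or REML, with optional initial-size covariate
  adjustment and power transforms.
- **Hierarchical Q indices** from those components, with
  V_A = k·σ²_family (k = 4 half-sib default):
  Q_SR = σ²_P/(σ²_P + 2V_A) and Q_RT = σ²_R/(σ²_R + 2(σ²_P + V_A))
  (a pooled-denominator alternative is always reported alongside).
- **Hierarchical AMOVA** on allele-identity distances giving F_RT, F_SR,
  F_ST, plus standardized F′ indices (each F divided by its maximum under
  allele recoding) and Hedrick's G′_ST.
- **Delete-one-population jackknife** 95% CIs for every index, and
  CI-overlap **selection calls**: diversifying (Q above F′), unifying
  (Q below F′) or neutral, at both levels, plus the Q_RT vs Q_SR
  comparison.
- **Trait–elevation Pearson correlations** (two-stage family-mean
  aggregation, sequential Holm–Bonferroni correction per population
  subset) and **G tests** on phenological-stage contingency tables.
- A **synthetic-data module** generating design-matched phenotypes
  (nested Gaussian effects), genotypes (hierarchical Dirichlet drift with
  E(F) = 1/(1+c)) and phenology, so the whole pipeline runs and is tested
  without any external data.

## Worked example

The package ships the published interval estimates of a 21-population,
4-region alpine bellflower study as `hierqst.worked_example`. Feeding the
seven traits' printed Q_RT/Q_SR intervals and the molecular F′_RT = 0.092
(0.080–0.105) / F′_SR = 0.499 (0.488–0.510) to the comparison logic:

```
$ hierqst compare --q-table q.csv --f-table f.csv
trait,among_regions,within_regions,q_rt_vs_q_sr
above_ground_biomass,diversifying,unifying,greater
leaf_ratio_2008,neutral,unifying,equal
leaf_ratio_2009,unifying,unifying,less
max_inflorescence_height,diversifying,unifying,greater
number_of_flowers,neutral,neutral,equal
number_of_inflorescences,neutral,unifying,greater
number_of_leaves,unifying,unifying,equal
```

Height and biomass differentiated among regions beyond neutral
expectation (diversifying selection in glacial refugia), while nearly
every trait shows within-region differentiation *below* the neutral
F′_SR = 0.499 (unifying selection during recolonisation). On synthetic
genotypes (`hierqst simulate --seed 3`, θ_RT = 0.1, θ_SR = 0.3):

```
$ hierqst amova --genotypes simdata/genotypes.csv --design simdata/design.csv
index,estimate
F_RT,0.08599497649337513
F_SR,0.29995771536677795
F_ST,0.3601578351781805
F'_RT,0.31080217270359134
F'_SR,0.6069587440314469
F'_ST,0.7287590634688876
G'_ST,0.7087483582212566
```

The raw F_RT and F_SR sit at their generating values; standardization
(dividing by the allele-recoded maximum) raises each index, and G′_ST
tracks F′_ST as expected.

The full pipeline — variance components, Q and F′ with jackknife CIs,
selection calls, correlations and G tests, written as CSVs plus a run
manifest — is one command, deterministic for a given seed:

```
hierqst pipeline --seed 11 --out results/
```

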