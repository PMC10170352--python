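# Methods

This note documents the models and procedures `aorweb` implements, the
parameters that matter, the choices made where conventions diverge, and
what the synthetic-data generator does and does not emulate.

## Species delimitation

### K2P distances

`k2p_distance` computes the Kimura two-parameter distance
*d* = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) from the transition proportion
*P* and transversion proportion *Q* over the sites that survive
**pairwise deletion**: any column with a gap (`-`) or ambiguous base
(anything outside A/C/G/T) in either sequence is dropped for that pair
only. Pairwise deletion is the convention for barcode data, where
missing data cluster at fragment ends and complete deletion would
discard most of the alignment.

Two failure modes are explicit errors, never silently patched:

- no comparable sites after deletion (`NoOverlapError`);
- a saturated pair with 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0
  (`SaturatedDistanceError`). `pairwise_distances` aborts and lists the
  offending individuals. Clamping saturated distances to some large
  value would silently distort the clustering that follows; listing the
  pair lets the user remove it as probable contamination.

### UPGMA and the threshold cut

`upgma` is implemented in the package rather than delegated, because the
delimitation contract requires a *deterministic* tie-break: among
cluster pairs at equal average distance, the pair whose
lexicographically smallest member id is least merges first (then the
other cluster's smallest id). Merge heights are the average
inter-cluster distances in substitutions/site; the dendrogram's
cophenetic distance between two tips is the height at which they first
join. Newick export halves the height differences so the patristic
tip-to-tip path through the tree equals the cophenetic distance.

`cut_lineages` applies a **flat cut at cophenetic height equal to the
divergence threshold** (default 0.068 substitutions/site): lineages are
the maximal subtrees whose internal merges all sit at or below the
threshold. Cutting cophenetic rather than raw distances is the standard
threshold-clustering reading and guarantees a partition; with a raw-
distance rule, "all within-lineage pairs below the threshold" need not
be satisfiable by any partition. The cut is monotone: a smaller
threshold always yields a refinement of a larger threshold's partition
(property-tested).

### The PU reconciliation cascade

Per lineage, with PU = parataxonomic unit (a field-assigned
morphological unit) and morphological distinctness supplied by the user
(it comes from expert revision, not from sequence data):

1. one PU, all of its individuals → one species (CLEAN);
2. a PU segregating across lineages → every species touching it is
   flagged SPLIT_PU_REVISED; individuals listed in the config's
   `exclusions` (the human revision outcome, e.g. contamination) are
   dropped before the rules run. The pipeline never auto-resolves
   assignment error — there is no defensible classifier for it;
3. several PUs, none declared distinct → one merged species
   (MERGED_PUS);
4. declared-distinct PUs, each monophyletic within the lineage → one
   species per PU;
5. declared-distinct PUs without mtDNA segregation → all members
   removed (REMOVED_INCOMPLETE_SORTING), the signature of recent
   speciation with incomplete lineage sorting or gene flow. Any
   conflict at the rule-4/5 boundary falls to rule 5: removal is the
   conservative outcome.

## Abundance extrapolation

Within a PU at a site, sequenced individuals keep their species
identities; the unsequenced remainder is split in the proportions the
sequenced individuals show **at that site**. Quotas are integerized by
**largest-remainder apportionment** (floors first, leftovers to the
largest fractional parts, ties to the smaller species id). Independent
rounding of each quota can create or destroy individuals; largest
remainder conserves the total exactly (tested exhaustively for
remainders ≤ 20 and ≤ 4 species) and reproduces the intuitive worked
case — 3:7 sequenced → 30%/70% assigned.

A multi-species PU with *no* sequenced individuals at some site needs a
fallback. The default borrows the PU's sequenced proportions from the
same island, then globally — nearest information first; `strict` mode
raises instead. This situation is undefined in the procedure the module
formalizes, so the policy is explicit and configurable.

## Trait categorization

Niche breadth is binary (laurel-forest specialist vs non-specialist) by
a two-step procedure. Step 1: experts vote; abstentions do not count
toward the ≥ 2-voter minimum; unanimous or majority verdicts stand; ties
and under-voted species defer to step 2. Step 2: a species is a
specialist if the percentage of its occupied 500 × 500 m cells lying in
habitat is at or above a threshold, set at a quantile (default 0.50,
options 0.10/0.25/0.75 for robustness checks) of the step-1 specialists'
percentages. Quantiles use linear interpolation between order statistics
(numpy default, identical to R type 7). Species at exactly the threshold
count as specialists — a 100%-habitat species must not fall out of the
category; `specialist_at_threshold=False` flips this. Species without
distribution records stay `uncategorized`. The three sources (expert,
quantile, none) partition the species list exactly once.

Dispersal ability is a family-level lookup table (ballooning vs
non-ballooning), shipped as data by the caller, since ballooning
propensity is strongly conserved within spider families.

## Abundance, occupancy, and AOR models

Mean site abundance of a species is its total count divided by the
number of **occupied** sites; species absent from a domain are excluded
rather than zero-filled, since a per-occupied-site mean is undefined for
them. Occupancy is occupied/total sites, or occupied/total islands.
Sites sampled but empty of species still count in the denominators.

The AOR model is a binomial GLM on (occupied, total − occupied) pairs
with logit link: log abundance as covariate, trait categories
dummy-coded against stated reference levels (ballooning,
non-specialist), optional covariate × category interactions. Fitting is
IRLS via statsmodels; the test suite checks coefficients against an
independently written IRLS oracle at 1e−6. With treatment coding, the
full interaction model decomposes algebraically into the per-category
subset fits (reference level = subset intercept/slope; other level =
reference + main effect + interaction), which the suite asserts
numerically.

Conventions: Wald z p-values for binomial/Poisson, t for Gaussian;
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with plain AIC also reported (the
Gaussian family counts its scale parameter in k); McFadden
R² = 1 − ℓ/ℓ₀ against the intercept-only model on the same data and
family; the 2×2 chi-squared test applies the Yates continuity correction
by default, matching R's `chisq.test`. Quasi-perfect separation in
binomial fits is detected (extreme coefficients or fitted probabilities
at the boundary) and flagged with a warning, never returned silently.

Mixed models (`fit_mixed`) are random-intercept GLMMs with the grouping
factor (typically island) and a **Laplace-approximate** marginal
likelihood: an inner vectorized Newton solve for the per-group modes
nested in an outer Nelder–Mead over fixed effects and log σᵤ, standard
errors from the numerical Hessian. On a 200-group Poisson benchmark the
fixed effects, σᵤ and the log-likelihood agree with lme4's `glmer`
(also Laplace) to three to four decimals. Like any Laplace fit, σᵤ is
biased downward when clusters carry little information (few, small
counts); the recovery test therefore uses binomial clusters with 30
trials, where coverage is nominal. A fit driving σᵤ → 0 is valid (it
reduces to the plain GLM) but is reported as non-converged so singular
fits are visible.

## Blomberg's K

With V the phylogenetic covariance matrix (shared root-to-MRCA branch
length), the phylogenetically corrected mean is
â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1), and

K = [(x−â)ᵀ(x−â) / (x−â)ᵀV⁻¹(x−â)] ÷ [(tr V − n/(1ᵀV⁻¹1)) / (n−1)].

V⁻¹ is applied via solves, never an explicit inverse; a condition number
above 1e10 raises rather than returning a meaningless ratio; constant
traits raise `DegenerateTraitError`. K is invariant to affine trait
transformations and to uniform branch-length rescaling (asserted to
1e−8), and its mean under Brownian simulation on 64-tip pure-birth trees
is within 0.1 of 1 over 500 replicates. The implementation is
cross-checked against both a naive matrix-algebra oracle and
`picante::Kcalc` in R. No randomization p-value is attached: K is
reported as a descriptive statistic; permutation tests can be built from
`blomberg_k` directly if wanted. Whether to log-transform abundance
before computing K is left to the caller; K is not invariant to that
choice.

`prune` takes the induced subtree on the community species (suppressing
degree-2 nodes with branch lengths summed), preserving patristic
distances and ultrametricity. Tree *estimation* and dating are out of
scope: the module consumes a user-supplied ultrametric Newick.

## Synthetic data

The generator (`synthetic_data`) emulates a four-island, 31-site
(14/7/6/4) survey of a 123-species assemblage — the defaults describe a
Canary-Islands-style laurel-forest spider inventory:

- **Sequences**: 658-bp COI, species ancestors radiating from a root at
  half the inter-species divergence target (default 0.12) and
  individuals at half the intra-species target (default 0.01), evolved
  under the exact K2P site-substitution process (transition/transversion
  ratio 3), so estimated pairwise K2P distances are unbiased for the
  targets and straddle the 6.8% threshold. Realized means sit within
  ±20% of the targets at this length.
- **Parataxonomic error**: per-species label splitting and sister-pair
  lumping at configurable rates (defaults 0), exercising every branch of
  the reconciliation cascade.
- **Metacommunity**: per species, mean site abundance λ is lognormal
  (log-mean 1.2, log-sd 1.1 — giving a realistically right-skewed
  community of roughly 2×10⁴ individuals); each site is occupied
  independently with probability logistic(α_c + β_c log λ) with
  category-specific coefficients defaulting to the published
  per-category AOR fits (ballooning −2.0816/1.5101, non-ballooning
  −2.9312/1.9871); counts at occupied sites are zero-truncated
  Poisson(λ), so occupancy and abundance remain separable (occupied
  means ≥ 1 individual). `coef_on="both"` keys the curves by
  dispersal × niche cell for two-effect simulations.
- **Votes, habitat, tree**: expert votes flip with a configurable error
  rate and abstain at a configurable rate; habitat percentages come from
  Beta(8,1) for specialists vs Beta(2,4) for non-specialists; trees are
  pure-birth (rate 1) with a terminal waiting period so tip branches are
  positive, and traits are Brownian (σ² = 1).

Everything is driven by one integer seed through per-component
`SeedSequence` streams; a fixed seed gives byte-identical output files.

What the generator does **not** emulate — and what passing tests
therefore do not establish about field data: alignment error and indels
(sequences are generated aligned, substitutions only), rate variation
across sites and lineages, spatial autocorrelation among sites,
detection failure (a present species is always counted), correlated
trait assignment (dispersal and niche are drawn independently), and any
relationship between the phylogeny and the community structure (the
trait tree is simulated separately). Tests against synthetic data
validate the *computations*; they do not validate the biological
assumptions those computations encode.

`recovery_table` supports parameter-recovery checks: it regresses
occupancy — including species that occupied zero sites, which a field
survey could never see — on the *true* log mean abundance. Conditioning
on observed species and estimated abundance (as a real analysis must)
induces a mild truncation bias in steep-slope categories; using the
simulation's full knowledge makes fitted coefficients directly
comparable to the generating values, and 95% Wald intervals then show
nominal coverage.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations for
tight feedback: 1000 random matrices of ≤ 8 tips for the UPGMA oracle,
100 seeds of 12-species alignments for delimitation recovery, 500
Brownian replicates on 64-tip trees for the K calibration, 100
metacommunity seeds for AICc model selection, and 200 replicates of
400-species communities for slope recovery. All are configurable
upward through `SimConfig`.
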