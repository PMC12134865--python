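# Methods

## Scope and model

`sigrev` implements the in-silico arm of a signature-reversal drug
repurposing workflow for a two-group disease contrast (invasive vs
non-invasive bladder cancer is the motivating setting), together with
the downstream dose-response and in-vivo calculators used to evaluate
candidate drugs. The core objects are:

1. per-feature two-group rank statistics and selection rules,
2. a consolidated signed disease signature,
3. a two-tag weighted Kolmogorov-Smirnov (KS) connectivity score with
   permutation significance,
4. conjunctive annotation gates for shortlisting, and
5. closed-form pharmacological calculators plus a 4PL curve fit.

Everything upstream of the calculators operates purely on ranks, which
is why the synthetic-data generators only need to reproduce ordinal
structure, not realistic abundance distributions.

## Differential statistics

The Mann-Whitney U statistic is oriented group2-over-group1 (U counts
pairs where the group-2 value wins, ties half). The p-value is exact —
the full label-permutation distribution — when `n1 + n2 <= 12` and the
pooled sample has no ties; otherwise the normal approximation with tie
correction is used, without continuity correction, so the asymptotic
p-values stay symmetric around the null median. The discriminatory AUC
is `U/(n1*n2)`, the probability a random group-2 value exceeds a random
group-1 value. Because a marker can discriminate in either direction,
selection thresholds are applied to `max(AUC, 1 - AUC)`; the comparison
is `>=` by default (configurable to strict `>`), so a threshold of 0.6
admits both up- and down-regulated discriminators.

Log-fold change is `mean(log2 group2) - mean(log2 group1)`; base 2 is a
convention choice. A feature's direction is "up" iff its log-fold change
is positive.

Multiplicity adjustment defaults to Benjamini-Hochberg step-up (with
monotonicity enforcement, capped at 1) with Bonferroni selectable; both
delegate to `statsmodels`. Untestable features (fewer than two usable
values in a group) carry NaN p-values, are excluded from the adjustment
family, and can never be selected.

Proteomic (dual-platform) selection tests each platform separately with
pairwise missing-value exclusion — never imputation — and a
per-platform adjustment family. The DAP rule is conjunctive:
significant in at least one platform; detected (non-missing) in more
than `detect_min` of samples in at least one platform; log-fold-change
signs concordant among the platforms in which the feature is
significant; not on the contaminant list. Exclusion reasons are
evaluated in the order low detection, not significant, directional
conflict, contaminant, and recorded per feature. The merged per-feature
report takes the mean of available platform log-fold changes (the
combination rule is otherwise underdetermined), the p/AUC of the more
significant platform, and per-group detection maxima.

## Signature construction

Protein IDs are first harmonized to gene level through a user-supplied
mapping; same-direction duplicates collapse, opposite-direction
duplicates survive so consolidation can record the conflict, and
unmapped features pass through under their own ID with a warning.
Consolidation then admits a feature when every source reporting it
agrees on direction (one source alone counts as "unique") and excludes
it with reason "directional conflict" otherwise. The operation is
order-independent; entries are sorted by feature ID.

Partitioning into K query subsets is uniform random without
replacement with sizes differing by at most one (1,575 entries at
K = 10 give five subsets of 158 and five of 157). Direction-stratified
splitting is available but off by default, since a plain random split
is the baseline behaviour; the larger up-chunks are paired with the
smaller down-chunks under stratification so the size bound still holds.
A small subset can therefore be one-sided (no up or no down members);
downstream scoring handles this by using the single available
enrichment score (`raw = ES_up` or `raw = -ES_down`) and logging the
subset as degenerate.

## Connectivity scoring

Gene rankings are descending by differential-expression value with ties
broken by gene ID, so rankings are deterministic. The enrichment score
of a tag set at ascending positions `p(1..t)` in a universe of n is

    a  = max_j [ j/t - p(j)/n ],   b = max_j [ p(j)/n - (j-1)/t ],
    ES = a if a > b else -b.

The raw two-tag score is 0 when `ES_up` and `ES_down` share a strict
sign and `ES_up - ES_down` otherwise; swapping the tag sets negates it.
Within each subset, raw scores are normalized across drugs to [-1, 1]
per sign class (positives by the max positive, negatives by the largest
negative magnitude), preserving sign and within-class order.

Permutation significance is one-sided for negative enrichment with the
add-one estimator `p = (1 + #{raw_perm <= raw_obs})/(B + 1)`, B = 1,000
by default. Because permuted tags are drawn uniformly without
replacement from the universe, their positions on any fixed ranking are
uniform random ranks: the null distribution depends only on
`(n, t_up, t_down)` and is computed once per tag-size combination and
shared across drugs — mathematically identical to re-drawing per drug,
and the reason B = 1,000 over thousands of drug-subset pairs is cheap.

The same-sign collapse puts a probability atom at raw = 0, so null
p-values are sub-uniform (conservative) rather than exactly uniform;
they are exactly uniform for one-sided tag sets, whose statistic is
effectively continuous. Significance calling only requires validity
(`P(p <= a) <= a`), which the test suite checks directly.

Aggregation over the K subsets is the mean of per-subset normalized
scores (the per-subset table is always emitted so any other rule can be
recomputed). The aggregate p-value is the permutation p of the mean
*raw* score under jointly re-drawn tags for all subsets: cross-drug
normalization cannot be replayed inside a single-drug permutation, and
the mean raw score is the monotone analogue of the reported aggregate.
A drug is flagged a significant reverser when its aggregate score is
negative and its aggregate p is below alpha (0.05 default); no
multiple-testing correction is applied across drugs by default, with BH
available. Ties in the final ranking break by drug ID.

The scoring engine is behind a `score_variant` configuration key
(currently only the classical two-tag weighted-KS variant, `"ks"`), so
a running-sum GSEA-style variant can be added behind the same contract.

## Shortlisting

All annotation criteria — FDA approval, availability, no prior disease
association, no reported carcinogenicity — are hard boolean gates
applied conjunctively to the significant reversers; every rejected drug
records all gates it failed. Missing annotation rows are hard errors;
missing flag values are rejected rather than defaulted.

## Pharmacological calculators

The 4PL inhibition model is `R(c) = bottom + (top - bottom)/(1 +
(c/IC50)^h)`: response falls from `top` toward `bottom`, and the
noiseless response at `c = IC50` is the midpoint. Fitting is nonlinear
least squares (`scipy.optimize.curve_fit`) parameterized in
log10(IC50), initialized from the data (top = max response,
bottom = min, IC50 = the mid-range of tested log-concentrations,
h = 1) with the Hill slope bounded to [0.1, 10]. A fit is reported
"ambiguous" — with no IC50 — when the optimizer fails, the fitted IC50
falls outside the tested concentration range, or SE(log10 IC50)
exceeds 0.5; flat response vectors short-circuit to ambiguous. The
out-of-range and standard-error gates mirror the "ambiguous"/"n.d."
behaviour of standard curve-fitting software and are configurable
constants. At least 4 distinct positive concentrations are required.

Closed-form calculators: control-relative ratio `value / mean(control)`
(colonies, viability, confluence, densitometry alike); caspase fold
`(caspase/viability)_treated / (caspase/viability)_control`, which
separates genuine apoptosis induction from mere loss of cells; caliper
tumor volume `V = 1/2 * length * width^2` in mm^3 with the convention
width <= length; percent reduction `100 * (control - treated)/control`,
reported to one decimal; Reagan-Shaw human-equivalent dose
`HED = dose * Km_animal / Km_human` with defaults Km mouse = 3,
Km human = 37 and a 60-kg adult for the daily dose (rounded to the
nearest mg) — the standard body-surface-area factors.

## Synthetic data: what it emulates, and what it does not

Cohorts are log-normal on the log2 scale: per-feature baseline means
~ N(7, 1.5), within-group SD 1. A planted fraction of features
(`round(frac_shifted * n_features)`, split evenly up/down with odd
remainders to "up") receives an additive group-2 shift of
`effect_size` SD units. Defaults — 20 + 20 samples, 1,000 features,
10% shifted, effect size 1.5 — are desk-scale conditions chosen so
planted effects are detectable but not trivial (effect size 1.5 gives a
per-feature AUC of about 0.86); they are free knobs, not estimates of
any real cohort's noise structure.

Dual-platform proteomic matrices decompose each cell into a shared
sample-level component (weight `sqrt(platform_corr)`) plus independent
platform noise, so the per-feature cross-platform correlation equals
`platform_corr` (default 0.8) and the platforms coincide at 1.
Missingness is completely at random per platform (default rate 0.2);
intensity-dependent missingness is deliberately not modelled.

The literature list draws from planted features and flips an exact
fraction of directions to exercise the conflict-exclusion rule. The
perturbation reference gives null drugs iid standard-normal profiles;
a planted reverser subtracts `reversal_strength` (default 3) times the
signature's signed indicator from its profile, a mimic adds it.
Dose-response tables are 4PL plus iid Gaussian response noise on an
8-point 0.1-100 umol/L log grid.

Consequences for interpretation: passing tests demonstrate correctness
of the statistics and recovery under clean ordinal structure — they say
nothing about batch effects, heavy-tailed counts, correlated features,
intensity-dependent dropout, or the composition of any real
perturbation reference, none of which the generators emulate. No raw
spectra, reads, or real Connectivity-Map build semantics are simulated.

## Numerical and design choices

- All randomness flows from one integer seed through named
  `numpy.random.Generator` instances; identical spec + seed is
  bit-reproducible, and pipeline stages derive their seeds from the run
  seed with fixed offsets.
- Rank ties break by gene ID; ranking is therefore deterministic.
- Degenerate inputs are explicit errors naming the offending field
  (invalid spec fields, empty tag sets, K exceeding the signature size,
  non-positive controls, fewer than 4 distinct concentrations) except
  where the contract says otherwise (untestable features are flagged,
  directional conflicts are data).
- Matrices are one strict dialect: tab-delimited UTF-8, features as
  rows, first column feature ID, header of sample IDs, `NA` for
  missing. Gene sets are GMT; signatures serialize as `NAME_UP` /
  `NAME_DOWN` pairs.
- The pipeline manifest records the full configuration, seed, package
  version and per-stage counts, so the selection funnel and any output
  are reconstructable from the manifest alone.

## Problem sizes

Default analyses and the reproduction script run at desk scale: cohorts
of 20 + 20 samples with 600-2,000 features, references of 50-100 drugs
over 1,000-2,000 genes, K = 10 partitions and B = 1,000 permutations —
sizes at which the full pipeline completes in seconds while every
statistical property of interest (type-I control, calibration, planted
recovery) is measurable. Larger inputs only change runtime, not code
paths; the permutation-null sharing described above makes B the cheap
dimension.

## Known limitations

- The exact Mann-Whitney path requires a tie-free pooled sample; tied
  small samples fall back to the asymptotic approximation.
- The aggregate permutation p uses mean raw scores (see above);
  aggregate normalized scores and aggregate p are therefore computed on
  slightly different scales, though both are monotone in the same
  underlying enrichment.
- One reference profile per drug: replicate perturbation instances and
  instance-level aggregation are out of scope.
- The 4PL fit assumes a decreasing (inhibition) curve; activation
  curves fit poorly and surface as ambiguous rather than being
  modelled.
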