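# sigrev

Signature-reversal drug repurposing for two-group disease contrasts, built
around the muscle-invasive vs non-muscle-invasive bladder cancer (MIBC vs
NMIBC) setting: construct a signed multi-omics disease signature, score
drugs for reversing it against a perturbation reference, filter the
significant reversers through annotation gates, and evaluate candidate
drugs with standard pharmacological calculators.

## Who this is for

Computational biologists who have (i) feature-by-sample abundance matrices
(transcripts and/or proteins) for two phenotype groups, (ii) optionally a
signed literature feature list, and (iii) a drug-perturbation reference
(drug x gene differential-expression matrix), and who want a reproducible,
tested implementation of the connectivity-mapping reversal workflow plus
the downstream in vitro / in vivo readout calculators. A synthetic-data
module generates every input with the statistical structure the analysis
assumes, so the whole pipeline runs and is testable without external data.

## The method

**Differential statistics.** Each feature is tested between groups with
the Mann-Whitney U test (exact for small tie-free samples, normal
approximation with tie correction otherwise), oriented group2-over-group1,
with the rank-sum AUC `U/(n1*n2)` as a discriminatory filter and
Benjamini-Hochberg (default) or Bonferroni adjustment. Transcriptomic
features are selected at adjusted p < 0.05 and discriminatory AUC >= 0.6;
proteomic features follow the dual-platform rule (significant in >= 1
platform, detected in > 10% of samples in >= 1 platform, directionally
concordant among significant platforms, not a listed contaminant).

**Signature.** Selected features from transcriptomics, proteomics and
literature are consolidated: a feature kept by every source that reports
it (with one direction) enters the signed signature; any directional
disagreement excludes it with a recorded reason. The signature is split
into K random near-equal subsets used as query tag sets.

**Connectivity.** Each drug profile becomes a gene ranking (rank 1 = most
up-regulated). For a tag set at ascending positions `p(1..t)` in a
universe of n genes, the enrichment score is the two-sided weighted
Kolmogorov-Smirnov statistic

```
a  = max_j [ j/t - p(j)/n ]
b  = max_j [ p(j)/n - (j-1)/t ]
ES = a  if a > b  else  -b
```

The raw connectivity score is 0 when ES_up and ES_down share a sign and
`ES_up - ES_down` otherwise; a reverser (up tags pushed down, down tags
pushed up) scores negative. Raw scores are normalized to [-1, 1] within
sign class across drugs; significance is a one-sided permutation test for
negative enrichment with tags re-drawn uniformly from the universe
(`p = (1 + #{raw_perm <= raw_obs}) / (B + 1)`). Per-subset normalized
scores are averaged into the aggregate score and drugs ranked most
negative first.

**Pharmacological calculators.** 4PL concentration-response fitting
`R(c) = bottom + (top-bottom)/(1 + (c/IC50)^h)` with an explicit
"ambiguous" status (no convergence, IC50 outside the tested range, or
SE(log10 IC50) > 0.5); control-relative ratios; viability-normalized
caspase fold change; caliper tumor volume `V = 1/2 * length * width^2`;
percent tumor-volume reduction; and the Reagan-Shaw body-surface-area
conversion `HED = dose * Km_animal / Km_human`.

## Worked example

```python
from sigrev import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(seed=1), "out")
for s in manifest["stages"]:
    print(s["stage"], s["counts"])
```

prints (seed 1, default configuration):

```
simulate {'transcriptomic_features': 1000, 'proteomic_features': 600, 'planted_transcriptomic': 100, 'planted_proteomic': 60, 'literature_entries': 40}
diff_expr {'features_tested_transcriptomic': 1000, 'degs_selected': 98, 'features_tested_proteomic': 600, 'daps_selected': 54}
signature {'signature_entries': 147, 'signature_up': 72, 'signature_down': 75, 'excluded_conflicts': 4, 'partitions': 10}
connectivity {'drugs_scored': 50, 'significant_reversers': 3}
shortlist {'candidates': 3, 'rejected': 0}
```

Reading the funnel: of 1,000 simulated transcripts, 98 pass the DEG
thresholds (100 carried a planted shift); 54 of 600 proteins pass the
dual-platform DAP rule; consolidation with the literature list yields a
147-feature signed signature with 4 directional conflicts excluded; the
three drugs planted as signature reversers in the 50-drug reference are
the three significant hits, and all three survive the annotation gates
into the shortlist.

The same stages are exposed as CLI subcommands
(`sigrev simulate | diff | build-signature | connect | shortlist |
fit-ic50 | tumor-growth | dose-convert | run-all`), e.g.

```
$ sigrev dose-convert --animal-dose 75
HED: 6.081 mg/kg; daily dose: 365 mg/day (60-kg adult)
```

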