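# apoepgs

Polygenic scores for Alzheimer's disease with explicit handling of the
*APOE* locus, and repeated-measures logistic models of dementia in
longitudinal ageing cohorts.

## The problem

Alzheimer's disease has one overwhelming common genetic risk locus — the
*APOE*/*TOMM40*/*APOC1* LD block on chromosome 19, whose ε4 haplotype is
defined by two SNPs (rs429358, rs7412) — plus many small effects scattered
across the genome. A polygenic score (PGS) that simply sums weighted
variants through this region neither captures the full ε4 risk nor
isolates the polygenic remainder. This package implements the analysis
design that addresses this: build PGSs at a grid of discovery p-value
thresholds **with and without** excision of the APOE region, call ε4
diplotypes directly from the two defining SNPs, and model dementia with
the score and ε4 copy-number indicators as separate terms.

The core quantities:

* **Score**: `PGS_i = Σ_j w_j d_ij`, where `d_ij` is individual *i*'s
  dosage of variant *j*'s effect allele and `w_j` is the discovery-GWAS
  log-odds weight; a variant enters the pT score only if its discovery
  p-value is `< pT`, for `pT ∈ {0.001, 0.01, 0.05, 0.1, 0.3, 1.0}` (no LD
  clumping or pruning). Scores are standardized to mean 0, SD 1 in the
  analytic sample.
* **APOE exclusion region**: chr19:45,384,477–45,432,606 (build 37) — the
  *TOMM40* start −10 kb through the *APOC1* stop +10 kb, removed in its
  entirety for the region-free scores.
* **ε4 calling**: haplotype map ε4 = (rs429358-C, rs7412-C),
  ε3 = (T, C), ε2 = (T, T); the unphased double heterozygote resolves to
  ε2/ε4 (ε1 treated as absent).
* **Outcome**: Langa–Weir classification of cognition scores
  (self-respondents 0–6 dementia / 7–11 CIND / 12–27 normal; proxy 6–11 /
  3–5 / 0–2), contrasting dementia vs. normal with CIND excluded.
* **Model**: marginal logistic regression fitted by generalized
  estimating equations (binomial, logit link, unstructured working
  correlation, robust SEs) with repeated measures on the individual and
  covariates age, sex, education, calendar year, stroke history, five
  ancestry PCs, ε4 indicators and one PGS.

Because the cohort data this design targets are access-restricted, the
package ships a synthetic-cohort generator (`apoepgs.simulate`) producing
genotypes with LD and an APOE-like haplotype block, GWAS-style summary
statistics, and a longitudinal dementia process with known marginal odds
ratios — so every stage is testable end to end.

## Worked example

```bash
apoepgs all --seed 7 --out-dir run/
```

simulates a 2,000-person, 5-wave cohort with 1,000 variants, builds the
twelve standardized scores, calls ε4, assembles the panel and fits the
model grid. The console log shows the exclusion accounting:

```
INFO apoepgs.cognition: build_panel: retained 7540/10000 observations
(1632 missing cognition, 825 CIND, 3 missing stroke); removed 3 individuals
```

and `run/model_results.tsv` contains one row per term per model, e.g. for
pT = 0.01 with the APOE region removed (seed 7):

```
pT    region_excluded  term     odds_ratio  robust_se  ci_low  ci_high
0.01  True             one_e4   2.363       0.110      1.904   2.933
0.01  True             two_e4   4.694       0.236      2.954   7.458
0.01  True             pgs      1.153       0.049      1.049   1.269
```

Read: one ε4 copy raises the odds of dementia (vs. normal cognition)
roughly 2.4-fold and two copies 4.7-fold in this replicate, while the
region-free score adds about 15% per SD — one draw from a generator whose
true marginal odds ratios are 2.1, 4.4 and 1.08 (the robust SEs are on
the log-odds scale; all three intervals cover the truth). `run/manifest.json`
records the seed, config hash and per-artifact digests; re-running with
the same seed reproduces every table byte for byte.

The same stages are importable as a library (`build_score_grid`,
`call_cohort`, `build_panel`, `run_model_grid`,
`run_sensitivity_suite`, ...) and each stage's CLI subcommand reads and
writes plain tab-delimited files, so real summary-statistics/dosage/
phenotype inputs drop in where the simulator's outputs sit.

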