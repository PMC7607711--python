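# Methods

This note documents the statistical model, the design choices where the
design was genuinely open, the synthetic-cohort generator, and what the
test suite does and does not establish.

## Score construction

A polygenic score is the weighted dosage sum `PGS_i = Σ_j w_j d_ij`.
Weights come from discovery-GWAS summary statistics; membership at
threshold pT is **strict** (`p < pT`), since `p ≤ pT` is the other common
dialect and the two differ at boundary p-values; `pT = 1.0` is the
all-variant score and retains records with p exactly 1. No LD clumping or
pruning stage exists anywhere in the package — the intended genotype input
is a set of array tag-SNPs, effectively pre-thinned — and none is planned.

Allele alignment orients each GWAS effect allele to the genotype file's
counted allele: a direct match keeps `β`, a swapped match negates it, and
a variant whose allele pair matches in neither orientation is excluded
and counted in the alignment report. Strand-ambiguous (A/T, C/G) variants
are aligned by allele identity like any other variant — the expected use
case pairs same-build array data with same-build summary statistics, so
silently dropping palindromes would over-prune — but they are counted in
the report and `exclude_palindromic` removes them on request. Variant
matching is by rs-ID with a chromosome:position fallback
(`match_on="position"`). Note that flipping a variant's orientation
(counted↔alt, `d → 2−d`) shifts every individual's contribution by the
same constant `2β`; between-individual contrasts, and therefore the
standardized scores, are orientation-invariant.

Missing dosages are mean-imputed per variant at scoring time (the
standard scoring convention); a variant with no observed dosages
contributes zero. Standardization is a z-transform against the sample
mean and sample SD (ddof = 1) of the analytic sample, re-done whenever
the sample changes (e.g. after a cohort-exclusion sensitivity refit);
a zero-variance score raises rather than silently returning zeros.

The APOE exclusion interval is chr19:45,384,477–45,432,606 — *TOMM40*
start (45,394,477) −10 kb through *APOC1* stop (45,422,606) +10 kb,
build 37, **1-based and inclusive on both ends** (the endpoint convention
is ours; the published coordinates do not state one). Region-included
scores let every region variant passing pT contribute (including
rs429358/rs7412 when present), which yields the exact per-individual
decomposition `raw(region-in) = raw(region-out) + raw(region-only)`
verified in the tests to ~1e-10 (floating-point summation order prevents
bitwise equality).

## ε4 calling

Haplotype map: ε4 = (rs429358-C, rs7412-C), ε3 = (T, C), ε2 = (T, T),
ε1 = (C, T). Unphased two-site genotypes resolve uniquely except the
double heterozygote, which is consistent with ε2/ε4 or ε1/ε3 and is
assigned ε2/ε4 (standard convention; ε1 is extremely rare). The three
genotype pairs that force an ε1 haplotype in every phasing (e.g.
rs429358 C/C with rs7412 C/T) are flagged no-calls, never coerced into
the six common categories. Fractional imputed dosages are hard-called
when within ±0.1 (configurable) of an integer; out-of-band dosages are
flagged no-calls and excluded from analysis. The module works on {C,T}
allele labels with an explicit counted-allele declaration per site,
because silently miscoding either site transposes ε2 and ε4.

## Cognition classification and panel assembly

Langa–Weir cut points: self-respondents (0–27 scale) 0–6 dementia, 7–11
CIND, 12–27 normal; proxy respondents (0–11 scale) 6–11 dementia, 3–5
CIND, 0–2 normal. Classification uses each wave's own respondent type,
which may change across waves. The analytic panel contrasts dementia
(1) against normal cognition (0); exclusions are applied
observation-level first, in order — missing cognition, CIND, missing
stroke — and only then are individuals with no remaining observations
dropped, so an individual contributing any complete dementia/normal
observation stays. The exclusion report satisfies
`m_input = m_retained + m_missing_cognition + m_CIND + m_missing_stroke`
exactly. "Dementia at first visit" in the descriptive table means the
first *retained* observation.

## Association models

Marginal logistic models are fitted by GEE (statsmodels: binomial family,
logit link) with repeated measures on the individual and robust sandwich
standard errors — always reported; model-based SEs are not exposed.
The default working correlation is unstructured, with wave pairs indexed
by each subject's within-subject wave rank so unequal visit counts are
handled; if the unstructured fit fails or does not converge the model is
automatically refitted with an exchangeable structure and
`structure_used` records the fallback. Coefficients are exponentiated to
odds ratios with normal-theory intervals `exp(logOR ± 1.96·SE)`;
two-sided α = 0.05. Calendar year enters as a continuous per-year term
centered at the first panel year (centering moves only the intercept).
Coefficients with |logOR| > 15 raise a separation diagnostic rather than
reporting astronomically inflated ORs. The result table reports the
robust SE on the log-odds scale plus `se_exp = exp(SE)`, the
multiplicative-scale form some software prints, since published tables
are ambiguous between the two.

The model grid fits one model per (pT × region flag) cell — twelve for
the default thresholds — each with age, sex, education, year, stroke,
five PCs, both ε4 indicators and one standardized PGS. The sensitivity
suite covers: (a) refitting after dropping the two oldest birth cohorts,
(b) the grid with ε4-residualized scores (OLS residuals on intercept +
one-copy + two-copy indicators, re-standardized), (c) PGS-only models
without ε4 adjustment, and (d) an ε4-only model without a PGS. The
interaction model adds PGS×one-copy and PGS×two-copy product terms.

## Synthetic cohort

The generator emulates the three inputs at desk scale. Defaults:
2,000 individuals, 1,000 variants, 5 biennial waves starting in 2000.

**Genotypes.** Variants have binomial(2, MAF) Hardy–Weinberg marginals,
MAF ~ U(0.05, 0.5); within-block LD (block size 10, ρ = 0.3) is induced
by a latent Gaussian copula (a shared block factor plus idiosyncratic
noise, mapped through the binomial quantile). The APOE block is generated
haplotype-wise: two isoform draws per individual from
(f_ε2, f_ε3, f_ε4) = (0.08, 0.77, 0.15) under random mating — chosen to
reproduce European-ancestry carrier rates of roughly 24% one-copy / 2%
two-copy — which determines rs429358/rs7412 dosages exactly; 20
additional block variants tag the ε4 haplotype with a 10% per-haplotype
error, and the two defining SNPs receive N(0, 0.02) dosage jitter
emulating high-confidence imputation.

**Summary statistics.** A 5% causal subset receives β ~ N(0, 0.08) with
p-values spread as 10^−U(0.5, 8) so the threshold grid separates variant
sets; null variants get small noise weights and uniform p-values;
APOE-block variants get large ε4-tagging weights and p < 1e-8, emulating
the dense association peak at the locus. Effect/other alleles are
randomly swapped (with β negated) for 30% of variants so alignment is
always exercised.

**Phenotypes.** Each wave's dementia indicator is Bernoulli with
conditional probability `expit(η_c + σ_u u_i)`, `u_i ~ N(0,1)`,
σ_u = 1 — the random intercept induces within-subject correlation. The
configured effects are **marginal** log odds ratios (defaults: PGS per SD
log 1.08, one ε4 copy log 2.1, two copies log 4.4, age log 1.15/yr,
male sex log 1.12, education log 0.76/yr, year log 1.12, stroke
log 3.37, baseline prevalence 0.03 at the covariate reference), and the
conditional predictor is calibrated numerically so each observation's
marginal probability equals `expit(η_m)`: `η_c = G⁻¹(expit(η_m))` with
`G(η) = E_u[expit(η + σ_u u)]` evaluated by 48-node Gauss–Hermite
quadrature and inverted by monotone interpolation. This makes the
marginal model exactly logit-linear in the configured coefficients — the
estimand of the GEE — whereas the familiar closed-form attenuation factor
`√(1 + (16√3/15π)² σ_u²)` (kept as `SimulationConfig.attenuation` for
reference) is only first-order accurate and leaves a detectable bias on
large coefficients at replicate-study precision.

Cognition scores are drawn uniformly within the Langa–Weir band
consistent with the drawn class and respondent type (the analysis uses
only the class); CIND (10%), missing cognition (16%), missing stroke
(0.03%) and proxy responses (5%) are injected at rates matching the
exclusion-flow proportions of a large ageing panel; stroke is an
absorbing state (4% baseline, 1%/wave hazard). Age, education, sex and
birth-cohort distributions follow the same panel's descriptive
statistics. Everything is deterministic given the config seed.

**What the simulator does not emulate**: realistic recombination maps or
coalescent ancestry, imputation error beyond dosage jitter, genotype
missingness, informative dropout/mortality selection, persistence of the
dementia state across waves (waves are conditionally independent given
the random intercept), measurement error in covariates, and survey
weights. Passing recovery tests therefore establish that the pipeline's
estimators are correct under the assumed marginal model, not that the
design is robust to these real-data features.

## Verification

The suite verifies, among else: the exclusion region's coordinates; the
classifier's bands by exhaustive enumeration; the score decomposition
identity on a 1,000 × 5,000 cohort; equality of single-wave
independence-GEE estimates with the ordinary logistic MLE (≤1e-6); exact
duplication behaviour of the sandwich (cloned clusters leave estimates
unchanged and shrink robust SEs by 1/√2); and a 200-replicate recovery
study at the default configuration, checking mean estimates against the
generating marginal logORs within 2 Monte-Carlo SEs and 95% CI coverage
within [92%, 98%]. The recovery harness and the replicate study in
`scripts/acceptance.py` fit with an exchangeable working correlation —
GEE point estimates are consistent under any working structure and the
exchangeable fit is roughly twice as fast as the unstructured one at
these problem sizes; the primary model grid keeps the unstructured
default. Problem sizes throughout (2,000 × 5 replicates, 1,000 × 5,000
decomposition) were chosen as the smallest at which the checked
properties are statistically sharp.

## Known limitations

* VCF input is restricted to biallelic records; BGEN is not supported.
* The dosage-table dialect carries no allele annotations of its own; a
  companion variant-info table is needed for alignment and ε4 calling.
* The unstructured working correlation can be slow or unstable on very
  sparse wave patterns; the exchangeable fallback is automatic but
  changes the working model (never the estimand).
* Scores re-read from disk lose their raw-scale provenance
  (`raw_mean`/`raw_sd` are NaN); they are already standardized.
* The ε4 caller ignores the rare ε1 and ε3r isoforms by design; cohorts
  where ε1 is plausible will see those individuals flagged, not called.
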