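"""Synthetic cohort generation for the dementia-PGS pipeline.

Generates the three inputs the analysis consumes — genotype dosages with
LD structure and an APOE-like haplotype block, discovery-GWAS summary
statistics, and a longitudinal phenotype table — with the statistical
structure the downstream models assume, so the whole pipeline is testable
without restricted cohort data.

Genotypes are drawn with Hardy-Weinberg marginals; within-block LD comes
from a latent Gaussian copula (a shared block factor at correlation
``ld_rho``). The APOE block is generated haplotype-wise: each individual
draws two isoform haplotypes from (f_e2, f_e3, f_e4) under random mating,
which determines rs429358/rs7412 dosages exactly, and neighbouring block
variants tag the e4 haplotype with a configurable error rate.

The dementia process is a per-wave Bernoulli draw from a logistic model in
the standardized PGS, e4 copy-number indicators and covariates, with a
subject-level Gaussian random intercept inducing within-subject
correlation. Because the analysis model is marginal (GEE) while the random
intercept makes the generating model conditional, the conditional linear
predictor is calibrated numerically so that the *marginal* success
probability of every observation equals expit of the configured marginal
linear predictor: eta_cond = G^{-1}(expit(eta_marginal)), where
G(eta) = E_u[expit(eta + sigma_u u)] is evaluated by Gauss-Hermite
quadrature and inverted by monotone interpolation. The marginal model is
then exactly logit-linear in the configured coefficients, which are the
quantities the GEE estimates (the familiar closed-form attenuation factor
sqrt(1 + c^2 sigma_u^2), c = 16*sqrt(3)/(15*pi), is the first-order
approximation to this correction and is kept as a reference property).

Cognition scores are back-generated uniformly within the Langa-Weir band
consistent with the drawn class and respondent type; CIND class and
missingness are injected at configured rates; stroke evolves as an
absorbing per-wave hazard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import binom

from .genotype_io import GenotypeMatrix, SummaryStats
from .score import APOC1_STOP, TOMM40_START

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "MARGINAL_ATTENUATION_C",
    "simulate_genotypes",
    "simulate_summary_stats",
    "simulate_phenotypes",
    "simulate_cohort",
]

#: Logit/probit attenuation constant 16*sqrt(3)/(15*pi).
MARGINAL_ATTENUATION_C = 16 * math.sqrt(3) / (15 * math.pi)

RS429358_POS = 45_411_941
RS7412_POS = 45_412_079

def _marginal_to_conditional(eta_m: np.ndarray, sigma_u: float) -> np.ndarray:
    """Map marginal linear predictors to conditional ones.

    Returns eta_c with E_u[expit(eta_c + sigma_u u)] = expit(eta_m) for
    u ~ N(0,1), via Gauss-Hermite quadrature on a dense grid and monotone
    interpolation of the inverse. Exact to interpolation error (~1e-8 on
    the probability scale), so marginal generating coefficients are
    recovered without the bias of the closed-form attenuation factor.
    """
    if sigma_u == 0:
        return np.asarray(eta_m, dtype=float)
    nodes, weights = np.polynomial.hermite_e.hermegauss(48)
    weights = weights / weights.sum()
    grid = np.linspace(-16.0, 16.0, 2001)
    g = expit(grid[:, None] + sigma_u * nodes[None, :]) @ weights
    # g is strictly increasing in eta; invert by interpolation
    p_target = expit(np.asarray(eta_m, dtype=float))
    return np.interp(p_target, g, grid)


_COHORT_BINS = [
    (-10_000, 1923, "AHEAD"),
    (1924, 1930, "CODA"),
    (1931, 1941, "HRS"),
    (1942, 1947, "WB"),
    (1948, 1953, "EBB"),
    (1954, 10_000, "MBB"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Effect sizes are marginal log odds ratios on the scale the GEE
    estimates; defaults follow the observed association pattern in a large
    ageing-cohort analysis of dementia (per-SD PGS logOR log 1.08, one
    e4 copy log 2.1, two copies log 4.4, with strong age/education/stroke
    covariate effects and ~3% baseline prevalence).
    """

    n_individuals: int = 2000
    n_variants: int = 1000
    n_waves: int = 5
    seed: int = 0

    # genotype structure
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.3
    # APOE-like block
    f_e2: float = 0.08
    f_e3: float = 0.77
    f_e4: float = 0.15
    n_apoe_block_variants: int = 20
    apoe_tag_error: float = 0.1
    apoe_dosage_jitter: float = 0.02

    # summary-statistics generation
    causal_fraction: float = 0.05
    causal_beta_sd: float = 0.08
    null_beta_sd: float = 0.005
    allele_swap_rate: float = 0.3

    # disease model (marginal scale)
    baseline_prevalence: float = 0.03
    beta_pgs: float = math.log(1.08)
    beta_one_e4: float = math.log(2.1)
    beta_two_e4: float = math.log(4.4)
    beta_age: float = math.log(1.15)
    beta_sex: float = math.log(1.12)
    beta_education: float = math.log(0.76)
    beta_year: float = math.log(1.12)
    beta_stroke: float = math.log(3.37)
    sigma_u: float = 1.0

    # covariate/demography model
    age_mean: float = 63.3
    age_sd: float = 10.3
    education_mean: float = 13.2
    education_sd: float = 2.5
    prop_male: float = 0.42
    first_year: int = 2000
    years_between_waves: int = 2
    stroke_baseline: float = 0.04
    stroke_hazard: float = 0.01

    # observation process
    proxy_rate: float = 0.05
    cind_rate: float = 0.10
    missing_cognition_rate: float = 0.16
    missing_stroke_rate: float = 0.0003

    def __post_init__(self) -> None:
        if not math.isclose(self.f_e2 + self.f_e3 + self.f_e4, 1.0, abs_tol=1e-9):
            raise ValueError("haplotype frequencies f_e2 + f_e3 + f_e4 must sum to 1")
        for name in ("proxy_rate", "cind_rate", "missing_cognition_rate",
                     "missing_stroke_rate", "baseline_prevalence",
                     "stroke_baseline", "stroke_hazard", "causal_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")

    @property
    def attenuation(self) -> float:
        """Conditional-to-marginal inflation factor sqrt(1 + c^2 sigma_u^2)."""
        return math.sqrt(1 + (MARGINAL_ATTENUATION_C * self.sigma_u) ** 2)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulatedCohort:
    """Bundle of one simulated dataset plus its generating truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    summary_stats: SummaryStats
    phenotypes: pd.DataFrame
    generating_score: pd.Series
    e4_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _draw_apoe_haplotypes(config: SimulationConfig, rng: np.random.Generator):
    """Two isoform haplotypes per individual under random mating."""
    freqs = np.array([config.f_e2, config.f_e3, config.f_e4])
    # 0 = e2, 1 = e3, 2 = e4
    return rng.choice(3, size=(config.n_individuals, 2), p=freqs)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw the dosage matrix; returns (genotypes, apoe_haplotypes).

    Non-APOE variants have binomial(2, maf) marginals with within-block LD
    from a shared latent Gaussian factor at correlation ``ld_rho``. The
    APOE block (rs429358, rs7412 and ``n_apoe_block_variants`` tag
    variants inside chr19:45,384,477-45,432,606) is derived from the
    haplotype draw; the two defining SNPs receive a small Gaussian jitter
    emulating high-confidence imputation dosages.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    m_free = config.n_variants - 2 - config.n_apoe_block_variants
    if m_free < 0:
        raise ValueError("n_variants too small for the APOE block")

    # --- genome-wide variants with block LD -------------------------------
    mafs = rng.uniform(*config.maf_range, size=m_free)
    blocks = np.arange(m_free) // max(config.ld_block_size, 1)
    n_blocks = blocks.max() + 1 if m_free else 0
    shared = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, m_free))
    rho = config.ld_rho
    z = math.sqrt(rho) * shared[:, blocks] + math.sqrt(1 - rho) * eps
    from scipy.stats import norm

    u = norm.cdf(z)
    free_dosages = binom.ppf(u, 2, mafs[None, :]).astype(float)

    chroms = (np.arange(m_free) % 22 + 1).astype(str)
    positions = 1_000_000 + 1_000 * np.arange(m_free)  # chr19 ones stay < 45 Mb

    # --- APOE block -------------------------------------------------------
    haps = _draw_apoe_haplotypes(config, rng)  # 0=e2, 1=e3, 2=e4
    d_429358 = (haps == 2).sum(axis=1).astype(float)  # C allele counts e4
    d_7412 = (haps == 0).sum(axis=1).astype(float)    # T allele counts e2
    if config.apoe_dosage_jitter > 0:
        d_429358 = np.clip(
            d_429358 + rng.normal(0, config.apoe_dosage_jitter, n), 0, 2
        )
        d_7412 = np.clip(
            d_7412 + rng.normal(0, config.apoe_dosage_jitter, n), 0, 2
        )

    k = config.n_apoe_block_variants
    tag_alleles = (haps[:, :, None] == 2) ^ (
        rng.random((n, 2, k)) < config.apoe_tag_error
    )
    tag_dosages = tag_alleles.sum(axis=1).astype(float)
    tag_positions = np.linspace(
        TOMM40_START - 9_000, APOC1_STOP + 9_000, k
    ).astype(int)

    variants = pd.DataFrame(
        {
            "variant_id": (
                [f"snp{i}" for i in range(m_free)]
                + ["rs429358", "rs7412"]
                + [f"apoe_tag{i}" for i in range(k)]
            ),
            "chromosome": np.concatenate([chroms, ["19", "19"], ["19"] * k]),
            "position": np.concatenate(
                [positions, [RS429358_POS, RS7412_POS], tag_positions]
            ),
            "counted_allele": ["A"] * m_free + ["C", "T"] + ["A"] * k,
            "alt_allele": ["G"] * m_free + ["T", "C"] + ["G"] * k,
        }
    )
    dosages = np.column_stack([free_dosages, d_429358, d_7412, tag_dosages])
    individual_ids = [f"ind{i:05d}" for i in range(n)]
    return GenotypeMatrix(individual_ids, variants, dosages), haps


def simulate_summary_stats(
    config: SimulationConfig,
    geno: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> SummaryStats:
    """Discovery-GWAS-like weights and p-values for the simulated variants.

    A random causal subset receives substantial betas with small p-values
    spread across the threshold grid; the rest get small noise betas with
    uniform p-values. APOE-block variants get large e4-tagging betas and
    genome-wide-significant p-values, emulating the dense association peak
    at the locus. Effect/other alleles are randomly swapped (with the beta
    negated) at ``allele_swap_rate`` so allele alignment is exercised.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    var = geno.variants
    m = len(var)
    is_apoe = var["variant_id"].str.startswith(("rs429358", "rs7412", "apoe_tag"))

    beta = rng.normal(0, config.null_beta_sd, m)
    p = rng.uniform(0, 1, m)
    causal = (~is_apoe) & (rng.random(m) < config.causal_fraction)
    beta[causal] = rng.normal(0, config.causal_beta_sd, int(causal.sum()))
    p[causal] = 10.0 ** (-rng.uniform(0.5, 8.0, int(causal.sum())))

    # e4-tagging weights: positive for the allele tracking e4, protective
    # for the e2-counting rs7412 orientation
    n_apoe = int(is_apoe.sum())
    beta[is_apoe.to_numpy()] = rng.normal(0.8, 0.15, n_apoe)
    i7412 = var.index[var["variant_id"] == "rs7412"]
    beta[i7412] = rng.normal(-0.5, 0.1)
    p[is_apoe.to_numpy()] = 10.0 ** (-rng.uniform(8.0, 40.0, n_apoe))

    effect = var["counted_allele"].to_numpy().copy()
    other = var["alt_allele"].to_numpy().copy()
    swap = rng.random(m) < config.allele_swap_rate
    effect[swap], other[swap] = other[swap], effect[swap].copy()
    beta = np.where(swap, -beta, beta)

    df = pd.DataFrame(
        {
            "variant_id": var["variant_id"],
            "chromosome": var["chromosome"],
            "position": var["position"],
            "effect_allele": effect,
            "other_allele": other,
            "beta": beta,
            "p_value": p,
        }
    )
    return SummaryStats(df)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _birth_cohort(birth_year: np.ndarray) -> np.ndarray:
    out = np.empty(birth_year.shape, dtype=object)
    for lo, hi, label in _COHORT_BINS:
        out[(birth_year >= lo) & (birth_year <= hi)] = label
    return out


def _cognition_band(cls: str, respondent_type: str) -> tuple[int, int]:
    bands = {
        ("self", "dementia"): (0, 6),
        ("self", "CIND"): (7, 11),
        ("self", "normal"): (12, 27),
        ("proxy", "dementia"): (6, 11),
        ("proxy", "CIND"): (3, 5),
        ("proxy", "normal"): (0, 2),
    }
    return bands[(respondent_type, cls)]


def simulate_phenotypes(
    config: SimulationConfig,
    scores: pd.Series,
    e4_indicators: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Longitudinal phenotype table driven by the configured logistic model.

    ``scores`` is the standardized generating PGS (indexed by individual
    ID); ``e4_indicators`` provides 0/1 ``one_e4``/``two_e4`` columns. Each
    wave's dementia indicator is Bernoulli with conditional probability
    expit(eta_cond + sigma_u * u_i), where eta_cond is numerically
    calibrated so the observation's marginal probability equals
    expit(eta_marginal); eta_marginal centres age, education and year so
    ``baseline_prevalence`` applies at the covariate reference. Cognition
    scores land uniformly inside the class-consistent
    Langa-Weir band; class and score observation noise (CIND, missingness)
    are injected at configured rates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    ids = list(scores.index)
    n, w = len(ids), config.n_waves
    pgs = scores.to_numpy(float)
    one_e4 = e4_indicators["one_e4"].reindex(ids).to_numpy(float)
    two_e4 = e4_indicators["two_e4"].reindex(ids).to_numpy(float)

    age0 = np.clip(rng.normal(config.age_mean, config.age_sd, n), 51, 95)
    sex = (rng.random(n) < config.prop_male).astype(int)  # 1 = male
    edu = np.clip(rng.normal(config.education_mean, config.education_sd, n), 0, 25)
    birth_year = config.first_year - age0.astype(int)
    cohort = _birth_cohort(birth_year)
    pcs = rng.standard_normal((n, 5))
    u_i = rng.normal(0, config.sigma_u, n)

    step = config.years_between_waves
    years = config.first_year + step * np.arange(w)
    age = age0[:, None] + step * np.arange(w)[None, :]

    # stroke: absorbing state with baseline prevalence + per-wave hazard
    stroke = np.zeros((n, w), dtype=int)
    stroke[:, 0] = rng.random(n) < config.stroke_baseline
    for t in range(1, w):
        new = rng.random(n) < config.stroke_hazard
        stroke[:, t] = stroke[:, t - 1] | new

    age_center = config.age_mean + step * (w - 1) / 2
    year_center = float(years.mean())
    eta_m = (
        logit(config.baseline_prevalence)
        + config.beta_age * (age - age_center)
        + config.beta_sex * sex[:, None]
        + config.beta_education * (edu[:, None] - config.education_mean)
        + config.beta_year * (years[None, :] - year_center)
        + config.beta_stroke * stroke
        + config.beta_one_e4 * one_e4[:, None]
        + config.beta_two_e4 * two_e4[:, None]
        + config.beta_pgs * pgs[:, None]
    )
    eta_c = _marginal_to_conditional(eta_m, config.sigma_u)
    p_cond = expit(eta_c + u_i[:, None])
    dementia = rng.random((n, w)) < p_cond

    proxy = rng.random((n, w)) < config.proxy_rate
    cind = rng.random((n, w)) < config.cind_rate
    miss_cog = rng.random((n, w)) < config.missing_cognition_rate
    miss_stroke = rng.random((n, w)) < config.missing_stroke_rate
    band_u = rng.random((n, w))

    rows = []
    for i, iid in enumerate(ids):
        for t in range(w):
            rtype = "proxy" if proxy[i, t] else "self"
            cls = "CIND" if cind[i, t] else ("dementia" if dementia[i, t] else "normal")
            if miss_cog[i, t]:
                cog = np.nan
            else:
                lo, hi = _cognition_band(cls, rtype)
                cog = lo + int(band_u[i, t] * (hi - lo + 1))
            rows.append(
                (
                    iid, int(years[t]), cog, rtype, float(age[i, t]), int(sex[i]),
                    float(edu[i]), cohort[i],
                    np.nan if miss_stroke[i, t] else int(stroke[i, t]),
                    *pcs[i],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "wave_year", "cognition_score", "respondent_type",
            "age", "sex", "education", "birth_cohort", "stroke",
            "pc1", "pc2", "pc3", "pc4", "pc5",
        ],
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """End-to-end simulation: genotypes -> summary stats -> phenotypes.

    The generating PGS is the pipeline's own standardized APOE-region-free
    score at pT = 0.01 computed from the simulated inputs, so the fitted
    model's score term targets ``beta_pgs`` exactly; e4 status enters the
    outcome model through the true haplotype draw. Fully deterministic
    given ``config.seed``.
    """
    from .score import (
        apply_region_mask,
        build_score_grid,  # noqa: F401  (re-exported convenience)
        compute_score,
        default_apoe_region,
        filter_by_threshold,
        standardize,
    )
    from .genotype_io import align_alleles

    rng = np.random.default_rng(config.seed)
    geno, haps = simulate_genotypes(config, rng)
    stats = simulate_summary_stats(config, geno, rng)

    masked = apply_region_mask(
        filter_by_threshold(stats, 0.01), default_apoe_region()
    )
    alignment = align_alleles(masked, geno)
    raw, n_used = compute_score(geno, alignment)
    gen_score = standardize(raw, 0.01, True, n_used).scores

    e4_count = (haps == 2).sum(axis=1)
    e4_truth = pd.DataFrame(
        {
            "individual_id": geno.individual_ids,
            "e4_count": e4_count,
            "one_e4": (e4_count == 1).astype(int),
            "two_e4": (e4_count == 2).astype(int),
        }
    ).set_index("individual_id")

    pheno = simulate_phenotypes(config, gen_score, e4_truth, rng)
    return SimulatedCohort(
        config=config,
        genotypes=geno,
        summary_stats=stats,
        phenotypes=pheno,
        generating_score=gen_score,
        e4_truth=e4_truth.reset_index(),
    )
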