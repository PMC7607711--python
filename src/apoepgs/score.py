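"""Polygenic score construction at a p-value-threshold grid.

A polygenic score is the weighted sum of an individual's genotype dosages,
PGS_i = sum_j w_j d_ij, with weights taken from discovery-GWAS effect sizes
and variant membership controlled by a discovery p-value threshold pT.
Scores are built both with and without the APOE region (the dense LD block
spanning TOMM40/APOE/APOC1 on chromosome 19) and standardised to mean 0,
SD 1 in the analytic sample. No LD clumping or pruning is applied anywhere:
the intended inputs are array tag-SNPs, already an approximately
LD-thinned set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (
    Alignment,
    GenotypeMatrix,
    RegionMask,
    SummaryStats,
    ValidationError,
    align_alleles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PGSResult",
    "DEFAULT_THRESHOLDS",
    "TOMM40_START",
    "APOC1_STOP",
    "default_apoe_region",
    "filter_by_threshold",
    "apply_region_mask",
    "compute_score",
    "standardize",
    "build_score_grid",
    "score_correlation_matrix",
    "residualize_on_apoe",
    "write_scores",
]

#: The six discovery p-value thresholds of the default score grid.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1, 0.3, 1.0)

#: TOMM40 transcription start and APOC1 transcription stop, build 37 (bp).
TOMM40_START = 45_394_477
APOC1_STOP = 45_422_606


class DegenerateScoreError(ValidationError):
    """Raised when scores cannot be standardised (zero variance) or no
    variant survives filtering."""


@dataclass
class PGSResult:
    """A standardized polygenic score with its provenance.

    ``scores`` is a pandas Series of z-scores indexed by individual ID
    (sample mean 0, sample SD 1 in the scoring sample); ``threshold`` is
    the discovery p-value cutoff pT, ``region_excluded`` records whether
    the APOE region was excised before scoring, and ``raw_mean``/``raw_sd``
    allow mapping back to the raw weighted-sum scale.
    """

    scores: pd.Series
    threshold: float
    region_excluded: bool
    n_variants_used: int
    raw_mean: float
    raw_sd: float

    @property
    def label(self) -> str:
        region = "noAPOE" if self.region_excluded else "withAPOE"
        return f"pT{self.threshold:g}_{region}"


def default_apoe_region(flank: int = 10_000) -> RegionMask:
    """The chromosome-19 APOE exclusion interval.

    Defined as the TOMM40 start position minus ``flank`` to the APOC1 stop
    position plus ``flank`` (build 37, both ends inclusive); the default
    10 kb flank gives chr19:45,384,477-45,432,606. The whole interval is
    excised because the three genes (TOMM40, APOE, APOC1) sit in one dense
    LD block in European ancestries, so weighted variants anywhere in it
    proxy the e4 haplotype.
    """
    return RegionMask("19", TOMM40_START - flank, APOC1_STOP + flank)


def filter_by_threshold(stats: SummaryStats, p_threshold: float) -> SummaryStats:
    """Retain variants with discovery p-value strictly below ``p_threshold``.

    Membership is strict (p < pT); the boundary convention matters because
    p <= pT is the other common dialect. pT = 1.0 is the all-variant score
    and retains every record, including any with p exactly 1.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p-value threshold must lie in (0, 1], got {p_threshold}")
    if p_threshold == 1.0:
        return SummaryStats(stats.df.copy())
    keep = stats.df["p_value"] < p_threshold
    return SummaryStats(stats.df[keep].reset_index(drop=True))


def apply_region_mask(
    stats: SummaryStats, mask: RegionMask, invert: bool = False
) -> SummaryStats:
    """Remove (or with ``invert``, keep only) variants inside a region.

    The interval is inclusive on both ends; chromosome labels are compared
    after stripping any ``chr`` prefix.
    """
    inside = mask.contains(stats.df["chromosome"], stats.df["position"])
    keep = inside if invert else ~inside
    return SummaryStats(stats.df[keep].reset_index(drop=True))


def compute_score(geno: GenotypeMatrix, alignment: Alignment) -> tuple[pd.Series, int]:
    """Raw weighted-sum scores, score_i = sum_j w_j d_ij.

    Missing dosages are imputed per variant to that variant's sample mean
    dosage (a variant with no observed dosage contributes zero). Returns
    the raw scores (indexed by individual ID) and the variant count used.
    """
    if len(alignment) == 0:
        raise DegenerateScoreError("no usable variants: cannot compute a score")
    d = geno.dosages[:, alignment.column_indices]
    if np.isnan(d).any():
        # a fully missing variant has no defined mean; it contributes zero
        all_nan = np.isnan(d).all(axis=0)
        filled = np.where(all_nan[None, :], 0.0, d)
        with np.errstate(invalid="ignore"):
            col_mean = np.where(all_nan, 0.0, np.nanmean(filled, axis=0))
        d = np.where(np.isnan(d), col_mean[None, :], d)
    raw = d @ alignment.weights
    return pd.Series(raw, index=pd.Index(geno.individual_ids, name="individual_id")), len(alignment)


def standardize(
    raw: pd.Series,
    threshold: float,
    region_excluded: bool,
    n_variants_used: int,
) -> PGSResult:
    """Z-score raw scores against their own sample mean and sample SD."""
    if len(raw) < 2:
        raise DegenerateScoreError("need at least 2 individuals to standardize")
    mean = float(raw.mean())
    sd = float(raw.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateScoreError("scores have zero variance; cannot standardize")
    return PGSResult(
        scores=(raw - mean) / sd,
        threshold=threshold,
        region_excluded=region_excluded,
        n_variants_used=n_variants_used,
        raw_mean=mean,
        raw_sd=sd,
    )


def build_score_grid(
    stats: SummaryStats,
    geno: GenotypeMatrix,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    mask: RegionMask | None = None,
    match_on: str = "variant_id",
    exclude_palindromic: bool = False,
) -> list[PGSResult]:
    """One standardized score per (pT x {region-in, region-out}) cell.

    With the default six thresholds this yields twelve scores. Region-in
    scores use the full summary statistics (all region variants passing pT
    contribute); region-out scores first excise the mask interval.
    """
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    if mask is None:
        mask = default_apoe_region()
    results: list[PGSResult] = []
    for p_threshold, region_excluded in itertools.product(
        thresholds, (False, True)
    ):
        sub = filter_by_threshold(stats, p_threshold)
        if region_excluded:
            sub = apply_region_mask(sub, mask)
        alignment = align_alleles(
            sub, geno, match_on=match_on, exclude_palindromic=exclude_palindromic
        )
        raw, n_used = compute_score(geno, alignment)
        results.append(standardize(raw, p_threshold, region_excluded, n_used))
        logger.info(
            "score pT=%g region_excluded=%s: %d variants", p_threshold,
            region_excluded, n_used,
        )
    return results


def score_correlation_matrix(results: list[PGSResult]) -> pd.DataFrame:
    """Pairwise Pearson correlations between scores (symmetric, unit diagonal)."""
    if not results:
        raise ValueError("no scores given")
    index0 = results[0].scores.index
    for r in results[1:]:
        if not r.scores.index.equals(index0):
            raise ValidationError("scores computed over different individual sets")
    mat = pd.DataFrame({r.label: r.scores for r in results})
    return mat.corr(method="pearson")


def residualize_on_apoe(
    result: PGSResult, one_e4: pd.Series, two_e4: pd.Series
) -> PGSResult:
    """Regress e4 copy-number indicators out of a score and re-standardize.

    Ordinary-least-squares residuals of the score on intercept + one-copy +
    two-copy indicators isolate the polygenic signal uncorrelated with APOE
    genotype; re-standardization restores the mean-0/SD-1 contract.
    """
    y = result.scores
    x1 = one_e4.reindex(y.index)
    x2 = two_e4.reindex(y.index)
    if x1.isna().any() or x2.isna().any():
        raise ValidationError("e4 indicators missing for some scored individuals")
    X = np.column_stack([np.ones(len(y)), x1.to_numpy(float), x2.to_numpy(float)])
    coef, *_ = np.linalg.lstsq(X, y.to_numpy(float), rcond=None)
    resid = pd.Series(y.to_numpy(float) - X @ coef, index=y.index)
    return standardize(
        resid, result.threshold, result.region_excluded, result.n_variants_used
    )


def write_scores(results: list[PGSResult], path) -> None:
    """Write scores as tab-delimited long format (one row per individual x score)."""
    frames = []
    for r in results:
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": r.scores.index,
                    "score": r.scores.to_numpy(),
                    "pT": r.threshold,
                    "region_excluded": r.region_excluded,
                    "n_variants_used": r.n_variants_used,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
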