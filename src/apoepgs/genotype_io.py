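"""Reading and validating GWAS summary statistics and genotype dosages.

This module defines the pipeline's data model for discovery-GWAS weights
(:class:`SummaryStats`), individual-level dosages (:class:`GenotypeMatrix`)
and genomic exclusion intervals (:class:`RegionMask`), plus the allele
alignment step that orients summary-statistic effect alleles against the
counted allele of the genotype data.

Coordinate convention: all positions are 1-based, both-ends-inclusive,
genome build 37 (hg19). Chromosome labels are normalised by stripping any
``chr`` prefix before comparisons and joins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "GenotypeMatrix",
    "RegionMask",
    "AlignmentReport",
    "Alignment",
    "ConfigurationError",
    "ValidationError",
    "KUNKLE_DIALECT",
    "read_summary_stats",
    "read_dosages",
    "write_dosage_table",
    "align_alleles",
    "load_dialect",
    "normalize_chrom",
]


class ConfigurationError(ValueError):
    """A column mapping or config file is unusable."""


class ValidationError(ValueError):
    """Input data violate an invariant of the data model."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome label."""
    s = str(chrom)
    return s[3:] if s.lower().startswith("chr") else s


# Column mapping for the NIAGADS NG00075 summary-statistics layout
# (canonical field -> column name in the file).
KUNKLE_DIALECT: Mapping[str, str] = {
    "variant_id": "MarkerName",
    "chromosome": "Chromosome",
    "position": "Position",
    "effect_allele": "Effect_allele",
    "other_allele": "Non_Effect_allele",
    "beta": "Beta",
    "p_value": "Pvalue",
}

_REQUIRED_FIELDS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "p_value",
)


@dataclass(frozen=True)
class SummaryStats:
    """Per-variant discovery-GWAS effect-allele weights and p-values.

    ``df`` holds one row per variant with columns ``variant_id``,
    ``chromosome``, ``position``, ``effect_allele``, ``other_allele``,
    ``beta`` and ``p_value``. The beta is the per-effect-allele log-scale
    weight used in polygenic scoring; the p-value controls threshold
    membership.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_FIELDS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"summary stats missing columns: {missing}")
        dups = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dups):
            raise ValidationError(
                f"duplicate variant_id in summary stats: {sorted(set(dups))[:5]}"
            )
        if (self.df["position"] < 1).any():
            raise ValidationError("summary stats contain positions < 1")
        p = self.df["p_value"]
        if ((p <= 0) | (p > 1)).any():
            raise ValidationError("summary stats p-values must lie in (0, 1]")
        same = self.df["effect_allele"] == self.df["other_allele"]
        if same.any():
            bad = self.df.loc[same, "variant_id"].iloc[0]
            raise ValidationError(f"effect and other allele identical for {bad}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> pd.Series:
        return self.df["variant_id"]


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage table with variant annotations.

    ``dosages`` is an ``(n_individuals, n_variants)`` float array of counted
    allele dosages in [0, 2] with ``NaN`` marking missing values.
    ``variants`` carries one row per dosage column: ``variant_id``,
    ``chromosome``, ``position``, ``counted_allele``, ``alt_allele``.
    """

    individual_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValidationError("individual count does not match dosage rows")
        if len(self.variants) != m:
            raise ValidationError("variant annotation count does not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("individual_ids are not unique")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.nansum(bad):
            raise ValidationError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self) -> pd.Series:
        """Map variant_id -> column index."""
        return pd.Series(np.arange(self.n_variants), index=self.variants["variant_id"])

    def subset_variants(self, col_idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(col_idx, dtype=int)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )


@dataclass(frozen=True)
class RegionMask:
    """A 1-based, both-ends-inclusive genomic interval on one chromosome."""

    chromosome: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValidationError(
                f"region start {self.start} exceeds stop {self.stop}"
            )
        if self.start < 1:
            raise ValidationError("region start must be >= 1")

    def contains(self, chromosome, position) -> np.ndarray:
        """Vectorised membership test (inclusive on both ends)."""
        chrom = pd.Series(chromosome).map(normalize_chrom)
        pos = np.asarray(position)
        want = normalize_chrom(self.chromosome)
        return ((chrom == want) & (pos >= self.start) & (pos <= self.stop)).to_numpy()


def load_dialect(path: str | Path) -> Mapping[str, str]:
    """Load a summary-statistics column mapping from a YAML file."""
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"dialect file {path} must contain a mapping")
    return mapping


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> SummaryStats:
    """Read whitespace/tab-delimited GWAS summary statistics.

    ``dialect`` maps canonical field names to the file's column names;
    the default is the NG00075 (Kunkle et al. meta-analysis) layout.
    Rows whose beta or p-value fail to parse, or whose p-value falls
    outside (0, 1], are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary statistics file not found: {path}")
    dialect = dict(dialect or KUNKLE_DIALECT)
    missing = [f for f in _REQUIRED_FIELDS if f not in dialect]
    if missing:
        raise ConfigurationError(f"dialect missing mappings for: {missing}")

    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    absent = [col for col in dialect.values() if col not in raw.columns]
    if absent:
        raise ConfigurationError(
            f"summary statistics file {path} lacks mapped columns: {absent}"
        )

    df = pd.DataFrame(
        {canon: raw[col] for canon, col in dialect.items() if canon in _REQUIRED_FIELDS}
    )
    df["chromosome"] = df["chromosome"].map(normalize_chrom)
    df["position"] = pd.to_numeric(df["position"], errors="coerce")
    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    parseable = (
        df["beta"].notna()
        & df["p_value"].notna()
        & df["position"].notna()
        & (df["p_value"] > 0)
        & (df["p_value"] <= 1)
    )
    n_dropped = int((~parseable).sum())
    if n_dropped:
        logger.info(
            "read_summary_stats: dropped %d of %d rows with unparseable or "
            "out-of-range beta/p-value", n_dropped, len(df),
        )
    df = df[parseable].reset_index(drop=True)
    df["position"] = df["position"].astype(int)
    return SummaryStats(df)


# ---------------------------------------------------------------------------
# Dosage input: VCF and the tabular dosage dialect
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    rows = []
    cols = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} not supported"
            )
        # Prefer a per-sample dosage field; fall back to hard-genotype ALT counts.
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(rec.genotype.array())[:, :2]
            d = (gt == 1).sum(axis=1).astype(float)
            d[(gt < 0).any(axis=1)] = np.nan
        with np.errstate(invalid="ignore"):
            if np.nansum((d < 0) | (d > 2)):
                raise ValidationError(
                    f"dosage outside [0, 2] at {rec.CHROM}:{rec.POS}"
                )
        vid = rec.ID if rec.ID else f"{normalize_chrom(rec.CHROM)}:{rec.POS}"
        rows.append(
            {
                "variant_id": vid,
                "chromosome": normalize_chrom(rec.CHROM),
                "position": int(rec.POS),
                "counted_allele": rec.ALT[0],
                "alt_allele": rec.REF,
            }
        )
        cols.append(d)
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chromosome", "position", "counted_allele", "alt_allele"]
    )
    dos = np.column_stack(cols) if cols else np.empty((len(individual_ids), 0))
    return GenotypeMatrix(individual_ids, variants, dos)


def _read_dosage_table(path: Path, variant_info: str | Path | None) -> GenotypeMatrix:
    df = pd.read_csv(
        path, sep="\t", dtype={"individual_id": str}, na_values=["NA"],
        keep_default_na=False, float_precision="round_trip",
    )
    if df.columns[0] != "individual_id":
        raise ValidationError(
            f"dosage table {path} must start with an 'individual_id' column"
        )
    individual_ids = df["individual_id"].astype(str).tolist()
    variant_ids = list(df.columns[1:])
    dosages = df[variant_ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (dosages < 0) | (dosages > 2)
    if np.nansum(bad):
        i, j = np.argwhere(np.nan_to_num(bad))[0]
        raise ValidationError(
            f"dosage table {path}: value {dosages[i, j]} outside [0, 2] "
            f"(individual {individual_ids[i]}, variant {variant_ids[j]})"
        )
    if variant_info is not None:
        info = pd.read_csv(variant_info, sep="\t", dtype=str)
        info["position"] = pd.to_numeric(info["position"]).astype(int)
        info["chromosome"] = info["chromosome"].map(normalize_chrom)
        info = info.set_index("variant_id").reindex(variant_ids).reset_index()
        if info["chromosome"].isna().any():
            missing = info.loc[info["chromosome"].isna(), "variant_id"].tolist()
            raise ValidationError(f"variant_info lacks annotations for: {missing[:5]}")
        variants = info[
            ["variant_id", "chromosome", "position", "counted_allele", "alt_allele"]
        ]
    else:
        variants = pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chromosome": "",
                "position": 0,
                "counted_allele": "",
                "alt_allele": "",
            }
        )
    return GenotypeMatrix(individual_ids, variants.reset_index(drop=True), dosages)


def read_dosages(
    path: str | Path,
    format: str = "vcf",
    variant_info: str | Path | None = None,
) -> GenotypeMatrix:
    """Read genotype dosages from a VCF or the tabular dosage dialect.

    For VCF input the counted allele is the ALT allele; a per-sample ``DS``
    dosage field is used when present, otherwise hard genotypes are
    converted to ALT-allele counts. The tabular dialect is a tab-delimited
    file with header ``individual_id`` followed by variant IDs, one row per
    individual, missing values written ``NA``; variant annotations come from
    an optional companion table (``variant_info``).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"dosage file not found: {path}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-table":
        return _read_dosage_table(path, variant_info)
    raise ConfigurationError(f"unknown dosage format: {format!r}")


def write_dosage_table(
    geno: GenotypeMatrix,
    path: str | Path,
    variant_info_path: str | Path | None = None,
) -> None:
    """Write a GenotypeMatrix in the tabular dosage dialect (lossless)."""
    df = pd.DataFrame(geno.dosages, columns=geno.variants["variant_id"].tolist())
    df.insert(0, "individual_id", geno.individual_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    if variant_info_path is not None:
        geno.variants.to_csv(variant_info_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele alignment
# ---------------------------------------------------------------------------

_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass
class AlignmentReport:
    """Accounting of the summary-stats / genotype variant intersection."""

    n_shared: int = 0
    n_direct: int = 0
    n_flipped: int = 0
    n_excluded: int = 0
    n_palindromic: int = 0

    def as_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "n_direct": self.n_direct,
            "n_flipped": self.n_flipped,
            "n_excluded": self.n_excluded,
            "n_palindromic": self.n_palindromic,
        }


@dataclass
class Alignment:
    """Effect-allele weights oriented to the genotype counted allele.

    ``column_indices[k]`` is the genotype column for ``variant_ids[k]``;
    ``weights[k]`` is the summary-stats beta, sign-flipped where the
    counted allele is the GWAS other allele.
    """

    variant_ids: list[str]
    column_indices: np.ndarray
    weights: np.ndarray
    report: AlignmentReport = field(default_factory=AlignmentReport)

    def __len__(self) -> int:
        return len(self.weights)


def align_alleles(
    stats: SummaryStats,
    geno: GenotypeMatrix,
    match_on: str = "variant_id",
    exclude_palindromic: bool = False,
) -> Alignment:
    """Orient GWAS effect alleles to the genotype counted alleles.

    For every variant present in both inputs: if the genotype's counted
    allele equals the GWAS effect allele the weight is ``beta``; if it
    equals the other allele the weight is ``-beta`` (equivalent to counting
    the opposite allele); if the allele pairs match in neither orientation
    the variant is excluded and counted in the report. Strand-ambiguous
    (A/T, C/G) variants are aligned by allele identity like any other
    variant but counted, and optionally excluded, via
    ``exclude_palindromic``.

    ``match_on`` is ``"variant_id"`` (rs-ID join, the default) or
    ``"position"`` (chromosome:position join fallback).
    """
    sdf = stats.df
    gvar = geno.variants.copy()
    gvar["gcol"] = np.arange(len(gvar))
    if match_on == "variant_id":
        merged = sdf.merge(gvar, on="variant_id", suffixes=("", "_g"))
    elif match_on == "position":
        key_s = sdf.assign(chromosome=sdf["chromosome"].map(normalize_chrom))
        key_g = gvar.assign(chromosome=gvar["chromosome"].map(normalize_chrom))
        merged = key_s.merge(
            key_g, on=["chromosome", "position"], suffixes=("", "_g")
        )
    else:
        raise ConfigurationError(f"unknown match_on: {match_on!r}")

    report = AlignmentReport(n_shared=len(merged))
    ids: list[str] = []
    cols: list[int] = []
    weights: list[float] = []
    for row in merged.itertuples(index=False):
        eff, oth = row.effect_allele, row.other_allele
        counted, alt = str(row.counted_allele).upper(), str(row.alt_allele).upper()
        pal = frozenset({eff, oth}) in _PALINDROMIC
        if pal:
            report.n_palindromic += 1
            if exclude_palindromic:
                report.n_excluded += 1
                continue
        # empty alt annotation (bare dosage table) matches any other allele
        if counted == eff and (alt in ("", "NAN") or alt == oth):
            report.n_direct += 1
            w = row.beta
        elif counted == oth and (alt in ("", "NAN") or alt == eff):
            report.n_flipped += 1
            w = -row.beta
        else:
            report.n_excluded += 1
            continue
        ids.append(row.variant_id)
        cols.append(int(row.gcol))
        weights.append(float(w))
    return Alignment(
        variant_ids=ids,
        column_indices=np.asarray(cols, dtype=int),
        weights=np.asarray(weights, dtype=float),
        report=report,
    )
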