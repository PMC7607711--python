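"""Langa-Weir cognitive-status classification and analytic-panel assembly.

HRS-style cognition scores are mapped to three classes with separate cut
points for self- and proxy-respondents:

* self-respondents (0-27 scale): 0-6 dementia, 7-11 cognitively impaired
  non-dementia (CIND), 12-27 normal;
* proxy respondents (0-11 scale): 6-11 dementia, 3-5 CIND, 0-2 normal.

The analytic panel contrasts dementia against normal cognition only, so
observations with missing cognition, CIND classifications, and missing
stroke status are excluded (in that order), then individuals left with no
observations are removed. Respondent type may change across waves;
classification always uses the wave's own respondent type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES",
    "SELF_RANGE",
    "PROXY_RANGE",
    "ExclusionReport",
    "classify",
    "classify_frame",
    "build_panel",
    "cohort_filter",
    "descriptive_table",
    "DEFAULT_COLUMNS",
]

CLASSES = ("dementia", "CIND", "normal")
SELF_RANGE = (0, 27)
PROXY_RANGE = (0, 11)

# (respondent_type) -> list of (lo, hi, class), bands closed on both ends
_CUTPOINTS = {
    "self": [(0, 6, "dementia"), (7, 11, "CIND"), (12, 27, "normal")],
    "proxy": [(6, 11, "dementia"), (3, 5, "CIND"), (0, 2, "normal")],
}

#: Default column names of the long-format phenotype table.
DEFAULT_COLUMNS = {
    "individual_id": "individual_id",
    "wave_year": "wave_year",
    "cognition_score": "cognition_score",
    "respondent_type": "respondent_type",
    "age": "age",
    "sex": "sex",
    "education": "education",
    "birth_cohort": "birth_cohort",
    "stroke": "stroke",
    "pcs": ["pc1", "pc2", "pc3", "pc4", "pc5"],
}


def classify(score: int, respondent_type: str) -> str:
    """Map one cognition score to dementia / CIND / normal."""
    if respondent_type not in _CUTPOINTS:
        raise ValidationError(f"unknown respondent_type: {respondent_type!r}")
    lo, hi = SELF_RANGE if respondent_type == "self" else PROXY_RANGE
    if not (isinstance(score, (int, np.integer)) and lo <= score <= hi):
        raise ValidationError(
            f"score {score!r} outside the {respondent_type} range [{lo}, {hi}]"
        )
    for band_lo, band_hi, cls in _CUTPOINTS[respondent_type]:
        if band_lo <= score <= band_hi:
            return cls
    raise AssertionError("cut points do not cover the score range")  # pragma: no cover


def classify_frame(
    scores: pd.Series, respondent_types: pd.Series
) -> pd.Series:
    """Vectorised classification; missing scores classify as 'missing'."""
    out = pd.Series("missing", index=scores.index, dtype=object)
    present = scores.notna()
    for rtype in ("self", "proxy"):
        sel = present & (respondent_types == rtype)
        if not sel.any():
            continue
        vals = scores[sel].astype(int)
        lo, hi = SELF_RANGE if rtype == "self" else PROXY_RANGE
        if ((vals < lo) | (vals > hi)).any():
            bad = vals[(vals < lo) | (vals > hi)].iloc[0]
            raise ValidationError(
                f"score {bad} outside the {rtype} range [{lo}, {hi}]"
            )
        cls = pd.Series("", index=vals.index, dtype=object)
        for band_lo, band_hi, c in _CUTPOINTS[rtype]:
            cls[(vals >= band_lo) & (vals <= band_hi)] = c
        out[sel] = cls
    unknown = present & ~respondent_types.isin(["self", "proxy"])
    if unknown.any():
        raise ValidationError(
            f"unknown respondent_type values: {sorted(respondent_types[unknown].unique())}"
        )
    return out


@dataclass
class ExclusionReport:
    """Observation- and individual-level exclusion accounting."""

    n_input_observations: int = 0
    n_missing_cognition: int = 0
    n_cind: int = 0
    n_missing_stroke: int = 0
    n_retained_observations: int = 0
    n_input_individuals: int = 0
    n_individuals_removed: int = 0
    n_retained_individuals: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_panel(
    pheno: pd.DataFrame,
    columns: dict | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Assemble the dementia-vs-normal analytic panel.

    Exclusions are applied observation-level first, in order: missing
    cognition, CIND classification, missing stroke status; individuals
    with zero remaining observations are then dropped. The returned panel
    has one row per retained individual-wave with a binary ``dementia``
    column (1 = dementia, 0 = normal cognition) and all covariates passed
    through; the report tallies each exclusion step.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    iid, wave = cols["individual_id"], cols["wave_year"]
    df = pheno.copy()
    if df.duplicated(subset=[iid, wave]).any():
        dup = df[df.duplicated(subset=[iid, wave])].iloc[0]
        raise ValidationError(
            f"duplicate individual-wave row: {dup[iid]} / {dup[wave]}"
        )
    report = ExclusionReport(
        n_input_observations=len(df),
        n_input_individuals=df[iid].nunique(),
    )
    df["cognition_class"] = classify_frame(
        df[cols["cognition_score"]], df[cols["respondent_type"]]
    )

    missing_cog = df["cognition_class"] == "missing"
    report.n_missing_cognition = int(missing_cog.sum())
    df = df[~missing_cog]

    cind = df["cognition_class"] == "CIND"
    report.n_cind = int(cind.sum())
    df = df[~cind]

    missing_stroke = df[cols["stroke"]].isna()
    report.n_missing_stroke = int(missing_stroke.sum())
    df = df[~missing_stroke]

    report.n_retained_observations = len(df)
    report.n_retained_individuals = df[iid].nunique()
    report.n_individuals_removed = (
        report.n_input_individuals - report.n_retained_individuals
    )

    panel = df.copy()
    panel["dementia"] = (panel["cognition_class"] == "dementia").astype(int)
    panel = panel.sort_values([iid, wave]).reset_index(drop=True)
    logger.info(
        "build_panel: retained %d/%d observations (%d missing cognition, "
        "%d CIND, %d missing stroke); removed %d individuals",
        report.n_retained_observations, report.n_input_observations,
        report.n_missing_cognition, report.n_cind, report.n_missing_stroke,
        report.n_individuals_removed,
    )
    return panel, report


def cohort_filter(
    panel: pd.DataFrame,
    excluded_cohorts: set[str],
    cohort_col: str = "birth_cohort",
) -> pd.DataFrame:
    """Drop rows belonging to the listed birth cohorts.

    Used for the mortality-selection sensitivity analysis that removes the
    two oldest cohorts. Unknown cohort labels warn rather than fail.
    """
    present = set(panel[cohort_col].unique())
    unknown = set(excluded_cohorts) - present
    if unknown:
        logger.warning("cohort_filter: cohorts not present in panel: %s",
                       sorted(unknown))
    keep = ~panel[cohort_col].isin(excluded_cohorts)
    out = panel[keep].reset_index(drop=True)
    logger.info("cohort_filter: removed %d rows (%d individuals)",
                len(panel) - len(out),
                panel["individual_id"].nunique() - out["individual_id"].nunique())
    return out


def _mean_sd(x: pd.Series) -> str:
    if len(x) == 0:
        return "-"
    return f"{x.mean():.1f} ({x.std(ddof=1):.1f})"


def _n_pct(flag: pd.Series) -> str:
    if len(flag) == 0:
        return "0 (-)"
    n = int(flag.sum())
    return f"{n} ({100 * n / len(flag):.1f})"


def descriptive_table(
    panel: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    apoe_calls: pd.DataFrame | None = None,
    sex_col: str = "sex",
) -> dict[str, pd.DataFrame]:
    """Individual- and observation-level descriptive summaries by sex.

    Individual-level rows use each individual's first retained visit
    (earliest wave in the panel) for age, stroke and dementia status.
    ``scores`` (long format: individual_id, score, pT, region_excluded) and
    ``apoe_calls`` add per-stratum score means and e4 copy-number counts.
    Returns ``{"individuals": ..., "observations": ...}``.
    """
    if panel.empty:
        raise ValidationError("cannot describe an empty panel")
    first = (
        panel.sort_values(["individual_id", "wave_year"])
        .groupby("individual_id", as_index=False)
        .first()
    )
    visits = panel.groupby("individual_id").size()

    def strata(df: pd.DataFrame):
        return {
            "Male": df[df[sex_col] == 1],
            "Female": df[df[sex_col] == 0],
            "Overall": df,
        }

    ind_rows: dict[str, dict] = {}
    for name, sub in strata(first).items():
        row = {
            "n": len(sub),
            "visits": _mean_sd(visits.loc[sub["individual_id"]]),
            "dementia_first_visit": _n_pct(sub["dementia"]),
            "age_first_visit": _mean_sd(sub["age"]),
            "education": _mean_sd(sub["education"]),
            "stroke_first_visit": _n_pct(sub["stroke"]),
        }
        if "birth_cohort" in sub:
            for cohort, cnt in sub["birth_cohort"].value_counts().items():
                row[f"cohort_{cohort}"] = f"{cnt} ({100 * cnt / len(sub):.1f})"
        if apoe_calls is not None:
            calls = apoe_calls.set_index("individual_id").reindex(sub["individual_id"])
            for k, label in ((0, "no_e4"), (1, "one_e4"), (2, "two_e4")):
                row[label] = _n_pct(calls["e4_count"] == k)
        if scores is not None:
            for (p_threshold, region_excluded), grp in scores.groupby(
                ["pT", "region_excluded"]
            ):
                s = grp.set_index("individual_id")["score"].reindex(sub["individual_id"])
                tag = "noAPOE" if region_excluded else "withAPOE"
                row[f"pgs_pT{p_threshold:g}_{tag}"] = f"{s.mean():.2f} ({s.std(ddof=1):.1f})"
        ind_rows[name] = row

    obs_rows: dict[str, dict] = {}
    for name, sub in strata(panel).items():
        row = {
            "m": len(sub),
            "dementia": _n_pct(sub["dementia"]),
            "age": _mean_sd(sub["age"]),
            "stroke": _n_pct(sub["stroke"]),
        }
        for year, cnt in sub["wave_year"].value_counts().sort_index().items():
            row[f"year_{year}"] = f"{cnt} ({100 * cnt / len(sub):.1f})"
        obs_rows[name] = row

    return {
        "individuals": pd.DataFrame(ind_rows),
        "observations": pd.DataFrame(obs_rows),
    }
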