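"""Repeated-measures logistic models of dementia via GEE.

The association models are marginal logistic regressions of the binary
dementia indicator on a polygenic score, APOE-e4 copy-number indicators
and covariates, fitted by generalized estimating equations (binomial
family, logit link) with repeated measures on the individual. The default
working correlation is unstructured (one free parameter per wave pair,
indexed by within-subject wave rank); non-convergence triggers an
automatic refit with an exchangeable structure, flagged in the result.
Standard errors are robust (sandwich) throughout, and coefficients are
exponentiated to odds ratios with normal-theory 95% intervals,
exp(logOR +/- 1.96 * robust SE).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotype_io import ValidationError
from .score import PGSResult, residualize_on_apoe

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelResult",
    "SeparationError",
    "BASE_COVARIATES",
    "fit_gee",
    "run_model_grid",
    "run_interaction_model",
    "run_sensitivity_suite",
    "results_to_table",
]

#: Covariates entering every association model (plus e4 indicators and PGS).
BASE_COVARIATES = (
    "age", "sex", "education", "year_c", "stroke",
    "pc1", "pc2", "pc3", "pc4", "pc5",
)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """The logistic fit diverged, consistent with (quasi-)separation."""


@dataclass
class ModelSpec:
    """Declarative description of one GEE model.

    ``terms`` are column names; interaction pairs are written ``"a:b"``.
    ``correlation_structure`` is one of unstructured, exchangeable,
    independence. Subjects are identified by ``subject_id`` and ordered
    within subject by ``time_order`` (wave rank is derived from it).
    """

    outcome: str
    terms: tuple[str, ...]
    correlation_structure: str = "unstructured"
    subject_id: str = "individual_id"
    time_order: str = "wave_year"

    def validate(self, panel: pd.DataFrame) -> None:
        needed = {self.outcome, self.subject_id, self.time_order}
        for t in self.terms:
            needed.update(t.split(":"))
        missing = sorted(needed - set(panel.columns))
        if missing:
            raise ValidationError(f"model terms reference absent columns: {missing}")
        if self.correlation_structure not in (
            "unstructured", "exchangeable", "independence"
        ):
            raise ValidationError(
                f"unknown correlation structure: {self.correlation_structure!r}"
            )


@dataclass
class ModelResult:
    """Per-term odds ratios with robust inference for one fitted model.

    ``table`` has one row per model term: odds_ratio, robust_se (log-odds
    scale), se_exp (the exponentiated-scale multiplicative SE,
    exp(robust_se), as some software prints), ci_low, ci_high, p_value.
    """

    table: pd.DataFrame
    n_individuals: int
    n_observations: int
    converged: bool
    structure_used: str
    meta: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _design_matrix(panel: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    X = pd.DataFrame(index=panel.index)
    X["Intercept"] = 1.0
    for t in spec.terms:
        parts = t.split(":")
        col = panel[parts[0]].astype(float)
        for p in parts[1:]:
            col = col * panel[p].astype(float)
        X[t] = col
    return X


def _make_cov_struct(name: str):
    return {
        "unstructured": sm.cov_struct.Unstructured,
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }[name]()


def fit_gee(panel: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit one marginal logistic GEE model.

    Solves the estimating equations for logit-link binomial marginal means
    under the specified working correlation, with robust (sandwich)
    standard errors. Unstructured correlation indexes wave pairs by each
    subject's wave rank, so unequal visit counts are handled. If the
    unstructured fit fails to converge the model is refitted with an
    exchangeable structure and ``structure_used`` records the fallback.
    """
    spec.validate(panel)
    df = panel.sort_values([spec.subject_id, spec.time_order]).reset_index(drop=True)
    y = df[spec.outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError(f"outcome {spec.outcome!r} is not binary 0/1")
    if df[spec.subject_id].nunique() < 2:
        raise ValidationError("GEE requires at least 2 subjects")
    X = _design_matrix(df, spec)
    groups = df[spec.subject_id].to_numpy()
    time = df.groupby(spec.subject_id)[spec.time_order].rank(method="dense")
    time = (time - 1).astype(int).to_numpy()

    def _attempt(structure: str):
        model = sm.GEE(
            y.to_numpy(),
            X.to_numpy(),
            groups=groups,
            time=time,
            family=sm.families.Binomial(),
            cov_struct=_make_cov_struct(structure),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, cov_type="robust")
        return res

    structure_used = spec.correlation_structure
    try:
        res = _attempt(structure_used)
        converged = bool(getattr(res, "converged", True))
        if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
            raise RuntimeError("non-finite estimates")
    except Exception as exc:  # noqa: BLE001 - any solver failure triggers fallback
        if structure_used != "unstructured":
            raise
        logger.warning("unstructured GEE failed (%s); refitting exchangeable", exc)
        structure_used = "exchangeable"
        res = _attempt(structure_used)
        converged = bool(getattr(res, "converged", True))
    if not converged and structure_used == "unstructured":
        logger.warning("unstructured GEE did not converge; refitting exchangeable")
        structure_used = "exchangeable"
        res = _attempt(structure_used)
        converged = bool(getattr(res, "converged", True))

    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if np.any(np.abs(params) > 15):
        raise SeparationError(
            "implausibly large coefficients; data are likely separated"
        )
    names = list(X.columns)
    table = pd.DataFrame(
        {
            "odds_ratio": np.exp(params),
            "robust_se": bse,
            "se_exp": np.exp(bse),
            "ci_low": np.exp(params - _Z95 * bse),
            "ci_high": np.exp(params + _Z95 * bse),
            "p_value": np.asarray(res.pvalues, dtype=float),
            "log_or": params,
        },
        index=pd.Index(names, name="term"),
    )
    return ModelResult(
        table=table,
        n_individuals=int(df[spec.subject_id].nunique()),
        n_observations=len(df),
        converged=converged,
        structure_used=structure_used,
    )


def _join_scores(panel: pd.DataFrame, score: PGSResult,
                 subject_id: str = "individual_id") -> pd.DataFrame:
    df = panel.copy()
    df["pgs"] = df[subject_id].map(score.scores)
    if df["pgs"].isna().any():
        missing = df.loc[df["pgs"].isna(), subject_id].nunique()
        raise ValidationError(f"{missing} panel individuals lack a score")
    return df


def _join_apoe(panel: pd.DataFrame, apoe_calls: pd.DataFrame,
               subject_id: str = "individual_id") -> pd.DataFrame:
    ok = apoe_calls[apoe_calls["call_flag"] == "ok"].set_index("individual_id")
    df = panel.copy()
    for col in ("one_e4", "two_e4"):
        df[col] = df[subject_id].map(ok[col])
    if df[["one_e4", "two_e4"]].isna().any().any():
        missing = df.loc[df["one_e4"].isna(), subject_id].nunique()
        raise ValidationError(f"{missing} panel individuals lack an APOE call")
    return df


def run_model_grid(
    panel: pd.DataFrame,
    scores: list[PGSResult],
    apoe_calls: pd.DataFrame,
    covariates: tuple[str, ...] = BASE_COVARIATES,
    structure: str = "unstructured",
    adjust_apoe: bool = True,
) -> dict[tuple[float, bool], ModelResult]:
    """Fit the full (pT x region flag) grid of association models.

    Each model regresses dementia on the covariates, the two e4 indicators
    (unless ``adjust_apoe`` is off) and one standardized PGS. Keys of the
    returned dict are ``(pT, region_excluded)``.
    """
    base = _join_apoe(panel, apoe_calls) if adjust_apoe else panel
    apoe_terms = ("one_e4", "two_e4") if adjust_apoe else ()
    out: dict[tuple[float, bool], ModelResult] = {}
    for score in scores:
        df = _join_scores(base, score)
        spec = ModelSpec(
            outcome="dementia",
            terms=tuple(covariates) + apoe_terms + ("pgs",),
            correlation_structure=structure,
        )
        res = fit_gee(df, spec)
        res.meta = {"pT": score.threshold, "region_excluded": score.region_excluded}
        out[(score.threshold, score.region_excluded)] = res
    return out


def run_e4_only_model(
    panel: pd.DataFrame,
    apoe_calls: pd.DataFrame,
    covariates: tuple[str, ...] = BASE_COVARIATES,
    structure: str = "unstructured",
) -> ModelResult:
    """Dementia on e4 indicators and covariates, with no PGS term."""
    df = _join_apoe(panel, apoe_calls)
    spec = ModelSpec(
        outcome="dementia",
        terms=tuple(covariates) + ("one_e4", "two_e4"),
        correlation_structure=structure,
    )
    res = fit_gee(df, spec)
    res.meta = {"model": "e4_only"}
    return res


def run_interaction_model(
    panel: pd.DataFrame,
    score: PGSResult,
    apoe_calls: pd.DataFrame,
    covariates: tuple[str, ...] = BASE_COVARIATES,
    structure: str = "unstructured",
) -> ModelResult:
    """Main-effects model plus PGS x e4 copy-number product terms."""
    df = _join_scores(_join_apoe(panel, apoe_calls), score)
    spec = ModelSpec(
        outcome="dementia",
        terms=tuple(covariates)
        + ("one_e4", "two_e4", "pgs", "pgs:one_e4", "pgs:two_e4"),
        correlation_structure=structure,
    )
    res = fit_gee(df, spec)
    res.meta = {
        "model": "interaction",
        "pT": score.threshold,
        "region_excluded": score.region_excluded,
    }
    return res


def run_sensitivity_suite(
    panel: pd.DataFrame,
    scores: list[PGSResult],
    apoe_calls: pd.DataFrame,
    excluded_cohorts: set[str] = frozenset({"AHEAD", "CODA"}),
    covariates: tuple[str, ...] = BASE_COVARIATES,
    structure: str = "unstructured",
) -> dict[str, dict | ModelResult]:
    """The four sensitivity analyses around the primary model grid.

    (a) refit of the grid after dropping the oldest birth cohorts;
    (b) the grid with e4-residualized scores (scores are re-standardized
    over the panel's individuals after residualization); (c) PGS-only
    models without e4 adjustment; (d) an e4-only model without a PGS.
    """
    from .cognition import cohort_filter

    out: dict[str, dict | ModelResult] = {}

    reduced = cohort_filter(panel, excluded_cohorts)
    out["cohort_excluded"] = run_model_grid(
        reduced, scores, apoe_calls, covariates=covariates, structure=structure
    )

    ok = apoe_calls[apoe_calls["call_flag"] == "ok"].set_index("individual_id")
    resid_scores = [
        residualize_on_apoe(s, ok["one_e4"], ok["two_e4"]) for s in scores
    ]
    out["residualized"] = run_model_grid(
        panel, resid_scores, apoe_calls, covariates=covariates, structure=structure
    )

    out["pgs_only"] = run_model_grid(
        panel, scores, apoe_calls, covariates=covariates, structure=structure,
        adjust_apoe=False,
    )
    out["e4_only"] = run_e4_only_model(
        panel, apoe_calls, covariates=covariates, structure=structure
    )
    return out


def results_to_table(results: dict[tuple[float, bool], ModelResult]) -> pd.DataFrame:
    """Flatten a model grid to a tab-delimitable long table."""
    frames = []
    for (p_threshold, region_excluded), res in results.items():
        t = res.table.reset_index()
        t.insert(0, "region_excluded", region_excluded)
        t.insert(0, "pT", p_threshold)
        t["n_individuals"] = res.n_individuals
        t["n_observations"] = res.n_observations
        t["structure_used"] = res.structure_used
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
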