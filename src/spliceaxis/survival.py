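"""Survival analysis of AS events and composite risk modeling.

Events are dichotomized at their mean PSI ('<mean' vs '>mean'); prognosis
is assessed by Kaplan-Meier curves with the logrank test and by Cox
proportional-hazards regression (Efron tie handling, Harrell's C-index on
the linear predictor).  A composite risk model screens the top-variance
expressed events, dichotomizes them, and selects predictors by backward
elimination together with the standard clinical covariates (ISS, 1q
gain/amp, del(17p), t(14;16), t(4;14), TP53 loss of function, Double-Hit).
Unfavorable-marker accumulation stratifies patients into low (0-2),
medium (3-4) and high (>=5 markers) risk tiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index

from .events import PsiMatrix
from .io import SampleAnnotation, SpliceaxisError, annotation_frame

logger = logging.getLogger(__name__)

#: clinical covariates entering multivariate models (flag / derived columns)
CLINICAL_COVARIATES = (
    "iss_stage",
    "gain_or_amp_1q",
    "del17p",
    "t_14_16",
    "t_4_14",
    "tp53_lof",
    "double_hit",
)


class SurvivalError(SpliceaxisError):
    pass


@dataclass
class RiskModel:
    endpoint: str
    candidates: list[str]
    summary: pd.DataFrame  # final predictors: hr, ci_low, ci_high, p
    c_index: float
    unfavorable_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.unfavorable_markers = [
            m for m in self.summary.index if self.summary.loc[m, "hr"] > 1.0
        ]


def survival_frame(
    annotations: Sequence[SampleAnnotation], endpoint: str = "PFS"
) -> pd.DataFrame:
    """duration/event columns for one endpoint, tumor samples with data."""
    if endpoint not in ("PFS", "OS"):
        raise SurvivalError(f"unknown endpoint {endpoint!r}")
    df = annotation_frame(annotations)
    prefix = endpoint.lower()
    out = pd.DataFrame(
        {
            "duration": df[f"{prefix}_days"].astype(float),
            "event": df[f"{prefix}_event"].astype(float),
        }
    )
    out = out[(df["cohort"] == "tumor") & out["duration"].notna()]
    out["event"] = out["event"].astype(int)
    return out


def clinical_design(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """The standard high-risk clinical covariates as a numeric design."""
    df = annotation_frame(annotations)
    df = df[df["cohort"] == "tumor"]
    design = pd.DataFrame(index=df.index)
    design["iss_stage"] = df["iss_stage"].astype(float)
    design["gain_or_amp_1q"] = (df["gain1q"] | df["amp1q"]).astype(float)
    design["del17p"] = df["del17p"].astype(float)
    design["t_14_16"] = df["t_14_16"].astype(float)
    design["t_4_14"] = df["t_4_14"].astype(float)
    design["tp53_lof"] = (df["mut_TP53"] | df["biallelic_TP53"]).astype(float)
    design["double_hit"] = df["double_hit"].astype(float)
    return design


def dichotomize_mean_psi(psi_row: pd.Series) -> pd.Series | None:
    """'below'/'above' labels split at the mean PSI (ties go above).

    Missing PSI is excluded.  Returns None (caller should skip the event)
    when either side is empty, e.g. for constant PSI.
    """
    values = psi_row.dropna()
    if len(values) < 2:
        return None
    mean = values.mean()
    labels = pd.Series(
        np.where(values < mean, "below", "above"), index=values.index
    )
    if labels.nunique() < 2:
        logger.info("dichotomize_mean_psi: degenerate split, event skipped")
        return None
    return labels


def km_logrank(
    groups: pd.Series, survival: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group and the k-sample logrank test.

    Returns (curves, chi-square statistic with k-1 df, p-value).
    """
    common = groups.index.intersection(survival.index)
    groups = groups[common]
    surv = survival.loc[common]
    if groups.nunique() < 2:
        raise SurvivalError("km_logrank: need >= 2 groups")
    if surv["event"].sum() < 1:
        raise SurvivalError("km_logrank: no events observed")
    curves = {}
    for label in sorted(groups.unique()):
        ids = groups.index[groups == label]
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[ids, "duration"], surv.loc[ids, "event"], label=str(label))
        curves[str(label)] = kmf.survival_function_
    res = multivariate_logrank_test(
        surv["duration"], groups.astype(str), surv["event"]
    )
    return curves, float(res.test_statistic), float(res.p_value)


def median_survival(groups: pd.Series, survival: pd.DataFrame) -> dict[str, float]:
    """KM median survival time per group (NaN if not reached)."""
    out = {}
    common = groups.index.intersection(survival.index)
    for label in sorted(groups[common].unique()):
        ids = groups[common].index[groups[common] == label]
        kmf = KaplanMeierFitter()
        kmf.fit(survival.loc[ids, "duration"], survival.loc[ids, "event"])
        out[str(label)] = float(kmf.median_survival_time_)
    return out


def cox_fit(
    design: pd.DataFrame, survival: pd.DataFrame, robust: bool = False
) -> tuple[pd.DataFrame, float]:
    """Cox proportional-hazards fit (Efron ties).

    Returns (summary with hr / ci_low / ci_high / p per covariate,
    Harrell's C-index of the linear predictor).
    """
    common = design.index.intersection(survival.index)
    design = design.loc[common]
    surv = survival.loc[common]
    for col in design.columns:
        if design[col].nunique() <= 1:
            raise SurvivalError(f"cox_fit: constant covariate {col!r}")
    if design.shape[1] >= 2:
        corr = design.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if (corr > 0.9999).any().any():
            pair = corr.stack().idxmax()
            warnings.warn(f"cox_fit: collinear covariates {pair}", stacklevel=2)
    n_events = int(surv["event"].sum())
    if n_events < 5 * design.shape[1]:
        warnings.warn(
            f"cox_fit: only {n_events} events for {design.shape[1]} covariates",
            stacklevel=2,
        )
    frame = design.join(surv)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="duration", event_col="event", robust=robust)
    summary = pd.DataFrame(
        {
            "hr": np.exp(cph.params_),
            "ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0]),
            "ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1]),
            "p": cph.summary["p"],
        }
    )
    lp = cph.predict_partial_hazard(frame)
    c_index = concordance_index(surv["duration"], -lp, surv["event"])
    return summary, float(c_index)


def expressed_top_variance_events(
    psi: PsiMatrix,
    event_tpm: pd.DataFrame,
    top_k: int = 200,
    tpm_min: float = 1.0,
    expressed_fraction: float = 0.5,
) -> list[str]:
    """Top-variance events among those expressed in >= half the samples."""
    expressed = (event_tpm.loc[psi.data.index] > tpm_min).mean(axis=1) >= expressed_fraction
    pool = psi.data.loc[expressed[expressed].index]
    variances = pool.var(axis=1, ddof=1).fillna(0.0)
    order = variances.sort_values(ascending=False, kind="stable")
    return list(order.index[:top_k])


def candidate_design(
    psi: PsiMatrix,
    event_ids: Sequence[str],
    annotations: Sequence[SampleAnnotation],
    include_clinical: bool = True,
) -> pd.DataFrame:
    """Dichotomized event indicators ('<mean' = 1) plus clinical covariates."""
    clinical = clinical_design(annotations)
    design = pd.DataFrame(index=clinical.index)
    for eid in event_ids:
        labels = dichotomize_mean_psi(psi.data.loc[eid])
        if labels is None:
            continue
        col = (labels == "below").astype(float).reindex(design.index)
        design[eid] = col.fillna(col.mean())
    if include_clinical:
        design = design.join(clinical)
    return design


def backward_eliminate(
    design: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
    prescreen_alpha: float | None = 0.2,
    endpoint: str = "PFS",
) -> RiskModel:
    """Backward elimination over all candidates (clinical included).

    A univariate Cox pre-screen at ``prescreen_alpha`` (disable with None)
    guards against fitting more covariates than the events can support; the
    pool is additionally capped at n/3 candidates by ascending univariate
    p.  Then the full model is iteratively refit, dropping the largest Wald
    p >= alpha until all remaining predictors are significant.
    """
    if design.shape[1] == 0:
        raise SurvivalError("backward_eliminate: empty candidate list")
    common = design.index.intersection(survival.index)
    design = design.loc[common]
    surv = survival.loc[common]
    design = design.loc[:, design.nunique() > 1]
    candidates = list(design.columns)

    uni_p = {}
    for col in candidates:
        try:
            summary, _ = cox_fit(design[[col]], surv)
            uni_p[col] = float(summary["p"].iloc[0])
        except Exception:  # numerically degenerate candidate
            uni_p[col] = 1.0
    pool = sorted(candidates, key=lambda c: (uni_p[c], c))
    if prescreen_alpha is not None:
        pool = [c for c in pool if uni_p[c] < prescreen_alpha]
    cap = max(1, len(common) // 3)
    pool = pool[:cap]

    empty = pd.DataFrame(columns=["hr", "ci_low", "ci_high", "p"])
    if not pool:
        # nothing passes the pre-screen: an empty model is a valid outcome
        logger.info("backward_eliminate[%s]: no candidate survives pre-screen", endpoint)
        return RiskModel(endpoint=endpoint, candidates=candidates, summary=empty, c_index=0.5)

    current = list(pool)
    summary, c_index = cox_fit(design[current], surv)
    while True:
        worst = summary["p"].idxmax()
        if summary.loc[worst, "p"] < alpha or len(current) == 1:
            break
        current.remove(worst)
        with warnings.catch_warnings():
            # the events-per-covariate warning already fired on the full fit
            warnings.filterwarnings("ignore", message="cox_fit: only")
            summary, c_index = cox_fit(design[current], surv)
    if len(current) == 1 and summary["p"].max() >= alpha:
        # nothing significant at all: empty final model
        summary = empty
        current = []
        c_index = 0.5
    logger.info(
        "backward_eliminate[%s]: %d candidates -> %d predictors (C=%.3f)",
        endpoint,
        len(candidates),
        len(current),
        c_index,
    )
    return RiskModel(
        endpoint=endpoint,
        candidates=candidates,
        summary=summary,
        c_index=c_index,
    )


def marker_accumulation(
    marker_flags: pd.DataFrame, survival: pd.DataFrame
) -> tuple[pd.Series, dict]:
    """Risk tiers by count of unfavorable markers: 0-2 low, 3-4 medium,
    >=5 high; KM + logrank across tiers."""
    counts = marker_flags.astype(bool).sum(axis=1)
    tier = pd.Series(
        pd.cut(
            counts,
            bins=[-0.5, 2.5, 4.5, np.inf],
            labels=["low", "medium", "high"],
        ).astype(str),
        index=counts.index,
    )
    present = [t for t in ("low", "medium", "high") if (tier == t).any()]
    result: dict = {"tier_counts": tier.value_counts().to_dict()}
    if len(present) >= 2:
        curves, stat, p = km_logrank(tier, survival)
        result.update(
            {
                "logrank_statistic": stat,
                "logrank_p": p,
                "median_survival": median_survival(tier, survival),
            }
        )
    return tier, result
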