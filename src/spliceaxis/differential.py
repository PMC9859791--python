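"""Case-vs-control differential splicing with normal-cell subtraction.

A comparison contrasts mean PSI between two disjoint sample groups defined
by genomic flags.  Per event the effect size is dPSI = mean(case) -
mean(control), significance is a two-sided Mann-Whitney U test, and an
event *passes* when |dPSI| exceeds ``dpsi_min`` (default 0.10), the mean
event TPM exceeds ``tpm_min`` (default 1.0), raw p < ``alpha`` (default
0.05), and the event survives the normal-plasma-cell filter.  No multiple-
testing correction is applied by default (an optional BH switch is
provided); the raw-p + effect + expression triple filter is the documented
contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import ASEvent, EVENT_TYPES, PsiMatrix
from .io import SampleAnnotation, SpliceaxisError, annotation_frame

logger = logging.getLogger(__name__)


class ComparisonError(SpliceaxisError):
    """A comparison spec selects an empty or overlapping arm."""


@dataclass
class ComparisonSpec:
    """A case-vs-control contrast over sample annotations.

    Arms are defined either by flag predicates (``case``/``control`` dicts
    with ``all``/``any``/``none`` lists of flag names, applied to tumor
    samples) or by explicit sample id lists.
    """

    name: str
    case: Mapping[str, Sequence[str]] | None = None
    control: Mapping[str, Sequence[str]] | None = None
    case_samples: Sequence[str] | None = None
    control_samples: Sequence[str] | None = None
    dpsi_min: float = 0.10
    tpm_min: float = 1.0
    alpha: float = 0.05
    min_group: int = 3
    bh_correct: bool = False

    def arms(self, annotations: Sequence[SampleAnnotation]) -> tuple[list[str], list[str]]:
        if self.case_samples is not None and self.control_samples is not None:
            case, control = list(self.case_samples), list(self.control_samples)
        else:
            df = annotation_frame(annotations)
            tumors = df[df["cohort"] == "tumor"]
            case = list(tumors.index[_predicate(self.case)(tumors)])
            control = list(tumors.index[_predicate(self.control)(tumors)])
        if not case or not control:
            raise ComparisonError(f"comparison {self.name!r}: empty arm")
        if set(case) & set(control):
            raise ComparisonError(f"comparison {self.name!r}: overlapping arms")
        return case, control


def _predicate(clause: Mapping[str, Sequence[str]] | None) -> Callable[[pd.DataFrame], pd.Series]:
    clause = clause or {}

    def apply(df: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=df.index)
        for flag in clause.get("all", []):
            mask &= df[flag]
        any_flags = clause.get("any", [])
        if any_flags:
            mask &= df[list(any_flags)].any(axis=1)
        for flag in clause.get("none", []):
            mask &= ~df[flag]
        return mask

    return apply


def comparison_specs_from_config(entries: Iterable[Mapping]) -> list[ComparisonSpec]:
    """Build specs from parsed YAML entries."""
    specs = []
    for e in entries:
        specs.append(
            ComparisonSpec(
                name=e["name"],
                case=e.get("case"),
                control=e.get("control"),
                dpsi_min=float(e.get("dpsi_min", 0.10)),
                tpm_min=float(e.get("tpm_min", 1.0)),
                alpha=float(e.get("alpha", 0.05)),
            )
        )
    return specs


@dataclass
class DifferentialEvent:
    """Per-event result of one comparison."""

    event_id: str
    dpsi: float
    p_value: float
    mean_event_tpm: float
    n_case: int
    n_control: int
    passes: bool
    case_mean: float
    control_mean: float
    cell_type_specific: bool = False
    p_adjusted: float | None = None


def _mwu_two_sided(case: np.ndarray, control: np.ndarray) -> float:
    pooled = np.concatenate([case, control])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(case, control, alternative="two-sided").pvalue)


def run_comparison(
    psi: PsiMatrix,
    event_tpm: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    spec: ComparisonSpec,
) -> list[DifferentialEvent]:
    """Differential splicing for one comparison.

    Missing PSI is excluded pairwise; events with fewer than ``min_group``
    non-missing values in either arm are skipped (count logged).  Results
    are sorted by |dPSI| descending.
    """
    case_ids, control_ids = spec.arms(annotations)
    case_ids = [s for s in case_ids if s in psi.data.columns]
    control_ids = [s for s in control_ids if s in psi.data.columns]
    if not case_ids or not control_ids:
        raise ComparisonError(f"comparison {spec.name!r}: arm absent from PSI matrix")
    case_df = psi.data[case_ids]
    control_df = psi.data[control_ids]
    tpm_df = event_tpm[case_ids + control_ids]
    results: list[DifferentialEvent] = []
    skipped = 0
    for event_id in psi.data.index:
        case = case_df.loc[event_id].dropna().to_numpy()
        control = control_df.loc[event_id].dropna().to_numpy()
        if len(case) < spec.min_group or len(control) < spec.min_group:
            skipped += 1
            continue
        dpsi = float(case.mean() - control.mean())
        p = _mwu_two_sided(case, control)
        mean_tpm = float(tpm_df.loc[event_id].mean())
        results.append(
            DifferentialEvent(
                event_id=event_id,
                dpsi=dpsi,
                p_value=p,
                mean_event_tpm=mean_tpm,
                n_case=len(case),
                n_control=len(control),
                passes=False,
                case_mean=float(case.mean()),
                control_mean=float(control.mean()),
            )
        )
    if spec.bh_correct and results:
        adj = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    for r in results:
        p_eff = r.p_adjusted if spec.bh_correct else r.p_value
        r.passes = (
            abs(r.dpsi) > spec.dpsi_min
            and r.mean_event_tpm > spec.tpm_min
            and p_eff < spec.alpha
        )
    results.sort(key=lambda r: (-abs(r.dpsi), r.event_id))
    logger.info(
        "run_comparison[%s]: %d/%d tested (%d skipped), %d pass",
        spec.name,
        len(results),
        psi.data.shape[0],
        skipped,
        sum(r.passes for r in results),
    )
    return results


def filter_normals(
    diff_events: Sequence[DifferentialEvent],
    psi: PsiMatrix,
    annotations: Sequence[SampleAnnotation],
    spec: ComparisonSpec,
) -> list[DifferentialEvent]:
    """Remove cell-type-specific events using the normal-cell panel.

    An event is flagged cell-type specific (and its ``passes`` cleared)
    when BOTH arms deviate from the normal mean PSI by more than
    ``dpsi_min`` in the same direction — a tumor-wide shift rather than a
    subgroup effect.  Events with no non-missing normal PSI are retained
    with a warning.
    """
    normal_ids = [
        a.sample_id
        for a in annotations
        if a.cohort == "normal" and a.sample_id in psi.data.columns
    ]
    if not normal_ids:
        raise ComparisonError("filter_normals: no normal samples in cohort")
    normal_df = psi.data[normal_ids]
    n_missing = 0
    for r in diff_events:
        normal = normal_df.loc[r.event_id].dropna()
        if normal.empty:
            n_missing += 1
            continue
        n_mean = float(normal.mean())
        d_case = r.case_mean - n_mean
        d_control = r.control_mean - n_mean
        same_direction = (
            (d_case > spec.dpsi_min and d_control > spec.dpsi_min)
            or (d_case < -spec.dpsi_min and d_control < -spec.dpsi_min)
        )
        if same_direction:
            r.cell_type_specific = True
            r.passes = False
    if n_missing:
        logger.warning(
            "filter_normals[%s]: %d events had no normal PSI; retained",
            spec.name,
            n_missing,
        )
    return list(diff_events)


def event_type_composition(
    diff_events: Sequence[DifferentialEvent], events: Sequence[ASEvent]
) -> dict[str, float]:
    """Proportion of each of the 7 event types among passing events."""
    type_of = {e.event_id: e.event_type for e in events}
    passing = [r for r in diff_events if r.passes]
    if not passing:
        raise SpliceaxisError("event_type_composition: no passing events")
    counts = {t: 0 for t in EVENT_TYPES}
    for r in passing:
        counts[type_of[r.event_id]] += 1
    total = len(passing)
    return {t: counts[t] / total for t in EVENT_TYPES}


@dataclass
class OverlapSummary:
    membership: pd.DataFrame  # event x set booleans
    intersection_all: int
    pairwise: pd.DataFrame  # set x set intersection counts
    unique_counts: dict[str, int]


def overlap_sets(named_sets: Sequence[tuple[str, set[str]]]) -> OverlapSummary:
    """Membership table and intersection/unique counts for >= 2 event sets."""
    if len(named_sets) < 2:
        raise SpliceaxisError("overlap_sets: need at least two sets")
    names = [n for n, _ in named_sets]
    universe = sorted(set().union(*(s for _, s in named_sets)))
    membership = pd.DataFrame(
        {n: [e in s for e in universe] for n, s in named_sets}, index=universe
    )
    pairwise = pd.DataFrame(
        [
            [int((membership[a] & membership[b]).sum()) for b in names]
            for a in names
        ],
        index=names,
        columns=names,
    )
    in_all = int(membership.all(axis=1).sum())
    exactly_one = membership.sum(axis=1) == 1
    unique = {n: int((membership[n] & exactly_one).sum()) for n in names}
    return OverlapSummary(
        membership=membership,
        intersection_all=in_all,
        pairwise=pairwise,
        unique_counts=unique,
    )


def compare_transcript_expression(
    transcript_tpm,
    annotations: Sequence[SampleAnnotation],
    spec: ComparisonSpec,
    transcript_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-transcript log2 fold change and one-sided t-test.

    log2FC is the difference of mean log2(TPM + 1); the one-sided p-value
    is taken in the direction of the observed sign (p = 0.5 for identical
    arms).
    """
    case_ids, control_ids = spec.arms(annotations)
    data = transcript_tpm.data if hasattr(transcript_tpm, "data") else transcript_tpm
    missing = [t for t in transcript_ids if t not in data.index]
    if missing:
        raise SpliceaxisError(f"transcripts absent from matrix: {missing[:5]}")
    log2 = np.log2(data.loc[list(transcript_ids)] + 1.0)
    rows = []
    for tid in transcript_ids:
        case = log2.loc[tid, case_ids].to_numpy()
        control = log2.loc[tid, control_ids].to_numpy()
        log2fc = float(case.mean() - control.mean())
        alternative = "greater" if log2fc >= 0 else "less"
        if np.ptp(np.concatenate([case, control])) == 0:
            p = 0.5
        elif case.std(ddof=1) == 0 and control.std(ddof=1) == 0:
            p = 0.0  # complete separation with constant arms
        else:
            p = float(
                stats.ttest_ind(case, control, alternative=alternative).pvalue
            )
        rows.append({"transcript_id": tid, "log2fc": log2fc, "p_value": p})
    return pd.DataFrame(rows).set_index("transcript_id")


def top_variate_selection(
    psi: PsiMatrix, fraction: float = 0.01, top_n: int | None = None
) -> list[str]:
    """Event ids with the largest PSI variance (missing values ignored)."""
    if top_n is None:
        if not 0 < fraction <= 1:
            raise SpliceaxisError("fraction must be in (0, 1]")
        top_n = max(1, int(round(fraction * psi.data.shape[0])))
    variances = psi.data.var(axis=1, ddof=1).fillna(0.0)
    order = variances.sort_values(ascending=False, kind="stable")
    return list(order.index[:top_n])


def umap_embed(
    psi: PsiMatrix,
    event_ids: Sequence[str],
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """2-D UMAP embedding of samples over the selected events.

    Missing PSI is mean-imputed per event (for the embedding only).
    """
    import umap

    sub = psi.data.loc[list(event_ids)]
    imputed = sub.apply(lambda row: row.fillna(row.mean()), axis=1).fillna(0.0)
    x = imputed.to_numpy().T  # samples x events
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, max(2, x.shape[0] - 1)),
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(x)
    return pd.DataFrame(coords, index=sub.columns, columns=["umap1", "umap2"])


def differential_table(results: Sequence[DifferentialEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [r.event_id for r in results],
            "dpsi": [r.dpsi for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "mean_event_tpm": [r.mean_event_tpm for r in results],
            "n_case": [r.n_case for r in results],
            "n_control": [r.n_control for r in results],
            "case_mean": [r.case_mean for r in results],
            "control_mean": [r.control_mean for r in results],
            "cell_type_specific": [r.cell_type_specific for r in results],
            "passes": [r.passes for r in results],
        }
    )
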