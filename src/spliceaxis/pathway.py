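"""Pathway expression activity and its link to splicing frequency.

Pathway activity per sample is the mean z-score of member-gene
log2(TPM + 1); the cohort is split at tertiles into high/mid/low activity
groups.  Per-sample *splicing frequency* is operationalized as the count of
events whose PSI deviates from the cohort median by more than ``dpsi_min``
among events expressed (event TPM > ``tpm_min``) in that sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .differential import ComparisonSpec, DifferentialEvent, run_comparison
from .events import PsiMatrix
from .io import ExpressionMatrix, GeneSet, SampleAnnotation, SpliceaxisError, annotation_frame

logger = logging.getLogger(__name__)


@dataclass
class PathwayActivity:
    """Per-sample activity score and tertile group for one pathway."""

    pathway: str
    score: pd.Series  # per-sample mean z-score
    group: pd.Series  # 'high' / 'mid' / 'low'
    member_genes: tuple[str, ...]

    def samples(self, label: str) -> list[str]:
        return list(self.group.index[self.group == label])


def _log2p1(df: pd.DataFrame) -> pd.DataFrame:
    return np.log2(df + 1.0)


def fold_change_matrix(
    gene_tpm: ExpressionMatrix,
    specs: Sequence[ComparisonSpec],
    annotations: Sequence[SampleAnnotation],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Gene x comparison |log2FC| matrix (mean log2(TPM+1) difference)."""
    genes = [g for g in genes if g in gene_tpm.data.index]
    if len(genes) < 2 or len(specs) < 2:
        raise SpliceaxisError("fold_change_matrix: need >=2 genes and >=2 comparisons")
    log2 = _log2p1(gene_tpm.data.loc[genes])
    cols = {}
    for spec in specs:
        case, control = spec.arms(annotations)
        case = [s for s in case if s in log2.columns]
        control = [s for s in control if s in log2.columns]
        cols[spec.name] = (
            log2[case].mean(axis=1) - log2[control].mean(axis=1)
        ).abs()
    return pd.DataFrame(cols)


def cluster_genes(fc_matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage Euclidean hierarchical clustering of the rows.

    Returns the scipy linkage matrix and the leaf order (gene names).
    """
    if fc_matrix.shape[0] < 2:
        raise SpliceaxisError("cluster_genes: need >= 2 genes")
    linkage = hierarchy.linkage(fc_matrix.to_numpy(), method="average", metric="euclidean")
    order = hierarchy.leaves_list(linkage)
    return linkage, [fc_matrix.index[i] for i in order]


def correlate_fc_with_counts(
    fc_row: pd.Series, counts: pd.Series, rho_flag: float = 0.65
) -> tuple[float, bool]:
    """Spearman rank correlation of per-comparison |log2FC| against passing
    event counts; flags genes above ``rho_flag``."""
    common = fc_row.index.intersection(counts.index)
    if len(common) < 4:
        raise SpliceaxisError("correlate_fc_with_counts: need >= 4 paired values")
    rho = float(stats.spearmanr(fc_row[common], counts[common]).statistic)
    return rho, rho > rho_flag


def define_activity_groups(
    gene_tpm: ExpressionMatrix,
    gene_set: GeneSet,
    q_low: float = 1 / 3,
    q_high: float = 2 / 3,
    samples: Sequence[str] | None = None,
) -> PathwayActivity:
    """Tertile (by default) activity grouping from member-gene z-scores."""
    data = gene_tpm.data if samples is None else gene_tpm.data[list(samples)]
    members = [g for g in sorted(gene_set.genes) if g in data.index]
    if not members:
        raise SpliceaxisError(f"no member genes of {gene_set.name} in matrix")
    if data.shape[1] < 3:
        raise SpliceaxisError("define_activity_groups: need >= 3 samples")
    log2 = _log2p1(data.loc[members])
    z = log2.sub(log2.mean(axis=1), axis=0).div(
        log2.std(axis=1, ddof=0).replace(0.0, 1.0), axis=0
    )
    score = z.mean(axis=0)
    lo = float(np.quantile(score, q_low))
    hi = float(np.quantile(score, q_high))
    group = pd.Series("mid", index=score.index)
    group[score > hi] = "high"
    group[score < lo] = "low"
    if (group == "high").sum() == 0 or (group == "low").sum() == 0:
        raise SpliceaxisError("degenerate activity grouping (empty high or low)")
    return PathwayActivity(
        pathway=gene_set.name, score=score, group=group, member_genes=tuple(members)
    )


@dataclass
class SplicingFrequency:
    sample_id: str
    frequency: int


def splicing_frequency(
    psi: PsiMatrix,
    event_tpm: pd.DataFrame,
    dpsi_min: float = 0.10,
    tpm_min: float = 1.0,
) -> list[SplicingFrequency]:
    """Per-sample count of events deviating from the cohort median PSI.

    Only events expressed in the sample (event TPM > tpm_min) and with
    non-missing PSI contribute.
    """
    if psi.data.shape[1] < 3:
        raise SpliceaxisError("splicing_frequency: need >= 3 samples")
    median = psi.data.median(axis=1)
    deviates = (
        psi.data.sub(median, axis=0).abs().gt(dpsi_min)
        & psi.data.notna()
        & event_tpm.loc[psi.data.index, psi.data.columns].gt(tpm_min)
    )
    counts = deviates.sum(axis=0)
    return [SplicingFrequency(s, int(counts[s])) for s in psi.data.columns]


def frequency_series(frequencies: Sequence[SplicingFrequency]) -> pd.Series:
    return pd.Series(
        {f.sample_id: f.frequency for f in frequencies}, name="splicing_frequency"
    )


def group_burden(
    psi: PsiMatrix,
    event_tpm: pd.DataFrame,
    activity: PathwayActivity,
    annotations: Sequence[SampleAnnotation],
    dpsi_min: float = 0.10,
    tpm_min: float = 1.0,
    alpha: float = 0.05,
    min_group: int = 3,
) -> tuple[list[DifferentialEvent], dict]:
    """High-vs-low activity differential splicing plus burden summary."""
    high = activity.samples("high")
    low = activity.samples("low")
    if len(high) < min_group or len(low) < min_group:
        raise SpliceaxisError("group_burden: high/low groups too small")
    spec = ComparisonSpec(
        name=f"{activity.pathway}_high_vs_low",
        case_samples=high,
        control_samples=low,
        dpsi_min=dpsi_min,
        tpm_min=tpm_min,
        alpha=alpha,
        min_group=min_group,
    )
    diff = run_comparison(psi, event_tpm, annotations, spec)
    freqs = frequency_series(splicing_frequency(psi, event_tpm, dpsi_min, tpm_min))
    burden_p = compare_burdens(freqs, activity.group)
    summary = {
        "pathway": activity.pathway,
        "n_high": len(high),
        "n_low": len(low),
        "passing_events": int(sum(r.passes for r in diff)),
        "burden_p": burden_p,
    }
    return diff, summary


def compare_burdens(frequencies: pd.Series, group: pd.Series) -> float:
    """One-sided Mann-Whitney p for higher splicing frequency in 'high'."""
    high = frequencies[group.index[group == "high"]].dropna()
    low = frequencies[group.index[group == "low"]].dropna()
    return float(
        stats.mannwhitneyu(high, low, alternative="greater").pvalue
    )


def enrichment_test(
    group: pd.Series, flag: pd.Series, target: str = "high"
) -> tuple[float, float]:
    """Fisher's exact test for enrichment of a boolean flag in ``target``.

    Returns (odds ratio, two-sided exact p).  The odds ratio uses the
    Haldane correction (+0.5 to all cells) when any cell is zero; the
    p-value always comes from the exact hypergeometric enumeration of the
    uncorrected table.
    """
    common = group.index.intersection(flag.index)
    g = group[common] == target
    f = flag[common].astype(bool)
    a = int((g & f).sum())
    b = int((g & ~f).sum())
    c = int((~g & f).sum())
    d = int((~g & ~f).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        raise SpliceaxisError("enrichment_test: degenerate 2x2 margins")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


def compare_sv_counts(
    annotations: Sequence[SampleAnnotation], group: pd.Series
) -> dict:
    """Group SV-count means, one-sided MWU (high > low) and per-group KS
    normality p-values (reported, not gating)."""
    df = annotation_frame(annotations)
    sv = df["sv_count"].astype(float)
    out: dict = {"means": {}, "ks_normality_p": {}}
    for label in ("high", "mid", "low"):
        ids = group.index[group == label]
        vals = sv.reindex(ids).dropna()
        if len(vals):
            out["means"][label] = float(vals.mean())
            mu, sd = vals.mean(), vals.std(ddof=0)
            out["ks_normality_p"][label] = (
                float(stats.kstest(vals, "norm", args=(mu, max(sd, 1e-9))).pvalue)
            )
    high = sv.reindex(group.index[group == "high"]).dropna()
    low = sv.reindex(group.index[group == "low"]).dropna()
    if high.isna().any() or low.isna().any() or not len(high) or not len(low):
        raise SpliceaxisError("compare_sv_counts: missing sv_count in groups")
    out["mwu_p"] = float(stats.mannwhitneyu(high, low, alternative="greater").pvalue)
    return out
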