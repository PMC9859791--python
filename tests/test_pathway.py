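import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceaxis.events import PsiMatrix, event_tpm_matrix
from spliceaxis.io import ExpressionMatrix, GeneSet, SampleAnnotation
from spliceaxis.pathway import (
    cluster_genes,
    compare_burdens,
    compare_sv_counts,
    correlate_fc_with_counts,
    define_activity_groups,
    enrichment_test,
    fold_change_matrix,
    frequency_series,
    group_burden,
    splicing_frequency,
)


# ---------------------------------------------------------------------------
# fold-change clustering
# ---------------------------------------------------------------------------


def _bruteforce_average_linkage(matrix: np.ndarray):
    """Naive agglomerative average linkage; returns merge heights in order."""
    clusters = {i: [i] for i in range(matrix.shape[0])}
    heights = []
    next_id = matrix.shape[0]
    dist = {
        (i, j): float(np.linalg.norm(matrix[i] - matrix[j]))
        for i, j in itertools.combinations(range(matrix.shape[0]), 2)
    }

    def cluster_distance(a, b):
        return float(
            np.mean(
                [
                    dist[tuple(sorted((i, j)))]
                    for i in clusters[a]
                    for j in clusters[b]
                ]
            )
        )

    while len(clusters) > 1:
        pairs = list(itertools.combinations(sorted(clusters), 2))
        best = min(pairs, key=lambda p: cluster_distance(*p))
        heights.append(cluster_distance(*best))
        clusters[next_id] = clusters.pop(best[0]) + clusters.pop(best[1])
        next_id += 1
    return heights


def test_identical_profiles_merge_first_distant_last():
    fc = pd.DataFrame(
        {
            "c1": [1.0, 1.0, 0.0, 9.0],
            "c2": [2.0, 2.0, 0.0, 9.0],
        },
        index=["g_dup1", "g_dup2", "g_zero", "g_big"],
    )
    linkage, order = cluster_genes(fc)
    # first merge is the duplicate pair at distance 0
    first = sorted(linkage[0, :2].astype(int))
    assert [fc.index[i] for i in first] == ["g_dup1", "g_dup2"]
    assert linkage[0, 2] == 0.0
    # the outlier joins last
    assert linkage[-1, 2] == max(linkage[:, 2])


def test_linkage_matches_bruteforce_oracle(rng):
    fc = pd.DataFrame(
        rng.uniform(0, 3, size=(4, 5)), index=[f"g{i}" for i in range(4)]
    )
    linkage, _ = cluster_genes(fc)
    expected = _bruteforce_average_linkage(fc.to_numpy())
    np.testing.assert_allclose(linkage[:, 2], expected, rtol=1e-12)


def test_fold_change_matrix_values(small_cohort):
    from spliceaxis.differential import ComparisonSpec

    tumor = [a.sample_id for a in small_cohort.annotations if a.cohort == "tumor"]
    specs = [
        ComparisonSpec(name="a", case={"all": ["t_4_14"]}, control={"none": ["t_4_14"]}),
        ComparisonSpec(name="b", case_samples=tumor[:20], control_samples=tumor[20:]),
    ]
    fc = fold_change_matrix(
        small_cohort.gene_tpm, specs, small_cohort.annotations, ["XRCC4", "LIG4"]
    )
    assert fc.shape == (2, 2)
    assert (fc.to_numpy() >= 0).all()


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------


def test_spearman_monotone_and_reversed():
    fc = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    counts = pd.Series([10, 20, 30, 40], index=list("abcd"))
    rho, flagged = correlate_fc_with_counts(fc, counts)
    assert rho == pytest.approx(1.0) and flagged
    rho, flagged = correlate_fc_with_counts(fc, counts.iloc[::-1].set_axis(list("abcd")))
    assert rho == pytest.approx(-1.0) and not flagged


def test_spearman_ties_match_average_rank_formula():
    fc = pd.Series([1.0, 1.0, 2.0, 3.0, 3.0], index=list("abcde"))
    counts = pd.Series([5.0, 7.0, 7.0, 9.0, 10.0], index=list("abcde"))
    rho, _ = correlate_fc_with_counts(fc, counts)
    rx = stats.rankdata(fc)
    ry = stats.rankdata(counts)
    manual = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(manual, abs=1e-12)


# ---------------------------------------------------------------------------
# activity groups
# ---------------------------------------------------------------------------


def _expr_blocks():
    # 30 samples in three blocks of 10 at log2 levels 8 / 5 / 2 on 3 genes
    cols = [f"s{i}" for i in range(30)]
    base = np.array([[8.0] * 10 + [5.0] * 10 + [2.0] * 10] * 3)
    jitter = np.linspace(0, 0.01, 30)  # break ties deterministically
    data = 2 ** (base + jitter) - 1
    return ExpressionMatrix(pd.DataFrame(data, index=["g1", "g2", "g3"], columns=cols))


def test_activity_groups_recover_blocks_exactly():
    act = define_activity_groups(_expr_blocks(), GeneSet("P", frozenset({"g1", "g2", "g3"})))
    assert act.samples("high") == [f"s{i}" for i in range(10)]
    assert act.samples("low") == [f"s{i}" for i in range(20, 30)]
    assert act.samples("mid") == [f"s{i}" for i in range(10, 20)]


def test_single_member_gene_score_is_its_zscore():
    m = _expr_blocks()
    act = define_activity_groups(m, GeneSet("P", frozenset({"g1"})))
    log2 = np.log2(m.data.loc["g1"] + 1)
    z = (log2 - log2.mean()) / log2.std(ddof=0)
    np.testing.assert_allclose(act.score.to_numpy(), z.to_numpy(), atol=1e-12)


def test_activity_groups_match_latent_truth(coupling_cohort):
    from spliceaxis.pipeline import packaged_gmt

    nhej = next(s for s in packaged_gmt() if s.name == "NHEJ")
    tumor = [a.sample_id for a in coupling_cohort.annotations if a.cohort == "tumor"]
    act = define_activity_groups(coupling_cohort.gene_tpm, nhej, samples=tumor)
    truth = coupling_cohort.truth.nhej_group
    agreement = (act.group[truth.index] == truth).mean()
    assert agreement >= 0.95


# ---------------------------------------------------------------------------
# splicing frequency
# ---------------------------------------------------------------------------


def test_identical_samples_have_zero_frequency():
    data = pd.DataFrame(0.4, index=[f"e{i}" for i in range(5)], columns=list("abc"))
    etpm = pd.DataFrame(10.0, index=data.index, columns=data.columns)
    freqs = splicing_frequency(PsiMatrix(data), etpm)
    assert all(f.frequency == 0 for f in freqs)


def test_single_shifted_sample_counted():
    data = pd.DataFrame(0.4, index=[f"e{i}" for i in range(5)], columns=list("abcde"))
    data["a"] += 0.2
    etpm = pd.DataFrame(10.0, index=data.index, columns=data.columns)
    freqs = {f.sample_id: f.frequency for f in splicing_frequency(PsiMatrix(data), etpm)}
    assert freqs == {"a": 5, "b": 0, "c": 0, "d": 0, "e": 0}


def test_frequency_order_invariance(small_cohort):
    psi = small_cohort.psi_true
    etpm = event_tpm_matrix(small_cohort.events, small_cohort.transcript_tpm)
    base = frequency_series(splicing_frequency(psi, etpm))
    shuffled = PsiMatrix(psi.data.iloc[::-1, ::-1])
    other = frequency_series(splicing_frequency(shuffled, etpm))
    assert base.sort_index().equals(other.sort_index())


def test_frequency_tracks_planted_deviations(coupling_cohort):
    psi = coupling_cohort.psi_true
    etpm = event_tpm_matrix(coupling_cohort.events, coupling_cohort.transcript_tpm)
    tumor = list(coupling_cohort.truth.true_frequency.index)
    freqs = frequency_series(
        splicing_frequency(PsiMatrix(psi.data[tumor]), etpm[tumor])
    )
    rho = stats.spearmanr(
        coupling_cohort.truth.true_frequency, freqs[tumor]
    ).statistic
    assert rho >= 0.9


# ---------------------------------------------------------------------------
# burden / enrichment / SV counts
# ---------------------------------------------------------------------------


def test_burden_mwu_exact_enumeration():
    """{10,12,14} vs {1,2,3}: the only arrangement with U = 9 out of
    C(6,3) = 20 -> one-sided p = 0.05."""
    freqs = pd.Series({"a": 10, "b": 12, "c": 14, "d": 1, "e": 2, "f": 3})
    group = pd.Series(
        {"a": "high", "b": "high", "c": "high", "d": "low", "e": "low", "f": "low"}
    )
    assert compare_burdens(freqs, group) == pytest.approx(0.05)


def test_fisher_enrichment_table():
    """a=15, b=85, c=6, d=94 -> OR = 15*94/(85*6) = 2.76."""
    group = pd.Series(["high"] * 100 + ["low"] * 100)
    flag = pd.Series([True] * 15 + [False] * 85 + [True] * 6 + [False] * 94)
    odds, p = enrichment_test(group, flag)
    assert odds == pytest.approx(15 * 94 / (85 * 6))
    assert round(odds, 2) == 2.76
    expected_p = stats.fisher_exact([[15, 85], [6, 94]]).pvalue
    assert p == pytest.approx(expected_p)


def test_fisher_null_and_haldane_paths():
    group = pd.Series(["high"] * 20 + ["low"] * 20)
    flag = pd.Series(([True] * 5 + [False] * 15) * 2)
    odds, p = enrichment_test(group, flag)
    assert odds == pytest.approx(1.0)
    assert p == pytest.approx(1.0)
    flag0 = pd.Series([False] * 20 + [True] * 5 + [False] * 15)
    odds0, p0 = enrichment_test(group, flag0)
    assert np.isfinite(odds0) and odds0 > 0
    assert 0 <= p0 <= 1


def test_enrichment_symmetry_properties():
    group = pd.Series(["high"] * 50 + ["low"] * 60)
    flag = pd.Series([True] * 20 + [False] * 30 + [True] * 12 + [False] * 48)
    odds, _ = enrichment_test(group, flag)
    # swapping both margins leaves OR unchanged
    flipped_group = group.map({"high": "low", "low": "high"})
    odds_both, _ = enrichment_test(flipped_group, ~flag, target="high")
    assert odds_both == pytest.approx(odds)
    # swapping one margin inverts it
    odds_one, _ = enrichment_test(group, ~flag)
    assert odds_one == pytest.approx(1 / odds)


def test_sv_count_exact_small_sample():
    """{100,90,80} vs {10,20,30} one-sided MWU p = 0.05."""
    anns = []
    for i, v in enumerate([100, 90, 80]):
        anns.append(SampleAnnotation(sample_id=f"h{i}", sv_count=v))
    for i, v in enumerate([10, 20, 30]):
        anns.append(SampleAnnotation(sample_id=f"l{i}", sv_count=v))
    group = pd.Series(
        {"h0": "high", "h1": "high", "h2": "high", "l0": "low", "l1": "low", "l2": "low"}
    )
    res = compare_sv_counts(anns, group)
    assert res["mwu_p"] == pytest.approx(0.05)
    assert res["means"]["high"] == pytest.approx(90.0)
    assert res["means"]["low"] == pytest.approx(20.0)


def test_sv_identical_groups_not_significant():
    anns = [SampleAnnotation(sample_id=f"s{i}", sv_count=50) for i in range(10)]
    group = pd.Series({f"s{i}": ("high" if i < 5 else "low") for i in range(10)})
    res = compare_sv_counts(anns, group)
    assert res["mwu_p"] > 0.5


def test_group_burden_null_is_alpha_level(null_cohort):
    """With no planted coupling, high-vs-low passing events stay at the
    false-positive level implied by the triple filter."""
    from spliceaxis.pipeline import packaged_gmt

    psi = null_cohort.psi_true
    etpm = event_tpm_matrix(null_cohort.events, null_cohort.transcript_tpm)
    tumor = [a.sample_id for a in null_cohort.annotations if a.cohort == "tumor"]
    nhej = next(s for s in packaged_gmt() if s.name == "NHEJ")
    act = define_activity_groups(null_cohort.gene_tpm, nhej, samples=tumor)
    diff, summary = group_burden(
        PsiMatrix(psi.data[tumor]), etpm[tumor], act, null_cohort.annotations
    )
    n = len(diff)
    assert summary["passing_events"] <= 0.05 * n
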