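import numpy as np
import pandas as pd
import pytest

from spliceaxis.differential import (
    ComparisonError,
    ComparisonSpec,
    compare_transcript_expression,
    event_type_composition,
    filter_normals,
    overlap_sets,
    run_comparison,
    top_variate_selection,
    umap_embed,
)
from spliceaxis.events import PsiMatrix, event_tpm_matrix
from spliceaxis.io import ExpressionMatrix, SampleAnnotation, annotation_frame


def _toy_inputs(case_vals, control_vals, tpm=5.0, normal_vals=None):
    """One-event PSI/TPM matrices plus annotations for explicit arms."""
    case_ids = [f"C{i}" for i in range(len(case_vals))]
    control_ids = [f"K{i}" for i in range(len(control_vals))]
    normal_ids = [f"N{i}" for i in range(len(normal_vals or []))]
    samples = case_ids + control_ids + normal_ids
    values = list(case_vals) + list(control_vals) + list(normal_vals or [])
    psi = PsiMatrix(pd.DataFrame([values], index=["E1"], columns=samples))
    etpm = pd.DataFrame([[tpm] * len(samples)], index=["E1"], columns=samples)
    anns = [SampleAnnotation(sample_id=s) for s in case_ids + control_ids]
    anns += [SampleAnnotation(sample_id=s, cohort="normal") for s in normal_ids]
    spec = ComparisonSpec(name="toy", case_samples=case_ids, control_samples=control_ids)
    return psi, etpm, anns, spec


def test_clear_separation_passes():
    psi, etpm, anns, spec = _toy_inputs([0.9] * 10, [0.5] * 10)
    res = run_comparison(psi, etpm, anns, spec)
    assert len(res) == 1
    assert res[0].dpsi == pytest.approx(0.4)
    assert res[0].p_value < 0.05
    assert res[0].passes


def test_small_dpsi_fails_despite_significance():
    psi, etpm, anns, spec = _toy_inputs([0.55] * 20, [0.50] * 20)
    res = run_comparison(psi, etpm, anns, spec)
    assert res[0].p_value < 1e-5
    assert abs(res[0].dpsi) < 0.1
    assert not res[0].passes


def test_low_tpm_fails():
    psi, etpm, anns, spec = _toy_inputs([0.9] * 10, [0.5] * 10, tpm=0.5)
    res = run_comparison(psi, etpm, anns, spec)
    assert not res[0].passes


def test_arm_swap_flips_dpsi_exactly(small_cohort):
    psi = small_cohort.psi_true
    etpm = event_tpm_matrix(small_cohort.events, small_cohort.transcript_tpm)
    fwd = ComparisonSpec(name="fwd", case={"all": ["t_4_14"]}, control={"none": ["t_4_14"]})
    rev = ComparisonSpec(name="rev", case={"none": ["t_4_14"]}, control={"all": ["t_4_14"]})
    a = {r.event_id: r.dpsi for r in run_comparison(psi, etpm, small_cohort.annotations, fwd)}
    b = {r.event_id: r.dpsi for r in run_comparison(psi, etpm, small_cohort.annotations, rev)}
    assert set(a) == set(b)
    for k in a:
        assert a[k] == -b[k]


def test_all_missing_sample_changes_nothing():
    psi, etpm, anns, spec = _toy_inputs([0.9] * 8, [0.5] * 8)
    base = run_comparison(psi, etpm, anns, spec)[0]
    psi2 = PsiMatrix(psi.data.assign(extra=np.nan))
    etpm2 = etpm.assign(extra=np.nan)
    anns2 = anns + [SampleAnnotation(sample_id="extra")]
    spec2 = ComparisonSpec(
        name="toy",
        case_samples=list(spec.case_samples) + ["extra"],
        control_samples=spec.control_samples,
    )
    res = run_comparison(psi2, etpm2, anns2, spec2)[0]
    assert (res.dpsi, res.p_value, res.mean_event_tpm, res.passes) == (
        base.dpsi, base.p_value, base.mean_event_tpm, base.passes,
    )


def test_empty_arm_raises():
    psi, etpm, anns, _ = _toy_inputs([0.9] * 3, [0.5] * 3)
    spec = ComparisonSpec(name="bad", case_samples=[], control_samples=["K0"])
    with pytest.raises(ComparisonError, match="bad"):
        run_comparison(psi, etpm, anns, spec)


def test_overlapping_arms_raise():
    psi, etpm, anns, _ = _toy_inputs([0.9] * 3, [0.5] * 3)
    spec = ComparisonSpec(
        name="dup", case_samples=["C0", "C1"], control_samples=["C1", "K0"]
    )
    with pytest.raises(ComparisonError):
        run_comparison(psi, etpm, anns, spec)


@pytest.mark.parametrize(
    "case_m, control_m, normal_m, removed",
    [
        (0.8, 0.4, 0.4, False),  # control matches normal: subgroup effect
        (0.8, 0.7, 0.3, True),  # both arms shifted up: tumor-wide
        (0.2, 0.3, 0.7, True),  # both arms shifted down
    ],
)
def test_normal_filter_rule(case_m, control_m, normal_m, removed):
    psi, etpm, anns, spec = _toy_inputs(
        [case_m] * 6, [control_m] * 6, normal_vals=[normal_m] * 3
    )
    res = run_comparison(psi, etpm, anns, spec)
    res = filter_normals(res, psi, anns, spec)
    assert res[0].cell_type_specific is removed
    if removed:
        assert not res[0].passes


def test_normal_filter_retains_when_normals_missing(caplog):
    import logging

    psi, etpm, anns, spec = _toy_inputs(
        [0.8] * 6, [0.7] * 6, normal_vals=[np.nan] * 3
    )
    res = run_comparison(psi, etpm, anns, spec)
    with caplog.at_level(logging.WARNING):
        res = filter_normals(res, psi, anns, spec)
    assert not res[0].cell_type_specific
    assert "no normal PSI" in caplog.text


def test_normal_filter_requires_normals():
    psi, etpm, anns, spec = _toy_inputs([0.8] * 6, [0.4] * 6)
    res = run_comparison(psi, etpm, anns, spec)
    with pytest.raises(ComparisonError):
        filter_normals(res, psi, anns, spec)


def test_filter_normals_removes_tumor_wide_shifts_in_cohort(small_cohort):
    """Planted cell-type-specific events are the ones flagged."""
    psi = small_cohort.psi_true
    etpm = event_tpm_matrix(small_cohort.events, small_cohort.transcript_tpm)
    spec = ComparisonSpec(name="t_4_14", case={"all": ["t_4_14"]}, control={"none": ["t_4_14"]})
    res = run_comparison(psi, etpm, small_cohort.annotations, spec)
    res = filter_normals(res, psi, small_cohort.annotations, spec)
    flagged = {r.event_id for r in res if r.cell_type_specific}
    cts = set(small_cohort.truth.cell_type_specific)
    # the planted tumor-wide shift is 0.25 - comfortably detectable
    assert len(flagged & cts) / len(cts) >= 0.8
    assert len(flagged - cts) <= 0.05 * len(res)


def test_event_type_composition(small_cohort):
    from spliceaxis.differential import DifferentialEvent

    events = small_cohort.events
    picks = [events[0], events[1], events[2], events[7]]

    def de(eid, ok=True):
        return DifferentialEvent(
            event_id=eid, dpsi=0.3, p_value=0.01, mean_event_tpm=5, n_case=5,
            n_control=5, passes=ok, case_mean=0.6, control_mean=0.3,
        )

    comp = event_type_composition([de(e.event_id) for e in picks], events)
    assert sum(comp.values()) == pytest.approx(1.0)
    assert comp[picks[0].event_type] >= 0.25
    single = event_type_composition([de(picks[0].event_id)], events)
    assert single[picks[0].event_type] == 1.0


def test_overlap_sets_counts():
    res = overlap_sets([("A", {"e1", "e2"}), ("B", {"e2"})])
    assert res.pairwise.loc["A", "B"] == 1
    assert res.unique_counts == {"A": 1, "B": 0}
    same = overlap_sets([("A", {"e1"}), ("B", {"e1"})])
    assert same.unique_counts == {"A": 0, "B": 0}
    assert same.intersection_all == 1


def test_overlap_matches_bruteforce(rng):
    universe = [f"e{i}" for i in range(30)]
    sets = [
        ("S1", {e for e in universe if rng.random() < 0.4}),
        ("S2", {e for e in universe if rng.random() < 0.4}),
        ("S3", {e for e in universe if rng.random() < 0.4}),
    ]
    res = overlap_sets(sets)
    for a, sa in sets:
        for b, sb in sets:
            assert res.pairwise.loc[a, b] == len(sa & sb)
    assert res.intersection_all == len(sets[0][1] & sets[1][1] & sets[2][1])
    for name, s in sets:
        others = set().union(*(t for n, t in sets if n != name))
        assert res.unique_counts[name] == len(s - others)


def test_transcript_expression_closed_form():
    tpm = ExpressionMatrix(
        pd.DataFrame(
            [[8.0] * 5 + [2.0] * 5], index=["T1"],
            columns=[f"C{i}" for i in range(5)] + [f"K{i}" for i in range(5)],
        )
    )
    anns = [SampleAnnotation(sample_id=f"C{i}") for i in range(5)]
    anns += [SampleAnnotation(sample_id=f"K{i}") for i in range(5)]
    spec = ComparisonSpec(
        name="x", case_samples=[f"C{i}" for i in range(5)],
        control_samples=[f"K{i}" for i in range(5)],
    )
    res = compare_transcript_expression(tpm, anns, spec, ["T1"])
    assert res.loc["T1", "log2fc"] == pytest.approx(np.log2(9 / 3))
    assert res.loc["T1", "p_value"] < 0.05  # constant-arm separation


def test_transcript_expression_identical_arms():
    tpm = ExpressionMatrix(
        pd.DataFrame(
            [[4.0, 5.0, 6.0, 4.0, 5.0, 6.0]], index=["T1"],
            columns=["C0", "C1", "C2", "K0", "K1", "K2"],
        )
    )
    anns = [SampleAnnotation(sample_id=s) for s in ["C0", "C1", "C2", "K0", "K1", "K2"]]
    spec = ComparisonSpec(
        name="x", case_samples=["C0", "C1", "C2"], control_samples=["K0", "K1", "K2"]
    )
    res = compare_transcript_expression(tpm, anns, spec, ["T1"])
    assert res.loc["T1", "log2fc"] == 0.0
    assert res.loc["T1", "p_value"] == pytest.approx(0.5)


def test_planted_twofold_shift_detected(rng):
    """2-fold transcript shift at n=30/30 detected at p < 0.05 in >=90%
    of simulation replicates."""
    hits = 0
    n_rep = 40
    for rep in range(n_rep):
        r = np.random.default_rng(1000 + rep)
        case = 2 ** (3.0 + 1.0 + r.normal(0, 0.8, 30)) - 1
        ctrl = 2 ** (3.0 + r.normal(0, 0.8, 30)) - 1
        tpm = ExpressionMatrix(
            pd.DataFrame(
                [np.concatenate([case, ctrl]).clip(0)], index=["T1"],
                columns=[f"C{i}" for i in range(30)] + [f"K{i}" for i in range(30)],
            )
        )
        anns = [SampleAnnotation(sample_id=f"C{i}") for i in range(30)]
        anns += [SampleAnnotation(sample_id=f"K{i}") for i in range(30)]
        spec = ComparisonSpec(
            name="x", case_samples=[f"C{i}" for i in range(30)],
            control_samples=[f"K{i}" for i in range(30)],
        )
        res = compare_transcript_expression(tpm, anns, spec, ["T1"])
        if res.loc["T1", "p_value"] < 0.05 and res.loc["T1", "log2fc"] > 0:
            hits += 1
    assert hits >= 0.9 * n_rep


def test_top_variate_selection_orders_by_variance(rng):
    data = pd.DataFrame(
        rng.uniform(0, 1, size=(100, 20)),
        index=[f"e{i}" for i in range(100)],
        columns=[f"s{j}" for j in range(20)],
    )
    data.iloc[0] = 0.5  # constant event
    psi = PsiMatrix(data)
    top = top_variate_selection(psi, fraction=0.1)
    assert len(top) == 10
    variances = data.var(axis=1)
    assert set(top) == set(variances.sort_values(ascending=False).index[:10])
    assert "e0" not in top


def test_constant_events_never_selected_while_variable_exist():
    data = pd.DataFrame(
        {"s1": [0.5, 0.1], "s2": [0.5, 0.9], "s3": [0.5, 0.4]},
        index=["const", "var"],
    )
    top = top_variate_selection(PsiMatrix(data), top_n=1)
    assert top == ["var"]


def test_umap_separates_planted_subgroups(recovery_cohort):
    """50 planted events: k-means on the embedding separates t(4;14)
    carriers with high adjusted Rand index."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    psi = recovery_cohort.psi_true
    df = annotation_frame(recovery_cohort.annotations)
    tumor = [a.sample_id for a in recovery_cohort.annotations if a.cohort == "tumor"]
    sub = PsiMatrix(psi.data[tumor])
    top = top_variate_selection(sub, fraction=0.1)
    coords = umap_embed(sub, top, seed=7)
    labels = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(coords)
    truth = df.loc[coords.index, "t_4_14"].astype(int).to_numpy()
    assert adjusted_rand_score(truth, labels) >= 0.8


def test_monotone_planting_sensitivity(null_cohort):
    """Planted |dPSI| 0.1 -> 0.2 -> 0.3 gives non-decreasing sensitivity."""
    from spliceaxis.synthetic import SyntheticConfig, simulate_cohort

    sens = []
    for dpsi in (0.1, 0.2, 0.3):
        cfg = SyntheticConfig(
            seed=77, n_tumor=60, n_normal=2, events_per_type=30,
            subgroup_fractions={"t_4_14": 0.5}, planted_subgroups=("t_4_14",),
            n_planted_per_subgroup=30, planted_dpsi=dpsi, psi_noise_sd=0.08,
            cell_type_specific_fraction=0.0, n_frequency_events=0,
            n_background_genes=5,
        )
        cohort = simulate_cohort(cfg)
        etpm = event_tpm_matrix(cohort.events, cohort.transcript_tpm)
        spec = ComparisonSpec(
            name="t_4_14", case={"all": ["t_4_14"]}, control={"none": ["t_4_14"]}
        )
        res = run_comparison(cohort.psi_true, etpm, cohort.annotations, spec)
        planted = set(cohort.truth.planted_events["t_4_14"])
        hits = sum(r.passes for r in res if r.event_id in planted)
        sens.append(hits / len(planted))
    assert sens[0] <= sens[1] <= sens[2]
    assert sens[2] >= 0.9
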