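"""End-to-end pipeline: simulate -> events -> PSI -> differential ->
pathway -> survival -> network, with a run manifest.

Every stage reads the previous stage's on-disk artifacts, so a run
directory is a complete, reproducible record.  Reruns with the same config
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, differential, events as ev, io, network, pathway, survival, synthetic

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out: str = "spliceaxis_run"
    dpsi_min: float = 0.10
    tpm_min: float = 1.0
    alpha: float = 0.05
    rho_min: float = 0.3
    n_min_pairs: int = 10
    top_variance_fraction: float = 0.01
    q_low: float = 1 / 3
    q_high: float = 2 / 3
    top_k_events: int = 200
    network_events: int = 25
    network_subgroups: tuple[str, ...] = ("t_11_14", "t_4_14", "t_14_16")
    comparisons_path: str | None = None  # None -> packaged default
    cohort: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.read_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise io.ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def thresholds_ok(self) -> None:
        if not (0 < self.dpsi_min <= 1 and 0 <= self.alpha <= 1 and 0 <= self.rho_min < 1):
            raise io.ValidationError("threshold out of documented range")


def default_comparisons() -> list[differential.ComparisonSpec]:
    with resources.files("spliceaxis.data").joinpath("comparisons.yaml").open() as fh:
        import yaml

        raw = yaml.safe_load(fh)
    return differential.comparison_specs_from_config(raw["comparisons"])


def packaged_gmt() -> list[io.GeneSet]:
    path = resources.files("spliceaxis.data").joinpath("pathways.gmt")
    with resources.as_file(path) as p:
        return io.read_gmt(p)


def packaged_sf_list() -> list[str]:
    text = resources.files("spliceaxis.data").joinpath("splicing_factors.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def _stage_seed(master: int, stage: str) -> int:
    # derived per-stage seeds, logged in the manifest
    import zlib

    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([master, tag]).generate_state(1)[0] % (2**31))


_STAGE_NAMES = ("simulate", "events", "psi", "diff", "pathway", "survival", "network")


def run_all(config: PipelineConfig) -> Path:
    """Run every stage on the synthetic cohort; returns the run directory."""
    config.thresholds_ok()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "spliceaxis_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in _STAGE_NAMES},
        "stages": {},
    }

    # --- simulate ----------------------------------------------------------
    cohort_cfg = synthetic.SyntheticConfig(
        seed=_stage_seed(config.seed, "simulate"), **config.cohort
    )
    cohort = synthetic.simulate_cohort(cohort_cfg)
    paths = synthetic.write_cohort(cohort, outdir / "cohort")
    manifest["stages"]["simulate"] = {
        "n_tumor": cohort_cfg.n_tumor,
        "n_normal": cohort_cfg.n_normal,
        "n_transcripts": len(cohort.transcripts),
    }

    # --- events + psi (from the on-disk artifacts) -------------------------
    try:
        transcripts = io.read_gtf(paths["gtf"])
    except io.SpliceaxisError as e:
        raise io.SpliceaxisError(f"stage 'events' failed on {paths['gtf']}: {e}") from e
    events = ev.generate_events(transcripts)
    io.write_table(ev.events_table(events), outdir / "events.tsv")
    try:
        tx_tpm = io.read_matrix(paths["transcript_tpm"])
    except (io.SpliceaxisError, OSError, ValueError) as e:
        raise io.SpliceaxisError(
            f"stage 'psi' failed on {paths['transcript_tpm']}: {e}"
        ) from e
    psi = ev.psi_matrix(events, tx_tpm)
    etpm = ev.event_tpm_matrix(events, tx_tpm)
    io.write_matrix(psi.data, outdir / "psi.tsv")
    io.write_matrix(etpm, outdir / "event_tpm.tsv")
    manifest["stages"]["events"] = {"n_events": len(events)}
    annotations = io.read_annotations(paths["annotations"])

    # --- differential splicing --------------------------------------------
    diff_dir = outdir / "diff"
    diff_dir.mkdir(exist_ok=True)
    specs = (
        default_comparisons()
        if config.comparisons_path is None
        else differential.comparison_specs_from_config(
            io.read_yaml(config.comparisons_path)["comparisons"]
        )
    )
    counts = {}
    passing_sets = {}
    for spec in specs:
        spec.dpsi_min, spec.tpm_min, spec.alpha = (
            config.dpsi_min,
            config.tpm_min,
            config.alpha,
        )
        try:
            res = differential.run_comparison(psi, etpm, annotations, spec)
        except differential.ComparisonError as e:
            logger.warning("stage 'diff': skipping %s (%s)", spec.name, e)
            continue
        before = sum(r.passes for r in res)
        res = differential.filter_normals(res, psi, annotations, spec)
        after = sum(r.passes for r in res)
        io.write_table(
            differential.differential_table(res), diff_dir / f"{spec.name}.tsv"
        )
        counts[spec.name] = {"pass_before_normal_filter": before, "pass": after}
        passing_sets[spec.name] = {r.event_id for r in res if r.passes}
    io.write_table(
        pd.DataFrame(
            [{"comparison": k, **v} for k, v in sorted(counts.items())]
        ),
        diff_dir / "summary.tsv",
    )
    manifest["stages"]["diff"] = counts

    top = differential.top_variate_selection(psi, fraction=config.top_variance_fraction)
    embedding = differential.umap_embed(psi, top, seed=_stage_seed(config.seed, "diff"))
    io.write_table(embedding.reset_index(names="sample_id"), outdir / "umap.tsv")

    # --- pathway activity --------------------------------------------------
    pw_dir = outdir / "pathway"
    pw_dir.mkdir(exist_ok=True)
    gene_tpm = io.read_matrix(paths["gene_tpm"])
    tumor_ids = [a.sample_id for a in annotations if a.cohort == "tumor"]
    gene_sets = {gs.name: gs for gs in packaged_gmt()}
    nhej = pathway.define_activity_groups(
        gene_tpm, gene_sets["NHEJ"], config.q_low, config.q_high, samples=tumor_ids
    )
    io.write_table(
        pd.DataFrame(
            {"sample_id": nhej.score.index, "score": nhej.score.to_numpy(), "group": nhej.group.to_numpy()}
        ),
        pw_dir / "nhej_activity.tsv",
    )
    diff_high_low, burden = pathway.group_burden(
        psi, etpm, nhej, annotations,
        dpsi_min=config.dpsi_min, tpm_min=config.tpm_min, alpha=config.alpha,
    )
    io.write_table(
        differential.differential_table(diff_high_low), pw_dir / "nhej_high_vs_low.tsv"
    )
    freqs = pathway.frequency_series(
        pathway.splicing_frequency(psi, etpm, config.dpsi_min, config.tpm_min)
    )
    io.write_table(
        freqs.rename_axis("sample_id").reset_index(), pw_dir / "splicing_frequency.tsv"
    )
    ann_df = io.annotation_frame(annotations).loc[tumor_ids]
    enrich_rows = []
    for flag in ("mut_TP53", "biallelic_TENT5C", "biallelic_TP53", "apobec_high", "loh_high"):
        odds, p = pathway.enrichment_test(nhej.group, ann_df[flag])
        enrich_rows.append({"flag": flag, "odds_ratio": odds, "p": p})
    io.write_table(pd.DataFrame(enrich_rows), pw_dir / "nhej_enrichment.tsv")
    sv = pathway.compare_sv_counts(annotations, nhej.group)
    (pw_dir / "sv_counts.json").write_text(json.dumps(sv, indent=1, sort_keys=True))
    pass_counts = pd.Series(
        {k: v["pass"] for k, v in counts.items()}, dtype=float
    )
    fc = pathway.fold_change_matrix(
        gene_tpm, specs, annotations, sorted(gene_sets["SPLICEOSOME"].genes)
    )
    _, leaf_order = pathway.cluster_genes(fc)
    rho_rows = []
    for gene in fc.index:
        rho, flagged = pathway.correlate_fc_with_counts(fc.loc[gene], pass_counts)
        rho_rows.append({"gene": gene, "rho": rho, "rho_gt_0.65": flagged})
    io.write_table(
        pd.DataFrame(rho_rows).sort_values("gene", kind="stable"),
        pw_dir / "spliceosome_fc_correlation.tsv",
    )
    manifest["stages"]["pathway"] = {
        "burden": {k: (v if not isinstance(v, float) else round(v, 6)) for k, v in burden.items()},
        "cluster_leaf_order": leaf_order,
        "sv_means": sv["means"],
    }

    # --- survival -----------------------------------------------------------
    sv_dir = outdir / "survival"
    sv_dir.mkdir(exist_ok=True)
    surv = survival.survival_frame(annotations, "PFS")
    top200 = survival.expressed_top_variance_events(
        psi, etpm, top_k=config.top_k_events, tpm_min=config.tpm_min
    )
    design = survival.candidate_design(psi, top200, annotations)
    model = survival.backward_eliminate(design, surv, alpha=config.alpha, endpoint="PFS")
    model_json = {
        "endpoint": model.endpoint,
        "c_index": model.c_index,
        "n_candidates": len(model.candidates),
        "predictors": {
            str(k): {
                "hr": float(model.summary.loc[k, "hr"]),
                "ci_low": float(model.summary.loc[k, "ci_low"]),
                "ci_high": float(model.summary.loc[k, "ci_high"]),
                "p": float(model.summary.loc[k, "p"]),
            }
            for k in model.summary.index
        },
        "unfavorable_markers": list(model.unfavorable_markers),
    }
    (sv_dir / "risk_model.json").write_text(json.dumps(model_json, indent=1, sort_keys=True))
    marker_flags = design[model.unfavorable_markers].gt(0.5) if model.unfavorable_markers else pd.DataFrame(index=design.index)
    extra = ann_df.reindex(marker_flags.index)
    marker_flags = marker_flags.assign(nhej_high=extra["nhej_high"].astype(bool))
    tier, tier_info = survival.marker_accumulation(marker_flags, surv)
    io.write_table(
        pd.DataFrame({"sample_id": tier.index, "tier": tier.to_numpy()}),
        sv_dir / "risk_tiers.tsv",
    )
    (sv_dir / "tier_logrank.json").write_text(json.dumps(tier_info, indent=1, sort_keys=True, default=float))
    manifest["stages"]["survival"] = {
        "c_index": model.c_index,
        "n_predictors": int(model.summary.shape[0]),
        "tier_counts": tier_info["tier_counts"],
    }

    # --- networks ------------------------------------------------------------
    net_dir = outdir / "network"
    net_dir.mkdir(exist_ok=True)
    sf_genes = [g for g in packaged_sf_list() if g in gene_tpm.data.index]
    sf_expr = io.ExpressionMatrix(gene_tpm.data.loc[sf_genes])
    selected = differential.top_variate_selection(psi, top_n=config.network_events)
    psi_sel = ev.PsiMatrix(psi.data.loc[selected])
    nets = []
    for sg in config.network_subgroups:
        members = list(ann_df.index[ann_df[sg]])
        if len(members) < config.n_min_pairs:
            logger.warning("stage 'network': subgroup %s too small, skipped", sg)
            continue
        g = network.build_network(
            sf_expr, psi_sel, samples=members,
            rho_min=config.rho_min, n_min=config.n_min_pairs, subgroup=sg,
        )
        network.export_network(g, net_dir, prefix=sg)
        nets.append(g)
    if len(nets) >= 2:
        consistency = network.network_consistency(nets)
        io.write_table(consistency, net_dir / "consistency.tsv")
        manifest["stages"]["network"] = {
            "edges": {g.graph["subgroup"]: g.number_of_edges() for g in nets},
            "shared_all": int(consistency["in_all"].sum()) if len(consistency) else 0,
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    logger.info("run_all: complete -> %s", outdir)
    return outdir
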