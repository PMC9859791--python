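"""Synthetic multiple-myeloma cohort generator.

Emulates the data structure of a newly-diagnosed MM RNA-seq cohort (tumor
samples plus a small normal plasma-cell panel): a toy transcriptome whose
genes each instantiate one local AS event, transcript- and gene-level TPM
matrices, genomic subgroup annotations, survival endpoints and structural
variant counts — together with a ground-truth ledger so that every
downstream stage of the pipeline can be validated against what was planted.

Statistical structure:

* PSI is generated on the logit scale (logit-normal noise keeps values in
  (0, 1)); subgroup effects are planted as shifts of the target PSI mean.
* A latent per-sample DNA-damage activity factor drives NHEJ pathway gene
  expression and, with configurable coupling, the number of events in which
  a sample deviates from the cohort PSI median ("splicing frequency").
* Survival is exponential with log-hazard additive in marker flags and
  administrative censoring at a fixed horizon; SV counts are negative
  binomial with an elevated mean in NHEJ-high samples.

Defaults mirror the cohort scale of the study this package models:
598 tumors, 5 normals, translocation/hyperdiploidy subtype fractions at
their published population frequencies, SV means 87 vs 19, and an
NHEJ-splicing coupling of 0.7.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .events import ASEvent, EVENT_TYPES, PsiMatrix, generate_events
from .io import (
    ExpressionMatrix,
    SampleAnnotation,
    TranscriptModel,
    write_annotations,
    write_gtf,
    write_matrix,
)

# published population frequencies of the primary subtype axes and the
# most relevant secondary abnormalities
DEFAULT_SUBGROUP_FRACTIONS: dict[str, float] = {
    "t_11_14": 0.15,
    "t_4_14": 0.12,
    "t_14_16": 0.03,
    "t_14_20": 0.02,
    "t_6_14": 0.01,
    "hyperdiploid": 0.57,
    "gain1q": 0.30,
    "amp1q": 0.10,
    "del17p": 0.08,
    "mut_DIS3": 0.09,
    "mut_TENT5C": 0.08,
    "mut_TP53": 0.08,
    "mut_SF3B1": 0.04,
}

#: primary subtype flags assigned mutually exclusively
PRIMARY_FLAGS = ("t_11_14", "t_4_14", "t_14_16", "t_14_20", "t_6_14", "hyperdiploid")

DEFAULT_HAZARDS: dict[str, float] = {
    "nhej_high": math.log(1.7),
    "double_hit": math.log(2.0),
    "del17p": math.log(1.6),
    "amp1q": math.log(1.5),
    "t_4_14": math.log(1.3),
    "t_14_16": math.log(1.3),
}


@dataclass
class SyntheticConfig:
    """All knobs of the cohort generator (defaults are the study conditions)."""

    seed: int = 0
    n_tumor: int = 598
    n_normal: int = 5
    events_per_type: int = 72
    subgroup_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_FRACTIONS)
    )
    # planted differential-splicing effects; None derives a default plan
    planted_effects: list[tuple[str, str, float]] | None = None
    planted_subgroups: tuple[str, ...] = (
        "t_4_14",
        "t_11_14",
        "t_14_16",
        "biallelic_DIS3",
        "mut_SF3B1_hotspot",
    )
    n_planted_per_subgroup: int = 8
    planted_dpsi: float = 0.3
    amp1q_dpsi: float = 0.3
    gain1q_dpsi: float = 0.1
    psi_noise_sd: float = 0.25  # logit scale
    cell_type_specific_fraction: float = 0.08
    cell_type_shift: float = 0.25  # PSI scale, tumor-wide vs normal
    n_frequency_events: int = 200
    frequency_dpsi: float = 0.3
    frequency_p_range: tuple[float, float] = (0.02, 0.6)
    nhej_coupling: float = 0.7
    expression_noise_sd: float = 0.2  # log2 scale
    pathway_effect: float = 1.0  # log2 shift per latent s.d. on NHEJ genes
    hsp_effect: float = 0.5  # milder coupling of the HSP spliceosome block
    sf_coupling_rho: float = 0.6
    n_sf_couplings: int = 10
    n_background_genes: int = 100
    gene_log2_tpm_mean: float = 5.0
    gene_log2_tpm_sd: float = 1.0
    hazard_log_hr: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    baseline_hazard: float = 2.8e-4  # per day
    os_hazard_scale: float = 0.5  # OS hazard relative to PFS hazard
    censor_horizon_days: float = 2555.0
    sv_mean_high: float = 87.0
    sv_mean_low: float = 19.0
    sv_dispersion: float = 2.0

    def validate(self) -> None:
        if self.events_per_type < 1:
            raise ValueError("events_per_type must be >= 1")
        for k, v in self.subgroup_fractions.items():
            if not 0 <= v <= 1:
                raise ValueError(f"fraction {k}={v} outside [0,1]")
        if abs(self.planted_dpsi) > 1 or abs(self.gain1q_dpsi) > 1:
            raise ValueError("|planted dPSI| must be <= 1")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    planted_events: dict[str, dict[str, float]]
    cell_type_specific: dict[str, float]
    frequency_events: list[str]
    true_frequency: pd.Series
    nhej_latent: pd.Series
    nhej_group: pd.Series
    sf_couplings: list[tuple[str, str, float]]
    marker_hazards: dict[str, float]

    def to_json(self) -> str:
        obj = {
            "planted_events": self.planted_events,
            "cell_type_specific": self.cell_type_specific,
            "frequency_events": list(self.frequency_events),
            "true_frequency": self.true_frequency.to_dict(),
            "nhej_latent": {k: float(v) for k, v in self.nhej_latent.items()},
            "nhej_group": self.nhej_group.to_dict(),
            "sf_couplings": [list(c) for c in self.sf_couplings],
            "marker_hazards": self.marker_hazards,
        }
        return json.dumps(obj, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    transcripts: list[TranscriptModel]
    events: list[ASEvent]
    transcript_tpm: ExpressionMatrix
    gene_tpm: ExpressionMatrix
    psi_true: PsiMatrix
    annotations: list[SampleAnnotation]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# transcriptome templates: each gene instantiates exactly one event
# ---------------------------------------------------------------------------

# exon chains for the two forms of each type, on a 10-kb local scale;
# keys are the event type realised on the '+' strand
_PLUS_TEMPLATES: dict[str, tuple[tuple, tuple]] = {
    "SE": (((100, 200), (300, 400), (500, 600)), ((100, 200), (500, 600))),
    "RI": (((100, 400),), ((100, 200), (300, 400))),
    "A5": (((100, 250), (500, 600)), ((100, 200), (500, 600))),
    "A3": (((100, 200), (400, 600)), ((100, 200), (500, 600))),
    "MX": (
        ((100, 200), (300, 400), (700, 800)),
        ((100, 200), (500, 600), (700, 800)),
    ),
    "AF": (((100, 200), (500, 600)), ((300, 400), (500, 600))),
    "AL": (((100, 200), (300, 400)), ((100, 200), (500, 600))),
}

# realising a strand-relative type on the '-' strand uses the mirror
# template of its partner type (AF<->AL, A5<->A3); SE/RI/MX are symmetric
_MINUS_SOURCE = {"SE": "SE", "RI": "RI", "MX": "MX", "A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF"}


def build_transcriptome(
    config: SyntheticConfig,
) -> tuple[list[TranscriptModel], list[ASEvent]]:
    """One gene per requested event; alternating strands per type.

    Gene ``G_<TYPE>_<k>`` carries two transcripts (``..._in`` the inclusion
    form, ``..._ex`` the exclusion form) instantiating exactly one event of
    ``<TYPE>``.  Even-numbered genes are on '+', odd-numbered on '-', so the
    strand-relative types (A5/A3/AF/AL) are exercised on both strands.
    """
    config.validate()
    transcripts: list[TranscriptModel] = []
    offset = 0
    for etype in EVENT_TYPES:
        for k in range(config.events_per_type):
            strand = "+" if k % 2 == 0 else "-"
            template = etype if strand == "+" else _MINUS_SOURCE[etype]
            inc_exons, exc_exons = _PLUS_TEMPLATES[template]
            gene = f"G_{etype}_{k:04d}"
            chrom = f"chr{1 + (offset // 200)}"
            base = 10_000 * (offset % 200) + 1
            offset += 1
            for suffix, exons in (("in", inc_exons), ("ex", exc_exons)):
                transcripts.append(
                    TranscriptModel(
                        transcript_id=f"{gene}_{suffix}",
                        gene_id=gene,
                        chrom=chrom,
                        strand=strand,
                        exons=tuple((base + s, base + e) for s, e in exons),
                    )
                )
    events = generate_events(transcripts)
    assert len(events) == 7 * config.events_per_type
    # sanity: templates must yield the advertised type with the '_in'
    # transcript as the inclusion form
    for ev in events:
        expected = ev.gene_id.split("_")[1]
        if ev.event_type != expected or ev.inclusion_transcripts != {
            f"{ev.gene_id}_in"
        }:
            raise AssertionError(f"template mismatch for {ev.event_id}")
    return transcripts, events


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def _exact_subset(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with an exact round(fraction*n) positives, random placement."""
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


def simulate_annotations(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[SampleAnnotation], pd.Series]:
    """Sample ids, genomic flags and clinical covariates; returns the latent
    NHEJ activity factor alongside (needed by expression simulation)."""
    n = config.n_tumor
    tumor_ids = [f"MM{i + 1:04d}" for i in range(n)]
    normal_ids = [f"NPC{i + 1:02d}" for i in range(config.n_normal)]
    latent = pd.Series(rng.standard_normal(n), index=tumor_ids, name="nhej_latent")
    ranks = latent.rank(method="first")
    tertile = pd.cut(ranks, bins=3, labels=["low", "mid", "high"]).astype(str)

    frac = config.subgroup_fractions
    flags = pd.DataFrame(False, index=tumor_ids, columns=[])
    # mutually exclusive primary subtypes, exact composition
    primary = [f for f in PRIMARY_FLAGS if frac.get(f, 0) > 0]
    counts = {f: int(round(frac[f] * n)) for f in primary}
    order = rng.permutation(n)
    pos = 0
    for f in primary:
        idx = order[pos : pos + counts[f]]
        col = np.zeros(n, dtype=bool)
        col[idx] = True
        flags[f] = col
        pos += counts[f]
    # 1q: gain and amp mutually exclusive
    order = rng.permutation(n)
    n_amp = int(round(frac.get("amp1q", 0) * n))
    n_gain = int(round(frac.get("gain1q", 0) * n))
    amp = np.zeros(n, dtype=bool)
    gain = np.zeros(n, dtype=bool)
    amp[order[:n_amp]] = True
    gain[order[n_amp : n_amp + n_gain]] = True
    flags["amp1q"], flags["gain1q"] = amp, gain
    flags["del17p"] = _exact_subset(rng, n, frac.get("del17p", 0))
    # del13q rides with t(4;14) (95% co-occurrence), background ~45%
    p13 = np.where(flags.get("t_4_14", np.zeros(n, dtype=bool)), 0.95, 0.45)
    flags["del13q"] = rng.random(n) < p13
    # mutation flags; TP53/TENT5C enriched in latent-high samples
    high = (tertile == "high").to_numpy()
    for gene_flag in ("mut_DIS3", "mut_TENT5C", "mut_TP53", "mut_SF3B1"):
        p = frac.get(gene_flag, 0)
        if gene_flag in ("mut_TP53", "mut_TENT5C"):
            pv = np.where(high, 2.0 * p, 0.6 * p)
        elif gene_flag == "mut_DIS3":
            pv = np.where(flags.get("t_4_14", np.zeros(n, dtype=bool)), 2.5 * p, 0.8 * p)
        else:
            pv = np.full(n, p)
        flags[gene_flag] = rng.random(n) < np.clip(pv, 0, 1)
    flags["mut_SF3B1_hotspot"] = flags["mut_SF3B1"] & (rng.random(n) < 0.5)
    for gene in ("DIS3", "TENT5C", "TP53"):
        flags[f"biallelic_{gene}"] = flags[f"mut_{gene}"] & (rng.random(n) < 0.5)
    flags["double_hit"] = flags["biallelic_TP53"] | (flags["amp1q"] & flags["del17p"])
    flags["apobec_high"] = _exact_subset(rng, n, 0.10)
    flags["nhej_high"] = high

    loh = rng.beta(1.5, 40.0, size=n)
    age = np.clip(rng.normal(65, 10, size=n), 30, 92)
    iss = rng.choice([1, 2, 3], size=n, p=[0.35, 0.35, 0.30])

    annotations = [
        SampleAnnotation(
            sample_id=sid,
            cohort="tumor",
            flags={c: bool(flags.loc[sid, c]) for c in flags.columns},
            age=float(age[i]),
            iss_stage=int(iss[i]),
            loh_fraction=float(loh[i]),
        )
        for i, sid in enumerate(tumor_ids)
    ]
    annotations += [
        SampleAnnotation(sample_id=sid, cohort="normal") for sid in normal_ids
    ]
    return annotations, latent


# ---------------------------------------------------------------------------
# expression + PSI
# ---------------------------------------------------------------------------

NHEJ_GENES = (
    "XRCC4", "LIG4", "XRCC5", "XRCC6", "PRKDC", "DCLRE1C", "NHEJ1",
    "POLL", "POLM", "DNTT", "MRE11", "RAD50", "FEN1",
)
HR_GENES = (
    "BRCA1", "BRCA2", "RAD51", "RAD52", "RAD54L", "PALB2", "XRCC2",
    "XRCC3", "BRIP1", "BARD1",
)
MMEJ_GENES = ("POLQ", "PARP1", "LIG1", "LIG3", "XRCC1", "NBN")
HSP_GENES = ("HSPA1A", "HSPA1B", "HSPA6", "HSPA8", "HSPA1L")
SPLICEOSOME_EXTRA = (
    "SF3B1", "SF3A1", "SNRPA", "SNRPB", "SNRPD1", "PRPF8", "PRPF19",
    "EFTUD2", "SNRNP200", "U2AF1", "U2AF2", "SRSF1", "SRSF2", "LSM2", "DDX5",
)

SPLICING_FACTORS = (
    "SRSF1", "SRSF2", "SRSF3", "SRSF4", "SRSF5", "SRSF6", "SRSF7", "SRSF8",
    "SRSF9", "SRSF10", "SRSF11", "SRSF12",
    "HNRNPA1", "HNRNPA2B1", "HNRNPC", "HNRNPD", "HNRNPF", "HNRNPH1",
    "HNRNPH3", "HNRNPK", "HNRNPL", "HNRNPM", "HNRNPU",
    "U2AF1", "U2AF2", "SF1", "SF3A1", "SF3A2", "SF3A3", "SF3B1", "SF3B2",
    "SF3B3", "SF3B4",
    "RBM5", "RBM10", "RBM17", "RBM22", "RBM25", "RBM39",
    "PTBP1", "PTBP2", "ELAVL1", "ELAVL2", "CELF1", "CELF2",
    "MBNL1", "MBNL2", "MBNL3",
    "QKI", "FUS", "TARDBP", "EWSR1", "TIA1", "TIAL1", "KHDRBS1",
    "TRA2A", "TRA2B", "ESRP1", "ESRP2", "NOVA1", "NOVA2",
    "SRPK1", "SRPK2", "CLK1", "DDX17", "DDX39B", "SNRNP70", "RBFOX1",
    "RBFOX2",
)
assert len(set(SPLICING_FACTORS)) == 69


def _round_robin_events(events: Sequence[ASEvent]) -> list[ASEvent]:
    """Interleave events across the 7 types so planted blocks mix types."""
    by_type: dict[str, list[ASEvent]] = {t: [] for t in EVENT_TYPES}
    for ev in events:
        by_type[ev.event_type].append(ev)
    out: list[ASEvent] = []
    i = 0
    while any(by_type.values()):
        t = EVENT_TYPES[i % 7]
        if by_type[t]:
            out.append(by_type[t].pop(0))
        i += 1
    return out


def _planted_plan(
    config: SyntheticConfig, events: Sequence[ASEvent]
) -> tuple[dict[str, dict[str, float]], dict[str, float], list[str]]:
    """Assign event blocks: cell-type-specific, per-subgroup planted,
    frequency-responsive.  Deterministic in the catalog order."""
    ordered = _round_robin_events(events)
    cursor = 0
    n_cts = int(round(config.cell_type_specific_fraction * len(ordered)))
    cts: dict[str, float] = {}
    for ev in ordered[cursor : cursor + n_cts]:
        cts[ev.event_id] = config.cell_type_shift
    cursor += n_cts

    planted: dict[str, dict[str, float]] = {}
    if config.planted_effects is not None:
        for flag, event_id, dpsi in config.planted_effects:
            planted.setdefault(flag, {})[event_id] = float(dpsi)
    else:
        for flag in config.planted_subgroups:
            block = ordered[cursor : cursor + config.n_planted_per_subgroup]
            cursor += config.n_planted_per_subgroup
            planted[flag] = {ev.event_id: config.planted_dpsi for ev in block}
        # 1q escalation: same events, smaller effect for gain than amp
        block = ordered[cursor : cursor + config.n_planted_per_subgroup]
        cursor += config.n_planted_per_subgroup
        planted["amp1q"] = {ev.event_id: config.amp1q_dpsi for ev in block}
        planted["gain1q"] = {ev.event_id: config.gain1q_dpsi for ev in block}

    used = set(cts) | {e for d in planted.values() for e in d}
    freq_pool = [ev.event_id for ev in ordered if ev.event_id not in used]
    freq_events = freq_pool[: config.n_frequency_events]
    return planted, cts, freq_events


def simulate_expression(
    config: SyntheticConfig,
    transcripts: Sequence[TranscriptModel],
    events: Sequence[ASEvent],
    annotations: Sequence[SampleAnnotation],
    latent: pd.Series,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PsiMatrix, GroundTruth]:
    """Generate transcript/gene TPM and the true PSI matrix."""
    tumor_ids = [a.sample_id for a in annotations if a.cohort == "tumor"]
    normal_ids = [a.sample_id for a in annotations if a.cohort == "normal"]
    samples = tumor_ids + normal_ids
    flag_frame = pd.DataFrame(
        {a.sample_id: a.flags for a in annotations}
    ).T.loc[samples]

    planted, cts, freq_events = _planted_plan(config, events)
    event_ids = [ev.event_id for ev in events]
    n_ev, n_s = len(events), len(samples)

    base = rng.uniform(0.25, 0.75, size=n_ev)
    base_s = pd.Series(base, index=event_ids)
    # direction of any planted shift: toward the farther PSI boundary
    direction = np.where(base < 0.5, 1.0, -1.0)
    dir_s = pd.Series(direction, index=event_ids)

    target = np.tile(base[:, None], (1, n_s))
    is_tumor = np.array([s in set(tumor_ids) for s in samples])
    for eid, shift in cts.items():
        i = event_ids.index(eid)
        target[i, is_tumor] += dir_s[eid] * shift
    for flag, block in planted.items():
        if flag not in flag_frame.columns:
            continue
        carriers = flag_frame[flag].to_numpy(dtype=bool) & is_tumor
        for eid, dpsi in block.items():
            i = event_ids.index(eid)
            target[i, carriers] += dir_s[eid] * dpsi

    # latent splicing-frequency propensity coupled to NHEJ activity
    rho = config.nhej_coupling
    eps = rng.standard_normal(len(tumor_ids))
    s_lat = rho * latent.loc[tumor_ids].to_numpy() + math.sqrt(max(0.0, 1 - rho**2)) * eps
    p_lo, p_hi = config.frequency_p_range
    p_dev = p_lo + (p_hi - p_lo) * norm.cdf(s_lat)
    freq_idx = [event_ids.index(e) for e in freq_events]
    deviates = rng.random((len(freq_idx), len(tumor_ids))) < p_dev[None, :]
    for row, i in enumerate(freq_idx):
        cols = np.flatnonzero(is_tumor)[deviates[row]]
        target[i, cols] += direction[i] * config.frequency_dpsi
    true_freq = pd.Series(
        deviates.sum(axis=0), index=tumor_ids, name="true_frequency"
    )

    target = np.clip(target, 0.01, 0.99)
    noise = rng.normal(0.0, config.psi_noise_sd, size=target.shape)
    psi = expit(logit(target) + noise)
    psi_df = pd.DataFrame(psi, index=event_ids, columns=samples)

    # gene expression
    event_genes = sorted({ev.gene_id for ev in events})
    pathway_genes = sorted(
        set(NHEJ_GENES) | set(HR_GENES) | set(MMEJ_GENES) | set(HSP_GENES)
        | set(SPLICEOSOME_EXTRA) | set(SPLICING_FACTORS)
    )
    background = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    genes = event_genes + pathway_genes + background
    mu = config.gene_log2_tpm_mean + rng.normal(
        0.0, config.gene_log2_tpm_sd, size=len(genes)
    )
    coupling = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g in NHEJ_GENES:
            coupling[i] = config.pathway_effect
        elif g in HSP_GENES:
            coupling[i] = config.hsp_effect
    a_all = np.concatenate([latent.loc[tumor_ids].to_numpy(), np.zeros(len(normal_ids))])
    log2 = (
        mu[:, None]
        + coupling[:, None] * a_all[None, :]
        + rng.normal(0.0, config.expression_noise_sd, size=(len(genes), n_s))
    )
    gene_df = pd.DataFrame(
        np.maximum(np.exp2(log2) - 1.0, 0.0), index=genes, columns=samples
    )

    # planted SF-event couplings: SF log2 expression follows the event's
    # realised logit-PSI at a fixed target correlation
    sf_couplings: list[tuple[str, str, float]] = []
    # couple SFs to the variable (frequency-responsive) events when present:
    # those carry real cross-sample variance, as SF-driven events would
    pool = list(freq_events) + [
        e for e in event_ids if e not in cts and e not in freq_events
    ]
    targets = pool[: config.n_sf_couplings]
    r = config.sf_coupling_rho
    lam = config.expression_noise_sd * r / math.sqrt(max(1e-12, 1 - r**2))
    sf_pool = ["HNRNPH1"] + [g for g in SPLICING_FACTORS if g != "HNRNPH1"]
    for sf, eid in zip(sf_pool[: config.n_sf_couplings], targets):
        z = logit(np.clip(psi_df.loc[eid].to_numpy(), 1e-6, 1 - 1e-6))
        z = (z - z.mean()) / max(z.std(), 1e-9)
        i = genes.index(sf)
        gene_df.loc[sf] = np.maximum(
            np.exp2(
                mu[i] + lam * z + rng.normal(0.0, config.expression_noise_sd, size=n_s)
            )
            - 1.0,
            0.0,
        )
        sf_couplings.append((sf, eid, r))

    # transcript TPM: gene TPM split by the true PSI for event genes
    tx_index = []
    tx_values = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    ev_by_gene = {ev.gene_id: ev for ev in events}
    for gene in event_genes:
        ev = ev_by_gene[gene]
        g_tpm = gene_df.loc[gene].to_numpy()
        p = psi_df.loc[ev.event_id].to_numpy()
        for t in sorted(by_gene[gene], key=lambda t: t.transcript_id):
            share = p if t.transcript_id in ev.inclusion_transcripts else 1.0 - p
            tx_index.append(t.transcript_id)
            tx_values.append(g_tpm * share)
    tx_df = pd.DataFrame(tx_values, index=tx_index, columns=samples)

    tumor_rank = latent.loc[tumor_ids].rank(method="first")
    nhej_group = pd.cut(tumor_rank, bins=3, labels=["low", "mid", "high"]).astype(str)

    truth = GroundTruth(
        planted_events=planted,
        cell_type_specific=cts,
        frequency_events=freq_events,
        true_frequency=true_freq,
        nhej_latent=latent.loc[tumor_ids],
        nhej_group=nhej_group,
        sf_couplings=sf_couplings,
        marker_hazards=dict(config.hazard_log_hr),
    )
    return (
        ExpressionMatrix(tx_df),
        ExpressionMatrix(gene_df),
        PsiMatrix(psi_df),
        truth,
    )


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def simulate_outcomes(
    config: SyntheticConfig,
    annotations: Sequence[SampleAnnotation],
    rng: np.random.Generator,
) -> list[SampleAnnotation]:
    """Fill survival endpoints and SV counts in place (tumors only).

    Survival is exponential with log-hazard additive in the configured
    marker effects; censoring is administrative at the config horizon.
    """
    for a in annotations:
        if a.cohort != "tumor":
            continue
        lp = sum(
            beta for flag, beta in config.hazard_log_hr.items() if a.flags.get(flag)
        )
        for endpoint, scale in (("pfs", 1.0), ("os", config.os_hazard_scale)):
            lam = config.baseline_hazard * scale * math.exp(lp)
            t = rng.exponential(1.0 / lam)
            observed = t <= config.censor_horizon_days
            setattr(a, f"{endpoint}_days", float(min(t, config.censor_horizon_days)))
            setattr(a, f"{endpoint}_event", int(observed))
        mean = config.sv_mean_high if a.flags.get("nhej_high") else config.sv_mean_low
        size = config.sv_dispersion
        a.sv_count = int(rng.negative_binomial(size, size / (size + mean)))
    return list(annotations)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Build the full synthetic cohort deterministically from the seed."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_ann = np.random.default_rng(streams[0])
    rng_expr = np.random.default_rng(streams[1])
    rng_out = np.random.default_rng(streams[2])
    transcripts, events = build_transcriptome(config)
    annotations, latent = simulate_annotations(config, rng_ann)
    tx_tpm, gene_tpm, psi_true, truth = simulate_expression(
        config, transcripts, events, annotations, latent, rng_expr
    )
    annotations = simulate_outcomes(config, annotations, rng_out)
    return SyntheticCohort(
        config=config,
        transcripts=transcripts,
        events=events,
        transcript_tpm=tx_tpm,
        gene_tpm=gene_tpm,
        psi_true=psi_true,
        annotations=annotations,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort artifacts; returns the path of each."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": outdir / "transcriptome.gtf",
        "transcript_tpm": outdir / "transcript_tpm.tsv",
        "gene_tpm": outdir / "gene_tpm.tsv",
        "annotations": outdir / "annotations.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "cohort_config.json",
    }
    write_gtf(cohort.transcripts, paths["gtf"])
    write_matrix(cohort.transcript_tpm, paths["transcript_tpm"])
    write_matrix(cohort.gene_tpm, paths["gene_tpm"])
    write_annotations(cohort.annotations, paths["annotations"])
    paths["ground_truth"].write_text(cohort.truth.to_json())
    cfg = asdict(cohort.config)
    cfg["planted_effects"] = (
        None
        if cohort.config.planted_effects is None
        else [list(x) for x in cohort.config.planted_effects]
    )
    paths["config"].write_text(json.dumps(cfg, indent=1, sort_keys=True, default=list))
    return paths


# ---------------------------------------------------------------------------
# random toy genes (validation substrate for the event calculus)
# ---------------------------------------------------------------------------


def random_toy_genes(
    n_genes: int,
    seed: int | np.random.Generator = 0,
    max_transcripts: int = 5,
    n_slots: int = 5,
) -> list[TranscriptModel]:
    """Random small gene models that exercise all seven event types.

    Each gene draws 2..max_transcripts transcripts over a shared grid of
    exon "slots" with variant start/end boundaries; adjacent chosen slots
    are occasionally fused into one exon (creating retained introns).
    Transcripts have at most ``n_slots + 3`` exons.  Strand is random.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    models: list[TranscriptModel] = []
    for g in range(n_genes):
        gene = f"TOY{g + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(2, max_transcripts + 1))
        starts = [(1000 * k + 100, 1000 * k + 180) for k in range(n_slots)]
        ends = [(1000 * k + 420, 1000 * k + 500) for k in range(n_slots)]
        for t in range(n_tx):
            keep = [k for k in range(n_slots) if rng.random() < 0.7]
            if not keep:
                keep = [int(rng.integers(0, n_slots))]
            exons = []
            for k in keep:
                s = starts[k][int(rng.integers(0, 2))]
                e = ends[k][int(rng.integers(0, 2))]
                exons.append((s, e))
            # fuse some adjacent exon pairs into retained-intron exons
            fused = []
            i = 0
            while i < len(exons):
                if i + 1 < len(exons) and rng.random() < 0.15:
                    fused.append((exons[i][0], exons[i + 1][1]))
                    i += 2
                else:
                    fused.append(exons[i])
                    i += 1
            models.append(
                TranscriptModel(
                    transcript_id=f"{gene}_T{t + 1}",
                    gene_id=gene,
                    chrom="chrT",
                    strand=strand,
                    exons=tuple(fused),
                )
            )
    return models
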