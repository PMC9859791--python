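import numpy as np
import pandas as pd
import pytest

from spliceaxis.io import TranscriptModel, ExpressionMatrix
from spliceaxis.synthetic import SyntheticConfig, simulate_cohort


def make_transcript(tid, gene, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand, exons=tuple(exons)
    )


@pytest.fixture
def se_gene():
    """Cassette-exon gene: A carries the exon, B skips it."""
    return [
        make_transcript("A", "G1", [(100, 200), (300, 400), (500, 600)]),
        make_transcript("B", "G1", [(100, 200), (500, 600)]),
    ]


@pytest.fixture
def se_tpm():
    return ExpressionMatrix(
        pd.DataFrame(
            {"s1": [3.0, 1.0], "s2": [0.0, 0.0], "s3": [2.0, 2.0]},
            index=["A", "B"],
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced two-arm cohort used across module tests."""
    cfg = SyntheticConfig(
        seed=11,
        n_tumor=60,
        n_normal=4,
        events_per_type=6,
        subgroup_fractions={"t_4_14": 0.5},
        planted_subgroups=("t_4_14",),
        n_planted_per_subgroup=4,
        cell_type_specific_fraction=0.1,
        n_frequency_events=12,
        n_background_genes=20,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_cohort():
    """30 vs 30 samples, ~500 events, 50 planted at |dPSI| = 0.3, logit
    noise sd 0.08 — the differential-splicing recovery condition."""
    cfg = SyntheticConfig(
        seed=101,
        n_tumor=60,
        n_normal=5,
        events_per_type=72,
        subgroup_fractions={"t_4_14": 0.5},
        planted_subgroups=("t_4_14",),
        n_planted_per_subgroup=50,
        planted_dpsi=0.3,
        psi_noise_sd=0.08,
        cell_type_specific_fraction=0.0,
        n_frequency_events=0,
        n_background_genes=10,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def coupling_cohort():
    """300 tumors with the NHEJ-splicing-frequency coupling at 0.7."""
    cfg = SyntheticConfig(
        seed=202,
        n_tumor=300,
        n_normal=3,
        events_per_type=72,
        subgroup_fractions={},
        planted_subgroups=(),
        n_planted_per_subgroup=0,
        nhej_coupling=0.7,
        n_background_genes=20,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects anywhere; >= 2000 events for type-I calibration."""
    cfg = SyntheticConfig(
        seed=303,
        n_tumor=60,
        n_normal=3,
        events_per_type=290,
        subgroup_fractions={"t_4_14": 0.5},
        planted_subgroups=(),
        n_planted_per_subgroup=0,
        amp1q_dpsi=0.0,
        gain1q_dpsi=0.0,
        cell_type_specific_fraction=0.0,
        n_frequency_events=0,
        n_background_genes=5,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
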