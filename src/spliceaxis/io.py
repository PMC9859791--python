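"""Readers and writers for the formats the pipeline touches.

All genomic coordinates are 1-based inclusive (GTF native) throughout the
package.  Matrices are features-in-rows, samples-in-columns, tab-separated,
``NA`` for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: LOH fraction above which a sample is called LOH-high.
LOH_HIGH_THRESHOLD = 0.046

#: Boolean genomic-subgroup flags carried by every sample annotation.
FLAG_COLUMNS = (
    "t_4_14",
    "t_11_14",
    "t_14_16",
    "t_6_14",
    "t_14_20",
    "hyperdiploid",
    "gain1q",
    "amp1q",
    "del17p",
    "del13q",
    "mut_DIS3",
    "mut_TENT5C",
    "mut_TP53",
    "mut_SF3B1",
    "mut_SF3B1_hotspot",
    "biallelic_DIS3",
    "biallelic_TENT5C",
    "biallelic_TP53",
    "double_hit",
    "apobec_high",
    "loh_high",
    "nhej_high",
)

_NUMERIC_COLUMNS = (
    "age",
    "iss_stage",
    "loh_fraction",
    "sv_count",
    "pfs_days",
    "pfs_event",
    "os_days",
    "os_event",
)


class SpliceaxisError(Exception):
    """Base class for pipeline errors."""


class ParseError(SpliceaxisError):
    """Malformed input file."""


class ValidationError(SpliceaxisError):
    """Input violates a documented invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript.

    Exons are ``(start, end)`` pairs, 1-based inclusive, sorted ascending by
    start and pairwise non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if start > end:
                raise ValidationError(
                    f"{self.transcript_id}: exon {start}-{end} has start > end"
                )
            if prev_end is not None and start <= prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons near {start}"
                )
            prev_end = end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Junctions as (donor-exon end, acceptor-exon start) pairs."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


class ExpressionMatrix:
    """Feature x sample non-negative abundance matrix (TPM)."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = data.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValidationError("negative TPM values")
        self.data = data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.data.shape[0]} features x {self.data.shape[1]} samples)"


@dataclass
class SampleAnnotation:
    """Genomic, clinical and survival annotation of one sample."""

    sample_id: str
    cohort: str = "tumor"
    flags: dict[str, bool] = field(default_factory=dict)
    age: float | None = None
    iss_stage: int | None = None
    loh_fraction: float | None = None
    sv_count: int | None = None
    pfs_days: float | None = None
    pfs_event: int | None = None
    os_days: float | None = None
    os_event: int | None = None

    def __post_init__(self) -> None:
        if self.cohort not in ("tumor", "normal"):
            raise ValidationError(f"{self.sample_id}: bad cohort {self.cohort!r}")
        self.flags = {k: bool(self.flags.get(k, False)) for k in FLAG_COLUMNS}
        if self.loh_fraction is not None and not np.isnan(self.loh_fraction):
            self.flags["loh_high"] = self.loh_fraction > LOH_HIGH_THRESHOLD
        for col in ("pfs_days", "os_days"):
            v = getattr(self, col)
            if v is not None and not np.isnan(v) and v <= 0:
                raise ValidationError(f"{self.sample_id}: {col} must be > 0")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (GMT record)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name}: empty")


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon records from a GTF into transcript models.

    Exons are merged per transcript and sorted; coordinates are kept 1-based
    inclusive as in the file.
    """
    import pyranges as pr

    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "exon"]
    if df.empty:
        return []
    for attr in ("transcript_id", "gene_id"):
        if attr not in df.columns or df[attr].isna().any() or (df[attr] == "").any():
            bad = _find_bad_gtf_line(path, attr)
            raise ParseError(f"{path}: line {bad}: exon record missing {attr}")
    models: list[TranscriptModel] = []
    # pyranges uses 0-based half-open starts internally; restore GTF coords.
    for (tid, gid), grp in df.groupby(["transcript_id", "gene_id"], sort=True):
        exons = sorted(
            (int(s) + 1, int(e)) for s, e in zip(grp["Start"], grp["End"])
        )
        merged: list[tuple[int, int]] = []
        for start, end in exons:
            if merged and start <= merged[-1][1] + 0:
                if start <= merged[-1][1]:
                    raise ValidationError(
                        f"{path}: transcript {tid}: overlapping exons at {start}"
                    )
            merged.append((start, end))
        strand = str(grp["Strand"].iloc[0])
        chrom = str(grp["Chromosome"].iloc[0])
        models.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=str(gid),
                chrom=chrom,
                strand=strand,
                exons=tuple(merged),
            )
        )
    logger.info("read_gtf: %d transcripts from %s", len(models), path)
    return models


def _find_bad_gtf_line(path: Path, attr: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 8 and fields[2] == "exon" and f'{attr} "' not in line:
                return i
    return -1


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF exon records."""
    with open(path, "w") as fh:
        for t in transcripts:
            for start, end in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\tspliceaxis\texon\t{start}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a feature x sample TSV matrix (first column: feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ExpressionMatrix(df)


def write_matrix(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", na_rep="NA")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the sample annotation TSV.

    Unknown columns are ignored with a warning; boolean flags accept
    0/1/true/false.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    known = {"sample_id", "cohort", *FLAG_COLUMNS, *_NUMERIC_COLUMNS}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("read_annotations: ignoring unknown columns %s", unknown)
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in annotation table")
    out: list[SampleAnnotation] = []
    for _, row in df.iterrows():
        flags = {}
        for flag in FLAG_COLUMNS:
            if flag in df.columns and not pd.isna(row[flag]):
                flags[flag] = bool(_as_bool(row[flag]))
        kwargs = {}
        for col in _NUMERIC_COLUMNS:
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = row[col]
        out.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                cohort=str(row.get("cohort", "tumor")),
                flags=flags,
                **kwargs,
            )
        )
    return out


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "t", "yes")
    return bool(value)


def annotation_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Tabular view of annotations, indexed by sample id."""
    rows = []
    for a in annotations:
        row: dict[str, object] = {"sample_id": a.sample_id, "cohort": a.cohort}
        row.update(a.flags)
        for col in _NUMERIC_COLUMNS:
            row[col] = getattr(a, col)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    for flag in FLAG_COLUMNS:
        df[flag] = df[flag].astype(bool)
    return df


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    df = annotation_frame(annotations).reset_index()
    for flag in FLAG_COLUMNS:
        df[flag] = df[flag].astype(int)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {i}: GMT needs >= 3 fields")
            genes = [g for g in fields[2:] if g]
            if len(set(genes)) != len(genes):
                raise ValidationError(f"{path}: line {i}: duplicate genes")
            sets.append(GeneSet(name=fields[0], description=fields[1], genes=frozenset(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{s.description}\t{genes}\n")


def write_table(rows: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a generic result table as TSV with NA for missing."""
    rows.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True)
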