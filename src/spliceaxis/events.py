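"""Local alternative-splicing event generation and PSI quantification.

Seven event types are generated from transcript models: skipped exon (SE),
retained intron (RI), alternative 5'/3' splice site (A5/A3), mutually
exclusive exons (MX), and alternative first/last exon (AF/AL).  Every event
is a *two-form* contrast between an inclusion and an exclusion set of
transcripts of one gene; PSI is the TPM of the inclusion form divided by the
TPM of both forms.  Multi-form sites are emitted as pairwise two-form
events.

Classification contracts (strand-relative where it matters):

* SE — a cassette exon with both flanking junctions present in the inclusion
  transcripts and a single flank-to-flank junction in the exclusion
  transcripts; flanking boundaries shared.
* RI — an unspliced exon spanning exactly the two exons (shared outer
  boundaries) that another transcript splits by an intron.  Inclusion =
  retention.
* A5/A3 — two introns sharing one boundary whose alternative-boundary exons
  overlap (the same exon lengthened or shortened).  A boundary on the
  donor side is a 5' event on '+' and a 3' event on '-'.  Inclusion = the
  shorter-intron (longer-exon) form.
* AF/AL — two introns sharing one boundary whose alternative exons do NOT
  overlap and are genuine terminal (first resp. last, strand-relative)
  exons of their transcripts.  Inclusion = the form whose alternative exon
  starts at the smaller genomic coordinate.
* MX — two non-overlapping cassette exons with identical flanking
  boundaries that never co-occur in one transcript.  Inclusion = the form
  whose cassette starts at the smaller genomic coordinate.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TranscriptModel, ValidationError

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "RI", "A5", "A3", "MX", "AF", "AL")

#: Minimum summed TPM over both forms for PSI to be defined.
DENOM_MIN = 1e-3


@dataclass(frozen=True)
class ASEvent:
    """One local splicing event with its two transcript forms."""

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    event_type: str
    coordinates: tuple[int, ...]
    inclusion_transcripts: frozenset[str]
    total_transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_transcripts:
            raise ValidationError(f"{self.event_id}: empty inclusion set")
        if not self.inclusion_transcripts < self.total_transcripts:
            raise ValidationError(
                f"{self.event_id}: inclusion set must be a proper subset of total"
            )
        if len(self.total_transcripts) < 2:
            raise ValidationError(f"{self.event_id}: fewer than two transcripts")

    @property
    def exclusion_transcripts(self) -> frozenset[str]:
        return self.total_transcripts - self.inclusion_transcripts


class PsiMatrix:
    """Event x sample PSI values in [0, 1], NaN where undefined."""

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValidationError("PSI values outside [0, 1]")
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValidationError("duplicate event or sample ids")
        self.data = data.astype(float)

    @property
    def event_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PsiMatrix({self.data.shape[0]} events x {self.data.shape[1]} samples)"


def _event_id(gene: str, etype: str, chrom: str, coords: Sequence[int], strand: str) -> str:
    if etype == "SE":
        c = f"{coords[0]}-{coords[1]}:{coords[2]}-{coords[3]}"
    elif etype == "RI":
        c = f"{coords[0]}:{coords[1]}-{coords[2]}:{coords[3]}"
    elif etype in ("A5", "A3"):
        c = ":".join(f"{a}-{b}" for a, b in zip(coords[0::2], coords[1::2]))
    elif etype == "MX":
        c = (
            f"{coords[0]}-{coords[1]}:{coords[2]}-{coords[3]}:"
            f"{coords[0]}-{coords[4]}:{coords[5]}-{coords[3]}"
        )
    else:  # AF / AL
        c = ":".join(str(x) for x in coords)
    return f"{gene};{etype}:{chrom}:{c}:{strand}"


class _GeneIndex:
    """Coordinate indices over the transcripts of one gene."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.transcripts = {t.transcript_id: t for t in transcripts}
        self.intron_to_tx: dict[tuple[int, int], set[str]] = defaultdict(set)
        self.exon_to_tx: dict[tuple[int, int], set[str]] = defaultdict(set)
        self.first_exon: dict[str, tuple[int, int]] = {}
        self.last_exon: dict[str, tuple[int, int]] = {}
        for t in transcripts:
            for intron in t.introns:
                self.intron_to_tx[intron].add(t.transcript_id)
            for exon in t.exons:
                self.exon_to_tx[exon].add(t.transcript_id)
            self.first_exon[t.transcript_id] = t.exons[0]
            self.last_exon[t.transcript_id] = t.exons[-1]

    def upstream_exons(self, intron: tuple[int, int]) -> set[tuple[int, int]]:
        """Exons ending at the intron's left boundary in transcripts using it."""
        out = set()
        for tid in self.intron_to_tx[intron]:
            t = self.transcripts[tid]
            for exon in t.exons:
                if exon[1] == intron[0]:
                    out.add(exon)
        return out

    def downstream_exons(self, intron: tuple[int, int]) -> set[tuple[int, int]]:
        out = set()
        for tid in self.intron_to_tx[intron]:
            t = self.transcripts[tid]
            for exon in t.exons:
                if exon[0] == intron[1]:
                    out.add(exon)
        return out


def generate_events(transcripts: Iterable[TranscriptModel]) -> list[ASEvent]:
    """Enumerate all local AS events over transcripts grouped by gene.

    Returns events deduplicated by canonical id, sorted by id.  Genes with a
    single transcript yield no events.
    """
    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_gene[t.gene_id].append(t)
    events: dict[str, ASEvent] = {}
    for gene_id in sorted(by_gene):
        models = by_gene[gene_id]
        if len(models) < 2:
            continue
        chrom = models[0].chrom
        strand = models[0].strand
        idx = _GeneIndex(models)
        for ev in _gene_events(gene_id, chrom, strand, idx):
            prev = events.get(ev.event_id)
            if prev is not None:
                ev = _merge(prev, ev)
            events[ev.event_id] = ev
    out = [events[k] for k in sorted(events)]
    logger.info("generate_events: %d events from %d genes", len(out), len(by_gene))
    return out


def _merge(a: ASEvent, b: ASEvent) -> ASEvent:
    return ASEvent(
        event_id=a.event_id,
        gene_id=a.gene_id,
        chrom=a.chrom,
        strand=a.strand,
        event_type=a.event_type,
        coordinates=a.coordinates,
        inclusion_transcripts=a.inclusion_transcripts | b.inclusion_transcripts,
        total_transcripts=a.total_transcripts | b.total_transcripts,
    )


def _make(gene, chrom, strand, etype, coords, inc, exc) -> ASEvent | None:
    inc, exc = set(inc), set(exc)
    exc -= inc
    if not inc or not exc:
        return None
    total = inc | exc
    return ASEvent(
        event_id=_event_id(gene, etype, chrom, coords, strand),
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        event_type=etype,
        coordinates=tuple(coords),
        inclusion_transcripts=frozenset(inc),
        total_transcripts=frozenset(total),
    )


def _gene_events(gene: str, chrom: str, strand: str, idx: _GeneIndex):
    yield from _se_events(gene, chrom, strand, idx)
    yield from _ri_events(gene, chrom, strand, idx)
    yield from _alt_site_events(gene, chrom, strand, idx)
    yield from _mx_events(gene, chrom, strand, idx)


def _se_events(gene, chrom, strand, idx: _GeneIndex):
    for t in idx.transcripts.values():
        introns = t.introns
        for (e_a, s_b), (e_b, s_c) in zip(introns, introns[1:]):
            skip = (e_a, s_c)
            if skip not in idx.intron_to_tx:
                continue
            inc = idx.intron_to_tx[(e_a, s_b)] & idx.intron_to_tx[(e_b, s_c)]
            exc = idx.intron_to_tx[skip]
            ev = _make(gene, chrom, strand, "SE", (e_a, s_b, e_b, s_c), inc, exc)
            if ev:
                yield ev


def _ri_events(gene, chrom, strand, idx: _GeneIndex):
    for t in idx.transcripts.values():
        exons = t.exons
        for (a, e1), (s2, b) in zip(exons, exons[1:]):
            spanning = (a, b)
            if spanning not in idx.exon_to_tx:
                continue
            # exclusion: transcripts splicing the intron with both flanking
            # exon outer boundaries matching the retained exon
            exc = (
                idx.intron_to_tx[(e1, s2)]
                & idx.exon_to_tx[(a, e1)]
                & idx.exon_to_tx[(s2, b)]
            )
            inc = idx.exon_to_tx[spanning]
            ev = _make(gene, chrom, strand, "RI", (a, e1, s2, b), inc, exc)
            if ev:
                yield ev


def _alt_site_events(gene, chrom, strand, idx: _GeneIndex):
    by_acceptor: dict[int, list[tuple[int, int]]] = defaultdict(list)
    by_donor: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for intron in idx.intron_to_tx:
        by_acceptor[intron[1]].append(intron)
        by_donor[intron[0]].append(intron)

    # varying left (donor-side) boundary, shared acceptor
    for s, introns in sorted(by_acceptor.items()):
        for i1, i2 in _pairs(sorted(introns)):
            d1, d2 = i1[0], i2[0]  # d1 < d2
            x1 = idx.upstream_exons(i1)
            x2 = idx.upstream_exons(i2)
            if not x1 or not x2:
                continue
            overlap = any(a2 <= d1 for a2, _ in x2)
            if overlap:
                etype = "A5" if strand == "+" else "A3"
                # shorter intron (d2) is the longer-exon inclusion form
                ev = _make(
                    gene, chrom, strand, etype, (d1, s, d2, s),
                    idx.intron_to_tx[i2], idx.intron_to_tx[i1],
                )
                if ev:
                    yield ev
            else:
                etype = "AF" if strand == "+" else "AL"
                yield from _terminal_events(
                    gene, chrom, strand, etype, idx, i1, i2, side="left", shared=s
                )

    # varying right (acceptor-side) boundary, shared donor
    for d, introns in sorted(by_donor.items()):
        for i1, i2 in _pairs(sorted(introns, key=lambda x: x[1])):
            s1, s2 = i1[1], i2[1]  # s1 < s2
            x1 = idx.downstream_exons(i1)
            x2 = idx.downstream_exons(i2)
            if not x1 or not x2:
                continue
            overlap = any(b1 >= s2 for _, b1 in x1)
            if overlap:
                etype = "A3" if strand == "+" else "A5"
                # shorter intron (s1) is the longer-exon inclusion form
                ev = _make(
                    gene, chrom, strand, etype, (d, s1, d, s2),
                    idx.intron_to_tx[i1], idx.intron_to_tx[i2],
                )
                if ev:
                    yield ev
            else:
                etype = "AL" if strand == "+" else "AF"
                yield from _terminal_events(
                    gene, chrom, strand, etype, idx, i1, i2, side="right", shared=d
                )


def _terminal_events(gene, chrom, strand, etype, idx: _GeneIndex, i1, i2, side, shared):
    """Alternative first/last exon events for a pair of boundary-sharing introns."""

    def terminal_forms(intron):
        forms: dict[tuple[int, int], set[str]] = defaultdict(set)
        for tid in idx.intron_to_tx[intron]:
            t = idx.transcripts[tid]
            if side == "left":
                exon = idx.first_exon[tid]
                if exon[1] == intron[0] and t.introns[0] == intron:
                    forms[exon].add(tid)
            else:
                exon = idx.last_exon[tid]
                if exon[0] == intron[1] and t.introns[-1] == intron:
                    forms[exon].add(tid)
        return forms

    forms1, forms2 = terminal_forms(i1), terminal_forms(i2)
    for e1, tx1 in sorted(forms1.items()):
        for e2, tx2 in sorted(forms2.items()):
            if e1[1] >= e2[0] and e2[1] >= e1[0]:  # overlapping terminal exons
                continue
            first, second = sorted([(e1, i1, tx1), (e2, i2, tx2)])
            if side == "left":
                coords = (
                    first[0][0], first[0][1], first[1][1],
                    second[0][0], second[0][1], second[1][1],
                )
            else:
                coords = (
                    first[1][0], first[0][0], first[0][1],
                    second[1][0], second[0][0], second[0][1],
                )
            # inclusion: the form whose alternative exon starts first
            ev = _make(gene, chrom, strand, etype, coords, first[2], second[2])
            if ev:
                yield ev


def _mx_events(gene, chrom, strand, idx: _GeneIndex):
    cassettes: dict[tuple[int, int], dict[tuple[int, int], set[str]]] = defaultdict(dict)
    for t in idx.transcripts.values():
        introns = t.introns
        for (e_a, s_b), (e_b, s_c) in zip(introns, introns[1:]):
            key = (e_a, s_c)
            cassettes[key].setdefault((s_b, e_b), set()).update(
                idx.intron_to_tx[(e_a, s_b)] & idx.intron_to_tx[(e_b, s_c)]
            )
    for (e_flank, s_flank), forms in sorted(cassettes.items()):
        for (b1, b2) in _pairs(sorted(forms)):
            if b1[1] >= b2[0]:  # overlapping cassettes
                continue
            tx1, tx2 = forms[b1], forms[b2]
            if tx1 & tx2:  # cassettes co-occur in one transcript
                continue
            coords = (e_flank, b1[0], b1[1], s_flank, b2[0], b2[1])
            ev = _make(gene, chrom, strand, "MX", coords, tx1, tx2)
            if ev:
                yield ev


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


# ---------------------------------------------------------------------------
# PSI quantification
# ---------------------------------------------------------------------------


def _check_members(event: ASEvent, tpm: ExpressionMatrix) -> None:
    missing = event.total_transcripts - set(tpm.data.index)
    if missing:
        raise ValidationError(
            f"{event.event_id}: transcripts absent from matrix: {sorted(missing)}"
        )


def compute_psi(
    event: ASEvent,
    transcript_tpm: ExpressionMatrix,
    sample: str,
    denom_min: float = DENOM_MIN,
) -> float:
    """PSI of one event in one sample: inclusion TPM over total TPM.

    Returns NaN when the summed TPM of both forms is below ``denom_min``.
    """
    _check_members(event, transcript_tpm)
    col = transcript_tpm.data[sample]
    inc = col.loc[sorted(event.inclusion_transcripts)].sum()
    exc = col.loc[sorted(event.exclusion_transcripts)].sum()
    denom = inc + exc
    if denom < denom_min:
        return float("nan")
    # minority form as the ratio, majority as its complement: the two
    # complementary forms of an event then sum to exactly 1.0
    if inc <= exc:
        return float(inc / denom)
    return float(1.0 - exc / denom)


def event_tpm(
    event: ASEvent, transcript_tpm: ExpressionMatrix, sample: str | None = None
):
    """Summed TPM over the event's two forms (one sample or all)."""
    _check_members(event, transcript_tpm)
    sums = transcript_tpm.data.loc[sorted(event.total_transcripts)].sum(axis=0)
    if sample is not None:
        return float(sums[sample])
    return sums


def psi_matrix(
    events: Sequence[ASEvent],
    transcript_tpm: ExpressionMatrix,
    denom_min: float = DENOM_MIN,
) -> PsiMatrix:
    """Vectorized PSI over all events and samples."""
    tx = transcript_tpm.data
    inc_rows = []
    exc_rows = []
    for ev in events:
        _check_members(ev, transcript_tpm)
        inc_rows.append(tx.loc[sorted(ev.inclusion_transcripts)].sum(axis=0))
        exc_rows.append(tx.loc[sorted(ev.exclusion_transcripts)].sum(axis=0))
    index = [ev.event_id for ev in events]
    inc = pd.DataFrame(inc_rows, index=index).to_numpy()
    exc = pd.DataFrame(exc_rows, index=index).to_numpy()
    denom = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        # minority-form ratio with exact complement (see compute_psi)
        psi = np.where(inc <= exc, inc / denom, 1.0 - exc / denom)
    psi = np.where(denom >= denom_min, psi, np.nan)
    return PsiMatrix(
        pd.DataFrame(psi, index=index, columns=tx.columns)
    )


def event_tpm_matrix(
    events: Sequence[ASEvent], transcript_tpm: ExpressionMatrix
) -> pd.DataFrame:
    """Event x sample summed-TPM matrix over each event's two forms."""
    rows = []
    for ev in events:
        _check_members(ev, transcript_tpm)
        rows.append(transcript_tpm.data.loc[sorted(ev.total_transcripts)].sum(axis=0))
    return pd.DataFrame(rows, index=[ev.event_id for ev in events])


def events_table(events: Sequence[ASEvent]) -> pd.DataFrame:
    """Flat table of events (for the ``events.tsv`` artifact)."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "gene_id": [e.gene_id for e in events],
            "event_type": [e.event_type for e in events],
            "chrom": [e.chrom for e in events],
            "strand": [e.strand for e in events],
            "coordinates": [",".join(map(str, e.coordinates)) for e in events],
            "inclusion_transcripts": [
                ",".join(sorted(e.inclusion_transcripts)) for e in events
            ],
            "total_transcripts": [
                ",".join(sorted(e.total_transcripts)) for e in events
            ],
        }
    )


def events_from_table(df: pd.DataFrame) -> list[ASEvent]:
    out = []
    for _, r in df.iterrows():
        out.append(
            ASEvent(
                event_id=r["event_id"],
                gene_id=r["gene_id"],
                chrom=r["chrom"],
                strand=r["strand"],
                event_type=r["event_type"],
                coordinates=tuple(int(x) for x in str(r["coordinates"]).split(",")),
                inclusion_transcripts=frozenset(
                    str(r["inclusion_transcripts"]).split(",")
                ),
                total_transcripts=frozenset(str(r["total_transcripts"]).split(",")),
            )
        )
    return out
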