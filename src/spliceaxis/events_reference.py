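"""Brute-force reference enumerator for local AS events.

This module re-derives the seven event types by exhaustive comparison of
every ordered transcript pair of a gene, classifying each candidate pattern
directly from the two exon chains and assigning transcript sets by scanning
all transcripts for pattern containment.  It shares no code with the
indexed generator in :mod:`spliceaxis.events` and is deliberately naive; it
exists to validate the production generator on small gene models and is far
too slow for genome-scale annotation.

The classification contracts are those documented in
:mod:`spliceaxis.events`.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

from .events import ASEvent, _event_id
from .io import TranscriptModel


def _introns(t: TranscriptModel) -> list[tuple[int, int]]:
    return [(t.exons[i][1], t.exons[i + 1][0]) for i in range(len(t.exons) - 1)]


def _has_intron(t: TranscriptModel, intron: tuple[int, int]) -> bool:
    return intron in _introns(t)


def _has_exon(t: TranscriptModel, exon: tuple[int, int]) -> bool:
    return exon in t.exons


def enumerate_events_pairwise(
    transcripts: Iterable[TranscriptModel],
) -> list[ASEvent]:
    """Enumerate all local AS events by exhaustive pairwise comparison."""
    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_gene[t.gene_id].append(t)
    found: dict[str, ASEvent] = {}
    for gene in sorted(by_gene):
        models = sorted(by_gene[gene], key=lambda t: t.transcript_id)
        if len(models) < 2:
            continue
        for rec in _gene_pairwise(gene, models):
            prev = found.get(rec.event_id)
            if prev is not None:
                rec = ASEvent(
                    event_id=rec.event_id,
                    gene_id=rec.gene_id,
                    chrom=rec.chrom,
                    strand=rec.strand,
                    event_type=rec.event_type,
                    coordinates=rec.coordinates,
                    inclusion_transcripts=prev.inclusion_transcripts
                    | rec.inclusion_transcripts,
                    total_transcripts=prev.total_transcripts | rec.total_transcripts,
                )
            found[rec.event_id] = rec
    return [found[k] for k in sorted(found)]


def _emit(gene, chrom, strand, etype, coords, inc, exc):
    inc = set(inc) - set()
    exc = set(exc) - set(inc)
    if not inc or not exc:
        return None
    return ASEvent(
        event_id=_event_id(gene, etype, chrom, coords, strand),
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        event_type=etype,
        coordinates=tuple(coords),
        inclusion_transcripts=frozenset(inc),
        total_transcripts=frozenset(inc) | frozenset(exc),
    )


def _gene_pairwise(gene: str, models: list[TranscriptModel]):
    chrom, strand = models[0].chrom, models[0].strand
    for t1 in models:
        for t2 in models:
            if t1.transcript_id == t2.transcript_id:
                continue
            yield from _pair_se(gene, chrom, strand, t1, t2, models)
            yield from _pair_ri(gene, chrom, strand, t1, t2, models)
            yield from _pair_alt(gene, chrom, strand, t1, t2, models)
            yield from _pair_mx(gene, chrom, strand, t1, t2, models)


def _pair_se(gene, chrom, strand, t1, t2, models):
    """t1 carries the cassette exon, t2 the skip junction."""
    in1 = _introns(t1)
    for k in range(len(in1) - 1):
        (e_a, s_b), (e_b, s_c) = in1[k], in1[k + 1]
        if _has_intron(t2, (e_a, s_c)):
            inc = [
                t.transcript_id
                for t in models
                if _has_intron(t, (e_a, s_b)) and _has_intron(t, (e_b, s_c))
            ]
            exc = [t.transcript_id for t in models if _has_intron(t, (e_a, s_c))]
            ev = _emit(gene, chrom, strand, "SE", (e_a, s_b, e_b, s_c), inc, exc)
            if ev:
                yield ev


def _pair_ri(gene, chrom, strand, t1, t2, models):
    """t1 retains an intron that t2 splices, outer boundaries shared."""
    for a, b in t1.exons:
        for k, (e1, s2) in enumerate(_introns(t2)):
            if t2.exons[k][0] == a and t2.exons[k + 1][1] == b:
                inc = [t.transcript_id for t in models if _has_exon(t, (a, b))]
                exc = [
                    t.transcript_id
                    for t in models
                    if _has_intron(t, (e1, s2))
                    and _has_exon(t, (a, e1))
                    and _has_exon(t, (s2, b))
                ]
                ev = _emit(gene, chrom, strand, "RI", (a, e1, s2, b), inc, exc)
                if ev:
                    yield ev


def _boundary_exons(models, intron, side):
    """All exons flanking ``intron`` on ``side`` in transcripts using it."""
    out = set()
    for t in models:
        if _has_intron(t, intron):
            for exon in t.exons:
                if side == "left" and exon[1] == intron[0]:
                    out.add(exon)
                if side == "right" and exon[0] == intron[1]:
                    out.add(exon)
    return out


def _pair_alt(gene, chrom, strand, t1, t2, models):
    """Shared-boundary intron pairs between t1 and t2: A5/A3/AF/AL."""
    for i1 in _introns(t1):
        for i2 in _introns(t2):
            if i1 == i2:
                continue
            if i1[1] == i2[1] and i1[0] < i2[0]:
                yield from _alt_left(gene, chrom, strand, i1, i2, models)
            if i1[0] == i2[0] and i1[1] < i2[1]:
                yield from _alt_right(gene, chrom, strand, i1, i2, models)


def _alt_left(gene, chrom, strand, i1, i2, models):
    """Donor-side variation (i1 has the smaller donor), shared acceptor."""
    d1, d2, s = i1[0], i2[0], i1[1]
    x1 = _boundary_exons(models, i1, "left")
    x2 = _boundary_exons(models, i2, "left")
    if not x1 or not x2:
        return
    if any(a2 <= d1 for a2, _ in x2):
        etype = "A5" if strand == "+" else "A3"
        inc = [t.transcript_id for t in models if _has_intron(t, i2)]
        exc = [t.transcript_id for t in models if _has_intron(t, i1)]
        ev = _emit(gene, chrom, strand, etype, (d1, s, d2, s), inc, exc)
        if ev:
            yield ev
        return
    etype = "AF" if strand == "+" else "AL"
    for e1 in sorted(x1):
        for e2 in sorted(x2):
            if e1[1] >= e2[0] and e2[1] >= e1[0]:
                continue
            tx1 = [
                t.transcript_id
                for t in models
                if _has_intron(t, i1) and t.exons[0] == e1 and _introns(t)[0] == i1
            ]
            tx2 = [
                t.transcript_id
                for t in models
                if _has_intron(t, i2) and t.exons[0] == e2 and _introns(t)[0] == i2
            ]
            if not tx1 or not tx2:
                continue
            (ea, ia, ta), (eb, ib, tb) = sorted(
                [(e1, i1, tuple(tx1)), (e2, i2, tuple(tx2))]
            )
            coords = (ea[0], ea[1], ia[1], eb[0], eb[1], ib[1])
            ev = _emit(gene, chrom, strand, etype, coords, ta, tb)
            if ev:
                yield ev


def _alt_right(gene, chrom, strand, i1, i2, models):
    """Acceptor-side variation (i1 has the smaller acceptor), shared donor."""
    d, s1, s2 = i1[0], i1[1], i2[1]
    x1 = _boundary_exons(models, i1, "right")
    x2 = _boundary_exons(models, i2, "right")
    if not x1 or not x2:
        return
    if any(b1 >= s2 for _, b1 in x1):
        etype = "A3" if strand == "+" else "A5"
        inc = [t.transcript_id for t in models if _has_intron(t, i1)]
        exc = [t.transcript_id for t in models if _has_intron(t, i2)]
        ev = _emit(gene, chrom, strand, etype, (d, s1, d, s2), inc, exc)
        if ev:
            yield ev
        return
    etype = "AL" if strand == "+" else "AF"
    for e1 in sorted(x1):
        for e2 in sorted(x2):
            if e1[1] >= e2[0] and e2[1] >= e1[0]:
                continue
            tx1 = [
                t.transcript_id
                for t in models
                if _has_intron(t, i1) and t.exons[-1] == e1 and _introns(t)[-1] == i1
            ]
            tx2 = [
                t.transcript_id
                for t in models
                if _has_intron(t, i2) and t.exons[-1] == e2 and _introns(t)[-1] == i2
            ]
            if not tx1 or not tx2:
                continue
            (ea, ia, ta), (eb, ib, tb) = sorted(
                [(e1, i1, tuple(tx1)), (e2, i2, tuple(tx2))]
            )
            coords = (ia[0], ea[0], ea[1], ib[0], eb[0], eb[1])
            ev = _emit(gene, chrom, strand, etype, coords, ta, tb)
            if ev:
                yield ev


def _cassette_tx(models, e_flank, cassette, s_flank):
    s_b, e_b = cassette
    return [
        t.transcript_id
        for t in models
        if _has_intron(t, (e_flank, s_b)) and _has_intron(t, (e_b, s_flank))
    ]


def _pair_mx(gene, chrom, strand, t1, t2, models):
    in1, in2 = _introns(t1), _introns(t2)
    for k in range(len(in1) - 1):
        (ea1, sb1), (eb1, sc1) = in1[k], in1[k + 1]
        for m in range(len(in2) - 1):
            (ea2, sb2), (eb2, sc2) = in2[m], in2[m + 1]
            if (ea1, sc1) != (ea2, sc2):
                continue
            b1, b2 = (sb1, eb1), (sb2, eb2)
            if b1 >= b2 or b1[1] >= b2[0]:
                continue
            tx1 = _cassette_tx(models, ea1, b1, sc1)
            tx2 = _cassette_tx(models, ea1, b2, sc1)
            if set(tx1) & set(tx2):
                continue
            coords = (ea1, b1[0], b1[1], sc1, b2[0], b2[1])
            ev = _emit(gene, chrom, strand, "MX", coords, tx1, tx2)
            if ev:
                yield ev
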