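"""Alternative-splicing event classification from multi-transcript
annotation.

Events are called by pairwise comparison of the isoforms annotated for a
gene, using junction/interval definitions:

cassette_exon
    an internal exon of one isoform is skipped by the other, which
    carries the junction joining the two flanking exons;
alt_3ss / alt_5ss
    two introns share one splice site (donor resp. acceptor) and differ
    at the other, with the alternative exons overlapping each other (the
    overlap requirement keeps a skipped exon from also being reported as
    an alternative splice-site pair);
retained_intron
    an intron of one isoform lies strictly inside a single exon of the
    other.

When one region satisfies several definitions the fixed precedence
retained_intron > alt_3ss > alt_5ss > cassette_exon applies (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import TranscriptModel
from .scan import RepaCall

logger = logging.getLogger(__name__)

__all__ = [
    "ASEvent",
    "ASTypeDistribution",
    "EVENT_TYPES",
    "detect_as_events",
    "associate_sites",
    "type_distribution",
    "write_events_tsv",
]

EVENT_TYPES = ("cassette_exon", "alt_3ss", "alt_5ss", "retained_intron", "other")

#: Higher value = higher precedence when one region matches several types.
_PRECEDENCE = {"retained_intron": 4, "alt_3ss": 3, "alt_5ss": 2, "cassette_exon": 1}


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    interval: tuple[int, int]  # genomic 1-based closed, defines the event
    acceptor_coords: tuple[int, ...]  # genomic coords of implicated acceptors
    witness_transcripts: tuple[str, str]

    @property
    def key(self) -> tuple:
        """Identity used for deduplication across transcript pairs."""
        return (self.chrom, self.strand, self.event_type, self.interval,
                self.acceptor_coords)

    @property
    def region(self) -> tuple:
        return (self.chrom, self.strand, self.interval)


@dataclass(frozen=True)
class _Junction:
    start: int  # genomic first intronic base
    end: int    # genomic last intronic base
    strand: str
    up_exon: tuple[int, int]    # exon 5' of the intron (transcription order)
    down_exon: tuple[int, int]  # exon 3' of the intron

    @property
    def donor(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start


def _junctions(model: TranscriptModel) -> list[_Junction]:
    out = []
    for up, down in zip(model.exons, model.exons[1:]):
        if model.strand == "+":
            start, end = up[1] + 1, down[0] - 1
        else:
            start, end = down[1] + 1, up[0] - 1
        if end >= start:
            out.append(_Junction(start, end, model.strand, up, down))
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _pair_events(a: TranscriptModel, b: TranscriptModel) -> list[ASEvent]:
    """Events between one ordered transcript pair (a scrutinised against
    b); the caller runs both orders and deduplicates."""
    events: list[ASEvent] = []
    ja, jb = _junctions(a), _junctions(b)
    witnesses = tuple(sorted((a.transcript_id, b.transcript_id)))

    def emit(etype: str, interval: tuple[int, int], acceptors: Iterable[int]) -> None:
        events.append(ASEvent(
            gene_id=a.gene_id, event_type=etype, chrom=a.chrom, strand=a.strand,
            interval=interval, acceptor_coords=tuple(sorted(set(acceptors))),
            witness_transcripts=witnesses,
        ))

    # alternative 3'SS / 5'SS: one shared splice site, overlapping exons
    for x in ja:
        for y in jb:
            if x.donor == y.donor and x.acceptor != y.acceptor \
                    and _overlap(x.down_exon, y.down_exon):
                lo, hi = sorted((x.acceptor, y.acceptor))
                emit("alt_3ss", (lo, hi), (x.acceptor, y.acceptor))
            if x.acceptor == y.acceptor and x.donor != y.donor \
                    and _overlap(x.up_exon, y.up_exon):
                lo, hi = sorted((x.donor, y.donor))
                emit("alt_5ss", (lo, hi), (x.acceptor,))

    # cassette exon: internal exon of a skipped by a junction of b
    for k in range(1, a.n_exons - 1):
        into = ja[k - 1]   # junction entering the candidate exon
        outof = ja[k]      # junction leaving it
        for y in jb:
            if y.donor == into.donor and y.acceptor == outof.acceptor:
                emit("cassette_exon", a.exons[k],
                     (into.acceptor, outof.acceptor))

    # retained intron: intron of a strictly inside one exon of b
    for x in ja:
        lo, hi = min(x.start, x.end), max(x.start, x.end)
        for exon in b.exons:
            if exon[0] < lo and exon[1] > hi:
                emit("retained_intron", (lo, hi), (x.acceptor,))
    return events


def detect_as_events(
    models: Iterable[TranscriptModel] | Mapping[str, Sequence[TranscriptModel]],
) -> list[ASEvent]:
    """Detect events across all transcript pairs of every gene.

    Accepts a flat transcript collection (grouped here by gene_id) or a
    pre-grouped mapping.  Results are deduplicated across pairs; when
    the same region matches several definitions only the highest-
    precedence type is kept.
    """
    if isinstance(models, Mapping):
        by_gene = {g: list(ms) for g, ms in models.items()}
    else:
        by_gene = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)

    dedup: dict[tuple, ASEvent] = {}
    for gene, txs in by_gene.items():
        for i in range(len(txs)):
            for j in range(len(txs)):
                if i == j:
                    continue
                for ev in _pair_events(txs[i], txs[j]):
                    dedup.setdefault(ev.key, ev)

    # precedence among events defining the same region
    by_region: dict[tuple, ASEvent] = {}
    for ev in dedup.values():
        prev = by_region.get(ev.region)
        if prev is None:
            by_region[ev.region] = ev
        elif _PRECEDENCE[ev.event_type] > _PRECEDENCE[prev.event_type]:
            logger.info(
                "region %s: %s supersedes %s by precedence",
                ev.region, ev.event_type, prev.event_type,
            )
            by_region[ev.region] = ev
    return sorted(
        by_region.values(),
        key=lambda e: (e.chrom, e.interval, e.event_type),
    )


def _site_coord(site_id: str) -> tuple[str, str, int]:
    chrom, strand, coord = site_id.rsplit(":", 2)
    return chrom, strand, int(coord)


def associate_sites(
    events: Sequence[ASEvent],
    repa_calls: Sequence[RepaCall],
) -> dict[str, dict]:
    """Per-site alternative-splicing annotation.

    A site is alternative iff at least one event's defining acceptor
    coincides with the site's acceptor coordinate or the event interval
    covers it; multi-type sites carry every matching type.
    """
    out: dict[str, dict] = {}
    for call in repa_calls:
        chrom, strand, coord = _site_coord(call.site_id)
        types = set()
        for ev in events:
            if ev.chrom != chrom or ev.strand != strand:
                continue
            if coord in ev.acceptor_coords or ev.interval[0] <= coord <= ev.interval[1]:
                types.add(ev.event_type)
        out[call.site_id] = {
            "is_alternative": bool(types),
            "event_types": sorted(types),
        }
    return out


def events_for_sites(
    events: Sequence[ASEvent],
    repa_calls: Sequence[RepaCall],
) -> list[ASEvent]:
    """The subset of events whose defining acceptor or interval touches
    at least one of the given sites (same touch rule as
    :func:`associate_sites`)."""
    coords = {_site_coord(c.site_id) for c in repa_calls}
    out = []
    for ev in events:
        hit = any(
            chrom == ev.chrom and strand == ev.strand
            and (coord in ev.acceptor_coords
                 or ev.interval[0] <= coord <= ev.interval[1])
            for chrom, strand, coord in coords
        )
        if hit:
            out.append(ev)
    return out


@dataclass
class ASTypeDistribution:
    counts: dict[str, int]
    proportions: dict[str, float]
    reference_proportions: dict[str, float] | None
    fold_enrichment: dict[str, float] | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for etype, n in self.counts.items():
            rows.append({
                "event_type": etype,
                "count": n,
                "proportion": self.proportions[etype],
                "reference_proportion": (self.reference_proportions or {}).get(etype),
                "fold_enrichment": (self.fold_enrichment or {}).get(etype),
            })
        return pd.DataFrame(rows)


def type_distribution(
    events: Sequence[ASEvent],
    reference_proportions: Mapping[str, float] | None = None,
) -> ASTypeDistribution:
    """Event-type counts/proportions and fold enrichment over reference
    (e.g. transcriptome-wide) proportions; folds are only defined where
    the reference proportion is positive."""
    if not events:
        raise ValueError("no events to summarize")
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.event_type] = counts.get(ev.event_type, 0) + 1
    total = sum(counts.values())
    props = {t: n / total for t, n in counts.items()}
    folds = None
    ref = dict(reference_proportions) if reference_proportions else None
    if ref:
        folds = {
            t: props[t] / ref[t]
            for t in props
            if ref.get(t, 0) > 0
        }
    return ASTypeDistribution(counts, props, ref, folds)


def write_events_tsv(events: Sequence[ASEvent], path: str | Path) -> None:
    rows = [
        {
            "gene_id": e.gene_id,
            "event_type": e.event_type,
            "chrom": e.chrom,
            "strand": e.strand,
            "start": e.interval[0],
            "end": e.interval[1],
            "acceptor_coords": ",".join(map(str, e.acceptor_coords)),
            "witness_transcripts": ",".join(e.witness_transcripts),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=[
        "gene_id", "event_type", "chrom", "strand", "start", "end",
        "acceptor_coords", "witness_transcripts",
    ]).to_csv(path, sep="\t", index=False)
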