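"""Genome/annotation input and acceptor-window extraction.

Reads a genome (FASTA, via :mod:`pyfaidx`) and a transcript annotation
(GTF or GFF3, via :mod:`gffutils`), derives introns from adjacent exon
pairs, and cuts strand-corrected windows anchored at the intron 3' end
(the acceptor splice site).  Windows are indexed with the intron-relative
convention of :mod:`repa.coords` (position -1 = last intronic base,
+1 = first exonic base, no zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .coords import gtf_to_bed, pos_to_index, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "Intron",
    "AcceptorWindow",
    "parse_annotation",
    "derive_introns",
    "extract_window",
    "extract_windows",
    "open_genome",
    "write_sites_bed",
    "write_sites_tsv",
    "read_sites_tsv",
]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exons as genomic 1-based closed intervals, stored
    in transcription order (descending genomic coordinate on the minus
    strand)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for start, end in self.exons:
            if end < start:
                raise ValueError(f"exon end {end} < start {start}")
        genomic = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: {self.exons}"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class Intron:
    """One intron (genomic 1-based closed interval of intronic bases).

    ``acceptor_dinucleotide`` is the last two intronic bases on the
    transcribed strand (``AG`` for canonical acceptors); it is filled in
    when a genome is available.
    """

    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str = ""
    upstream_exon_id: str = ""
    downstream_exon_id: str = ""
    acceptor_dinucleotide: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def acceptor_coord(self) -> int:
        """Genomic coordinate of the last intronic base (position -1)."""
        return self.end if self.strand == "+" else self.start

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.acceptor_coord}"


@dataclass(frozen=True)
class AcceptorWindow:
    """A 3' splice-site window on the transcribed strand.

    ``window`` covers intron-relative positions ``-intron_span..-1`` then
    ``+1..+exon_span``.  ``truncated`` marks windows clipped by a short
    intron/exon or a contig edge.
    """

    site_id: str
    window: str
    intron_span: int
    exon_span: int
    chrom: str = ""
    strand: str = "+"
    intron_start: int = 0
    intron_end: int = 0
    gene_id: str = ""
    truncated: bool = False

    def at(self, pos: int) -> str:
        return self.window[pos_to_index(pos, self.intron_span)]

    def subseq(self, from_pos: int, to_pos: int) -> str:
        """Window slice between intron-relative positions, inclusive."""
        i = pos_to_index(from_pos, self.intron_span)
        j = pos_to_index(to_pos, self.intron_span)
        if j < i:
            raise ValueError(f"range {from_pos}..{to_pos} not 5'->3'")
        return self.window[i : j + 1]

    @property
    def acceptor_dinucleotide(self) -> str:
        return self.subseq(-2, -1)

    @property
    def acceptor_coord(self) -> int:
        return self.intron_end if self.strand == "+" else self.intron_start


def _read_text(path: str | Path) -> str:
    try:
        return Path(path).read_text()
    except OSError as exc:  # unreadable file is fatal per contract
        raise OSError(f"cannot read annotation {path}: {exc}") from exc


def parse_annotation(gtf_path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF or GFF3 file into transcript models.

    The dialect is auto-detected by gffutils.  Records with ``end <
    start`` are rejected (counted in a log line); transcripts on an
    unparseable strand are dropped with a warning.
    """
    text = _read_text(gtf_path)
    kept_lines: list[str] = []
    n_rejected = 0
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            kept_lines.append(line)
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            n_rejected += 1
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            n_rejected += 1
            continue
        if end < start:
            n_rejected += 1
            continue
        kept_lines.append(line)
    if n_rejected:
        logger.warning("%s: rejected %d malformed record(s)", gtf_path, n_rejected)

    db = gffutils.create_db(
        "\n".join(kept_lines) + "\n",
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        verbose=False,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # transcript -> gene map for GFF3 (exon Parent points at the mRNA).
    parent_gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            tid = feat.attributes.get("transcript_id", feat.attributes.get("ID", [feat.id]))[0]
            gid = feat.attributes.get("gene_id", feat.attributes.get("Parent", [""]))
            parent_gene[tid] = gid[0] if gid else ""
            parent_gene[feat.id] = parent_gene[tid]

    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for exon in db.features_of_type("exon"):
        attrs = exon.attributes
        if "transcript_id" in attrs:
            tids = attrs["transcript_id"]
        elif "Parent" in attrs:
            tids = attrs["Parent"]
        else:
            n_rejected += 1
            continue
        for tid in tids:
            gid = attrs.get("gene_id", [parent_gene.get(tid, "")])[0]
            exons_by_tx.setdefault(tid, []).append((exon.start, exon.end))
            meta[tid] = (gid, exon.seqid, exon.strand)

    models: list[TranscriptModel] = []
    n_bad_strand = 0
    for tid, exons in exons_by_tx.items():
        gid, chrom, strand = meta[tid]
        if strand not in "+-":
            n_bad_strand += 1
            logger.warning("transcript %s dropped: unparseable strand %r", tid, strand)
            continue
        exons = sorted(set(exons), reverse=(strand == "-"))
        models.append(TranscriptModel(tid, gid, chrom, strand, tuple(exons)))
    if n_bad_strand:
        logger.warning("%d transcript(s) dropped for bad strand", n_bad_strand)
    return models


def derive_introns(
    models: Iterable[TranscriptModel],
    genome: Mapping[str, object] | None = None,
) -> list[Intron]:
    """Derive introns from adjacent exon pairs, deduplicated genome-wide
    by (chrom, strand, start, end) so every acceptor site is counted once."""
    seen: dict[tuple[str, str, int, int], Intron] = {}
    n_single = 0
    n_zero_gap = 0
    for model in models:
        if model.n_exons < 2:
            n_single += 1
            continue
        for i, (up, down) in enumerate(zip(model.exons, model.exons[1:])):
            if model.strand == "+":
                start, end = up[1] + 1, down[0] - 1
            else:
                start, end = down[1] + 1, up[0] - 1
            if end < start:
                n_zero_gap += 1
                logger.warning(
                    "zero-length gap between exons %d/%d of %s", i + 1, i + 2,
                    model.transcript_id,
                )
                continue
            intron = Intron(
                chrom=model.chrom,
                strand=model.strand,
                start=start,
                end=end,
                gene_id=model.gene_id,
                upstream_exon_id=f"{model.transcript_id}.exon{i + 1}",
                downstream_exon_id=f"{model.transcript_id}.exon{i + 2}",
            )
            seen.setdefault(intron.key, intron)
    if n_single:
        logger.info("%d single-exon transcript(s) yield no introns", n_single)
    introns = sorted(seen.values(), key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
    if genome is not None:
        introns = [
            replace(iv, acceptor_dinucleotide=_fetch(genome, iv.chrom, iv.end - 1, iv.end + 1)
                    if iv.strand == "+"
                    else revcomp(_fetch(genome, iv.chrom, iv.start - 1, iv.start + 1)))
            for iv in introns
        ]
        introns = [replace(iv, acceptor_dinucleotide=(iv.acceptor_dinucleotide or "").upper())
                   for iv in introns]
    return introns


def open_genome(path: str | Path):
    """Open a FASTA genome for random access (pyfaidx)."""
    import pyfaidx

    return pyfaidx.Fasta(str(path), as_raw=False, sequence_always_upper=False)


def _fetch(genome: Mapping[str, object], chrom: str, start0: int, end0: int) -> str:
    """0-based half-open fetch, clipped at the left contig edge."""
    start0 = max(start0, 0)
    return str(genome[chrom][start0:end0])


def extract_window(
    genome: Mapping[str, object],
    intron: Intron,
    intron_span: int = 20,
    exon_span: int = 3,
) -> AcceptorWindow:
    """Cut the acceptor window of one intron from the genome.

    Minus-strand windows are reverse-complemented so the returned string
    always reads 5'->3' on the transcribed strand; soft-masked lowercase
    is uppercased.  A window clipped by a short intron or a contig edge
    is returned truncated and flagged rather than dropped.
    """
    if intron.chrom not in genome:
        raise KeyError(f"contig {intron.chrom!r} missing from genome")
    eff_intron = min(intron_span, intron.length)
    if intron.strand == "+":
        intronic = _fetch(genome, intron.chrom, intron.end - eff_intron, intron.end)
        exonic = _fetch(genome, intron.chrom, intron.end, intron.end + exon_span)
    else:
        intronic = revcomp(_fetch(genome, intron.chrom, intron.start - 1,
                                  intron.start - 1 + eff_intron))
        exonic = revcomp(_fetch(genome, intron.chrom,
                                intron.start - 1 - exon_span, intron.start - 1))
    window = (intronic + exonic).upper()
    truncated = eff_intron < intron_span or len(exonic) < exon_span
    return AcceptorWindow(
        site_id=intron.site_id,
        window=window,
        intron_span=len(intronic),
        exon_span=len(exonic),
        chrom=intron.chrom,
        strand=intron.strand,
        intron_start=intron.start,
        intron_end=intron.end,
        gene_id=intron.gene_id,
        truncated=truncated,
    )


def extract_windows(
    genome: Mapping[str, object],
    introns: Iterable[Intron],
    intron_span: int = 20,
    exon_span: int = 3,
) -> tuple[list[AcceptorWindow], list[dict]]:
    """Batch extraction; a missing contig yields a per-site error record
    instead of aborting the run.

    Windows are deduplicated by site_id: introns that share an acceptor
    (e.g. the two introns of an alternative-5'SS pair) describe the same
    3' splice site and yield one window.
    """
    windows: dict[str, AcceptorWindow] = {}
    errors: list[dict] = []
    for intron in introns:
        try:
            w = extract_window(genome, intron, intron_span, exon_span)
        except KeyError as exc:
            errors.append({"site_id": intron.site_id, "error": str(exc)})
            continue
        prev = windows.get(w.site_id)
        if prev is None:
            windows[w.site_id] = w
        elif prev.window != w.window:
            logger.warning("site %s: conflicting windows, keeping first", w.site_id)
    if errors:
        logger.warning("%d site(s) skipped (missing contig)", len(errors))
    return list(windows.values()), errors


_TSV_COLUMNS = [
    "site_id", "chrom", "strand", "intron_start", "intron_end", "gene_id",
    "intron_span", "exon_span", "truncated", "window",
]


def write_sites_tsv(windows: Sequence[AcceptorWindow], path: str | Path) -> None:
    rows = [
        {
            "site_id": w.site_id, "chrom": w.chrom, "strand": w.strand,
            "intron_start": w.intron_start, "intron_end": w.intron_end,
            "gene_id": w.gene_id, "intron_span": w.intron_span,
            "exon_span": w.exon_span, "truncated": w.truncated, "window": w.window,
        }
        for w in windows
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[AcceptorWindow]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "site_id": str})
    return [
        AcceptorWindow(
            site_id=row.site_id, window=row.window,
            intron_span=int(row.intron_span), exon_span=int(row.exon_span),
            chrom=row.chrom, strand=row.strand,
            intron_start=int(row.intron_start), intron_end=int(row.intron_end),
            gene_id="" if pd.isna(row.gene_id) else str(row.gene_id),
            truncated=bool(row.truncated),
        )
        for row in df.itertuples()
    ]


def write_sites_bed(windows: Sequence[AcceptorWindow], path: str | Path) -> None:
    """BED6 of the acceptor dinucleotide (0-based half-open), sorted by
    chrom then start."""
    records = []
    for w in windows:
        if w.strand == "+":
            start1, end1 = w.intron_end - 1, w.intron_end
        else:
            start1, end1 = w.intron_start, w.intron_start + 1
        b_start, b_end = gtf_to_bed(start1, end1)
        records.append((w.chrom, b_start, b_end, w.site_id, 0, w.strand))
    records.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(map(str, rec)) + "\n")
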