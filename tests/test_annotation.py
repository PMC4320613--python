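"""Annotation parsing, intron derivation and window extraction."""

import textwrap

import pytest
from hypothesis import given, settings, strategies as st

from repa.annotation import (AcceptorWindow, Intron, TranscriptModel,
                             derive_introns, extract_window, extract_windows,
                             parse_annotation, read_sites_tsv, write_sites_bed,
                             write_sites_tsv)
from repa.coords import revcomp


def _gtf(text: str):
    return textwrap.dedent(text).strip() + "\n"


TWO_EXON_PLUS = _gtf("""
    chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
    chr1\tsrc\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
""")


@pytest.fixture
def gtf_file(tmp_path):
    def write(content):
        p = tmp_path / "anno.gtf"
        p.write_text(content)
        return p

    return write


class TestParseAnnotation:
    def test_two_exon_plus_strand(self, gtf_file):
        models = parse_annotation(gtf_file(TWO_EXON_PLUS))
        assert len(models) == 1
        m = models[0]
        assert m.exons == ((1, 100), (201, 300))
        assert len(derive_introns(models)) == 1

    def test_minus_strand_transcription_order(self, gtf_file):
        content = TWO_EXON_PLUS.replace("\t+\t", "\t-\t")
        (m,) = parse_annotation(gtf_file(content))
        assert m.exons == ((201, 300), (1, 100))  # descending genomic

    def test_gff3_dialect(self, gtf_file):
        content = _gtf("""
            chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1
            chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=t1
            chr1\tsrc\texon\t201\t300\t.\t+\t.\tParent=t1
        """)
        (m,) = parse_annotation(gtf_file(content))
        assert m.transcript_id == "t1"
        assert m.gene_id == "g1"
        assert m.exons == ((1, 100), (201, 300))

    def test_bad_coordinates_rejected_bad_strand_dropped(self, gtf_file):
        content = TWO_EXON_PLUS + _gtf("""
            chr1\tsrc\texon\t500\t400\t.\t+\t.\tgene_id "g2"; transcript_id "t2";
            chr1\tsrc\texon\t600\t700\t.\t.\t.\tgene_id "g3"; transcript_id "t3";
        """)
        models = parse_annotation(gtf_file(content))
        assert {m.transcript_id for m in models} == {"t1"}

    def test_unreadable_file_is_fatal(self, tmp_path):
        with pytest.raises(OSError):
            parse_annotation(tmp_path / "missing.gtf")

    def test_synthetic_annotation_bookkeeping(self, small_genome_files):
        synth, paths = small_genome_files
        models = parse_annotation(paths["gtf"])
        assert len(models) == len(synth.models)
        introns = derive_introns(models)
        truth_ids = set(synth.truth.site_id)
        assert truth_ids <= {iv.site_id for iv in introns}


class TestDeriveIntrons:
    def test_intron_between_exons(self):
        m = TranscriptModel("t", "g", "chr1", "+", ((1, 100), (201, 300)))
        (iv,) = derive_introns([m])
        assert (iv.start, iv.end) == (101, 200)
        assert iv.acceptor_coord == 200

    def test_shared_intron_deduplicated(self):
        a = TranscriptModel("t1", "g", "chr1", "+", ((1, 100), (201, 300)))
        b = TranscriptModel("t2", "g", "chr1", "+", ((1, 100), (201, 300), (401, 500)))
        introns = derive_introns([a, b])
        assert len(introns) == 2  # [101,200] once, [301,400] once

    def test_three_exons_two_introns(self):
        m = TranscriptModel("t", "g", "chr1", "+",
                            ((1, 50), (101, 150), (201, 250)))
        assert len(derive_introns([m])) == 2

    def test_minus_strand_acceptor_is_intron_start(self):
        m = TranscriptModel("t", "g", "chr1", "-", ((201, 300), (1, 100)))
        (iv,) = derive_introns([m])
        assert (iv.start, iv.end) == (101, 200)
        assert iv.acceptor_coord == 101

    def test_single_exon_and_zero_gap_skipped(self):
        single = TranscriptModel("t1", "g", "chr1", "+", ((1, 100),))
        abutting = TranscriptModel("t2", "g", "chr1", "+", ((1, 100), (101, 200)))
        assert derive_introns([single, abutting]) == []


class TestExtractWindow:
    GENOME = {"chr1": "A" * 85 + "GTCTTGGGGGTTTAG" + "CCCAAA" + "T" * 20}
    # intron occupies [81, 100]; its last 15 bases are the G-tract tail

    def intron(self, strand="+"):
        return Intron("chr1", strand, 81, 100)

    def test_plus_strand_window(self):
        w = extract_window(self.GENOME, self.intron(), intron_span=15, exon_span=0)
        assert w.window == "GTCTTGGGGGTTTAG"
        assert w.subseq(-2, -1) == "AG"
        assert not w.truncated

    def test_strand_round_trip(self):
        seq = self.GENOME["chr1"]
        mirrored = {"chr1": revcomp(seq)}
        L = len(seq)
        iv = Intron("chr1", "-", L - 100 + 1, L - 81 + 1)
        w = extract_window(mirrored, iv, intron_span=15, exon_span=0)
        assert w.window == "GTCTTGGGGGTTTAG"

    def test_exonic_bases_appended(self):
        w = extract_window(self.GENOME, self.intron(), intron_span=15, exon_span=3)
        assert w.window.endswith("AGCCC")
        assert w.exon_span == 3

    def test_short_intron_truncated_and_flagged(self):
        iv = Intron("chr1", "+", 91, 100)  # length 10
        w = extract_window(self.GENOME, iv, intron_span=20, exon_span=0)
        assert w.truncated
        assert w.intron_span == 10

    def test_lowercase_uppercased(self):
        genome = {"chr1": self.GENOME["chr1"].lower()}
        w = extract_window(genome, self.intron(), intron_span=15, exon_span=0)
        assert w.window == "GTCTTGGGGGTTTAG"

    def test_missing_contig_is_per_site_error(self):
        good, bad = self.intron(), Intron("chrNOPE", "+", 81, 100)
        windows, errors = extract_windows(self.GENOME, [good, bad],
                                          intron_span=15, exon_span=0)
        assert len(windows) == 1 and len(errors) == 1
        assert "chrNOPE" in errors[0]["error"]


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_strand_roundtrip_property(seed):
    """Extraction is invariant under mirroring the genome: the minus-
    strand read of the reverse-complemented contig is the plus-strand
    window."""
    import numpy as np

    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    genome = {"c": seq}
    start, end = 101, 200
    w_plus = extract_window(genome, Intron("c", "+", start, end), 20, 3)
    L = len(seq)
    w_minus = extract_window({"c": revcomp(seq)},
                             Intron("c", "-", L - end + 1, L - start + 1), 20, 3)
    assert w_plus.window == w_minus.window


class TestSiteIO:
    def _windows(self):
        g = TestExtractWindow.GENOME
        w = extract_window(g, Intron("chr1", "+", 81, 100, gene_id="g1"),
                           intron_span=15, exon_span=3)
        return [w]

    def test_tsv_roundtrip(self, tmp_path):
        ws = self._windows()
        p = tmp_path / "sites.tsv"
        write_sites_tsv(ws, p)
        assert read_sites_tsv(p) == ws

    def test_bed_coordinates(self, tmp_path):
        p = tmp_path / "sites.bed"
        write_sites_bed(self._windows(), p)
        chrom, start, end, name, score, strand = \
            p.read_text().strip().split("\t")
        # acceptor AG at 1-based [99, 100] -> BED 98..100
        assert (chrom, int(start), int(end), strand) == ("chr1", 98, 100, "+")

    def test_empty_set_header_only(self, tmp_path):
        p = tmp_path / "sites.tsv"
        write_sites_tsv([], p)
        assert p.read_text().startswith("site_id\t")
        assert read_sites_tsv(p) == []

    def test_bed_sorted(self, small_genome_files, tmp_path):
        synth, paths = small_genome_files
        from repa.annotation import open_genome, parse_annotation
        models = parse_annotation(paths["gtf"])
        windows, _ = extract_windows(open_genome(paths["fasta"]),
                                     derive_introns(models))
        p = tmp_path / "all.bed"
        write_sites_bed(windows, p)
        starts = [int(l.split("\t")[1]) for l in p.read_text().splitlines()]
        assert starts == sorted(starts)
        assert len(starts) == len(windows)
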