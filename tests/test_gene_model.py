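"""Gene-model parsing, splicing arithmetic and exon-skip simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skipdesign.gene_model import (
    AnnotationError,
    Exon,
    GenomeSequence,
    SequenceError,
    Transcript,
    classify_exon_frame,
    extract_target_region,
    parse_annotation,
    reverse_complement,
    simulate_exon_skip,
    spliced_sequence,
)
from skipdesign.synthetic_data import FixtureSpec, make_toy_gene

STOPS = {"TAA", "TAG", "TGA"}


class TestParseAnnotation:
    def test_gff3_coordinates_become_zero_based_half_open(
        self, simple_gff3, simple_fasta
    ):
        genome = GenomeSequence.from_fasta(simple_fasta)
        (t,) = parse_annotation(simple_gff3, genome)
        assert t.exon_lengths() == (10, 10)
        assert [(e.start, e.end) for e in t.exons] == [(10, 20), (30, 40)]

    def test_gtf_dialect_parses_identically(
        self, simple_gtf, simple_gff3, simple_fasta
    ):
        genome = GenomeSequence.from_fasta(simple_fasta)
        (t_gtf,) = parse_annotation(simple_gtf, genome)
        (t_gff,) = parse_annotation(simple_gff3, genome)
        assert [(e.start, e.end) for e in t_gtf.exons] == [
            (e.start, e.end) for e in t_gff.exons
        ]

    def test_minus_strand_exon_one_is_genomically_last(
        self, simple_gff3_minus, simple_fasta
    ):
        genome = GenomeSequence.from_fasta(simple_fasta)
        (t,) = parse_annotation(simple_gff3_minus, genome)
        assert t.exons[0].start == 30  # transcription order reversed
        assert t.exons[0].index == 1

    def test_orphan_exon_raises_naming_the_line(self, simple_fasta):
        genome = GenomeSequence.from_fasta(simple_fasta)
        gff = (
            "##gff-version 3\n"
            "chr1\ttest\tmRNA\t11\t40\t.\t+\t.\tID=tx1\n"
            "chr1\ttest\texon\t11\t20\t.\t+\t.\tID=orphan;Parent=ghost\n"
        )
        with pytest.raises(AnnotationError, match="parent"):
            parse_annotation(gff, genome)

    def test_unknown_seq_id_raises_naming_it(self, simple_gff3):
        genome = GenomeSequence({"other": "ACGT" * 20})
        with pytest.raises(AnnotationError, match="chr1"):
            parse_annotation(simple_gff3, genome)

    def test_cds_offsets_computed_on_spliced_mrna(self, toy_gene):
        t = toy_gene.transcript()
        assert (t.cds_start, t.cds_end) == tuple(toy_gene.truth.cds_spliced)
        mrna = spliced_sequence(t, toy_gene.genome())
        assert mrna[t.cds_start : t.cds_start + 3] == "ATG"
        assert mrna[t.cds_end - 3 : t.cds_end] in STOPS


class TestSplicedSequence:
    def test_single_exon_plus_is_substring(self, simple_fasta):
        genome = GenomeSequence.from_fasta(simple_fasta)
        t = Transcript(
            id="t", strand="+", exons=(Exon("chr1", 5, 15, 1),)
        )
        assert spliced_sequence(t, genome) == genome["chr1"][5:15]

    def test_minus_strand_concatenated_reverse_complement(self):
        genome = GenomeSequence({"c": "TTAAACTTGGGTTT"})
        t = Transcript(
            id="t",
            strand="-",
            exons=(Exon("c", 8, 12, 1), Exon("c", 2, 6, 2)),
        )
        # revcomp("GGGT") + revcomp("AAAC") hand-computed
        assert spliced_sequence(t, genome) == "ACCCGTTT"

    def test_out_of_bounds_exon_raises(self):
        genome = GenomeSequence({"c": "ACGT"})
        t = Transcript(id="t", strand="+", exons=(Exon("c", 0, 10, 1),))
        with pytest.raises(SequenceError):
            spliced_sequence(t, genome)

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_reverse_complement_is_an_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestExonFrame:
    @pytest.mark.parametrize(
        "length,expected",
        [(185, "out_of_frame"), (227, "out_of_frame"), (99, "in_frame"),
         (1, "out_of_frame"), (3, "in_frame")],
    )
    def test_frame_classification(self, length, expected):
        assert classify_exon_frame(length) == expected

    @pytest.mark.parametrize("bad", [0, -3])
    def test_nonpositive_length_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_exon_frame(bad)


def _random_transcript(rng):
    lengths = rng.integers(10, 120, size=3)
    seq = "".join(rng.choice(list("ACGT"), size=int(lengths.sum()) + 40))
    genome = GenomeSequence({"c": seq})
    exons, pos = [], 5
    for i, L in enumerate(lengths, start=1):
        exons.append(Exon("c", pos, pos + int(L), i))
        pos += int(L) + 10
    # keep exons inside the sequence
    genome = GenomeSequence({"c": seq + "A" * (pos - len(seq) + 10)})
    return Transcript(id="t", strand="+", exons=tuple(exons)), genome, int(lengths[1])


class TestSimulateExonSkip:
    def test_skip_length_and_frameshift_on_185nt_exon(self, toy_gene_185):
        t = toy_gene_185.transcript()
        report = simulate_exon_skip(t, 2, toy_gene_185.genome())
        assert len(report.mrna) == 220
        assert report.frameshift
        assert report.product_frame_mod == 2

    def test_in_frame_skip_is_clean_deletion(self):
        gene = make_toy_gene(FixtureSpec(seed=5, exon_lengths=(100, 99, 120)))
        t = gene.transcript()
        report = simulate_exon_skip(t, 2, gene.genome())
        assert not report.frameshift
        assert len(report.mrna) == 220
        wt = spliced_sequence(t, gene.genome())
        assert report.mrna == wt[:100] + wt[199:]

    def test_ptc_and_nmd_match_exhaustive_translation(self, toy_gene):
        t = toy_gene.transcript()
        report = simulate_exon_skip(t, toy_gene.truth.target_exon, toy_gene.genome())
        # independent oracle: brute-force codon scan of the skipped mRNA
        skip_start, skip_len = (
            t.exon_spliced_span(toy_gene.truth.target_exon)[0],
            len(t.exons[toy_gene.truth.target_exon - 1]),
        )
        expected_ptc = None
        for pos in range(t.cds_start, len(report.mrna) - 2, 3):
            codon = report.mrna[pos : pos + 3]
            if codon in STOPS and pos >= skip_start - 2:
                expected_ptc = pos
                break
        assert report.ptc_mrna_offset == expected_ptc
        assert report.frameshift
        assert report.nmd_predicted == toy_gene.truth.expected_skip["nmd_predicted"]
        assert report.nmd_predicted  # PTC sits >= 50 nt before the last junction

    def test_terminal_exon_skip_rejected(self, toy_gene):
        t = toy_gene.transcript()
        genome = toy_gene.genome()
        for idx in (1, len(t.exons)):
            with pytest.raises(ValueError, match="terminal"):
                simulate_exon_skip(t, idx, genome)

    def test_mass_balance_and_frameshift_rule_over_random_transcripts(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            t, genome, mid_len = _random_transcript(rng)
            wt = spliced_sequence(t, genome)
            report = simulate_exon_skip(t, 2, genome)
            assert len(report.mrna) + mid_len == len(wt)
            assert report.frameshift == (mid_len % 3 != 0)


class TestExtractTargetRegion:
    def test_fifty_nt_flanks_around_internal_exon(self, toy_gene_185):
        t = toy_gene_185.transcript()
        region = extract_target_region(t, 2, toy_gene_185.genome(), flank=50)
        assert len(region) == 285
        assert region.exon_span == (50, 235)
        assert region.truncated == (False, False)

    def test_short_intron_truncates_flank(self):
        genome = GenomeSequence({"c": "ACGT" * 100})
        t = Transcript(
            id="t",
            strand="+",
            exons=(Exon("c", 0, 60, 1), Exon("c", 80, 140, 2), Exon("c", 200, 260, 3)),
        )  # left intron only 20 nt
        region = extract_target_region(t, 2, genome, flank=50)
        assert len(region) == 60 + 20 + 50
        assert region.flank_lengths == (20, 50)
        assert region.truncated == (True, False)

    def test_zero_flank_is_exactly_the_exon(self, toy_gene):
        t = toy_gene.transcript()
        genome = toy_gene.genome()
        region = extract_target_region(t, 2, genome, flank=0)
        assert region.sequence == spliced_sequence(t, genome)[
            slice(*t.exon_spliced_span(2))
        ]

    def test_strand_round_trip_gives_identical_region(self, toy_gene):
        t = toy_gene.transcript()
        genome = toy_gene.genome()
        plus_region = extract_target_region(t, 2, genome, flank=50)

        seq = genome[t.seq_id]
        L = len(seq)
        flipped = GenomeSequence({t.seq_id: reverse_complement(seq)})
        minus = Transcript(
            id=t.id,
            strand="-",
            exons=tuple(
                Exon(t.seq_id, L - e.end, L - e.start, e.index) for e in t.exons
            ),
        )
        minus_region = extract_target_region(minus, 2, flipped, flank=50)
        assert minus_region.sequence == plus_region.sequence
        assert minus_region.exon_span == plus_region.exon_span
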