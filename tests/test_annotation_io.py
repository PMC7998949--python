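"""Coordinate system and FASTA/GTF round trips."""

import pytest
from hypothesis import assume, given, settings, strategies as st

from fivep.annotation_io import (
    GenomeSequence,
    TranscriptModel,
    read_annotation,
    read_genome,
    reverse_complement,
    select_representative,
    write_annotation,
)
from fivep.synthetic_degradome import DecayModelParams, build_toy_reference


def model(exons, strand="+", cds_start_t=None, cds_stop_t=None, tid="t1"):
    n = sum(e - s for s, e in exons)
    if cds_start_t is None:
        cds_start_t, cds_stop_t = 0, ((n - 1) // 3) * 3
        if cds_stop_t <= cds_start_t:
            cds_stop_t = 3
    return TranscriptModel(transcript_id=tid, gene_id="g_" + tid, reference="chr1",
                           strand=strand, exons=tuple(exons),
                           cds_start_t=cds_start_t, cds_stop_t=cds_stop_t)


class TestReadGenome:
    def test_basic_and_lowercase_normalization(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>chr2\nacgtN\n")
        recs = read_genome(p)
        assert [(r.name, r.seq) for r in recs] == [("chr1", "ACGT"), ("chr2", "ACGTN")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_genome(p) == []

    def test_malformed_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n>chr1\nACGT\n")
        with pytest.raises(ValueError, match="line 1"):
            read_genome(p)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            GenomeSequence(name="x", seq="ACGU")


class TestCoordinateConversion:
    def test_plus_anchor(self):
        m = model([(100, 200)])
        assert m.genomic_to_transcript(100) == 0
        assert m.transcript_to_genomic(0) == 100

    def test_minus_anchor(self):
        m = model([(100, 200)], strand="-")
        assert m.genomic_to_transcript(199) == 0
        assert m.transcript_to_genomic(0) == 199

    def test_two_exon_splice(self):
        # brute-force enumeration of the spliced positions
        m = model([(0, 50), (100, 150)])
        spliced = list(range(0, 50)) + list(range(100, 150))
        assert m.genomic_to_transcript(100) == 50
        for t, g in enumerate(spliced):
            assert m.genomic_to_transcript(g) == t
            assert m.transcript_to_genomic(t) == g

    def test_intronic_and_outside_positions_are_none(self):
        m = model([(0, 50), (100, 150)])
        for g in (50, 99, 150, 1000):
            assert m.genomic_to_transcript(g) is None

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        gaps=st.lists(st.tuples(st.integers(1, 30), st.integers(1, 40)),
                      min_size=1, max_size=6),
        strand=st.sampled_from("+-"),
    )
    def test_round_trip_bijection(self, gaps, strand):
        """transcript_to_genomic inverts genomic_to_transcript over all exonic
        positions, bijectively, on both strands."""
        exons, pos = [], 0
        for gap, length in gaps:
            pos += gap
            exons.append((pos, pos + length))
            pos += length
        assume(sum(e - s for s, e in exons) >= 5)  # room for a >=3 nt CDS
        m = model(exons, strand=strand)
        seen = set()
        for g in m.exonic_positions():
            t = m.genomic_to_transcript(g)
            assert t is not None and m.transcript_to_genomic(t) == g
            seen.add(t)
        assert seen == set(range(m.spliced_length))


GTF_PLUS = (
    'chr1\tx\texon\t1\t300\t.\t+\t.\tgene_id "gA"; transcript_id "tA";\n'
    'chr1\tx\tCDS\t101\t250\t.\t+\t.\tgene_id "gA"; transcript_id "tA";\n'
    'chr1\tx\tstop_codon\t251\t253\t.\t+\t.\tgene_id "gA"; transcript_id "tA";\n'
)
GTF_MINUS = (
    'chr1\tx\texon\t1\t300\t.\t-\t.\tgene_id "gB"; transcript_id "tB";\n'
    'chr1\tx\tCDS\t51\t200\t.\t-\t.\tgene_id "gB"; transcript_id "tB";\n'
    'chr1\tx\tstop_codon\t48\t50\t.\t-\t.\tgene_id "gB"; transcript_id "tB";\n'
)


class TestReadAnnotation:
    def test_plus_strand_coordinates(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_PLUS)
        (m,) = read_annotation(p)
        assert (m.cds_start_t, m.cds_stop_t) == (100, 250)

    def test_minus_strand_coordinates(self, tmp_path):
        p = tmp_path / "b.gtf"
        p.write_text(GTF_MINUS)
        (m,) = read_annotation(p)
        assert m.cds_stop_t == 250
        assert m.cds_start_t == 100

    def test_minus_strand_stop_by_reverse_complement(self, tmp_path):
        """Brute-force check: place revcomp('TAA') at the stop_codon feature
        and confirm the spliced sequence shows TAA at cds_stop_t."""
        p = tmp_path / "b.gtf"
        p.write_text(GTF_MINUS)
        (m,) = read_annotation(p)
        seq = ["A"] * 300
        seq[47:50] = list(reverse_complement("TAA"))
        genome = {"chr1": GenomeSequence("chr1", "".join(seq))}
        t = m.spliced_sequence(genome)
        assert t[m.cds_stop_t : m.cds_stop_t + 3] == "TAA"

    def test_cds_not_multiple_of_three_rejected(self, tmp_path):
        bad = GTF_PLUS.replace("\t101\t250\t", "\t101\t200\t")  # CDS length 100
        p = tmp_path / "c.gtf"
        p.write_text(bad)
        assert read_annotation(p) == []

    def test_missing_stop_codon_rejected(self, tmp_path):
        p = tmp_path / "d.gtf"
        p.write_text("".join(l for l in GTF_PLUS.splitlines(keepends=True)
                             if "stop_codon" not in l))
        assert read_annotation(p) == []

    def test_write_read_identity_on_simulator_models(self, tmp_path):
        params = DecayModelParams(n_transcripts=6, total_reads=100, seed=3)
        _, models = build_toy_reference(params)
        p = tmp_path / "sim.gtf"
        write_annotation(models, p)
        back = read_annotation(p)
        key = lambda m: (m.transcript_id, m.gene_id, m.reference, m.strand,
                         m.exons, m.cds_start_t, m.cds_stop_t)
        assert sorted(map(key, back)) == sorted(map(key, models))


def test_select_representative_longest_then_lexicographic():
    def iso(tid, exons):
        return TranscriptModel(transcript_id=tid, gene_id="g", reference="chr1",
                               strand="+", exons=exons, cds_start_t=0, cds_stop_t=30)

    a = iso("t2", ((0, 90),))
    b = iso("t1", ((0, 60),))
    c = iso("t0", ((100, 190),))
    # t2 and t0 share the max length; the lexicographically smaller id wins
    assert [m.transcript_id for m in select_representative([a, b, c])] == ["t0"]


def test_model_invariant_enforcement():
    with pytest.raises(ValueError, match="overlap"):
        model([(0, 50), (40, 90)])
    with pytest.raises(ValueError, match="divisible by 3"):
        model([(0, 100)], cds_start_t=0, cds_stop_t=50)
    with pytest.raises(ValueError, match="outside spliced length"):
        model([(0, 30)], cds_start_t=0, cds_stop_t=30)
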