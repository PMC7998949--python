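"""Generative-model contracts: geometry, determinism, mixture structure."""

import dataclasses

import numpy as np
import pytest

from fivep.annotation_io import SiteAnnotation
from fivep.synthetic_degradome import (
    DecayModelParams,
    build_toy_reference,
    emit_reads,
    sample_fiveprime_ends,
    toy_contaminants,
)


def params(**kw):
    base = dict(n_transcripts=4, total_reads=10_000, seed=5)
    base.update(kw)
    return DecayModelParams(**base)


class TestBuildToyReference:
    def test_geometry_and_codons(self):
        p = params(n_transcripts=1, utr5_len=60, cds_len=300, utr3_len=90)
        genomes, (m,) = build_toy_reference(p)
        assert m.spliced_length == 450
        assert (m.cds_start_t, m.cds_stop_t) == (60, 357)
        genome = {g.name: g for g in genomes}
        t = m.spliced_sequence(genome)
        assert t[60:63] == "ATG"
        assert t[357:360] in ("TAA", "TAG", "TGA")
        # the annotated stop is the first in-frame stop of the CDS
        internal = [t[i : i + 3] for i in range(60, 357, 3)]
        assert not any(c in ("TAA", "TAG", "TGA") for c in internal)

    def test_strand_alternation(self):
        _, models = build_toy_reference(params(n_transcripts=10))
        strands = [m.strand for m in models]
        assert strands.count("+") == 5 and strands.count("-") == 5

    def test_deterministic_per_seed(self):
        g1, m1 = build_toy_reference(params())
        g2, m2 = build_toy_reference(params())
        assert [x.seq for x in g1] == [x.seq for x in g2]
        assert m1 == m2
        g3, _ = build_toy_reference(params(seed=6))
        assert [x.seq for x in g3] != [x.seq for x in g1]


class TestSampleFivePrimeEnds:
    def test_pure_periodic_is_frame_anchored(self):
        p = params(p_periodic=1.0, p_term=0.0, p_background=0.0)
        _, models = build_toy_reference(p)
        truth = sample_fiveprime_ends(p, models)
        start = {m.transcript_id: m.cds_start_t for m in models}
        rel = truth.reads.pos_t.to_numpy() - truth.reads.transcript_id.map(start).to_numpy()
        assert (rel % 3 == 0).all()
        assert (truth.reads.label == "periodic").all()

    def test_pure_periodic_autocorrelation_peaks_at_lag_3(self):
        """Brute-force oracle: the pooled CDS-relative end histogram of the
        comb component has its first nonzero-lag autocorrelation max at 3."""
        p = params(p_periodic=1.0, p_term=0.0, p_background=0.0)
        _, models = build_toy_reference(p)
        truth = sample_fiveprime_ends(p, models)
        start = {m.transcript_id: m.cds_start_t for m in models}
        rel = (truth.reads.pos_t.to_numpy()
               - truth.reads.transcript_id.map(start).to_numpy())
        hist = np.bincount(rel)
        x = hist - hist.mean()
        ac = [np.dot(x[:-lag], x[lag:]) for lag in range(1, 13)]
        assert int(np.argmax(ac)) + 1 == 3

    def test_pure_term_all_at_offset(self):
        for off in (17, 16):
            p = params(p_periodic=0.0, p_term=1.0, p_background=0.0, term_offset=off)
            _, models = build_toy_reference(p)
            truth = sample_fiveprime_ends(p, models)
            stop = {m.transcript_id: m.cds_stop_t for m in models}
            assert (truth.reads.pos_t
                    == truth.reads.transcript_id.map(stop) - off).all()

    def test_component_fractions_within_binomial_error(self):
        p = params(total_reads=10_000)
        _, models = build_toy_reference(p)
        truth = sample_fiveprime_ends(p, models)
        obs = truth.reads.label.value_counts(normalize=True)
        for label, expected in (("periodic", p.p_periodic), ("term", p.p_term),
                                ("background", p.p_background)):
            se = np.sqrt(expected * (1 - expected) / p.total_reads)
            assert abs(obs.get(label, 0.0) - expected) < 3 * se

    def test_site_beyond_transcript_raises_before_sampling(self):
        p = params()
        _, models = build_toy_reference(p)
        bad = SiteAnnotation(models[0].transcript_id, 10_000, "mirna_cleavage")
        with pytest.raises(ValueError, match="beyond"):
            sample_fiveprime_ends(p, models, sites=[bad], site_weight=0.05)

    def test_site_component_lands_exactly_on_site(self):
        p = params(total_reads=5000)
        _, models = build_toy_reference(p)
        site = SiteAnnotation(models[1].transcript_id, 120, "uorf_stall", "u1")
        truth = sample_fiveprime_ends(p, models, sites=[site], site_weight=0.2)
        s = truth.reads[truth.reads.label == "site"]
        assert len(s) > 0
        assert (s.pos_t == 120).all() and (s.transcript_id == site.transcript_id).all()


class TestEmitReads:
    def test_conservation_and_determinism(self, tmp_path):
        p = params(total_reads=2000)
        genomes, models = build_toy_reference(p)
        truth = sample_fiveprime_ends(p, models)
        out = {}
        for run in ("a", "b"):
            d = tmp_path / run
            out[run] = emit_reads(truth, models, genomes, d)
        n_fastq = out["a"]["fastq"].read_text().count("\n") // 4
        n_bed = len(out["a"]["bed"].read_text().splitlines())
        assert n_fastq == n_bed == len(truth) == p.total_reads
        for k in ("fastq", "bed", "alignments"):
            assert out["a"][k].read_bytes() == out["b"][k].read_bytes()

    def test_bed_positions_match_strand_convention(self, tmp_path):
        p = params(n_transcripts=2, total_reads=500, p_periodic=0.0,
                   p_term=1.0, p_background=0.0)
        genomes, models = build_toy_reference(p)
        truth = sample_fiveprime_ends(p, models)
        paths = emit_reads(truth, models, genomes, tmp_path)
        by_tid = {m.transcript_id: m for m in models}
        rows = [l.split("\t") for l in paths["bed"].read_text().splitlines()]
        expected = {m.strand: m.transcript_to_genomic(m.cds_stop_t - p.term_offset)
                    for m in models}
        for ref, start, end, name, score, strand in rows:
            assert int(end) == int(start) + 1
            assert int(start) == expected[strand]

    def test_read_sequences_come_from_the_five_prime_end(self, tmp_path):
        p = params(n_transcripts=2, total_reads=200)
        genomes, models = build_toy_reference(p)
        genome = {g.name: g for g in genomes}
        truth = sample_fiveprime_ends(p, models)
        paths = emit_reads(truth, models, genomes, tmp_path)
        tseq = {m.transcript_id: m.spliced_sequence(genome) for m in models}
        lines = paths["fastq"].read_text().splitlines()
        for (_, row), i in zip(truth.reads.iterrows(), range(0, len(lines), 4)):
            expect = tseq[row.transcript_id][row.pos_t : row.pos_t + p.read_length]
            assert lines[i + 1] == expect

    def test_empty_truth_gives_valid_empty_outputs(self, tmp_path):
        p = params(total_reads=2000)
        genomes, models = build_toy_reference(p)
        truth = sample_fiveprime_ends(p, models)
        truth.reads = truth.reads.iloc[0:0]
        paths = emit_reads(truth, models, genomes, tmp_path)
        assert paths["fastq"].read_text() == ""
        assert paths["bed"].read_text() == ""

    def test_contaminant_component_labelled_and_emitted(self, tmp_path):
        p = params(p_contaminant=0.3, total_reads=3000)
        genomes, models = build_toy_reference(p)
        contam = toy_contaminants(p)
        truth = sample_fiveprime_ends(p, models, contaminants=contam)
        frac = (truth.reads.label == "contaminant").mean()
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / p.total_reads)
        paths = emit_reads(truth, models, genomes, tmp_path, contaminants=contam)
        assert paths["fastq"].read_text().count("\n") // 4 == p.total_reads
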