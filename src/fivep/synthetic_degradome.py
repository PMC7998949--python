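"""Synthetic 5'P degradome generator.

Emulates the signal structure of co-translational mRNA decay: a 5'->3'
exoribonuclease (XRN1/XRN4) trails the last translating ribosome codon by
codon, so captured 5'P ends form (a) a frame-anchored 3-nt comb within the
CDS, (b) an over-accumulation at a fixed distance upstream of the stop codon
(the footprint boundary of a ribosome with its A site on the stop; default
17 nt), and (c) a uniform decay background.  Optional single-position
components model miRNA cleavage spikes and uORF stall footprints, and an
optional contaminant component draws reads from an rRNA-like contig.

Outputs are a toy genome (FASTA), annotation (GTF), reads (FASTQ), true
5'-end positions (BED6) and an alignment table (TSV), plus a per-read ground
truth so every downstream read-out can be scored by parameter recovery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    GenomeSequence,
    SiteAnnotation,
    TranscriptModel,
    reverse_complement,
    write_annotation,
    write_genome,
    write_sites_bed,
)

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
#: DNA sequence of the 5' adapter ligated to 5'P ends (for exercising trimming)
RA5_DNA = "GTTCAGAGTTCTACAGTCCGACGATC"

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

COMPONENT_LABELS = ("periodic", "term", "background", "site", "contaminant")


@dataclass(frozen=True)
class DecayModelParams:
    """Parameters of the generative co-translational decay model.

    Lengths are nt; ``cds_len`` includes the stop codon.  The mixture weights
    ``p_periodic`` (3-nt comb), ``p_term`` (termination pause at
    ``term_offset`` nt upstream of the stop codon's first nucleotide) and
    ``p_background`` (uniform decay) must sum to 1.  ``p_contaminant`` is an
    extra fraction of reads drawn from an rRNA-like contaminant contig,
    applied on top (the mRNA mixture is scaled by 1 - p_contaminant).
    """

    n_transcripts: int = 200
    utr5_len: int = 60
    cds_len: int = 300
    utr3_len: int = 90
    abundance_dispersion: float = 1.0
    p_periodic: float = 0.55
    p_term: float = 0.15
    p_background: float = 0.30
    term_offset: int = 17
    frame_anchor: int = 0
    read_length: int = 75
    total_reads: int = 500_000
    seed: int = 0
    p_contaminant: float = 0.0

    def __post_init__(self) -> None:
        w = (self.p_periodic, self.p_term, self.p_background)
        if any(x < 0 for x in w):
            raise ValueError("mixture weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(w)}")
        if not 0.0 <= self.p_contaminant < 1.0:
            raise ValueError("p_contaminant must be in [0, 1)")
        if self.term_offset < 0:
            raise ValueError("term_offset must be >= 0")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.cds_len % 3 != 0 or self.cds_len < 6:
            raise ValueError("cds_len must be divisible by 3 and >= 6")
        if self.frame_anchor not in (0, 1, 2):
            raise ValueError("frame_anchor must be 0, 1 or 2")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "DecayModelParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GroundTruth:
    """Per-read ground truth: one row per emitted read.

    Columns: read_id, transcript_id, pos_t (5'-end transcript coordinate),
    label (mixture component), reference, gpos (genomic position of the
    5'-most nucleotide), strand.
    """

    reads: pd.DataFrame
    params: DecayModelParams

    def __len__(self) -> int:
        return len(self.reads)


def _rngs(params: DecayModelParams) -> tuple[np.random.Generator, ...]:
    """Independent streams for (reference, sampling, contaminant) from one seed."""
    ss = np.random.SeedSequence(params.seed)
    return tuple(np.random.default_rng(c) for c in ss.spawn(3))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def toy_contaminants(params: DecayModelParams, length: int = 3000) -> list[GenomeSequence]:
    """An rRNA-like contaminant contig (deterministic per seed)."""
    rng = _rngs(params)[2]
    return [GenomeSequence(name="contam_rRNA", seq=_random_seq(rng, length))]


def build_toy_reference(
    params: DecayModelParams, batch_size: int = 50, spacer: int = 100,
) -> tuple[list[GenomeSequence], list[TranscriptModel]]:
    """Toy genome + annotation: single-exon transcripts, alternating strand.

    Transcripts are laid out on contigs of up to ``batch_size`` transcripts,
    separated by >= ``spacer`` nt of random sequence.  Each transcript carries
    ATG at ``cds_start_t`` and a stop codon at ``cds_stop_t``; internal codons
    are drawn from the 61 sense codons so the single annotated stop is the
    first in-frame stop of the CDS.
    """
    rng = _rngs(params)[0]
    p = params
    tlen = p.utr5_len + p.cds_len + p.utr3_len
    genomes: list[GenomeSequence] = []
    models: list[TranscriptModel] = []
    width = len(str(max(p.n_transcripts, 1)))

    i = 0
    contig_idx = 0
    while i < p.n_transcripts:
        contig_idx += 1
        chunks: list[str] = []
        pos = 0
        contig_name = f"synchr{contig_idx}"
        for _ in range(min(batch_size, p.n_transcripts - i)):
            chunks.append(_random_seq(rng, spacer))
            pos += spacer
            n_codons = p.cds_len // 3
            cds = "ATG" + "".join(
                _SENSE_CODONS[j] for j in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
            ) + STOP_CODONS[rng.integers(0, 3)]
            tseq = _random_seq(rng, p.utr5_len) + cds + _random_seq(rng, p.utr3_len)
            strand = "+" if i % 2 == 0 else "-"
            chunks.append(tseq if strand == "+" else reverse_complement(tseq))
            tid = f"SYNT{i + 1:0{width}d}"
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=f"SYNG{i + 1:0{width}d}",
                    reference=contig_name,
                    strand=strand,
                    exons=((pos, pos + tlen),),
                    cds_start_t=p.utr5_len,
                    cds_stop_t=p.utr5_len + p.cds_len - 3,
                )
            )
            pos += tlen
            i += 1
        chunks.append(_random_seq(rng, spacer))
        genomes.append(GenomeSequence(name=contig_name, seq="".join(chunks)))
    return genomes, models


def sample_fiveprime_ends(
    params: DecayModelParams,
    models: Sequence[TranscriptModel],
    sites: Sequence[SiteAnnotation] = (),
    site_weight: float = 0.0,
    contaminants: Sequence[GenomeSequence] = (),
) -> GroundTruth:
    """Draw ``total_reads`` 5'P ends from the mixture model.

    Per-transcript expected depth is proportional to a log-normal abundance
    draw (sd ``abundance_dispersion`` on the log scale).  Within a transcript
    the 5'-end position is drawn from: the frame-anchored comb restricted to
    ``[cds_start_t, cds_stop_t - term_offset)``; the termination pause at
    exactly ``cds_stop_t - term_offset``; the uniform background over
    ``[0, spliced_length - read_length]``; and, on transcripts carrying
    annotated sites, a mass of ``site_weight`` at each site position.
    All reads come from a single multinomial draw, so regeneration with the
    same seed is exactly reproducible.
    """
    p = params
    rng = _rngs(p)[1]
    by_tid = {m.transcript_id: m for m in models}
    sites_by_tid: dict[str, list[SiteAnnotation]] = {}
    for s in sites:
        if s.transcript_id not in by_tid:
            raise ValueError(f"site references unknown transcript {s.transcript_id!r}")
        if s.position_t >= by_tid[s.transcript_id].spliced_length:
            raise ValueError(
                f"site position {s.position_t} beyond transcript "
                f"{s.transcript_id} (length {by_tid[s.transcript_id].spliced_length})"
            )
        sites_by_tid.setdefault(s.transcript_id, []).append(s)
    if p.p_contaminant > 0 and not contaminants:
        raise ValueError("p_contaminant > 0 but no contaminant sequences given")

    abundance = rng.lognormal(mean=0.0, sigma=p.abundance_dispersion, size=len(models))
    t_mass = abundance / abundance.sum() * (1.0 - p.p_contaminant)

    cell_tid: list[str] = []
    cell_pos: list[int] = []
    cell_label: list[str] = []
    cell_prob: list[float] = []

    for m, mass in zip(models, t_mass):
        tsites = sites_by_tid.get(m.transcript_id, [])
        site_mass_total = site_weight * len(tsites)
        if site_mass_total >= 1.0:
            raise ValueError(f"site_weight x n_sites >= 1 on {m.transcript_id}")
        mix_mass = mass * (1.0 - site_mass_total)
        for s in tsites:
            cell_tid.append(m.transcript_id)
            cell_pos.append(s.position_t)
            cell_label.append("site")
            cell_prob.append(mass * site_weight)
        # frame-anchored comb
        if p.p_periodic > 0:
            lo = m.cds_start_t + p.frame_anchor
            hi = m.cds_stop_t - p.term_offset
            comb = list(range(lo, hi, 3)) if lo < hi else []
            if not comb:
                raise ValueError(
                    f"no comb positions on {m.transcript_id}; CDS too short "
                    f"for term_offset {p.term_offset}"
                )
            w = mix_mass * p.p_periodic / len(comb)
            for q in comb:
                cell_tid.append(m.transcript_id)
                cell_pos.append(q)
                cell_label.append("periodic")
                cell_prob.append(w)
        # termination pause
        if p.p_term > 0:
            cell_tid.append(m.transcript_id)
            cell_pos.append(m.cds_stop_t - p.term_offset)
            cell_label.append("term")
            cell_prob.append(mix_mass * p.p_term)
        # uniform decay background
        if p.p_background > 0:
            hi = m.spliced_length - p.read_length
            if hi < 0:
                raise ValueError(f"transcript {m.transcript_id} shorter than read_length")
            w = mix_mass * p.p_background / (hi + 1)
            for q in range(0, hi + 1):
                cell_tid.append(m.transcript_id)
                cell_pos.append(q)
                cell_label.append("background")
                cell_prob.append(w)

    if p.p_contaminant > 0:
        contam = contaminants[0]
        hi = len(contam) - p.read_length
        w = p.p_contaminant / (hi + 1)
        for q in range(0, hi + 1):
            cell_tid.append(contam.name)
            cell_pos.append(q)
            cell_label.append("contaminant")
            cell_prob.append(w)

    prob = np.asarray(cell_prob)
    prob = prob / prob.sum()  # guard tiny float drift
    counts = rng.multinomial(p.total_reads, prob)

    idx = np.repeat(np.arange(len(counts)), counts)
    tids = np.array(cell_tid, dtype=object)[idx]
    poss = np.array(cell_pos)[idx]
    labels = np.array(cell_label, dtype=object)[idx]

    # genomic position of the 5'-most nucleotide, per unique cell
    gpos_cell = np.empty(len(counts), dtype=np.int64)
    ref_cell = np.empty(len(counts), dtype=object)
    strand_cell = np.empty(len(counts), dtype=object)
    for j in range(len(counts)):
        if counts[j] == 0:
            continue
        if cell_label[j] == "contaminant":
            gpos_cell[j] = cell_pos[j]
            ref_cell[j] = cell_tid[j]
            strand_cell[j] = "+"
        else:
            m = by_tid[cell_tid[j]]
            gpos_cell[j] = m.transcript_to_genomic(cell_pos[j])
            ref_cell[j] = m.reference
            strand_cell[j] = m.strand

    n = len(idx)
    width = len(str(max(n, 1)))
    df = pd.DataFrame(
        {
            "read_id": [f"r{k + 1:0{width}d}" for k in range(n)],
            "transcript_id": tids,
            "pos_t": poss,
            "label": labels,
            "reference": ref_cell[idx],
            "gpos": gpos_cell[idx],
            "strand": strand_cell[idx],
        }
    )
    return GroundTruth(reads=df, params=p)


# ---------------------------------------------------------------------- #
# read emission


def iter_alignment_records(truth: GroundTruth, models: Sequence[TranscriptModel],
                           contaminants: Sequence[GenomeSequence] = ()):
    """Alignment records (read_id, reference, pos0, strand, mapq, length) for
    every read in the ground truth, as if produced by a perfect unique aligner."""
    from .read_processing import AlignmentRecord

    by_tid = {m.transcript_id: m for m in models}
    contam_len = {c.name: len(c) for c in contaminants}
    p = truth.params
    for row in truth.reads.itertuples(index=False):
        if row.label == "contaminant":
            length = min(p.read_length, contam_len.get(row.transcript_id, p.read_length)
                         - row.pos_t)
            yield AlignmentRecord(row.read_id, row.reference, int(row.gpos), "+", 60, length)
        else:
            m = by_tid[row.transcript_id]
            length = min(p.read_length, m.spliced_length - row.pos_t)
            if m.strand == "+":
                left = int(row.gpos)
            else:
                left = m.transcript_to_genomic(row.pos_t + length - 1)
            yield AlignmentRecord(row.read_id, row.reference, left, m.strand, 60, length)


def emit_reads(
    truth: GroundTruth,
    models: Sequence[TranscriptModel],
    genomes: Sequence[GenomeSequence],
    out_dir: str | Path,
    prefix: str = "sim",
    contaminants: Sequence[GenomeSequence] = (),
    adapter_fraction: float = 0.0,
    adapter_seq: str = RA5_DNA,
) -> dict[str, Path]:
    """Write FASTQ reads, true 5'-end BED and the alignment TSV.

    Read sequences run from the 5'P end for ``read_length`` nt, truncated at
    the transcript 3' end; constant quality.  ``adapter_fraction`` > 0
    prepends the 5' adapter to that fraction of reads (deterministic per
    seed) to exercise the fixed-length trimming contract downstream.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = truth.params
    genome = {g.name: g for g in genomes}
    contam = {c.name: c for c in contaminants}
    by_tid = {m.transcript_id: m for m in models}
    tseq = {tid: m.spliced_sequence(genome) for tid, m in by_tid.items()}

    if adapter_fraction > 0:
        arng = np.random.default_rng(np.random.SeedSequence([p.seed, 0xADA9]))
        with_adapter = arng.random(len(truth.reads)) < adapter_fraction
    else:
        with_adapter = np.zeros(len(truth.reads), dtype=bool)

    fastq = out_dir / f"{prefix}.fastq"
    bed = out_dir / f"{prefix}.true_ends.bed"
    tsv = out_dir / f"{prefix}.alignments.tsv"
    with open(fastq, "w") as fq, open(bed, "w") as fb, open(tsv, "w") as ft:
        ft.write("read_id\treference\tpos0\tstrand\tmapq\tlength\n")
        for k, row in enumerate(truth.reads.itertuples(index=False)):
            if row.label == "contaminant":
                src = contam[row.transcript_id].seq
                seq = src[row.pos_t : row.pos_t + p.read_length]
                strand = "+"
                left = int(row.gpos)
            else:
                m = by_tid[row.transcript_id]
                seq = tseq[row.transcript_id][row.pos_t : row.pos_t + p.read_length]
                strand = m.strand
                left = (int(row.gpos) if strand == "+"
                        else m.transcript_to_genomic(row.pos_t + len(seq) - 1))
            if with_adapter[k]:
                seq = adapter_seq + seq
            fq.write(f"@{row.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            fb.write(f"{row.reference}\t{row.gpos}\t{int(row.gpos) + 1}\t"
                     f"{row.read_id}\t0\t{row.strand}\n")
            ft.write(f"{row.read_id}\t{row.reference}\t{left}\t{strand}\t60\t{len(seq)}\n")
    return {"fastq": fastq, "bed": bed, "alignments": tsv}


def simulate(
    params: DecayModelParams,
    out_dir: str | Path,
    sites: Sequence[SiteAnnotation] = (),
    site_weight: float = 0.0,
    prefix: str = "sim",
) -> dict[str, Path]:
    """End-to-end simulation: reference, annotation, reads, truth, params echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genomes, models = build_toy_reference(params)
    contaminants = toy_contaminants(params) if params.p_contaminant > 0 else []
    truth = sample_fiveprime_ends(params, models, sites=sites,
                                  site_weight=site_weight, contaminants=contaminants)
    paths = emit_reads(truth, models, genomes, out_dir, prefix=prefix,
                       contaminants=contaminants)
    paths["genome"] = out_dir / f"{prefix}.genome.fasta"
    write_genome(list(genomes) + list(contaminants), paths["genome"])
    paths["gtf"] = out_dir / f"{prefix}.annotation.gtf"
    write_annotation(models, paths["gtf"])
    paths["truth"] = out_dir / f"{prefix}.truth.tsv"
    truth.reads.to_csv(paths["truth"], sep="\t", index=False)
    paths["params"] = out_dir / f"{prefix}.params.json"
    params.to_json(paths["params"])
    if sites:
        paths["sites"] = out_dir / f"{prefix}.sites.bed"
        write_sites_bed(sites, models, paths["sites"])
    if contaminants:
        paths["contaminants"] = out_dir / f"{prefix}.contaminants.fasta"
        write_genome(contaminants, paths["contaminants"])
    return paths
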