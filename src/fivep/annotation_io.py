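"""Genome FASTA / GTF annotation / BED I/O and the transcript coordinate system.

Every positional read-out in the pipeline (stop-codon metagene, CDS
periodicity vector, peak calling) is defined in *transcript coordinates*:
0-based positions along the spliced transcript running 5'->3', so that on a
minus-strand transcript position 0 is the genomic 3'-most exon base.  All
internal coordinates are 0-based half-open; GTF I/O converts from/to the
1-based closed convention, BED I/O is natively 0-based half-open.

The anchor convention used throughout: ``cds_stop_t`` is the transcript
coordinate of the FIRST nucleotide of the stop codon, and the stop codon is
not part of ``[cds_start_t, cds_stop_t)``.  "17 nt before the stop codon"
therefore means transcript position ``cds_stop_t - 17``, metagene offset -17.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence (chromosome/contig) over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError(f"genome sequence {self.name!r} is empty")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"genome sequence {self.name!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SiteAnnotation:
    """A single-nucleotide event annotation on a transcript.

    ``kind`` distinguishes a uORF ribosome-stall footprint in the 5'UTR from
    an endonucleolytic (miRNA-guided) cleavage position.
    """

    transcript_id: str
    position_t: int
    kind: str  # {"uorf_stall", "mirna_cleavage"}
    label: str = ""

    def __post_init__(self) -> None:
        if self.position_t < 0:
            raise ValueError("site position must be >= 0")
        if self.kind not in ("uorf_stall", "mirna_cleavage"):
            raise ValueError(f"unknown site kind {self.kind!r}")


@dataclass(frozen=True)
class TranscriptModel:
    """Spliced transcript with exon structure, CDS span and strand.

    ``exons`` are genomic 0-based half-open intervals, non-overlapping and
    sorted by genomic coordinate regardless of strand.  ``cds_start_t`` is
    the transcript coordinate of the A of the start codon; ``cds_stop_t``
    the transcript coordinate of the first nucleotide of the stop codon
    (stop codon excluded from the CDS interval).
    """

    transcript_id: str
    gene_id: str
    reference: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_t: int
    cds_stop_t: int
    _cumlen: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise ValueError(f"{self.transcript_id}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = end
        cum = [0]
        for start, end in exons:
            cum.append(cum[-1] + (end - start))
        object.__setattr__(self, "_cumlen", tuple(cum))
        n = self.spliced_length
        if not (0 <= self.cds_start_t < self.cds_stop_t < n):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start_t},{self.cds_stop_t}) "
                f"outside spliced length {n}"
            )
        if (self.cds_stop_t - self.cds_start_t) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")

    @property
    def spliced_length(self) -> int:
        return self._cumlen[-1]

    @property
    def cds_length(self) -> int:
        """CDS length in nt, stop codon excluded."""
        return self.cds_stop_t - self.cds_start_t

    # ------------------------------------------------------------------ #
    # coordinate conversion

    def _plus_offset(self, gpos: int) -> int | None:
        """Offset of gpos along the concatenated exons in genomic order."""
        starts = [e[0] for e in self.exons]
        i = bisect_right(starts, gpos) - 1
        if i < 0:
            return None
        start, end = self.exons[i]
        if gpos >= end:
            return None
        return self._cumlen[i] + (gpos - start)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Transcript coordinate of a genomic position, or None if intronic/outside."""
        off = self._plus_offset(gpos)
        if off is None:
            return None
        return off if self.strand == "+" else self.spliced_length - 1 - off

    def transcript_to_genomic(self, tpos: int) -> int:
        """Genomic position of transcript coordinate ``tpos`` (inverse of above)."""
        n = self.spliced_length
        if not 0 <= tpos < n:
            raise ValueError(f"transcript position {tpos} outside [0,{n})")
        off = tpos if self.strand == "+" else n - 1 - tpos
        i = bisect_right(self._cumlen, off) - 1
        start, _ = self.exons[i]
        return start + (off - self._cumlen[i])

    def exonic_positions(self) -> Iterator[int]:
        """All genomic positions covered by exons, in genomic order."""
        for start, end in self.exons:
            yield from range(start, end)

    def transcript_interval_to_genomic(self, t0: int, t1: int) -> list[tuple[int, int]]:
        """Map transcript interval [t0,t1) to genomic intervals (sorted, merged)."""
        if not 0 <= t0 < t1 <= self.spliced_length:
            raise ValueError(f"bad transcript interval [{t0},{t1})")
        gpos = sorted(self.transcript_to_genomic(t) for t in range(t0, t1))
        out: list[tuple[int, int]] = []
        for g in gpos:
            if out and g == out[-1][1]:
                out[-1] = (out[-1][0], g + 1)
            else:
                out.append((g, g + 1))
        return out

    def spliced_sequence(self, genome: dict[str, GenomeSequence]) -> str:
        """Spliced transcript sequence 5'->3' (reverse-complemented on minus strand)."""
        ref = genome[self.reference].seq
        s = "".join(ref[start:end] for start, end in self.exons)
        return s if self.strand == "+" else reverse_complement(s)

    def region_of(self, tpos: int) -> str:
        """Classify a transcript position as 5UTR / CDS / 3UTR.

        The stop codon itself counts as CDS.
        """
        if tpos < self.cds_start_t:
            return "5UTR"
        if tpos < self.cds_stop_t + 3:
            return "CDS"
        return "3UTR"


# ---------------------------------------------------------------------- #
# FASTA


def read_genome(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA into GenomeSequence records, uppercasing sequences."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header starting "
                        f"with '>', got {line.strip()[:30]!r}"
                    )
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSequence(name=rec.id, seq=str(rec.seq).upper()))
    return records


def write_genome(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------- #
# GTF


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF with exon/CDS/stop_codon features.

    Transcripts whose CDS length is not divisible by 3, or that lack a
    stop_codon feature, fail their invariants: they are skipped with a
    logged warning, not fatal.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tid: dict[str, dict[str, list]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for f in db.all_features():
        if f.featuretype not in ("exon", "CDS", "start_codon", "stop_codon"):
            continue
        try:
            tid = f["transcript_id"][0]
            gid = f["gene_id"][0]
        except KeyError:
            log.warning("feature without transcript_id/gene_id skipped: %s", f)
            continue
        d = by_tid.setdefault(tid, {"exon": [], "CDS": [], "start_codon": [], "stop_codon": []})
        # GTF is 1-based closed; convert to 0-based half-open
        d[f.featuretype].append((f.start - 1, f.end))
        meta[tid] = (gid, f.seqid, f.strand)

    models: list[TranscriptModel] = []
    for tid, d in by_tid.items():
        gid, ref, strand = meta[tid]
        exons = tuple(sorted(d["exon"]))
        if not exons or not d["CDS"]:
            log.warning("transcript %s skipped: missing exon or CDS features", tid)
            continue
        if not d["stop_codon"]:
            log.warning("transcript %s skipped: missing stop codon", tid)
            continue
        cds_len = sum(e - s for s, e in d["CDS"])
        if cds_len % 3 != 0:
            log.warning("transcript %s skipped: CDS length %d not divisible by 3", tid, cds_len)
            continue
        try:
            conv = _ExonConverter(exons, strand)
            cds_min = min(s for s, _ in d["CDS"])
            cds_max = max(e for _, e in d["CDS"])
            stop_min = min(s for s, _ in d["stop_codon"])
            stop_max = max(e for _, e in d["stop_codon"])
            if strand == "+":
                cds_start_t = conv.g2t(cds_min)
                cds_stop_t = conv.g2t(stop_min)
            else:
                cds_start_t = conv.g2t(cds_max - 1)
                cds_stop_t = conv.g2t(stop_max - 1)
            if cds_start_t is None or cds_stop_t is None:
                raise ValueError("CDS/stop codon not on exons")
            models.append(
                TranscriptModel(
                    transcript_id=tid, gene_id=gid, reference=ref, strand=strand,
                    exons=exons, cds_start_t=cds_start_t, cds_stop_t=cds_stop_t,
                )
            )
        except ValueError as exc:
            log.warning("transcript %s skipped: %s", tid, exc)
    return models


class _ExonConverter:
    """Minimal genomic->transcript converter over an exon scaffold."""

    def __init__(self, exons: Sequence[tuple[int, int]], strand: str):
        self.exons = list(exons)
        self.strand = strand
        self.cum = [0]
        for s, e in self.exons:
            self.cum.append(self.cum[-1] + (e - s))

    def g2t(self, gpos: int) -> int | None:
        for i, (s, e) in enumerate(self.exons):
            if s <= gpos < e:
                off = self.cum[i] + (gpos - s)
                return off if self.strand == "+" else self.cum[-1] - 1 - off
        return None


def write_annotation(models: Iterable[TranscriptModel], path: str | Path,
                     source: str = "fivep") -> None:
    """Write transcript models as GTF2.2 (exon, CDS, start_codon, stop_codon)."""

    def gtf_line(m: TranscriptModel, ftype: str, start0: int, end0: int) -> str:
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        return (f"{m.reference}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t.\t"
                f"{m.strand}\t.\t{attrs}\n")

    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                fh.write(gtf_line(m, "exon", s, e))
            for s, e in m.transcript_interval_to_genomic(m.cds_start_t, m.cds_stop_t):
                fh.write(gtf_line(m, "CDS", s, e))
            for s, e in m.transcript_interval_to_genomic(m.cds_start_t, m.cds_start_t + 3):
                fh.write(gtf_line(m, "start_codon", s, e))
            for s, e in m.transcript_interval_to_genomic(m.cds_stop_t, m.cds_stop_t + 3):
                fh.write(gtf_line(m, "stop_codon", s, e))


def select_representative(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """One model per gene: the longest spliced isoform, ties broken by transcript_id."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (cur is None
                or m.spliced_length > cur.spliced_length
                or (m.spliced_length == cur.spliced_length
                    and m.transcript_id < cur.transcript_id)):
            best[m.gene_id] = m
    return sorted(best.values(), key=lambda m: m.transcript_id)


# ---------------------------------------------------------------------- #
# site BED export


def write_sites_bed(sites: Iterable[SiteAnnotation],
                    models: dict[str, TranscriptModel] | Iterable[TranscriptModel],
                    path: str | Path) -> None:
    """Export site annotations as BED6 in genomic coordinates (name = kind:label)."""
    if not isinstance(models, dict):
        models = {m.transcript_id: m for m in models}
    with open(path, "w") as fh:
        for s in sites:
            m = models[s.transcript_id]
            g = m.transcript_to_genomic(s.position_t)
            name = f"{s.kind}:{s.label}" if s.label else s.kind
            fh.write(f"{m.reference}\t{g}\t{g + 1}\t{name}\t0\t{m.strand}\n")
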