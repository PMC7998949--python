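"""Pre-alignment contracts: fixed-length trimming, contaminant subtraction,
alignment ingestion with the unique-mapping filter.

Trimming truncates the 3' end only — the 5' nucleotide is the measurement
and must never be clipped.  Contaminant removal is an exact k-mer prefix
match against the contaminant set (and its reverse complement); a
pre-filtered BAM from any aligner is equally accepted downstream.  Alignment
ingestion drops unmapped/secondary/supplementary records and applies the
samtools ``-q`` semantics: drop MAPQ strictly below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .annotation_io import GenomeSequence, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_TRIM_LENGTH = 50
DEFAULT_MAPQ_MIN = 10
DEFAULT_CONTAMINANT_K = 20

ALIGNMENT_TSV_COLUMNS = ("read_id", "reference", "pos0", "strand", "mapq")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read: leftmost 0-based reference position and strand.

    ``read_length`` is the reference span of the alignment; it is needed to
    recover the 5' end of minus-strand reads and may be None when the source
    format does not carry it.
    """

    read_id: str
    reference: str
    pos0: int
    strand: str
    mapq: int
    read_length: int | None = None

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError("alignment position must be >= 0")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


# ---------------------------------------------------------------------- #
# FASTQ


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield ReadRecord(read_id=rec.id, sequence=str(rec.seq), quality=qual)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


# ---------------------------------------------------------------------- #
# operations


def trim_to_length(reads: Iterable[ReadRecord],
                   max_len: int = DEFAULT_TRIM_LENGTH) -> Iterator[ReadRecord]:
    """Truncate every read to at most ``max_len`` nt from the 3' end.

    Idempotent; read count conserved; qualities truncated identically.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    for r in reads:
        if len(r) <= max_len:
            yield r
        else:
            yield ReadRecord(r.read_id, r.sequence[:max_len], r.quality[:max_len])


def contaminant_kmer_index(contaminant_seqs: Iterable[GenomeSequence],
                           k: int = DEFAULT_CONTAMINANT_K) -> frozenset[str]:
    """All k-mers of the contaminant sequences and their reverse complements."""
    kmers: set[str] = set()
    for g in contaminant_seqs:
        for s in (g.seq, reverse_complement(g.seq)):
            kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    return frozenset(kmers)


def filter_contaminants(reads: Iterable[ReadRecord],
                        contaminant_seqs: Iterable[GenomeSequence],
                        k: int = DEFAULT_CONTAMINANT_K) -> Iterator[ReadRecord]:
    """Drop reads whose first k nt occur verbatim in a contaminant sequence
    (either strand).  With an empty contaminant set, every read is kept."""
    index = (contaminant_kmer_index(contaminant_seqs, k)
             if not isinstance(contaminant_seqs, frozenset) else contaminant_seqs)
    n_in = n_dropped = 0
    for r in reads:
        n_in += 1
        if r.sequence[:k] in index:
            n_dropped += 1
            continue
        yield r
    log.info("filter_contaminants: dropped %d of %d reads", n_dropped, n_in)


def load_alignments(path: str | Path,
                    mapq_min: int = DEFAULT_MAPQ_MIN) -> Iterator[AlignmentRecord]:
    """Stream alignments from BAM/SAM (via pysam) or the alignment TSV dialect.

    BAM/SAM: unmapped, secondary (0x100) and supplementary (0x800) records
    are dropped before the MAPQ filter; the reference span of the alignment
    provides ``read_length``.  TSV: tab-separated with a header line
    ``read_id reference pos0 strand mapq [length]``.
    Records with ``mapq < mapq_min`` are dropped (samtools -q semantics);
    the dropped count is logged.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".bam", ".sam", ".cram"):
        yield from _load_bam(path, mapq_min)
    elif suffix in (".tsv", ".txt"):
        yield from _load_tsv(path, mapq_min)
    else:
        raise ValueError(
            f"unknown alignment format {path.name!r}: expected .bam/.sam/.cram "
            f"or the .tsv alignment-table dialect"
        )


def _load_bam(path: Path, mapq_min: int) -> Iterator[AlignmentRecord]:
    n_dropped = 0
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for a in bam.fetch(until_eof=True):
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                n_dropped += 1
                continue
            if a.mapping_quality < mapq_min:
                n_dropped += 1
                continue
            yield AlignmentRecord(
                read_id=a.query_name,
                reference=a.reference_name,
                pos0=a.reference_start,
                strand="-" if a.is_reverse else "+",
                mapq=a.mapping_quality,
                read_length=a.reference_end - a.reference_start,
            )
    log.info("load_alignments(%s): dropped %d records", path.name, n_dropped)


def _load_tsv(path: Path, mapq_min: int) -> Iterator[AlignmentRecord]:
    n_dropped = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:5]) != ALIGNMENT_TSV_COLUMNS:
            raise ValueError(
                f"{path}: bad alignment TSV header {header[:5]}; "
                f"expected {list(ALIGNMENT_TSV_COLUMNS)}"
            )
        has_len = len(header) > 5 and header[5] == "length"
        for line in fh:
            f = line.rstrip("\n").split("\t")
            mapq = int(f[4])
            if mapq < mapq_min:
                n_dropped += 1
                continue
            yield AlignmentRecord(
                read_id=f[0], reference=f[1], pos0=int(f[2]), strand=f[3],
                mapq=mapq, read_length=int(f[5]) if has_len else None,
            )
    log.info("load_alignments(%s): dropped %d records", path.name, n_dropped)
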