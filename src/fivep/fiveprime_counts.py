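"""Single-nucleotide 5'P end extraction, transcript-level counting and the
RPM detection rule.

A degradome read reports one molecule's 5'P extremity: the leftmost aligned
base on the plus strand, the rightmost on the minus strand.  Ends are
assigned to genes at single-nucleotide resolution with union-mode ambiguity
semantics (an end exonic in two or more genes on the matching strand is
ambiguous and discarded).  RPM uses the total of uniquely mapped ends
*before* assignment as the per-million denominator, and transcript detection
is the strict rule RPM > threshold (default 5).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation_io import TranscriptModel
from .read_processing import AlignmentRecord

log = logging.getLogger(__name__)

DEFAULT_RPM_THRESHOLD = 5.0


@dataclass(frozen=True)
class FivePrimeEnd:
    """One observed 5'P extremity (single nucleotide) with multiplicity."""

    reference: str
    position: int
    strand: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class CountTable:
    """Per-transcript raw 5'P end counts and RPM.

    ``library_total`` is the number of uniquely mapped ends before gene
    assignment — the RPM denominator.  ``ambiguous``/``intergenic`` account
    for the ends not assigned, so assigned + ambiguous + intergenic =
    library_total.
    """

    raw: dict[str, int]
    library_total: int
    ambiguous: int = 0
    intergenic: int = 0

    def rpm(self, transcript_id: str) -> float:
        if self.library_total == 0:
            return 0.0
        return self.raw.get(transcript_id, 0) / self.library_total * 1e6

    @property
    def assigned_total(self) -> int:
        return sum(self.raw.values())

    def to_frame(self, rpm_threshold: float = DEFAULT_RPM_THRESHOLD) -> pd.DataFrame:
        tids = sorted(self.raw)
        df = pd.DataFrame({
            "transcript_id": tids,
            "raw_count": [self.raw[t] for t in tids],
        })
        df["rpm"] = df["raw_count"] / self.library_total * 1e6 if self.library_total else 0.0
        df["detected"] = df["rpm"] > rpm_threshold
        return df


@dataclass
class ReplicateComparison:
    """Replicate agreement: Pearson r on log2(rpm+1) over the union of the
    two detected sets, and the detected-set overlap partition."""

    pearson_r: float | None
    n_common: int
    n_a_only: int
    n_b_only: int
    transform: str = "log2(rpm+1)"


def ends_to_dict(ends: Iterable[FivePrimeEnd]) -> dict[tuple[str, int, str], int]:
    """Aggregate ends into a {(reference, position, strand): count} map."""
    d: dict[tuple[str, int, str], int] = {}
    for e in ends:
        key = (e.reference, e.position, e.strand)
        d[key] = d.get(key, 0) + e.count
    return d


def extract_five_prime_ends(
    alignments: Iterable[AlignmentRecord],
    read_lengths: int | Mapping[str, int] | None = None,
) -> list[FivePrimeEnd]:
    """Collapse alignments to single-nucleotide 5' ends.

    Plus-strand read at leftmost position p -> end at p; minus-strand read
    spanning [p, p+L) -> end at p+L-1.  ``read_lengths`` supplies L when the
    records do not carry it: a constant, or a read_id -> length mapping.
    Identical (reference, position, strand) triples are aggregated.
    """
    counter: Counter[tuple[str, int, str]] = Counter()
    for a in alignments:
        if a.strand == "+":
            pos = a.pos0
        else:
            if a.read_length is not None:
                length = a.read_length
            elif isinstance(read_lengths, int):
                length = read_lengths
            elif read_lengths is not None:
                length = read_lengths[a.read_id]
            else:
                raise ValueError(
                    f"read length unknown for minus-strand read {a.read_id!r}; "
                    f"pass read_lengths"
                )
            pos = a.pos0 + length - 1
        counter[(a.reference, pos, a.strand)] += 1
    return [
        FivePrimeEnd(reference=r, position=p, strand=s, count=c)
        for (r, p, s), c in sorted(counter.items())
    ]


def assign_to_transcripts(
    ends: Iterable[FivePrimeEnd],
    models: Sequence[TranscriptModel],
) -> CountTable:
    """Union-mode gene assignment of single-nucleotide ends.

    An end counts for a gene iff its position is exonic in exactly one gene
    on the matching strand; ends exonic in two or more genes are ambiguous,
    ends in no gene intergenic — both discarded but tallied so the total is
    conserved.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    gene_to_tid: dict[str, str] = {}
    for m in models:
        tree = trees.setdefault((m.reference, m.strand), IntervalTree())
        for s, e in m.exons:
            tree[s:e] = m.gene_id
        gene_to_tid[m.gene_id] = m.transcript_id

    raw: dict[str, int] = {m.transcript_id: 0 for m in models}
    total = ambiguous = intergenic = 0
    for e in ends:
        total += e.count
        tree = trees.get((e.reference, e.strand))
        genes = {iv.data for iv in tree[e.position]} if tree is not None else set()
        if len(genes) == 1:
            raw[gene_to_tid[genes.pop()]] += e.count
        elif len(genes) > 1:
            ambiguous += e.count
        else:
            intergenic += e.count
    return CountTable(raw=raw, library_total=total,
                      ambiguous=ambiguous, intergenic=intergenic)


def detected_set(table: CountTable,
                 rpm_threshold: float = DEFAULT_RPM_THRESHOLD) -> set[str]:
    """Transcripts detected under the strict rule RPM > threshold."""
    return {t for t in table.raw if table.rpm(t) > rpm_threshold}


def compare_replicates(
    a: CountTable,
    b: CountTable,
    rpm_threshold: float = DEFAULT_RPM_THRESHOLD,
) -> ReplicateComparison:
    """Detected-set overlap and Pearson correlation of log2(rpm+1) between
    two libraries, computed over the union of their detected sets."""
    if not a.raw or not b.raw:
        raise ValueError("both count tables must be nonempty")
    da, db = detected_set(a, rpm_threshold), detected_set(b, rpm_threshold)
    union = sorted(da | db)
    r: float | None = None
    if len(union) >= 3:
        xa = np.log2([a.rpm(t) + 1 for t in union])
        xb = np.log2([b.rpm(t) + 1 for t in union])
        if np.ptp(xa) > 0 and np.ptp(xb) > 0:
            r = float(stats.pearsonr(xa, xb).statistic)
        elif np.array_equal(xa, xb):
            r = 1.0
    return ReplicateComparison(
        pearson_r=r,
        n_common=len(da & db),
        n_a_only=len(da - db),
        n_b_only=len(db - da),
    )


# ---------------------------------------------------------------------- #
# BED / TSV I/O


def write_ends_bed(ends: Iterable[FivePrimeEnd], path: str | Path) -> None:
    """BED6 export of aggregated 5' ends; the score column carries the count."""
    with open(path, "w") as fh:
        for e in ends:
            fh.write(f"{e.reference}\t{e.position}\t{e.position + 1}\t"
                     f"end\t{e.count}\t{e.strand}\n")


def read_ends_bed(path: str | Path) -> list[FivePrimeEnd]:
    ends = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            if end != start + 1:
                raise ValueError(f"{path}: not a single-nucleotide 5'-end record: {line!r}")
            count = int(f[4]) if len(f) > 4 and int(f[4]) > 0 else 1
            ends.append(FivePrimeEnd(reference=f[0], position=start,
                                     strand=f[5] if len(f) > 5 else "+", count=count))
    return ends


def write_count_table(table: CountTable, path: str | Path,
                      rpm_threshold: float = DEFAULT_RPM_THRESHOLD) -> None:
    table.to_frame(rpm_threshold).to_csv(path, sep="\t", index=False)
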