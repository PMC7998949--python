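"""Single-position 5'P accumulation events: uORF stalls and miRNA cleavage.

A stalled ribosome (e.g. on a uORF) or an endonucleolytic cut guided by a
miRNA leaves a sharp spike of 5'P ends at one transcript position.  Calls
are descriptive: a position is a peak iff its end count clears an absolute
floor and a fold-enrichment over the transcript's own mean per-position
coverage, which makes the call depth-invariant.  The universal termination
pause (offsets -18..-15 to the stop codon) is masked by default so it is
not called on every well-expressed transcript.  No p-value is attached —
both thresholds are exposed instead of inventing a null model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import SiteAnnotation, TranscriptModel
from .fiveprime_counts import FivePrimeEnd, ends_to_dict

log = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 10
DEFAULT_MIN_FOLD = 20.0
DEFAULT_TERM_MASK = (-18, -15)  # offsets to the stop codon's first nt, inclusive


@dataclass(frozen=True)
class PeakCall:
    transcript_id: str
    position_t: int
    count: int
    fold_enrichment: float
    region: str  # {"5UTR", "CDS", "3UTR"}


@dataclass
class RecoveryResult:
    recall: float
    precision: float | None  # None when there are no calls
    hits: pd.DataFrame  # one row per truth site: transcript_id, position_t, kind, hit, call_pos


def call_peaks(
    ends: Iterable[FivePrimeEnd] | Mapping[tuple[str, int, str], int],
    models: Sequence[TranscriptModel],
    min_count: int = DEFAULT_MIN_COUNT,
    min_fold: float = DEFAULT_MIN_FOLD,
    term_mask: tuple[int, int] | None = DEFAULT_TERM_MASK,
) -> list[PeakCall]:
    """Call single-position peaks per transcript.

    A position is called iff count >= min_count and count >= min_fold x
    (transcript total ends / spliced length).  ``term_mask`` excludes the
    stated offset range around the stop codon (None disables).  Calls are
    sorted by fold enrichment, descending.
    """
    if min_count <= 0 or min_fold <= 0:
        raise ValueError("thresholds must be positive")
    end_map = ends if isinstance(ends, Mapping) else ends_to_dict(ends)
    calls: list[PeakCall] = []
    for m in models:
        per_pos: dict[int, int] = {}
        for t in range(m.spliced_length):
            g = m.transcript_to_genomic(t)
            c = end_map.get((m.reference, g, m.strand), 0)
            if c:
                per_pos[t] = c
        total = sum(per_pos.values())
        if total == 0:
            continue
        mean = total / m.spliced_length
        if term_mask is not None:
            masked = range(m.cds_stop_t + term_mask[0], m.cds_stop_t + term_mask[1] + 1)
            masked = set(masked)
        else:
            masked = set()
        for t, c in per_pos.items():
            if t in masked:
                continue
            if c >= min_count and c >= min_fold * mean:
                calls.append(PeakCall(
                    transcript_id=m.transcript_id, position_t=t, count=c,
                    fold_enrichment=c / mean, region=m.region_of(t),
                ))
    calls.sort(key=lambda c: (-c.fold_enrichment, c.transcript_id, c.position_t))
    return calls


def evaluate_recovery(
    calls: Sequence[PeakCall],
    truth_sites: Sequence[SiteAnnotation],
    tolerance: int = 0,
) -> RecoveryResult:
    """Score calls against annotated sites.

    A truth site is hit iff a call exists on the same transcript within
    ``tolerance`` nt; recall = hits / truth sites, precision = matched calls
    / all calls (None when there are no calls).
    """
    calls_by_tid: dict[str, list[PeakCall]] = {}
    for c in calls:
        calls_by_tid.setdefault(c.transcript_id, []).append(c)

    rows = []
    for s in truth_sites:
        near = [c for c in calls_by_tid.get(s.transcript_id, [])
                if abs(c.position_t - s.position_t) <= tolerance]
        rows.append({
            "transcript_id": s.transcript_id, "position_t": s.position_t,
            "kind": s.kind, "hit": bool(near),
            "call_pos": near[0].position_t if near else pd.NA,
        })
    hits = pd.DataFrame(rows, columns=["transcript_id", "position_t", "kind",
                                       "hit", "call_pos"])
    recall = float(hits["hit"].mean()) if len(hits) else 0.0

    site_index = {(s.transcript_id, s.position_t) for s in truth_sites}
    n_matched = sum(
        1 for c in calls
        if any((c.transcript_id, s.position_t) in site_index
               and abs(c.position_t - s.position_t) <= tolerance
               for s in truth_sites if s.transcript_id == c.transcript_id)
    )
    precision = n_matched / len(calls) if calls else None
    return RecoveryResult(recall=recall, precision=precision, hits=hits)


def write_peaks_tsv(calls: Iterable[PeakCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tcount\tfold\tregion\n")
        for c in calls:
            fh.write(f"{c.transcript_id}\t{c.position_t}\t{c.count}\t"
                     f"{c.fold_enrichment:.4g}\t{c.region}\n")


def write_peaks_bed(calls: Iterable[PeakCall],
                    models: Sequence[TranscriptModel] | dict[str, TranscriptModel],
                    path: str | Path) -> None:
    """BED6 export of peak calls in genomic coordinates (score = count)."""
    if not isinstance(models, dict):
        models = {m.transcript_id: m for m in models}
    with open(path, "w") as fh:
        for c in calls:
            m = models[c.transcript_id]
            g = m.transcript_to_genomic(c.position_t)
            fh.write(f"{m.reference}\t{g}\t{g + 1}\t{c.transcript_id}:{c.region}\t"
                     f"{c.count}\t{m.strand}\n")
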