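# fivep — 5′P degradome analysis of co-translational mRNA decay

`fivep` analyzes 5′P degradome sequencing data (GMUCT / PARE-style
libraries), in which the 5′ monophosphate ends of mRNA decay intermediates
are captured and sequenced. During co-translational decay, a 5′→3′
exoribonuclease (XRN1 in yeast, XRN4 in *Arabidopsis*) degrades an mRNA
while it is still being translated, advancing codon by codon behind the last
ribosome. This leaves two diagnostic signatures in the positions of 5′P
ends:

- a **3-nt periodicity** of 5′P ends within coding sequences (the codon
  step of the trailing ribosome), and
- an **over-accumulation of 5′P ends 16–17 nt upstream of stop codons** —
  the protected-fragment boundary of a ribosome whose A site holds the stop
  codon during the slow termination step.

The package computes these read-outs (and transcript-level 5′P counts,
replicate comparison, and single-position peak calls for uORF ribosome
stalls and miRNA cleavage sites), condenses them into a machine-readable
library-QC verdict, and ships a synthetic degradome generator with per-read
ground truth so every read-out can be validated by parameter recovery —
no external sequencing data required.

## Core quantities

For a transcript with spliced coordinates 0‥n−1 and the stop codon's first
nucleotide at position `s`:

- **5′P end**: the leftmost aligned base of a plus-strand read, the
  rightmost of a minus-strand read, collapsed to single-nucleotide
  resolution.
- **RPM**: per-transcript raw 5′P end count × 10⁶ / total uniquely mapped
  ends; a transcript is *detected* iff RPM > 5 (strict).
- **Stop metagene**: pooled end counts at offsets −50‥+10 around `s`
  (offset 0 = first stop nucleotide, so "17 nt before the stop" is offset
  −17), 1-nt bins, normalized by the in-window total.
- **Periodicity spectrum**: DFT magnitudes |X_k|, k = 1‥L/2, of the
  mean-subtracted pooled CDS end-count vector (margins exclude initiation
  and termination pile-ups; L truncated to a multiple of 3). The dominant
  period is L/argmax_k |X_k|; a healthy library gives 3.
- **QC verdict**: `pass` iff dominant period = 3 **and** the stop-metagene
  peak falls in −18‥−15; `warn` if exactly one holds; `fail` otherwise.

## Worked example

```python
from fivep import (DecayModelParams, build_toy_reference, sample_fiveprime_ends,
                   extract_five_prime_ends, build_metagene, peak_offset,
                   cds_end_vector, fft_periodicity, frame_fractions,
                   assign_to_transcripts, detected_set)
from fivep.synthetic_degradome import iter_alignment_records

params = DecayModelParams(n_transcripts=50, total_reads=100_000, seed=7)
genomes, models = build_toy_reference(params)
truth = sample_fiveprime_ends(params, models)
ends = extract_five_prime_ends(iter_alignment_records(truth, models))

table = assign_to_transcripts(ends, models)
print(f"detected transcripts (RPM > 5): {len(detected_set(table))}")

profile = build_metagene(ends, models, anchor="stop", win_up=-50, win_down=10)
peak = peak_offset(profile)
print(f"stop-codon peak: offset {peak.offset}, prominence {peak.prominence:.1f}")

spec = fft_periodicity(cds_end_vector(ends, models))
frames = frame_fractions(ends, models)
print(f"dominant period: {spec.dominant_period} nt "
      f"(power share at 3 nt: {spec.relative_power_3nt:.2f})")
print("frame fractions:", [round(float(f), 3) for f in frames.fractions])
```

prints

```
detected transcripts (RPM > 5): 50
stop-codon peak: offset -17, prominence 182.3
dominant period: 3.0 nt (power share at 3 nt: 0.62)
frame fractions: [0.672, 0.244, 0.084]
```

All 50 simulated transcripts clear the detection threshold; the metagene
peaks at −17 (the injected termination-pause offset, recovered exactly and
standing ~180× above the median bin); the DFT identifies the 3-nt codon
step, with most CDS 5′P ends in the frame the comb was anchored to.

The same analyses are available from the shell:

```bash
fivep simulate --params params.json --out sim/
fivep qc --config qc.json --out qcdir/        # exit status 1 on verdict "fail"
fivep count|metagene|periodicity|peaks --help
```

`fivep qc` runs the full stage order — fixed-length trimming (50 nt, 3′ end
only, the 5′ nucleotide *is* the measurement), contaminant subtraction,
alignment ingestion with the unique-mapping filter (MAPQ ≥ 10), 5′-end
extraction, counting, metagene and periodicity — and writes
`qc_report.json` with the verdict and every stage's parameters.

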