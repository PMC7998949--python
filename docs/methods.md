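# Methods

## The measurement

A 5′P degradome library captures RNA molecules with a 5′ monophosphate —
the chemical end left by decapping or endonucleolytic cleavage — and
sequences them from the 5′ extremity (single-read, 75 cycles by default).
Each read therefore reports exactly one coordinate: the 5′-most aligned
nucleotide. Everything in this package is built on that single-nucleotide
signal; full read spans are used only to locate the 5′ end of minus-strand
alignments.

During co-translational decay the 5′→3′ exoribonuclease advances only when
the last translating ribosome translocates, so the ensemble of 5′P ends
carries ribosome-dynamic information: a 3-nt comb through the CDS, and a
pile-up where the ribosome dwells longest — termination — at a fixed
distance upstream of the stop codon set by the ribosome's protected
footprint (16 or 17 nt depending on tissue/condition; this package's
simulator defaults to 17).

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF I/O converts from the
1-based closed convention, BED is natively 0-based. Transcript coordinates
run 5′→3′ along the spliced transcript; on a minus-strand transcript
position 0 is the genomic 3′-most exon base. `cds_stop_t` is the transcript
position of the **first** nucleotide of the stop codon, and the stop codon
is excluded from `[cds_start_t, cds_stop_t)`. Consequently "a peak 17 nt
before the stop codon" is metagene offset −17 with no ±1 ambiguity; the
convention is echoed in all outputs. When a gene has several isoforms, one
representative model is used for positional analyses: the longest spliced
isoform, ties broken lexicographically by transcript id (annotation sets
rarely state which isoform positional read-outs should anchor on; a single
deterministic choice keeps the stop anchor unambiguous).

## Pipeline stages and their parameters

| stage | parameter | default | why |
|---|---|---|---|
| trimming | `trim_len` | 50 nt | protocol standard for SR75 degradome reads; truncation is 3′-only so the 5′P coordinate is never touched |
| contaminant filter | `k` | 20 nt | a read is dropped iff its first k nt occur verbatim in the contaminant set (chloroplast/mito/rRNA/small RNA) or its reverse complement; an exact-prefix contract is deterministic and auditable, and a pre-filtered BAM from a local aligner is accepted instead |
| unique-mapping filter | `mapq_min` | 10 | samtools `-q` semantics: drop MAPQ strictly below the threshold, so MAPQ 10 passes |
| counting | `rpm_threshold` | 5 | detection rule is strict: RPM > 5. The RPM denominator is the total of uniquely mapped ends *before* gene assignment |
| metagene | `win_up`, `win_down` | −50, +10 | covers the −17 signal with margin; transcripts not fully covering the window are excluded, never zero-padded (padding biases the flanks) |
| periodicity | `start_margin`, `stop_margin` | 9, 24 | excludes initiation and termination pile-ups from the elongation-periodicity estimate — the termination peak would otherwise leak power into the spectrum |
| peak calling | `min_count`, `min_fold` | 10, 20 | see below |
| QC verdict | `peak_window` | −18‥−15 | covers both reported termination-pause distances (16 and 17 nt) |

Counting uses union-mode semantics at single-nucleotide resolution: an end
counts for a gene iff its position is exonic in exactly one gene on the
matching strand; ends exonic in ≥2 genes are ambiguous, ends in none
intergenic, and assigned + ambiguous + intergenic equals the library total
(a conservation law the tests enforce). This differs from interval-overlap
union counting on full read spans: the degradome signal is the 5′P
position, and single-nucleotide assignment makes the ambiguity class
well-defined. Replicate agreement is summarized as Pearson r on
log2(rpm+1) over the union of the two detected sets (the log tames the
heteroscedasticity of count data; the transform is recorded in the output).

## Periodicity spectrum

The pooled CDS end-count vector (common analysis length L = shortest
transcript's margin-trimmed CDS, truncated to a multiple of 3 so period 3
is an exact DFT frequency) is mean-subtracted and transformed; amplitudes
|X_k| are reported for k = 1‥⌊L/2⌋, the dominant period is L/argmax, and
`relative_power_3nt` = |X_{L/3}| / Σ|X_k|. Mean subtraction removes the k=0
component that would otherwise dominate any spectrum of nonnegative counts.
One DFT is taken on the aggregate vector rather than averaging
per-transcript spectra: at desk-scale depth most individual transcripts are
too sparse for a stable per-transcript estimate. A constant vector yields an
all-zero spectrum and an undefined dominant period rather than an arbitrary
argmax.

## Peak calling

uORF stalls and miRNA cleavage sites appear as single-position spikes. A
position is called iff its end count ≥ `min_count` **and** ≥ `min_fold` ×
the transcript's own mean per-position count. Enrichment against the
transcript's own coverage (not a global background) makes calls
depth-invariant, matching how such events are identified on browser tracks.
Offsets −18‥−15 relative to the stop codon are masked by default —
otherwise the universal termination pause would be "called" on every
well-expressed transcript. No p-value is attached: there is no agreed null
model for degradome spikes, and both thresholds are exposed rather than a
significance number that would imply one.

## The synthetic degradome generator

The generator is the package's test bed and defines its study conditions.
Per-read 5′P ends are drawn from a mixture over each transcript:

- `p_periodic` (default 0.55): uniform over the frame-anchored comb
  {cds_start + frame_anchor + 3k} within [cds_start, cds_stop − term_offset);
- `p_term` (default 0.15): exactly at cds_stop − term_offset (default 17);
- `p_background` (default 0.30): uniform decay background over
  [0, spliced_length − read_length];
- optional per-site mass (`site_weight`) at annotated uORF-stall / cleavage
  positions, and an optional contaminant fraction drawn from an rRNA-like
  contig.

The comb/termination/background split is a modeling choice (the relative
magnitudes of these components are not standardized quantities); the
defaults give a clearly decaying-library signal without making the
background negligible, and all three are parameters. Per-transcript
abundance is log-normal (sd 1.0 on the log scale, a standard desk-scale
stand-in for expression distributions), renormalized by a single multinomial
over (transcript, position, component) cells — so one seed fixes every
output byte-for-byte. Toy transcripts are single-exon (60/300/90 nt
UTR5/CDS/UTR3 by default), laid out with ≥100-nt spacers, alternating
strand, ATG at the start and a single in-frame stop at the annotated stop;
intron-containing models are exercised through the annotation unit fixtures
instead. Reads are emitted "pre-trimmed": no adapter or quality noise by
default (an `adapter_fraction` option prepends the 5′ adapter to exercise
trimming), and the alignment table is written by construction rather than by
running an aligner — alignment itself is upstream tooling, not part of this
package's scope.

What the simulator does **not** emulate: sequencing errors, PCR
duplicates, mappability structure, isoform mixtures, codon-specific pause
heterogeneity, or 5′UTR/3′UTR length variation. Passing parameter-recovery
tests therefore demonstrates that the read-outs measure what they claim on
data with the assumed signal structure — not that real libraries will be
this clean.

## Problem sizes and validation

The bundled validation study simulates 200 transcripts at 5×10⁵ reads for
the two headline recoveries (termination-pause offset; dominant period) —
deep enough that both read-outs are stable across seeds — and smaller
configurations (≤10³ ends) where read-outs are checked against brute-force
oracles: metagene bins against a direct double loop, the period-3 amplitude
against single-frequency summation (relative error ≤ 1e-9), per-transcript
counts against the generator's per-read labels, and spectrum energy against
Parseval's identity. Site recovery uses 20 transcripts of mRNA-realistic
length (150/1200/150 nt) at 10⁵ reads with 5% per-site mass across 10
seeds: at that geometry a true site sits ~3.8× above the fold threshold, so
recovery failures would indicate a caller defect rather than shot noise at
the decision boundary.

## Known limitations

- Union-mode assignment at 5′-nucleotide resolution diverges from
  interval-based counting for reads whose 5′ end falls in one gene but
  whose body spans another.
- The QC verdict is a deliberate simplification (two boolean read-outs); it
  does not grade periodicity strength, and `relative_power_3nt` is reported
  but unthresholded.
- `fold_enrichment` for peak calls compares against the transcript mean,
  which is inflated for transcripts that are themselves dominated by one
  spike; recall is unaffected but the reported fold is conservative there.
- Metagene and periodicity pool counts globally (no per-transcript
  weighting), so a few very deep transcripts can dominate both read-outs —
  matching the single-global-denominator normalization they are defined
  with.
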