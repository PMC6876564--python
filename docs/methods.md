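# Methods

## Problem and pipeline model

Libraries sequenced here retain the mRNA poly(A) tail in the cDNA, so a
circular-consensus (CCS) read contains, 5'→3': a shared cDNA primer,
the transcript body, the poly(A) tail, and the reverse complement of a
sample probe (16-nt barcode + first 6 nt of the template-switching
oligo, 22 nt total). Consensus accuracy is governed by the number of
polymerase passes; all base-resolved tail analyses require ≥ 10 passes
(`min_passes`, default 10), which is applied once, at tail calling, and
not re-applied downstream.

### Demultiplexing and cleanup

Probe matching is semi-global (infix) alignment under total Levenshtein
distance — substitutions and indels count together — with
`max_edits = 2`. The phrase "mismatches or indels" is read as a
combined bound because that is both the standard reading and strictly
more conservative. Multiple occurrences are found best-first (edlib
infix alignment, matched window masked between rounds) with ties broken
leftmost-then-shortest; overlapping placements resolve to the
lowest-edit one.

Per read: probes of all samples are searched on both strands. Hits to
two or more barcodes discard the read as ambiguous. A single barcode
hit orients the read so the probe's reverse complement sits at the 3'
end; the probe and everything 3' of it are trimmed. Interior probe
occurrences mark concatemers: the interior match and all sequence 5' of
it are dropped, keeping the 3'-most library unit. A probe matching both
strands of one read is an orientation conflict and the read is set
aside (discarding is the conservative choice; the layout cannot be
established). The shared 5' primer is removed when present (searched
within the first 50 nt; a primer found beyond that window is treated as
a residual concatemer joint). Cleaned sequences shorter than `min_len`
(default 50 nt, plumbing choice, configurable) are dropped. Barcodes
must be separated by more than `2*max_edits` edits for error-bounded
reads to be unambiguous; the `ProbeSet` warns when they are not.

### Tail calling

The tail is the terminal clipped segment at the read's 3' end of a
primary spliced alignment (secondary and supplementary records are
rejected, never silently used). For minus-strand alignments this is the
left clip of the stored record; the sequence is always reported in read
orientation and is sliced from the clean read itself, so hard-clipped
bases are recovered. Acceptance requires, in order: length ≥ 15 nt; a
run of ≥ 5 consecutive A; non-A residues < 50% of the clip and < 20 in
number (N counts as non-A everywhere — an uncalled base is never
credited as adenosine). A read whose 5'-end clip would also pass all
three criteria is rejected as suspicious rather than risk calling a
residual adapter a tail. Tail length is the clip length; no upper cap
is imposed. Per-gene length is the geometric mean, with `min_reads = 3`
for distribution-style summaries and 10 for cross-replicate
correlations.

### Non-A residues

Per transcript, G/C/U(T) counts are divided by tail length; the non-A
ratio is their sum. Per gene, counts and lengths are pooled before
dividing (not a mean of ratios). The run spectrum counts maximal
same-base non-A runs in categories 1/2/3/4+. "Internal" fractions are
reported twice: after stripping the maximal terminal non-A run
(terminal residues are partially lost to adapter pairing during library
construction and are unreliable) and raw; length-binned tables carry
both a per-read fraction and a per-base frequency column since both
conventions are in use. Positional profiles use K = 20 equal
relative-position bins plus an absolute 5'-anchored variant, because
tails vary in length and either convention may be wanted.

The T30VN classifier takes an oriented, adapter-trimmed read and the
query coordinate where the aligned 3'-UTR ends. The terminal A stretch
(complement of the primer's T30) must be ≥ 25 nt (30 minus tolerance;
configurable, no published threshold exists). If the segment between
UTR end and terminal stretch is one or more A followed by exactly 1–2
non-A bases, the primer anchored within the tail body (model b, with
the anchor bases reported); anything else is model a.

### Spike-ins

Spike-in reads are parsed structurally: orientation from a body-terminal
anchor (last 30 nt of the reporter CDS, ≤ 3 edits), then 5' primer
(≤ 2 edits) before the body, 3' primer (≤ 2 edits) after it; the tail
is the sequence between body anchor and 3' primer, and the design is
the lowest-edit barcode match after the 5' primer (ties rejected).
Reads missing any element are excluded as not full length. Per design
the report gives n, the arithmetic mean tail length (designed tails are
homogeneous, so no log transform is warranted), recovery fraction, and
the mismatch rate (non-A bases over tail bases) that bounds artefacts
introduced after reverse transcription. No minimum-length filter
applies, keeping the 10-nt design measurable. The packaged design files
are synthetic stand-ins with the published layout and designed lengths
(10/30/50/70/100 nt); real design tables load via `load_panel`.

### Genes and polyadenylation sites

Exons are read from GTF (1-based inclusive → 0-based half-open), merged
per gene with duplicates removed, and indexed in an interval tree.
Reads overlap genes through their M/=/X/D reference blocks (intron N
gaps do not count); a unique ≥ 1 bp overlap assigns the gene,
multi-gene overlaps discard the read. Cleavage positions (strand-aware
genomic 3' ends of tail-bearing reads) are clustered per gene by
single-linkage with a 24-nt window — a typical scale of cleavage
heterogeneity — and clusters below `min_support = 2` are dropped. The
site position is the modal end, ties resolved to the most distal; sites
are ordered proximal-first along the transcript. This window clustering
is a deliberately simple, fully documented substitute for a dedicated
APA pipeline, so published APA counts can be compared only
qualitatively. Splice isoforms are grouped by exact intron-chain
equality.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the library structure above on a toy genome
(default 20 genes, 2 chromosomes, 1–4 exons of 150–500 nt per gene) and
plants every quantity the pipeline later estimates:

- tail lengths: per-gene lognormal, `mu_g ~ Normal(ln 60, 0.4)`,
  `sigma_g = 0.5`, truncated to [1, 500] nt — lengths centred where
  oocyte-like distributions sit, wide enough to exercise both the
  15-nt filter and the > 200 nt regime;
- internal non-A: each tail base converted with probability
  `mod_rate = 0.007` (matching the ~0.7% in-tail non-A frequency this
  kind of data shows), positions drawn with 5'-biased exponential
  weight (`tau = 0.3` in relative position), uniform U/G/C identity; an
  optional mode adds 3'-enriched G. Terminal 1–2-base non-A additions
  at rate 0.02;
- pass numbers: `1 + Poisson(14)`, so ~92% of reads clear the 10-pass
  filter, resembling a length-selected CCS run;
- errors: per-base rate `error_rate` (default 0 — ground-truth mode)
  split 75% substitution / 12.5% insertion / 12.5% deletion;
  substitutions never reproduce the original base;
- concatemers at rate 0.01; stored-strand flips at 0.5; half the genes
  carry a second, proximal cleavage site 150 nt upstream.

Alignments are emitted by construction, not by an aligner: the CIGAR is
assembled alongside the error injection, so soft-clip lengths and
reference blocks are exactly consistent with the emitted sequence, and
the tail is always the read-3' terminal clip. Consequently passing
tests demonstrate correctness of demultiplexing, tail extraction,
counting and clustering logic — they do not probe aligner behaviour
(clip misplacement, spurious secondary alignments, reference bias), nor
polymerase-realistic error structure, base-quality information, or
genomic A-rich internal priming artefacts. Real runs should therefore
still inspect the spike-in mismatch rate and the suspicious-5'-clip
counts.

Determinism: one `numpy.random.Generator` seeded from `SimConfig.seed`
drives all sampling; identical seeds give byte-identical files.

## Numerical and testing choices

- Geometric means are computed as `exp(mean(log L))`; empty input is an
  error, zero lengths cannot occur (tails have length ≥ 1).
- Half-open 0-based coordinates everywhere internally; conversion only
  at the GTF/SAM boundaries.
- The parameter-recovery test for per-gene geometric means compares
  against the truncated-lognormal log-mean
  `mu + sigma * phi(a)/(1 - Phi(a))`, `a = (ln 14.5 - mu)/sigma`,
  because the ≥ 15-nt acceptance filter truncates the accepted sample
  for genes whose tails sit near the bound; the expression reduces to
  `mu` when truncation is negligible. Tolerance is `3 sigma/sqrt(n)` on
  the log scale plus 0.02 for integer rounding.
- Problem sizes in the test suite (10^4 reads for the exhaustive demux
  and criteria-oracle checks, 3,000 reads / 20 genes for end-to-end
  recovery, 1,000 reads per spike-in design) keep the whole suite in
  the tens of seconds while leaving binomial error bars far smaller
  than the tested tolerances.
- Brute-force oracles (semi-global probe placement scan, naive
  three-criteria re-check, union-find single linkage) live in the test
  suite and share no code with the implementation paths they check.

## Known limitations

- Concatemer resolution keeps only the 3'-most unit; upstream units are
  discarded rather than salvaged as extra observations.
- The APA caller has no internal-priming filter and no reference-free
  site annotation; `min_support` has no claimed correspondence to any
  published pipeline's internals.
- Orientation conflicts (probe on both strands) discard the read; no
  attempt is made to pick the more plausible layout.
- The T30VN classifier assumes the UTR-end coordinate is correct; a
  misaligned 3'-UTR end shifts model-a/b calls.
- Quality values are not modelled anywhere; pass count is the only
  accuracy proxy.
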