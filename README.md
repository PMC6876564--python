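# paiso

A toolkit for poly(A)-inclusive long-read isoform sequencing analysis:
measuring mRNA poly(A) tail length and composition from PacBio-style
circular-consensus (CCS) reads of barcoded, adapter-flanked full-length
cDNA libraries in which the poly(A) tail is retained and sequenced.

It is written for transcriptomics groups studying poly(A)-tail
regulation (for example in transcriptionally silent oocytes, where
stored mRNAs are controlled through their tails) who have CCS reads in
hand and an external spliced aligner, and need everything around the
alignment step:

- **Demultiplexing and cleanup** — each sample is identified by a 22-nt
  probe (16-nt barcode + first 6 nt of the template-switching oligo)
  located anywhere in the read at a Levenshtein distance of at most 2;
  reads matching two samples are discarded as ambiguous, reads are
  oriented 5'→3', 3' adapters and 5' primers are trimmed, and
  concatemers are resolved by keeping the 3'-most library unit.
- **Poly(A) tail calling** — the tail of a read is the terminal
  soft/hard clip at its 3' end in a spliced genome alignment, accepted
  when it is ≥ 15 nt, contains ≥ 5 consecutive A, and its non-A
  residues are both < 50% and < 20. Per-gene tail length is the
  geometric mean `exp(mean(ln L))`, appropriate for the lognormal-like
  per-gene length distributions.
- **Non-A residue profiling** — counts and ratios of U (read as T), G
  and C inside tail bodies, per transcript (`count / tail length`) and
  per gene (pooled counts over pooled lengths), run-length spectra of
  mono/oligo non-A stretches, positional profiles, and a classifier for
  oligo(dT)-T30VN reads that detects RT primers anchored at internal
  non-A bases.
- **Spike-in calibration** — structural parsing of synthetic reads
  (5' primer + barcode + reporter CDS + tail + 3' primer) with designed
  tails of 10/30/50/70/100 nt; no minimum-length filter applies, so the
  10-nt design is measurable.
- **Gene assignment and APA** — reads are assigned to genes via merged
  annotation exons (multi-gene overlaps discarded); cleavage sites are
  clustered by single-linkage within a 24-nt window into
  polyadenylation sites and genes are classified by site count.
- **A ground-truth simulator** — generates barcoded reads, a toy
  genome, GTF, truth table and SAM alignments (tail as 3' soft-clip) so
  the entire pipeline is testable without downloads or an aligner.

## Worked example

Simulate a two-sample dataset and run every stage:

```bash
paiso simulate --seed 7 --out sim --n-reads 400
paiso run-all --reads sim/reads.fastq --barcodes sim/barcodes.tsv \
    --sam sim/alignments.sam --gtf sim/annotation.gtf \
    --primer5 AAGCAGTGGTATCAACGCAGAGT --out run
```

From a run of exactly these commands, `run/manifest.json` records
400/400 reads demultiplexed (214 to `s01`, 186 to `s02`, 0 ambiguous, 2
concatemer-trimmed), 371 accepted tails after the ≥ 10-pass filter (the
rejected handful are genuine sub-15-nt tails), an internal non-A read
fraction of 0.326 after stripping terminal non-A residues (0.337 raw),
26 called polyadenylation sites, and a per-gene tail-length correlation
between the two samples of Pearson 0.90 / Spearman 0.79 over the 7
genes with ≥ 10 reads in both. With the default simulation settings
(~0.7% of tail bases carrying internal U/G/C) roughly a third of reads
carry at least one internal non-A residue, which is what the 0.326
reflects.

Real data follow the same path; the pipeline consumes alignments rather
than producing them, and prints the recommended spliced-aligner
invocation (`minimap2 -ax splice -uf -C5 --secondary=no ...`) after
demultiplexing.

As a library:

```python
from paiso import builtin_panel, parse_spikein, spikein_report
from paiso.synthetic import generate_spikein_reads

panel = builtin_panel()
reads, truth = generate_spikein_reads(1000, seed=1, panel=panel)
table = spikein_report([parse_spikein(r, panel) for r in reads], panel)
print(table[["design_id", "designed_tail", "n", "mean_tail_length", "mismatch_rate"]])
```

prints one row per design with `mean_tail_length` exactly equal to the
designed 10/30/50/70/100 nt and `mismatch_rate` 0.0 on error-free
reads — the calibration that justifies trusting absolute tail lengths
from the alignment-based caller.

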