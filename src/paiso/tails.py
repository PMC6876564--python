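"""Poly(A) tail extraction from terminal soft-clips and length summaries.

After a clean read is spliced-aligned to the genome (secondary
alignments suppressed), its poly(A) tail is the unaligned terminal
segment at the read's 3' end.  The clip is accepted as a tail when all
three hold:

1. it is at least 15 nt long;
2. it contains at least five continuous adenosines;
3. non-A residues make up less than 50% of it and number fewer than 20.

Tail length is the clip length.  Per-gene length is summarised by the
geometric mean, because per-gene tail lengths are lognormal-like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .io import AlignmentRecord, alignment_from_pysam
from .sequtils import longest_a_run, non_a_count, revcomp

MIN_TAIL_LENGTH = 15
MIN_A_RUN = 5
MAX_NON_A_COUNT = 20  # non-A count must be strictly below this
MAX_NON_A_FRACTION = 0.5  # non-A fraction must be strictly below this


@dataclass
class TailCall:
    """An accepted poly(A) tail, reported in read 5'->3' orientation."""

    read_id: str
    tail_seq: str
    num_passes: int = 1
    gene_id: Optional[str] = None
    # Alignment context for polyadenylation-site calling, when known.
    ref_name: Optional[str] = None
    ref_strand: Optional[str] = None
    cleavage_pos: Optional[int] = None

    @property
    def tail_length(self) -> int:
        return len(self.tail_seq)

    @property
    def counts(self) -> dict[str, int]:
        s = self.tail_seq
        return {b: s.count(b) for b in "AGCTN"}


@dataclass
class Rejection:
    read_id: str
    reason: str


TailResult = Union[TailCall, Rejection]


def check_tail_criteria(clip: str) -> Optional[str]:
    """Test a clipped sequence against the three tail criteria.

    Returns ``None`` on acceptance, else the first failed criterion:
    ``short_clip`` (< 15 nt), ``no_A5_run`` (no run of five continuous
    A), ``too_many_nonA`` (non-A fraction >= 50% or count >= 20).
    N bases count as non-A.
    """
    if len(clip) < MIN_TAIL_LENGTH:
        return "short_clip"
    if longest_a_run(clip) < MIN_A_RUN:
        return "no_A5_run"
    non_a = non_a_count(clip)
    if non_a >= MAX_NON_A_COUNT or non_a / len(clip) >= MAX_NON_A_FRACTION:
        return "too_many_nonA"
    return None


def _terminal_clips(ops: Sequence[tuple[str, int]]) -> tuple[int, int]:
    """(left, right) clipped lengths (soft + hard) of a CIGAR op list."""
    left = right = 0
    i = 0
    while i < len(ops) and ops[i][0] in "SH":
        left += ops[i][1]
        i += 1
    j = len(ops) - 1
    while j >= 0 and ops[j][0] in "SH":
        right += ops[j][1]
        j -= 1
    return left, right


def extract_tail(
    aln: AlignmentRecord,
    clean_seq: str,
    check_five_prime: bool = True,
) -> TailResult:
    """Extract the 3'-terminal clip of an alignment as a tail candidate.

    ``clean_seq`` is the full clean read in read (5'->3') orientation;
    slicing it rather than the stored SAM sequence recovers hard-clipped
    bases too.  For a minus-strand alignment the read-3' clip is the
    left clip of the stored record.  A read whose 5'-end clip would
    itself pass all tail criteria is rejected as suspicious, to avoid
    calling a residual adapter a tail.
    """
    if aln.is_secondary or aln.is_supplementary:
        return Rejection(aln.read_id, "nonprimary")
    ops = aln.cigar_ops()
    if not ops or aln.ref_name in ("*", None):
        return Rejection(aln.read_id, "unmapped")
    left, right = _terminal_clips(ops)
    # Clip lengths in read orientation.
    clip3 = left if aln.ref_strand == "-" else right
    clip5 = right if aln.ref_strand == "-" else left
    candidate = clean_seq[len(clean_seq) - clip3 :] if clip3 else ""

    reason = check_tail_criteria(candidate)
    if reason is not None:
        return Rejection(aln.read_id, reason)
    if check_five_prime and clip5:
        if check_tail_criteria(clean_seq[:clip5]) is None:
            return Rejection(aln.read_id, "suspicious_5prime")
    if aln.ref_strand == "-":
        cleavage = aln.ref_start
    else:
        ref_len = sum(n for op, n in ops if op in "MDN=X")
        cleavage = aln.ref_start + ref_len
    return TailCall(
        aln.read_id,
        candidate,
        ref_name=aln.ref_name,
        ref_strand=aln.ref_strand,
        cleavage_pos=cleavage,
    )


def tails_from_alignments(
    bam_path: str | Path,
    reads_by_id: dict[str, tuple[str, int]],
    check_five_prime: bool = True,
) -> Iterator[TailResult]:
    """Call tails for every primary alignment in a SAM/BAM file.

    ``reads_by_id`` maps read_id to ``(sequence, num_passes)`` of the
    clean read (read orientation), e.g. built from the demultiplexed
    FASTQ.  Secondary/supplementary/unmapped records are rejected, not
    silently dropped.
    """
    path = Path(bam_path)
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                yield Rejection(rec.query_name, "unmapped")
                continue
            aln = alignment_from_pysam(rec)
            if rec.query_name in reads_by_id:
                clean_seq, passes = reads_by_id[rec.query_name]
            else:
                stored = rec.query_sequence or ""
                clean_seq = revcomp(stored) if rec.is_reverse else stored
                passes = 1
            result = extract_tail(aln, clean_seq, check_five_prime=check_five_prime)
            if isinstance(result, TailCall):
                result.num_passes = passes
            yield result


def gene_geometric_mean(lengths: Sequence[float]) -> float:
    """exp(mean(ln lengths)); the per-gene tail-length summary."""
    if len(lengths) == 0:
        raise ValueError("geometric mean of an empty list is undefined")
    arr = np.asarray(lengths, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("lengths must be positive")
    return float(np.exp(np.mean(np.log(arr))))


@dataclass
class GeneTailSummary:
    gene_id: str
    n_reads: int
    geo_mean_length: float
    non_a_ratio: float  # pooled: sum(non-A) / sum(length)
    lengths: list[int] = field(default_factory=list, repr=False)


def summarize_genes(
    tails: Iterable[TailCall], min_reads: int = 3
) -> list[GeneTailSummary]:
    """One summary per gene with at least ``min_reads`` tails.

    Genes are returned in sorted gene_id order (deterministic).  Tails
    without a gene assignment are ignored.
    """
    by_gene: dict[str, list[TailCall]] = {}
    for t in tails:
        if t.gene_id is not None:
            by_gene.setdefault(t.gene_id, []).append(t)
    out = []
    for gene_id in sorted(by_gene):
        calls = by_gene[gene_id]
        if len(calls) < min_reads:
            continue
        lengths = [t.tail_length for t in calls]
        total = sum(lengths)
        non_a = sum(non_a_count(t.tail_seq) for t in calls)
        out.append(
            GeneTailSummary(
                gene_id=gene_id,
                n_reads=len(calls),
                geo_mean_length=gene_geometric_mean(lengths),
                non_a_ratio=non_a / total if total else 0.0,
                lengths=lengths,
            )
        )
    return out


def length_distribution(
    lengths: Sequence[int], bin_width: int = 10, max_length: Optional[int] = None
) -> pd.DataFrame:
    """Histogram of tail lengths in fixed-width bins; counts conserve n."""
    lengths = np.asarray(list(lengths), dtype=int)
    if max_length is None:
        max_length = int(lengths.max()) + 1 if lengths.size else bin_width
    edges = np.arange(0, max_length + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def long_tail_table(lengths: Sequence[int], threshold: int = 200, bin_width: int = 20) -> pd.DataFrame:
    """Distribution of tails longer than ``threshold`` nt in 20-nt bins."""
    long = [x for x in lengths if x > threshold]
    if not long:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    hi = max(long)
    edges = np.arange(threshold, hi + bin_width, bin_width)
    counts, _ = np.histogram(long, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})


def tail_table(tails: Iterable[TailCall]) -> pd.DataFrame:
    """Flat per-read tail table (TSV-ready)."""
    rows = []
    for t in tails:
        c = t.counts
        rows.append(
            {
                "read_id": t.read_id,
                "gene_id": t.gene_id if t.gene_id is not None else ".",
                "tail_length": t.tail_length,
                "A": c["A"],
                "G": c["G"],
                "C": c["C"],
                "T": c["T"],
                "N": c["N"],
                "num_passes": t.num_passes,
                "tail_seq": t.tail_seq,
            }
        )
    cols = ["read_id", "gene_id", "tail_length", "A", "G", "C", "T", "N", "num_passes", "tail_seq"]
    return pd.DataFrame(rows, columns=cols)
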