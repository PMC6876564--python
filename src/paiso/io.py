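"""Reading and writing circular-consensus (CCS) reads.

CCS reads arrive as FASTA/FASTQ (with the pass count carried as an
``np=K`` token in the header description) or as unaligned BAM with the
PacBio ``np`` integer tag.  Everything downstream works on the
:class:`CcsRead` record; alignments consumed later in the pipeline are
normalised to :class:`AlignmentRecord`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

_NP_TOKEN = re.compile(r"\bnp=(\d+)\b")

#: CIGAR operations that consume the query sequence (M, I, S, =, X).
QUERY_CONSUMING = frozenset("MIS=X")
#: CIGAR operations that consume the reference (M, D, N, =, X).
REF_CONSUMING = frozenset("MDN=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class CcsRead:
    """One circular-consensus read.

    ``num_passes`` is the number of polymerase passes that contributed to
    the consensus; it bounds the base accuracy of the read and is the
    quantity the >=10-pass filter acts on.
    """

    read_id: str
    sequence: str
    num_passes: int = 1
    source: str = "fastq"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.read_id}: empty sequence")
        if self.num_passes < 1:
            raise ValueError(f"{self.read_id}: num_passes must be >= 1")


@dataclass
class AlignmentRecord:
    """A genome alignment of a clean read, normalised from SAM/BAM.

    ``read_sequence_as_stored`` is in aligner orientation: for a
    minus-strand alignment it is the reverse complement of the read.
    """

    read_id: str
    ref_name: str
    ref_strand: str  # "+" or "-"
    cigar: str
    ref_start: int  # 0-based leftmost reference position
    is_secondary: bool = False
    is_supplementary: bool = False
    read_sequence_as_stored: str = ""

    def cigar_ops(self) -> list[tuple[str, int]]:
        return [(op, int(n)) for n, op in _CIGAR_RE.findall(self.cigar)]

    def query_consumed_length(self) -> int:
        return sum(n for op, n in self.cigar_ops() if op in QUERY_CONSUMING)


@dataclass
class ScanSummary:
    """Per-file read-scan accounting."""

    n_read: int = 0
    n_malformed: int = 0
    n_missing_passes: int = 0
    by_source: dict = field(default_factory=dict)


def _passes_from_description(description: str) -> Optional[int]:
    m = _NP_TOKEN.search(description)
    return int(m.group(1)) if m else None


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix == ".bam":
        return "ubam"
    if suffix == ".sam":
        return "ubam"
    raise ValueError(f"cannot guess read format from {path.name}; pass fmt=")


def read_ccs(
    path: str | Path,
    fmt: Optional[str] = None,
    summary: Optional[ScanSummary] = None,
) -> Iterator[CcsRead]:
    """Stream :class:`CcsRead` records from FASTA, FASTQ or unaligned BAM.

    The pass count is taken from an ``np=K`` header token (FASTA/FASTQ)
    or the ``np`` tag (BAM).  Records without one default to
    ``num_passes=1`` with a warning, so that they survive only a
    ``min_passes=1`` filter.  Malformed records are skipped and counted
    in ``summary`` when one is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _guess_format(path)
    if summary is None:
        summary = ScanSummary()

    if fmt in {"fasta", "fastq"}:
        for rec in SeqIO.parse(str(path), fmt):
            passes = _passes_from_description(rec.description)
            if passes is None:
                logger.warning("%s: no np=K pass annotation, defaulting to 1", rec.id)
                summary.n_missing_passes += 1
                passes = 1
            seq = str(rec.seq).upper()
            if not seq:
                summary.n_malformed += 1
                continue
            summary.n_read += 1
            yield CcsRead(rec.id, seq, passes, source=fmt)
    elif fmt == "ubam":
        mode = "rb" if path.suffix == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
            for rec in bam.fetch(until_eof=True):
                if rec.query_sequence is None:
                    summary.n_malformed += 1
                    continue
                if rec.has_tag("np"):
                    passes = int(rec.get_tag("np"))
                else:
                    passes = _passes_from_description(rec.query_name) or 1
                    if not rec.has_tag("np") and passes == 1:
                        logger.warning(
                            "%s: no np tag, defaulting num_passes to 1", rec.query_name
                        )
                        summary.n_missing_passes += 1
                summary.n_read += 1
                yield CcsRead(
                    rec.query_name, rec.query_sequence.upper(), passes, source="ubam"
                )
    else:
        raise ValueError(f"unknown read format {fmt!r}")


def filter_by_passes(reads: Iterable[CcsRead], min_passes: int) -> Iterator[CcsRead]:
    """Keep reads with ``num_passes >= min_passes``, order preserved.

    The default downstream threshold is 10 passes, which bounds the
    consensus error low enough to trust single-base calls inside
    homopolymer tails.
    """
    if min_passes < 1:
        raise ValueError("min_passes must be >= 1")
    for read in reads:
        if read.num_passes >= min_passes:
            yield read


def write_fastq(reads: Iterable[CcsRead], path: str | Path) -> int:
    """Write reads as FASTQ, carrying the pass count as an ``np=K`` token.

    Returns the number of records written.  Base qualities are constant
    (Q40 placeholders): CCS quality is summarised by the pass count here.
    """
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id} np={read.num_passes}\n{read.sequence}\n+\n")
            fh.write("I" * len(read.sequence) + "\n")
            n += 1
    return n


def alignment_from_pysam(rec: pysam.AlignedSegment) -> AlignmentRecord:
    """Normalise a pysam alignment to :class:`AlignmentRecord`."""
    return AlignmentRecord(
        read_id=rec.query_name,
        ref_name=rec.reference_name or "*",
        ref_strand="-" if rec.is_reverse else "+",
        cigar=rec.cigarstring or "",
        ref_start=rec.reference_start,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        read_sequence_as_stored=rec.query_sequence or "",
    )
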