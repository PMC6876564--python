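"""Demultiplex, orient and adapter-trim CCS reads.

A library mixes samples distinguished by a 16-nt barcode that, together
with the first six bases of the TSO, forms a 22-nt probe appearing (as
its reverse complement) at the 3' end of a sense read:

    5'primer --- cDNA --- poly(A) tail --- revcomp(probe)

Cleaning (1) assigns the read to the unique sample whose probe matches
within ``max_edits`` Levenshtein edits — hits to two or more barcodes
discard the read as ambiguous; (2) orients it 5'->3'; (3) trims the
probe and everything 3' of it; (4) resolves concatemers by keeping only
the 3'-most unit; and (5) strips the 5' cDNA primer when present.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .io import CcsRead, write_fastq
from .matching import ProbeHit, edit_distance, find_probe
from .sequtils import revcomp

logger = logging.getLogger(__name__)

#: Window (nt) at the 5' end searched for the cDNA primer.
PRIMER5_WINDOW = 50


@dataclass
class ProbeSet:
    """Per-sample demultiplexing probes plus the shared 5' cDNA primer.

    All probes must have equal length (22 nt in the standard design).
    A warning is raised when two probes are within ``2 * max_edits``
    edits of one another, because reads corrupted by up to ``max_edits``
    errors could then become ambiguous by construction.
    """

    probes: dict[str, str]
    five_prime_primer: str = ""
    max_edits: int = 2

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("ProbeSet needs at least one probe")
        lengths = {len(p) for p in self.probes.values()}
        if len(lengths) != 1:
            raise ValueError(f"probes must share one length, got {sorted(lengths)}")
        ids = list(self.probes)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                d = edit_distance(self.probes[a], self.probes[b])
                if d <= 2 * self.max_edits:
                    logger.warning(
                        "probes %s and %s are only %d edits apart (<= 2*max_edits=%d); "
                        "demultiplexing may be ambiguous",
                        a, b, d, 2 * self.max_edits,
                    )

    @classmethod
    def from_tsv(
        cls, path: str | Path, five_prime_primer: str = "", max_edits: int = 2
    ) -> "ProbeSet":
        """Load a headered TSV with columns ``barcode_id`` and ``probe``."""
        probes: dict[str, str] = {}
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                bid = row["barcode_id"]
                if bid in probes:
                    raise ValueError(f"duplicate barcode_id {bid!r}")
                probes[bid] = row["probe"].upper()
        return cls(probes, five_prime_primer=five_prime_primer.upper(), max_edits=max_edits)


@dataclass
class CleanRead:
    """A demultiplexed read, oriented 5'->3' with adapters removed."""

    read_id: str
    barcode_id: str
    sequence: str
    num_passes: int
    trim_log: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class Unassigned:
    read_id: str
    reason: str  # no_probe | orientation_conflict | too_short


@dataclass
class Ambiguous:
    """Read matching probes of two or more samples; always discarded."""

    read_id: str
    barcode_ids: tuple[str, ...]


DemuxResult = Union[CleanRead, Unassigned, Ambiguous]


@dataclass
class DemuxReport:
    assigned: dict[str, int] = field(default_factory=dict)
    ambiguous: int = 0
    unassigned: int = 0
    concatemers: int = 0
    total: int = 0

    def count(self, result: DemuxResult) -> None:
        self.total += 1
        if isinstance(result, CleanRead):
            self.assigned[result.barcode_id] = self.assigned.get(result.barcode_id, 0) + 1
            if any(ev == "concatemer_trim" for ev, _, _ in result.trim_log):
                self.concatemers += 1
        elif isinstance(result, Ambiguous):
            self.ambiguous += 1
        else:
            self.unassigned += 1


def clean_read(read: CcsRead, probes: ProbeSet, min_len: int = 50) -> DemuxResult:
    """Assign, orient and trim one read.

    Returns :class:`Ambiguous` when probes of two or more samples match,
    :class:`Unassigned` when none does (or the probe matches both strands,
    or the retained sequence is shorter than ``min_len``), else a
    :class:`CleanRead` whose sequence ends where the matched 3' probe
    began.
    """
    hits_by_barcode = {
        bid: hits
        for bid, probe in probes.probes.items()
        if (hits := find_probe(read.sequence, probe, probes.max_edits))
    }
    if not hits_by_barcode:
        return Unassigned(read.read_id, "no_probe")
    if len(hits_by_barcode) > 1:
        return Ambiguous(read.read_id, tuple(sorted(hits_by_barcode)))

    (barcode_id, hits), = hits_by_barcode.items()
    strands = {h.strand for h in hits}
    if strands == {"+", "-"}:
        # The probe cannot sit at the 3' end on both strands of one read.
        return Unassigned(read.read_id, "orientation_conflict")

    trim_log: list[tuple[str, int, int]] = []
    seq = read.sequence
    if strands == {"+"}:
        # Probe matched in sense orientation: the stored read is the
        # reverse complement of the transcript; flip it so that
        # revcomp(probe) lies at the 3' end.
        n = len(seq)
        seq = revcomp(seq)
        hits = [ProbeHit(n - h.end, n - h.start, "-", h.edits) for h in hits]
        trim_log.append(("oriented_rc", 0, n))
    hits.sort(key=lambda h: h.start)

    # 3' adapter: the 3'-most probe occurrence; drop it and anything after.
    adapter = hits[-1]
    trim_log.append(("adapter_trim", adapter.start, len(seq)))
    seq = seq[: adapter.start]

    # Concatemer: further probe occurrences in the interior mark earlier
    # library units; keep only the 3'-most unit.
    interior = [h for h in hits[:-1] if h.end <= len(seq)]
    if interior:
        cut = interior[-1].end
        trim_log.append(("concatemer_trim", 0, cut))
        seq = seq[cut:]

    # 5' cDNA primer, expected within the first PRIMER5_WINDOW nt; also
    # treat a primer beyond that window as a residual concatemer joint.
    if probes.five_prime_primer:
        primer_hits = [
            h
            for h in find_probe(seq, probes.five_prime_primer, probes.max_edits)
            if h.strand == "+"
        ]
        if primer_hits:
            last = primer_hits[-1]
            if last.start >= PRIMER5_WINDOW:
                trim_log.append(("concatemer_trim", 0, last.start))
            trim_log.append(("primer5_trim", last.start, last.end))
            seq = seq[last.end :]
        else:
            logger.debug("%s: 5' primer not found (tolerated)", read.read_id)

    if len(seq) < min_len:
        return Unassigned(read.read_id, "too_short")
    return CleanRead(read.read_id, barcode_id, seq, read.num_passes, trim_log)


def demux_stream(
    reads: Iterable[CcsRead],
    probes: ProbeSet,
    min_len: int = 50,
    report: Optional[DemuxReport] = None,
) -> Iterator[DemuxResult]:
    """Clean a stream of reads, tallying outcomes into ``report``."""
    for read in reads:
        result = clean_read(read, probes, min_len=min_len)
        if report is not None:
            report.count(result)
        yield result


def demux_to_files(
    reads: Iterable[CcsRead],
    probes: ProbeSet,
    out_dir: str | Path,
    min_len: int = 50,
) -> DemuxReport:
    """Demultiplex into one FASTQ per sample plus a TSV report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = DemuxReport()
    per_sample: dict[str, list[CcsRead]] = {bid: [] for bid in probes.probes}
    for result in demux_stream(reads, probes, min_len=min_len, report=report):
        if isinstance(result, CleanRead):
            per_sample[result.barcode_id].append(
                CcsRead(result.read_id, result.sequence, result.num_passes)
            )
    for bid, clean in per_sample.items():
        write_fastq(clean, out_dir / f"{bid}.clean.fastq")
    with open(out_dir / "demux_report.tsv", "w") as fh:
        fh.write("category\tcount\n")
        for bid in sorted(probes.probes):
            fh.write(f"assigned:{bid}\t{report.assigned.get(bid, 0)}\n")
        fh.write(f"ambiguous\t{report.ambiguous}\n")
        fh.write(f"unassigned\t{report.unassigned}\n")
        fh.write(f"concatemers\t{report.concatemers}\n")
        fh.write(f"total\t{report.total}\n")
    return report
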