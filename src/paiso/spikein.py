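"""Structural parsing and calibration statistics for poly(A) spike-ins.

A spike-in read has a fixed layout::

    5'primer -- barcode -- reporter CDS -- poly(A) tail -- 3'primer

where the barcode (placed before the start codon) encodes the designed
tail length of the pool the molecule came from (10/30/50/70/100 nt in
the standard design).  Only full-length reads showing every element are
used; the sequence between the CDS and the 3' primer is the measured
tail.  No minimum-length filter applies here — the 10-nt design must be
measurable — which is what makes spike-ins a calibration for the
alignment-based tail caller.

The designs shipped under ``paiso/data`` are synthetic stand-ins with
the same layout and designed tail lengths as the published pool; real
design tables can be loaded with :func:`load_panel`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO

from .io import CcsRead
from .matching import find_probe
from .sequtils import non_a_count, revcomp


@dataclass(frozen=True)
class SpikeInDesign:
    design_id: str
    barcode: str
    designed_tail: int

    def __post_init__(self) -> None:
        if self.designed_tail <= 0:
            raise ValueError("designed_tail must be positive")


@dataclass
class SpikeInPanel:
    """A set of spike-in designs sharing primers and reporter body."""

    designs: list[SpikeInDesign]
    body: str
    five_prime_primer: str
    three_prime_primer: str
    primer_max_edits: int = 2
    anchor_max_edits: int = 3
    barcode_max_edits: int = 1
    anchor_length: int = 30  # body-terminal anchor locating the tail start

    def __post_init__(self) -> None:
        barcodes = [d.barcode for d in self.designs]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("spike-in barcodes must be pairwise distinct")

    @property
    def body_anchor(self) -> str:
        return self.body[-self.anchor_length :]

    def read_for(self, design: SpikeInDesign, tail_seq: Optional[str] = None) -> str:
        """The full-length read sequence for one design (error-free)."""
        tail = tail_seq if tail_seq is not None else "A" * design.designed_tail
        return (
            self.five_prime_primer
            + design.barcode
            + self.body
            + tail
            + self.three_prime_primer
        )


def load_panel(design_tsv: str | Path, elements_fasta: str | Path, **kwargs) -> SpikeInPanel:
    """Load a panel from a design TSV plus a FASTA of primers and body.

    The TSV is headered with columns ``design_id``, ``barcode``,
    ``designed_tail``; the FASTA must contain records named
    ``five_prime_primer``, ``three_prime_primer`` and ``body``.
    """
    designs = []
    with open(design_tsv) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            designs.append(
                SpikeInDesign(row["design_id"], row["barcode"].upper(), int(row["designed_tail"]))
            )
    elements = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(elements_fasta), "fasta")}
    return SpikeInPanel(
        designs=designs,
        body=elements["body"],
        five_prime_primer=elements["five_prime_primer"],
        three_prime_primer=elements["three_prime_primer"],
        **kwargs,
    )


def builtin_panel(**kwargs) -> SpikeInPanel:
    """The packaged stand-in panel (designed tails 10/30/50/70/100 nt)."""
    data = resources.files("paiso") / "data"
    return load_panel(data / "spikein_design.tsv", data / "spikein_elements.fasta", **kwargs)


@dataclass
class SpikeInCall:
    read_id: str
    design_id: str
    tail_seq: str

    @property
    def tail_length(self) -> int:
        return len(self.tail_seq)


@dataclass
class NotFullLength:
    read_id: str
    reason: str


SpikeInResult = Union[SpikeInCall, NotFullLength]


def parse_spikein(read: CcsRead, panel: SpikeInPanel) -> SpikeInResult:
    """Parse one read against the panel layout.

    Orientation is decided by the body-terminal anchor; the 5' primer,
    anchor and 3' primer must all be found (edit-bounded infix matches)
    or the read is rejected as not full length.  The tail is everything
    between the body anchor and the 3' primer; the design is the
    lowest-edit barcode match in the window after the 5' primer, with
    ties rejected.
    """
    anchor_hits = find_probe(read.sequence, panel.body_anchor, panel.anchor_max_edits)
    if not anchor_hits:
        return NotFullLength(read.read_id, "no_body")
    best = min(anchor_hits, key=lambda h: h.edits)
    seq = read.sequence if best.strand == "+" else revcomp(read.sequence)

    fwd_anchor = [h for h in find_probe(seq, panel.body_anchor, panel.anchor_max_edits) if h.strand == "+"]
    if not fwd_anchor:
        return NotFullLength(read.read_id, "no_body")
    anchor = min(fwd_anchor, key=lambda h: h.edits)

    p5 = [
        h
        for h in find_probe(seq, panel.five_prime_primer, panel.primer_max_edits)
        if h.strand == "+" and h.end <= anchor.start
    ]
    if not p5:
        return NotFullLength(read.read_id, "no_5primer")
    p5_hit = p5[0]

    p3 = [
        h
        for h in find_probe(seq, panel.three_prime_primer, panel.primer_max_edits)
        if h.strand == "+" and h.start >= anchor.end
    ]
    if not p3:
        return NotFullLength(read.read_id, "no_3primer")
    p3_hit = p3[0]

    # Barcode sits between the 5' primer and the start codon; allow a
    # little slack for indels around the junction.
    window = seq[p5_hit.end : p5_hit.end + max(len(d.barcode) for d in panel.designs) + 4]
    scored = []
    for d in panel.designs:
        hits = find_probe(window, d.barcode, panel.barcode_max_edits)
        fwd = [h for h in hits if h.strand == "+"]
        if fwd:
            scored.append((min(h.edits for h in fwd), d))
    if not scored:
        return NotFullLength(read.read_id, "no_barcode")
    scored.sort(key=lambda t: t[0])
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        return NotFullLength(read.read_id, "barcode_ambiguous")
    design = scored[0][1]

    tail = seq[anchor.end : p3_hit.start]
    return SpikeInCall(read.read_id, design.design_id, tail)


def spikein_report(
    calls: Iterable[SpikeInResult], panel: SpikeInPanel
) -> pd.DataFrame:
    """Per-design calibration table.

    Columns: number of full-length reads, arithmetic mean measured tail
    length (the designed tails are homogeneous, so the arithmetic mean
    is the natural estimator), recovery fraction of all full-length
    calls, and the non-A mismatch rate (mismatching bases over total
    tail bases) that bounds post-RT artefacts.
    """
    calls = list(calls)
    full = [c for c in calls if isinstance(c, SpikeInCall)]
    total = len(full)
    rows = []
    for d in panel.designs:
        mine = [c for c in full if c.design_id == d.design_id]
        n = len(mine)
        tail_bases = sum(c.tail_length for c in mine)
        mismatches = sum(non_a_count(c.tail_seq) for c in mine)
        rows.append(
            {
                "design_id": d.design_id,
                "designed_tail": d.designed_tail,
                "n": n,
                "mean_tail_length": (sum(c.tail_length for c in mine) / n) if n else float("nan"),
                "recovery_fraction": n / total if total else 0.0,
                "mismatch_rate": mismatches / tail_bases if tail_bases else 0.0,
            }
        )
    return pd.DataFrame(rows)
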