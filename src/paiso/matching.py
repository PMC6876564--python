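"""Approximate infix (semi-global) probe matching on both strands.

The demultiplexing probe is a 22-mer (16-nt sample barcode plus the
first six bases of the template-switching oligo).  It is located inside
a read allowing a bounded Levenshtein distance — substitutions and
indels count together — using edlib's infix ("HW") alignment mode.
Multiple non-overlapping occurrences are recovered by best-first search
with masking, so among overlapping candidate placements the
lowest-edit one wins (ties: leftmost, then shortest).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .sequtils import revcomp

#: Masking character: matches nothing in the DNA alphabet.
_MASK = "#"


@dataclass(frozen=True)
class ProbeHit:
    """One probe placement on the forward sequence.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    (as-given) sequence even for minus-strand hits.  ``strand`` is "+"
    when the probe itself matches, "-" when its reverse complement does.
    """

    start: int
    end: int
    strand: str
    edits: int

    def overlaps(self, other: "ProbeHit") -> bool:
        return self.start < other.end and other.start < self.end


def _best_placement(locations: list[tuple[int, int]]) -> tuple[int, int]:
    # edlib reports every optimal placement; prefer leftmost, then shortest.
    return min(locations, key=lambda loc: (loc[0], loc[1] - loc[0]))


def _hits_one_strand(seq: str, probe: str, max_edits: int) -> list[tuple[int, int, int]]:
    """All non-overlapping placements on one strand, best-first.

    Returns (start, end, edits) triples.  After each best hit the matched
    window is masked, so later rounds surface strictly worse or disjoint
    placements; a final overlap filter enforces non-overlap.
    """
    hits: list[tuple[int, int, int]] = []
    work = seq
    while True:
        res = edlib.align(probe, work, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] == -1:
            break
        start, end_inclusive = _best_placement(res["locations"])
        end = end_inclusive + 1
        if not any(start < h_end and h_start < end for h_start, h_end, _ in hits):
            hits.append((start, end, res["editDistance"]))
        work = work[:start] + _MASK * (end - start) + work[end:]
    return hits


def find_probe(sequence: str, probe: str, max_edits: int) -> list[ProbeHit]:
    """Find every non-overlapping approximate occurrence of ``probe``.

    Searches the forward sequence and its reverse complement; minus-strand
    placements are mapped back to forward coordinates.  Hits are returned
    in ascending start order.  A probe longer than the sequence yields no
    hits.
    """
    if not probe:
        raise ValueError("probe must be non-empty")
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    if len(probe) > len(sequence):
        return []

    n = len(sequence)
    hits = [
        ProbeHit(start, end, "+", edits)
        for start, end, edits in _hits_one_strand(sequence, probe, max_edits)
    ]
    for start_rc, end_rc, edits in _hits_one_strand(revcomp(sequence), probe, max_edits):
        hits.append(ProbeHit(n - end_rc, n - start_rc, "-", edits))
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def edit_distance(a: str, b: str) -> int:
    """Global Levenshtein distance between two sequences."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]
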