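"""Non-adenosine residues within poly(A) tail bodies.

High-pass CCS reads (>= 10 passes by default) resolve single bases
inside homopolymer tails, so U (read as T), G and C residues within a
tail can be counted directly.  Per transcript the G/C/U ratio is the
count divided by tail length; per gene the counts and lengths are
pooled before dividing.  The module also classifies conventional
oligo(dT)-T30VN reads by where the RT primer anchored: at the
3'-UTR/tail junction (model a) or — evidence for internal non-A — at a
non-A base inside the tail body (model b).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .sequtils import non_a_count
from .tails import TailCall

NON_A_BASES = ("T", "G", "C")  # U is read as T in consensus sequences
RUN_CATEGORIES = ("1", "2", "3", "4+")

_MODEL_B = re.compile(r"A+([^A]{1,2})$")


@dataclass
class NonAProfile:
    """Per-transcript non-A composition of one tail."""

    read_id: str
    tail_length: int
    counts: dict[str, int]  # keys G, C, T, N
    run_spectrum: dict[tuple[str, str], int]  # (base, run-length category) -> count

    @property
    def ratios(self) -> dict[str, float]:
        return {b: self.counts[b] / self.tail_length for b in ("G", "C", "T")}

    @property
    def non_a_ratio(self) -> float:
        # N excluded from G/C/U but still non-A; ratio here follows the
        # G+C+U definition.
        return sum(self.ratios.values())


def _run_spectrum(tail: str) -> dict[tuple[str, str], int]:
    spectrum: dict[tuple[str, str], int] = {}
    for base, grp in groupby(tail):
        if base == "A" or base == "N":
            continue
        run = len(list(grp))
        cat = str(run) if run < 4 else "4+"
        key = (base, cat)
        spectrum[key] = spectrum.get(key, 0) + 1
    return spectrum


def profile_tail(tail: Union[TailCall, str], read_id: str = "") -> NonAProfile:
    """Exact per-base composition of one tail.

    N bases are counted separately and excluded from the G/C/U tallies
    and from the run spectrum.
    """
    if isinstance(tail, TailCall):
        seq, read_id = tail.tail_seq, tail.read_id
    else:
        seq = tail
    counts = {b: seq.count(b) for b in ("G", "C", "T", "N")}
    return NonAProfile(
        read_id=read_id,
        tail_length=len(seq),
        counts=counts,
        run_spectrum=_run_spectrum(seq),
    )


def gene_non_a_ratio(tails: Sequence[TailCall]) -> float:
    """Pooled non-A ratio of one gene: sum of counts over sum of lengths."""
    total = sum(t.tail_length for t in tails)
    if total == 0:
        raise ValueError("no tail bases")
    non_a = sum(non_a_count(t.tail_seq) for t in tails)
    return non_a / total


def run_spectrum_table(tails: Iterable[Union[TailCall, str]]) -> pd.DataFrame:
    """Mono- and oligo-non-A residue counts pooled over tails."""
    pooled: dict[tuple[str, str], int] = {}
    for t in tails:
        for key, n in profile_tail(t).run_spectrum.items():
            pooled[key] = pooled.get(key, 0) + n
    rows = [
        {"base": b, "run_length": cat, "count": pooled.get((b, cat), 0)}
        for b in NON_A_BASES
        for cat in RUN_CATEGORIES
    ]
    return pd.DataFrame(rows)


def positional_histogram(
    tails: Iterable[Union[TailCall, str]], k: int = 20
) -> pd.DataFrame:
    """Non-A frequency versus relative position within the tail.

    Each tail is divided into ``k`` equal relative-position bins
    (5'->3'); for every bin the table reports, per base, the count of
    that base and its frequency among all tail bases falling in the bin.
    Tails shorter than ``k`` still contribute: each base lands in bin
    floor(i / L * k).
    """
    counts = np.zeros((k, len(NON_A_BASES)), dtype=int)
    totals = np.zeros(k, dtype=int)
    base_idx = {b: j for j, b in enumerate(NON_A_BASES)}
    for t in tails:
        seq = t.tail_seq if isinstance(t, TailCall) else t
        L = len(seq)
        for i, ch in enumerate(seq):
            b = min(int(i / L * k), k - 1)
            totals[b] += 1
            if ch in base_idx:
                counts[b, base_idx[ch]] += 1
    rows = []
    for b in range(k):
        for j, base in enumerate(NON_A_BASES):
            rows.append(
                {
                    "bin": b,
                    "rel_start": b / k,
                    "base": base,
                    "count": int(counts[b, j]),
                    "bases_in_bin": int(totals[b]),
                    "frequency": counts[b, j] / totals[b] if totals[b] else 0.0,
                }
            )
    return pd.DataFrame(rows)


def absolute_positional_histogram(
    tails: Iterable[Union[TailCall, str]], max_pos: int = 100
) -> pd.DataFrame:
    """5'-anchored variant: non-A frequency at each absolute tail position."""
    counts = np.zeros((max_pos, len(NON_A_BASES)), dtype=int)
    totals = np.zeros(max_pos, dtype=int)
    base_idx = {b: j for j, b in enumerate(NON_A_BASES)}
    for t in tails:
        seq = t.tail_seq if isinstance(t, TailCall) else t
        for i, ch in enumerate(seq[:max_pos]):
            totals[i] += 1
            if ch in base_idx:
                counts[i, base_idx[ch]] += 1
    rows = []
    for i in range(max_pos):
        for j, base in enumerate(NON_A_BASES):
            rows.append(
                {
                    "position": i,
                    "base": base,
                    "count": int(counts[i, j]),
                    "tails_covering": int(totals[i]),
                    "frequency": counts[i, j] / totals[i] if totals[i] else 0.0,
                }
            )
    return pd.DataFrame(rows)


def strip_terminal_non_a(seq: str) -> str:
    """Remove the maximal terminal (3') run of non-A residues.

    Terminal non-A bases are partially lost to adapter pairing during
    library construction and are therefore unreliable; internal-residue
    statistics strip them first.
    """
    return seq.rstrip("CGTN")


def has_internal_non_a(seq: str, strip_terminal: bool = True) -> bool:
    body = strip_terminal_non_a(seq) if strip_terminal else seq
    return non_a_count(body) > 0


def fraction_with_internal_non_a(
    tails: Sequence[Union[TailCall, str]],
    strip_terminal: bool = True,
    bin_width: int = 20,
) -> tuple[float, pd.DataFrame]:
    """Fraction of reads carrying non-A residues inside the tail body.

    Returns the overall fraction plus a tail-length-binned table with,
    per bin, the fraction of reads that are internally modified and the
    per-base non-A frequency (both figure conventions exist in the
    literature, so both columns are emitted).
    """
    seqs = [t.tail_seq if isinstance(t, TailCall) else t for t in tails]
    if not seqs:
        return 0.0, pd.DataFrame(
            columns=["bin_start", "bin_end", "n_reads", "n_modified",
                     "read_fraction", "base_frequency"]
        )
    flags = [has_internal_non_a(s, strip_terminal) for s in seqs]
    overall = sum(flags) / len(seqs)

    max_len = max(len(s) for s in seqs)
    # half-open bins; one extra bin so the maximum length is included
    edges = list(range(0, max_len + 2 * bin_width, bin_width))
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [(s, f) for s, f in zip(seqs, flags) if lo <= len(s) < hi]
        n = len(in_bin)
        n_mod = sum(f for _, f in in_bin)
        bases = sum(len(s) for s, _ in in_bin)
        non_a = sum(non_a_count(s) for s, _ in in_bin)
        rows.append(
            {
                "bin_start": lo,
                "bin_end": hi,
                "n_reads": n,
                "n_modified": n_mod,
                "read_fraction": n_mod / n if n else 0.0,
                "base_frequency": non_a / bases if bases else 0.0,
            }
        )
    return overall, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# T30VN anchoring analysis of conventional Iso-seq reads
# ---------------------------------------------------------------------------

@dataclass
class VnAnchorCall:
    """Where the T30VN RT primer anchored on one read.

    Model "a": at the 3'-UTR end (the tail is pure A up to the terminal
    oligo(dT) complement).  Model "b": at one or two non-A bases inside
    the tail body, leaving A residues 5' of the anchor and the terminal
    A stretch 3' of it.
    """

    read_id: str
    model: str  # "a" or "b"
    n_anchor_non_a: int = 0
    anchor_bases: str = ""


@dataclass
class NotClassifiable:
    read_id: str
    reason: str = "no_terminal_a_run"


def classify_vn_anchor(
    sequence: str,
    utr_end: int,
    read_id: str = "",
    min_terminal_a: int = 25,
) -> Union[VnAnchorCall, NotClassifiable]:
    """Classify one oriented, adapter-trimmed T30VN Iso-seq read.

    ``utr_end`` is the read coordinate where the aligned 3'-UTR ends
    (query alignment end).  The terminal A stretch — the complement of
    the primer's T30 — must be at least ``min_terminal_a`` long; between
    it and the UTR, a pattern of one or more A followed by 1-2 non-A
    bases is called model b, anything else model a.
    """
    terminal = len(sequence) - len(sequence.rstrip("A"))
    if terminal < min_terminal_a:
        return NotClassifiable(read_id)
    between = sequence[utr_end : len(sequence) - terminal]
    m = _MODEL_B.fullmatch(between)
    if m:
        anchor = m.group(1)
        return VnAnchorCall(read_id, "b", n_anchor_non_a=len(anchor), anchor_bases=anchor)
    return VnAnchorCall(read_id, "a")


def vn_anchor_summary(
    calls: Iterable[Union[VnAnchorCall, NotClassifiable]]
) -> pd.DataFrame:
    """Model percentages and anchor-base category counts."""
    calls = list(calls)
    classified = [c for c in calls if isinstance(c, VnAnchorCall)]
    n = len(classified)
    rows = []
    for model in ("a", "b"):
        k = sum(1 for c in classified if c.model == model)
        rows.append({"category": f"model_{model}", "count": k,
                     "fraction": k / n if n else float("nan")})
    anchors: dict[str, int] = {}
    for c in classified:
        if c.model == "b":
            anchors[c.anchor_bases] = anchors.get(c.anchor_bases, 0) + 1
    for bases in sorted(anchors):
        rows.append({"category": f"anchor_{bases}", "count": anchors[bases],
                     "fraction": anchors[bases] / n})
    rows.append({"category": "not_classifiable",
                 "count": len(calls) - n, "fraction": float("nan")})
    return pd.DataFrame(rows)
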