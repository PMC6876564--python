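"""Small DNA sequence helpers shared across the toolkit."""

from __future__ import annotations

from functools import lru_cache

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


@lru_cache(maxsize=8)
def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements).

    Memoized with a small cache: probe searches reverse-complement the
    same read once per probe.
    """
    return seq.translate(_COMPLEMENT)[::-1]


def non_a_count(seq: str) -> int:
    """Number of residues that are not adenosine.

    N counts as non-A: an uncalled base cannot be credited as A.
    """
    return len(seq) - seq.count("A")


def longest_a_run(seq: str) -> int:
    """Length of the longest run of consecutive A residues."""
    best = cur = 0
    for ch in seq:
        if ch == "A":
            cur += 1
            if cur > best:
                best = cur
        else:
            cur = 0
    return best
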