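"""Small sequence utilities shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def comp(seq: str) -> str:
    """Base-wise complement, same direction."""
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def booth_least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation of ``s`` (Booth's algorithm)."""
    t = s + s
    n = len(t)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = t[j]
        i = f[j - k - 1]
        while i != -1 and sj != t[k + i + 1]:
            if sj < t[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != t[k + i + 1]:
            if sj < t[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def min_rotation(s: str) -> str:
    if not s:
        return s
    k = booth_least_rotation(s)
    return s[k:] + s[:k]


def canonical_circular(seq: str) -> str:
    """Canonical form of a circular DNA sequence: the smaller of the least
    rotations of the two strands.  Rotation- and strand-invariant."""
    return min(min_rotation(seq), min_rotation(revcomp(seq)))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def interval_union_length(intervals) -> int:
    """Total bases covered by 1-based inclusive [start, end] intervals,
    each base counted once."""
    ivs = sorted((s, e) for s, e in intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total
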