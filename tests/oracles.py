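"""Independent brute-force oracles used to verify the finders.

These re-derive results from first principles (exhaustive enumeration over
diagonals / subsets / alignment columns) and deliberately share no code
with the implementations they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Dict, List, Set, Tuple

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _cmp(s: str) -> str:
    return s.translate(_COMP)


# ---------------------------------------------------------------------------
# SSRs

def brute_ssrs(records: Dict[str, str], minimums=(10, 5, 4, 3, 3, 3)):
    """Exhaustive scan: at every position and motif length, grow the longest
    tandem run, then keep maximal primitive runs meeting the thresholds."""
    hits = set()
    for rid, s in records.items():
        n = len(s)
        for k in range(1, 7):
            for start in range(n - k + 1):
                motif = s[start : start + k]
                if "N" in motif:
                    continue
                if any(
                    k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
                ):
                    continue  # non-primitive
                count = 1
                while (
                    start + (count + 1) * k <= n
                    and s[start + count * k : start + (count + 1) * k] == motif
                ):
                    count += 1
                if count < minimums[k - 1]:
                    continue
                # maximal: the period-k tandem region must begin exactly at
                # `start` (one SSR per tandem region, leftmost phase)
                if (
                    start > 0
                    and start + k - 1 < n
                    and s[start - 1] not in ("N",)
                    and s[start + k - 1] not in ("N",)
                    and s[start - 1] == s[start + k - 1]
                ):
                    continue
                hits.add((rid, start + 1, start + count * k, k, count))
    return hits


# ---------------------------------------------------------------------------
# dispersed repeats

def _brute_evalue(length: int, mismatches: int, search_space: int) -> float:
    num = sum(comb(length, j) * 3 ** j for j in range(mismatches + 1))
    return float(search_space) ** 2 * num / 4.0 ** length


def brute_dispersed(
    records: Dict[str, str],
    min_len: int = 30,
    max_mm: int = 3,
    evalue_cutoff: float = 1e-5,
) -> Set[Tuple]:
    """Exhaustive dispersed-repeat enumeration on the spacer-joined genome.

    For every diagonal of every relation, every window bounded on both ends
    by a mismatch or a boundary/N wall with at most ``max_mm`` interior
    mismatches is a maximal pair; overlapping windows on one diagonal form
    one locus represented by (fewest mismatches, longest, leftmost);
    filters (self-identical, E-value, forward SSR shadows) as documented.
    Returns tuples (cls, rec1, s1, e1, rec2, s2, e2, length, mm).
    """
    ids = list(records)
    spacer = "N" * 100
    t = spacer.join(records[r] for r in ids)
    n = len(t)
    offsets = {}
    pos = 0
    for r in ids:
        offsets[r] = pos
        pos += len(records[r]) + 100
    search_space = sum(len(v) for v in records.values())

    ssr_runs: Dict[str, List[Tuple[int, int]]] = {}
    for rid, s1, e1, _k, _c in brute_ssrs(records):
        ssr_runs.setdefault(rid, []).append((s1, e1))

    def back(start0: int, length: int):
        for r in ids:
            off = offsets[r]
            if off <= start0 and start0 + length <= off + len(records[r]):
                return r, start0 - off + 1, start0 - off + length
        return None

    out: Set[Tuple] = set()
    for cls in ("forward", "reverse", "complement", "palindromic"):
        if cls == "forward":
            u = t
        elif cls == "reverse":
            u = t[::-1]
        elif cls == "complement":
            u = _cmp(t)
        else:
            u = _rc(t)
        # collect candidate pairs per diagonal family
        families: Dict[Tuple, List[Tuple[int, int, int, int]]] = {}
        for d in range(-(n - 1), n):
            if cls == "forward" and d == 0:
                continue
            lo = max(0, -d)
            hi = min(n, n - d)  # t[i] vs u[i+d], i in [lo, hi)
            if hi - lo < min_len:
                continue
            events: List[Tuple[int, bool]] = [(lo - 1, True)]
            for i in range(lo, hi):
                a, b = t[i], u[i + d]
                if a == "N" or b == "N":
                    events.append((i, True))  # wall
                elif a != b:
                    events.append((i, False))
            events.append((hi, True))
            m = len(events)
            for ei in range(m - 1):
                for ek in range(ei + 1, min(ei + max_mm + 2, m)):
                    interior = events[ei + 1 : ek]
                    if any(w for _, w in interior):
                        continue  # N inside the window
                    i1 = events[ei][0] + 1
                    i2 = events[ek][0] - 1
                    length = i2 - i1 + 1
                    if length < min_len:
                        continue
                    mm = len(interior)
                    a0 = i1
                    if cls in ("forward", "complement"):
                        b0 = i1 + d
                        dkey = abs(d)
                    else:
                        b0 = n - (i2 + d) - 1
                        dkey = d
                    if a0 == b0:
                        continue
                    lo2, hi2 = min(a0, b0), max(a0, b0)
                    families.setdefault((dkey,), []).append((lo2, hi2, length, mm))
        for key in sorted(families):
            group = sorted(set(families[key]))
            # cluster by overlap of the first interval
            cluster: List[Tuple[int, int, int, int]] = []
            cend = -1

            def flush(cluster):
                if not cluster:
                    return
                rep = min(cluster, key=lambda c: (c[3], -c[2], c[0]))
                lo2, hi2, length, mm = rep
                if _brute_evalue(length, mm, search_space) >= evalue_cutoff:
                    return
                ba = back(lo2, length)
                bb = back(hi2, length)
                if ba is None or bb is None:
                    return
                ra, sa, ea = ba
                rb, sb, eb = bb
                if ra == rb:
                    for rs, re_ in ssr_runs.get(ra, ()):
                        ov_a = min(ea, re_) - max(sa, rs) + 1
                        ov_b = min(eb, re_) - max(sb, rs) + 1
                        if ov_a > length / 2 and ov_b > length / 2:
                            return
                if (ra, sa) > (rb, sb):
                    ra, sa, ea, rb, sb, eb = rb, sb, eb, ra, sa, ea
                out.add((cls, ra, sa, ea, rb, sb, eb, length, mm))

            for c in group:
                if cluster and c[0] > cend:
                    flush(cluster)
                    cluster = []
                    cend = -1
                cluster.append(c)
                cend = max(cend, c[0] + c[2] - 1)
            flush(cluster)
    return out


# ---------------------------------------------------------------------------
# species discrimination

def brute_minimal_set(alleles: Dict[str, Dict[str, str]]):
    """Exhaustive subset search over all locus subsets in increasing size
    (lexicographic within a size); returns (subset or None, unresolved)."""
    species = sorted(alleles)
    loci = sorted(next(iter(alleles.values())))
    pairs = list(combinations(species, 2))

    def covered(subset):
        return all(
            any(alleles[a][l] != alleles[b][l] for l in subset) for a, b in pairs
        )

    for k in range(1, len(loci) + 1):
        for subset in combinations(loci, k):
            if covered(subset):
                return list(subset), []
    unresolved = [
        (a, b)
        for a, b in pairs
        if all(alleles[a][l] == alleles[b][l] for l in loci)
    ]
    return None, unresolved


# ---------------------------------------------------------------------------
# alignment column walk (identity recomputation)

def column_identity(qseq: str, sseq: str) -> float:
    """Identity from the spelled alignment rows: matching columns over all
    columns, gaps counting as mismatch columns."""
    assert len(qseq) == len(sseq)
    matches = sum(1 for a, b in zip(qseq, sseq) if a == b and a != "-")
    return matches / len(qseq)
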