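"""SSRs and dispersed maximal repeats across a multi-chromosome genome.

SSRs (microsatellites) are maximal tandem runs of a primitive 1-6 bp motif
meeting a class-specific minimum repeat count; the default thresholds for
mono- through hexanucleotide motifs are 10, 5, 4, 3, 3 and 3.

Dispersed repeats are maximal pairs of equal-length segments, at least
30 bp long and within Hamming distance 3, in four relations:

* forward      — direct copy (S vs S),
* reverse      — copy read backwards without complementation,
* complement   — base-complemented, same direction,
* palindromic  — reverse complement.

Detection runs on the concatenation of all chromosomes (a 100-N spacer
keeps hits from spanning two chromosomes) and back-maps hits onto
per-chromosome coordinates.  Pairs whose chance expectation (binomial
E-value over a uniform i.i.d. base model) is above the cutoff are removed,
as are trivially self-identical pairs and tandem shadows of reported SSR
runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from ._util import comp, interval_union_length, min_rotation, revcomp
from .model import GenomeSet

REPEAT_CLASSES = ("forward", "reverse", "complement", "palindromic")


@dataclass(frozen=True)
class SsrThresholds:
    """Minimum repeat counts per motif length 1..6."""

    counts: Tuple[int, int, int, int, int, int] = (10, 5, 4, 3, 3, 3)

    def minimum(self, motif_length: int) -> int:
        return self.counts[motif_length - 1]


@dataclass(frozen=True)
class SsrHit:
    record_id: str
    start: int  # 1-based inclusive
    end: int
    motif: str  # canonical (lexicographically least rotation)
    motif_length: int
    repeat_count: int


@dataclass(frozen=True)
class DispersedParams:
    min_length: int = 30
    max_mismatches: int = 3
    evalue_cutoff: float = 1e-5


@dataclass(frozen=True)
class RepeatPair:
    cls: str
    rec1: str
    start1: int
    end1: int
    rec2: str
    start2: int
    end2: int
    length: int
    mismatches: int
    e_value: float


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def find_ssrs(
    genome: GenomeSet, thresholds: SsrThresholds = SsrThresholds()
) -> List[SsrHit]:
    """All maximal primitive-motif tandem runs meeting the thresholds.

    A run reported at motif length k is not re-reported at multiples of k
    (the longer motif is non-primitive); runs containing N are split at the
    N.  Only complete motif copies count toward the reported interval.
    """
    hits: List[SsrHit] = []
    for rec in genome:
        s = rec.sequence
        n = len(s)
        for k in range(1, 7):
            need = thresholds.minimum(k)
            i = 0
            # scan maximal zero-runs of the period-k mismatch sequence
            run_start = 0
            while run_start <= n - k - 1:
                if (
                    s[run_start] == "N"
                    or s[run_start + k] == "N"
                    or s[run_start] != s[run_start + k]
                ):
                    run_start += 1
                    continue
                run_end = run_start
                while (
                    run_end + 1 <= n - k - 1
                    and s[run_end + 1] != "N"
                    and s[run_end + 1 + k] != "N"
                    and s[run_end + 1] == s[run_end + 1 + k]
                ):
                    run_end += 1
                span = run_end - run_start + 1 + k  # tandem region length
                count = span // k
                motif = s[run_start : run_start + k]
                if count >= need and "N" not in motif and _is_primitive(motif):
                    hits.append(
                        SsrHit(
                            rec.id,
                            run_start + 1,
                            run_start + count * k,
                            min_rotation(motif),
                            k,
                            count,
                        )
                    )
                run_start = run_end + 2
    hits.sort(key=lambda h: (h.record_id, h.start, h.motif_length))
    return hits


# ---------------------------------------------------------------------------
# E-value (binomial chance-pair model)

def evalue(length: int, mismatches: int, search_space: int) -> float:
    """Expected number of chance segment pairs of the given length with up
    to ``mismatches`` differences in a search space of ``search_space``
    bases, under a uniform i.i.d. base model:

        E = N^2 * sum_{j=0}^{m} C(L, j) * 3^j * (1/4)^L
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    log_n2 = 2.0 * math.log(search_space)
    log4 = math.log(4.0)
    log3 = math.log(3.0)
    terms = []
    for j in range(min(mismatches, length) + 1):
        lc = math.lgamma(length + 1) - math.lgamma(j + 1) - math.lgamma(length - j + 1)
        terms.append(lc + j * log3)
    mx = max(terms)
    log_sum = mx + math.log(sum(math.exp(t - mx) for t in terms))
    log_e = log_n2 + log_sum - length * log4
    if log_e < -745.0:
        return 0.0
    return math.exp(log_e)


# ---------------------------------------------------------------------------
# dispersed repeats: seed and extend

_SPACER = "N" * 100


def _transform(t: str, cls: str) -> str:
    if cls == "forward":
        return t
    if cls == "reverse":
        return t[::-1]
    if cls == "complement":
        return comp(t)
    if cls == "palindromic":
        return revcomp(t)
    raise ValueError(f"unknown repeat class {cls!r}")


def _walk(
    t: str, u: str, i0: int, d: int, step: int, max_mm: int
) -> Tuple[List[int], Optional[int]]:
    """Walk along diagonal d from i0 in the given direction.  Returns the
    offsets (T coordinates) of up to ``max_mm + 1`` mismatches, plus the
    offset of the first boundary/N wall if one is hit before that many
    mismatches are seen (None otherwise)."""
    mms: List[int] = []
    i = i0
    n_t, n_u = len(t), len(u)
    while len(mms) <= max_mm:
        j = i + d
        if i < 0 or j < 0 or i >= n_t or j >= n_u or t[i] == "N" or u[j] == "N":
            return mms, i
        if t[i] != u[j]:
            mms.append(i)
        i += step
    return mms, None


def _seed_windows(
    t: str, u: str, a: int, b: int, w: int, min_len: int, max_mm: int
) -> Set[Tuple[int, int, int, int]]:
    """Maximal windows (start, end in T coords, diagonal, mismatches)
    around an exact seed t[a:a+w] == u[b:b+w].

    A window with j mismatches is maximal when each end abuts the next
    mismatch or a boundary/N wall; every such window for j = 0..max_mm
    containing the seed is emitted."""
    d = b - a
    left_mms, wall_l = _walk(t, u, a - 1, d, -1, max_mm)
    right_mms, wall_r = _walk(t, u, a + w, d, +1, max_mm)
    out: Set[Tuple[int, int, int, int]] = set()
    for j in range(max_mm + 1):
        for p in range(j + 1):  # p mismatches taken on the left, j-p right
            q = j - p
            if p > len(left_mms) or q > len(right_mms):
                continue
            if p == len(left_mms):
                if wall_l is None:
                    continue
                i1 = wall_l + 1
            else:
                i1 = left_mms[p] + 1
            if q == len(right_mms):
                if wall_r is None:
                    continue
                i2 = wall_r - 1
            else:
                i2 = right_mms[q] - 1
            if i2 - i1 + 1 >= min_len:
                out.add((i1, i2, d, p + q))
    return out


def _forward_pairs(
    t: str, u: str, min_len: int, max_mm: int, self_compare: bool
) -> Set[Tuple[int, int, int, int]]:
    """All containment-maximal matching windows between t and u, as
    (start, end, diagonal, mismatches) in T coordinates."""
    # pigeonhole: any window of length >= min_len with <= max_mm mismatches
    # contains an exact stretch of at least ceil((min_len-max_mm)/(max_mm+1))
    w = max(4, math.ceil((min_len - max_mm) / (max_mm + 1)))
    index: Dict[str, List[int]] = {}
    for j in range(len(u) - w + 1):
        wm = u[j : j + w]
        if "N" in wm:
            continue
        index.setdefault(wm, []).append(j)
    seen_seed: Set[Tuple[int, int]] = set()
    out: Set[Tuple[int, int, int, int]] = set()
    for a in range(len(t) - w + 1):
        wm = t[a : a + w]
        if "N" in wm:
            continue
        for b in index.get(wm, ()):
            d = b - a
            if self_compare and d == 0:
                continue
            if (d, a) in seen_seed:
                continue
            seen_seed.add((d, a))
            out.update(_seed_windows(t, u, a, b, w, min_len, max_mm))
    return out


def find_dispersed(
    genome: GenomeSet,
    params: DispersedParams = DispersedParams(),
    ssr_thresholds: Optional[SsrThresholds] = SsrThresholds(),
) -> List[RepeatPair]:
    """Maximal dispersed repeat pairs in all four relations.

    A pair with j mismatches is maximal when extending either end by one
    base would add a mismatch or leave the sequence.  Overlapping maximal
    windows on one diagonal describe a single repeat locus and are reported
    once, represented by the window with the fewest mismatches (ties:
    longest, then leftmost).  Self-identical interval pairs are dropped;
    tandem shadows of reported SSR runs (pairs whose two intervals both lie
    mostly within one SSR run) are dropped; pairs at or above the E-value
    cutoff are dropped.
    """
    t = _SPACER.join(r.sequence for r in genome)
    n = len(t)
    offsets: List[Tuple[str, int, int]] = []  # (record, 0-based start in t, length)
    pos = 0
    for r in genome:
        offsets.append((r.id, pos, len(r)))
        pos += len(r) + len(_SPACER)
    search_space = genome.total_length

    ssr_runs: Dict[str, List[Tuple[int, int]]] = {}
    if ssr_thresholds is not None:
        for h in find_ssrs(genome, ssr_thresholds):
            ssr_runs.setdefault(h.record_id, []).append((h.start, h.end))

    def back_map(start0: int, length: int) -> Tuple[str, int, int]:
        for rid, off, rlen in offsets:
            if off <= start0 and start0 + length <= off + rlen:
                return rid, start0 - off + 1, start0 - off + length
        raise AssertionError("window spans the N spacer")

    pairs: List[RepeatPair] = []
    for cls in REPEAT_CLASSES:
        u = _transform(t, cls)
        windows = _forward_pairs(
            t, u, params.min_length, params.max_mismatches, self_compare=(cls == "forward")
        )
        # convert windows to unordered interval pairs in T coordinates
        cands: Set[Tuple[int, int, int, int]] = set()
        for i1, i2, d, mm in windows:
            length = i2 - i1 + 1
            a0 = i1
            if cls in ("forward", "complement"):
                b0 = i1 + d
                dkey = abs(d)
            else:  # reverse / palindromic: U is T reversed
                b0 = n - (i2 + d) - 1
                dkey = d
            if a0 == b0:
                continue  # self-identical interval pair
            lo, hi = min(a0, b0), max(a0, b0)
            cands.add((dkey, lo, hi, length * 10_000 + mm))
        for rep in _cluster_representatives(cands):
            dkey, lo, hi, packed = rep
            length, mm = divmod(packed, 10_000)
            e = evalue(length, mm, search_space)
            if e >= params.evalue_cutoff:
                continue
            rec_a, sa, ea = back_map(lo, length)
            rec_b, sb, eb = back_map(hi, length)
            # tandem shadows: both intervals mostly inside one SSR run
            shadow = False
            if rec_a == rec_b:
                for rs, re_ in ssr_runs.get(rec_a, ()):
                    ov_a = min(ea, re_) - max(sa, rs) + 1
                    ov_b = min(eb, re_) - max(sb, rs) + 1
                    if ov_a > length / 2 and ov_b > length / 2:
                        shadow = True
                        break
            if shadow:
                continue
            if (rec_a, sa) > (rec_b, sb):
                rec_a, sa, ea, rec_b, sb, eb = rec_b, sb, eb, rec_a, sa, ea
            pairs.append(RepeatPair(cls, rec_a, sa, ea, rec_b, sb, eb, length, mm, e))
    pairs.sort(
        key=lambda p: (p.cls, p.rec1, p.start1, p.rec2, p.start2, p.length)
    )
    return pairs


def _cluster_representatives(
    cands: Set[Tuple[int, int, int, int]]
) -> List[Tuple[int, int, int, int]]:
    """Overlapping maximal windows on one diagonal describe the same repeat
    locus (the mismatch budget can be split between the two ends in several
    ways).  Cluster per diagonal key by first-interval overlap and keep one
    representative per locus: fewest mismatches, then longest, then
    leftmost.  Entries are (diag key, start_a, start_b, length*10000+mm)."""
    by_diag: Dict[int, List[Tuple[int, int, int, int]]] = {}
    for c in cands:
        by_diag.setdefault(c[0], []).append(c)
    reps: List[Tuple[int, int, int, int]] = []
    for dkey in sorted(by_diag):
        group = sorted(by_diag[dkey], key=lambda c: c[1])
        cluster: List[Tuple[int, int, int, int]] = []
        cluster_end = -1
        def flush() -> None:
            if cluster:
                reps.append(
                    min(cluster, key=lambda c: (c[3] % 10_000, -(c[3] // 10_000), c[1]))
                )
        for c in group:
            length = c[3] // 10_000
            if cluster and c[1] > cluster_end:
                flush()
                cluster = []
                cluster_end = -1
            cluster.append(c)
            cluster_end = max(cluster_end, c[1] + length - 1)
        flush()
    return reps


# ---------------------------------------------------------------------------
# summary

def summarize_repeats(
    ssrs: Sequence[SsrHit],
    pairs: Sequence[RepeatPair],
    genome: GenomeSet,
) -> dict:
    """Counts by class plus non-redundant dispersed coverage (every base
    counted once across all pair intervals)."""
    by_len: Dict[int, int] = {k: 0 for k in range(1, 7)}
    by_motif: Dict[str, int] = {}
    for h in ssrs:
        by_len[h.motif_length] += 1
        by_motif[h.motif] = by_motif.get(h.motif, 0) + 1
    by_class = {c: 0 for c in REPEAT_CLASSES}
    per_record: Dict[str, List[Tuple[int, int]]] = {}
    longest = 0
    over_100 = 0
    for p in pairs:
        by_class[p.cls] += 1
        per_record.setdefault(p.rec1, []).append((p.start1, p.end1))
        per_record.setdefault(p.rec2, []).append((p.start2, p.end2))
        longest = max(longest, p.length)
        if p.length > 100:
            over_100 += 1
    union_len = sum(interval_union_length(ivs) for ivs in per_record.values())
    total = genome.total_length
    return {
        "ssr_total": len(ssrs),
        "ssr_by_motif_length": by_len,
        "ssr_by_motif": by_motif,
        "dispersed_pairs": len(pairs),
        "dispersed_by_class": by_class,
        "dispersed_union_length": union_len,
        "dispersed_fraction": union_len / total if total else 0.0,
        "dispersed_pairs_over_100bp": over_100,
        "dispersed_longest": longest,
    }
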