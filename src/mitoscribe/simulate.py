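"""Seeded generators for every input the pipeline consumes, with truth
ledgers.

The generators emulate the target system — a multi-chromosome plant
mitogenome next to a quadripartite plastome — at desk scale: 19 circular
chromosomes, a plastome with a pair of inverted-repeat (IR) arms, planted
SSRs of every motif class, planted dispersed repeats of all four
relations, plastid fragments copied into the mitogenome at controlled
identities (MTPTs), a tangled assembly graph whose repeat nodes are shared
by several chromosomes together with long-read node paths that
disambiguate it, per-species intron haplotypes with planted indel loci,
and C-to-U edit-site tables with per-site probabilities.

Every generator draws from its own RNG stream derived from
``(seed, generator name)``, so adding a generator never perturbs the
others, and identical configs give byte-identical output.  Each generator
returns a machine-readable truth ledger sufficient to score the
corresponding finder's precision and recall exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np

from ._util import revcomp, comp
from .graph import AssemblyGraph, ReadPath
from .model import GeneFeature, GenomeRecord, GenomeSet

_BASES = np.array(list("ACGT"))


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SsrPlant:
    motif: str
    count: int


@dataclass(frozen=True)
class DispersedPlant:
    cls: str  # forward | reverse | complement | palindromic
    length: int
    mismatches: int
    cross_chromosome: bool = False


@dataclass(frozen=True)
class MtptPlant:
    length: int
    identity: float
    in_ir: bool = False


@dataclass(frozen=True)
class OrganelleSpec:
    n_chromosomes: int = 19
    chromosome_length: Tuple[int, int] = (2500, 4000)
    gc: float = 0.46  # mirrors the mitogenome's measured base composition
    plastome_length: int = 20000
    plastome_gc: float = 0.35
    ir_length: int = 1500
    ssrs: Tuple[SsrPlant, ...] = (
        SsrPlant("T", 12),
        SsrPlant("A", 11),
        SsrPlant("CT", 7),
        SsrPlant("AT", 6),
        SsrPlant("TCT", 5),
        SsrPlant("AGAT", 4),
        SsrPlant("AACTG", 3),
        SsrPlant("AACTGC", 3),
    )
    dispersed: Tuple[DispersedPlant, ...] = (
        DispersedPlant("forward", 60, 0),
        DispersedPlant("forward", 45, 2),
        DispersedPlant("forward", 400, 0, cross_chromosome=True),
        DispersedPlant("palindromic", 50, 0),
        DispersedPlant("palindromic", 80, 1, cross_chromosome=True),
        DispersedPlant("reverse", 40, 0),
        DispersedPlant("complement", 40, 0),
    )
    mtpts: Tuple[MtptPlant, ...] = (
        MtptPlant(40, 1.0),
        MtptPlant(120, 1.0),
        MtptPlant(250, 0.95),
        MtptPlant(400, 0.95),
        MtptPlant(600, 0.85),
        MtptPlant(300, 0.85),
        MtptPlant(500, 0.75),
        MtptPlant(450, 0.75, in_ir=True),
    )


@dataclass(frozen=True)
class GraphSpec:
    n_chromosomes: int = 19
    n_repeats: int = 10
    repeat_multiplicity: int = 2
    unique_length: Tuple[int, int] = (400, 900)
    repeat_length: Tuple[int, int] = (300, 500)
    baseline_depth: float = 30.0  # typical organelle short-read depth
    depth_noise: float = 0.10
    tiling_passes: int = 2  # systematic read coverage of every junction
    n_random_reads: int = 100
    read_len_nodes: int = 3
    wrong_path_rate: float = 0.0
    gc: float = 0.46


SPECIES = ("A_albus", "A_konjac", "A_krausei", "A_bulbifer", "A_paeoniifolius")


@dataclass(frozen=True)
class IntronLocusPlant:
    size: int
    gapped_species: Tuple[str, ...]


@dataclass(frozen=True)
class IntronSpec:
    species: Tuple[str, ...] = SPECIES
    region_length: int = 700
    substitution_rate: float = 0.005
    # allele design: each locus uniquely separates one species pair, so the
    # minimal discriminating set is all four loci
    regions: Mapping[str, Tuple[IntronLocusPlant, ...]] = field(
        default_factory=lambda: {
            "nad2i156": (
                IntronLocusPlant(14, ("A_konjac",)),
                IntronLocusPlant(8, ("A_krausei", "A_bulbifer", "A_paeoniifolius")),
            ),
            "nad4i976": (
                IntronLocusPlant(12, ("A_krausei",)),
                IntronLocusPlant(15, ("A_krausei", "A_bulbifer")),
            ),
        }
    )


@dataclass(frozen=True)
class EditSpec:
    """Per-gene site counts and amino-acid transition mix; the defaults
    produce a realistic land-plant composition (676 sites, 651
    non-synonymous, top transitions Ser->Leu / Pro->Leu / Ser->Phe)."""

    gene_counts: Optional[Mapping[str, int]] = None  # None -> built-in table
    decoy_rate: float = 0.1  # below-threshold rows per accepted site


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    organelles: OrganelleSpec = OrganelleSpec()
    graph: GraphSpec = GraphSpec()
    introns: IntronSpec = IntronSpec()
    edits: EditSpec = EditSpec()


# ---------------------------------------------------------------------------
# truth ledgers

@dataclass
class PlantedSsr:
    record_id: str
    start: int
    end: int
    motif: str
    count: int


@dataclass
class PlantedPair:
    cls: str
    rec1: str
    start1: int
    end1: int
    rec2: str
    start2: int
    end2: int
    length: int
    mismatches: int


@dataclass
class PlantedMtpt:
    record_id: str
    start: int
    end: int
    plast_start: int
    plast_end: int
    length: int
    identity: float
    identity_bin: str
    in_ir: bool


@dataclass
class OrganelleTruth:
    ssrs: List[PlantedSsr] = field(default_factory=list)
    dispersed: List[PlantedPair] = field(default_factory=list)
    mtpts: List[PlantedMtpt] = field(default_factory=list)
    ir_arms: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None


@dataclass
class GraphTruth:
    chromosome_sequences: List[str]  # spelled circular sequences
    plans: List[List[Tuple[str, str]]]  # oriented node cycles
    multiplicity: Dict[str, int]
    repeat_ids: List[str]
    expected_unresolved: List[str]  # repeats reads cannot resolve


@dataclass
class IntronTruth:
    loci: List[dict]  # region, columns, size, gapped species
    species_sequences: Dict[str, Dict[str, str]]  # region -> species -> ungapped
    primers: Dict[str, Tuple[str, str]]  # region -> (fwd, rev)
    expected_minimal: List[str]


@dataclass
class EditTruth:
    per_gene: Dict[str, int]
    transitions: Dict[Tuple[str, str], int]
    nonsynonymous: int
    total: int
    starts_created: List[str]
    stops_created: List[str]


# ---------------------------------------------------------------------------
# SSR hygiene for random backgrounds

_DEFAULT_MIN = (10, 5, 4, 3, 3, 3)


def _scan_ssr_runs(s: str, minimums=_DEFAULT_MIN) -> List[Tuple[int, int, int]]:
    """Direct scan for tandem runs meeting the thresholds; returns 0-based
    (start, end_exclusive, motif length).  Used only to keep random
    backgrounds free of accidental SSRs."""
    out = []
    n = len(s)
    for k, need in enumerate(minimums, start=1):
        i = 0
        while i <= n - k - 1:
            if s[i] != s[i + k] or s[i] == "N":
                i += 1
                continue
            j = i
            while j + 1 <= n - k - 1 and s[j + 1] == s[j + 1 + k] and s[j + 1] != "N":
                j += 1
            count = (j - i + 1 + k) // k
            if count >= need:
                out.append((i, i + count * k, k))
            i = j + 2
    return out


def _scrub_ssrs(
    chars: List[str], rng: np.random.Generator, protected: List[Tuple[int, int]]
) -> None:
    """Resample single bases until the background contains no accidental
    SSR run, leaving protected 0-based [start, end) intervals untouched."""
    def inside_protected(i: int) -> bool:
        return any(ps <= i < pe for ps, pe in protected)

    for _ in range(50):
        dirty = False
        for a, b, k in _scan_ssr_runs("".join(chars)):
            free = [i for i in range(a, b) if not inside_protected(i)]
            if not free:
                continue  # the run is a planted feature
            dirty = True
            mid = free[len(free) // 2]
            old = chars[mid]
            choices = [c for c in "ACGT" if c != old]
            chars[mid] = choices[int(rng.integers(len(choices)))]
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental SSRs from background")


def _mutate(
    seq: str, n_mut: int, rng: np.random.Generator, keep_ends: int = 0, min_gap: int = 2
) -> str:
    """Substitute ``n_mut`` bases at interior positions spaced at least
    ``min_gap`` apart (keeps local mismatch density moderate so local
    alignment spans the fragment)."""
    if n_mut == 0:
        return seq
    lo, hi = keep_ends, len(seq) - keep_ends
    candidates = list(range(lo, hi))
    if len(candidates) < n_mut * (min_gap + 1):
        raise ValueError("fragment too short for requested mutations")
    chars = list(seq)
    chosen: List[int] = []
    attempts = 0
    while len(chosen) < n_mut:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("mutation placement failed")
        p = int(rng.integers(lo, hi))
        if all(abs(p - q) > min_gap for q in chosen):
            chosen.append(p)
    for p in sorted(chosen):
        old = chars[p]
        choices = [c for c in "ACGT" if c != old]
        chars[p] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# organelles

def _bin_of(identity: float) -> str:
    pct = identity * 100
    if pct >= 90:
        return "90-100"
    if pct >= 80:
        return "80-90"
    if pct >= 70:
        return "70-80"
    return "<70"


class _Placer:
    """Non-overlapping slot allocation within one chromosome (0-based)."""

    def __init__(self, length: int, rng: np.random.Generator, margin: int = 30):
        self.length = length
        self.rng = rng
        self.margin = margin
        self.used: List[Tuple[int, int]] = []

    def alloc(self, size: int, pad: int = 12) -> int:
        for _ in range(300):
            p = int(self.rng.integers(self.margin, self.length - size - self.margin))
            if all(not (p - pad < e and s < p + size + pad) for s, e in self.used):
                self.used.append((p, p + size))
                return p
        raise RuntimeError("no free slot; chromosome too crowded for the plant spec")


def _build_plastome(
    spec: OrganelleSpec, rng: np.random.Generator
) -> Tuple[GenomeRecord, Tuple[Tuple[int, int], Tuple[int, int]]]:
    ir = spec.ir_length
    ssc = spec.plastome_length // 6
    lsc = spec.plastome_length - ssc - 2 * ir
    arm = _random_seq(rng, ir, spec.plastome_gc)
    seq_chars = list(
        _random_seq(rng, lsc, spec.plastome_gc)
        + arm
        + _random_seq(rng, ssc, spec.plastome_gc)
        + revcomp(arm)
    )
    ira = (lsc + 1, lsc + ir)  # 1-based arms
    irb = (lsc + ir + ssc + 1, spec.plastome_length)
    _scrub_ssrs(seq_chars, rng, protected=[])
    # re-sync IRb with the scrubbed IRa so the arms stay exact copies
    arm_seq = "".join(seq_chars[lsc : lsc + ir])
    seq_chars[lsc + ir + ssc :] = list(revcomp(arm_seq))
    seq = "".join(seq_chars)

    # planted plastid gene annotations (sequence content is irrelevant to
    # gene-content reporting; coordinates are what matters)
    features: List[GeneFeature] = []
    def add(name: str, kind: str, start: int, length: int, strand: str = "+") -> None:
        features.append(GeneFeature(name, kind, strand, [(start, start + length - 1)]))

    add("psbA", "PCG", 200, 1000)
    add("rpoB", "PCG", 1600, 1200, "-")
    add("rbcL", "PCG", 3200, 900)
    add("trnH-GUG", "tRNA", 4400, 75)
    add("trnW-CCA", "tRNA", 4700, 74, "-")
    add("trnM-CAU", "tRNA", 5000, 73)
    # genes inside IRa, mirrored into IRb (reverse-complement copy)
    ira_off = 200  # offset within the arm
    add("trnA-UGC", "tRNA", ira[0] + ira_off, 76)
    add("rrn16S", "rRNA", ira[0] + 500, 800)
    for name, kind, length, off in (
        ("trnA-UGC", "tRNA", 76, ira_off),
        ("rrn16S", "rRNA", 800, 500),
    ):
        s_in_arm = off + 1
        e_in_arm = off + length
        add(name, kind, irb[0] + (ir - e_in_arm), length, "-")
    record = GenomeRecord("plastome", seq, topology="circular", features=features)
    return record, (ira, irb)


def make_organelles(
    config: SimConfig,
) -> Tuple[GenomeSet, GenomeRecord, OrganelleTruth]:
    """Toy plastome plus multi-chromosome mitogenome with planted SSRs,
    dispersed repeats and MTPT insertions, and the exact truth ledger.

    Planted features are written over random background (which is scrubbed
    of accidental SSR runs); planted blocks get mismatching borders so that
    maximal extension stays within a few bases of the planted core.
    """
    spec = config.organelles
    rng = _rng(config.seed, "organelles")
    plastome, ir_arms = _build_plastome(spec, rng)
    truth = OrganelleTruth(ir_arms=ir_arms)

    n = spec.n_chromosomes
    lengths = [
        int(rng.integers(spec.chromosome_length[0], spec.chromosome_length[1] + 1))
        for _ in range(n)
    ]
    chroms = [list(_random_seq(rng, L, spec.gc)) for L in lengths]
    placers = [_Placer(L, rng) for L in lengths]
    ids = [f"chr{i+1}" for i in range(n)]
    protected: List[List[Tuple[int, int]]] = [[] for _ in range(n)]

    def write_block(ci: int, pos: int, block: str) -> None:
        chroms[ci][pos : pos + len(block)] = list(block)
        protected[ci].append((pos, pos + len(block)))

    def pick_slot(size: int, exclude: Optional[int] = None) -> Tuple[int, int]:
        """A chromosome index and start with room for ``size`` bases; falls
        back to the least-loaded chromosome when a random pick is full."""
        order = [int(rng.integers(n)) for _ in range(10)]
        order += sorted(
            range(n), key=lambda ci: sum(e - s for s, e in placers[ci].used)
        )
        for ci in order:
            if ci == exclude or lengths[ci] < size + 2 * placers[ci].margin:
                continue
            try:
                return ci, placers[ci].alloc(size)
            except RuntimeError:
                continue
        raise RuntimeError("no chromosome can host a planted feature of this size")

    # --- SSRs
    for plant in spec.ssrs:
        k = len(plant.motif)
        run = plant.motif * plant.count
        ci, pos = pick_slot(len(run) + 2)
        write_block(ci, pos + 1, run)
        # break period-k continuation at both borders
        left_ban = plant.motif[-1]
        right_ban = plant.motif[0]
        chroms[ci][pos] = [c for c in "ACGT" if c != left_ban][
            int(rng.integers(3))
        ]
        chroms[ci][pos + 1 + len(run)] = [c for c in "ACGT" if c != right_ban][
            int(rng.integers(3))
        ]
        protected[ci].append((pos, pos + len(run) + 2))
        from .repeats import _is_primitive  # planted motifs must be primitive

        assert _is_primitive(plant.motif)
        truth.ssrs.append(
            PlantedSsr(ids[ci], pos + 2, pos + 1 + len(run), plant.motif, plant.count)
        )

    # --- dispersed repeats
    def relation_copy(block: str, cls: str) -> str:
        if cls == "forward":
            return block
        if cls == "reverse":
            return block[::-1]
        if cls == "complement":
            return comp(block)
        if cls == "palindromic":
            return revcomp(block)
        raise ValueError(cls)

    for plant in spec.dispersed:
        block = _random_seq(rng, plant.length, spec.gc)
        mutated = _mutate(block, plant.mismatches, rng, keep_ends=8)
        ci1, p1 = pick_slot(plant.length)
        if plant.cross_chromosome:
            ci2, p2 = pick_slot(plant.length, exclude=ci1)
        else:
            ci2, p2 = ci1, placers[ci1].alloc(plant.length)
        write_block(ci1, p1, block)
        write_block(ci2, p2, relation_copy(mutated, plant.cls))
        a = (ids[ci1], p1 + 1, p1 + plant.length)
        b = (ids[ci2], p2 + 1, p2 + plant.length)
        if a > b:
            a, b = b, a
        truth.dispersed.append(
            PlantedPair(plant.cls, *a, *b, plant.length, plant.mismatches)
        )

    # --- MTPT insertions copied from the plastome
    # sources are non-overlapping plastome loci (LSC, or inside IRa for
    # in_ir plants) so the fragments never create mito-mito repeats
    ira, _irb = ir_arms
    lsc_placer = _Placer(ira[0] - 1, rng, margin=100)
    ir_placer = _Placer(ira[1] - ira[0] + 1, rng, margin=10)
    for plant in spec.mtpts:
        if plant.in_ir:
            src = ira[0] - 1 + ir_placer.alloc(plant.length)
        else:
            src = lsc_placer.alloc(plant.length)
        fragment = plastome.sequence[src : src + plant.length]
        k_mut = round((1 - plant.identity) * plant.length)
        mutated = _mutate(fragment, k_mut, rng, keep_ends=12)
        ci, pos = pick_slot(plant.length)
        write_block(ci, pos, mutated)
        truth.mtpts.append(
            PlantedMtpt(
                ids[ci],
                pos + 1,
                pos + plant.length,
                src + 1,
                src + plant.length,
                plant.length,
                1 - k_mut / plant.length,
                _bin_of(1 - k_mut / plant.length),
                plant.in_ir,
            )
        )

    for ci in range(n):
        _scrub_ssrs(chroms[ci], rng, protected[ci])
    records = [
        GenomeRecord(ids[i], "".join(chroms[i]), topology="circular") for i in range(n)
    ]
    truth.mtpts.sort(key=lambda m: (ids.index(m.record_id), m.start))
    return GenomeSet(records), plastome, truth


# ---------------------------------------------------------------------------
# assembly graph

def make_graph(
    config: SimConfig,
) -> Tuple[AssemblyGraph, List[ReadPath], GraphTruth]:
    """Tangled assembly graph built from known circular chromosomes that
    share repeat segments, plus simulated long-read node paths.

    Nodes are unique/repeat segments with depths proportional to copy
    number (with noise); edges are blunt (overlap 0) adjacencies.  Reads
    are contiguous windows of the true circular node paths: a configurable
    number of systematic tiling passes guarantees junction coverage, plus
    random reads; with zero passes and zero reads the ledger lists the
    repeats as expected-unresolved.
    """
    spec = config.graph
    rng = _rng(config.seed, "graph")
    if spec.repeat_multiplicity > spec.n_chromosomes:
        raise ValueError("repeat multiplicity cannot exceed chromosome count")

    # segment plans: each repeat is inserted into `repeat_multiplicity`
    # distinct chromosomes, always flanked by unique segments
    assignments: List[List[int]] = [[] for _ in range(spec.n_chromosomes)]
    repeat_ids = [f"R{j+1}" for j in range(spec.n_repeats)]
    for j in range(spec.n_repeats):
        chosen = rng.choice(spec.n_chromosomes, size=spec.repeat_multiplicity, replace=False)
        for ci in sorted(int(c) for c in chosen):
            assignments[ci].append(j)

    graph = AssemblyGraph()
    mult: Dict[str, int] = {}
    for j, rid in enumerate(repeat_ids):
        L = int(rng.integers(*spec.repeat_length))
        m = sum(rid_list.count(j) for rid_list in assignments)
        depth = spec.baseline_depth * m * (
            1 + spec.depth_noise * float(rng.uniform(-1, 1))
        )
        graph.add_node(rid, _random_seq(rng, L, spec.gc), depth)
        mult[rid] = m

    plans: List[List[Tuple[str, str]]] = []
    u_counter = 0
    for ci in range(spec.n_chromosomes):
        plan: List[Tuple[str, str]] = []
        segments = [None] + [j for j in assignments[ci]]  # leading unique + repeats
        for j in segments:
            # a unique segment before each repeat (and one leading)
            uid = f"U{u_counter}"
            u_counter += 1
            L = int(rng.integers(*spec.unique_length))
            depth = spec.baseline_depth * (
                1 + spec.depth_noise * float(rng.uniform(-1, 1))
            )
            flipped = bool(rng.random() < 0.3)
            seq = _random_seq(rng, L, spec.gc)
            graph.add_node(uid, revcomp(seq) if flipped else seq, depth)
            mult[uid] = 1
            plan.append((uid, "-" if flipped else "+"))
            if j is not None:
                plan.append((repeat_ids[j], "+"))
        plans.append(plan)
        for i in range(len(plan)):
            a, ao = plan[i]
            b, bo = plan[(i + 1) % len(plan)]
            graph.add_edge(a, ao, b, bo, 0)

    def spell(plan: List[Tuple[str, str]]) -> str:
        return "".join(
            revcomp(graph.nodes[nid].sequence) if o == "-" else graph.nodes[nid].sequence
            for nid, o in plan
        )

    truth = GraphTruth(
        chromosome_sequences=[spell(p) for p in plans],
        plans=plans,
        multiplicity=dict(mult),
        repeat_ids=list(repeat_ids),
        expected_unresolved=(
            list(repeat_ids)
            if spec.tiling_passes == 0 and spec.n_random_reads == 0
            else []
        ),
    )

    def window(plan: List[Tuple[str, str]], start: int, k: int) -> List[Tuple[str, str]]:
        return [plan[(start + i) % len(plan)] for i in range(k)]

    reads: List[ReadPath] = []
    k = spec.read_len_nodes
    for p_i in range(spec.tiling_passes):
        for ci, plan in enumerate(plans):
            for s in range(len(plan)):
                steps = window(plan, s, min(k, len(plan) + 1))
                reads.append(ReadPath(f"tile{p_i}_{ci}_{s}", steps))
    weights = np.array([len(p) for p in plans], dtype=float)
    weights /= weights.sum()
    for r_i in range(spec.n_random_reads):
        ci = int(rng.choice(len(plans), p=weights))
        plan = plans[ci]
        s = int(rng.integers(len(plan)))
        steps = window(plan, s, min(k, len(plan) + 1))
        if rng.random() < 0.5:  # reverse-strand read
            steps = [(nid, "-" if o == "+" else "+") for nid, o in reversed(steps)]
        if rng.random() < spec.wrong_path_rate and len(steps) >= 3:
            other = [x for x in graph.nodes if x != steps[1][0]]
            steps[1] = (other[int(rng.integers(len(other)))], "+")
        reads.append(ReadPath(f"read{r_i}", steps))
    return graph, reads, truth


# ---------------------------------------------------------------------------
# species introns

def make_species_introns(
    config: SimConfig,
) -> Tuple[Dict[str, Dict[str, str]], IntronTruth]:
    """Pre-aligned per-species intron haplotypes with planted indel loci.

    Deletions relative to a common ancestor become gap columns; background
    substitutions (outside the loci and a 2-column buffer) add realistic
    single-column variation that falls below the locus size threshold.
    """
    spec = config.introns
    rng = _rng(config.seed, "introns")
    if len(spec.species) < 2:
        raise ValueError("need at least two species")
    alignments: Dict[str, Dict[str, str]] = {}
    truth = IntronTruth(
        loci=[],
        species_sequences={},
        primers={},
        expected_minimal=[],
    )
    for region, loci in spec.regions.items():
        unknown = [
            sp for pl in loci for sp in pl.gapped_species if sp not in spec.species
        ]
        if unknown:
            raise ValueError(f"unknown species in locus spec: {unknown}")
        L = spec.region_length
        anc_chars = list(_random_seq(rng, L, 0.42))
        _scrub_ssrs(anc_chars, rng, [])
        ancestor = "".join(anc_chars)
        # place loci left to right with >= 60 conserved columns between
        n_loci = len(loci)
        positions: List[int] = []
        cursor = 60
        span = (L - 120 - sum(pl.size for pl in loci)) // max(1, n_loci)
        for pl in loci:
            start = cursor + int(rng.integers(10, max(11, span - 50)))
            if start + pl.size > L - 60:
                raise ValueError("region too short for the requested loci")
            positions.append(start)
            cursor = start + pl.size + 60
        forbidden: Set[int] = set()
        for start, pl in zip(positions, loci):
            forbidden.update(range(start - 2, start + pl.size + 2))
        aln: Dict[str, str] = {}
        for sp in spec.species:
            chars = list(ancestor)
            for c in range(L):
                if c in forbidden:
                    continue
                if rng.random() < spec.substitution_rate:
                    chars[c] = [b for b in "ACGT" if b != chars[c]][
                        int(rng.integers(3))
                    ]
            for start, pl in zip(positions, loci):
                if sp in pl.gapped_species:
                    chars[start : start + pl.size] = ["-"] * pl.size
            aln[sp] = "".join(chars)
        alignments[region] = aln
        truth.species_sequences[region] = {
            sp: aln[sp].replace("-", "") for sp in spec.species
        }
        for i, (start, pl) in enumerate(zip(positions, loci), start=1):
            name = f"{region}_v{i}"
            truth.loci.append(
                {
                    "region": region,
                    "name": name,
                    "start_col": start + 1,
                    "end_col": start + pl.size,
                    "size": pl.size,
                    "gapped_species": list(pl.gapped_species),
                }
            )
            truth.expected_minimal.append(name)
        fwd = ancestor[positions[0] - 55 : positions[0] - 35]
        tail = positions[-1] + loci[-1].size
        rev = revcomp(ancestor[tail + 35 : tail + 55])
        truth.primers[region] = (fwd, rev)
    truth.expected_minimal.sort()
    return alignments, truth


# ---------------------------------------------------------------------------
# edit-site tables

_GENES_CORE = [
    "atp1", "atp4", "atp6", "atp8", "atp9", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    "cox1", "cox2", "cox3", "mttB", "matR", "ccmB", "ccmC", "ccmFC", "ccmFN",
]
_GENES_VARIABLE = [
    "rpl5", "rpl10", "rpl16", "rps1", "rps2", "rps3", "rps4", "rps7",
    "rps12", "rps13", "rps14", "sdh4",
]

_FIXED_COUNTS = {
    "nad4": 61, "ccmB": 40, "nad7": 40, "ccmC": 35, "nad2": 34, "nad5": 33,
    "mttB": 32, "ccmFN": 31, "nad1": 31, "rps14": 1,
}

# codon template per single C->T editable transition:
# (codon before, edited codon position 1-3, aa before, aa after)
_TEMPLATES = {
    ("S", "L"): ("TCA", 2),
    ("P", "L"): ("CCA", 2),
    ("S", "F"): ("TCT", 2),
    ("H", "Y"): ("CAT", 1),
    ("R", "W"): ("CGG", 1),
    ("R", "C"): ("CGT", 1),
    ("T", "I"): ("ACA", 2),
    ("A", "V"): ("GCA", 2),
    ("L", "F"): ("CTT", 1),
    ("P", "S"): ("CCG", 1),
    ("L", "L"): ("CTC", 3),  # synonymous wobble edit
}

_OTHER_POOL = [("H", "Y"), ("R", "W"), ("R", "C"), ("T", "I"), ("A", "V"),
               ("L", "F"), ("P", "S")]

# codons free of C, excluding stops: safe filler that can never collide
# with a planted or decoy edit site
_FILLERS = [
    c for c in (a + b + d for a in "AGT" for b in "AGT" for d in "AGT")
    if c not in ("TAA", "TAG", "TGA")
]


def default_gene_counts() -> Dict[str, int]:
    genes = _GENES_CORE + _GENES_VARIABLE
    counts = dict(_FIXED_COUNTS)
    rest = [g for g in genes if g not in counts]
    for g in rest:
        counts[g] = 13
    return {g: counts[g] for g in genes}


def make_edit_tables(
    config: SimConfig,
) -> Tuple[Dict[str, str], "pd.DataFrame", EditTruth]:
    """Per-gene CDS sequences plus an edit-site table (gene, cds_position,
    probability) with a realistic land-plant composition: start codons of nad1
    and nad4L created from ACG, stop codons of atp6 and ccmFC created from
    CAA/CGA, and an amino-acid transition mix dominated by Ser->Leu,
    Pro->Leu and Ser->Phe.  Decoy rows below the 0.9 probability threshold
    are included to exercise ingestion filtering."""
    import pandas as pd

    spec = config.edits
    rng = _rng(config.seed, "edits")
    gene_counts = dict(spec.gene_counts) if spec.gene_counts else default_gene_counts()
    total = sum(gene_counts.values())

    # global transition budget, then assignment to genes
    syn_total = round(total * 25 / 676)
    big = {("S", "L"): round(total * 146 / 676),
           ("P", "L"): round(total * 145 / 676),
           ("S", "F"): round(total * 107 / 676)}
    specials = []  # (gene, kind)
    if "nad1" in gene_counts:
        specials.append(("nad1", "start"))
    if "nad4L" in gene_counts:
        specials.append(("nad4L", "start"))
    if "atp6" in gene_counts:
        specials.append(("atp6", "stop_caa"))
    if "ccmFC" in gene_counts:
        specials.append(("ccmFC", "stop_cga"))
    n_other = total - syn_total - sum(big.values()) - len(specials)
    if n_other < 0:
        raise ValueError("transition mix exceeds total site budget")

    # build a flat multiset of transition labels, then deal them per gene
    labels: List[Tuple[str, str]] = []
    for tr, cnt in big.items():
        labels.extend([tr] * cnt)
    labels.extend([("L", "L")] * syn_total)
    for i in range(n_other):
        labels.extend([_OTHER_POOL[i % len(_OTHER_POOL)]])
    rng.shuffle(labels)  # type: ignore[arg-type]

    special_by_gene = {}
    for g, kind in specials:
        special_by_gene[g] = kind

    cds_out: Dict[str, str] = {}
    rows: List[Tuple[str, int, float]] = []
    truth = EditTruth(
        per_gene=dict(gene_counts),
        transitions={},
        nonsynonymous=0,
        total=total,
        starts_created=sorted(g for g, k in specials if k == "start"),
        stops_created=sorted(g for g, k in specials if k.startswith("stop")),
    )
    cursor = 0
    for gene, count in gene_counts.items():
        n_special = 1 if gene in special_by_gene else 0
        n_regular = count - n_special
        gene_labels = labels[cursor : cursor + n_regular]
        cursor += n_regular
        n_codons = max(2 * count + 10, 40)
        codons = [
            _FILLERS[int(rng.integers(len(_FILLERS)))] for _ in range(n_codons)
        ]
        # reserved interior codon slots for the planted sites
        interior = list(range(1, n_codons - 1))
        slots = sorted(
            int(x) for x in rng.choice(interior, size=n_regular, replace=False)
        )
        site_positions: List[Tuple[int, Tuple[str, str]]] = []
        for slot, tr in zip(slots, gene_labels):
            codon, pos = _TEMPLATES[tr]
            codons[slot] = codon
            site_positions.append((slot * 3 + pos, tr))
            truth.transitions[tr] = truth.transitions.get(tr, 0) + 1
            if tr[0] != tr[1]:
                truth.nonsynonymous += 1
        kind = special_by_gene.get(gene)
        if kind == "start":
            codons[0] = "ACG"
            site_positions.append((2, ("T", "M")))
        else:
            codons[0] = "ATG"
        if kind == "stop_caa":
            codons[-1] = "CAA"
            site_positions.append(((n_codons - 1) * 3 + 1, ("Q", "*")))
        elif kind == "stop_cga":
            codons[-1] = "CGA"
            site_positions.append(((n_codons - 1) * 3 + 1, ("R", "*")))
        else:
            codons[-1] = "TAA"
        if kind is not None:
            tr = site_positions[-1][1]
            truth.transitions[tr] = truth.transitions.get(tr, 0) + 1
            truth.nonsynonymous += 1
        cds = "".join(codons)
        cds_out[gene] = cds
        for pos, _tr in sorted(site_positions):
            rows.append((gene, pos, round(float(rng.uniform(0.91, 0.995)), 4)))
        # decoys: sub-threshold rows on C bases not already edited
        used = {p for p, _ in site_positions}
        c_positions = [
            i + 1 for i, ch in enumerate(cds) if ch == "C" and i + 1 not in used
        ]
        n_decoys = min(len(c_positions), int(round(count * spec.decoy_rate)))
        if n_decoys:
            for p in sorted(
                int(x) for x in rng.choice(c_positions, size=n_decoys, replace=False)
            ):
                rows.append((gene, p, round(float(rng.uniform(0.4, 0.85)), 4)))
    table = pd.DataFrame(rows, columns=["gene", "cds_position", "probability"])
    return cds_out, table, truth
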