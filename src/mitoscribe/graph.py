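"""Untangle a mitochondrial assembly graph into circular chromosomes.

Plant mitogenomes frequently assemble into a tangled graph in which
repeated segments are collapsed into single high-depth nodes shared by
several chromosomes.  This module resolves such a graph in three steps:

1. ``estimate_multiplicity`` — infer each node's copy number from read
   depth relative to a length-weighted median baseline;
2. ``thread_long_reads`` — count, for every repeat node, how often long
   reads traverse each (incoming edge, outgoing edge) combination;
3. ``resolve_chromosomes`` — duplicate repeat nodes to their copy number,
   wire the duplicated copies according to the best-supported junction
   pairings, and decompose the rewritten graph into simple cycles whose
   sequences are spelled out with overlaps collapsed.

``check_completeness`` audits the result: all 24 core mitochondrial genes
must be present and every chromosome must be circular (fully extended).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from ._util import canonical_circular, revcomp

#: The 24 widely conserved angiosperm mitochondrial protein-coding genes used
#: as the assembly-completeness criterion.
CORE_GENES = frozenset(
    {
        "atp1", "atp4", "atp6", "atp8", "atp9",
        "cob",
        "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
        "cox1", "cox2", "cox3",
        "mttB", "matR",
        "ccmB", "ccmC", "ccmFC", "ccmFN",
    }
)

End = Tuple[str, str]  # (node id, orientation "+"/"-")


class GraphError(ValueError):
    pass


class MissingDepthError(GraphError):
    pass


class UnresolvedJunctionError(GraphError):
    """A repeat junction could not be paired unambiguously."""

    def __init__(self, node: str, detail: str = "") -> None:
        self.node = node
        super().__init__(
            f"unresolved junction at repeat node {node!r}"
            + (f": {detail}" if detail else "")
        )


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


@dataclass
class GraphNode:
    sequence: str
    depth: Optional[float] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.depth is not None and self.depth < 0:
            raise GraphError("node depth must be >= 0")


def _canon_edge(a: str, ao: str, b: str, bo: str) -> Tuple[str, str, str, str]:
    fwd = (a, ao, b, bo)
    rev = (b, _flip(bo), a, _flip(ao))
    return min(fwd, rev)


@dataclass
class AssemblyGraph:
    """Nodes (sequence + mean read depth) and oriented overlap edges.

    An edge ``(a, ao, b, bo)`` means the end of ``a`` read in orientation
    ``ao`` overlaps the start of ``b`` read in orientation ``bo``; it is
    stored canonically so that the reverse traversal is the same edge.
    """

    nodes: Dict[str, GraphNode] = field(default_factory=dict)
    edges: Dict[Tuple[str, str, str, str], int] = field(default_factory=dict)

    def add_node(self, name: str, sequence: str, depth: Optional[float] = None) -> None:
        self.nodes[name] = GraphNode(sequence, depth)

    def add_edge(self, a: str, ao: str, b: str, bo: str, overlap: int = 0) -> None:
        if a not in self.nodes or b not in self.nodes:
            missing = a if a not in self.nodes else b
            raise GraphError(f"edge endpoint {missing!r} does not exist")
        self.edges[_canon_edge(a, ao, b, bo)] = overlap

    def has_edge(self, a: str, ao: str, b: str, bo: str) -> bool:
        return _canon_edge(a, ao, b, bo) in self.edges

    def successors(self, node: str, orient: str) -> List[Tuple[str, str, int]]:
        """All (next node, next orientation, overlap) reachable from the
        oriented node end."""
        out = []
        for (a, ao, b, bo), ov in self.edges.items():
            if (a, ao) == (node, orient):
                out.append((b, bo, ov))
            if (b, _flip(bo)) == (node, orient):
                out.append((a, _flip(ao), ov))
        return sorted(out)


@dataclass
class ReadPath:
    read_id: str
    path: List[End]


@dataclass
class ChromosomePath:
    id: str
    steps: List[End]  # original node ids (repeat copies collapsed back)
    circular: bool
    sequence: str

    @property
    def canonical_sequence(self) -> str:
        """Rotation- and strand-invariant form for circular paths; for
        linear paths, the lexicographically smaller strand."""
        if self.circular:
            return canonical_circular(self.sequence)
        return min(self.sequence, revcomp(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CompletenessReport:
    core_genes_present: Set[str]
    missing_core: Set[str]
    all_paths_circular: bool
    unextended_ends: List[Tuple[str, str]]  # (path id, "start"/"end")
    passed: bool


# ---------------------------------------------------------------------------
# multiplicity

def estimate_multiplicity(graph: AssemblyGraph) -> Dict[str, int]:
    """Copy number per node: round-half-up of depth over the length-weighted
    median node depth.  The median resists inflation by repeat nodes, which
    are few and short relative to unique sequence."""
    for name, node in graph.nodes.items():
        if node.depth is None:
            raise MissingDepthError(f"node {name!r} has no depth")
    items = sorted(
        ((node.depth, len(node.sequence)) for node in graph.nodes.values()),
    )
    total = sum(w for _, w in items)
    acc = 0.0
    baseline = items[-1][0]
    for d, w in items:
        acc += w
        if acc >= total / 2:
            baseline = d
            break
    if baseline <= 0:
        raise MissingDepthError("median node depth is zero")
    out = {}
    for name, node in graph.nodes.items():
        out[name] = max(1, int(node.depth / baseline + 0.5))
    return out


def repeat_nodes(multiplicity: Mapping[str, int]) -> Set[str]:
    return {n for n, m in multiplicity.items() if m >= 2}


# ---------------------------------------------------------------------------
# read threading

@dataclass
class JunctionSupport:
    """Counts of observed in->repeat->out traversals, keyed in the repeat
    node's plus frame."""

    counts: Dict[Tuple[str, End, End], int] = field(default_factory=dict)
    skipped_reads: int = 0

    def count(self, r: str, in_end: End, out_end: End) -> int:
        return self.counts.get((r, in_end, out_end), 0)

    def for_node(self, r: str) -> Dict[Tuple[End, End], int]:
        return {
            (ie, oe): c for (node, ie, oe), c in self.counts.items() if node == r
        }


def _canon_triple(a: End, r: End, b: End) -> Tuple[str, End, End]:
    """Normalize a traversal (a)->(r)->(b) into r's plus frame; the reverse
    strand traversal maps onto the same key."""
    if r[1] == "-":
        a, b = (b[0], _flip(b[1])), (a[0], _flip(a[1]))
    return (r[0], a, b)


def thread_long_reads(
    graph: AssemblyGraph,
    reads: Sequence[ReadPath],
    repeats: Set[str],
) -> JunctionSupport:
    """Tabulate junction support at repeat nodes from long-read node paths.

    Reads whose path uses a nonexistent edge are skipped (counted in
    ``skipped_reads``).
    """
    support = JunctionSupport()
    for read in reads:
        ok = all(
            graph.has_edge(*read.path[i], *read.path[i + 1])
            for i in range(len(read.path) - 1)
        )
        if not ok:
            support.skipped_reads += 1
            continue
        for i in range(1, len(read.path) - 1):
            node, orient = read.path[i]
            if node in repeats:
                key = _canon_triple(read.path[i - 1], read.path[i], read.path[i + 1])
                support.counts[key] = support.counts.get(key, 0) + 1
    return support


# ---------------------------------------------------------------------------
# resolution

def _incident_ends(graph: AssemblyGraph, r: str) -> Tuple[List[End], List[End]]:
    """(in-ends, out-ends) of repeat node r in its plus frame."""
    in_ends: Set[End] = set()
    out_ends: Set[End] = set()
    for (a, ao, b, bo) in graph.edges:
        if (b, bo) == (r, "+"):
            in_ends.add((a, ao))
        if (a, ao) == (r, "+"):
            out_ends.add((b, bo))
        if (a, _flip(ao)) == (r, "+"):  # edge leaves r-
            in_ends.add((b, _flip(bo)))
        if (b, _flip(bo)) == (r, "+"):
            out_ends.add((a, _flip(ao)))
    return sorted(in_ends), sorted(out_ends)


def _pair_junctions(
    graph: AssemblyGraph,
    multiplicity: Mapping[str, int],
    support: JunctionSupport,
    min_support: int,
) -> Dict[str, List[Tuple[End, End]]]:
    pairings: Dict[str, List[Tuple[End, End]]] = {}
    for r in sorted(repeat_nodes(multiplicity)):
        mult = multiplicity[r]
        in_ends, out_ends = _incident_ends(graph, r)
        cap_in = {e: multiplicity.get(e[0], 1) for e in in_ends}
        cap_out = {e: multiplicity.get(e[0], 1) for e in out_ends}
        cands = [
            (cnt, ie, oe)
            for (ie, oe), cnt in support.for_node(r).items()
            if cnt >= min_support and ie in cap_in and oe in cap_out
        ]
        cands.sort(key=lambda t: (-t[0], t[1], t[2]))
        chosen: List[Tuple[End, End]] = []
        for cnt, ie, oe in cands:
            if len(chosen) >= mult:
                break
            if cap_in[ie] > 0 and cap_out[oe] > 0:
                chosen.append((ie, oe))
                cap_in[ie] -= 1
                cap_out[oe] -= 1
        # forced completion by elimination
        while len(chosen) < mult:
            rem_in = [e for e in in_ends if cap_in[e] > 0]
            rem_out = [e for e in out_ends if cap_out[e] > 0]
            if len(rem_in) == 1 and len(rem_out) == 1:
                ie, oe = rem_in[0], rem_out[0]
                chosen.append((ie, oe))
                cap_in[ie] -= 1
                cap_out[oe] -= 1
            else:
                raise UnresolvedJunctionError(
                    r,
                    f"{mult - len(chosen)} of {mult} traversals unpaired and "
                    f"read support below min_support={min_support} "
                    f"(remaining in-ends {rem_in}, out-ends {rem_out})",
                )
        pairings[r] = chosen
    return pairings


def _rewrite_graph(
    graph: AssemblyGraph,
    multiplicity: Mapping[str, int],
    pairings: Mapping[str, List[Tuple[End, End]]],
) -> AssemblyGraph:
    reps = set(pairings)
    new = AssemblyGraph()
    for name, node in graph.nodes.items():
        if name in reps:
            for i in range(len(pairings[name])):
                new.add_node(f"{name}#{i}", node.sequence, node.depth)
        else:
            new.add_node(name, node.sequence, node.depth)
    # which copies of each repeat use each original edge
    usage: Dict[Tuple[str, str, str, str], Dict[str, List[str]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for r, prs in pairings.items():
        for i, (ie, oe) in enumerate(prs):
            copy = f"{r}#{i}"
            usage[_canon_edge(ie[0], ie[1], r, "+")][r].append(copy)
            usage[_canon_edge(r, "+", oe[0], oe[1])][r].append(copy)
    for key, ov in graph.edges.items():
        a, ao, b, bo = key
        ends_a = usage[key][a] if a in reps else [a]
        ends_b = usage[key][b] if b in reps else [b]
        if a in reps and b in reps:
            if len(ends_a) != len(ends_b):
                raise UnresolvedJunctionError(a, "inconsistent repeat-repeat edge usage")
            combos = list(zip(sorted(ends_a), sorted(ends_b)))
        elif a in reps:
            combos = [(ca, b) for ca in ends_a]
        elif b in reps:
            combos = [(a, cb) for cb in ends_b]
        else:
            combos = [(a, b)]
        for na, nb in combos:
            new.add_edge(na, ao, nb, bo, ov)
    return new


def _spell(path_nodes: List[End], overlaps: List[int], circular: bool,
           graph: AssemblyGraph) -> str:
    """Concatenate oriented node sequences, trimming each junction's overlap
    from the start of the entered node.  For circular paths ``overlaps`` has
    one entry per node (the overlap of the edge *entering* it, with the
    closing edge's overlap assigned to the first node); for linear paths the
    first node is untrimmed."""
    parts = []
    for i, (node, orient) in enumerate(path_nodes):
        seq = graph.nodes[node].sequence
        if orient == "-":
            seq = revcomp(seq)
        ov = overlaps[i] if i < len(overlaps) else 0
        parts.append(seq[ov:])
    return "".join(parts)


def resolve_chromosomes(
    graph: AssemblyGraph,
    multiplicity: Mapping[str, int],
    support: JunctionSupport,
    min_support: int = 2,
) -> List[ChromosomePath]:
    """Duplicate repeat nodes to their copy number, wire the copies by
    descending junction support (ties by lexicographic edge id, pairings
    below ``min_support`` discarded), and decompose the rewritten graph into
    simple cycles.

    Raises :class:`UnresolvedJunctionError` when a junction remains
    ambiguous; linear leftovers are returned with ``circular=False``.
    """
    pairings = _pair_junctions(graph, multiplicity, support, min_support)
    rewritten = _rewrite_graph(graph, multiplicity, pairings)

    adj: Dict[End, List[Tuple[str, str, int]]] = defaultdict(list)
    for (a, ao, b, bo), ov in rewritten.edges.items():
        adj[(a, ao)].append((b, bo, ov))
        adj[(b, _flip(bo))].append((a, _flip(ao), ov))
    for end, nxt in adj.items():
        if len(nxt) > 1:
            raise UnresolvedJunctionError(
                end[0].split("#")[0], f"node end {end} has {len(nxt)} successors"
            )

    visited: Set[str] = set()
    raw_paths: List[Tuple[List[End], List[int], bool]] = []
    for start in sorted(rewritten.nodes):
        if start in visited:
            continue
        path: List[End] = [(start, "+")]
        entering: List[int] = [0]
        circular = False
        cur: End = (start, "+")
        while True:
            nxt = adj.get(cur, [])
            if not nxt:
                break
            m, mo, ov = nxt[0]
            if (m, mo) == path[0]:
                circular = True
                entering[0] = ov
                break
            if m in {p[0] for p in path}:
                raise UnresolvedJunctionError(
                    m.split("#")[0], "path revisits a node in conflicting orientation"
                )
            path.append((m, mo))
            entering.append(ov)
            cur = (m, mo)
        if not circular:
            cur = (start, "-")
            while True:
                nxt = adj.get(cur, [])
                if not nxt:
                    break
                m, mo, ov = nxt[0]
                if m in {p[0] for p in path}:
                    break
                path.insert(0, (m, _flip(mo)))
                entering.insert(1, ov)
                cur = (m, mo)
        visited.update(p[0] for p in path)
        raw_paths.append((path, entering, circular))

    chroms: List[ChromosomePath] = []
    for path, entering, circular in raw_paths:
        seq = _spell(path, entering, circular, rewritten)
        steps = [(n.split("#")[0], o) for n, o in path]
        chroms.append(ChromosomePath("", steps, circular, seq))
    chroms.sort(key=lambda c: (-len(c), c.canonical_sequence))
    for i, c in enumerate(chroms, 1):
        c.id = f"chr{i}"
    return chroms


# ---------------------------------------------------------------------------
# auditing

def check_completeness(
    paths: Sequence[ChromosomePath],
    gene_placements: Mapping[str, Iterable[str]],
) -> CompletenessReport:
    """Audit an assembly by the two completeness principles: all 24 core
    genes present somewhere on the paths, and every path circular (fully
    extended).  ``gene_placements`` maps path id -> gene names on it."""
    present: Set[str] = set()
    for names in gene_placements.values():
        present.update(names)
    core_present = present & CORE_GENES
    missing = set(CORE_GENES) - present
    unextended = []
    for p in paths:
        if not p.circular:
            unextended.extend([(p.id, "start"), (p.id, "end")])
    all_circ = not unextended
    return CompletenessReport(
        core_genes_present=core_present,
        missing_core=missing,
        all_paths_circular=all_circ,
        unextended_ends=unextended,
        passed=not missing and all_circ,
    )


def retain_geneless(
    paths: Sequence[ChromosomePath],
    graph: AssemblyGraph,
    annotated: Set[str],
    baseline: Optional[float] = None,
    depth_tolerance: float = 0.5,
    homology: Optional[Set[str]] = None,
) -> Dict[str, bool]:
    """Retention verdict for each path: circular paths without any annotated
    gene are kept when their mean node depth is within ``depth_tolerance``
    (fractional) of the baseline, or when the caller supplies an external
    homology flag for them; everything annotated is kept."""
    if baseline is None:
        mult = estimate_multiplicity(graph)
        depths = sorted(
            (graph.nodes[n].depth, len(graph.nodes[n].sequence)) for n in graph.nodes
        )
        total = sum(w for _, w in depths)
        acc = 0.0
        baseline = depths[-1][0]
        for d, w in depths:
            acc += w
            if acc >= total / 2:
                baseline = d
                break
    homology = homology or set()
    verdict: Dict[str, bool] = {}
    for p in paths:
        if p.id in annotated:
            verdict[p.id] = True
            continue
        node_depths = [
            graph.nodes[n].depth
            for n, _ in p.steps
            if n in graph.nodes and graph.nodes[n].depth is not None
        ]
        mean_depth = sum(node_depths) / len(node_depths) if node_depths else 0.0
        close = abs(mean_depth - baseline) <= depth_tolerance * baseline
        verdict[p.id] = bool(p.circular and (close or p.id in homology))
    return verdict


def flag_plastid_nodes(
    graph: AssemblyGraph,
    plastome,
    min_identity: float = 0.95,
    min_coverage: float = 0.9,
) -> Set[str]:
    """Advisory flags for nodes that look plastid-derived: a node is flagged
    when at least ``min_coverage`` of its length aligns to the plastome at
    ``min_identity`` or better.  Flagged nodes are NOT removed — genuine
    mitochondrial regions of plastid origin (MTPTs) are part of the
    mitogenome."""
    from ._util import interval_union_length
    from .model import GenomeRecord, GenomeSet
    from .mtpt import AlignParams, local_align_many

    queries = GenomeSet(
        [GenomeRecord(name, node.sequence) for name, node in sorted(graph.nodes.items())]
    )
    hsps = local_align_many(queries, plastome, AlignParams())
    covered: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for h in hsps:
        if h.identity >= min_identity:
            covered[h.query_id].append(h.query_interval)
    flagged = set()
    for name, node in graph.nodes.items():
        cov = interval_union_length(covered.get(name, []))
        if cov >= min_coverage * len(node.sequence):
            flagged.add(name)
    return flagged
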