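"""Assembly-graph untangling: multiplicity, read threading, resolution,
completeness auditing."""

import pytest

from mitoscribe import graph as gr
from mitoscribe._util import canonical_circular
from mitoscribe.graph import (
    AssemblyGraph,
    CORE_GENES,
    ChromosomePath,
    ReadPath,
    UnresolvedJunctionError,
)
from mitoscribe.simulate import GraphSpec, SimConfig, make_graph


def _graph(nodes, edges):
    g = AssemblyGraph()
    for name, seq, depth in nodes:
        g.add_node(name, seq, depth)
    for e in edges:
        g.add_edge(*e)
    return g


class TestMultiplicity:
    def test_exact_doubling(self):
        g = _graph(
            [("a", "A" * 100, 30), ("b", "C" * 100, 30), ("c", "G" * 100, 60)], []
        )
        assert gr.estimate_multiplicity(g) == {"a": 1, "b": 1, "c": 2}

    def test_uniform_depths_all_single_copy(self):
        g = _graph([(f"n{i}", "ACGT" * 10, 25.0) for i in range(5)], [])
        assert set(gr.estimate_multiplicity(g).values()) == {1}

    def test_planted_triplication_with_noise(self):
        cfg = SimConfig(
            seed=11,
            graph=GraphSpec(
                n_chromosomes=3, n_repeats=1, repeat_multiplicity=3, depth_noise=0.1
            ),
        )
        g, _reads, truth = make_graph(cfg)
        mult = gr.estimate_multiplicity(g)
        assert mult["R1"] == 3
        assert truth.multiplicity == mult


class TestThreading:
    def test_single_read_counts_one(self):
        g = _graph(
            [("a", "AAAA", 30), ("r", "CCCC", 60), ("b", "GGGG", 30)],
            [("a", "+", "r", "+", 0), ("r", "+", "b", "+", 0)],
        )
        sup = gr.thread_long_reads(
            g, [ReadPath("x", [("a", "+"), ("r", "+"), ("b", "+")])], {"r"}
        )
        assert sup.count("r", ("a", "+"), ("b", "+")) == 1

    def test_reverse_strand_traversal_counts_same_junction(self):
        g = _graph(
            [("a", "AAAA", 30), ("r", "CCCC", 60), ("b", "GGGG", 30)],
            [("a", "+", "r", "+", 0), ("r", "+", "b", "+", 0)],
        )
        fwd = ReadPath("x", [("a", "+"), ("r", "+"), ("b", "+")])
        rev = ReadPath("y", [("b", "-"), ("r", "-"), ("a", "-")])
        sup = gr.thread_long_reads(g, [fwd, rev], {"r"})
        assert sup.count("r", ("a", "+"), ("b", "+")) == 2

    def test_read_with_nonexistent_edge_skipped(self):
        g = _graph(
            [("a", "AAAA", 30), ("r", "CCCC", 60), ("b", "GGGG", 30)],
            [("a", "+", "r", "+", 0)],
        )
        sup = gr.thread_long_reads(
            g, [ReadPath("x", [("a", "+"), ("r", "+"), ("b", "+")])], {"r"}
        )
        assert sup.skipped_reads == 1 and not sup.counts

    def test_only_true_pairings_supported_on_shared_repeat(self):
        cfg = SimConfig(
            seed=5, graph=GraphSpec(n_chromosomes=2, n_repeats=1, n_random_reads=50)
        )
        g, reads, _truth = make_graph(cfg)
        mult = gr.estimate_multiplicity(g)
        sup = gr.thread_long_reads(g, reads, gr.repeat_nodes(mult))
        pairings = {(ie, oe) for (r, ie, oe) in sup.counts}
        assert len(pairings) == 2  # exactly the two planted traversals


class TestResolution:
    def test_disjoint_circles_pass_through(self):
        nodes = [(f"n{i}", "ACGT" * (10 + i), 30.0) for i in range(3)]
        edges = [(f"n{i}", "+", f"n{i}", "+", 0) for i in range(3)]
        g = _graph(nodes, edges)
        mult = gr.estimate_multiplicity(g)
        chroms = gr.resolve_chromosomes(g, mult, gr.JunctionSupport())
        assert len(chroms) == 3 and all(c.circular for c in chroms)
        assert sorted(c.canonical_sequence for c in chroms) == sorted(
            canonical_circular(seq) for _n, seq, _d in nodes
        )

    def test_figure_eight_recovers_planted_chromosomes(self):
        cfg = SimConfig(seed=3, graph=GraphSpec(n_chromosomes=2, n_repeats=1))
        g, reads, truth = make_graph(cfg)
        mult = gr.estimate_multiplicity(g)
        sup = gr.thread_long_reads(g, reads, gr.repeat_nodes(mult))
        chroms = gr.resolve_chromosomes(g, mult, sup)
        assert sorted(c.canonical_sequence for c in chroms) == sorted(
            canonical_circular(s) for s in truth.chromosome_sequences
        )

    def test_figure_eight_without_reads_raises(self):
        cfg = SimConfig(
            seed=3,
            graph=GraphSpec(
                n_chromosomes=2, n_repeats=1, tiling_passes=0, n_random_reads=0
            ),
        )
        g, reads, truth = make_graph(cfg)
        assert truth.expected_unresolved == ["R1"]
        mult = gr.estimate_multiplicity(g)
        sup = gr.thread_long_reads(g, reads, gr.repeat_nodes(mult))
        with pytest.raises(UnresolvedJunctionError, match="R1"):
            gr.resolve_chromosomes(g, mult, sup)

    def test_length_conservation(self):
        cfg = SimConfig(seed=9, graph=GraphSpec(n_chromosomes=4, n_repeats=2))
        g, reads, _truth = make_graph(cfg)
        mult = gr.estimate_multiplicity(g)
        sup = gr.thread_long_reads(g, reads, gr.repeat_nodes(mult))
        chroms = gr.resolve_chromosomes(g, mult, sup)
        expected = sum(
            mult[n] * len(node.sequence) for n, node in g.nodes.items()
        )  # blunt joins: no overlap to subtract
        assert sum(len(c) for c in chroms) == expected

    def test_determinism(self):
        cfg = SimConfig(seed=13, graph=GraphSpec(n_chromosomes=5, n_repeats=3))
        results = []
        for _ in range(2):
            g, reads, _ = make_graph(cfg)
            mult = gr.estimate_multiplicity(g)
            sup = gr.thread_long_reads(g, reads, gr.repeat_nodes(mult))
            chroms = gr.resolve_chromosomes(g, mult, sup)
            results.append([(c.id, c.sequence, c.steps) for c in chroms])
        assert results[0] == results[1]


class TestCompleteness:
    def _circle(self, pid="p1", circular=True):
        return ChromosomePath(pid, [("n", "+")], circular, "ACGT" * 10)

    def test_all_core_genes_and_circular_passes(self):
        report = gr.check_completeness([self._circle()], {"p1": sorted(CORE_GENES)})
        assert report.passed and not report.missing_core

    def test_missing_gene_fails_and_is_listed(self):
        genes = sorted(CORE_GENES - {"atp1"})
        report = gr.check_completeness([self._circle()], {"p1": genes})
        assert not report.passed and report.missing_core == {"atp1"}

    def test_linear_path_fails_with_unextended_ends(self):
        paths = [self._circle(), self._circle("p2", circular=False)]
        report = gr.check_completeness(paths, {"p1": sorted(CORE_GENES)})
        assert not report.passed
        assert ("p2", "start") in report.unextended_ends

    def test_core_gene_list_is_the_24(self):
        assert len(CORE_GENES) == 24
        assert {"atp1", "nad4L", "ccmFN", "matR", "mttB"} <= CORE_GENES


class TestGenelessRetention:
    def test_depth_close_to_baseline_retained(self):
        g = _graph([("a", "A" * 100, 30), ("b", "C" * 100, 31), ("c", "G" * 100, 2)], [])
        paths = [
            ChromosomePath("p1", [("a", "+")], True, "A" * 100),
            ChromosomePath("p2", [("c", "+")], True, "G" * 100),
        ]
        verdict = gr.retain_geneless(paths, g, annotated=set(), baseline=30.0)
        assert verdict == {"p1": True, "p2": False}

    def test_external_homology_flag_rescues(self):
        g = _graph([("c", "G" * 100, 2)], [])
        paths = [ChromosomePath("p2", [("c", "+")], True, "G" * 100)]
        verdict = gr.retain_geneless(
            paths, g, annotated=set(), baseline=30.0, homology={"p2"}
        )
        assert verdict["p2"]


class TestPlastidFlags:
    def test_planted_plastid_nodes_flagged_exactly(self, organelles):
        mito, plastome, _truth = organelles
        g = AssemblyGraph()
        # three nodes that are verbatim plastome substrings + two random ones
        for i, start in enumerate((500, 3000, 9000)):
            g.add_node(f"cp{i}", plastome.sequence[start : start + 400], 30)
        g.add_node("mt0", mito.records[0].sequence[100:500], 30)
        g.add_node("mt1", mito.records[1].sequence[100:500], 30)
        flagged = gr.flag_plastid_nodes(g, plastome)
        assert flagged == {"cp0", "cp1", "cp2"}
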