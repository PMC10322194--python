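"""Intron extraction, variable loci, discrimination search, in-silico PCR."""

import numpy as np
import pytest

from mitoscribe import markers as mk
from mitoscribe._util import revcomp
from mitoscribe.model import GeneFeature, GenomeRecord
from oracles import brute_minimal_set

BASES = np.array(list("ACGT"))


def _rand(rng, n):
    return "".join(rng.choice(BASES, size=n))


class TestExtractIntrons:
    def test_naming_arithmetic(self):
        rec = GenomeRecord(
            "c", "A" * 1300,
            features=[GeneFeature("nad2", "PCG", "+", [(1, 156), (1157, 1300)])],
        )
        (intron,) = mk.extract_introns(rec)
        assert intron.name == "nad2i156"
        assert intron.interval == (157, 1156)

    def test_minus_strand_sequence_in_gene_orientation(self):
        rng = np.random.default_rng(0)
        seq = _rand(rng, 300)
        rec = GenomeRecord(
            "c", seq,
            features=[GeneFeature("g", "PCG", "-", [(201, 260), (41, 100)])],
        )
        (intron,) = mk.extract_introns(rec)
        assert intron.name == "gi60"
        assert intron.interval == (101, 200)
        assert intron.sequence == revcomp(seq[100:200])

    def test_single_exon_gene_yields_nothing(self):
        rec = GenomeRecord(
            "c", "A" * 100, features=[GeneFeature("atp9", "PCG", "+", [(1, 90)])]
        )
        assert mk.extract_introns(rec) == []

    def test_exon_intron_concatenation_reconstructs_span(self):
        rng = np.random.default_rng(1)
        seq = _rand(rng, 2000)
        feat = GeneFeature("nad5", "PCG", "+", [(11, 200), (301, 500), (901, 1200)])
        rec = GenomeRecord("c", seq, features=[feat])
        introns = mk.extract_introns(rec)
        pieces = sorted(
            [(s, e) for s, e in feat.exons] + [i.interval for i in introns]
        )
        rebuilt = "".join(seq[s - 1 : e] for s, e in pieces)
        assert rebuilt == seq[10:1200]

    def test_intron_containing_gene_count(self):
        feats = [
            GeneFeature("nad1", "PCG", "+", [(1, 10), (21, 30)]),
            GeneFeature("atp9", "PCG", "+", [(41, 60)]),
            GeneFeature("trnA-UGC", "tRNA", "+", [(71, 80), (91, 95)]),
        ]
        rec = GenomeRecord("c", "A" * 100, features=feats)
        assert mk.intron_containing_genes(rec) == ["nad1", "trnA-UGC"]


class TestVariableLoci:
    def _aln(self, **seqs):
        return seqs

    def test_identical_sequences_no_loci(self):
        aln = self._aln(a="ACGT" * 20, b="ACGT" * 20)
        assert mk.find_variable_loci(aln) == []

    def test_planted_deletion_one_locus_two_alleles(self):
        rng = np.random.default_rng(2)
        anc = _rand(rng, 120)
        gapped = anc[:50] + "-" * 14 + anc[64:]
        loci = mk.find_variable_loci({"a": anc, "b": gapped})
        assert len(loci) == 1
        l = loci[0]
        assert l.size == 14 and l.distinct_alleles() == 2
        assert (l.start_col, l.end_col) == (51, 64)

    def test_adjacent_indels_with_clean_gap_are_two_loci(self):
        rng = np.random.default_rng(3)
        anc = _rand(rng, 200)
        s = list(anc)
        s[50:58] = "-" * 8
        s[88:100] = "-" * 12  # 30 conserved columns between
        loci = mk.find_variable_loci({"a": anc, "b": "".join(s)})
        assert [l.size for l in loci] == [8, 12]

    def test_locus_below_min_size_dropped(self):
        rng = np.random.default_rng(4)
        anc = _rand(rng, 120)
        sub = anc[:60] + ("A" if anc[60] != "A" else "C") + anc[61:]
        assert mk.find_variable_loci({"a": anc, "b": sub}, min_size=5) == []
        assert len(mk.find_variable_loci({"a": anc, "b": sub}, min_size=1)) == 1

    def test_dirty_flank_suppresses_locus(self):
        rng = np.random.default_rng(5)
        anc = _rand(rng, 160)
        b = list(anc)
        b[70:78] = "-" * 8
        b[85] = "-"  # a gap inside the right flank
        loci = mk.find_variable_loci({"a": anc, "b": "".join(b)})
        assert all(l.start_col != 71 for l in loci)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            mk.find_variable_loci({"a": "ACGT", "b": "ACG"})


class TestDiscrimination:
    def _matrix(self, table):
        species = sorted(table)
        loci = sorted(next(iter(table.values())))
        return mk.DiscriminationMatrix(species, loci, table)

    def test_single_locus_with_all_distinct_alleles(self):
        table = {s: {"L1": str(i)} for i, s in enumerate("abcde")}
        res = mk.minimal_discriminating_set(self._matrix(table))
        assert res.loci == ["L1"]

    def test_all_identical_reports_all_pairs_unresolved(self):
        table = {s: {"L1": "x", "L2": "x"} for s in "abcde"}
        res = mk.minimal_discriminating_set(self._matrix(table))
        assert res.loci is None and len(res.unresolved_pairs) == 10

    def test_four_critical_loci_require_full_set(self):
        # each locus uniquely separates one species pair
        table = {
            "A": {"L1": "1", "L2": "1", "L3": "1", "L4": "1"},
            "K": {"L1": "2", "L2": "1", "L3": "1", "L4": "1"},
            "R": {"L1": "1", "L2": "2", "L3": "2", "L4": "2"},
            "B": {"L1": "1", "L2": "1", "L3": "2", "L4": "2"},
            "P": {"L1": "1", "L2": "1", "L3": "2", "L4": "1"},
        }
        res = mk.minimal_discriminating_set(self._matrix(table))
        assert res.loci == ["L1", "L2", "L3", "L4"]

    def test_monotonicity_adding_locus_never_hurts(self):
        rng = np.random.default_rng(6)
        table = {
            s: {f"L{j}": str(rng.integers(2)) for j in range(4)} for s in "abcde"
        }
        m = self._matrix(table)
        full = set(m.undistinguished_pairs(["L0", "L1", "L2", "L3"]))
        part = set(m.undistinguished_pairs(["L0", "L1"]))
        assert full <= part

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n_loci = int(rng.integers(2, 7))
        table = {
            s: {f"L{j}": str(rng.integers(3)) for j in range(n_loci)}
            for s in ("a", "b", "c", "d", "e")
        }
        res = mk.minimal_discriminating_set(self._matrix(table))
        want_loci, want_unresolved = brute_minimal_set(table)
        assert res.loci == want_loci
        assert sorted(res.unresolved_pairs) == sorted(want_unresolved)


class TestInsilicoPcr:
    def _template(self, rng, topology="linear"):
        seq = _rand(rng, 800)
        return GenomeRecord("t", seq, topology=topology)

    def test_planted_amplicon_of_constructed_length(self):
        rng = np.random.default_rng(7)
        t = self._template(rng)
        fwd = t.sequence[100:120]
        rev = revcomp(t.sequence[380:400])
        (amp,) = mk.insilico_pcr(t, fwd, rev)
        assert amp.length == 300 and amp.start == 101
        assert amp.sequence == t.sequence[100:400]

    def test_missing_reverse_primer_no_amplicon(self):
        rng = np.random.default_rng(8)
        t = self._template(rng)
        fwd = t.sequence[100:120]
        rev = "ACGT" * 5  # nowhere on the template
        assert mk.insilico_pcr(t, fwd, rev) == []

    def test_rotation_invariance_on_circular_template(self):
        rng = np.random.default_rng(9)
        seq = _rand(rng, 900)
        fwd = seq[700:720]
        rev = revcomp(seq[80:100])  # product wraps the origin
        t1 = GenomeRecord("t", seq, topology="circular")
        t2 = GenomeRecord("t", seq[100:] + seq[:100], topology="circular")
        a1 = mk.insilico_pcr(t1, fwd, rev)
        a2 = mk.insilico_pcr(t2, fwd, rev)
        assert [a.sequence for a in a1] == [a.sequence for a in a2]
        assert a1[0].length == 300

    def test_products_longer_than_cap_suppressed(self):
        rng = np.random.default_rng(10)
        t = self._template(rng)
        fwd = t.sequence[10:30]
        rev = revcomp(t.sequence[700:720])
        assert mk.insilico_pcr(t, fwd, rev, max_product=500) == []

    def test_primer_length_bounds_enforced(self):
        rng = np.random.default_rng(11)
        t = self._template(rng)
        with pytest.raises(ValueError, match="15-35"):
            mk.insilico_pcr(t, "ACGTACGTACGT", t.sequence[30:50])

    def test_species_amplicons_differ_by_planted_indels(self, sim_config):
        from mitoscribe.simulate import make_species_introns

        _aln, truth = make_species_introns(sim_config)
        for region, (fwd, rev) in truth.primers.items():
            sizes = {}
            for sp, seq in truth.species_sequences[region].items():
                amps = mk.insilico_pcr(GenomeRecord(sp, seq), fwd, rev, max_mismatch=2)
                assert len(amps) == 1
                sizes[sp] = amps[0].length
            deleted = {
                sp: sum(
                    d["size"]
                    for d in truth.loci
                    if d["region"] == region and sp in d["gapped_species"]
                )
                for sp in sizes
            }
            base = max(sizes.values())
            assert {sp: base - s for sp, s in sizes.items()} == deleted
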