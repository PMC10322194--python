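"""SSR and dispersed-repeat detection, E-value model, summaries."""

import numpy as np
import pytest

from mitoscribe import repeats as rp
from mitoscribe._util import revcomp
from mitoscribe.model import GenomeRecord, GenomeSet
from oracles import brute_dispersed, brute_ssrs

BASES = np.array(list("ACGT"))


def _rand(rng, n):
    return "".join(rng.choice(BASES, size=n))


def _genome(**recs):
    return GenomeSet([GenomeRecord(k, v) for k, v in recs.items()])


class TestSsrs:
    def test_threshold_boundary_mononucleotide(self):
        pad = "GCGC"
        assert rp.find_ssrs(_genome(r=pad + "A" * 9 + pad)) == []
        hits = rp.find_ssrs(_genome(r=pad + "A" * 10 + pad))
        assert len(hits) == 1
        h = hits[0]
        assert (h.motif, h.repeat_count, h.start, h.end) == ("A", 10, 5, 14)

    def test_primitivity_dimer_not_reported_as_monomers(self):
        hits = rp.find_ssrs(_genome(r="GC" + "AT" * 5 + "GC"))
        assert len(hits) == 1
        assert hits[0].motif_length == 2 and hits[0].repeat_count == 5

    def test_run_with_n_is_split(self):
        hits = rp.find_ssrs(_genome(r="G" + "A" * 6 + "N" + "A" * 6 + "G"))
        assert hits == []  # neither half reaches the threshold of 10

    def test_interval_arithmetic_invariant(self):
        rng = np.random.default_rng(0)
        seq = _rand(rng, 400) + "AGAT" * 6 + _rand(rng, 50)
        for h in rp.find_ssrs(_genome(r=seq)):
            assert h.end - h.start + 1 == h.motif_length * h.repeat_count

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            recs = {"r": _rand(rng, int(rng.integers(60, 250)))}
            if rng.random() < 0.5:  # ensure positives occur
                motif = ["T", "CT", "AGA", "AGAT"][int(rng.integers(4))]
                recs["r"] += motif * 12 + _rand(rng, 20)
            got = {
                (h.record_id, h.start, h.end, h.motif_length, h.repeat_count)
                for h in rp.find_ssrs(_genome(**recs))
            }
            assert got == brute_ssrs(recs)


class TestEvalue:
    def test_exact_30mer_formula_value(self):
        # E = N^2 * 4^-30 for the study-scale search space
        e = rp.evalue(30, 0, 537_044)
        assert e == pytest.approx(537_044**2 / 4.0**30, rel=1e-9)
        assert e < 1e-5 and e == pytest.approx(2.5e-7, rel=0.1)

    def test_monotone_in_mismatches_and_length(self):
        n = 537_044
        assert rp.evalue(30, 3, n) > rp.evalue(30, 1, n) > rp.evalue(30, 0, n)
        assert rp.evalue(60, 3, n) < rp.evalue(30, 3, n)

    def test_long_lengths_underflow_to_zero(self):
        assert rp.evalue(5000, 3, 537_044) == 0.0


class TestDispersed:
    def test_planted_exact_forward_pair(self):
        rng = np.random.default_rng(1)
        block = _rand(rng, 30)
        seq = _rand(rng, 120) + block + _rand(rng, 80) + block + _rand(rng, 60)
        pairs = rp.find_dispersed(_genome(r=seq))
        assert len(pairs) == 1
        p = pairs[0]
        assert p.cls == "forward" and p.mismatches == 0
        # the reported exact pair covers the planted copies (chance flank
        # matches may extend it by a base or two)
        assert p.start1 <= 121 and p.end1 >= 150
        assert p.start2 <= 231 and p.end2 >= 260
        assert p.start2 - p.start1 == 110

    def test_planted_palindromic_pair(self):
        rng = np.random.default_rng(2)
        block = _rand(rng, 40)
        seq = _rand(rng, 100) + block + _rand(rng, 90) + revcomp(block) + _rand(rng, 50)
        pairs = rp.find_dispersed(_genome(r=seq))
        assert [p.cls for p in pairs] == ["palindromic"]
        assert pairs[0].length >= 40

    def test_no_pair_spans_the_spacer_and_coordinates_in_record(self):
        rng = np.random.default_rng(3)
        block = _rand(rng, 35)
        g = _genome(
            a=_rand(rng, 60) + block + _rand(rng, 30),
            b=_rand(rng, 40) + block + _rand(rng, 55),
        )
        pairs = rp.find_dispersed(g)
        assert len(pairs) == 1
        for p in pairs:
            for rid, s, e in ((p.rec1, p.start1, p.end1), (p.rec2, p.start2, p.end2)):
                assert 1 <= s <= e <= len(g[rid])

    def test_concatenation_order_does_not_change_results(self):
        rng = np.random.default_rng(4)
        block = _rand(rng, 32)
        recs = {
            "a": _rand(rng, 70) + block + _rand(rng, 40),
            "b": _rand(rng, 90),
            "c": _rand(rng, 50) + block + _rand(rng, 30),
        }
        fwd = rp.find_dispersed(GenomeSet([GenomeRecord(k, recs[k]) for k in "abc"]))
        rev = rp.find_dispersed(GenomeSet([GenomeRecord(k, recs[k]) for k in "cba"]))
        as_set = lambda ps: {
            (p.cls, p.rec1, p.start1, p.end1, p.rec2, p.start2, p.end2, p.mismatches)
            for p in ps
        }
        assert as_set(fwd) == as_set(rev)

    def test_strand_symmetry_forward_and_palindromic_counts(self):
        rng = np.random.default_rng(5)
        b1, b2 = _rand(rng, 33), _rand(rng, 44)
        recs = {
            "a": _rand(rng, 50) + b1 + _rand(rng, 40) + b1 + _rand(rng, 30)
            + b2 + _rand(rng, 35) + revcomp(b2) + _rand(rng, 25),
        }
        counts = lambda g: {
            c: sum(1 for p in rp.find_dispersed(g) if p.cls == c)
            for c in ("forward", "palindromic")
        }
        before = counts(_genome(**recs))
        after = counts(_genome(a=revcomp(recs["a"])))
        assert before == after and before["forward"] >= 1 and before["palindromic"] >= 1

    def test_ssr_shadow_pairs_excluded(self):
        rng = np.random.default_rng(6)
        # a long mononucleotide SSR would otherwise shadow forward self-pairs
        seq = _rand(rng, 100) + "A" * 40 + _rand(rng, 100)
        pairs = rp.find_dispersed(_genome(r=seq))
        assert pairs == []

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        comp = str.maketrans("ACGT", "TGCA")
        for trial in range(15):
            recs = {"r1": _rand(rng, int(rng.integers(50, 140)))}
            if rng.random() < 0.5:
                recs["r2"] = _rand(rng, int(rng.integers(40, 90)))
            if rng.random() < 0.7:
                L = int(rng.integers(30, 55))
                mm = int(rng.integers(0, 4))
                cls = ["forward", "reverse", "complement", "palindromic"][
                    int(rng.integers(4))
                ]
                block = _rand(rng, L)
                b2 = list(block)
                for p in rng.choice(range(2, L - 2), size=mm, replace=False):
                    b2[p] = [c for c in "ACGT" if c != b2[p]][int(rng.integers(3))]
                b2 = "".join(b2)
                if cls == "reverse":
                    b2 = b2[::-1]
                elif cls == "complement":
                    b2 = b2.translate(comp)
                elif cls == "palindromic":
                    b2 = b2.translate(comp)[::-1]
                keys = list(recs)
                recs[keys[0]] += block + _rand(rng, 5)
                recs[keys[-1]] += b2 + _rand(rng, 5)
            got = {
                (p.cls, p.rec1, p.start1, p.end1, p.rec2, p.start2, p.end2,
                 p.length, p.mismatches)
                for p in rp.find_dispersed(_genome(**recs))
            }
            assert got == brute_dispersed(recs), f"trial {trial}"


class TestSummary:
    def test_empty_inputs_all_zero(self):
        g = _genome(r="ACGT" * 30)
        s = rp.summarize_repeats([], [], g)
        assert s["ssr_total"] == 0 and s["dispersed_pairs"] == 0
        assert s["dispersed_union_length"] == 0 and s["dispersed_longest"] == 0

    def test_overlapping_intervals_union_semantics(self):
        g = _genome(r="A" * 100)
        pairs = [
            rp.RepeatPair("forward", "r", 1, 40, "r", 21, 60, 40, 0, 1e-9),
        ]
        s = rp.summarize_repeats([], pairs, g)
        assert s["dispersed_union_length"] == 60  # not 80

    def test_class_and_length_tallies(self, organelles):
        mito, _plastome, truth = organelles
        ssrs = rp.find_ssrs(mito)
        pairs = rp.find_dispersed(mito)
        s = rp.summarize_repeats(ssrs, pairs, mito)
        assert s["ssr_total"] == len(truth.ssrs)
        by_class = {c: 0 for c in rp.REPEAT_CLASSES}
        for d in truth.dispersed:
            by_class[d.cls] += 1
        assert s["dispersed_by_class"] == by_class
        assert 0 < s["dispersed_fraction"] < 0.1
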