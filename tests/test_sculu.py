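"""Score matrices, annotation confidence, separability and merging."""

import numpy as np
import pytest

from conftest import make_instances, mutate_positions
from subfamnet.io_formats import ConsensusRecord
from subfamnet.sculu import (SculuParams, annotation_confidence,
                             confidence_matrix, merge_until_stable,
                             pair_separability, score_instances)

RNG = np.random.default_rng(202)
BASE = "".join(RNG.choice(list("ACGT"), 300))
BASE = BASE[:130] + "A" * 20 + BASE[150:]


def _cons(name, seq):
    return ConsensusRecord(name, seq)


class TestScores:
    def test_perfect_instance_scores_unmasked_length_in_bits(self):
        """300-nt instance, 20-column mask -> own score 280 bits."""
        scores, membership = score_instances(
            {"sf": {"i0": BASE}}, [_cons("sf", BASE)], SculuParams())
        assert scores.loc["i0", "sf"] == pytest.approx(280.0)
        assert membership == {"i0": "sf"}

    def test_identical_consensi_score_equally(self):
        scores, _ = score_instances(
            {"a": {"i0": BASE}, "b": {"i0b": BASE}},
            [_cons("a", BASE), _cons("b", BASE)], SculuParams())
        assert scores.loc["i0", "a"] == scores.loc["i0", "b"]

    def test_own_score_dominates_for_zero_divergence_instances(self):
        far = mutate_positions(BASE, list(range(0, 120, 4)))
        insts = {"a": {f"a{k}": BASE for k in range(3)},
                 "b": {f"b{k}": far for k in range(3)}}
        scores, membership = score_instances(
            insts, [_cons("a", BASE), _cons("b", far)], SculuParams())
        for iid, own in membership.items():
            row = scores.loc[iid]
            assert row[own] == row.max()

    def test_missing_instances_error(self):
        with pytest.raises(ValueError, match="no instances"):
            score_instances({"a": {}}, [_cons("a", BASE)], SculuParams())

    def test_sampling_cap_is_deterministic(self):
        insts = {"a": {f"i{k:03d}": BASE for k in range(50)}}
        p = SculuParams(instance_cap=10, seed=4)
        s1, m1 = score_instances(insts, [_cons("a", BASE)], p)
        s2, m2 = score_instances(insts, [_cons("a", BASE)], p)
        assert list(s1.index) == list(s2.index) and len(s1) == 10


class TestConfidence:
    def test_single_subfamily_confidence_one(self):
        assert annotation_confidence(np.array([123.0])) == pytest.approx([1.0])

    def test_two_equal_scores_split_half_half(self):
        np.testing.assert_allclose(
            annotation_confidence(np.array([7.0, 7.0])), [0.5, 0.5])

    def test_ten_bit_gap_matches_closed_form(self):
        conf = annotation_confidence(np.array([110.0, 100.0]))
        expect = np.array([2 ** 10 / (1 + 2 ** 10), 1 / (1 + 2 ** 10)])
        np.testing.assert_allclose(conf, expect, atol=1e-12)

    def test_rows_sum_to_one_within_1e9_even_for_extreme_scores(self):
        rng = np.random.default_rng(31)
        mat = rng.normal(0, 500, size=(40, 6))
        import pandas as pd
        conf = confidence_matrix(pd.DataFrame(mat))
        np.testing.assert_allclose(conf.sum(axis=1), 1.0, atol=1e-9)


class TestSeparability:
    def _conf(self, consensi, insts, params=None):
        params = params or SculuParams()
        scores, membership = score_instances(insts, consensi, params)
        return confidence_matrix(scores), membership

    def test_identical_consensi_non_separable(self):
        conf, memb = self._conf(
            [_cons("a", BASE), _cons("b", BASE)],
            {"a": {"ia": BASE}, "b": {"ib": BASE}})
        assert not pair_separability("a", "b", conf, memb)

    def test_tau_one_makes_all_pairs_separable(self):
        conf, memb = self._conf(
            [_cons("a", BASE), _cons("b", BASE)],
            {"a": {"ia": BASE}, "b": {"ib": BASE}})
        assert pair_separability("a", "b", conf, memb, tau=1.0)

    def test_thirty_substitutions_apart_separable_at_defaults(self):
        rng = np.random.default_rng(41)
        far = mutate_positions(BASE, [int(p) for p in
                                      rng.choice(120, 30, replace=False)], rng)
        insts = {"a": make_instances(BASE, 50, 0.02, rng, "a"),
                 "b": make_instances(far, 50, 0.02, rng, "b")}
        conf, memb = self._conf([_cons("a", BASE), _cons("b", far)], insts)
        assert pair_separability("a", "b", conf, memb)


class TestMerge:
    def test_duplicate_subfamilies_merge_distant_survives(self):
        rng = np.random.default_rng(51)
        far = mutate_positions(BASE, [int(p) for p in
                                      rng.choice(120, 40, replace=False)], rng)
        consensi = [_cons("dup1", BASE), _cons("dup2", BASE), _cons("far", far)]
        insts = {"dup1": make_instances(BASE, 15, 0.01, rng, "d1"),
                 "dup2": make_instances(BASE, 15, 0.01, rng, "d2"),
                 "far": make_instances(far, 15, 0.01, rng, "f")}
        plan = merge_until_stable(consensi, insts, SculuParams())
        assert plan.groups == [["far"], ["dup1", "dup2"]]
        assert plan.name_map == {"dup1": "merged_1", "dup2": "merged_1",
                                 "far": "far"}

    def test_transitive_union_chains_merge_into_one_group(self):
        """A~B and B~C non-separable -> single {A, B, C} group."""
        a = mutate_positions(BASE, [10])
        c = mutate_positions(BASE, [60])
        consensi = [_cons("A", a), _cons("B", BASE), _cons("C", c)]
        insts = {n: {f"{n}{k}": s for k in range(12)}
                 for n, s in [("A", a), ("B", BASE), ("C", c)]}
        plan = merge_until_stable(consensi, insts, SculuParams())
        assert plan.groups == [["A", "B", "C"]]

    def test_merge_output_is_idempotent(self):
        rng = np.random.default_rng(61)
        far = mutate_positions(BASE, [int(p) for p in
                                      rng.choice(120, 40, replace=False)], rng)
        consensi = [_cons("dup1", BASE), _cons("dup2", BASE), _cons("far", far)]
        insts = {"dup1": make_instances(BASE, 12, 0.01, rng, "d1"),
                 "dup2": make_instances(BASE, 12, 0.01, rng, "d2"),
                 "far": make_instances(far, 12, 0.01, rng, "f")}
        plan = merge_until_stable(consensi, insts, SculuParams())
        pooled = {}
        for group in plan.groups:
            name = plan.name_map[group[0]]
            pooled[name] = {}
            for member in group:
                pooled[name] |= insts[member]
        plan2 = merge_until_stable(plan.merged_consensi, pooled, SculuParams())
        assert all(len(g) == 1 for g in plan2.groups)

    def test_merged_naming_by_size_then_lexicographic(self):
        a1 = mutate_positions(BASE, [10])
        far = mutate_positions(BASE, list(range(0, 160, 4)))
        far2 = mutate_positions(far, [1])
        far3 = mutate_positions(far, [5])
        consensi = [_cons("p", BASE), _cons("q", a1),
                    _cons("x", far), _cons("y", far2), _cons("z", far3)]
        insts = {n: {f"{n}{k}": dict(p=BASE, q=a1, x=far, y=far2, z=far3)[n]
                     for k in range(11)} for n in "pqxyz"}
        plan = merge_until_stable(consensi, insts, SculuParams())
        # two merged groups: {p,q} (size 2) -> merged_1, {x,y,z} -> merged_2
        assert plan.name_map["p"] == "merged_1"
        assert plan.name_map["x"] == "merged_2"
        assert sorted(len(g) for g in plan.groups) == [2, 3]
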