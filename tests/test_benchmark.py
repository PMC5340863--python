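"""Simulator, ground-truth metrics, stability, UniFrac, UPGMA and Newick I/O."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from _oracles import branch_set_unifrac
from subotu.benchmark import (
    SimParams,
    TruthCommunity,
    hamming_upgma,
    make_truth_community,
    read_newick,
    score_against_truth,
    simulate_reads,
    stability_overlap,
    unweighted_unifrac,
    write_newick,
)
from subotu.denoise import DenoiseResult
from subotu.table import FeatureTable, build_table


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestMakeTruthCommunity:
    def test_single_member(self):
        t = make_truth_community(1, 50, 5, seed=0)
        assert len(t) == 1
        assert t.rel_abundances[0] == pytest.approx(1.0)

    def test_pairwise_distance_floor_holds_exhaustively(self):
        t = make_truth_community(20, 150, 10, seed=3)
        dists = [
            hamming(a, b)
            for i, a in enumerate(t.sequences)
            for b in t.sequences[i + 1 :]
        ]
        assert len(dists) == 190
        assert min(dists) >= 10

    def test_distances_concentrate_near_the_radius(self):
        t = make_truth_community(20, 150, 10, seed=3)
        dists = [
            hamming(a, b)
            for i, a in enumerate(t.sequences)
            for b in t.sequences[i + 1 :]
        ]
        # a similarity radius, not a vacuous floor: members are genuinely close
        assert min(dists) <= 14
        assert max(dists) <= 45

    def test_same_seed_reproduces_community(self):
        a = make_truth_community(10, 80, 6, "lognormal", seed=9)
        b = make_truth_community(10, 80, 6, "lognormal", seed=9)
        assert a.sequences == b.sequences
        assert np.array_equal(a.rel_abundances, b.rel_abundances)

    def test_lognormal_respects_min_abundance_floor(self):
        t = make_truth_community(20, 100, 8, "lognormal", seed=4)
        assert t.rel_abundances.min() >= 0.005

    def test_infeasible_constraint_errors(self):
        with pytest.raises(ValueError):
            make_truth_community(5, 10, 50, seed=0)

    def test_abundances_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TruthCommunity(sequences=["AAAA", "CCCC"], rel_abundances=np.array([0.5, 0.4]))


class TestSimulateReads:
    def test_no_error_limit_reproduces_sources(self):
        t = make_truth_community(5, 60, 8, seed=1)
        s = simulate_reads(t, SimParams(n_reads=200, sub_rate=0, ins_rate=0, del_rate=0, seed=1))
        assert set(s.reads) <= set(t.sequences)
        assert len(s.reads) == 200

    def test_single_sequence_truth(self):
        t = TruthCommunity(sequences=["ACGTACGT"], rel_abundances=np.array([1.0]))
        s = simulate_reads(t, SimParams(n_reads=50, sub_rate=0, ins_rate=0, del_rate=0, seed=2))
        assert set(s.reads) == {"ACGTACGT"}

    def test_error_free_fraction_matches_closed_form(self):
        t = make_truth_community(10, 150, 10, seed=5)
        n = 10000
        s = simulate_reads(t, SimParams(n_reads=n, sub_rate=0.001, ins_rate=0, del_rate=0, seed=5))
        truth_set = set(t.sequences)
        frac = sum(r in truth_set for r in s.reads) / n
        p = 0.999**150
        sigma = (p * (1 - p) / n) ** 0.5
        assert abs(frac - p) < 3 * sigma

    def test_deterministic_given_seed(self):
        t = make_truth_community(5, 40, 5, seed=3)
        a = simulate_reads(t, SimParams(n_reads=100, seed=8))
        b = simulate_reads(t, SimParams(n_reads=100, seed=8))
        assert a.reads == b.reads

    def test_indels_shift_read_length(self):
        t = make_truth_community(2, 100, 10, seed=1)
        s = simulate_reads(
            t, SimParams(n_reads=2000, sub_rate=0, ins_rate=0.002, del_rate=0.002, seed=4)
        )
        lengths = {len(r) for r in s.reads}
        assert lengths != {100}


class TestScoreAgainstTruth:
    def truth(self):
        return TruthCommunity(
            sequences=["AAAA", "CCCC", "GGGG"],
            rel_abundances=np.array([0.5, 0.3, 0.2]),
        )

    def test_perfect_recovery(self):
        res = DenoiseResult(retained=[("AAAA", 50), ("CCCC", 30), ("GGGG", 20)])
        m = score_against_truth(res, self.truth())
        assert (m.recall, m.precision, m.observed_ratio) == (1.0, 1.0, 1.0)

    def test_one_spurious_feature(self):
        res = DenoiseResult(
            retained=[("AAAA", 50), ("CCCC", 30), ("GGGG", 20), ("TTTT", 5)]
        )
        m = score_against_truth(res, self.truth())
        assert m.recall == 1.0
        assert m.precision == pytest.approx(3 / 4)
        assert m.observed_ratio == pytest.approx(4 / 3)

    def test_empty_output_flagged(self):
        m = score_against_truth(DenoiseResult(retained=[]), self.truth())
        assert m.empty_output
        assert (m.recall, m.precision) == (0.0, 0.0)

    def test_truth_compared_at_retained_length(self):
        truth = TruthCommunity(
            sequences=["AAAATT", "CCCCGG"], rel_abundances=np.array([0.5, 0.5])
        )
        res = DenoiseResult(retained=[("AAAA", 10), ("CCCC", 10)])
        m = score_against_truth(res, truth)
        assert m.recall == 1.0 and m.precision == 1.0


class TestStabilityOverlap:
    def single(self, feats):
        return build_table({"s": DenoiseResult(retained=list(feats.items()))})

    def test_identical_tables_overlap_fully(self):
        t = self.single({"AAAA": 100, "CCCC": 5})
        curve = stability_overlap(t, t, [1, 10, 100])
        assert (curve["overlap_1_in_2"] == 1.0).all()

    def test_disjoint_tables_overlap_zero(self):
        a = self.single({"AAAA": 100})
        b = self.single({"CCCC": 100})
        curve = stability_overlap(a, b, [1, 10])
        assert (curve["overlap_1_in_2"] == 0.0).all()

    def test_threshold_excludes_low_count_misses(self):
        a = self.single({"AAAA": 100, "CCCC": 5})
        b = self.single({"AAAA": 80})
        curve = stability_overlap(a, b, [1, 10])
        assert curve["overlap_1_in_2"].tolist() == [0.5, 1.0]


class TestUnweightedUnifrac:
    def table(self, presence):
        features = sorted({f for row in presence.values() for f in row})
        counts = np.array(
            [[row.get(f, 0) for f in features] for row in presence.values()]
        )
        return FeatureTable(
            sample_ids=list(presence), feature_ids=features, counts=counts
        )

    def tree(self):
        return TreeNode.read(io.StringIO("((a:1,b:1):1,(c:1,d:1):1);"))

    def test_identical_presence_gives_zero(self):
        t = self.table({"s1": {"a": 3, "b": 1}, "s2": {"a": 1, "b": 9}})
        dm = unweighted_unifrac(t, self.tree())
        assert dm["s1", "s2"] == pytest.approx(0.0)

    def test_fully_disjoint_clades_give_one(self):
        t = self.table({"s1": {"a": 1, "b": 1}, "s2": {"c": 1, "d": 1}})
        dm = unweighted_unifrac(t, self.tree())
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_partial_overlap_hand_value(self):
        t = self.table({"s1": {"a": 1, "b": 1}, "s2": {"a": 1, "c": 1}})
        dm = unweighted_unifrac(t, self.tree())
        assert dm["s1", "s2"] == pytest.approx(0.6)

    def test_missing_leaf_names_feature(self):
        t = self.table({"s1": {"zz": 1}})
        with pytest.raises(ValueError, match="zz"):
            unweighted_unifrac(t, self.tree())

    def test_matches_branch_set_oracle_on_random_instances(self, rng, random_seq):
        for _ in range(25):
            n_leaves = int(rng.integers(4, 12))
            seqs = list({random_seq(rng, 25) for _ in range(n_leaves)})
            if len(seqs) < 3:
                continue
            tree = hamming_upgma(seqs)
            presence = {}
            for sid in ("s1", "s2", "s3"):
                mask = rng.random(len(seqs)) < 0.6
                if not mask.any():
                    mask[0] = True
                presence[sid] = {s: 1 for s, m in zip(seqs, mask) if m}
            t = self.table(presence)
            dm = unweighted_unifrac(t, tree)
            for x, y in (("s1", "s2"), ("s1", "s3"), ("s2", "s3")):
                expected = branch_set_unifrac(
                    tree, set(presence[x]), set(presence[y])
                )
                assert dm[x, y] == pytest.approx(expected, abs=1e-12)
            # metric sanity: symmetry, zero diagonal, triangle inequality
            m = dm.data
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0)
            assert m[0, 2] <= m[0, 1] + m[1, 2] + 1e-12


class TestHammingUpgma:
    def test_three_taxon_topology_and_heights(self):
        # d(A,B)=2, d(A,C)=d(B,C)=4 -> ((A,B),C), AB node at height 1
        a, b, c = "AACC", "AATT", "GGGG"
        assert hamming(a, b) == 2 and hamming(a, c) == 4 and hamming(b, c) == 4
        tree = hamming_upgma([a, b, c])
        tips = {t.name for t in tree.tips()}
        assert tips == {a, b, c}
        ab = tree.lca([a, b])
        assert {t.name for t in ab.tips()} == {a, b}
        assert ab.children[0].length == pytest.approx(1.0)

    def test_two_sequences_form_cherry_at_half_distance(self):
        tree = hamming_upgma(["AAAA", "AATT"])
        for tip in tree.tips():
            assert tip.length == pytest.approx(1.0)

    def test_equidistant_triple_merges_deterministically(self):
        seqs = ["AAAA", "CCCC", "GGGG"]
        t1 = str(hamming_upgma(seqs))
        t2 = str(hamming_upgma(list(reversed(seqs))))
        assert t1 == t2
        first_pair = hamming_upgma(seqs).lca(["AAAA", "CCCC"])
        assert {t.name for t in first_pair.tips()} == {"AAAA", "CCCC"}

    def test_ultrametric_tip_depths(self, rng, random_seq):
        seqs = list({random_seq(rng, 30) for _ in range(8)})
        tree = hamming_upgma(seqs)
        depths = {
            tip.name: tip.accumulate_to_ancestor(tree) for tip in tree.tips()
        }
        vals = list(depths.values())
        assert max(vals) - min(vals) < 1e-9


class TestNewickIO:
    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((a:1.0,b:1.0):1.0,c:2.0);\n")
        tree = read_newick(p)
        out = tmp_path / "o.nwk"
        write_newick(tree, out)
        tree2 = read_newick(out)
        assert {t.name for t in tree.tips()} == {t.name for t in tree2.tips()}
        for name in "abc":
            n1 = tree.find(name)
            n2 = tree2.find(name)
            assert abs(n1.length - n2.length) < 1e-10

    def test_unlabeled_internal_nodes_accepted(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((a:1,b:2):0.5,(c:1,d:1):0.5);")
        tree = read_newick(p)
        assert len(list(tree.tips())) == 4

    def test_mismatched_parenthesis_reports_offset(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a:1,b:1):1;")
        with pytest.raises(ValueError, match="offset"):
            read_newick(p)
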