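"""Fixed-tree scoring: lifted / direct-optimization / exact solvers."""

import random

import pytest

from _oracles import random_nested_topology, random_seq, sankoff_parsimony_score
from treelen.cost_model import preset
from treelen.formats import SequenceSet, tree_from_newick_like
from treelen.pairwise import edit_distance
from treelen.treelength import (
    do_assignment,
    exact_assignment,
    lifted_assignment,
    score_fixed_tree,
)


def random_instance(rng, n_min=3, n_max=5, len_min=1, len_max=4, alphabet="ACGT"):
    n = rng.randint(n_min, n_max)
    labels = [chr(97 + i) for i in range(n)]
    tree = tree_from_newick_like(None, random_nested_topology(labels, rng))
    seqs = SequenceSet([(l, random_seq(rng, len_min, len_max, alphabet)) for l in labels])
    return tree, seqs


class TestScoreFixedTree:
    def test_two_leaf_tree_is_edit_distance(self, any_scheme):
        tree = tree_from_newick_like(None, ("a", "b"))
        seqs = SequenceSet([("a", "ACCT"), ("b", "ACGT")])
        asn = score_fixed_tree(tree, seqs, any_scheme)
        assert asn.treelength == edit_distance("ACCT", "ACGT", any_scheme)

    def test_identical_leaves_score_zero(self, any_scheme):
        tree = tree_from_newick_like(None, (("a", "b"), "c", "d"))
        seqs = SequenceSet([(l, "ACGT") for l in "abcd"])
        for method in ("lifted", "do"):
            asn = score_fixed_tree(tree, seqs, any_scheme, method=method)
            assert asn.treelength == 0
            assert all(s == "ACGT" for s in asn.node_sequences.values())

    def test_label_mismatch_rejected(self, simple1):
        tree = tree_from_newick_like(None, ("a", "b", "c"))
        seqs = SequenceSet([("a", "A"), ("b", "A"), ("x", "A")])
        with pytest.raises(ValueError, match="mismatch"):
            score_fixed_tree(tree, seqs, simple1)

    def test_exact_limits_enforced(self, simple1):
        tree = tree_from_newick_like(None, ("a", "b", "c"))
        seqs = SequenceSet([("a", "ACGTA"), ("b", "A"), ("c", "A")])
        with pytest.raises(ValueError, match="length"):
            score_fixed_tree(tree, seqs, simple1, method="exact", max_len=4)

    def test_polytomies_scored_as_is(self, simple1):
        star = tree_from_newick_like(None, ("a", "b", "c", "d"))
        seqs = SequenceSet([("a", "A"), ("b", "A"), ("c", "A"), ("d", "G")])
        asn = score_fixed_tree(star, seqs, simple1)
        assert len(star.internal_nodes()) == 1
        assert asn.treelength == 1


class TestLifted:
    def test_internal_sequences_come_from_leaves(self, pyrng, affine):
        for _ in range(10):
            tree, seqs = random_instance(pyrng, n_max=6, len_max=6)
            asn = lifted_assignment(tree, seqs, affine)
            leaf_seqs = {s for _, s in seqs}
            assert all(s in leaf_seqs for s in asn.node_sequences.values())
            assert asn.recompute_treelength() == asn.treelength

    def test_three_leaf_star_picks_best_median_leaf(self, simple1):
        tree = tree_from_newick_like(None, ("a", "b", "c"))
        seqs = SequenceSet([("a", "AAAA"), ("b", "AAAT"), ("c", "GGGG")])
        asn = lifted_assignment(tree, seqs, simple1)
        # enumerate the three candidates by hand
        best = min(
            "AAAA AAAT GGGG".split(),
            key=lambda s: sum(edit_distance(s, t, simple1) for t in ("AAAA", "AAAT", "GGGG")),
        )
        center = [u for u in tree.internal_nodes()][0]
        assert asn.node_sequences[center] == best
        assert asn.treelength == sum(
            edit_distance(best, t, simple1) for t in ("AAAA", "AAAT", "GGGG")
        )


class TestDo:
    def test_cherry_of_identical_sequences(self, affine):
        tree = tree_from_newick_like(None, (("a", "b"), "c"))
        seqs = SequenceSet([("a", "ACGT"), ("b", "ACGT"), ("c", "TTTT")])
        asn = do_assignment(tree, seqs, affine)
        assert "ACGT" in [asn.node_sequences[u] for u in tree.internal_nodes()]

    def test_do_tracks_lifted_on_simulated_instances(self, simple1):
        """Paired DO-vs-lifted comparison harness on simulated data.

        DO is not provably dominant, so this reports the paired ratios and
        asserts only aggregate behavior: DO wins or ties in a clear majority
        of instances and the median ratio stays within 10% of lifted.
        """
        import statistics

        import numpy as np

        from treelen.simulator import SimParams, evolve
        from treelen.tree_moves import random_binary_tree

        rng = np.random.default_rng(7)
        ratios, wins = [], 0
        for _ in range(100):
            n = int(rng.integers(4, 7))
            t = random_binary_tree([chr(97 + j) for j in range(n)], int(rng.integers(1 << 30)))
            for u, v in t.edges():
                t.set_edge_length(u, v, float(rng.uniform(0.02, 0.2)))
            rec = evolve(t, SimParams(root_length=30, substitution_rate=0.3,
                                      indel_rate=0.02, seed=int(rng.integers(1 << 30))))
            do = do_assignment(t, rec.leaf_seqs, simple1)
            li = lifted_assignment(t, rec.leaf_seqs, simple1)
            assert do.recompute_treelength() == do.treelength
            if li.treelength == 0:
                continue
            ratios.append(float(do.treelength) / float(li.treelength))
            if do.treelength <= li.treelength:
                wins += 1
        assert wins > len(ratios) / 2
        assert statistics.median(ratios) <= 1.10


class TestExact:
    def test_two_leaves_equals_edit_distance(self, affine):
        tree = tree_from_newick_like(None, ("a", "b"))
        seqs = SequenceSet([("a", "ACG"), ("b", "AG")])
        asn = exact_assignment(tree, seqs, affine)
        assert asn.treelength == edit_distance("ACG", "AG", affine)

    def test_three_leaf_star_forced_center(self, simple1):
        tree = tree_from_newick_like(None, ("a", "b", "c"))
        seqs = SequenceSet([("a", "A"), ("b", "A"), ("c", "G")])
        asn = exact_assignment(tree, seqs, simple1, max_len=1)
        assert asn.treelength == 1
        center = tree.internal_nodes()[0]
        assert asn.node_sequences[center] == "A"

    def test_heuristics_never_beat_exact(self, simple1):
        rng = random.Random(11)
        for _ in range(50):
            tree, seqs = random_instance(rng, len_max=3, alphabet="AC")
            ex = exact_assignment(tree, seqs, simple1, max_len=3, alphabet="AC")
            li = lifted_assignment(tree, seqs, simple1)
            do = do_assignment(tree, seqs, simple1)
            assert ex.treelength <= li.treelength
            assert ex.treelength <= do.treelength

    def test_mp_limit_matches_per_site_sankoff(self, mp):
        """With gaps forbidden, treelength is the parsimony score (per-site Sankoff)."""
        rng = random.Random(13)
        for _ in range(10):
            n = rng.randint(3, 5)
            labels = [chr(97 + i) for i in range(n)]
            tree = tree_from_newick_like(None, random_nested_topology(labels, rng))
            L = rng.randint(1, 3)
            seqs = SequenceSet([(l, random_seq(rng, L, L)) for l in labels])
            ex = exact_assignment(tree, seqs, mp, max_len=3)
            leaf_seq = {u: seqs[tree.label(u)] for u in tree.leaves()}
            oracle = sankoff_parsimony_score(tree, leaf_seq, mp.substitution_cost)
            assert ex.treelength == oracle

    def test_lifted_within_twice_exact_under_metric_costs(self, simple1):
        rng = random.Random(17)
        for _ in range(30):
            tree, seqs = random_instance(rng, len_max=3, alphabet="AG")
            ex = exact_assignment(tree, seqs, simple1, max_len=3, alphabet="AG")
            li = lifted_assignment(tree, seqs, simple1)
            assert li.treelength <= 2 * ex.treelength
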