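"""Sequence-evolution simulator: homology bookkeeping, events, statistics."""

import statistics

import numpy as np
import pytest

from treelen.cost_model import preset
from treelen.formats import GAP
from treelen.metrics import bipartitions
from treelen.pairwise import edit_distance, score_alignment
from treelen.simulator import (
    GAP_PRESETS,
    GeometricGaps,
    MixtureGaps,
    SimParams,
    contract_zero_event_branches,
    empirical_stats,
    evolve,
)
from treelen.formats import AlignmentMatrix
from treelen.tree_moves import random_binary_tree


def model_tree(n=8, seed=0, lo=0.05, hi=0.3):
    t = random_binary_tree([f"t{i:02d}" for i in range(n)], seed)
    rng = np.random.default_rng(seed + 1)
    for u, v in t.edges():
        t.set_edge_length(u, v, float(rng.uniform(lo, hi)))
    return t


class TestEvolve:
    def test_rows_degap_to_leaf_sequences(self):
        rec = evolve(model_tree(), SimParams(root_length=120, seed=1))
        for taxon, row in zip(rec.true_alignment.taxa, rec.true_alignment.rows):
            assert row.replace(GAP, "") == rec.leaf_seqs[taxon]

    def test_no_indels_means_gapless_equal_length(self):
        rec = evolve(model_tree(), SimParams(root_length=100, indel_rate=0.0, seed=2))
        assert all(GAP not in row for row in rec.true_alignment.rows)
        assert len({len(s) for _, s in rec.leaf_seqs}) == 1

    def test_zero_branch_lengths_star_reference(self):
        t = model_tree(seed=3, lo=0.0, hi=0.0)
        for u, v in t.edges():
            t.set_edge_length(u, v, 0.0)
        rec = evolve(t, SimParams(root_length=50, seed=3))
        assert len(set(rec.true_alignment.rows)) == 1
        assert len(rec.reference_tree.internal_edges()) == 0
        assert empirical_stats(rec)["resolution"] == 0.0

    def test_no_substitutions_means_identical_aligned_columns(self):
        rec = evolve(model_tree(seed=4),
                     SimParams(root_length=100, substitution_rate=0.0, indel_rate=0.1, seed=4))
        aln = rec.true_alignment
        for j in range(aln.n_cols):
            bases = {r[j] for r in aln.rows} - {GAP}
            assert len(bases) == 1
        assert empirical_stats(rec)["gap_pct"] > 0

    def test_negative_branch_length_rejected(self):
        t = model_tree(seed=5)
        u, v = t.edges()[0]
        t.set_edge_length(u, v, -0.1)
        with pytest.raises(ValueError):
            evolve(t, SimParams(seed=5))

    def test_reference_bipartitions_subset_of_model(self):
        for seed in range(10):
            t = model_tree(seed=seed, lo=0.0, hi=0.15)
            rec = evolve(t, SimParams(root_length=60, seed=seed))
            assert bipartitions(rec.reference_tree).splits <= bipartitions(t).splits

    def test_indel_event_count_matches_draws(self):
        """Event-conservation cross-check: one recorded length per indel event."""
        rec = evolve(model_tree(seed=6), SimParams(root_length=150, indel_rate=0.1, seed=6))
        total_indels = sum(ind for _sub, ind in rec.branch_events.values())
        assert total_indels == len(rec.gap_length_draws)

    def test_geometric_mean_gap_length_recovered(self):
        """Moment recovery: drawn gap lengths average to 1/p within 3 SE."""
        p = 0.25
        draws = []
        seed = 0
        while len(draws) < 1200:
            rec = evolve(model_tree(seed=seed, n=6),
                         SimParams(root_length=200, substitution_rate=0.0, indel_rate=0.15,
                                   gap_length_model=GeometricGaps(p), seed=1000 + seed))
            draws.extend(rec.gap_length_draws)
            seed += 1
        mean = statistics.fmean(draws)
        se = statistics.stdev(draws) / len(draws) ** 0.5
        assert abs(mean - 1 / p) <= 3 * se
        # observed alignment runs can only merge events, never shrink them
        runs_mean = empirical_stats(rec)["avg_gap_len"]
        assert runs_mean >= 1.0

    def test_true_alignment_is_feasible_for_every_leaf_pair(self, affine):
        rec = evolve(model_tree(seed=7, n=5), SimParams(root_length=40, indel_rate=0.08, seed=7))
        aln = rec.true_alignment
        for i in range(len(aln.taxa)):
            for j in range(i + 1, len(aln.taxa)):
                cols = [(x, y) for x, y in zip(aln.rows[i], aln.rows[j])
                        if not (x == GAP and y == GAP)]
                ra = "".join(x for x, _ in cols)
                rb = "".join(y for _, y in cols)
                cost = score_alignment(ra, rb, affine)
                assert cost >= edit_distance(
                    aln.rows[i].replace(GAP, ""), aln.rows[j].replace(GAP, ""), affine
                )

    def test_seeded_reproducibility(self):
        t = model_tree(seed=8)
        r1 = evolve(t, SimParams(root_length=80, seed=9))
        r2 = evolve(t, SimParams(root_length=80, seed=9))
        assert r1.true_alignment.rows == r2.true_alignment.rows
        assert r1.branch_events == r2.branch_events


class TestContraction:
    def test_no_zero_event_edges_keeps_topology(self):
        t = model_tree(seed=10)
        events = {frozenset((u, v)): (1, 0) for u, v in t.edges()}
        out = contract_zero_event_branches(t, events)
        assert bipartitions(out).splits == bipartitions(t).splits

    def test_all_zero_internal_edges_give_star(self):
        t = model_tree(seed=11)
        events = {frozenset((u, v)): (0, 0) for u, v in t.edges()}
        out = contract_zero_event_branches(t, events)
        assert len(out.internal_edges()) == 0
        assert out.leaf_labels == t.leaf_labels

    def test_single_zero_event_edge_gives_degree_four_polytomy(self):
        t = random_binary_tree(list("abcde"), 12)
        events = {frozenset((u, v)): (1, 1) for u, v in t.edges()}
        internal = t.internal_edges()
        events[frozenset(internal[0])] = (0, 0)
        out = contract_zero_event_branches(t, events)
        assert max(out.degree(u) for u in out.internal_nodes()) == 4
        rec_resolution = len(out.internal_edges()) / (t.n_leaves() - 3)
        assert rec_resolution == 0.5

    def test_missing_tally_rejected(self):
        t = random_binary_tree(list("abcde"), 13)
        with pytest.raises(ValueError, match="tally"):
            contract_zero_event_branches(t, {})


class TestStats:
    def test_two_row_toy_counts(self):
        aln = AlignmentMatrix(["a", "b"], ["AC-G", "ACTG"])
        # wrap the toy in a minimal record via direct field assembly
        from treelen.formats import PhyloTree, SequenceSet
        from treelen.simulator import SimulationRecord

        t = PhyloTree()
        x = t.new_node("a")
        y = t.new_node("b")
        t.add_edge(x, y, 1.0)
        rec = SimulationRecord(
            model_tree=t,
            leaf_seqs=aln.degapped(),
            true_alignment=aln,
            branch_events={frozenset((x, y)): (0, 1)},
            reference_tree=t,
            node_sequences={x: "ACG", y: "ACTG"},
            node_columns={x: [0, 1, 3], y: [0, 1, 2, 3]},
        )
        st = empirical_stats(rec)
        assert st["gap_pct"] == pytest.approx(12.5)
        assert st["avg_gap_len"] == 1.0 and st["median_gap_len"] == 1.0

    def test_fully_binary_reference_resolution_one(self):
        rec = evolve(model_tree(seed=14, lo=0.3, hi=0.6), SimParams(root_length=200, seed=14))
        if len(rec.reference_tree.internal_edges()) == rec.model_tree.n_leaves() - 3:
            assert empirical_stats(rec)["resolution"] == 1.0

    def test_gap_presets_stochastically_ordered(self):
        """Short/medium/long presets produce increasing mean gap lengths."""
        means = {}
        for name, model in GAP_PRESETS.items():
            draws = []
            for seed in range(8):
                rec = evolve(model_tree(seed=seed, n=6),
                             SimParams(root_length=150, substitution_rate=0.0, indel_rate=0.1,
                                       gap_length_model=model, seed=seed))
                draws.extend(rec.gap_length_draws)
            means[name] = statistics.fmean(draws)
        assert means["short-gaps"] < means["medium-gaps"] < means["long-gaps"]

    def test_mixture_model_samples_and_means(self):
        mix = MixtureGaps((0.7, 0.3), (GeometricGaps(1.0), GeometricGaps(0.05)))
        assert mix.mean == pytest.approx(0.7 * 1 + 0.3 * 20)
        rng = np.random.default_rng(0)
        draws = [mix.sample(rng) for _ in range(4000)]
        assert statistics.median(draws) == 1  # heavy tail, median stays 1
        assert max(draws) > 20
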