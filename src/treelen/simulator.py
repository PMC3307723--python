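"""Sequence evolution with substitutions and indels along a tree.

The simulator is the package's fixture generator: it evolves a root sequence
down a model tree under a Kimura-style two-parameter substitution process
plus a Poisson indel process, keeps exact homology bookkeeping so the true
multiple alignment is known, tallies events per branch, and derives the
reference tree by contracting internal branches on which no event occurred
(reconstructing such branches is a matter of chance, so they are excluded
from tree-error denominators).

Mechanism per branch of length ``b`` on a sequence of current length ``L``:

* every site receives ``Poisson(substitution_rate * b)`` substitution
  events; each event is a transition with probability ``k/(k+1)`` (``k`` =
  ts/tv event-count ratio) and otherwise one of the two transversions,
  equiprobably;
* ``Poisson(indel_rate * b * L)`` indel events are applied sequentially;
  each is an insertion with probability ``insertion_fraction``, else a
  deletion; positions are uniform and lengths are drawn from the configured
  gap-length model (geometric, or a mixture of geometrics — real gap-length
  distributions are heavy-tailed with median 1, which a single geometric
  cannot reproduce).

Insertions create fresh homology columns placed immediately after their
anchor column; deletions gap the descendant lineage.  Preset gap-length
bundles (short/medium/long) give stochastically ordered mean gap lengths.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from .formats import GAP, AlignmentMatrix, PhyloTree, SequenceSet
from .tree_moves import contract_edges

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


# ---------------------------------------------------------------------------
# Gap length models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometricGaps:
    """Gap lengths ~ Geometric(p) on {1, 2, ...}; mean 1/p."""

    p: float

    def __post_init__(self):
        if not 0 < self.p <= 1:
            raise ValueError("geometric parameter must be in (0, 1]")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.geometric(self.p))

    @property
    def mean(self) -> float:
        return 1.0 / self.p


@dataclass(frozen=True)
class MixtureGaps:
    """Mixture of geometrics: heavy-tailed gap lengths (median 1, long tail)."""

    weights: tuple[float, ...]
    components: tuple[GeometricGaps, ...]

    def __post_init__(self):
        if len(self.weights) != len(self.components):
            raise ValueError("weights/components length mismatch")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def sample(self, rng: np.random.Generator) -> int:
        i = int(rng.choice(len(self.weights), p=np.asarray(self.weights)))
        return self.components[i].sample(rng)

    @property
    def mean(self) -> float:
        return sum(w * c.mean for w, c in zip(self.weights, self.components))


#: Gap-length preset bundles with stochastically ordered means (S < M < L).
GAP_PRESETS = {
    "short-gaps": GeometricGaps(0.5),
    "medium-gaps": GeometricGaps(0.25),
    "long-gaps": GeometricGaps(0.1),
}


@dataclass(frozen=True)
class SimParams:
    """Rates and models governing one simulation."""

    root_length: int = 200
    substitution_rate: float = 1.0
    indel_rate: float = 0.05
    insertion_fraction: float = 0.5
    gap_length_model: GeometricGaps | MixtureGaps = GeometricGaps(0.25)
    ts_tv_ratio: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if self.root_length < 1:
            raise ValueError("root_length must be positive")
        for rate in (self.substitution_rate, self.indel_rate):
            if rate < 0:
                raise ValueError("rates must be nonnegative")
        if not 0 <= self.insertion_fraction <= 1:
            raise ValueError("insertion_fraction must lie in [0, 1]")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be positive")


@dataclass
class SimulationRecord:
    """Everything the simulation knows: tree, sequences, truth, events."""

    model_tree: PhyloTree
    leaf_seqs: SequenceSet
    true_alignment: AlignmentMatrix
    branch_events: dict[frozenset, tuple[int, int]]  # edge -> (subs, indel events)
    reference_tree: PhyloTree
    node_sequences: dict[int, str] = field(default_factory=dict)
    node_columns: dict[int, list[int]] = field(default_factory=dict)
    gap_length_draws: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------


def _substitute(base: str, rng: np.random.Generator, ts_tv_ratio: float) -> str:
    if rng.random() < ts_tv_ratio / (ts_tv_ratio + 1.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][int(rng.integers(2))]


def evolve(model_tree: PhyloTree, params: SimParams) -> SimulationRecord:
    """Evolve sequences down ``model_tree``; returns the full record.

    Branch lengths must be >= 0; zero-length branches simply generate no
    events (and are then contracted out of the reference tree if internal).
    """
    model_tree.validate()
    for u, v in model_tree.edges():
        b = model_tree.edge_length(u, v)
        if b is None or b < 0:
            raise ValueError(f"branch ({u},{v}) needs a nonnegative length")

    rng = np.random.default_rng(params.seed)
    root, parent, children, postorder = model_tree.rooted()
    preorder = list(reversed(postorder))

    root_seq = "".join(_BASES[int(i)] for i in rng.integers(4, size=params.root_length))
    next_col = params.root_length
    master: list[int] = list(range(next_col))  # global column order
    master_pos = {c: i for i, c in enumerate(master)}

    def master_insert_after(anchor: int | None, new_cols: list[int]) -> None:
        # anchor None -> prepend
        idx = 0 if anchor is None else master_pos[anchor] + 1
        master[idx:idx] = new_cols
        for i in range(idx, len(master)):
            master_pos[master[i]] = i

    node_seq: dict[int, str] = {root: root_seq}
    node_cols: dict[int, list[int]] = {root: list(range(params.root_length))}
    branch_events: dict[frozenset, tuple[int, int]] = {}
    gap_draws: list[int] = []

    for v in preorder:
        p = parent[v]
        if p == -1:
            continue
        b = model_tree.edge_length(p, v)
        seq = list(node_seq[p])
        cols = list(node_cols[p])
        n_sub = 0
        # substitutions: per-site Poisson event counts
        if params.substitution_rate > 0 and b > 0 and seq:
            hits = rng.poisson(params.substitution_rate * b, size=len(seq))
            for i, h in enumerate(hits):
                for _ in range(int(h)):
                    seq[i] = _substitute(seq[i], rng, params.ts_tv_ratio)
                    n_sub += 1
        # indels
        n_indel = 0
        if params.indel_rate > 0 and b > 0:
            n_indel = int(rng.poisson(params.indel_rate * b * len(seq)))
            for _ in range(n_indel):
                length = params.gap_length_model.sample(rng)
                gap_draws.append(length)
                if rng.random() < params.insertion_fraction:
                    pos = int(rng.integers(len(seq) + 1))  # insert before seq[pos]
                    new_cols = list(range(next_col, next_col + length))
                    next_col += length
                    anchor = cols[pos - 1] if pos > 0 else None
                    master_insert_after(anchor, new_cols)
                    ins = [_BASES[int(i)] for i in rng.integers(4, size=length)]
                    seq[pos:pos] = ins
                    cols[pos:pos] = new_cols
                else:
                    if not seq:
                        continue
                    pos = int(rng.integers(len(seq)))
                    end = min(pos + length, len(seq))
                    del seq[pos:end]
                    del cols[pos:end]
        node_seq[v] = "".join(seq)
        node_cols[v] = cols
        branch_events[frozenset((p, v))] = (n_sub, n_indel)

    # assemble the true alignment over leaves
    leaves = sorted(model_tree.leaves(), key=lambda u: model_tree.label(u))
    used = set()
    for u in leaves:
        used.update(node_cols[u])
    order = [c for c in master if c in used]
    col_index = {c: i for i, c in enumerate(order)}
    rows = []
    for u in leaves:
        row = [GAP] * len(order)
        for ch, c in zip(node_seq[u], node_cols[u]):
            row[col_index[c]] = ch
        rows.append("".join(row))
    taxa = [model_tree.label(u) for u in leaves]
    true_aln = AlignmentMatrix(taxa, rows)
    leaf_seqs = SequenceSet([(t, r.replace(GAP, "")) for t, r in zip(taxa, rows)])

    reference = contract_zero_event_branches(model_tree, branch_events)
    return SimulationRecord(
        model_tree=model_tree,
        leaf_seqs=leaf_seqs,
        true_alignment=true_aln,
        branch_events=branch_events,
        reference_tree=reference,
        node_sequences=node_seq,
        node_columns=node_cols,
        gap_length_draws=gap_draws,
    )


def contract_zero_event_branches(
    model_tree: PhyloTree, branch_events: dict[frozenset, tuple[int, int]]
) -> PhyloTree:
    """Contract internal branches with zero substitutions and zero indels.

    Leaf branches are never contracted; the result may be multifurcating.
    """
    zero = []
    for u, v in model_tree.internal_edges():
        key = frozenset((u, v))
        if key not in branch_events:
            raise ValueError(f"missing event tally for edge ({u}, {v})")
        if branch_events[key] == (0, 0):
            zero.append((u, v))
    for u, v in model_tree.edges():
        if frozenset((u, v)) not in branch_events:
            raise ValueError(f"missing event tally for edge ({u}, {v})")
    return contract_edges(model_tree, zero)


# ---------------------------------------------------------------------------
# Empirical statistics
# ---------------------------------------------------------------------------


def _p_distance(row_a: str, row_b: str) -> float:
    """Normalized Hamming distance over sites where neither row is a gap."""
    shared = mismatch = 0
    for x, y in zip(row_a, row_b):
        if x != GAP and y != GAP:
            shared += 1
            if x != y:
                mismatch += 1
    return mismatch / shared if shared else 0.0


def _gap_runs(aln: AlignmentMatrix) -> list[int]:
    runs = []
    for row in aln.rows:
        run = 0
        for ch in row:
            if ch == GAP:
                run += 1
            elif run:
                runs.append(run)
                run = 0
        if run:
            runs.append(run)
    return runs


def empirical_stats(record: SimulationRecord) -> dict[str, float]:
    """Dataset-level statistics of the kind reported for simulation studies.

    Setwise and edgewise p-distances, gap percentage and gap-run length
    summaries of the true alignment, column count, and the reference tree's
    resolution (internal edges / (n-3)).
    """
    aln = record.true_alignment
    n = len(aln.taxa)
    pd = [
        _p_distance(aln.rows[i], aln.rows[j]) for i in range(n) for j in range(i + 1, n)
    ]
    cells = n * aln.n_cols
    gaps = sum(row.count(GAP) for row in aln.rows)
    runs = _gap_runs(aln)

    # edgewise p-distance over model-tree edges via shared homology columns
    edge_pd = []
    for u, v in record.model_tree.edges():
        cu = dict(zip(record.node_columns[u], record.node_sequences[u]))
        cv = dict(zip(record.node_columns[v], record.node_sequences[v]))
        shared = set(cu) & set(cv)
        if shared:
            mism = sum(1 for c in shared if cu[c] != cv[c])
            edge_pd.append(mism / len(shared))
        else:
            edge_pd.append(1.0)

    n_leaves = record.model_tree.n_leaves()
    max_internal = n_leaves - 3
    resolution = (
        len(record.reference_tree.internal_edges()) / max_internal if max_internal > 0 else 0.0
    )
    return {
        "setwise_avg_p_dist": statistics.fmean(pd) if pd else 0.0,
        "setwise_max_p_dist": max(pd, default=0.0),
        "gap_pct": 100.0 * gaps / cells if cells else 0.0,
        "n_cols": float(aln.n_cols),
        "avg_gap_len": statistics.fmean(runs) if runs else 0.0,
        "median_gap_len": float(statistics.median(runs)) if runs else 0.0,
        "max_gap_len": float(max(runs, default=0)),
        "edgewise_avg_p_dist": statistics.fmean(edge_pd) if edge_pd else 0.0,
        "edgewise_max_p_dist": max(edge_pd, default=0.0),
        "resolution": resolution,
    }
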