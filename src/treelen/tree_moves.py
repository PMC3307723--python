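"""Random p-ECR tree perturbations and supporting tree surgery.

A p-ECR (edge contraction and refinement) move contracts p randomly chosen
internal edges of a binary tree and then randomly refines the resulting
unresolved tree back to binary.  The output therefore shares at least
(n-3) - p bipartitions with the input.  The neighborhood sampler draws p
uniformly from {1..5} (clamped to the number of internal edges) and emits 20
perturbed trees per starting tree by default.

All randomized operations are pure functions of (input, seed): seeds are
integers fed to numpy's default generator, and a Generator instance may be
passed directly when composing moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats import PhyloTree

DEFAULT_NEIGHBORHOOD = 20
DEFAULT_P_MAX = 5


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class EcrMove:
    """Record of one applied p-ECR move."""

    p: int
    contracted_edges: tuple[tuple[int, int], ...]
    seed: int | None = None


def contract_edges(tree: PhyloTree, edges) -> PhyloTree:
    """Contract the listed internal edges; result may be multifurcating.

    Node ids of the input are preserved except the absorbed endpoint of each
    contracted edge (the larger id is merged into the smaller).
    """
    out = tree.copy()
    merged: dict[int, int] = {}  # absorbed id -> surviving id

    def resolve(x: int) -> int:
        while x in merged:
            x = merged[x]
        return x

    for u, v in edges:
        u, v = resolve(u), resolve(v)
        if u == v:
            continue  # both endpoints already merged together
        if out.is_leaf(u) or out.is_leaf(v):
            raise ValueError(f"cannot contract leaf edge ({u}, {v})")
        keep, drop = min(u, v), max(u, v)
        if drop not in out.neighbors(keep):
            raise ValueError(f"({u}, {v}) is not an edge")
        merged[drop] = keep
        for w in out.neighbors(drop):
            if w == keep:
                continue
            length = out.edge_length(drop, w)
            out.remove_edge(drop, w)
            out.add_edge(keep, w, length)
        out.remove_node(drop)
    return out


def random_refine(tree: PhyloTree, seed=None) -> PhyloTree:
    """Resolve every polytomy by uniform random pairing; binary output.

    Each polytomy is refined by repeatedly grouping a uniformly chosen pair
    of its incident branches under a fresh node.  Every bipartition of the
    input survives in the output.
    """
    rng = _rng(seed)
    out = tree.copy()
    for v in sorted(out.internal_nodes()):
        while out.degree(v) > 3:
            nbrs = sorted(out.neighbors(v))
            i, j = map(int, rng.choice(len(nbrs), size=2, replace=False))
            a, b = nbrs[i], nbrs[j]
            w = out.new_node()
            la, lb = out.edge_length(v, a), out.edge_length(v, b)
            out.remove_edge(v, a)
            out.remove_edge(v, b)
            out.add_edge(w, a, la)
            out.add_edge(w, b, lb)
            out.add_edge(v, w, 0.0)
    return out


def p_ecr(tree: PhyloTree, p: int, seed=None, return_move: bool = False):
    """One random p-ECR move: contract p random internal edges, then refine."""
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = _rng(seed)
    internal = sorted(tree.internal_edges())
    if not internal:
        raise ValueError("tree has no internal edges to contract")
    if p > len(internal):
        warnings.warn(
            f"p={p} exceeds the {len(internal)} internal edges; clamping", stacklevel=2
        )
        p = len(internal)
    chosen_idx = rng.choice(len(internal), size=p, replace=False)
    chosen = [internal[int(i)] for i in sorted(chosen_idx)]
    collapsed = contract_edges(tree, chosen)
    refined = random_refine(collapsed, rng)
    if return_move:
        return refined, EcrMove(p=p, contracted_edges=tuple(chosen))
    return refined


def neighborhood(
    tree: PhyloTree,
    count: int = DEFAULT_NEIGHBORHOOD,
    p_max: int = DEFAULT_P_MAX,
    seed=None,
    with_moves: bool = False,
):
    """``count`` independent p-ECR perturbations, p ~ Uniform{1..min(p_max, n-3)}.

    Each returned tree is one p-ECR move away from the input; draws are
    independent and not deduplicated.
    """
    rng = _rng(seed)
    n_internal = len(tree.internal_edges())
    if n_internal == 0:
        raise ValueError("tree has no internal edges")
    hi = min(p_max, n_internal)
    out = []
    for _ in range(count):
        p = int(rng.integers(1, hi + 1))
        t, move = p_ecr(tree, p, rng, return_move=True)
        out.append((t, move) if with_moves else t)
    return out


def random_binary_tree(labels, seed=None) -> PhyloTree:
    """Uniformly random unrooted binary topology via sequential edge attachment."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    rng = _rng(seed)
    t = PhyloTree()
    center = t.new_node()
    for lab in labels[:3]:
        t.add_edge(center, t.new_node(label=lab))
    for lab in labels[3:]:
        edges = sorted(t.edges())
        u, v = edges[int(rng.integers(len(edges)))]
        mid = t.new_node()
        t.remove_edge(u, v)
        t.add_edge(u, mid)
        t.add_edge(mid, v)
        t.add_edge(mid, t.new_node(label=lab))
    return t
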