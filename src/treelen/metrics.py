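"""Tree and alignment accuracy metrics.

Tree error is reported as the missing branch rate (false-negative rate): the
proportion of the reference tree's internal bipartitions absent from the
estimated tree.  Dividing only by the reference's edge count keeps the metric
honest when the estimate is unresolved — the symmetric Robinson-Foulds
distance is biased in favor of unresolved trees, so it is exposed only as a
secondary quantity.  Alignment error is the SP-FN score: the fraction of
homologous residue pairs of the reference alignment that the estimate fails
to recover.  A strict-majority consensus rounds out the toolbox.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .formats import GAP, AlignmentMatrix, PhyloTree


@dataclass
class BipartitionSet:
    """Non-trivial leaf-label splits of a tree, in canonical form.

    Each split is stored as the frozenset of labels on the side containing
    the lexicographically smallest taxon.
    """

    taxa: tuple[str, ...]
    splits: frozenset[frozenset[str]]

    def __len__(self) -> int:
        return len(self.splits)


def bipartitions(tree: PhyloTree) -> BipartitionSet:
    """One split per internal edge; trivial splits (a side < 2) excluded."""
    tree.validate()
    taxa = tuple(sorted(tree.leaf_labels))
    anchor = taxa[0] if taxa else ""
    n = len(taxa)
    splits = set()
    for u, v in tree.internal_edges():
        # leaves on the v side of edge (u, v)
        side = set()
        stack = [(v, u)]
        while stack:
            x, par = stack.pop()
            if tree.is_leaf(x):
                side.add(tree.label(x))
            for w in tree.neighbors(x):
                if w != par:
                    stack.append((w, x))
        if len(side) < 2 or n - len(side) < 2:
            continue
        if anchor not in side:
            side = set(taxa) - side
        splits.add(frozenset(side))
    return BipartitionSet(taxa, frozenset(splits))


def _check_same_leaves(ref: PhyloTree, est: PhyloTree) -> None:
    if ref.leaf_labels != est.leaf_labels:
        raise ValueError("trees have different leaf sets")


def missing_branch_rate(ref: PhyloTree, est: PhyloTree) -> float:
    """|bip(ref) - bip(est)| / |bip(ref)|: the false-negative branch rate."""
    _check_same_leaves(ref, est)
    bref = bipartitions(ref).splits
    best = bipartitions(est).splits
    if not bref:
        warnings.warn("reference tree has no internal edges; rate undefined")
        return math.nan
    return len(bref - best) / len(bref)


def robinson_foulds(ref: PhyloTree, est: PhyloTree) -> int:
    """Symmetric bipartition distance (secondary metric)."""
    _check_same_leaves(ref, est)
    bref = bipartitions(ref).splits
    best = bipartitions(est).splits
    return len(bref ^ best)


# ---------------------------------------------------------------------------
# SP-FN alignment error
# ---------------------------------------------------------------------------


def homology_pairs(aln: AlignmentMatrix) -> set[tuple]:
    """Aligned residue pairs {((taxon_i, site_k), (taxon_j, site_l))}, i < j.

    Sites are indexed within each degapped sequence, so the pair set is
    invariant to how the alignment is padded.
    """
    pairs = set()
    pos = {t: -1 for t in aln.taxa}
    order = sorted(range(len(aln.taxa)), key=lambda i: aln.taxa[i])
    for j in range(aln.n_cols):
        residues = []
        for i in order:
            t = aln.taxa[i]
            ch = aln.rows[i][j]
            if ch != GAP:
                pos[t] += 1
                residues.append((t, pos[t]))
        for a in range(len(residues)):
            for b in range(a + 1, len(residues)):
                pairs.add((residues[a], residues[b]))
    return pairs


def sp_fn(ref_aln: AlignmentMatrix, est_aln: AlignmentMatrix) -> float:
    """1 - |H(est) ∩ H(ref)| / |H(ref)| over homologous residue pairs."""
    if set(ref_aln.taxa) != set(est_aln.taxa):
        raise ValueError("alignments cover different taxa")
    for t in ref_aln.taxa:
        if ref_aln.row(t).replace(GAP, "") != est_aln.row(t).replace(GAP, ""):
            raise ValueError(f"degapped sequence of {t!r} differs between alignments")
    href = homology_pairs(ref_aln)
    if not href:
        warnings.warn("reference alignment has no homologous pairs; SP-FN undefined")
        return math.nan
    hest = homology_pairs(est_aln)
    return 1.0 - len(href & hest) / len(href)


# ---------------------------------------------------------------------------
# Majority consensus
# ---------------------------------------------------------------------------


def majority_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the splits present in more than half the inputs.

    Strict-majority splits are pairwise compatible, so they always assemble
    into one (possibly multifurcating) tree.
    """
    if not trees:
        raise ValueError("need at least one tree")
    taxa = sorted(trees[0].leaf_labels)
    for t in trees[1:]:
        if sorted(t.leaf_labels) != taxa:
            raise ValueError("trees have different leaf sets")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in bipartitions(t).splits:
            counts[split] = counts.get(split, 0) + 1
    majority = [s for s, c in counts.items() if c * 2 > len(trees)]

    # Assemble rooted at an anchor taxon: each split's non-anchor side is a
    # clade; insert clades largest-first into a star and group children.
    anchor = taxa[0]
    taxa_set = set(taxa)
    clades = sorted(
        (s if anchor not in s else frozenset(taxa_set - s) for s in majority),
        key=lambda c: (-len(c), sorted(c)),
    )

    children: dict[object, list] = {"root": [frozenset((t,)) for t in taxa]}
    cover: dict[object, frozenset] = {"root": frozenset(taxa)}
    for t in taxa:
        cover[frozenset((t,))] = frozenset((t,))
        children[frozenset((t,))] = []

    for clade in clades:
        host = "root"
        while True:
            deeper = next(
                (c for c in children[host] if clade <= cover[c] and len(children[c]) > 0),
                None,
            )
            if deeper is None:
                break
            host = deeper
        group = [c for c in children[host] if cover[c] <= clade]
        assert frozenset().union(*[cover[c] for c in group]) == clade
        node_key = ("clade", clade)
        children[node_key] = group
        cover[node_key] = clade
        children[host] = [c for c in children[host] if c not in group] + [node_key]

    out = PhyloTree()

    def build(key) -> int:
        kids = children[key]
        if not kids:
            (label,) = cover[key]
            return out.new_node(label=label)
        u = out.new_node()
        for c in kids:
            out.add_edge(u, build(c))
        return u

    build("root")
    out.splice_degree2()
    out.validate()
    return out
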