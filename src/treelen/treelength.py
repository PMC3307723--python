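"""Fixed-tree treelength scoring and implied multiple alignments.

The treelength of a tree whose every node carries a gap-free sequence is the
sum over edges of the pairwise edit distance between the endpoint sequences.
Finding internal-node sequences minimizing that sum is NP-hard even for a
fixed tree, so this module offers three solvers:

``lifted``
    Every internal node receives the sequence of some leaf, the combination
    chosen optimally by dynamic programming over the all-pairs leaf distance
    matrix.  Under a metric edit distance the optimum lifted labeling is a
    2-approximation of the true fixed-tree optimum.
``do``
    A direct-optimization-style pass: a post-order sweep assigns each
    internal node a consensus of its children's pairwise alignment, followed
    by hill-climbing that re-lifts nodes to neighboring sequences while the
    treelength drops.
``exact``
    Brute force for tiny instances: Sankoff-style dynamic programming over
    the space of all candidate ancestral strings up to a length bound.
    Serves as the verification oracle for the two heuristics.

:func:`implied_alignment` turns an assignment into a multiple sequence
alignment: each edge contributes its optimal pairwise alignment, and the
transitive closure of the induced site-homology relation defines the columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Literal

from .cost_model import Cost, CostScheme
from .formats import GAP, AlignmentMatrix, PhyloTree, SequenceSet
from .pairwise import align_pair, edit_distance

Method = Literal["lifted", "do", "exact"]


@dataclass
class TreeAssignment:
    """A tree with a sequence at every node and the resulting treelength."""

    tree: PhyloTree
    node_sequences: dict[int, str]
    treelength: Cost
    scheme: CostScheme
    method: str

    def recompute_treelength(self) -> Cost:
        """Edge-sum recomputed from node_sequences (the defining identity)."""
        total: Cost = Fraction(0)
        for u, v in self.tree.edges():
            total += edit_distance(self.node_sequences[u], self.node_sequences[v], self.scheme)
        return total


def _check_labels(tree: PhyloTree, seqs: SequenceSet) -> dict[int, str]:
    """Map leaf node -> sequence; error unless labels biject."""
    tree.validate()
    tree_labels = tree.leaf_labels
    seq_labels = set(seqs.labels)
    if tree_labels != seq_labels:
        missing = tree_labels ^ seq_labels
        raise ValueError(f"tree/sequence label mismatch: {sorted(missing)}")
    by_label = seqs.as_dict()
    return {u: by_label[tree.label(u)] for u in tree.leaves()}


def _distance_matrix(seqs: list[str], scheme: CostScheme) -> list[list[Cost]]:
    k = len(seqs)
    D: list[list[Cost]] = [[Fraction(0)] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            D[i][j] = D[j][i] = edit_distance(seqs[i], seqs[j], scheme)
    return D


def score_fixed_tree(
    tree: PhyloTree,
    seqs: SequenceSet,
    scheme: CostScheme,
    method: Method = "lifted",
    distance_matrix: list[list[Cost]] | None = None,
    **kwargs,
) -> TreeAssignment:
    """Assign internal sequences by ``method`` and return the scored tree.

    The returned treelength is an upper bound on the fixed-tree optimum for
    the heuristic methods and the optimum over the enumerated space for
    ``exact``.  ``distance_matrix`` lets callers scoring many trees on the
    same sequences reuse the all-pairs leaf distances (lifted method only;
    entries must be indexed by the order of ``seqs``).
    """
    if method == "lifted":
        return lifted_assignment(tree, seqs, scheme, distance_matrix=distance_matrix)
    if method == "do":
        return do_assignment(tree, seqs, scheme)
    if method == "exact":
        return exact_assignment(tree, seqs, scheme, **kwargs)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Lifted labeling
# ---------------------------------------------------------------------------


def lifted_assignment(
    tree: PhyloTree,
    seqs: SequenceSet,
    scheme: CostScheme,
    distance_matrix: list[list[Cost]] | None = None,
) -> TreeAssignment:
    """Optimal lifted labeling: internal nodes take leaf sequences, chosen by DP."""
    leaf_seq = _check_labels(tree, seqs)
    leaf_list = [seq for _, seq in seqs]
    idx_of = {}
    for i, (_, s) in enumerate(seqs):
        idx_of.setdefault(s, i)
    D = distance_matrix if distance_matrix is not None else _distance_matrix(leaf_list, scheme)
    k = len(leaf_list)

    if tree.n_leaves() == len(tree.nodes()):  # no internal nodes: 1- or 2-leaf tree
        node_seq = dict(leaf_seq)
        tl: Cost = Fraction(0)
        for u, v in tree.edges():
            tl += edit_distance(node_seq[u], node_seq[v], scheme)
        return TreeAssignment(tree, node_seq, tl, scheme, "lifted")

    root, parent, children, postorder = tree.rooted()
    INF = float("inf")
    cost: dict[int, list[Cost]] = {}
    choice: dict[int, list[list[int]]] = {}  # choice[v][c] = best child candidates
    for v in postorder:
        if tree.is_leaf(v):
            own = idx_of[leaf_seq[v]]
            cost[v] = [D[c][own] for c in range(k)]
            continue
        total = [Fraction(0)] * k
        pick: list[list[int]] = [[] for _ in range(k)]
        for w in children[v]:
            cw = cost[w]
            if tree.is_leaf(w):
                # leaf child is pinned to its own sequence
                own = idx_of[leaf_seq[w]]
                for c in range(k):
                    total[c] += D[c][own]
                    pick[c].append(own)
            else:
                for c in range(k):
                    best, best_c = INF, -1
                    for c2 in range(k):
                        val = cw[c2] + D[c][c2]
                        if val < best:
                            best, best_c = val, c2
                    total[c] += best
                    pick[c].append(best_c)
        cost[v] = total
        choice[v] = pick

    best_root = min(range(k), key=lambda c: cost[root][c])
    node_seq = dict(leaf_seq)
    assign: list[tuple[int, int]] = [(root, best_root)]
    while assign:
        v, c = assign.pop()
        if tree.is_leaf(v):
            continue
        node_seq[v] = leaf_list[c]
        for w, c2 in zip(children[v], choice[v][c]):
            assign.append((w, c2))
    tl = cost[root][best_root]
    return TreeAssignment(tree, node_seq, tl, scheme, "lifted")


# ---------------------------------------------------------------------------
# Direct-optimization-style heuristic
# ---------------------------------------------------------------------------


def _consensus(a: str, b: str, scheme: CostScheme) -> str:
    """Column consensus of the optimal pairwise alignment of a and b.

    Base/base ties resolve alphabetically; base/gap keeps the base, so the
    result is gap-free.
    """
    al = align_pair(a, b, scheme)
    out = []
    for x, y in al.columns():
        if x == GAP:
            out.append(y)
        elif y == GAP:
            out.append(x)
        elif x == y:
            out.append(x)
        else:
            out.append(min(x, y))
    return "".join(out)


def do_assignment(
    tree: PhyloTree, seqs: SequenceSet, scheme: CostScheme, max_rounds: int = 20
) -> TreeAssignment:
    """Post-order consensus assignment followed by neighbor-lift hill climbing."""
    leaf_seq = _check_labels(tree, seqs)
    node_seq = dict(leaf_seq)
    if tree.n_leaves() == len(tree.nodes()):
        tl: Cost = Fraction(0)
        for u, v in tree.edges():
            tl += edit_distance(node_seq[u], node_seq[v], scheme)
        return TreeAssignment(tree, node_seq, tl, scheme, "do")

    root, parent, children, postorder = tree.rooted()
    for v in postorder:
        if tree.is_leaf(v):
            continue
        kid_seqs = [node_seq[w] for w in children[v]]
        cur = kid_seqs[0]
        for nxt in kid_seqs[1:]:
            cur = _consensus(cur, nxt, scheme)
        node_seq[v] = cur

    # hill-climb: replace an internal node's sequence when a neighbor's
    # sequence, or a re-derived consensus of its neighbors, lowers the sum
    # of its incident edge costs; iterate to a fixed point
    internal = sorted(tree.internal_nodes())
    for _ in range(max_rounds):
        improved = False
        for v in internal:
            nbrs = sorted(tree.neighbors(v))
            cur_cost = sum(edit_distance(node_seq[v], node_seq[u], scheme) for u in nbrs)
            cands = [node_seq[u] for u in nbrs]
            folded = cands[0]
            for nxt in cands[1:]:
                folded = _consensus(folded, nxt, scheme)
            cands.append(folded)
            best_seq, best_cost = node_seq[v], cur_cost
            for cand in cands:
                if cand == best_seq:
                    continue
                c = sum(edit_distance(cand, node_seq[w], scheme) for w in nbrs)
                if c < best_cost:
                    best_seq, best_cost = cand, c
            if best_seq != node_seq[v]:
                node_seq[v] = best_seq
                improved = True
        if not improved:
            break

    tl = Fraction(0)
    for u, v in tree.edges():
        tl += edit_distance(node_seq[u], node_seq[v], scheme)
    return TreeAssignment(tree, node_seq, tl, scheme, "do")


# ---------------------------------------------------------------------------
# Exact brute force on tiny instances
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _candidate_space(alphabet: str, max_len: int, scheme: CostScheme):
    """All strings over ``alphabet`` with length <= max_len, plus their distances."""
    cands = [""]
    for l in range(1, max_len + 1):
        cands.extend("".join(t) for t in itertools.product(alphabet, repeat=l))
    k = len(cands)
    D: list[list[Cost]] = [[Fraction(0)] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            D[i][j] = D[j][i] = edit_distance(cands[i], cands[j], scheme)
    return cands, D


def exact_assignment(
    tree: PhyloTree,
    seqs: SequenceSet,
    scheme: CostScheme,
    max_len: int = 4,
    max_taxa: int = 5,
    alphabet: str = "ACGT",
) -> TreeAssignment:
    """Global minimum treelength over all ancestral strings of length <= max_len.

    Verification oracle for the heuristics; refuses oversized input.  The
    candidate alphabet may be restricted (e.g. to two bases) to enlarge the
    feasible length bound.
    """
    leaf_seq = _check_labels(tree, seqs)
    if tree.n_leaves() > max_taxa:
        raise ValueError(f"exact method limited to {max_taxa} taxa")
    longest = max((len(s) for s in leaf_seq.values()), default=0)
    if longest > max_len:
        raise ValueError(f"exact method limited to sequences of length <= {max_len}")
    for s in leaf_seq.values():
        if any(ch not in alphabet for ch in s):
            raise ValueError("leaf sequence uses a base outside the candidate alphabet")

    node_seq = dict(leaf_seq)
    if tree.n_leaves() == len(tree.nodes()):
        tl: Cost = Fraction(0)
        for u, v in tree.edges():
            tl += edit_distance(node_seq[u], node_seq[v], scheme)
        return TreeAssignment(tree, node_seq, tl, scheme, "exact")

    cands, D = _candidate_space(alphabet, max_len, scheme)
    index = {s: i for i, s in enumerate(cands)}
    k = len(cands)
    INF = float("inf")

    root, parent, children, postorder = tree.rooted()
    cost: dict[int, list[Cost]] = {}
    choice: dict[int, list[list[int]]] = {}
    for v in postorder:
        if tree.is_leaf(v):
            continue
        total: list[Cost] = [Fraction(0)] * k
        pick: list[list[int]] = [[] for _ in range(k)]
        for w in children[v]:
            if tree.is_leaf(w):
                own = index[leaf_seq[w]]
                for c in range(k):
                    total[c] = total[c] + D[c][own]
                    pick[c].append(own)
            else:
                cw = cost[w]
                for c in range(k):
                    best, best_c = INF, -1
                    row = D[c]
                    for c2 in range(k):
                        val = cw[c2] + row[c2]
                        if val < best:
                            best, best_c = val, c2
                    total[c] = total[c] + best
                    pick[c].append(best_c)
        cost[v] = total
        choice[v] = pick

    best_root = min(range(k), key=lambda c: cost[root][c])
    assign: list[tuple[int, int]] = [(root, best_root)]
    while assign:
        v, c = assign.pop()
        if tree.is_leaf(v):
            continue
        node_seq[v] = cands[c]
        for w, c2 in zip(children[v], choice[v][c]):
            assign.append((w, c2))
    return TreeAssignment(tree, node_seq, cost[root][best_root], scheme, "exact")


# ---------------------------------------------------------------------------
# Implied alignment
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def implied_alignment(assignment: TreeAssignment) -> AlignmentMatrix:
    """Multiple alignment implied by the edge-wise optimal pairwise alignments.

    For every edge the optimal pairwise alignment of its endpoint sequences
    (parent row first, deterministic traceback) declares site homologies;
    their transitive closure across the tree defines the columns.  Column
    order is a topological sort of the precedence relation read off the edge
    alignments; the rare ordering conflicts that transitivity can create are
    resolved by splitting the offending homology class so every sequence
    still reads out in site order.  Rows are restricted to leaves and
    all-gap columns dropped.
    """
    tree = assignment.tree
    node_seq = assignment.node_sequences
    nodes = tree.nodes()
    if len(nodes) == 1:
        u = nodes[0]
        return AlignmentMatrix([tree.label(u)], [node_seq[u]])

    root, parent, children, postorder = tree.rooted()
    uf = _UnionFind()
    # register every site
    for u in nodes:
        for i in range(len(node_seq[u])):
            uf.find((u, i))

    edge_chains: list[list[tuple[str, tuple]]] = []  # per edge: ordered column descriptors
    order_nodes = [v for v in reversed(postorder)]  # preorder
    for v in order_nodes:
        p = parent[v]
        if p == -1:
            continue
        al = align_pair(node_seq[p], node_seq[v], assignment.scheme)
        i = j = 0
        chain = []
        for x, y in al.columns():
            if x != GAP and y != GAP:
                uf.union((p, i), (v, j))
                chain.append(("pair", ((p, i), (v, j))))
                i += 1
                j += 1
            elif y == GAP:
                chain.append(("single", (p, i)))
                i += 1
            else:
                chain.append(("single", (v, j)))
                j += 1
        edge_chains.append(chain)

    # classes and membership
    members: dict[tuple, list[tuple]] = {}
    for u in nodes:
        for i in range(len(node_seq[u])):
            members.setdefault(uf.find((u, i)), []).append((u, i))

    def class_key(root_site):
        return min(members[root_site])

    # precedence graph: consecutive columns within each edge alignment
    succ: dict[tuple, set[tuple]] = {c: set() for c in members}
    indeg: dict[tuple, int] = {c: 0 for c in members}
    for chain in edge_chains:
        prev = None
        for kind, payload in chain:
            site = payload[0] if kind == "pair" else payload
            cls = uf.find(site)
            if prev is not None and prev != cls and cls not in succ[prev]:
                succ[prev].add(cls)
                indeg[cls] += 1
            prev = cls

    # Kahn topological sort, deterministic tie-break by smallest member
    import heapq

    ready = [(class_key(c), c) for c in members if indeg[c] == 0]
    heapq.heapify(ready)
    emitted: list[list[tuple]] = []
    done: set[tuple] = set()
    while ready:
        _, c = heapq.heappop(ready)
        emitted.append(members[c])
        done.add(c)
        for d in succ[c]:
            indeg[d] -= 1
            if indeg[d] == 0:
                heapq.heappush(ready, (class_key(d), d))

    if len(done) < len(members):
        # Ordering conflict (cycle through transitivity): fall back to a
        # frontier sweep over the remaining sites that may split classes.
        remaining_sites: dict[int, list[int]] = {u: [] for u in nodes}
        placed = {s for c in done for s in members[c]}
        for u in nodes:
            for i in range(len(node_seq[u])):
                if (u, i) not in placed:
                    remaining_sites[u].append(i)
        frontier = {u: 0 for u in nodes}

        def is_frontier(site):
            u, i = site
            ptr = frontier[u]
            return ptr < len(remaining_sites[u]) and remaining_sites[u][ptr] == i

        left = {c: [s for s in members[c] if s not in placed] for c in members if c not in done}
        left = {c: ms for c, ms in left.items() if ms}
        while left:
            full = [c for c, ms in left.items() if all(is_frontier(s) for s in ms)]
            if full:
                c = min(full, key=lambda c: min(left[c]))
                emit = left.pop(c)
            else:
                cands = [c for c, ms in left.items() if any(is_frontier(s) for s in ms)]
                c = min(cands, key=lambda c: min(s for s in left[c] if is_frontier(s)))
                emit = [s for s in left[c] if is_frontier(s)]
                rest = [s for s in left[c] if s not in emit]
                if rest:
                    left[c] = rest
                else:
                    left.pop(c)
            emitted.append(sorted(emit))
            for u, _i in emit:
                frontier[u] += 1

    # build rows for leaves, drop all-gap columns
    leaves = sorted(tree.leaves(), key=lambda u: tree.label(u))
    leaf_set = set(leaves)
    rows = {u: [] for u in leaves}
    for col in emitted:
        cells = {u: node_seq[u][i] for u, i in col if u in leaf_set}
        if not cells:
            continue
        for u in leaves:
            rows[u].append(cells.get(u, GAP))
    taxa = [tree.label(u) for u in leaves]
    return AlignmentMatrix(taxa, ["".join(rows[u]) for u in leaves])
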