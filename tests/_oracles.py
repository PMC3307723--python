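"""Independent oracles used by the test suite.

Deliberately implemented without reusing the package's code paths so that
agreement between oracle and implementation is meaningful.
"""

from __future__ import annotations

import itertools
import math


def sankoff_parsimony_score(tree, leaf_seq: dict[int, str], sub_cost) -> object:
    """Per-site Sankoff parsimony over a tree with equal-length leaf sequences.

    ``sub_cost(x, y)`` gives the substitution cost; the total is the sum over
    sites of the per-site minimum.  Independent of the package's edit-distance
    machinery (no gaps involved).
    """
    lengths = {len(s) for s in leaf_seq.values()}
    assert len(lengths) == 1, "sequences must have equal length"
    (L,) = lengths
    root, _parent, children, postorder = tree.rooted()
    bases = "ACGT"
    total = 0
    for site in range(L):
        cost: dict[int, dict[str, float]] = {}
        for v in postorder:
            if tree.is_leaf(v):
                ch = leaf_seq[v][site]
                cost[v] = {b: (0 if b == ch else math.inf) for b in bases}
            else:
                cost[v] = {
                    b: sum(
                        min(cost[w][b2] + (sub_cost(b, b2) if b != b2 else 0) for b2 in bases)
                        for w in children[v]
                    )
                    for b in bases
                }
        total += min(cost[root].values())
    return total


def alignment_pair_set(taxa: list[str], rows: list[str]) -> set:
    """Homologous residue pairs of an alignment, enumerated per taxon pair.

    Walks every taxon pair's projected rows column by column with explicit
    site counters — a different traversal than the package's column-wise
    accumulation.
    """
    pairs = set()
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    for a, b in itertools.combinations(order, 2):
        i = j = -1
        ta, tb = taxa[a], taxa[b]
        if ta > tb:
            ta, tb, a, b = tb, ta, b, a
        for x, y in zip(rows[a], rows[b]):
            if x != "-":
                i += 1
            if y != "-":
                j += 1
            if x != "-" and y != "-":
                pairs.add(((ta, i), (tb, j)))
    return pairs


def split_counts(trees) -> dict[frozenset, int]:
    """Count canonical non-trivial splits across trees by direct enumeration."""
    counts: dict[frozenset, int] = {}
    for t in trees:
        taxa = sorted(t.leaf_labels)
        anchor = taxa[0]
        for u, v in t.internal_edges():
            side = set()
            stack = [(v, u)]
            while stack:
                x, par = stack.pop()
                if t.is_leaf(x):
                    side.add(t.label(x))
                stack.extend((w, x) for w in t.neighbors(x) if w != par)
            if 2 <= len(side) <= len(taxa) - 2:
                key = frozenset(side if anchor in side else set(taxa) - side)
                counts[key] = counts.get(key, 0) + 1
    return counts


def random_nested_topology(labels, rng):
    """Random binary topology as nested tuples (for tree_from_newick_like)."""
    items = list(labels)
    while len(items) > 3:
        a = items.pop(rng.randrange(len(items)))
        b = items.pop(rng.randrange(len(items)))
        items.append((a, b))
    return tuple(items)


def random_seq(rng, min_len: int, max_len: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(rng.randint(min_len, max_len)))
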