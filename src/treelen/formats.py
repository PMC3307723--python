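"""Shared primitive types and FASTA/Newick input/output.

The toolkit works with three containers: :class:`SequenceSet` (unaligned or
aligned nucleotide sequences), :class:`PhyloTree` (an unrooted phylogenetic
tree that may contain polytomies), and :class:`AlignmentMatrix` (a multiple
sequence alignment).  FASTA parsing is delegated to Biopython and Newick
parsing/serialization to dendropy; this module validates the invariants the
rest of the package relies on (unique non-empty labels, a clean alphabet,
no all-gap alignment columns) and rejects violating input rather than
repairing it.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
from Bio import SeqIO

GAP = "-"
BASES = "ACGT"
#: IUPAC ambiguity codes collapsed to N under permissive parsing.
AMBIGUITY = set("NRYSWKMBDHV")


class FormatError(ValueError):
    """Raised when an input file violates a container invariant."""


# ---------------------------------------------------------------------------
# SequenceSet
# ---------------------------------------------------------------------------


@dataclass
class SequenceSet:
    """Ordered collection of labelled nucleotide sequences.

    Labels are unique and non-empty.  Unaligned sets contain no gap symbol;
    aligned sets may contain ``-``.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, _seq in self.records:
            if not label:
                raise FormatError("empty taxon label")
            if label in seen:
                raise FormatError(f"duplicate taxon label: {label!r}")
            seen.add(label)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.records]

    def as_dict(self) -> dict[str, str]:
        return dict(self.records)

    def __getitem__(self, label: str) -> str:
        for lab, seq in self.records:
            if lab == label:
                return seq
        raise KeyError(label)


def _validate_sequence(label: str, seq: str, aligned: bool, permissive: bool) -> str:
    seq = seq.upper().replace(".", GAP)
    allowed = set(BASES)
    if aligned:
        allowed.add(GAP)
    out = []
    for ch in seq:
        if ch in allowed:
            out.append(ch)
        elif permissive and ch in AMBIGUITY:
            out.append("N")
        else:
            raise FormatError(f"illegal character {ch!r} in record {label!r}")
    return "".join(out)


def read_fasta(path_or_stream, aligned: bool = False, permissive: bool = False) -> SequenceSet:
    """Parse FASTA into a :class:`SequenceSet`.

    Parameters
    ----------
    aligned
        Permit the gap symbol (``-`` or ``.``, the latter normalized to ``-``).
    permissive
        Map IUPAC ambiguity codes to ``N`` instead of rejecting them.
    """
    close = False
    if isinstance(path_or_stream, str):
        handle = open(path_or_stream)
        close = True
    elif isinstance(path_or_stream, io.StringIO) or hasattr(path_or_stream, "read"):
        handle = path_or_stream
    else:  # pathlib.Path and friends
        handle = open(path_or_stream)
        close = True
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.id, _validate_sequence(rec.id, str(rec.seq), aligned, permissive)))
    finally:
        if close:
            handle.close()
    if not records:
        raise FormatError("empty FASTA input")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet | "AlignmentMatrix", path_or_stream, width: int = 60) -> None:
    """Write FASTA with fixed-width sequence wrapping."""
    if isinstance(seqs, AlignmentMatrix):
        records: Iterable[tuple[str, str]] = zip(seqs.taxa, seqs.rows)
    else:
        records = seqs
    lines = []
    for label, seq in records:
        lines.append(f">{label}\n")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width] + "\n")
    text = "".join(lines)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# AlignmentMatrix
# ---------------------------------------------------------------------------


@dataclass
class AlignmentMatrix:
    """Multiple sequence alignment: rows of equal length over {A,C,G,T,-}."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise FormatError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon in alignment")
        if self.rows:
            n = len(self.rows[0])
            for t, r in zip(self.taxa, self.rows):
                if len(r) != n:
                    raise FormatError(f"row {t!r} has length {len(r)} != {n}")
            for j in range(n):
                if all(r[j] == GAP for r in self.rows):
                    raise FormatError(f"column {j} is entirely gaps")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def degapped(self) -> SequenceSet:
        return SequenceSet([(t, r.replace(GAP, "")) for t, r in zip(self.taxa, self.rows)])

    @classmethod
    def from_sequence_set(cls, seqs: SequenceSet) -> "AlignmentMatrix":
        return cls(list(seqs.labels), [seq for _, seq in seqs])


def read_alignment(path_or_stream, permissive: bool = False) -> AlignmentMatrix:
    """Read an aligned FASTA file into an :class:`AlignmentMatrix`."""
    seqs = read_fasta(path_or_stream, aligned=True, permissive=permissive)
    return AlignmentMatrix.from_sequence_set(seqs)


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


class PhyloTree:
    """Unrooted phylogenetic tree over labelled leaves.

    Stored as an adjacency structure keyed by integer node ids so that tree
    surgery (edge contraction, refinement) is cheap and explicit.  Leaves are
    degree-<=1 nodes and must carry a label; internal nodes may have any
    degree >= 3 (polytomies are first-class).  Edge data records an optional
    branch length.
    """

    def __init__(self) -> None:
        self._labels: dict[int, str | None] = {}
        self._adj: dict[int, dict[int, dict]] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._labels[nid] = label
        self._adj[nid] = {}
        return nid

    def add_edge(self, u: int, v: int, length: float | None = None) -> None:
        if v in self._adj[u]:
            raise ValueError("edge already present")
        data = {"length": length}
        self._adj[u][v] = data
        self._adj[v][u] = data

    def remove_edge(self, u: int, v: int) -> None:
        del self._adj[u][v]
        del self._adj[v][u]

    def remove_node(self, u: int) -> None:
        for v in list(self._adj[u]):
            self.remove_edge(u, v)
        del self._adj[u]
        del self._labels[u]

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._labels = dict(self._labels)
        t._next_id = self._next_id
        t._adj = {u: {} for u in self._adj}
        for u, v in self.edges():
            data = dict(self._adj[u][v])
            t._adj[u][v] = data
            t._adj[v][u] = data
        return t

    # -- inspection ---------------------------------------------------------

    def nodes(self) -> list[int]:
        return list(self._adj)

    def label(self, u: int) -> str | None:
        return self._labels[u]

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def neighbors(self, u: int) -> list[int]:
        return list(self._adj[u])

    def is_leaf(self, u: int) -> bool:
        return len(self._adj[u]) <= 1

    def leaves(self) -> list[int]:
        return [u for u in self._adj if self.is_leaf(u)]

    @property
    def leaf_labels(self) -> set[str]:
        out = set()
        for u in self.leaves():
            lab = self._labels[u]
            if lab is None:
                raise FormatError("leaf without label")
            out.add(lab)
        return out

    def leaf_by_label(self, label: str) -> int:
        for u in self.leaves():
            if self._labels[u] == label:
                return u
        raise KeyError(label)

    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self._adj for v in self._adj[u] if u < v]

    def edge_length(self, u: int, v: int) -> float | None:
        return self._adj[u][v]["length"]

    def set_edge_length(self, u: int, v: int, length: float | None) -> None:
        self._adj[u][v]["length"] = length

    def internal_nodes(self) -> list[int]:
        return [u for u in self._adj if not self.is_leaf(u)]

    def internal_edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, v in self.edges() if not self.is_leaf(u) and not self.is_leaf(v)]

    def is_binary(self) -> bool:
        return all(self.degree(u) in (1, 3) for u in self._adj) and len(self._adj) > 1

    def validate(self) -> None:
        """Check connectivity, acyclicity and leaf labelling."""
        nodes = self.nodes()
        if not nodes:
            raise FormatError("empty tree")
        seen = {nodes[0]}
        stack = [(nodes[0], -1)]
        edges_seen = 0
        while stack:
            u, parent = stack.pop()
            for v in self._adj[u]:
                if v == parent:
                    continue
                edges_seen += 1
                if v in seen:
                    raise FormatError("tree contains a cycle")
                seen.add(v)
                stack.append((v, u))
        if len(seen) != len(nodes):
            raise FormatError("tree is not connected")
        labels = [self._labels[u] for u in self.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise FormatError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate leaf labels")

    # -- traversal ----------------------------------------------------------

    def default_root(self) -> int:
        """Internal node adjacent to the lexicographically smallest leaf.

        Falls back to that leaf itself for 2-node trees, keeping traversal
        deterministic on degenerate inputs.
        """
        leaf = self.leaf_by_label(min(self.leaf_labels))
        nbrs = self.neighbors(leaf)
        if nbrs and not self.is_leaf(nbrs[0]):
            return nbrs[0]
        if self.internal_nodes():
            return sorted(self.internal_nodes())[0]
        return leaf

    def rooted(self, root: int | None = None) -> tuple[int, dict[int, int], dict[int, list[int]], list[int]]:
        """Orient the tree from ``root``; returns (root, parent, children, postorder)."""
        if root is None:
            root = self.default_root()
        parent: dict[int, int] = {root: -1}
        children: dict[int, list[int]] = {}
        order: list[int] = []
        stack = [root]
        while stack:
            u = stack.pop()
            order.append(u)
            kids = [v for v in sorted(self._adj[u]) if v != parent.get(u, -1)]
            children[u] = kids
            for v in kids:
                parent[v] = u
                stack.append(v)
        order.reverse()  # postorder: children before parents
        return root, parent, children, order

    def splice_degree2(self) -> None:
        """Remove unlabelled degree-2 nodes, summing branch lengths."""
        for u in list(self._adj):
            if u in self._adj and self.degree(u) == 2 and self._labels[u] is None:
                a, b = self.neighbors(u)
                la = self._adj[u][a]["length"]
                lb = self._adj[u][b]["length"]
                length = None if la is None and lb is None else (la or 0.0) + (lb or 0.0)
                self.remove_node(u)
                if b not in self._adj[a]:
                    self.add_edge(a, b, length)

    def __repr__(self) -> str:
        return f"<PhyloTree {self.n_leaves()} leaves, {len(self._adj)} nodes>"


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------


def _from_dendropy(dt: dendropy.Tree) -> PhyloTree:
    t = PhyloTree()
    ids: dict[int, int] = {}
    for nd in dt.preorder_node_iter():
        label = nd.taxon.label if nd.taxon is not None else nd.label
        nid = t.new_node(label=label)
        ids[id(nd)] = nid
        if nd.parent_node is not None:
            t.add_edge(ids[id(nd.parent_node)], nid, nd.edge.length)
    t.splice_degree2()
    t.validate()
    return t


def read_newick(path_or_stream) -> PhyloTree:
    """Parse a single Newick tree; underscores are literal (strict dialect)."""
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
    else:
        with open(path_or_stream) as fh:
            text = fh.read()
    return parse_newick(text)


def parse_newick(text: str) -> PhyloTree:
    if ";" not in text:
        raise FormatError("Newick string lacks terminating ';'")
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise FormatError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dt)


def write_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize to Newick; round-trip preserves the unrooted bipartition set."""
    tree.validate()
    root, _parent, children, _order = tree.rooted()

    def fmt_len(x: float | None) -> str:
        return "" if x is None else f":{round(float(x), precision):g}"

    def needs_quote(label: str) -> bool:
        return any(ch in label for ch in " ()[]{}:;,'\t\n")

    def fmt_label(label: str | None) -> str:
        if not label:
            return ""
        if needs_quote(label):
            return "'" + label.replace("'", "''") + "'"
        return label

    def rec(u: int, parent: int) -> str:
        kids = [v for v in children.get(u, []) if v != parent]
        blen = fmt_len(tree.edge_length(parent, u)) if parent != -1 else ""
        if not kids:
            return fmt_label(tree.label(u)) + blen
        inner = ",".join(rec(v, u) for v in kids)
        return "(" + inner + ")" + fmt_label(tree.label(u)) + blen

    return rec(root, -1) + ";"


def write_newick_file(tree: PhyloTree, path_or_stream, precision: int = 6) -> None:
    text = write_newick(tree, precision=precision) + "\n"
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


def tree_from_newick_like(labels: Sequence[str], nested) -> PhyloTree:
    """Build a tree from a nested-tuple topology (testing convenience).

    ``nested`` is a tuple-of-tuples/labels, e.g. ``(("a","b"),("c","d"))``.
    """
    t = PhyloTree()

    def build(spec) -> int:
        if isinstance(spec, str):
            return t.new_node(label=spec)
        u = t.new_node()
        for child in spec:
            v = build(child)
            t.add_edge(u, v)
        return u

    build(nested)
    t.splice_degree2()
    t.validate()
    return t
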