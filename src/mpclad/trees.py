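"""Unrooted phylogenetic trees over matrix taxa.

Trees are stored and compared *unrooted*; tree identity is equality of
non-trivial bipartition (split) sets, which uniquely determines an unrooted
topology.  Rooting on the outgroup is a display / clade-query operation only
— parsimony length is rooting-invariant.  Polytomies (internal nodes of
degree > 3) are allowed; they arise from zero-length-branch collapsing and
from strict consensus.
"""

from __future__ import annotations

import random
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "PhyloTree",
    "read_newick",
    "write_newick",
    "strict_consensus",
    "contains_clade",
    "collapse_zero_length",
    "random_binary_tree",
]


class PhyloTree:
    """Unrooted leaf-labelled tree.

    Internally an undirected adjacency over integer node ids; leaves carry
    string labels.  Construct via :func:`read_newick`,
    :meth:`from_bipartitions`, or :meth:`from_indexed_adjacency`.
    """

    def __init__(self, adj: Mapping[int, Iterable[int]], labels: Mapping[int, str]):
        self._adj: dict[int, tuple[int, ...]] = {
            u: tuple(vs) for u, vs in adj.items()
        }
        self._labels: dict[int, str] = dict(labels)
        for u, vs in self._adj.items():
            for v in vs:
                if u not in self._adj.get(v, ()):
                    raise ValueError("adjacency is not symmetric")
        leaves = {u for u, vs in self._adj.items() if len(vs) <= 1}
        if len(self._adj) == 2:  # degenerate 2-leaf tree
            leaves = set(self._adj)
        if leaves != set(self._labels):
            raise ValueError("labelled nodes must be exactly the leaves")
        if len(set(self._labels.values())) != len(self._labels):
            raise ValueError("duplicate leaf labels")
        self._splits: frozenset[frozenset[str]] | None = None

    # -- basics ------------------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    def is_binary(self) -> bool:
        return all(
            len(vs) in (1, 3) for u, vs in self._adj.items()
        ) or len(self._adj) == 2

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._adj, self._labels)

    def __repr__(self) -> str:
        return f"<PhyloTree {self.n_leaves} leaves: {write_newick(self)}>"

    # -- bipartitions and identity ------------------------------------------

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each given as the side *not* containing the
        lexicographically smallest leaf label."""
        if self._splits is not None:
            return self._splits
        ref = min(self._labels.values())
        n = self.n_leaves
        out = set()
        for u, vs in self._adj.items():
            for v in vs:
                if u < v:
                    side = self._side_labels(v, u)
                    if ref in side:
                        side = set(self._labels.values()) - side
                    if 2 <= len(side) <= n - 2:
                        out.add(frozenset(side))
        self._splits = frozenset(out)
        return self._splits

    def _side_labels(self, start: int, blocked: int) -> set[str]:
        """Leaf labels reachable from ``start`` without crossing ``blocked``."""
        seen = {blocked, start}
        stack = [start]
        labels = set()
        while stack:
            u = stack.pop()
            if u in self._labels:
                labels.add(self._labels[u])
            for v in self._adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return labels

    def same_topology(self, other: "PhyloTree") -> bool:
        return (
            self.leaf_labels == other.leaf_labels
            and self.bipartitions() == other.bipartitions()
        )

    # -- rooted views --------------------------------------------------------

    def rooted_at(self, outgroup: str) -> tuple[int, dict[int, tuple[int, ...]], dict[int, str]]:
        """Directed (children) view rooted on the outgroup's attachment node.

        Returns ``(root, children, labels)`` where ``root`` is the internal
        node adjacent to the outgroup leaf (so the outgroup appears as the
        first child of the root).  For a 2-leaf tree the root is the other
        leaf.
        """
        og = self._node_of(outgroup)
        if len(self._adj) == 2:
            other = self._adj[og][0]
            return other, {other: (og,), og: ()}, dict(self._labels)
        root = self._adj[og][0]
        children: dict[int, tuple[int, ...]] = {}
        stack = [(root, og)]
        order = [(root, og)]
        while stack:
            u, parent = stack.pop()
            kids = tuple(v for v in self._adj[u] if v != parent)
            if u == root:
                kids = (og,) + kids
            children[u] = kids
            for v in kids:
                if v not in self._labels:
                    stack.append((v, u))
                    order.append((v, u))
                else:
                    children[v] = ()
        return root, children, dict(self._labels)

    def clusters(self, outgroup: str) -> set[frozenset[str]]:
        """Descendant leaf sets of all nodes when rooted on ``outgroup``
        (singletons and the full ingroup included)."""
        root, children, labels = self.rooted_at(outgroup)
        out: set[frozenset[str]] = set()

        def walk(u: int) -> frozenset[str]:
            if u in labels:
                s = frozenset([labels[u]])
            else:
                s = frozenset().union(*(walk(v) for v in children[u]))
            out.add(s)
            return s

        for v in children[root]:
            if v != self._node_of(outgroup):
                walk(v)
        ingroup = frozenset(self._labels.values()) - {outgroup}
        out.add(ingroup)
        out |= {frozenset([l]) for l in self._labels.values()}
        return out

    def _node_of(self, label: str) -> int:
        for u, l in self._labels.items():
            if l == label:
                return u
        raise KeyError(f"no leaf labelled {label!r}")

    # -- conversions ---------------------------------------------------------

    @classmethod
    def from_bipartitions(
        cls, leaf_labels: Iterable[str], splits: Iterable[frozenset[str]]
    ) -> "PhyloTree":
        """Build the (unique) unrooted tree displaying exactly ``splits``.

        ``splits`` must be pairwise compatible and given as sides not
        containing the reference (smallest) label, as produced by
        :meth:`bipartitions`.
        """
        labels = sorted(set(leaf_labels))
        if len(labels) < 2:
            raise ValueError("need at least 2 leaves")
        ref = labels[0]
        clusters = sorted({frozenset(s) for s in splits}, key=len, reverse=True)
        for c in clusters:
            if ref in c or not 2 <= len(c) <= len(labels) - 2:
                raise ValueError(f"invalid split for this leaf set: {sorted(c)}")
        universe = frozenset(labels) - {ref}
        node_of: dict[frozenset[str], int] = {}
        nid = len(labels)
        leaf_id = {l: i for i, l in enumerate(labels)}
        adj: dict[int, set[int]] = {i: set() for i in range(len(labels))}
        root = nid
        adj[root] = set()
        node_of[universe] = root
        nid += 1
        # parent of each cluster = smallest strictly-containing cluster
        chain: list[frozenset[str]] = [universe]
        for c in clusters:
            if c == universe:
                continue
            parent = universe
            for d in clusters:
                if d != c and c < d and (parent == universe or len(d) < len(parent)):
                    if d != universe:
                        parent = d
            node_of[c] = nid
            adj[nid] = set()
            pa = node_of[parent]
            adj[nid].add(pa)
            adj[pa].add(nid)
            nid += 1
        # attach each leaf to the smallest cluster containing it
        for l in labels[1:]:
            best = universe
            for c in clusters:
                if l in c and len(c) < len(best):
                    best = c
            u = leaf_id[l]
            pa = node_of[best]
            adj[u].add(pa)
            adj[pa].add(u)
        adj[leaf_id[ref]].add(root)
        adj[root].add(leaf_id[ref])
        return cls(
            {u: tuple(vs) for u, vs in adj.items()},
            {i: l for l, i in leaf_id.items()},
        )

    @classmethod
    def from_indexed_adjacency(
        cls, adj: Mapping[int, Iterable[int]], taxa: list[str]
    ) -> "PhyloTree":
        """From an adjacency whose leaves are ``0..len(taxa)-1`` in taxon order."""
        return cls(adj, {i: t for i, t in enumerate(taxa)})

    def to_indexed_adjacency(self, taxa: list[str]) -> dict[int, tuple[int, ...]]:
        """Adjacency with leaves renumbered ``0..n-1`` in ``taxa`` order and
        internal nodes ``n..``."""
        if sorted(taxa) != self.leaf_labels:
            raise ValueError("taxa do not match tree leaves")
        mapping: dict[int, int] = {}
        for u, l in self._labels.items():
            mapping[u] = taxa.index(l)
        nxt = len(taxa)
        for u in self._adj:
            if u not in mapping:
                mapping[u] = nxt
                nxt += 1
        return {
            mapping[u]: tuple(mapping[v] for v in vs)
            for u, vs in self._adj.items()
        }


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy)
# ---------------------------------------------------------------------------

def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into an unrooted :class:`PhyloTree`.

    A rooted (degree-2 root) input is unrooted by suppressing the root node;
    polytomies are preserved.  Branch lengths and internal labels are
    ignored — only topology is kept.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    adj: dict[int, set[int]] = {}
    labels: dict[int, str] = {}
    ids: dict[object, int] = {}

    def nid(node) -> int:
        if node not in ids:
            ids[node] = len(ids)
            adj[ids[node]] = set()
        return ids[node]

    for edge in dtree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        u, v = nid(edge.tail_node), nid(edge.head_node)
        adj[u].add(v)
        adj[v].add(u)
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or leaf.taxon.label is None:
            raise ValueError("unlabelled leaf in Newick input")
        labels[nid(leaf)] = leaf.taxon.label
    if not labels:
        raise ValueError("no leaves in Newick input")
    # suppress degree-2 nodes (e.g. a rooted input's root)
    changed = True
    while changed:
        changed = False
        for u in list(adj):
            if u not in labels and len(adj[u]) == 2:
                a, b = adj[u]
                adj[a].discard(u)
                adj[b].discard(u)
                adj[a].add(b)
                adj[b].add(a)
                del adj[u]
                changed = True
    return PhyloTree({u: tuple(vs) for u, vs in adj.items()}, labels)


def write_newick(
    tree: PhyloTree,
    root_on: str | None = None,
    node_labels: Mapping[frozenset[str], str] | None = None,
) -> str:
    """Serialise to Newick, rooted for display on ``root_on`` (default: the
    lexicographically smallest leaf).  ``node_labels`` optionally annotates
    internal nodes, keyed by descendant leaf set (e.g. Bremer support on a
    consensus)."""
    og = root_on if root_on is not None else tree.leaf_labels[0]
    root, children, labels = tree.rooted_at(og)

    def fmt(u: int) -> tuple[str, frozenset[str]]:
        if u in labels:
            return _escape(labels[u]), frozenset([labels[u]])
        parts, leafset = [], frozenset()
        for v in children[u]:
            s, ls = fmt(v)
            parts.append(s)
            leafset |= ls
        lab = ""
        if node_labels and leafset in node_labels:
            lab = _escape(str(node_labels[leafset]))
        return "(" + ",".join(parts) + ")" + lab, leafset

    if tree.n_leaves == 2:
        a, b = tree.leaf_labels
        return f"({_escape(a)},{_escape(b)});"
    return fmt(root)[0] + ";"


def _escape(label: str) -> str:
    import re

    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


# ---------------------------------------------------------------------------
# Consensus, clade queries, collapsing
# ---------------------------------------------------------------------------

def strict_consensus(trees: Iterable[PhyloTree]) -> PhyloTree:
    """Strict consensus: the tree whose splits are exactly those shared by
    *all* input trees; conflict collapses to polytomy."""
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree set")
    leaves = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != leaves:
            raise ValueError("trees have mismatched leaf sets")
    shared = frozenset.intersection(*(t.bipartitions() for t in trees))
    return PhyloTree.from_bipartitions(leaves, shared)


def contains_clade(tree: PhyloTree, taxa: Iterable[str], outgroup: str) -> bool:
    """True iff ``taxa`` form a clade once the tree is rooted on ``outgroup``."""
    query = frozenset(taxa)
    if outgroup in query:
        raise ValueError("outgroup cannot be part of the queried clade")
    if not query <= set(tree.leaf_labels):
        raise ValueError("queried taxa are not all tree leaves")
    return query in tree.clusters(outgroup)


def collapse_zero_length(tree: PhyloTree, matrix, rule: str = "min") -> PhyloTree:
    """Collapse internal branches of zero length under the given rule.

    Under ``"min"`` (the default) a branch is collapsed when its *minimum*
    number of changes over all most-parsimonious reconstructions is zero
    (i.e. the branch is not unambiguously supported); under ``"max"`` only
    branches whose *maximum* is zero (no reconstruction puts any change on
    them) are collapsed.  Tree length is unchanged by collapsing.
    """
    if rule not in ("min", "max"):
        raise ValueError(f"unknown collapse rule {rule!r} (use 'min' or 'max')")
    from . import parsimony  # deferred: parsimony imports trees

    ranges = parsimony.branch_length_ranges(tree, matrix)
    keep = []
    for split, (lo, hi) in ranges.items():
        if (rule == "min" and lo > 0) or (rule == "max" and hi > 0):
            keep.append(split)
    return PhyloTree.from_bipartitions(tree.leaf_labels, keep)


# ---------------------------------------------------------------------------
# Random trees (testing / simulation)
# ---------------------------------------------------------------------------

def random_binary_tree(labels: list[str], rng: random.Random) -> PhyloTree:
    """Uniform-ish random unrooted binary tree via sequential random addition."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    if len(labels) == 2:
        return PhyloTree({0: (1,), 1: (0,)}, {0: labels[0], 1: labels[1]})
    order = list(range(len(labels)))
    rng.shuffle(order)
    n = len(labels)
    adj: dict[int, set[int]] = {order[0]: set(), order[1]: set(), order[2]: set()}
    centre = n
    adj[centre] = {order[0], order[1], order[2]}
    for i in order[:3]:
        adj[i] = {centre}
    nxt = n + 1
    edges = [(order[0], centre), (order[1], centre), (order[2], centre)]
    for leaf in order[3:]:
        u, v = edges[rng.randrange(len(edges))]
        w = nxt
        nxt += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[w] = {u, v, leaf}
        adj[u].add(w)
        adj[v].add(w)
        adj[leaf] = {w}
        edges.remove((u, v))
        edges += [(u, w), (v, w), (leaf, w)]
    return PhyloTree(
        {u: tuple(vs) for u, vs in adj.items()},
        {i: l for i, l in enumerate(labels)},
    )
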