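"""Diversity gate: identity distances, neighbor-joining, clustering.

The diversity stage keeps the experimental shortlist spread out in sequence
space: candidates are clustered on a neighbor-joining tree built from
pairwise global-alignment identity distances, one representative is kept
per cluster, and a patent-similarity cap rejects candidates too close to
the marketed reference drug.

Neighbor-joining is used for the tree: the tree's only role here is
clustering and representative selection, for which a distance-based method
with deterministic tie-breaking is sufficient and exactly reproducible
(it also recovers any additive metric without error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .peptide import AlignmentResult, PeptideRecord, global_align
from .stability import GateResult

__all__ = [
    "DistanceMatrix", "TreeNode", "PhyloTree", "ClusterSet",
    "identity_distance_matrix", "nj_tree", "write_newick", "read_newick",
    "cut_clusters", "select_representatives", "patent_gate",
    "tree_distance",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.ids)
        if n < 2:
            raise ValueError("need at least 2 ids")
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")
        if np.any(m < -1e-12):
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.matrix[i, j])


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Leaf-labeled tree with branch lengths; the unrooted NJ topology is
    canonicalized by a trifurcating root."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]


@dataclass(frozen=True)
class ClusterSet:
    """A partition of leaf ids, tagged with the cut method and parameter."""

    blocks: tuple[frozenset[str], ...]
    method: str
    parameter: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for block in self.blocks:
            if block & seen:
                raise ValueError("cluster blocks overlap")
            seen |= block


# --------------------------------------------------------------------------
# Distances

def identity_distance_matrix(records: list[PeptideRecord],
                             substitution=None, gap_penalty: float = 1.0,
                             correction: str = "none") -> DistanceMatrix:
    """Pairwise ``1 - identity`` distances from global alignments.

    ``correction="poisson"`` applies the multiple-hit correction
    ``-ln(1 - p)`` (a Jukes–Cantor-style stretch of large distances).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    if correction not in ("none", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    n = len(records)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln: AlignmentResult = global_align(records[i], records[j],
                                                substitution, gap_penalty)
            d = 1.0 - aln.identity
            if correction == "poisson":
                d = -math.log(max(1.0 - d, 1e-9))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(tuple(r.id for r in records), m)


# --------------------------------------------------------------------------
# Neighbor joining

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, moving the deficit to the
    sibling so the pair sum is preserved."""
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbor-joining with deterministic tie-breaking.

    The Q-matrix minimum is selected; ties break on the lexicographically
    lowest pair of cluster labels (a cluster's label is its smallest leaf
    id).  The final three clusters are joined at a trifurcating root by
    the three-point formulas; two taxa yield a single split edge.
    """
    ids = list(dm.ids)
    n = len(ids)
    nodes: dict[int, TreeNode] = {i: TreeNode(name=ids[i])
                                  for i in range(n)}
    labels: dict[int, str] = {i: ids[i] for i in range(n)}
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dm.matrix[i, j])

    def dist(i: int, j: int) -> float:
        return d[(i, j)] if i < j else d[(j, i)]

    active = list(range(n))
    next_id = n

    if n == 2:
        half = dist(0, 1) / 2.0
        a, b = nodes[0], nodes[1]
        a.length = b.length = half
        return PhyloTree(TreeNode(children=[a, b]))

    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(dist(i, k) for k in active if k != i)
                   for i in active}
        best = None
        best_key = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist(i, j) - row_sum[i] - row_sum[j]
                pair_label = tuple(sorted((labels[i], labels[j])))
                key = (q, pair_label)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best
        dij = dist(i, j)
        li = dij / 2.0 + (row_sum[i] - row_sum[j]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        u = next_id
        next_id += 1
        nodes[u] = parent
        labels[u] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            duk = (dist(i, k) + dist(j, k) - dij) / 2.0
            d[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    # Trifurcating root from the last three clusters (three-point formulas).
    i, j, k = sorted(active, key=lambda x: labels[x])
    dij, dik, djk = dist(i, j), dist(i, k), dist(j, k)
    nodes[i].length = max((dij + dik - djk) / 2.0, 0.0)
    nodes[j].length = max((dij + djk - dik) / 2.0, 0.0)
    nodes[k].length = max((dik + djk - dij) / 2.0, 0.0)
    return PhyloTree(TreeNode(children=[nodes[i], nodes[j], nodes[k]]))


# --------------------------------------------------------------------------
# Newick I/O

def _format_label(name: str) -> str:
    if any(c in name for c in " \t()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths to 6 decimals; labels needing it are
    single-quoted."""

    def fmt(node: TreeNode, with_length: bool = True) -> str:
        if node.is_leaf:
            body = _format_label(node.name or "")
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        return body + (f":{node.length:.6f}" if with_length else "")

    return ("(" + ",".join(fmt(c) for c in tree.root.children) + ");"
            if tree.root.children else
            _format_label(tree.root.name or "") + ";")


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string with branch lengths.

    Raises on unbalanced parentheses, trailing garbage and duplicate leaf
    labels.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> ValueError:
        return ValueError(f"Newick parse error at {pos}: {msg}")

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            raise error("unterminated quoted label")
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            label = parse_label()
            if label:
                node.name = label
        else:
            label = parse_label()
            if not label:
                raise error("empty leaf label")
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise error(f"bad branch length {s[start:pos]!r}") from None
        return node

    root = parse_node()
    if pos != len(s):
        raise error("trailing characters (unbalanced parentheses?)")
    tree = PhyloTree(root)
    names = tree.leaf_names()
    dups = {x for x in names if names.count(x) > 1}
    if dups:
        raise ValueError(f"duplicate leaf labels {sorted(dups)}")
    return tree


# --------------------------------------------------------------------------
# Clustering and representative selection

def _edges(tree: PhyloTree) -> list[tuple[int, int, float, int]]:
    """(parent idx, child idx, length, preorder rank) for every edge."""
    index: dict[int, int] = {}
    order: list[TreeNode] = []

    def walk(node: TreeNode) -> None:
        index[id(node)] = len(order)
        order.append(node)
        for c in node.children:
            walk(c)

    walk(tree.root)
    out = []
    rank = 0
    for node in order:
        for c in node.children:
            out.append((index[id(node)], index[id(c)], c.length, rank))
            rank += 1
    return out


def cut_clusters(tree: PhyloTree, k: int) -> ClusterSet:
    """Cut the tree into exactly ``k`` leaf clusters.

    Edges are removed greedily in order of decreasing branch length (ties
    broken by canonical preorder), skipping removals that do not separate
    leaf components, until ``k`` components each containing leaves remain.
    Cuts are nested: the clusters at ``k+1`` refine those at ``k``.
    """
    leaves = tree.leaf_names()
    n = len(leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")

    # node indexing
    nodes: list[TreeNode] = []

    def walk(node: TreeNode) -> None:
        nodes.append(node)
        for c in node.children:
            walk(c)

    walk(tree.root)
    idx = {id(node): i for i, node in enumerate(nodes)}
    edges = []
    for i, node in enumerate(nodes):
        for c in node.children:
            edges.append((i, idx[id(c)], c.length))
    order = sorted(range(len(edges)),
                   key=lambda e: (-edges[e][2], e))

    removed: set[int] = set()

    def leaf_components() -> list[set[str]]:
        adj: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
        for e, (p, c, _) in enumerate(edges):
            if e not in removed:
                adj[p].append(c)
                adj[c].append(p)
        seen: set[int] = set()
        comps: list[set[str]] = []
        for start in range(len(nodes)):
            if start in seen:
                continue
            stack = [start]
            seen.add(start)
            comp: set[str] = set()
            while stack:
                v = stack.pop()
                if nodes[v].is_leaf and nodes[v].name is not None:
                    comp.add(nodes[v].name)
                for w in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            if comp:
                comps.append(comp)
        return comps

    count = 1
    for e in order:
        if count >= k:
            break
        removed.add(e)
        comps = leaf_components()
        if len(comps) > count:
            count = len(comps)
        else:
            removed.discard(e)
    blocks = tuple(frozenset(c) for c in
                   sorted(leaf_components(), key=lambda c: min(c)))
    return ClusterSet(blocks, method="k-cut", parameter=float(k))


def select_representatives(clusters: ClusterSet, rule: str = "max_recovery",
                           recovery: dict[str, float] | None = None,
                           distances: DistanceMatrix | None = None
                           ) -> list[str]:
    """Pick exactly one id per cluster, deterministically.

    Rules: ``max_recovery`` keeps the member with the highest template
    recovery (requires the ``recovery`` map), ``medoid`` the member with
    the lowest total distance to its cluster mates (requires
    ``distances``), ``first`` the lexicographically smallest id.  All ties
    break to the lexicographically smallest id.
    """
    if rule not in ("max_recovery", "medoid", "first"):
        raise ValueError(f"unknown representative rule {rule!r}")
    out: list[str] = []
    for block in clusters.blocks:
        if not block:
            raise ValueError("empty cluster")
        members = sorted(block)
        if rule == "first":
            out.append(members[0])
        elif rule == "max_recovery":
            if recovery is None:
                raise ValueError("max_recovery rule needs recovery values")
            out.append(min(members, key=lambda m: (-recovery[m], m)))
        else:
            if distances is None:
                raise ValueError("medoid rule needs a distance matrix")
            out.append(min(
                members,
                key=lambda m: (sum(distances.get(m, o) for o in members
                                   if o != m), m),
            ))
    return out


def patent_gate(record: PeptideRecord, reference: PeptideRecord,
                max_identity: float = 0.90) -> GateResult:
    """Fail when global-alignment identity to the reference drug reaches
    the patent cap (``identity >= max_identity``)."""
    if not 0.0 < max_identity <= 1.0:
        raise ValueError("max_identity must be in (0, 1]")
    identity = global_align(record, reference).identity
    if identity >= max_identity:
        return GateResult(False, (("patent_identity", identity,
                                   max_identity),))
    return GateResult(True)


def tree_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique leaf-to-leaf path."""
    parent: dict[int, TreeNode | None] = {}
    found: dict[str, TreeNode] = {}

    def walk(node: TreeNode, par: TreeNode | None) -> None:
        parent[id(node)] = par
        if node.is_leaf and node.name is not None:
            found[node.name] = node
        for c in node.children:
            walk(c, node)

    walk(tree.root, None)
    for name in (a, b):
        if name not in found:
            raise KeyError(f"leaf {name!r} not in tree")
    if a == b:
        return 0.0

    def path_to_root(node: TreeNode) -> list[TreeNode]:
        out = [node]
        while parent[id(out[-1])] is not None:
            out.append(parent[id(out[-1])])
        return out

    pa = path_to_root(found[a])
    pb = path_to_root(found[b])
    ancestors_a = {id(n): i for i, n in enumerate(pa)}
    for n in pb:
        if id(n) in ancestors_a:
            lca = n
            break
    total = 0.0
    for node in pa:
        if node is lca:
            break
        total += node.length
    for node in pb:
        if node is lca:
            break
        total += node.length
    return total
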