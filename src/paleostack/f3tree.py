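"""Outgroup-f3 distance trees: 1/f3 distances, neighbor joining, Grafen heights.

Outgroup-f3(A, B; O) measures the drift shared by A and B since their
divergence from the outgroup, so its inverse behaves as a distance.  The
tree is built with classic neighbor joining (Q-criterion, Saitou-Nei branch
lengths, ties broken by lexicographic label order), rooted on the outgroup's
pendant edge, and — for visualization — node heights are replaced by
Grafen's transform (height proportional to descendant-tip count, tips at 0,
root at 1) followed by a power transform of the heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "TreeNode", "f3_to_distance", "neighbor_joining",
           "root_and_transform", "to_newick"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.D < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0             # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)
    height: float | None = None

    def tips(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [t for c in self.children for t in c.tips()]

    def is_tip(self) -> bool:
        return not self.children


def f3_to_distance(f3_table: pd.DataFrame) -> DistanceMatrix:
    """Build D[i, j] = 1 / f3(i, j; outgroup) from a table with columns
    pop_a, pop_b, f3.  Non-positive f3 values are an error naming the pair."""
    labels = sorted(set(f3_table["pop_a"]) | set(f3_table["pop_b"]))
    idx = {l: k for k, l in enumerate(labels)}
    D = np.zeros((len(labels), len(labels)))
    for row in f3_table.itertuples(index=False):
        if row.pop_a == row.pop_b:
            continue
        if row.f3 <= 0:
            raise ValueError(f"non-positive f3 for pair ({row.pop_a}, {row.pop_b})")
        d = 1.0 / row.f3
        D[idx[row.pop_a], idx[row.pop_b]] = d
        D[idx[row.pop_b], idx[row.pop_a]] = d
    return DistanceMatrix(labels, D)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic NJ; tie-break on the Q criterion by lexicographic label pair.

    Returns an unrooted tree represented with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=l) for l in dm.labels]
    # sort key per working node: smallest tip label under it, for tie-breaking
    keys = list(dm.labels)
    D = dm.D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = np.array([sum(D[i][j] for j in active if j != i) for i in active])
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i][j] - r[ai] - r[aj]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        ri = sum(D[i][k] for k in active if k != i)
        rj = sum(D[j][k] for k in active if k != j)
        li = 0.5 * D[i][j] + (ri - rj) / (2 * (m - 2))
        lj = D[i][j] - li
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        Dnew = {k: 0.5 * (D[i][k] + D[j][k] - D[i][j]) for k in active if k not in (i, j)}
        # grow matrix: reuse slot i for the new node
        for k, v in Dnew.items():
            D[i][k] = D[k][i] = v
        nodes[i] = new
        keys[i] = min(keys[i], keys[j])
        active.remove(j)
    # join the final three nodes at a trifurcation
    i, j, k = active
    nodes[i].length = 0.5 * (D[i][j] + D[i][k] - D[j][k])
    nodes[j].length = 0.5 * (D[i][j] + D[j][k] - D[i][k])
    nodes[k].length = 0.5 * (D[i][k] + D[j][k] - D[i][j])
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def root_and_transform(tree: TreeNode, outgroup: str, grafen: bool = True,
                       exponent: float = 0.5) -> TreeNode:
    """Root on the midpoint of the outgroup's pendant edge, then (optionally)
    apply Grafen's height transform followed by a power transform.

    After Grafen, tips sit at height 0 and the root at height 1 (heights are
    (descendant tips - 1)/(total tips - 1) raised to ``exponent``); branch
    lengths are rewritten as parent height - child height, so the tree is
    ultrametric.
    """
    rooted = _reroot_at_tip_edge(tree, outgroup)
    if grafen:
        total = len(rooted.tips())
        _grafen_heights(rooted, total, exponent)
        _heights_to_lengths(rooted, parent_height=rooted.height)
    return rooted


def _reroot_at_tip_edge(tree: TreeNode, outgroup: str) -> TreeNode:
    """Reroot on the midpoint of the outgroup's pendant edge.

    The tree is flattened to an undirected weighted graph, a new root node is
    inserted in the middle of the outgroup edge, and a fresh rooted tree is
    rebuilt by traversal.
    """
    nodes: list[TreeNode] = []
    adj: dict[int, list[tuple[int, float]]] = {}

    def collect(n: TreeNode) -> int:
        u = len(nodes)
        nodes.append(n)
        adj[u] = []
        for c in n.children:
            v = collect(c)
            adj[u].append((v, c.length))
            adj[v].append((u, c.length))
        return u

    collect(tree)
    try:
        o = next(u for u, n in enumerate(nodes) if n.is_tip() and n.name == outgroup)
    except StopIteration:
        raise ValueError(f"outgroup {outgroup!r} is not a tip of the tree") from None
    (p, length), = adj[o]
    root = len(nodes)
    nodes.append(TreeNode())
    adj[o] = [(root, length / 2.0)]
    adj[p] = [(v, l) for v, l in adj[p] if v != o] + [(root, length / 2.0)]
    adj[root] = [(o, length / 2.0), (p, length / 2.0)]

    def build(u: int, parent: int, blen: float) -> TreeNode:
        n = nodes[u]
        out = TreeNode(name=n.name if n.is_tip() else None, length=blen)
        for v, l in adj[u]:
            if v != parent:
                out.children.append(build(v, u, l))
        return out

    return build(root, -1, 0.0)


def _grafen_heights(node: TreeNode, total_tips: int, exponent: float) -> int:
    """Set node.height = ((descendant tips - 1)/(total - 1)) ** exponent."""
    if node.is_tip():
        node.height = 0.0
        return 1
    n = sum(_grafen_heights(c, total_tips, exponent) for c in node.children)
    node.height = ((n - 1) / (total_tips - 1)) ** exponent if total_tips > 1 else 0.0
    return n


def _heights_to_lengths(node: TreeNode, parent_height: float) -> None:
    for c in node.children:
        c.length = max(node.height - (c.height if c.height is not None else 0.0), 0.0)
        _heights_to_lengths(c, node.height)


def to_newick(node: TreeNode, with_lengths: bool = True) -> str:
    def rec(n: TreeNode) -> str:
        if n.is_tip():
            s = n.name or ""
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")" + (n.name or "")
        if with_lengths:
            s += f":{n.length:.6g}"
        return s
    return "(" + ",".join(rec(c) for c in node.children) + ");"
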