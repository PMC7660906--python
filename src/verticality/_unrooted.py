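"""Unrooted adjacency view over a dendropy tree.

Split-based operations (monophyly, sisters, MAD) are defined on the
unrooted topology.  This view exposes the tree as an undirected graph with
degree-2 nodes (e.g. a bifurcating Newick "root") suppressed, so that every
remaining edge is a genuine unrooted branch.
"""

from __future__ import annotations

from typing import Hashable, Iterator

import numpy as np

from .core_io import GeneTree

__all__ = ["UnrootedView"]


class UnrootedView:
    """Undirected, length-weighted view of a gene tree.

    Nodes are opaque hashables (dendropy nodes, or synthetic merge points);
    leaves are identified by their labels.
    """

    def __init__(self, gt: GeneTree):
        self.gt = gt
        adj: dict[Hashable, list[tuple[Hashable, float]]] = {}
        leaf_of: dict[Hashable, str] = {}
        for edge in gt.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = edge.tail_node, edge.head_node
            w = float(edge.length) if edge.length is not None else 0.0
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
        for lf in gt.tree.leaf_node_iter():
            leaf_of[lf] = lf.taxon.label
        if not adj:  # single-node tree
            for lf in gt.tree.leaf_node_iter():
                adj.setdefault(lf, [])
        self._suppress_degree_two(adj, leaf_of)
        self.adj = adj
        self.leaf_of = leaf_of
        self.leaves = sorted(leaf_of.values())
        self.leaf_index = {l: i for i, l in enumerate(self.leaves)}
        self._node_of_leaf = {lab: nd for nd, lab in leaf_of.items()}

    @staticmethod
    def _suppress_degree_two(adj, leaf_of) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(adj):
                if node in leaf_of or len(adj[node]) != 2:
                    continue
                (a, wa), (b, wb) = adj[node]
                if a is b:  # pathological loop; leave alone
                    continue
                adj[a] = [(n, w) for n, w in adj[a] if n is not node]
                adj[b] = [(n, w) for n, w in adj[b] if n is not node]
                adj[a].append((b, wa + wb))
                adj[b].append((a, wa + wb))
                del adj[node]
                changed = True

    # -- topology ---------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_of_leaf(self, label: str) -> Hashable:
        return self._node_of_leaf[label]

    def neighbors(self, node) -> list[tuple[Hashable, float]]:
        return self.adj[node]

    def edges(self) -> Iterator[tuple[Hashable, Hashable, float]]:
        """Each undirected edge once, as (u, v, length)."""
        seen = set()
        for u, nbrs in self.adj.items():
            for v, w in nbrs:
                key = (id(u), id(v)) if id(u) < id(v) else (id(v), id(u))
                if key in seen:
                    continue
                seen.add(key)
                yield u, v, w

    def leafset_beyond(self, frm, to) -> frozenset[str]:
        """Labels of leaves reachable from ``to`` without crossing ``frm``."""
        out: list[str] = []
        stack = [(frm, to)]
        while stack:
            parent, node = stack.pop()
            if node in self.leaf_of:
                out.append(self.leaf_of[node])
            for nbr, _ in self.adj[node]:
                if nbr is not parent:
                    stack.append((node, nbr))
        return frozenset(out)

    def separating_edge(self, leafset: frozenset[str]):
        """Directed edge (u, v, length) with ``leafset`` strictly beyond v,
        or None if no edge separates it."""
        for u, v, w in self.edges():
            side = self.leafset_beyond(u, v)
            if side == leafset:
                return u, v, w
            if self.leafset_beyond(v, u) == leafset:
                return v, u, w
        return None

    def subgroups(self, leafset: frozenset[str]) -> list[frozenset[str]]:
        """Maximal subtrees whose leaves all belong to ``leafset``.

        On the unrooted topology: a subgroup is one side of an edge composed
        purely of ``leafset`` leaves and not contained in a larger such side.
        If ``leafset`` covers every leaf the whole tree is one subgroup.
        """
        leafset = frozenset(leafset)
        if not leafset:
            return []
        all_leaves = frozenset(self.leaves)
        if not leafset <= all_leaves:
            missing = sorted(leafset - all_leaves)
            raise ValueError(f"leaves not in tree: {missing}")
        if leafset == all_leaves:
            return [leafset]
        ref = self._node_of_leaf[min(all_leaves - leafset)]

        pure_cache: dict[tuple[int, int], bool] = {}

        def pure(parent, node) -> bool:
            key = (id(parent), id(node))
            if key not in pure_cache:
                if node in self.leaf_of:
                    val = self.leaf_of[node] in leafset
                else:
                    val = all(
                        pure(node, nbr)
                        for nbr, _ in self.adj[node]
                        if nbr is not parent
                    )
                pure_cache[key] = val
            return pure_cache[key]

        groups: list[frozenset[str]] = []
        stack = [(None, ref)]
        while stack:
            parent, node = stack.pop()
            for nbr, _ in self.adj[node]:
                if nbr is parent:
                    continue
                if pure(node, nbr):
                    groups.append(self.leafset_beyond(node, nbr))
                else:
                    stack.append((node, nbr))
        return groups

    def is_monophyletic(self, leafset: frozenset[str]) -> bool:
        return len(self.subgroups(leafset)) == 1

    # -- metrics ----------------------------------------------------------

    def node_leaf_distances(self) -> dict[Hashable, np.ndarray]:
        """Path length from every node to every leaf (leaf order =
        ``self.leaves``)."""
        dists: dict[Hashable, np.ndarray] = {
            node: np.full(self.n_leaves, np.nan) for node in self.adj
        }
        for label in self.leaves:
            i = self.leaf_index[label]
            start = self._node_of_leaf[label]
            dists[start][i] = 0.0
            stack = [(None, start, 0.0)]
            while stack:
                parent, node, acc = stack.pop()
                for nbr, w in self.adj[node]:
                    if nbr is parent:
                        continue
                    dists[nbr][i] = acc + w
                    stack.append((node, nbr, acc + w))
        return dists

    def leaf_distance_matrix(self) -> np.ndarray:
        nld = self.node_leaf_distances()
        D = np.zeros((self.n_leaves, self.n_leaves))
        for label in self.leaves:
            D[self.leaf_index[label]] = nld[self._node_of_leaf[label]]
        return D
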