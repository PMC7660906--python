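"""Independent brute-force oracles.

Each oracle recomputes a quantity through a different route (dendropy
bipartition encodings, networkx shortest paths, exhaustive enumeration)
than the implementation it checks.
"""

from __future__ import annotations

import itertools

import dendropy
import networkx as nx
import numpy as np

from verticality import GeneTree


# -- monophyly via dendropy bipartition encoding --------------------------


def oracle_is_monophyletic(gt: GeneTree, leafset: frozenset[str]) -> bool:
    """A leaf set is monophyletic on the unrooted tree iff some edge's
    bipartition equals (leafset, complement)."""
    tree = dendropy.Tree.get(
        data=gt.as_newick(), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    tree.encode_bipartitions()
    ns = tree.taxon_namespace
    target = ns.taxa_bitmask(labels=leafset)
    full = ns.all_taxa_bitmask()
    for bip in tree.bipartition_encoding:
        mask = bip.leafset_bitmask
        if mask == target or mask == (full & ~target):
            return True
    return False


# -- graph-based helpers (networkx) ---------------------------------------


def tree_graph(gt: GeneTree) -> tuple[nx.Graph, dict[str, object]]:
    """Undirected graph over dendropy nodes with degree-2 nodes contracted
    away (independent contraction code from the package's view)."""
    g = nx.Graph()
    leaf_nodes = {}
    for edge in gt.tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(edge.tail_node, edge.head_node, length=edge.length or 0.0)
    for lf in gt.tree.leaf_node_iter():
        leaf_nodes[lf.taxon.label] = lf
    done = False
    while not done:
        done = True
        for node in list(g.nodes):
            if g.degree(node) == 2 and node not in leaf_nodes.values():
                (a, b) = list(g.neighbors(node))
                w = g[node][a]["length"] + g[node][b]["length"]
                g.remove_node(node)
                g.add_edge(a, b, length=w)
                done = False
    return g, leaf_nodes


def oracle_clade_sister(gt: GeneTree, clade: frozenset[str]):
    """Scan all edges for the separating edge, then all edges adjacent to
    the attachment node, picking the smallest-branch subtree (ties: fewer
    leaves, then smallest name)."""
    g, leaf_nodes = tree_graph(gt)
    labels = set(leaf_nodes)

    def side(u, v):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, v)
        return frozenset(l for l in labels if leaf_nodes[l] in comp)

    attachment = None
    for u, v in g.edges:
        if side(u, v) == clade:
            attachment = u
            break
        if side(v, u) == clade:
            attachment = v
            break
    assert attachment is not None, "clade not edge-separated"
    if attachment in leaf_nodes.values():
        label = next(l for l, n in leaf_nodes.items() if n is attachment)
        return frozenset({label})
    cands = []
    for nbr in g.neighbors(attachment):
        s = side(attachment, nbr)
        if s == clade:
            continue
        cands.append((g[attachment][nbr]["length"], len(s), min(s), s))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    return cands[0][3]


# -- MAD grid search ------------------------------------------------------


def oracle_mad_min_scores(
    gt: GeneTree, grid_step: float = 1e-4
) -> dict[frozenset[str], float]:
    """Per-branch minimal RMS relative deviation by brute-force grid search
    over the root position, using networkx shortest-path distances and the
    definitional per-pair ancestor (the projection of the candidate root
    onto the pair's path)."""
    g, leaf_nodes = tree_graph(gt)
    labels = sorted(leaf_nodes)
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    n = len(labels)
    D = np.array(
        [[dist[leaf_nodes[a]][leaf_nodes[b]] for b in labels] for a in labels]
    )
    iu = np.triu_indices(n, k=1)
    valid = D[iu] > 0
    rhos = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    out = {}
    for u, v in g.edges:
        w = g[u][v]["length"]
        h = g.copy()
        h.remove_edge(u, v)
        comp_v = nx.node_connected_component(h, v)
        side_v = frozenset(l for l in labels if leaf_nodes[l] in comp_v)
        dv = np.array([dist[v][leaf_nodes[l]] for l in labels])
        du = np.array([dist[u][leaf_nodes[l]] for l in labels])
        on_v = np.array([l in side_v for l in labels])
        # root-to-leaf distances for every grid position: (R, n)
        dR = np.where(
            on_v[None, :],
            dv[None, :] + rhos[:, None] * w,
            du[None, :] + (1 - rhos[:, None]) * w,
        )
        # ancestor depth on the i-j path = (dR_i + d_ij - dR_j) / 2
        anc = 0.5 * (dR[:, iu[0]] + D[iu][None, :] - dR[:, iu[1]])
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.abs(2.0 * anc / D[iu][None, :] - 1.0)
        scores = np.sqrt(np.mean(r[:, valid] ** 2, axis=1))
        out[side_v] = float(scores.min())
    return out


def oracle_root_to_tip_mean(gt: GeneTree) -> float:
    g = nx.Graph()
    for edge in gt.tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(edge.tail_node, edge.head_node, length=edge.length or 0.0)
    root = gt.tree.seed_node
    dist = nx.single_source_dijkstra_path_length(g, root, weight="length")
    leaves = [lf for lf in gt.tree.leaf_node_iter()]
    return float(np.mean([dist[lf] for lf in leaves]))


# -- duplication cherries via exhaustive MRCA enumeration ------------------


def oracle_terminal_duplications(gt: GeneTree) -> set[tuple[str, str, str]]:
    """Pairs of same-genome leaves whose rooted MRCA contains exactly the
    two of them."""
    tree = dendropy.Tree.get(
        data=gt.as_newick(), schema="newick", preserve_underscores=True
    )
    leaves = list(tree.leaf_node_iter())
    pairs = set()
    pdm = tree.phylogenetic_distance_matrix()
    for a, b in itertools.combinations(leaves, 2):
        mrca = pdm.mrca(a.taxon, b.taxon)
        below = {lf.taxon.label for lf in mrca.leaf_iter()}
        if below == {a.taxon.label, b.taxon.label}:
            ga = gt.genome_of_leaf(a.taxon.label)
            gb = gt.genome_of_leaf(b.taxon.label)
            if ga == gb:
                x, y = sorted((a.taxon.label, b.taxon.label))
                pairs.add((x, y, ga))
    return pairs


# -- exact RELL enumeration ------------------------------------------------


def oracle_exact_kh(diff: np.ndarray) -> float:
    """Exact KH p over all S^S equally weighted site resamples (small S)."""
    s = len(diff)
    delta = float(diff.sum())
    reps = np.array(
        [sum(diff[list(idx)]) for idx in itertools.product(range(s), repeat=s)]
    )
    centered = reps - reps.mean()
    return float((centered <= delta).mean())


def oracle_exact_sh(matrix: np.ndarray) -> np.ndarray:
    """Exact SH p-values over all S^S resamples (small S), per-tree
    centering."""
    t, s = matrix.shape
    totals = matrix.sum(axis=1)
    deltas = totals.max() - totals
    reps = np.array(
        [
            matrix[:, list(idx)].sum(axis=1)
            for idx in itertools.product(range(s), repeat=s)
        ]
    )  # (S^S, T)
    centered = reps - reps.mean(axis=0, keepdims=True)
    excess = centered.max(axis=1, keepdims=True) - centered
    return (excess >= deltas[None, :]).mean(axis=0)
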