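"""Minimal Ancestor Deviation (MAD) rooting.

MAD places the root at the point on the tree that minimizes the
root-mean-square *relative deviation* of inferred ancestors from pairwise
midpoints.  For a candidate root R and leaf pair (i, j) with path distance
d_ij, the induced ancestor is the projection of R onto the i–j path and the
deviation is

    r_ij = | 2 d(anc, i) / d_ij  -  1 |  =  | d_Ri - d_Rj | / d_ij ,

which is 0 when R sees i and j as perfectly clock-like and symmetric in i
and j.  For each branch the optimal interior position rho has a closed
form; the branch attaining the global minimum RMS hosts the root.

Trees whose two best branches score within a relative tolerance are flagged
ambiguous (downstream analyses that depend on the root discard them).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._unrooted import UnrootedView
from .core_io import GeneTree

logger = logging.getLogger(__name__)

__all__ = ["MADResult", "mad_root", "mean_root_to_tip"]

#: two candidate root branches closer than this (relative) => ambiguous
DEFAULT_AMBIGUITY_TOLERANCE = 1e-6


@dataclass
class MADResult:
    rooted_tree: GeneTree
    best_branch: frozenset[str]  # leafset of the child side of the root branch
    rho: float  # root position, as fraction of the branch from the child end
    score: float  # minimal RMS relative deviation
    branch_scores: dict[frozenset[str], float] = field(default_factory=dict)
    ambiguous: bool = False
    ambiguity_ratio: float = math.inf  # (second best - best) / best


def _branch_stats(D, dv, du, A, B, d_edge, valid):
    """(rho_hat, rms score) for one branch.

    D: full leaf distance matrix; dv/du: distances from the two branch
    endpoints to every leaf; A/B: leaf index arrays of the child/parent
    sides; valid: boolean pair mask (False where d_ij == 0).
    """
    # closed-form interior optimum from the cross pairs
    Dab = D[np.ix_(A, B)]
    Vab = valid[np.ix_(A, B)]
    dvi = dv[A][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv2 = np.where(Vab, 1.0 / (Dab * Dab), 0.0)
        numer = np.where(Vab, (Dab - 2.0 * dvi) * inv2, 0.0).sum()
    denom = 2.0 * d_edge * inv2.sum()
    if denom > 0:
        rho = float(np.clip(numer / denom, 0.0, 1.0))
    else:
        rho = 0.0

    dR = np.empty_like(dv)
    dR[A] = dv[A] + rho * d_edge
    dR[B] = du[B] + (1.0 - rho) * d_edge
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(dR[:, None] - dR[None, :]) / D
    iu = np.triu_indices(len(dv), k=1)
    r_pairs = r[iu]
    ok = valid[iu]
    if not ok.any():
        return rho, 0.0
    return rho, float(np.sqrt(np.mean(r_pairs[ok] ** 2)))


def mad_root(
    gt: GeneTree,
    ambiguity_tolerance: float = DEFAULT_AMBIGUITY_TOLERANCE,
) -> MADResult:
    """Root a gene tree by Minimal Ancestor Deviation.

    Returns the rooted tree (a new degree-2 root node splits the winning
    branch at the optimal position), per-branch minimal deviation scores,
    and an ambiguity flag.  Leaf pairs at zero path distance (identical
    sequences) are excluded from the deviation sums.
    """
    if gt.n_leaves < 3:
        raise ValueError("MAD requires at least 3 leaves")
    work = gt.clone()
    work.tree.deroot()
    view = UnrootedView(work)
    D = view.leaf_distance_matrix()
    n = view.n_leaves
    iu = np.triu_indices(n, k=1)
    valid = np.ones_like(D, dtype=bool)
    np.fill_diagonal(valid, False)
    zero_pairs = (D[iu] == 0).sum()
    if zero_pairs:
        logger.warning(
            "tree %s: %d identical-sequence pairs excluded from MAD",
            gt.tree_id or "<anon>",
            zero_pairs,
        )
        valid &= D > 0
    if not valid[iu].any():
        raise ValueError("MAD undefined on zero-length tree")

    nld = view.node_leaf_distances()
    results: list[tuple[float, float, object, object, float]] = []
    branch_scores: dict[frozenset[str], float] = {}
    for u, v, w in view.edges():
        side_v = view.leafset_beyond(u, v)
        A = np.array(sorted(view.leaf_index[l] for l in side_v))
        B = np.array(
            sorted(view.leaf_index[l] for l in set(view.leaves) - side_v)
        )
        rho, score = _branch_stats(D, nld[v], nld[u], A, B, w, valid)
        results.append((score, rho, u, v, w))
        branch_scores[side_v] = score

    results.sort(key=lambda t: t[0])
    best_score, best_rho, bu, bv, bw = results[0]
    if len(results) > 1:
        second = results[1][0]
        denom = best_score if best_score > 0 else 1.0
        ratio = (second - best_score) / denom
    else:
        ratio = math.inf
    ambiguous = ratio < ambiguity_tolerance

    # reroot the working copy on the winning branch: find the dendropy edge
    # whose head node is bv (or bu) — the view preserved node identity
    edge = None
    child_is_v = None
    for e in work.tree.preorder_edge_iter():
        if e.tail_node is None:
            continue
        if e.head_node is bv and e.tail_node is bu:
            edge, child_is_v = e, True
            break
        if e.head_node is bu and e.tail_node is bv:
            edge, child_is_v = e, False
            break
    if edge is None:  # pragma: no cover - defensive
        raise RuntimeError("winning branch not found in tree")
    # rho is the fraction of the branch measured from the *v* end
    rho_child = best_rho if child_is_v else 1.0 - best_rho
    work.tree.reroot_at_edge(
        edge,
        length1=(1.0 - rho_child) * bw,  # toward the old parent
        length2=rho_child * bw,  # toward the old child
        suppress_unifurcations=False,
    )
    rooted = GeneTree(
        tree=work.tree, scheme=gt.scheme, tree_id=gt.tree_id, rooted=True
    )
    return MADResult(
        rooted_tree=rooted,
        best_branch=view.leafset_beyond(bu, bv),
        rho=best_rho,
        score=best_score,
        branch_scores=branch_scores,
        ambiguous=ambiguous,
        ambiguity_ratio=ratio,
    )


def mean_root_to_tip(rooted: GeneTree) -> float:
    """Arithmetic mean of root-to-leaf path lengths."""
    if not rooted.rooted:
        raise ValueError("mean_root_to_tip requires a rooted tree")
    total = 0.0
    n = 0
    for leaf in rooted.tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        total += d
        n += 1
    if n == 0:
        raise ValueError("tree has no leaves")
    return total / n
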