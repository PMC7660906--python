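"""RELL-based tree topology tests and the eukaryote-monophyly workflow.

The Kishino-Hasegawa (KH) and Shimodaira-Hasegawa (SH) tests ask whether a
candidate (e.g. constrained) topology is significantly worse than the best
topology, given the per-site log-likelihoods of every tree on the same
alignment.  Instead of re-optimizing trees, RELL (resampling estimated log
likelihoods) bootstraps the site log-likelihood columns with replacement.

Conventions here: the KH test is one-sided (is the candidate worse than
the reference?), replicate sums are centered at their per-tree replicate
mean, and p-values are clamped below at 1/B so a finite bootstrap never
reports zero.  The AU test is not re-implemented (its multiscale bootstrap
belongs to specialist software); externally computed AU p-values can be
carried alongside in the monophyly decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._unrooted import UnrootedView
from .core_io import GeneTree

__all__ = [
    "SiteLogLikMatrix",
    "TopoTestResult",
    "rell_kh_test",
    "rell_sh_test",
    "topo_test_suite",
    "monophyly_decision",
]

DEFAULT_REPLICATES = 100_000


@dataclass
class SiteLogLikMatrix:
    """Trees x sites matrix of per-site log-likelihoods."""

    tree_ids: list[str]
    matrix: np.ndarray  # shape (T, S)
    best_row: str | None = None  # unconstrained/best tree id (default row 0)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (trees x sites)")
        if len(self.tree_ids) != self.matrix.shape[0]:
            raise ValueError("one tree id per matrix row required")
        if len(self.tree_ids) < 2:
            raise ValueError("need at least 2 trees")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite site log-likelihoods")
        if self.best_row is None:
            self.best_row = self.tree_ids[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, tree_id: str) -> np.ndarray:
        return self.matrix[self.tree_ids.index(tree_id)]

    @classmethod
    def from_tsv(cls, path, best_row: str | None = None) -> "SiteLogLikMatrix":
        ids, rows = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(tree_ids=ids, matrix=np.array(rows), best_row=best_row)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for tid, row in zip(self.tree_ids, self.matrix):
                fh.write(tid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


@dataclass
class TopoTestResult:
    tree_id: str
    delta_lnl: float
    p_kh: float | None = None
    p_sh: float | None = None
    p_au: float | None = None  # externally computed, carried through
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)

    def rejected(self, test: str = "kh") -> bool | None:
        p = getattr(self, f"p_{test}")
        return None if p is None else p <= self.alpha


def _resample_site_weights(
    n_sites: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial site weights for RELL replicates, shape (B, S)."""
    return rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites), size=n_reps)


def rell_kh_test(
    matrix: SiteLogLikMatrix,
    tree_a: str,
    tree_b: str,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    alpha: float = 0.05,
    _weights: np.ndarray | None = None,
) -> TopoTestResult:
    """One-sided KH test of whether ``tree_a`` is significantly worse than
    ``tree_b``.

    delta = sum_s (L_a[s] - L_b[s]); RELL replicates of delta are centered
    at their replicate mean and p is the fraction of centered replicates at
    or below the observed delta, clamped to [1/B, 1].
    """
    if matrix.n_sites < 2:
        raise ValueError("need at least 2 sites")
    diff = matrix.row(tree_a) - matrix.row(tree_b)
    delta = float(diff.sum())
    if _weights is None:
        rng = np.random.default_rng(seed)
        _weights = _resample_site_weights(matrix.n_sites, n_replicates, rng)
    reps = _weights @ diff
    centered = reps - reps.mean()
    b = len(reps)
    p = float(np.clip((centered <= delta).mean(), 1.0 / b, 1.0))
    return TopoTestResult(
        tree_id=tree_a, delta_lnl=delta, p_kh=p, alpha=alpha
    )


def rell_sh_test(
    matrix: SiteLogLikMatrix,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    alpha: float = 0.05,
    _weights: np.ndarray | None = None,
) -> list[TopoTestResult]:
    """SH test of every tree against the best tree in the set.

    For tree t, delta_t = max_k lnL_k - lnL_t; per replicate the resampled
    totals are centered at their per-tree replicate mean, and p_t is the
    fraction of replicates in which max_k centered_k - centered_t reaches
    delta_t.  Simultaneous use of the max makes SH conservative: its
    p-values dominate the pairwise KH p-values.
    """
    if _weights is None:
        rng = np.random.default_rng(seed)
        _weights = _resample_site_weights(matrix.n_sites, n_replicates, rng)
    totals = matrix.matrix.sum(axis=1)
    deltas = totals.max() - totals
    reps = _weights @ matrix.matrix.T  # (B, T)
    centered = reps - reps.mean(axis=0, keepdims=True)
    excess = centered.max(axis=1, keepdims=True) - centered  # (B, T)
    b = len(reps)
    results = []
    for t, tid in enumerate(matrix.tree_ids):
        p = float(np.clip((excess[:, t] >= deltas[t]).mean(), 1.0 / b, 1.0))
        results.append(
            TopoTestResult(
                tree_id=tid, delta_lnl=float(-deltas[t]), p_sh=p, alpha=alpha
            )
        )
    return results


def topo_test_suite(
    matrix: SiteLogLikMatrix,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[TopoTestResult]:
    """KH and SH p-values for every tree against the best row, computed on
    one shared set of RELL replicates."""
    rng = np.random.default_rng(seed)
    weights = _resample_site_weights(matrix.n_sites, n_replicates, rng)
    sh = rell_sh_test(matrix, alpha=alpha, _weights=weights)
    best = matrix.best_row
    out = []
    for res in sh:
        if res.tree_id == best:
            res.p_kh = 1.0
            res.delta_lnl = 0.0
        else:
            kh = rell_kh_test(
                matrix, res.tree_id, best, alpha=alpha, _weights=weights
            )
            res.p_kh = kh.p_kh
            res.delta_lnl = kh.delta_lnl
        out.append(res)
    return out


def monophyly_decision(
    trees: Sequence[GeneTree],
    euk_leaf_sets: Mapping[str, frozenset[str]],
    site_lls: Mapping[str, SiteLogLikMatrix] | None = None,
    alpha: float = 0.05,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
) -> dict:
    """Eukaryote-monophyly census with topology-test follow-up.

    For each tree, test whether the eukaryotic leaves form a split.  For
    non-monophyletic trees with a supplied site log-likelihood matrix
    (best unconstrained tree vs constrained alternatives), run the KH/SH
    suite; monophyly is rejected only when the best constrained tree is
    significantly worse than the unconstrained one (p <= alpha).  Trees
    without a matrix are reported untested.
    """
    site_lls = site_lls or {}
    monophyletic, to_test, untested = [], [], []
    results: dict[str, list[TopoTestResult]] = {}
    rejected: dict[str, dict[str, bool]] = {}
    rng = np.random.default_rng(seed)
    for gt in trees:
        euks = euk_leaf_sets[gt.tree_id]
        if not euks:
            raise ValueError(f"empty eukaryote leaf set for {gt.tree_id}")
        view = UnrootedView(gt)
        if view.is_monophyletic(frozenset(euks)):
            monophyletic.append(gt.tree_id)
            continue
        if gt.tree_id not in site_lls:
            untested.append(gt.tree_id)
            continue
        to_test.append(gt.tree_id)
        matrix = site_lls[gt.tree_id]
        res = topo_test_suite(
            matrix,
            n_replicates=n_replicates,
            seed=int(rng.integers(2**31 - 1)),
            alpha=alpha,
        )
        results[gt.tree_id] = res
        constrained = [r for r in res if r.tree_id != matrix.best_row]
        # the *best* constrained tree carries the decision
        best_c = max(constrained, key=lambda r: r.delta_lnl)
        rejected[gt.tree_id] = {
            "kh": bool(best_c.p_kh <= alpha),
            "sh": bool(best_c.p_sh <= alpha),
        }
    n_tested = len(to_test)
    return {
        "n_trees": len(trees),
        "n_monophyletic": len(monophyletic),
        "monophyletic": monophyletic,
        "tested": to_test,
        "untested": untested,
        "results": results,
        "rejected": rejected,
        "n_rejected_kh": sum(r["kh"] for r in rejected.values()),
        "n_rejected_sh": sum(r["sh"] for r in rejected.values()),
        "n_tested": n_tested,
    }
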