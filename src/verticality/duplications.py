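"""Terminal (genome-specific) gene duplications.

A terminal duplication is a pair of genes from the same genome that are
each other's sole sister in a rooted gene tree — a two-leaf cherry whose
leaves share a genome.  Counted on MAD-rooted trees (trees with ambiguous
roots are skipped), these pairs quantify *recent* duplications, the only
kind distinguishable from transfers without reconciliation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core_io import GeneTree
from .rooting import MADResult

logger = logging.getLogger(__name__)

__all__ = [
    "DuplicationRecord",
    "GenomeDupStats",
    "terminal_duplications",
    "terminal_duplications_batch",
    "tally_duplications",
    "duplication_statistics",
]


@dataclass
class DuplicationRecord:
    tree_id: str
    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    # (leaf_i, leaf_j, genome_id), leaves in sorted order

    def per_genome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, genome in self.pairs:
            counts[genome] = counts.get(genome, 0) + 1
        return counts


@dataclass
class GenomeDupStats:
    genome: str
    total_duplications: int
    genome_size: int | None = None
    fraction: float | None = None  # duplicated genes / genome size


def terminal_duplications(rooted: GeneTree) -> DuplicationRecord:
    """Same-genome reciprocal-sister pairs (cherries) in a rooted tree.

    Larger same-genome clades contribute only their internal two-leaf
    cherries: the unit counted is the pair, not the clade.
    """
    if not rooted.rooted:
        raise ValueError("terminal duplications require a rooted tree")
    record = DuplicationRecord(tree_id=rooted.tree_id)
    for node in rooted.tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            a, b = sorted(c.taxon.label for c in children)
            ga = rooted.genome_of_leaf(a)
            gb = rooted.genome_of_leaf(b)
            if ga == gb:
                record.pairs.append((a, b, ga))
    return record


def terminal_duplications_batch(
    mad_results: Iterable[MADResult],
) -> list[DuplicationRecord]:
    """Apply :func:`terminal_duplications` to unambiguously rooted trees,
    skipping (and logging) trees whose MAD root was ambiguous."""
    records = []
    n_skipped = 0
    for res in mad_results:
        if res.ambiguous:
            n_skipped += 1
            continue
        records.append(terminal_duplications(res.rooted_tree))
    if n_skipped:
        logger.warning("%d trees with ambiguous MAD roots skipped", n_skipped)
    return records


def tally_duplications(
    records: Iterable[DuplicationRecord],
) -> dict[str, int]:
    totals: dict[str, int] = {}
    for rec in records:
        for genome, n in rec.per_genome_counts().items():
            totals[genome] = totals.get(genome, 0) + n
    return totals


def duplication_statistics(
    per_genome_counts: Mapping[str, int],
    genome_sizes: Mapping[str, int] | None = None,
    group_map: Mapping[str, str] | None = None,
    subsample: int | None = None,
    reps: int = 100,
    seed: int | None = None,
):
    """Per-genome and per-group duplication statistics.

    ``per_genome_counts`` maps every genome in the dataset to its terminal
    duplication count — genomes with zero pairs must be present (with 0) so
    that group means divide by the full genome count.  Genome sizes
    (protein counts) enable the per-genome duplicated fraction
    2*pairs/size and its ECDF per group; ``subsample`` repeatedly draws
    that many genomes from each larger group to check that group contrasts
    are not sample-size artefacts.

    Returns a dict with per-genome stats, group means, ECDF tables and
    (optionally) subsampling summaries.
    """
    group_map = group_map or {}
    genome_sizes = genome_sizes or {}
    per_genome: list[GenomeDupStats] = []
    for genome in sorted(per_genome_counts):
        n = per_genome_counts[genome]
        size = genome_sizes.get(genome)
        if size is None:
            if genome_sizes:
                logger.warning("no genome size for %s; fraction omitted", genome)
            frac = None
        else:
            frac = 2.0 * n / size
        per_genome.append(
            GenomeDupStats(
                genome=genome, total_duplications=n, genome_size=size,
                fraction=frac,
            )
        )

    groups: dict[str, list[GenomeDupStats]] = {}
    for gs in per_genome:
        groups.setdefault(group_map.get(gs.genome, "all"), []).append(gs)

    group_means = {
        grp: sum(g.total_duplications for g in members) / len(members)
        for grp, members in groups.items()
    }
    mean_fractions = {}
    ecdfs: dict[str, pd.DataFrame] = {}
    for grp, members in groups.items():
        fracs = np.sort([g.fraction for g in members if g.fraction is not None])
        if len(fracs):
            mean_fractions[grp] = float(np.mean(fracs))
            ecdfs[grp] = pd.DataFrame(
                {
                    "fraction": fracs,
                    "cumulative": np.arange(1, len(fracs) + 1) / len(fracs),
                }
            )

    out = {
        "per_genome": per_genome,
        "group_means": group_means,
        "mean_fractions": mean_fractions,
        "ecdf": ecdfs,
    }

    if subsample is not None and len(groups) >= 1:
        rng = np.random.default_rng(seed)
        sub_means: dict[str, list[float]] = {}
        for grp, members in groups.items():
            if len(members) <= subsample:
                continue
            counts = np.array([g.total_duplications for g in members])
            fracs = np.array(
                [g.fraction if g.fraction is not None else np.nan for g in members]
            )
            have_fracs = not np.isnan(fracs).all()
            means, fmeans = [], []
            for _ in range(reps):
                idx = rng.choice(len(members), size=subsample, replace=False)
                means.append(float(counts[idx].mean()))
                if have_fracs:
                    fmeans.append(float(np.nanmean(fracs[idx])))
            sub_means[grp] = means
            if have_fracs:
                out.setdefault("subsample_fraction_means", {})[grp] = fmeans
        out["subsample_means"] = sub_means
    return out
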