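"""Gene verticality scoring.

The verticality of a gene family measures how consistent its tree is with
strictly vertical (parent-to-offspring) inheritance, read purely at the
tips.  For each higher-order taxon *a* present in an unrooted gene tree,
the monophyly score is

    S_a = n_a / N_a   if the taxon's sequences form a clade (one split side)
    S_a = 0           otherwise,

where n_a is the number of *genomes* of taxon a in the tree and N_a the
number of genomes of taxon a in the whole reference dataset.  The gene
verticality V_g is the sum of S_a over all taxa present; it ranges from 0
(no sampled taxon monophyletic) to the number of taxa present (all taxa
monophyletic and fully sampled).  A distribution-independent variant, the
weighted verticality V_w, multiplies the count of monophyletic taxa by the
tree's mean root-to-tip distance and therefore needs a rooted tree.

Aggregation averages V_g over trees per taxon (taxon verticality, with the
companion fraction P_mono of trees where the taxon is monophyletic) and per
genome (genome verticality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._unrooted import UnrootedView
from .core_io import GeneTree, TaxonMap
from .rooting import mean_root_to_tip

__all__ = [
    "TaxonStatus",
    "MonophylyReport",
    "VerticalityRecord",
    "TaxonSummary",
    "GenomeSummary",
    "ClusterScore",
    "taxon_split_status",
    "gene_verticality",
    "weighted_gene_verticality",
    "score_tree",
    "aggregate_verticality",
    "mean_branch_length",
    "count_rooted_tree_topologies",
    "distribution_correlation",
]

#: mean branch length at or below which a cluster counts as conserved
CONSERVED_THRESHOLD = 0.1


@dataclass
class TaxonStatus:
    taxon: str
    n_genomes: int
    n_sequences: int
    is_monophyletic: bool
    n_subgroups: int
    score: float  # S_a


@dataclass
class MonophylyReport:
    """Per-taxon monophyly of one gene tree."""

    tree_id: str
    statuses: dict[str, TaxonStatus] = field(default_factory=dict)

    def monophyletic_taxa(self) -> list[str]:
        return [t for t, s in self.statuses.items() if s.is_monophyletic]

    @property
    def n_taxa_present(self) -> int:
        return len(self.statuses)


@dataclass
class VerticalityRecord:
    cluster_id: str
    v_g: float
    n_genomes: int
    n_taxa_present: int
    mean_branch_length: float
    conserved: bool
    v_w: float | None = None
    excluded: bool = False  # single-taxon (or under-sampled) cluster


@dataclass
class TaxonSummary:
    taxon: str
    n_trees: int
    n_mono: int
    p_mono: float
    v_avg: float
    v_weighted: float | None = None  # signed mean of V_w (mono +, para -)


@dataclass
class GenomeSummary:
    genome: str
    v_g_avg: float
    n_clusters: int


@dataclass
class ClusterScore:
    """Scoring bundle for one cluster/tree, input to aggregation."""

    cluster_id: str
    record: VerticalityRecord
    report: MonophylyReport
    genomes: frozenset[str]


def taxon_split_status(
    gt: GeneTree,
    taxon_map: TaxonMap,
    score_singletons: bool = True,
) -> MonophylyReport:
    """Monophyly of every taxon present in an unrooted gene tree.

    A taxon is monophyletic iff its sequences occupy exactly one side of
    some branch (singletons included).  ``n_subgroups`` counts the maximal
    pure subtrees a paraphyletic taxon decomposes into.
    """
    view = UnrootedView(gt)
    by_taxon: dict[str, list[str]] = {}
    unmapped = []
    for label in view.leaves:
        genome = gt.genome_of_leaf(label)
        if genome not in taxon_map.assignments:
            unmapped.append(label)
            continue
        by_taxon.setdefault(taxon_map.taxon_of(genome), []).append(label)
    if unmapped:
        raise KeyError(f"leaves with unmapped genomes: {sorted(unmapped)}")

    report = MonophylyReport(tree_id=gt.tree_id)
    for taxon in sorted(by_taxon):
        labels = by_taxon[taxon]
        groups = view.subgroups(frozenset(labels))
        mono = len(groups) == 1
        n_genomes = len({gt.genome_of_leaf(l) for l in labels})
        n_a = taxon_map.totals[taxon]
        if mono and (score_singletons or len(labels) > 1):
            s_a = n_genomes / n_a
        else:
            s_a = 0.0
        report.statuses[taxon] = TaxonStatus(
            taxon=taxon,
            n_genomes=n_genomes,
            n_sequences=len(labels),
            is_monophyletic=mono,
            n_subgroups=len(groups),
            score=s_a,
        )
    return report


def mean_branch_length(
    gt: GeneTree, threshold: float = CONSERVED_THRESHOLD
) -> tuple[float, bool]:
    """Mean over all edges (terminal and internal) and the conserved flag
    (mean <= threshold, boundary inclusive)."""
    lengths = gt.branch_lengths()
    if not lengths:
        raise ValueError("tree has no edges")
    mean = float(np.mean(lengths))
    return mean, mean <= threshold


def gene_verticality(
    gt: GeneTree,
    taxon_map: TaxonMap,
    min_taxa: int = 2,
    min_genomes: int = 4,
    conserved_threshold: float = CONSERVED_THRESHOLD,
    score_singletons: bool = True,
    report: MonophylyReport | None = None,
) -> VerticalityRecord:
    """V_g of one gene tree: the sum of monophyly scores S_a.

    Clusters below the retention thresholds (by default at least 4 genomes
    spanning 2 taxa) are returned with ``excluded=True``; their V_g is
    still computed for inspection but should not enter aggregates.
    """
    if report is None:
        report = taxon_split_status(
            gt, taxon_map, score_singletons=score_singletons
        )
    v_g = sum(s.score for s in report.statuses.values())
    genomes = gt.genomes()
    mean_bl, conserved = mean_branch_length(gt, threshold=conserved_threshold)
    excluded = (
        report.n_taxa_present < min_taxa or len(genomes) < min_genomes
    )
    return VerticalityRecord(
        cluster_id=gt.tree_id,
        v_g=v_g,
        n_genomes=len(genomes),
        n_taxa_present=report.n_taxa_present,
        mean_branch_length=mean_bl,
        conserved=conserved,
        excluded=excluded,
    )


def weighted_gene_verticality(
    rooted: GeneTree,
    taxon_map: TaxonMap,
    report: MonophylyReport | None = None,
) -> float:
    """V_w = (number of monophyletic taxa present) x (mean root-to-tip
    distance).  Requires a MAD-rooted tree; the monophyly count itself is
    still an unrooted-split property."""
    if not rooted.rooted:
        raise ValueError("weighted verticality requires a rooted tree")
    if report is None:
        report = taxon_split_status(rooted, taxon_map)
    m = len(report.monophyletic_taxa())
    return m * mean_root_to_tip(rooted)


def score_tree(
    gt: GeneTree,
    taxon_map: TaxonMap,
    rooted: GeneTree | None = None,
    **kwargs,
) -> ClusterScore:
    """Convenience bundle: monophyly report + verticality record (+ V_w when
    a rooted companion tree is supplied)."""
    report = taxon_split_status(
        gt, taxon_map, score_singletons=kwargs.pop("score_singletons", True)
    )
    record = gene_verticality(gt, taxon_map, report=report, **kwargs)
    if rooted is not None:
        record.v_w = weighted_gene_verticality(rooted, taxon_map, report=report)
    return ClusterScore(
        cluster_id=gt.tree_id,
        record=record,
        report=report,
        genomes=frozenset(gt.genomes()),
    )


def aggregate_verticality(
    scores: list[ClusterScore],
    taxon_map: TaxonMap,
) -> tuple[list[TaxonSummary], list[GenomeSummary]]:
    """Average verticality over trees, per taxon and per genome.

    Per taxon: P_mono (fraction of trees containing the taxon in which it
    is monophyletic), the mean V_g over those trees, and — when V_w values
    are available — the signed weighted mean in which trees where the taxon
    is monophyletic contribute +V_w and trees where it is paraphyletic
    contribute -V_w, divided by the number of trees.
    """
    if not scores:
        raise ValueError("no cluster scores to aggregate")
    per_taxon: dict[str, dict] = {}
    per_genome: dict[str, list[float]] = {}
    for cs in scores:
        for taxon, status in cs.report.statuses.items():
            acc = per_taxon.setdefault(
                taxon,
                {"n_trees": 0, "n_mono": 0, "v_sum": 0.0, "vw": [], "vw_ok": True},
            )
            acc["n_trees"] += 1
            acc["v_sum"] += cs.record.v_g
            if status.is_monophyletic:
                acc["n_mono"] += 1
            if cs.record.v_w is None:
                acc["vw_ok"] = False
            else:
                sign = 1.0 if status.is_monophyletic else -1.0
                acc["vw"].append(sign * cs.record.v_w)
        for genome in cs.genomes:
            per_genome.setdefault(genome, []).append(cs.record.v_g)

    taxon_summaries = []
    for taxon in sorted(per_taxon):
        acc = per_taxon[taxon]
        n = acc["n_trees"]
        taxon_summaries.append(
            TaxonSummary(
                taxon=taxon,
                n_trees=n,
                n_mono=acc["n_mono"],
                p_mono=acc["n_mono"] / n,
                v_avg=acc["v_sum"] / n,
                v_weighted=(sum(acc["vw"]) / n) if acc["vw_ok"] else None,
            )
        )
    genome_summaries = [
        GenomeSummary(
            genome=g, v_g_avg=float(np.mean(vs)), n_clusters=len(vs)
        )
        for g, vs in sorted(per_genome.items())
    ]
    return taxon_summaries, genome_summaries


def count_rooted_tree_topologies(n: int) -> int:
    """Number of labelled rooted binary tree topologies on n leaves:
    (2n - 3)!! as an exact integer.  (With 52 leaves this is ~3e80, on the
    order of the number of protons in the universe — the reason pairwise
    whole-topology comparison of large trees is hopeless.)"""
    if n < 2:
        raise ValueError("need at least 2 leaves")
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


def distribution_correlation(
    records: list[VerticalityRecord],
) -> tuple[float, float, float]:
    """Pearson correlation of V_g against the number of genomes in the
    cluster (gene distribution density).  Returns (r, R^2, p)."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    v = np.array([r.v_g for r in records], dtype=float)
    n = np.array([r.n_genomes for r in records], dtype=float)
    if np.ptp(v) == 0 or np.ptp(n) == 0:
        raise ValueError("zero variance in verticality or distribution")
    r, p = stats.pearsonr(v, n)
    return float(r), float(r * r), float(p)
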