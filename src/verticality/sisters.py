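"""Sister-group composition analysis.

Every time a taxon occupies a tip-resident clade of an unrooted gene tree,
the composition of the neighbouring clade ("sister") carries a signal about
recent lateral exchange: a taxon that keeps turning up in other taxa's
sisters is a frequent LGT partner, and a taxon can even appear in its *own*
sister when a recent export to another phylum breaks its clade.

Two variants are implemented:

* prokaryote mode — per (tree, taxon) sister profiles.  A monophyletic
  taxon's sister is the adjacent subtree joined by the shortest branch; a
  paraphyletic taxon is decomposed into its maximal monophyletic subgroups,
  whose sister compositions are averaged weighted by the fraction of the
  taxon's genomes each subgroup holds.  Sister composition is scored by
  relative leaf occurrence, so each profile sums to 1.
* eukaryote mode — in eukaryote-prokaryote cluster (EPC) trees where the
  eukaryotes are monophyletic, the node adjacent to the eukaryote clade
  splits the prokaryotic side into two subclades; the smaller one is the
  putative sister and is classified pure (one prokaryotic phylum) or mixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._unrooted import UnrootedView
from .core_io import GeneTree, TaxonMap
from .scoring import MonophylyReport, VerticalityRecord

__all__ = [
    "SisterProfile",
    "EPCSisterCall",
    "EnrichmentResult",
    "clade_sister",
    "taxon_sister_profile",
    "aggregate_sister_matrix",
    "epc_sister_classification",
    "epc_summary",
    "pure_sister_verticality_enrichment",
]


@dataclass
class SisterProfile:
    tree_id: str
    taxon: str
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class EPCSisterCall:
    tree_id: str
    eukaryotes_monophyletic: bool
    sister_leaves: frozenset[str] | None = None
    sister_taxa: frozenset[str] = frozenset()
    sister_class: str | None = None  # "pure" | "mixed"
    sister_taxon: str | None = None  # set when pure
    sister_size: int = 0


@dataclass
class EnrichmentResult:
    taxon: str
    n_cases: int
    statistic: float
    p_value: float
    testable: bool


def _sister_of_subgroup(view: UnrootedView, clade: frozenset[str]):
    """(sister leafset, connecting branch length) of an edge-separated clade.

    Among the subtrees adjacent at the clade's attachment node the one with
    the shortest connecting branch wins; ties go to the fewer-leaved, then
    lexicographically smallest, subtree.
    """
    if clade == frozenset(view.leaves):
        raise ValueError("clade spans the whole tree; no sister exists")
    sep = view.separating_edge(clade)
    if sep is None:
        raise ValueError("leaf set is not separated by any edge")
    u, v, w = sep  # clade lies beyond v; u is the attachment node
    candidates = []
    for nbr, length in view.neighbors(u):
        if nbr is v:
            continue
        leafset = view.leafset_beyond(u, nbr)
        candidates.append((length, len(leafset), min(leafset), leafset))
    if not candidates:
        # the attachment node is itself a leaf: the rest of the tree is
        # that single leaf, which is the sister
        return frozenset({view.leaf_of[u]}), w
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    best = candidates[0]
    return best[3], best[0]


def clade_sister(
    gt: GeneTree, clade: frozenset[str]
) -> tuple[frozenset[str], float]:
    """Sister subtree (leaf labels) of an edge-separated clade, with the
    length of the branch connecting it to the attachment node."""
    return _sister_of_subgroup(UnrootedView(gt), frozenset(clade))


def _leaf_taxa(gt: GeneTree, taxon_map: TaxonMap, labels) -> list[str]:
    return [taxon_map.taxon_of(gt.genome_of_leaf(l)) for l in labels]


def taxon_sister_profile(
    gt: GeneTree, taxon_map: TaxonMap
) -> dict[str, SisterProfile]:
    """Sister composition profile of every taxon present in the tree.

    Profiles sum to 1 for any taxon that does not span the whole tree.
    """
    view = UnrootedView(gt)
    by_taxon: dict[str, list[str]] = {}
    for label in view.leaves:
        by_taxon.setdefault(
            taxon_map.taxon_of(gt.genome_of_leaf(label)), []
        ).append(label)

    profiles: dict[str, SisterProfile] = {}
    for taxon in sorted(by_taxon):
        labels = frozenset(by_taxon[taxon])
        profile = SisterProfile(tree_id=gt.tree_id, taxon=taxon)
        profiles[taxon] = profile
        if labels == frozenset(view.leaves):
            continue  # taxon spans the tree; no sister
        groups = view.subgroups(labels)
        genome_counts = [
            len({gt.genome_of_leaf(l) for l in g}) for g in groups
        ]
        total_genomes = sum(genome_counts)
        for g, n_gen in zip(groups, genome_counts):
            sister, _ = _sister_of_subgroup(view, g)
            weight = n_gen / total_genomes
            taxa = _leaf_taxa(gt, taxon_map, sister)
            for t in taxa:
                profile.scores[t] = (
                    profile.scores.get(t, 0.0) + weight / len(taxa)
                )
    return profiles


def aggregate_sister_matrix(profiles: list[SisterProfile]) -> pd.DataFrame:
    """Sum sister profiles per query taxon across trees and normalize each
    row by its maximum, so every nonzero row peaks at exactly 1."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    queries = sorted({p.taxon for p in profiles})
    sisters = sorted({t for p in profiles for t in p.scores})
    mat = pd.DataFrame(0.0, index=queries, columns=sisters)
    for p in profiles:
        for t, s in p.scores.items():
            mat.loc[p.taxon, t] += s
    row_max = mat.max(axis=1)
    nonzero = row_max > 0
    mat.loc[nonzero] = mat.loc[nonzero].div(row_max[nonzero], axis=0)
    return mat


def epc_sister_classification(
    gt: GeneTree,
    taxon_map: TaxonMap,
    euk_taxa: set[str],
) -> EPCSisterCall:
    """Classify the prokaryotic sister of the eukaryote clade in an EPC tree.

    If the eukaryotic leaves form a split, the adjacent node bisects the
    prokaryotic side into subclades; the one with the fewest leaves is the
    sister (ties broken by shorter connecting branch, then by name), and it
    is pure when it contains a single prokaryotic phylum.
    """
    view = UnrootedView(gt)
    euk_leaves = frozenset(
        l
        for l in view.leaves
        if taxon_map.taxon_of(gt.genome_of_leaf(l)) in euk_taxa
    )
    prok_leaves = frozenset(view.leaves) - euk_leaves
    if not prok_leaves:
        raise ValueError("tree has no prokaryotic leaves")
    if not euk_leaves:
        raise ValueError("tree has no eukaryotic leaves")
    if len(prok_leaves) < 2:
        raise ValueError("need at least 2 prokaryotic leaves")
    sep = view.separating_edge(euk_leaves)
    if sep is None:
        return EPCSisterCall(tree_id=gt.tree_id, eukaryotes_monophyletic=False)
    u, v, _ = sep  # eukaryote clade beyond v; u adjacent on the prok side
    subclades = []
    for nbr, length in view.neighbors(u):
        if nbr is v:
            continue
        leafset = view.leafset_beyond(u, nbr)
        subclades.append((len(leafset), length, min(leafset), leafset))
    if not subclades:  # attachment node is a single prokaryotic leaf
        subclades = [(1, 0.0, view.leaf_of[u], frozenset({view.leaf_of[u]}))]
    subclades.sort(key=lambda t: (t[0], t[1], t[2]))
    sister = subclades[0][3]
    taxa = frozenset(_leaf_taxa(gt, taxon_map, sister))
    pure = len(taxa) == 1
    return EPCSisterCall(
        tree_id=gt.tree_id,
        eukaryotes_monophyletic=True,
        sister_leaves=sister,
        sister_taxa=taxa,
        sister_class="pure" if pure else "mixed",
        sister_taxon=next(iter(taxa)) if pure else None,
        sister_size=len(sister),
    )


def epc_summary(
    calls: list[EPCSisterCall],
    reports: list[MonophylyReport],
    euk_taxa: set[str] = frozenset(),
) -> pd.DataFrame:
    """Per-taxon tally over EPC trees: P_mono, S_non, S_mix, S_pure and the
    mean pure-sister clade size S_p_avg.

    ``reports`` supply per-tree taxon presence and monophyly (keyed by
    tree_id); eukaryotic taxa are left out of the table.
    """
    if not calls:
        raise ValueError("no sister calls to summarize")
    report_by_id = {r.tree_id: r for r in reports}
    acc: dict[str, dict] = {}

    def slot(taxon):
        return acc.setdefault(
            taxon,
            {
                "n_trees": 0,
                "n_mono": 0,
                "s_pure": 0,
                "s_mix": 0,
                "s_non": 0,
                "pure_sizes": [],
            },
        )

    for report in reports:
        for taxon, status in report.statuses.items():
            if taxon in euk_taxa:
                continue
            s = slot(taxon)
            s["n_trees"] += 1
            if status.is_monophyletic:
                s["n_mono"] += 1
    for call in calls:
        if not call.eukaryotes_monophyletic:
            continue
        report = report_by_id.get(call.tree_id)
        present = (
            {t for t in report.statuses if t not in euk_taxa}
            if report
            else set(call.sister_taxa)
        )
        for taxon in present:
            s = slot(taxon)
            if taxon in call.sister_taxa:
                if call.sister_class == "pure":
                    s["s_pure"] += 1
                    s["pure_sizes"].append(call.sister_size)
                else:
                    s["s_mix"] += 1
            else:
                s["s_non"] += 1
    rows = []
    for taxon in sorted(acc):
        s = acc[taxon]
        rows.append(
            {
                "taxon": taxon,
                "n_trees": s["n_trees"],
                "p_mono": s["n_mono"] / s["n_trees"] if s["n_trees"] else math.nan,
                "s_non": s["s_non"],
                "s_mix": s["s_mix"],
                "s_pure": s["s_pure"],
                "s_p_avg": (
                    float(np.mean(s["pure_sizes"])) if s["pure_sizes"] else math.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def pure_sister_verticality_enrichment(
    records: list[VerticalityRecord],
    calls: list[EPCSisterCall],
    taxon: str,
    min_cases: int = 3,
) -> EnrichmentResult:
    """Are the clusters whose pure sister is ``taxon`` more vertical than
    the EPC sample as a whole?  Two-sided Wilcoxon rank-sum of their V_g
    against all clusters."""
    by_id = {r.cluster_id: r for r in records}
    case_ids = {
        c.tree_id
        for c in calls
        if c.eukaryotes_monophyletic
        and c.sister_class == "pure"
        and c.sister_taxon == taxon
    }
    cases = [by_id[i].v_g for i in case_ids if i in by_id]
    background = [r.v_g for r in records]
    if len(cases) < min_cases:
        return EnrichmentResult(taxon, len(cases), math.nan, math.nan, False)
    if np.ptp(np.concatenate([cases, background])) == 0:
        return EnrichmentResult(taxon, len(cases), 0.0, 1.0, True)
    stat, p = stats.ranksums(cases, background)
    return EnrichmentResult(taxon, len(cases), float(stat), float(p), True)
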