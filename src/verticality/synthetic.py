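"""Synthetic labelled gene trees with planted LGT and duplications.

The generator emulates the data regime the verticality framework was built
for — thousands of prokaryotic genomes grouped into dozens of higher-order
taxa — at desk scale.  A random ultrametric species tree places every
taxon's genomes in a clade; each gene tree samples genomes from it
(emulating patchy gene distribution), then plants a Poisson number of
single-leaf prune-and-regraft transfers (recent LGT, the signal the
tip-based measure detects) and of terminal same-genome duplications
(cherries), and finally jitters branch lengths.  Every event is logged so
downstream modules can be checked against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core_io import GeneTree, LabelScheme, TaxonMap

__all__ = [
    "SimConfig",
    "TransferEvent",
    "PlantedTruth",
    "simulate_species_tree",
    "simulate_gene_tree",
    "simulate_gene_trees",
    "simulate_site_loglik",
    "simulate_genome_sizes",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Defaults emulate, scaled down, a dataset of 42 prokaryote-level taxa:
    420 genomes of which each gene samples ~10% (trees of ~40 genomes, the
    order of the real clusters), one expected transfer and 0.1 expected
    terminal duplications per gene tree, and branch lengths in
    substitutions/site around a within-taxon depth of 0.1.
    """

    n_taxa: int = 42
    genomes_per_taxon: int = 10
    gene_presence: float = 0.1  # per-genome sampling probability q
    lgt_rate: float = 1.0  # expected transfers per gene tree (lambda)
    dup_rate: float = 0.1  # expected terminal duplications (mu)
    branch_scale: float = 0.1  # within-taxon tree depth, subst/site
    between_scale: float = 0.2  # additional backbone depth above taxa
    jitter_sd: float = 0.2  # lognormal sigma on branch lengths; 0 = clock
    min_genomes: int = 4  # retention: genomes per gene tree
    min_taxa: int = 2  # retention: taxa per gene tree
    on_small: str = "resample"  # or "skip"

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.genomes_per_taxon < 1:
            raise ValueError("need >= 2 taxa with >= 1 genome each")
        if not 0 < self.gene_presence <= 1:
            raise ValueError("gene_presence must be in (0, 1]")
        if self.lgt_rate < 0 or self.dup_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class TransferEvent:
    leaf: str
    donor_taxon: str
    recipient_clade: frozenset[str]  # leafset below the recipient edge
    attach_fraction: float


@dataclass
class PlantedTruth:
    tree_id: str
    transfers: list[TransferEvent] = field(default_factory=list)
    duplications: list[tuple[str, str, str]] = field(default_factory=list)
    true_root_side: frozenset[str] | None = None
    sampled_genomes: frozenset[str] = frozenset()


def _join_random_ultrametric(
    items: list[tuple[str, float]], heights: np.ndarray, rng: np.random.Generator
) -> tuple[str, float]:
    """Join (newick, height) subtrees at increasing node heights."""
    items = list(items)
    for h in np.sort(heights):
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (sa, ha) = items.pop(j)
        (sb, hb) = items.pop(i)
        items.append((f"({sa}:{h - ha:.10g},{sb}:{h - hb:.10g})", float(h)))
    assert len(items) == 1
    return items[0]


def simulate_species_tree(
    config: SimConfig, seed: int | None = None
) -> tuple[GeneTree, TaxonMap]:
    """Random ultrametric species tree with each taxon's genomes monophyletic.

    Leaves are genome ids ("T03G007"); within-taxon coalescences happen
    below ``branch_scale``, between-taxon ones above it, so every taxon is
    a clade of depth ``branch_scale`` hanging from a deeper backbone.
    """
    rng = np.random.default_rng(seed)
    assignments: dict[str, str] = {}
    taxon_subtrees: list[tuple[str, float]] = []
    tw = max(2, len(str(config.n_taxa)))
    gw = max(3, len(str(config.genomes_per_taxon)))
    for t in range(1, config.n_taxa + 1):
        taxon = f"T{t:0{tw}d}"
        genomes = [
            f"{taxon}G{g:0{gw}d}"
            for g in range(1, config.genomes_per_taxon + 1)
        ]
        for g in genomes:
            assignments[g] = taxon
        if len(genomes) == 1:
            taxon_subtrees.append((genomes[0], 0.0))
            continue
        hs = rng.uniform(0, config.branch_scale, size=len(genomes) - 1)
        hs[np.argmax(hs)] = config.branch_scale  # taxon clade depth exact
        sub = _join_random_ultrametric(
            [(g, 0.0) for g in genomes], hs, rng
        )
        taxon_subtrees.append(sub)
    lo = config.branch_scale
    hs = rng.uniform(lo * 1.0001, lo + config.between_scale, config.n_taxa - 1)
    hs[np.argmax(hs)] = lo + config.between_scale
    newick, _ = _join_random_ultrametric(taxon_subtrees, hs, rng)
    species = GeneTree.from_newick(
        newick + ";", scheme=LabelScheme(delimiter=None), tree_id="species"
    )
    return species, TaxonMap(assignments=assignments)


def _suppress_node(tree: dendropy.Tree, node: dendropy.Node) -> None:
    """Remove a now-degree-2 internal node (or a single-child root)."""
    children = node.child_nodes()
    parent = node.parent_node
    if parent is None:
        # root with a single child: promote the child to seed node
        if len(children) == 1:
            child = children[0]
            node.remove_child(child)
            child.edge.length = None
            tree.seed_node = child
        return
    if len(children) == 1:
        child = children[0]
        length = (node.edge.length or 0.0) + (child.edge.length or 0.0)
        node.remove_child(child)
        parent.remove_child(node)
        parent.add_child(child)
        child.edge.length = length


def _real_edges(tree: dendropy.Tree) -> list:
    return [
        e for e in tree.preorder_edge_iter() if e.tail_node is not None
    ]


def simulate_gene_tree(
    species: GeneTree,
    taxon_map: TaxonMap,
    config: SimConfig,
    seed: int | None = None,
    tree_id: str = "gene",
    rng: np.random.Generator | None = None,
) -> tuple[GeneTree, PlantedTruth] | None:
    """One gene tree: genome sampling, planted transfers and duplications.

    Returns None when the sampled gene is below the retention thresholds
    and ``config.on_small == "skip"``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    genomes = sorted(species.genomes())

    for attempt in range(1000):
        mask = rng.random(len(genomes)) < config.gene_presence
        sampled = [g for g, m in zip(genomes, mask) if m]
        taxa = {taxon_map.taxon_of(g) for g in sampled}
        if len(sampled) >= max(3, config.min_genomes) and len(taxa) >= config.min_taxa:
            break
        if config.on_small == "skip":
            return None
    else:
        raise RuntimeError(
            "could not sample a retained gene tree in 1000 draws; "
            "raise gene_presence or lower min_genomes/min_taxa"
        )

    # prune the species tree to the sampled genomes (reparse for an
    # independent taxon namespace) and relabel leaves genome|gene-copy
    pruned = species.tree.extract_tree_with_taxa_labels(sampled)
    tree = dendropy.Tree.get(
        data=pruned.as_string(schema="newick", suppress_rooting=True),
        schema="newick",
        preserve_underscores=True,
    )
    copy_counter = 0
    for leaf in tree.leaf_node_iter():
        copy_counter += 1
        leaf.taxon.label = f"{leaf.taxon.label}|g{copy_counter}"

    # record the species-root split restricted to the sampled leaves
    root_children = species.tree.seed_node.child_nodes()
    side = {
        lf.taxon.label
        for lf in root_children[0].leaf_iter()
        if lf.taxon.label in set(sampled)
    }
    leaf_by_genome = {
        l.taxon.label.split("|")[0]: l.taxon.label
        for l in tree.leaf_node_iter()
    }
    true_root_side = (
        frozenset(leaf_by_genome[g] for g in side)
        if 0 < len(side) < len(sampled)
        else None
    )

    truth = PlantedTruth(
        tree_id=tree_id,
        true_root_side=true_root_side,
        sampled_genomes=frozenset(sampled),
    )

    # --- planted transfers: leaf prune-and-regraft -----------------------
    n_transfers = int(rng.poisson(config.lgt_rate))
    for _ in range(n_transfers):
        leaves = [l for l in tree.leaf_node_iter()]
        leaf = leaves[int(rng.integers(len(leaves)))]
        label = leaf.taxon.label
        genome = label.split("|")[0]
        donor_taxon = taxon_map.taxon_of(genome)
        pendant = leaf.edge.length or 0.0
        parent = leaf.parent_node
        sibling_heads = [c for c in parent.child_nodes() if c is not leaf]
        parent.remove_child(leaf)
        _suppress_node(tree, parent)
        # candidate recipient edges: everything except the merged edge at
        # the original attachment point (every transfer changes topology)
        forbidden = set(id(s) for s in sibling_heads)
        candidates = [
            e for e in _real_edges(tree) if id(e.head_node) not in forbidden
        ]
        if not candidates:
            candidates = _real_edges(tree)
        edge = candidates[int(rng.integers(len(candidates)))]
        frac = float(rng.uniform(0.05, 0.95))
        tail, head = edge.tail_node, edge.head_node
        length = edge.length or 0.0
        recipient_clade = frozenset(
            l.taxon.label for l in head.leaf_iter()
        )
        graft = tail.new_child(edge_length=frac * length)
        tail.remove_child(head)
        graft.add_child(head)
        head.edge.length = (1.0 - frac) * length
        new_leaf = graft.new_child(
            taxon=dendropy.Taxon(label=label), edge_length=pendant
        )
        new_leaf.taxon.label = label
        truth.transfers.append(
            TransferEvent(
                leaf=label,
                donor_taxon=donor_taxon,
                recipient_clade=recipient_clade,
                attach_fraction=frac,
            )
        )

    # --- planted terminal duplications: same-genome cherries -------------
    leaves = [l for l in tree.leaf_node_iter()]
    n_dups = min(int(rng.poisson(config.dup_rate)), len(leaves))
    if n_dups:
        chosen = rng.choice(len(leaves), size=n_dups, replace=False)
        for k in chosen:
            leaf = leaves[int(k)]
            label = leaf.taxon.label
            genome = label.split("|")[0]
            pendant = leaf.edge.length or 0.0
            delta = min(0.05 * config.branch_scale, pendant / 2) or 1e-6
            parent = leaf.parent_node
            parent.remove_child(leaf)
            joint = parent.new_child(edge_length=pendant - delta)
            joint.add_child(leaf)
            leaf.edge.length = delta
            copy_counter += 1
            dup_label = f"{genome}|g{copy_counter}"
            joint.new_child(
                taxon=dendropy.Taxon(label=dup_label), edge_length=delta
            )
            a, b = sorted((label, dup_label))
            truth.duplications.append((a, b, genome))

    # --- branch-length jitter --------------------------------------------
    if config.jitter_sd > 0:
        sd = config.jitter_sd
        for e in _real_edges(tree):
            if e.length:
                e.length = float(
                    e.length * rng.lognormal(-0.5 * sd * sd, sd)
                )

    gt = GeneTree(
        tree=tree, scheme=LabelScheme(delimiter="|"), tree_id=tree_id
    )
    return gt, truth


def simulate_gene_trees(
    n_trees: int,
    species: GeneTree,
    taxon_map: TaxonMap,
    config: SimConfig,
    seed: int | None = None,
) -> list[tuple[GeneTree, PlantedTruth]]:
    rng = np.random.default_rng(seed)
    out = []
    width = max(4, len(str(n_trees)))
    for i in range(1, n_trees + 1):
        res = simulate_gene_tree(
            species,
            taxon_map,
            config,
            rng=rng,
            tree_id=f"g{i:0{width}d}",
        )
        if res is not None:
            out.append(res)
    return out


def simulate_site_loglik(
    n_sites: int,
    n_trees: int,
    shift: float = 0.0,
    noise_sd: float = 0.1,
    seed: int | None = None,
    base_mean: float = -3.0,
    base_sd: float = 1.0,
    tree_ids: list[str] | None = None,
):
    """Per-site log-likelihood matrix for topology-test checks.

    Row 0 ("best") is iid normal; every constrained row equals the best
    row minus ``shift``/S per site plus iid noise, so ``shift`` is the
    expected total log-likelihood deficit (0 = the null of topologies that
    explain the data equally well).
    """
    from .topo_tests import SiteLogLikMatrix

    if n_sites < 2 or n_trees < 2:
        raise ValueError("need >= 2 sites and >= 2 trees")
    rng = np.random.default_rng(seed)
    best = rng.normal(base_mean, base_sd, size=n_sites)
    rows = [best]
    for _ in range(n_trees - 1):
        rows.append(
            best - shift / n_sites + rng.normal(0.0, noise_sd, size=n_sites)
        )
    ids = tree_ids or ["best"] + [f"alt{i}" for i in range(1, n_trees)]
    return SiteLogLikMatrix(
        tree_ids=ids, matrix=np.vstack(rows), best_row=ids[0]
    )


def simulate_genome_sizes(
    genomes: list[str],
    seed: int | None = None,
    mean_proteins: float = 3000.0,
    sd_log: float = 0.3,
) -> dict[str, int]:
    """Plausible per-genome protein counts (lognormal around ~3000)."""
    rng = np.random.default_rng(seed)
    sizes = rng.lognormal(np.log(mean_proteins), sd_log, size=len(genomes))
    return {g: int(max(100, s)) for g, s in zip(sorted(genomes), sizes)}
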