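"""Trees, taxon maps and tabular inputs.

The central conventions live here: gene-tree leaves carry a compound label
``<genome>|<sequence>`` (delimiter configurable) from which the genome, and
through a :class:`TaxonMap` the higher-order taxon ("phylum"), of every
sequence is resolved.  Trees are read and written as Newick via dendropy and
treated as *unrooted* unless they passed through the rooting module.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "LabelScheme",
    "TaxonMap",
    "GeneTree",
    "NewickParseError",
    "TaxonMapError",
    "read_gene_trees",
    "read_taxon_map",
    "write_gene_trees",
    "write_table",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message names the offending file."""


class TaxonMapError(ValueError):
    """Inconsistent or empty genome-to-taxon map."""


@dataclass(frozen=True)
class LabelScheme:
    """How leaf names encode genome identity.

    With the default ``delimiter="|"`` and ``genome_field=0`` a leaf named
    ``"EcoliK12|b0001"`` belongs to genome ``"EcoliK12"``.  With
    ``delimiter=None`` the entire leaf name is the genome id (single-copy
    trees whose leaves are genomes).
    """

    delimiter: str | None = "|"
    genome_field: int = 0

    def genome_of(self, leaf_label: str) -> str:
        if self.delimiter is None:
            return leaf_label
        parts = leaf_label.split(self.delimiter)
        if len(parts) <= self.genome_field:
            # documented fallback: label without the delimiter is the genome
            return leaf_label
        genome = parts[self.genome_field]
        if not genome:
            raise ValueError(f"empty genome id in leaf label {leaf_label!r}")
        return genome


@dataclass
class TaxonMap:
    """Genome -> taxon assignment plus dataset-wide per-taxon genome totals.

    ``totals[a]`` is :math:`N_a`, the number of genomes of taxon *a* in the
    reference dataset — the denominator of the monophyly score.  It defaults
    to the observed count per taxon but can be overridden (e.g. when the map
    covers only the genomes present in a subset of trees).
    """

    assignments: dict[str, str]
    totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        observed: dict[str, int] = {}
        for taxon in self.assignments.values():
            observed[taxon] = observed.get(taxon, 0) + 1
        if not self.totals:
            self.totals = observed
        for taxon, n_obs in observed.items():
            if taxon not in self.totals:
                raise TaxonMapError(f"no total N_a given for taxon {taxon!r}")
            if self.totals[taxon] < n_obs:
                raise TaxonMapError(
                    f"total N_a={self.totals[taxon]} for taxon {taxon!r} is "
                    f"smaller than the {n_obs} genomes mapped to it"
                )

    def taxon_of(self, genome_id: str) -> str:
        try:
            return self.assignments[genome_id]
        except KeyError:
            raise KeyError(f"genome {genome_id!r} not in taxon map") from None

    @property
    def taxa(self) -> list[str]:
        return sorted(self.totals)

    def observed_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for taxon in self.assignments.values():
            counts[taxon] = counts.get(taxon, 0) + 1
        return counts


@dataclass
class GeneTree:
    """A branch-length Newick gene tree with genome-labelled leaves.

    The underlying dendropy tree retains multifurcations as hard polytomies.
    ``rooted`` is only set by the rooting module (or by the caller for trees
    rooted upstream); every split-based operation treats the tree as
    unrooted regardless.
    """

    tree: dendropy.Tree
    scheme: LabelScheme = field(default_factory=LabelScheme)
    tree_id: str = ""
    rooted: bool = False

    # -- basic views ------------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def genome_of_leaf(self, leaf_label: str) -> str:
        return self.scheme.genome_of(leaf_label)

    def genomes(self) -> set[str]:
        return {self.scheme.genome_of(l) for l in self.leaf_labels()}

    def taxa_present(self, taxon_map: TaxonMap) -> set[str]:
        return {taxon_map.taxon_of(g) for g in self.genomes()}

    def branch_lengths(self) -> list[float]:
        """Lengths of all real edges (the rootward edge of the seed node,
        which has no branch, is excluded)."""
        out = []
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            out.append(edge.length if edge.length is not None else 0.0)
        return out

    def clone(self) -> "GeneTree":
        return GeneTree(
            tree=self.tree.clone(depth=1),
            scheme=self.scheme,
            tree_id=self.tree_id,
            rooted=self.rooted,
        )

    def as_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier=".12g",
            ).strip()
        )

    @classmethod
    def from_newick(
        cls,
        newick: str,
        scheme: LabelScheme | None = None,
        tree_id: str = "",
        rooted: bool = False,
    ) -> "GeneTree":
        scheme = scheme or LabelScheme()
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon labels" in str(exc):
                raise NewickParseError(
                    f"duplicate leaf names in tree {tree_id or '<anon>'}: {exc}"
                ) from exc
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        gt = cls(tree=tree, scheme=scheme, tree_id=tree_id, rooted=rooted)
        _validate_leaves(gt)
        _default_missing_lengths(gt)
        return gt


def _validate_leaves(gt: GeneTree) -> None:
    labels = gt.leaf_labels()
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(
            f"duplicate leaf names in tree {gt.tree_id or '<anon>'}: {dupes}"
        )


def _default_missing_lengths(gt: GeneTree) -> None:
    n_missing = 0
    for edge in gt.tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
        elif edge.length < 0:
            raise NewickParseError(
                f"negative branch length in tree {gt.tree_id or '<anon>'}"
            )
    if n_missing:
        logger.warning(
            "tree %s: %d missing branch lengths set to 0",
            gt.tree_id or "<anon>",
            n_missing,
        )


def read_gene_trees(
    paths: Iterable[str | os.PathLike],
    scheme: LabelScheme | None = None,
) -> list[GeneTree]:
    """Read one Newick gene tree per file.

    Trees with duplicate leaf names are skipped with a logged warning;
    malformed Newick raises :class:`NewickParseError` naming the file.
    """
    scheme = scheme or LabelScheme()
    trees: list[GeneTree] = []
    for path in paths:
        path = Path(path)
        text = path.read_text()
        try:
            gt = GeneTree.from_newick(text, scheme=scheme, tree_id=path.stem)
        except NewickParseError as exc:
            if "duplicate leaf names" in str(exc):
                logger.warning("skipping %s: %s", path, exc)
                continue
            raise NewickParseError(f"{path}: {exc}") from exc
        trees.append(gt)
    return trees


def write_gene_trees(
    trees: Iterable[GeneTree], out_dir: str | os.PathLike
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, gt in enumerate(trees):
        name = gt.tree_id or f"tree{i:05d}"
        p = out_dir / f"{name}.nwk"
        p.write_text(gt.as_newick() + "\n")
        written.append(p)
    return written


def read_taxon_map(path: str | os.PathLike | io.TextIOBase) -> TaxonMap:
    """Read a TSV ``genome_id<TAB>taxon_id[<TAB>N_a]`` map.

    A third column, when present, overrides the per-taxon totals
    :math:`N_a` (all rows of a taxon must then agree).
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = "<stream>"
    else:
        lines = Path(path).read_text().splitlines()
        name = str(path)
    assignments: dict[str, str] = {}
    overrides: dict[str, int] = {}
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TaxonMapError(f"{name}:{lineno}: expected >= 2 columns")
        genome, taxon = parts[0], parts[1]
        if genome in assignments and assignments[genome] != taxon:
            raise TaxonMapError(
                f"{name}:{lineno}: genome {genome!r} mapped to both "
                f"{assignments[genome]!r} and {taxon!r}"
            )
        assignments[genome] = taxon
        if len(parts) >= 3 and parts[2]:
            n = int(parts[2])
            if taxon in overrides and overrides[taxon] != n:
                raise TaxonMapError(
                    f"{name}:{lineno}: conflicting N_a overrides for {taxon!r}"
                )
            overrides[taxon] = n
    if not assignments:
        raise TaxonMapError(f"{name}: empty taxon map")
    totals: dict[str, int] = {}
    if overrides:
        observed = {}
        for t in assignments.values():
            observed[t] = observed.get(t, 0) + 1
        for taxon, n_obs in observed.items():
            totals[taxon] = overrides.get(taxon, n_obs)
    return TaxonMap(assignments=assignments, totals=totals)


def write_taxon_map(taxon_map: TaxonMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for genome in sorted(taxon_map.assignments):
            taxon = taxon_map.assignments[genome]
            fh.write(f"{genome}\t{taxon}\t{taxon_map.totals[taxon]}\n")


def write_table(rows: Sequence[Mapping], path: str | os.PathLike) -> None:
    """Write a list of homogeneous dict rows as a TSV with a header row."""
    import pandas as pd

    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)
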