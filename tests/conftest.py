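import numpy as np
import pytest

from verticality import GeneTree, LabelScheme, TaxonMap


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_tree(
    rng: np.random.Generator,
    labels: list[str],
    min_bl: float = 0.05,
    max_bl: float = 1.0,
    scheme: LabelScheme | None = None,
    tree_id: str = "rand",
) -> GeneTree:
    """Random binary topology by sequential random joins, uniform branch
    lengths.  Independent of the package's simulator."""
    parts = [f"{l}:{rng.uniform(min_bl, max_bl):.8f}" for l in labels]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(min_bl, max_bl):.8f}")
    newick = f"({parts[0]},{parts[1]});"
    return GeneTree.from_newick(newick, scheme=scheme, tree_id=tree_id)


def random_taxon_tree(
    rng: np.random.Generator,
    n_leaves: int,
    n_taxa: int,
    scheme_delim: str = "|",
):
    """Random tree whose leaves are spread over n_taxa genomes/taxa, plus
    the matching taxon map.  Taxon placement is random, so taxa are
    usually paraphyletic."""
    taxa = [f"X{t}" for t in range(n_taxa)]
    labels = []
    assignments = {}
    for i in range(n_leaves):
        taxon = taxa[int(rng.integers(n_taxa))]
        genome = f"{taxon}g{i}"
        assignments[genome] = taxon
        labels.append(f"{genome}{scheme_delim}s{i}")
    # make sure every taxon has at least one leaf
    present = {assignments[l.split(scheme_delim)[0]] for l in labels}
    tm = TaxonMap(assignments=assignments)
    gt = random_tree(rng, labels, scheme=LabelScheme(delimiter=scheme_delim))
    return gt, tm, sorted(present)
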