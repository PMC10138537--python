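"""Small helpers around dendropy trees (Newick I/O, RF distance)."""

from __future__ import annotations

import dendropy
from dendropy.calculate import treecompare

__all__ = ["parse_newick", "to_newick", "rf_distance", "leaf_labels"]


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds (symmetric difference) distance.

    Trees are re-read into a shared taxon namespace keyed by leaf label, so
    any two trees over the same label set can be compared.
    """
    if leaf_labels(a) != leaf_labels(b):
        raise ValueError("trees have different leaf label sets")
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=to_newick(a), schema="newick", taxon_namespace=ns)
    tb = dendropy.Tree.get(data=to_newick(b), schema="newick", taxon_namespace=ns)
    for t in (ta, tb):
        t.is_rooted = False
        t.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)
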