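"""Neighbor-joining and BioNJ tree construction.

Both are agglomerative: at each step the pair minimizing the Saitou-Nei
Q-criterion is joined. BioNJ additionally tracks variance estimates of the
reduced distances and chooses the averaging weight that minimizes them
(Gascuel 1997). Ties in the Q-matrix are broken by the lexicographically
lowest cluster-label pair, a cluster's label being the smallest leaf label
it contains, so the output is deterministic. On an additive matrix both
algorithms recover the generating topology and branch lengths exactly.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .distance import DistanceMatrix

__all__ = ["nj_tree", "bionj_tree"]


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining. Requires at least 3 taxa."""
    return _agglomerate(dm, bionj=False)


def bionj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """BioNJ (variance-weighted neighbor joining). Requires at least 3 taxa."""
    return _agglomerate(dm, bionj=True)


def _agglomerate(dm: DistanceMatrix, bionj: bool) -> dendropy.Tree:
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=ns)

    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)
    # cluster label used only for deterministic tie-breaking
    labels = list(dm.labels)
    d = dm.d.astype(float).copy()
    v = d.copy()  # BioNJ variance estimates
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qij = (m - 2) * d[i, j] - r[i] - r[j]
                key = (qij, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)

        if bionj:
            vij = v[i, j]
            if vij > 0:
                lam = 0.5 + sum(
                    v[j, k] - v[i, k] for k in active if k not in (i, j)
                ) / (2 * (m - 2) * vij)
                lam = min(1.0, max(0.0, lam))
            else:
                lam = 0.5
        else:
            lam = 0.5

        # reduce: cluster u replaces slot i; raw (unclamped) lengths are used
        for k in active:
            if k in (i, j):
                continue
            if bionj:
                duk = lam * (d[i, k] - li) + (1 - lam) * (d[j, k] - lj)
            else:
                duk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            vuk = lam * v[i, k] + (1 - lam) * v[j, k] - lam * (1 - lam) * v[i, j]
            d[i, k] = d[k, i] = duk
            v[i, k] = v[k, i] = vuk
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    # final three-point join
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree
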