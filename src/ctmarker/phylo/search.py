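"""Maximum-likelihood tree search: branch-length optimization and NNI.

The search mirrors the classic heuristic: build NJ and BioNJ starting trees
from TN93 distances, estimate GTR parameters on the NJ start, then for each
start optimize branch lengths (per-branch Brent optimization) and hill-climb
through nearest-neighbor interchanges, accepting a move only when it
improves the log-likelihood. The higher-scoring result is returned, so the
final likelihood is never below that of either starting tree.
"""

from __future__ import annotations

import dendropy
from scipy.optimize import minimize_scalar

from ..seq_io import Alignment
from .distance import distance_matrix
from .gtr import GTRParams, estimate_gtr_params, gtr_loglik
from .nj import bionj_tree, nj_tree

__all__ = ["optimize_branch_lengths", "nni_search", "ml_search"]

_MIN_BL = 1e-9
_MAX_BL = 5.0


def optimize_branch_lengths(
    tree: dendropy.Tree,
    alignment: Alignment,
    params: GTRParams,
    *,
    tol: float = 1e-6,
    max_passes: int = 10,
) -> float:
    """Optimize every branch length in place; returns the final lnL.

    Each pass optimizes branches one at a time with bounded scalar
    optimization; passes repeat until the likelihood gain drops below
    *tol* (or *max_passes* is hit).
    """
    edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    lnl = gtr_loglik(tree, alignment, params)
    for _ in range(max_passes):
        for node in edges:
            def neg(t: float, node=node) -> float:
                node.edge.length = t
                return -gtr_loglik(tree, alignment, params)

            res = minimize_scalar(
                neg, bounds=(_MIN_BL, _MAX_BL), method="bounded",
                options={"xatol": tol / 10},
            )
            node.edge.length = float(res.x)
        new = gtr_loglik(tree, alignment, params)
        if new - lnl < tol:
            lnl = max(new, lnl)
            break
        lnl = new
    return lnl


def _nni_moves(tree: dendropy.Tree):
    """Enumerate NNI moves as (u, v, sibling, child) node tuples.

    One internal edge (u, v) yields two moves: swapping either child of v
    with the first other child of u covers both alternative topologies
    around the edge.
    """
    moves = []
    for v in tree.preorder_node_iter():
        if v.is_leaf() or v.parent_node is None:
            continue
        u = v.parent_node
        siblings = [s for s in u.child_nodes() if s is not v]
        if not siblings:
            continue
        s = siblings[0]
        for c in list(v.child_nodes()):
            moves.append((u, v, s, c))
    return moves


def _swap(u, v, s, c) -> None:
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)


def nni_search(
    tree: dendropy.Tree,
    alignment: Alignment,
    params: GTRParams,
    *,
    tol: float = 1e-6,
    max_rounds: int = 20,
) -> float:
    """Greedy NNI hill-climb in place; returns the final lnL.

    Moves are scanned in deterministic order; the first move that improves
    the (branch-length-reoptimized) likelihood by more than *tol* is
    accepted and the scan restarts. Terminates at a local optimum.
    """
    lnl = optimize_branch_lengths(tree, alignment, params)
    for _ in range(max_rounds):
        improved = False
        for u, v, s, c in _nni_moves(tree):
            saved = {
                nd: nd.edge.length
                for nd in tree.preorder_node_iter()
                if nd.parent_node is not None
            }
            _swap(u, v, s, c)
            cand = optimize_branch_lengths(tree, alignment, params, max_passes=1)
            if cand > lnl + tol:
                lnl = optimize_branch_lengths(tree, alignment, params)
                improved = True
                break
            _swap(u, v, c, s)  # revert
            for nd, length in saved.items():
                nd.edge.length = length
        if not improved:
            break
    return lnl


def ml_search(
    alignment: Alignment,
    *,
    params: GTRParams | None = None,
    starts: tuple[str, ...] = ("nj", "bionj"),
    min_site_coverage: float | None = None,
) -> dendropy.Tree:
    """GTR maximum-likelihood tree from NJ/BioNJ starting points.

    With fewer than 4 taxa the topology is forced, so the NJ tree (with
    ML-optimized branch lengths) is returned directly. The returned tree
    carries its log-likelihood as ``tree.ln_likelihood``.
    """
    from .distance import filter_columns

    if min_site_coverage is not None:
        alignment = filter_columns(alignment, min_site_coverage)
    if len(alignment) < 3:
        raise ValueError("tree search needs at least 3 sequences")
    dm = distance_matrix(alignment, "tn93")
    builders = {"nj": nj_tree, "bionj": bionj_tree}
    start_trees = [builders[s](dm) for s in starts]
    if params is None:
        params = estimate_gtr_params(start_trees[0], alignment)
    if len(alignment) < 4:
        tree = start_trees[0]
        tree.ln_likelihood = optimize_branch_lengths(tree, alignment, params)
        tree.gtr_params = params
        return tree
    best_tree, best_lnl = None, None
    for tree in start_trees:
        lnl = nni_search(tree, alignment, params)
        if best_lnl is None or lnl > best_lnl:
            best_tree, best_lnl = tree, lnl
    best_tree.ln_likelihood = best_lnl
    best_tree.gtr_params = params
    return best_tree
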