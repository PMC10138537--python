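"""General time-reversible (GTR) substitution model.

The model is parameterized by six exchangeabilities s_AC..s_GT and four
stationary base frequencies pi. The rate matrix is

    Q_ij = s_ij * pi_j   (i != j),   Q_ii = -sum_j Q_ij,

rescaled so the expected substitution rate at stationarity is one, i.e.
branch lengths are in expected substitutions per site. Time-reversibility
(pi_i Q_ij = pi_j Q_ji) lets transition matrices be computed from a single
symmetric eigendecomposition, and makes the tree likelihood independent of
root placement.

This module provides transition matrices, sequence simulation along a tree,
the pruning log-likelihood with IUPAC-ambiguity-aware tip states, and
maximum-likelihood estimation of the exchangeabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize

from ..seq_io import Alignment, NucSequence, expand_iupac

__all__ = [
    "BASES",
    "GTRParams",
    "transition_matrix",
    "simulate_gtr_alignment",
    "gtr_loglik",
    "empirical_base_freqs",
    "estimate_gtr_params",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_PAIR_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass(frozen=True)
class GTRParams:
    """Exchangeabilities (AC, AG, AT, CG, CT, GT order) and base frequencies."""

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_freqs: tuple[float, ...] = (0.25,) * 4

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or any(
            x < 0 for x in self.exchangeabilities
        ):
            raise ValueError("need 6 non-negative exchangeabilities")
        pi = np.asarray(self.base_freqs, float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("base_freqs must be 4 positive values summing to 1")

    def rate_matrix(self) -> np.ndarray:
        """The scaled rate matrix Q (rows sum to zero, mean rate 1)."""
        s = np.zeros((4, 4))
        for rate, pair in zip(self.exchangeabilities, _PAIR_ORDER):
            i, j = _BASE_INDEX[pair[0]], _BASE_INDEX[pair[1]]
            s[i, j] = s[j, i] = rate
        pi = np.asarray(self.base_freqs)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix (all exchangeabilities zero?)")
        return q / mu

    def _eigen(self):
        """Eigendecomposition of Q via the symmetrized matrix (cached)."""
        cache = _EIG_CACHE.get(self)
        if cache is None:
            pi = np.asarray(self.base_freqs)
            q = self.rate_matrix()
            rpi = np.sqrt(pi)
            b = (rpi[:, None] * q) / rpi[None, :]
            w, u = np.linalg.eigh((b + b.T) / 2)
            cache = (w, u, rpi)
            _EIG_CACHE[self] = cache
        return cache


_EIG_CACHE: dict[GTRParams, tuple] = {}


def transition_matrix(params: GTRParams, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows index the parent state."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    w, u, rpi = params._eigen()
    inner = (u * np.exp(w * t)) @ u.T
    p = (inner / rpi[:, None]) * rpi[None, :]
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# simulation


def simulate_gtr_alignment(
    tree: dendropy.Tree,
    n_sites: int,
    params: GTRParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> Alignment:
    """Evolve *n_sites* i.i.d. sites along *tree* under the GTR model.

    Branch lengths are read as expected substitutions per site; leaves must
    carry taxa with unique labels. Returns an ungapped alignment with one
    sequence per leaf.
    """
    params = params or GTRParams()
    rng = np.random.default_rng(rng)
    pi = np.asarray(params.base_freqs)
    root = tree.seed_node
    states: dict[int, np.ndarray] = {
        id(root): rng.choice(4, size=n_sites, p=pi)
    }
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        p = transition_matrix(params, t)
        child = np.empty(n_sites, dtype=np.int64)
        u = rng.random(n_sites)
        cum = np.cumsum(p, axis=1)
        for b in range(4):
            sel = parent_state == b
            child[sel] = np.searchsorted(cum[b], u[sel], side="right")
        states[id(node)] = np.minimum(child, 3)
    seqs = []
    for leaf in tree.leaf_node_iter():
        arr = states[id(leaf)]
        seqs.append(NucSequence(leaf.taxon.label, "".join(BASES[i] for i in arr)))
    seqs.sort(key=lambda s: s.id)
    return Alignment(seqs)


# ---------------------------------------------------------------------------
# likelihood


def _tip_partials(seq: str) -> np.ndarray:
    """Per-site partial likelihoods for a tip; IUPAC codes and gaps allowed.

    An ambiguity code contributes likelihood 1 to every base it covers; a
    gap is treated as completely missing data (all ones).
    """
    out = np.zeros((len(seq), 4))
    for k, char in enumerate(seq):
        if char == "-":
            out[k, :] = 1.0
        else:
            for b in expand_iupac(char):
                out[k, _BASE_INDEX[b]] = 1.0
    return out


def gtr_loglik(
    tree: dendropy.Tree, alignment: Alignment, params: GTRParams
) -> float:
    """Log-likelihood of *alignment* on *tree* by Felsenstein pruning.

    Works for any (multifurcating) tree whose leaf taxon labels match the
    alignment ids. Per-node rescaling keeps the computation stable for long
    alignments. Raises ``ValueError`` when the result is not finite, naming
    the first offending column.
    """
    by_id = {s.id: s.residues for s in alignment.sequences}
    n_sites = alignment.column_count
    logscale = np.zeros(n_sites)
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in by_id:
                raise ValueError(f"no alignment row for leaf {label!r}")
            partials[id(node)] = _tip_partials(by_id[label])
            continue
        prod = np.ones((n_sites, 4))
        for child in node.child_nodes():
            p = transition_matrix(params, child.edge.length or 0.0)
            prod *= partials.pop(id(child)) @ p.T
        mx = prod.max(axis=1)
        bad = mx <= 0
        if np.any(bad):
            col = int(np.nonzero(bad)[0][0]) + 1
            raise ValueError(f"zero site likelihood at alignment column {col}")
        logscale += np.log(mx)
        partials[id(node)] = prod / mx[:, None]
    root_partial = partials[id(tree.seed_node)]
    site_lik = root_partial @ np.asarray(params.base_freqs)
    lnl = float(np.sum(np.log(site_lik)) + logscale.sum())
    if not np.isfinite(lnl):
        raise ValueError("non-finite log-likelihood")
    return lnl


def empirical_base_freqs(alignment: Alignment, pseudocount: float = 1.0) -> tuple:
    """Empirical A/C/G/T frequencies over unambiguous characters."""
    counts = np.full(4, pseudocount)
    for seq in alignment.sequences:
        for char in seq.residues:
            idx = _BASE_INDEX.get(char)
            if idx is not None:
                counts[idx] += 1
    freqs = counts / counts.sum()
    return tuple(float(f) for f in freqs)


def estimate_gtr_params(
    tree: dendropy.Tree, alignment: Alignment, *, tol: float = 1e-6
) -> GTRParams:
    """Estimate GTR exchangeabilities by ML on a fixed tree.

    Base frequencies are the empirical alignment frequencies; the five free
    exchangeabilities (GT fixed at 1) are optimized on a log scale with
    L-BFGS-B.
    """
    pi = empirical_base_freqs(alignment)

    def neg_loglik(log_rates: np.ndarray) -> float:
        rates = tuple(np.exp(log_rates)) + (1.0,)
        try:
            return -gtr_loglik(tree, alignment, GTRParams(rates, pi))
        except (ValueError, FloatingPointError):
            return 1e12

    res = minimize(
        neg_loglik,
        np.zeros(5),
        method="L-BFGS-B",
        bounds=[(-7, 7)] * 5,
        options={"ftol": tol},
    )
    rates = tuple(float(x) for x in np.exp(res.x)) + (1.0,)
    return GTRParams(rates, pi)
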