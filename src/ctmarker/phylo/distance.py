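"""Pairwise distances, site-coverage filtering and the distance matrix type.

The tree-building procedure first removes alignment columns with less than
95% site coverage (a column's coverage is the fraction of sequences with an
unambiguous, non-gap base there — the "partial deletion" convention), then
estimates pairwise distances. The p-distance is the raw mismatch proportion;
the TN93 distance is the closed-form Tamura-Nei estimate, which corrects
for multiple hits with distinct transition rates within purines and
pyrimidines. Saturated pairs (where the TN93 logarithms are undefined) are
reported at a large flagged value rather than raising.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..seq_io import Alignment, NucSequence

__all__ = [
    "SATURATION_DISTANCE",
    "DistanceMatrix",
    "filter_columns",
    "p_distance",
    "tn93_distance",
    "distance_matrix",
    "write_phylip",
]

#: Distance reported for saturated pairs (TN93 logarithm undefined).
SATURATION_DISTANCE = 10.0

_UNAMBIGUOUS = frozenset("ACGT")


def filter_columns(alignment: Alignment, min_coverage: float = 0.95) -> Alignment:
    """Drop columns whose coverage is below *min_coverage*.

    Coverage counts sequences with an unambiguous A/C/G/T base; gaps and
    IUPAC ambiguity codes are missing data. Raises ``ValueError`` when no
    column survives.
    """
    if not 0 <= min_coverage <= 1:
        raise ValueError("min_coverage must be in [0, 1]")
    n = len(alignment)
    keep = []
    for col in range(1, alignment.column_count + 1):
        chars = alignment.column(col)
        covered = sum(c in _UNAMBIGUOUS for c in chars)
        if covered / n >= min_coverage:
            keep.append(col)
    if not keep:
        raise ValueError("no columns pass the coverage filter")
    return alignment.take_columns(keep)


def _valid_pair_sites(a: str, b: str) -> list[int]:
    return [
        i
        for i in range(len(a))
        if a[i] in _UNAMBIGUOUS and b[i] in _UNAMBIGUOUS
    ]


def p_distance(a: NucSequence | str, b: NucSequence | str) -> float:
    """Proportion of mismatching sites, gaps/ambiguities excluded pairwise."""
    sa = a.residues if isinstance(a, NucSequence) else a
    sb = b.residues if isinstance(b, NucSequence) else b
    if len(sa) != len(sb):
        raise ValueError("sequences must have equal (aligned) length")
    sites = _valid_pair_sites(sa, sb)
    if not sites:
        raise ValueError("no valid (unambiguous, ungapped) sites shared by the pair")
    mismatches = sum(sa[i] != sb[i] for i in sites)
    return mismatches / len(sites)


def tn93_distance(a: NucSequence | str, b: NucSequence | str) -> float:
    """Tamura-Nei (1993) distance by its closed form.

    Base frequencies are taken from the pooled pair. Degenerate frequency
    situations fall back to counting-based special cases; saturation
    returns :data:`SATURATION_DISTANCE` with a warning.
    """
    sa = a.residues if isinstance(a, NucSequence) else a
    sb = b.residues if isinstance(b, NucSequence) else b
    if len(sa) != len(sb):
        raise ValueError("sequences must have equal (aligned) length")
    sites = _valid_pair_sites(sa, sb)
    if not sites:
        raise ValueError("no valid (unambiguous, ungapped) sites shared by the pair")
    n = len(sites)
    counts = {c: 0.0 for c in "ACGT"}
    p1 = p2 = q = 0
    for i in sites:
        x, y = sa[i], sb[i]
        counts[x] += 0.5
        counts[y] += 0.5
        if x != y:
            pair = {x, y}
            if pair == {"A", "G"}:
                p1 += 1
            elif pair == {"C", "T"}:
                p2 += 1
            else:
                q += 1
    if p1 + p2 + q == 0:
        return 0.0
    ga, gc, gg, gt = (counts[c] / n for c in "ACGT")
    gr, gy = ga + gg, gc + gt
    p1, p2, q = p1 / n, p2 / n, q / n
    if min(ga, gc, gg, gt) <= 0:
        # a base absent from the pair: transition corrections collapse
        return _jc69_fallback(p1 + p2 + q)
    k1 = 2 * ga * gg / gr
    k2 = 2 * gc * gt / gy
    k3 = 2 * (gr * gy - ga * gg * gy / gr - gc * gt * gr / gy)
    w1 = 1 - p1 / k1 - q / (2 * gr)
    w2 = 1 - p2 / k2 - q / (2 * gy)
    w3 = 1 - q / (2 * gr * gy)
    if min(w1, w2, w3) <= 0:
        warnings.warn("TN93 distance saturated; reporting flagged large value")
        return SATURATION_DISTANCE
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def _jc69_fallback(p: float) -> float:
    arg = 1 - 4 * p / 3
    if arg <= 0:
        warnings.warn("distance saturated; reporting flagged large value")
        return SATURATION_DISTANCE
    return -0.75 * math.log(arg)


@dataclass
class DistanceMatrix:
    """A labelled symmetric matrix of distances in substitutions/site."""

    labels: list[str]
    d: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.d[ia, ib])


def distance_matrix(alignment: Alignment, method: str = "tn93") -> DistanceMatrix:
    """All pairwise distances of an alignment ('p' or 'tn93')."""
    fn = {"p": p_distance, "tn93": tn93_distance}[method]
    labels = [s.id for s in alignment.sequences]
    n = len(labels)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            dij = fn(alignment.sequences[i], alignment.sequences[j])
            d[i, j] = d[j, i] = dij
            if dij >= SATURATION_DISTANCE:
                saturated.append((labels[i], labels[j]))
    return DistanceMatrix(labels, d, saturated)


def write_phylip(dm: DistanceMatrix, target) -> None:
    """Write a PHYLIP square distance matrix."""
    from pathlib import Path

    lines = [f"{len(dm)}"]
    for label, row in zip(dm.labels, dm.d):
        lines.append(
            f"{label:<10s} " + " ".join(f"{x:.6f}" for x in row)
        )
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)
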