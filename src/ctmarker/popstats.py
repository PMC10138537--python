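"""Allele frequencies, variability summaries, hybrid flags and consensus.

Frequency counting convention: a diploid contributes its full allele
multiset (homozygote = 2 counts), while tetra-/hexaploids contribute one
count per distinct allele carried — Sanger traces give no dosage, and this
presence-counting bias is documented rather than hidden.

The intra- vs inter-specific variability comparison is the marker's
fitness test as a phylogenetic marker: if within-species allele distances
were as large as between-species distances, species clades could not be
expected to be homogeneous. Hybrid-origin alleles (an allele sitting
closer to another species than to its own kin) can be flagged and excluded
before building per-species consensus sequences; the flag is advisory and
never applied silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import pandas as pd

from .phasing import PhaseAssignment
from .phylo.distance import p_distance
from .seq_io import NucSequence, expand_iupac, iupac_code

__all__ = [
    "AlleleFrequencyTable",
    "VariabilityReport",
    "ConsensusRecord",
    "allele_frequencies",
    "variability_report",
    "flag_hybrid_alleles",
    "species_consensus",
]


@dataclass
class AlleleFrequencyTable:
    """Ranked allele counts and frequencies for one species."""

    species: str
    entries: list[tuple[str, int, float]]  # (allele_id, count, frequency)

    def __post_init__(self) -> None:
        if self.entries:
            total = sum(f for _, _, f in self.entries)
            if abs(total - 1) > 1e-9:
                raise ValueError("frequencies must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["allele_id", "count", "frequency"]
        ).assign(species=self.species)


@dataclass
class VariabilityReport:
    """Mean within- vs between-species pairwise distance (subs/site)."""

    mean_intra: float
    mean_inter: float
    per_species_intra: dict[str, float]
    n_intra_pairs: int
    n_inter_pairs: int

    @property
    def ratio(self) -> float:
        return self.mean_intra / self.mean_inter if self.mean_inter > 0 else float("nan")

    @property
    def intra_below_inter(self) -> bool:
        return self.mean_intra < self.mean_inter


@dataclass
class ConsensusRecord:
    """A species' column-majority consensus with its exclusion audit."""

    species: str
    sequence: NucSequence
    excluded_alleles: list[tuple[str, str]] = field(default_factory=list)


def allele_frequencies(
    assignments: Sequence[PhaseAssignment],
    species: str,
    names: Mapping[str, str] | None = None,
    ploidy: int = 2,
) -> AlleleFrequencyTable:
    """Allele counts/frequencies from resolved assignments of one species.

    Only resolved samples count. Entries are ordered by decreasing
    frequency (ties by allele id) so the table is deterministic.
    """
    counts: dict[str, int] = {}
    for asg in assignments:
        if asg.status != "resolved":
            continue
        vectors = asg.alleles if ploidy == 2 else asg.distinct_alleles
        for b in vectors:
            key = names.get(b, b) if names else b
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        warnings.warn(f"species {species!r}: no resolved samples, empty table")
        return AlleleFrequencyTable(species, [])
    total = sum(counts.values())
    entries = [
        (a, c, c / total)
        for a, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return AlleleFrequencyTable(species, entries)


def _pairs_mean(distances: list[float]) -> float:
    return sum(distances) / len(distances) if distances else 0.0


def variability_report(
    alleles_by_species: Mapping[str, Sequence[NucSequence]],
    distance: Callable[[NucSequence, NucSequence], float] = p_distance,
) -> VariabilityReport:
    """Average within- vs between-species pairwise allele distance.

    Species with a single allele contribute no within-species pairs.
    Symmetric in species order. Raises with fewer than two species.
    """
    species = sorted(alleles_by_species)
    if len(species) < 2:
        raise ValueError("variability comparison needs at least 2 species")
    intra: list[float] = []
    per_species: dict[str, float] = {}
    for sp in species:
        seqs = alleles_by_species[sp]
        pair_d = [distance(a, b) for a, b in combinations(seqs, 2)]
        if pair_d:
            per_species[sp] = _pairs_mean(pair_d)
            intra.extend(pair_d)
    inter: list[float] = []
    for sa, sb in combinations(species, 2):
        for a in alleles_by_species[sa]:
            for b in alleles_by_species[sb]:
                inter.append(distance(a, b))
    return VariabilityReport(
        mean_intra=_pairs_mean(intra),
        mean_inter=_pairs_mean(inter),
        per_species_intra=per_species,
        n_intra_pairs=len(intra),
        n_inter_pairs=len(inter),
    )


def flag_hybrid_alleles(
    alleles_by_species: Mapping[str, Sequence[NucSequence]],
    distance: Callable[[NucSequence, NucSequence], float] = p_distance,
) -> list[tuple[str, str]]:
    """Advisory flags for alleles of presumable hybrid origin.

    An allele is flagged iff every nearest neighbor (minimum distance over
    all other alleles) belongs to a different species AND that distance is
    strictly below the mean within-species allele distance of its own
    species. Species with a single allele define no threshold and are
    never flagged. Returns (allele_id, reason) pairs.
    """
    species = sorted(alleles_by_species)
    if len(species) < 2:
        raise ValueError("hybrid flagging needs at least 2 species")
    intra_mean: dict[str, float] = {}
    for sp in species:
        pair_d = [
            distance(a, b) for a, b in combinations(alleles_by_species[sp], 2)
        ]
        if pair_d:
            intra_mean[sp] = _pairs_mean(pair_d)
    flagged = []
    everything = [
        (sp, seq) for sp in species for seq in alleles_by_species[sp]
    ]
    for sp, seq in everything:
        if sp not in intra_mean:
            continue
        best_d, best_species = None, set()
        for other_sp, other in everything:
            if other is seq:
                continue
            d = distance(seq, other)
            if best_d is None or d < best_d - 1e-15:
                best_d, best_species = d, {other_sp}
            elif abs(d - best_d) <= 1e-15:
                best_species.add(other_sp)
        if best_d is None:
            continue
        if sp not in best_species and best_d < intra_mean[sp]:
            foreign = ",".join(sorted(best_species))
            flagged.append(
                (
                    seq.id,
                    f"nearest neighbor in {foreign} at d={best_d:.4g} < "
                    f"own-species mean {intra_mean[sp]:.4g}",
                )
            )
    return flagged


def species_consensus(
    alleles: Sequence[NucSequence],
    species: str = "",
    excluded: Sequence[tuple[str, str]] = (),
) -> ConsensusRecord:
    """Column-wise majority consensus over the included alleles.

    Alleles named in *excluded* (id, reason) are dropped first. Per
    column: the strict majority base wins; ties among bases give the IUPAC
    code of the tied set; a strict majority of gaps gives a gap (bases win
    a base/gap tie). Ambiguity codes in the input contribute one vote per
    covered base. Raises if every allele is excluded.
    """
    drop = {a for a, _ in excluded}
    kept = [a for a in alleles if a.id not in drop]
    if not kept:
        raise ValueError(f"species {species!r}: all alleles excluded")
    lengths = {len(a) for a in kept}
    if len(lengths) != 1:
        raise ValueError("alleles must be aligned (equal length)")
    n_cols = lengths.pop()
    out = []
    for i in range(n_cols):
        chars = [a.residues[i] for a in kept]
        gaps = sum(c == "-" for c in chars)
        votes: dict[str, int] = {}
        for c in chars:
            if c in ("-", "N"):
                continue
            for b in expand_iupac(c):
                votes[b] = votes.get(b, 0) + 1
        if not votes or gaps > len(chars) - gaps:
            out.append("-" if gaps else "N")
            continue
        top = max(votes.values())
        tied = sorted(b for b, v in votes.items() if v == top)
        out.append(tied[0] if len(tied) == 1 else iupac_code(tied))
    cons_id = f"{species}_consensus" if species else "consensus"
    return ConsensusRecord(
        species,
        NucSequence(cons_id, "".join(out)),
        list(excluded),
    )
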