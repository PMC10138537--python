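"""Parsimony allele reconstruction from ambiguous genotype patterns.

A Sanger consensus of a heterozygous genotype shows an IUPAC code wherever
its alleles disagree. Over a species' biallelic polymorphic sites each
sample is a string over {1, 0, H}; the phasing problem is to explain every
sample as a multiset of binary haplotypes ("alleles").

The procedure is Clark-style parsimony, generalized to polyploids:

1. *seeding* — samples with no H site contribute their own vector to the
   allele pool; samples with exactly one H site contribute both of its
   resolutions (either way of reading a single heterozygous position is a
   real allele of the genotype);
2. *complementary-pair resolution* (diploids) — a pool allele consistent
   with a sample implies its complement (the alternative value at every H
   site), which is inferred, added to the pool, and the pair assigned;
   passes repeat until a fixpoint;
3. *minimal explanation* (tetra-/hexaploids) — the smallest subsets of the
   pool that cover every H site with both values; Sanger traces carry no
   dosage, so only the distinct-allele set is reported.

Samples with no explanation, or with several equally parsimonious ones,
keep an explicit ``unresolved``/``ambiguous`` status — in the wet lab these
are exactly the genotypes that get cloned and re-sequenced. Alleles are
only ever added to the pool, never mutated, and the processing order
(fewest H sites first, ties by sample id) is fixed so output is
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .polymorphism import GenotypePattern, PolymorphicSites
from .seq_io import NucSequence

__all__ = [
    "Allele",
    "PhaseAssignment",
    "seed_pool",
    "clark_resolve",
    "explain_polyploid",
    "phase_report",
    "name_alleles",
    "realize_alleles",
    "complement_for",
]


@dataclass(frozen=True)
class Allele:
    """A phased haplotype: binary vector over sites, optional full sequence."""

    allele_id: str
    binary: str
    sequence: NucSequence | None = None

    def __post_init__(self) -> None:
        bad = set(self.binary) - set("01")
        if bad:
            raise ValueError(f"allele vector must be over 0/1, got {sorted(bad)}")


@dataclass(frozen=True)
class PhaseAssignment:
    """A sample's explanation: multiset of allele vectors plus a status.

    For diploids ``alleles`` is the (sorted) pair, duplicates meaning
    homozygosity; for higher ploidies it is the distinct-allele set (dosage
    is not knowable from a Sanger trace). ``candidate_sets`` lists every
    equally parsimonious explanation when the status is ``ambiguous``.
    """

    sample_id: str
    alleles: tuple[str, ...]
    status: str  # 'resolved' | 'ambiguous' | 'unresolved'
    candidate_sets: tuple[tuple[str, ...], ...] = ()

    @property
    def distinct_alleles(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.alleles)))


def _consistent(allele: str, codes: str) -> bool:
    """Does the allele match the pattern at every 0/1 site (H/X free)?"""
    return all(p not in "01" or a == p for a, p in zip(allele, codes))


def complement_for(allele: str, codes: str) -> str:
    """The homologous partner: flipped at every H site, identical elsewhere."""
    return "".join(
        ("1" if a == "0" else "0") if p == "H" else a
        for a, p in zip(allele, codes)
    )


def _pool_binaries(pool: Iterable[Allele | str]) -> list[str]:
    out: list[str] = []
    for item in pool:
        binary = item.binary if isinstance(item, Allele) else item
        if binary not in out:
            out.append(binary)
    return out


def _as_alleles(binaries: Iterable[str]) -> list[Allele]:
    return [Allele(f"h{i + 1}", b) for i, b in enumerate(binaries)]


def seed_pool(patterns: Sequence[GenotypePattern]) -> list[Allele]:
    """Primary allele pool from homozygotes and single-H samples.

    A pattern with no H site is itself an allele; a pattern with exactly
    one H site yields both resolutions. Patterns with masked (X) sites are
    not seedable. The pool is deduplicated, order of first appearance.
    """
    binaries: list[str] = []
    for pat in sorted(patterns, key=lambda p: (p.n_het, p.sample_id)):
        if "X" in pat.codes:
            continue
        if pat.n_het == 0:
            candidates = [pat.codes]
        elif pat.n_het == 1:
            candidates = [
                pat.codes.replace("H", "0"),
                pat.codes.replace("H", "1"),
            ]
        else:
            continue
        for b in candidates:
            if b not in binaries:
                binaries.append(b)
    if not binaries:
        warnings.warn(
            "no homozygous or single-H samples: empty seed pool "
            "(samples would need cloning)"
        )
    return _as_alleles(binaries)


def _candidate_pairs(pat: GenotypePattern, pool: list[str]) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    if "H" not in pat.codes and "X" not in pat.codes:
        pairs.append((pat.codes, pat.codes))
    for allele in pool:
        if _consistent(allele, pat.codes):
            pair = tuple(sorted((allele, complement_for(allele, pat.codes))))
            if pair not in pairs:
                pairs.append(pair)
    return pairs


def clark_resolve(
    patterns: Sequence[GenotypePattern],
    pool: Iterable[Allele | str] = (),
) -> tuple[list[PhaseAssignment], list[Allele]]:
    """Complementary-pair resolution of diploid patterns to a fixpoint.

    In each pass, every still-unexplained sample whose explanations against
    the current pool reduce to exactly one allele pair is resolved and its
    inferred partner added to the pool; passes repeat until nothing
    changes. Samples explainable by several distinct pairs end
    ``ambiguous`` (all pairs listed), samples with no explanation
    ``unresolved``. Returns assignments (input order) and the final pool
    (a superset of the seed pool; alleles are only added, never mutated).
    """
    pool_list = _pool_binaries(pool)
    order = sorted(patterns, key=lambda p: (p.n_het, p.sample_id))
    resolved: dict[str, tuple[str, str]] = {}
    changed = True
    while changed:
        changed = False
        for pat in order:
            if pat.sample_id in resolved:
                continue
            pairs = _candidate_pairs(pat, pool_list)
            if len(pairs) == 1:
                pair = pairs[0]
                resolved[pat.sample_id] = pair
                for b in pair:
                    if b not in pool_list:
                        pool_list.append(b)
                changed = True
    assignments = []
    for pat in patterns:
        if pat.sample_id in resolved:
            assignments.append(
                PhaseAssignment(pat.sample_id, resolved[pat.sample_id], "resolved")
            )
            continue
        pairs = _candidate_pairs(pat, pool_list)
        if pairs:
            assignments.append(
                PhaseAssignment(
                    pat.sample_id, (), "ambiguous", tuple(sorted(pairs))
                )
            )
        else:
            assignments.append(PhaseAssignment(pat.sample_id, (), "unresolved"))
    return assignments, _as_alleles(pool_list)


def explain_polyploid(
    pattern: GenotypePattern,
    pool: Iterable[Allele | str],
    ploidy: int,
) -> PhaseAssignment:
    """Minimal-cardinality explanation of a polyploid pattern from a pool.

    Searches subsets of pool alleles of increasing size (up to *ploidy*)
    such that every 0/1 site is matched by all members and every H site is
    covered by both values. A unique minimal subset resolves the sample;
    several are reported as ambiguous; none as unresolved.
    """
    if ploidy < 2:
        raise ValueError("ploidy must be >= 2")
    pool_list = _pool_binaries(pool)
    candidates = [a for a in pool_list if _consistent(a, pattern.codes)]
    h_sites = [i for i, p in enumerate(pattern.codes) if p == "H"]
    solutions: list[tuple[str, ...]] = []
    for k in range(1, min(ploidy, len(candidates)) + 1):
        for subset in combinations(candidates, k):
            if all(
                {a[i] for a in subset} == {"0", "1"} for i in h_sites
            ):
                solutions.append(tuple(sorted(subset)))
        if solutions:
            break
    if len(solutions) == 1:
        return PhaseAssignment(pattern.sample_id, solutions[0], "resolved")
    if solutions:
        return PhaseAssignment(
            pattern.sample_id, (), "ambiguous", tuple(sorted(solutions))
        )
    return PhaseAssignment(pattern.sample_id, (), "unresolved")


# ---------------------------------------------------------------------------
# reporting and realization


def phase_report(
    assignments: Mapping[str, Sequence[PhaseAssignment]],
    ploidies: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-species summary: genotype/allele counts and zygosity.

    *assignments* maps species to its samples' assignments. Homozygotes are
    resolved samples with a single distinct allele. The unresolved column
    lists samples that stayed ambiguous/unresolved (the cloning-needed
    list).
    """
    rows = []
    for species in sorted(assignments):
        asg = assignments[species]
        resolved = [a for a in asg if a.status == "resolved"]
        uniq = sorted({b for a in resolved for b in a.alleles})
        n_hom = sum(len(set(a.alleles)) == 1 for a in resolved)
        pending = sorted(a.sample_id for a in asg if a.status != "resolved")
        rows.append(
            {
                "species": species,
                "n_genotypes": len(asg),
                "n_unique_alleles": len(uniq),
                "n_homozygotes": n_hom,
                "n_heterozygotes": len(resolved) - n_hom,
                "max_alleles_per_plant": max(
                    (len(set(a.alleles)) for a in resolved), default=0
                ),
                "ploidy": (ploidies or {}).get(species, ""),
                "unresolved_samples": ",".join(pending),
            }
        )
    return pd.DataFrame(rows)


def name_alleles(
    assignments: Sequence[PhaseAssignment],
    prefix: str = "",
    ploidy: int = 2,
) -> dict[str, str]:
    """Letter names (A, B, C ...) by decreasing allele frequency.

    Counting follows the frequency convention: diploids contribute their
    full multiset (a homozygote counts twice), polyploids one presence per
    carrier. Ties are broken by the binary vector, so naming is
    deterministic.
    """
    counts: dict[str, int] = {}
    for asg in assignments:
        if asg.status != "resolved":
            continue
        vectors = asg.alleles if ploidy == 2 else asg.distinct_alleles
        for b in vectors:
            counts[b] = counts.get(b, 0) + 1
    ordered = sorted(counts, key=lambda b: (-counts[b], b))
    names = {}
    for i, b in enumerate(ordered):
        letter = ""
        k = i
        while True:
            letter = chr(ord("A") + k % 26) + letter
            k = k // 26 - 1
            if k < 0:
                break
        names[b] = f"{prefix}{letter}"
    return names


def realize_alleles(
    sites: PolymorphicSites,
    names: Mapping[str, str],
    backbone: NucSequence,
) -> list[Allele]:
    """Turn binary vectors into full sequences on a species backbone.

    The backbone is the species' (aligned) consensus; each allele replaces
    the polymorphic columns with its major ('1') or minor ('0') base.
    """
    alleles = []
    for binary, allele_id in names.items():
        residues = list(backbone.residues)
        for bit, site in zip(binary, sites.sites):
            residues[site.column - 1] = site.major if bit == "1" else site.minor
        alleles.append(
            Allele(allele_id, binary, NucSequence(allele_id, "".join(residues)))
        )
    return alleles
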