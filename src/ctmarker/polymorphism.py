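"""Polymorphic-site discovery, binary genotype encoding and indel calls.

A species' variable alignment columns are summarized as ranked base
frequencies: at each biallelic column the commoner base is written "1" and
the rarer base "0", so a sample becomes a short string over {1, 0, H} where
H marks a heterozygous (IUPAC-ambiguous) position covering both states.
This is the representation the combinatorial phasing stage consumes.

Base counting expands ambiguity codes, so a heterozygote contributes one
observation to each base it covers; ``N`` and gaps are treated as missing.
Columns containing alignment gaps are excluded from SNP discovery — length
variation is handled separately by :func:`catalog_indels`, which aligns an
allele to the reference coding sequence (affine gap penalties chosen so one
biological indel appears as one gap run) and reports every gap run with
1-based reference coordinates and a reading-frame flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .seq_io import Alignment, NucSequence, expand_iupac

__all__ = [
    "Site",
    "PolymorphicSites",
    "GenotypePattern",
    "IndelRecord",
    "DeletionSpan",
    "find_polymorphic_sites",
    "binary_encode",
    "catalog_indels",
    "deletion_span",
]


@dataclass(frozen=True)
class Site:
    """One biallelic polymorphic alignment column (1-based)."""

    column: int
    major: str
    minor: str
    major_count: int
    minor_count: int

    def __post_init__(self) -> None:
        if self.major == self.minor:
            raise ValueError("major and minor base must differ")
        if self.major_count < self.minor_count:
            raise ValueError("major_count must be >= minor_count")


@dataclass
class PolymorphicSites:
    """Ranked-frequency site list for one species (columns increasing)."""

    species: str
    sites: list[Site]
    multiallelic_columns: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = [s.column for s in self.sites]
        if cols != sorted(set(cols)):
            raise ValueError("site columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def columns(self) -> list[int]:
        return [s.column for s in self.sites]


@dataclass(frozen=True)
class GenotypePattern:
    """A sample over the polymorphic sites: '1', '0', 'H' or 'X' (masked)."""

    sample_id: str
    codes: str
    ploidy: int = 2

    def __post_init__(self) -> None:
        bad = set(self.codes) - set("10HX")
        if bad:
            raise ValueError(f"invalid pattern codes {sorted(bad)}")

    @property
    def n_het(self) -> int:
        return self.codes.count("H")

    @property
    def is_unambiguous(self) -> bool:
        return "H" not in self.codes


@dataclass(frozen=True)
class IndelRecord:
    """A gap run relative to the reference CDS, 1-based inclusive.

    An insertion has zero reference extent; its coordinates give the
    reference base immediately 5' of the inserted material (0 for an
    insertion before the first base).
    """

    allele_id: str
    ref_start: int
    ref_end: int
    kind: str  # 'insertion' | 'deletion'
    length: int

    @property
    def frame_preserving(self) -> bool:
        return self.length % 3 == 0


@dataclass(frozen=True)
class DeletionSpan:
    """The largest deletion of a sample, in reference CDS coordinates."""

    start: int
    end: int
    to_end_of_gene: bool = False

    def __str__(self) -> str:
        suffix = " (to end of gene)" if self.to_end_of_gene else ""
        return f"{self.start}-{self.end}{suffix}"


# ---------------------------------------------------------------------------
# SNP sites


def _base_counts(chars: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for char in chars:
        if char in ("-", "N"):
            continue
        for base in expand_iupac(char):
            counts[base] = counts.get(base, 0) + 1
    return counts


def find_polymorphic_sites(
    alignment: Alignment,
    species: str = "",
    sample_ids: Sequence[str] | None = None,
) -> PolymorphicSites:
    """Biallelic polymorphic columns among a species' samples.

    *sample_ids* restricts the scan to a subset of the alignment (one
    species); omit it to scan jointly. Columns containing any alignment gap
    are excluded from SNP discovery, as are columns with more than two
    observed bases (counted in ``multiallelic_columns`` — the binary
    representation is biallelic by design). A frequency tie is broken
    alphabetically (major = alphabetically first) with a warning.
    """
    sub = alignment.select(sample_ids) if sample_ids is not None else alignment
    result = PolymorphicSites(species, [])
    if len(sub) < 2:
        msg = f"species {species!r}: fewer than 2 sequences, no sites callable"
        warnings.warn(msg)
        result.warnings.append(msg)
        return result
    sites = []
    for col in range(1, sub.column_count + 1):
        chars = sub.column(col)
        if "-" in chars:
            continue
        counts = _base_counts(chars)
        if len(counts) < 2:
            continue
        if len(counts) > 2:
            result.multiallelic_columns.append(col)
            continue
        (b1, c1), (b2, c2) = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if c1 == c2:
            msg = (
                f"species {species!r} column {col}: frequency tie {b1}/{b2}, "
                "major assigned alphabetically"
            )
            warnings.warn(msg)
            result.warnings.append(msg)
        sites.append(Site(col, b1, b2, c1, c2))
    result.sites = sites
    return result


def binary_encode(sites: PolymorphicSites, sample: NucSequence) -> GenotypePattern:
    """Encode one (aligned) sample over a species' polymorphic sites.

    Per site: the major base gives '1', the minor '0', an ambiguity code
    covering both gives 'H'. A base covering neither (a third allele, a
    gap, or N at the site) is flagged and masked as 'X'; masked sites are
    ignored by the phasing stage for this sample.
    """
    codes = []
    for site in sites.sites:
        char = sample.residues[site.column - 1]
        if char in ("-", "N"):
            covered = frozenset()
        else:
            covered = expand_iupac(char) & {site.major, site.minor}
        if covered == {site.major}:
            codes.append("1")
        elif covered == {site.minor}:
            codes.append("0")
        elif covered == {site.major, site.minor}:
            codes.append("H")
        else:
            warnings.warn(
                f"sample {sample.id!r} column {site.column}: base {char!r} covers "
                "neither major nor minor (multi-allelic); site masked for this sample"
            )
            codes.append("X")
    return GenotypePattern(sample.id, "".join(codes))


# ---------------------------------------------------------------------------
# indels


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def catalog_indels(allele: NucSequence, reference_cds: NucSequence) -> list[IndelRecord]:
    """Gap runs of a global allele-vs-reference alignment.

    Both inputs are unaligned (gap-free) sequences; the allele is aligned
    to the reference with affine gap scoring (match +1, mismatch -1, gap
    open -10, extend -0.5) so that one biological indel yields one gap run.
    Each maximal run is reported with 1-based reference CDS coordinates and
    a frame-preservation flag (length divisible by three).
    """
    a = allele.residues.replace("-", "")
    r = reference_cds.residues.replace("-", "")
    if not a or not r:
        raise ValueError("empty sequence")
    alignment = _make_aligner().align(r, a)[0]
    ref_row, allele_row = str(alignment[0]), str(alignment[1])
    records: list[IndelRecord] = []
    ref_pos = 0  # 1-based coordinate of the last consumed reference base
    run_kind: str | None = None
    run_start = run_len = 0
    for rc, ac in zip(ref_row, allele_row):
        kind = None
        if rc == "-":
            kind = "insertion"
        elif ac == "-":
            kind = "deletion"
        if kind != run_kind and run_kind is not None:
            records.append(_close_run(allele.id, run_kind, run_start, run_len, ref_pos))
            run_kind = None
        if kind is not None:
            if run_kind is None:
                run_kind = kind
                run_start = ref_pos + 1  # first deleted ref base (deletions)
                run_len = 0
            run_len += 1
        if rc != "-":
            ref_pos += 1
    if run_kind is not None:
        records.append(_close_run(allele.id, run_kind, run_start, run_len, ref_pos))
    return records


def _close_run(allele_id, kind, run_start, run_len, ref_pos) -> IndelRecord:
    if kind == "deletion":
        return IndelRecord(allele_id, run_start, run_start + run_len - 1, kind, run_len)
    # insertion: anchored at the reference base 5' of the run
    anchor = run_start - 1
    return IndelRecord(allele_id, anchor, anchor, kind, run_len)


def deletion_span(
    sample_sequence: NucSequence, reference_cds: NucSequence
) -> DeletionSpan | None:
    """The largest deletion of a sample relative to the reference CDS.

    Returns ``None`` for a full-length sample. A span reaching the final
    reference base is labelled ``to_end_of_gene``. Ties on length are
    broken by the leftmost span.
    """
    deletions = [
        r for r in catalog_indels(sample_sequence, reference_cds)
        if r.kind == "deletion"
    ]
    if not deletions:
        return None
    best = max(deletions, key=lambda r: (r.length, -r.ref_start))
    ref = reference_cds.residues.replace("-", "")
    ref_len = len(ref)
    start, end = best.ref_start, best.ref_end
    # a deletion inside a repeat has several equivalent placements; slide it
    # right so a terminal truncation is reported as reaching the gene end
    s, e = start, end
    while e < ref_len and ref[s - 1] == ref[e]:
        s += 1
        e += 1
    if e == ref_len:
        start, end = s, e
    return DeletionSpan(start, end, end == ref_len)
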