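"""In-silico PCR and open-reading-frame annotation for the marker locus.

The marker here is a single-copy *rolB/C*-like cT-DNA gene; PCR primers for
it are anchored in the flanking host sequence or inside the coding sequence.
``find_amplicon`` predicts product coordinates and sizes for a primer pair,
``find_orf`` annotates ATG->stop open reading frames on both strands.

Amplicon sizes include both primers, so a predicted size is directly
comparable with a product length on a gel. All coordinates are 1-based
inclusive on the forward strand of the template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from Bio.Seq import Seq

from .seq_io import NucSequence, expand_iupac, revcomp

__all__ = [
    "PrimerPair",
    "AmpliconHit",
    "OrfRecord",
    "STUDY_PRIMERS",
    "find_amplicon",
    "find_orf",
    "read_primer_table",
]


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair; both sequences written 5'->3'."""

    name: str
    forward: NucSequence
    reverse: NucSequence
    annealing_temp: float | None = None
    expected_size: int | None = None

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if not 15 <= len(primer) <= 35:
                raise ValueError(
                    f"primer {primer.id!r}: length {len(primer)} outside 15..35 nt"
                )
            if any(c not in "ACGT" for c in primer.residues):
                raise ValueError(f"primer {primer.id!r}: must be unambiguous A/C/G/T")


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product on the + strand of a template."""

    template_id: str
    start: int  # 1-based, 5' end of the forward primer site
    end: int  # 1-based inclusive, 3' end of the reverse primer site
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class OrfRecord:
    """An ATG->stop open reading frame; the span includes the stop codon."""

    template_id: str
    cds_start: int
    cds_end: int
    strand: str  # '+' or '-'
    protein_length: int  # amino acids, stop codon excluded

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def coding_length(self) -> int:
        """CDS length in nt excluding the stop codon (protein_length * 3)."""
        return self.length - 3


def _primer_pair(name, fwd_name, fwd, rev_name, rev, tm, size):
    return PrimerPair(
        name,
        NucSequence(fwd_name, fwd),
        NucSequence(rev_name, rev),
        annealing_temp=tm,
        expected_size=size,
    )


#: The published primer pairs for the marker locus, keyed by pair name.
#: Sizes are the published product sizes on the reference fragment.
STUDY_PRIMERS: dict[str, PrimerPair] = {
    "Vacc_vn": _primer_pair(
        "Vacc_vn",
        "VaccFvn", "TCCTAACCCTAACCCTGACC",
        "VaccRvn", "AACTCGTGATTGTACCTCGTT",
        50, 1503,
    ),
    "Vacc": _primer_pair(
        "Vacc",
        "VaccF", "CACGTGTAAAGCCCGTGATGTT",
        "VaccR", "TTACTGGCCGGTCCTCATCA",
        55, 1002,
    ),
    "Vacc_ts": _primer_pair(
        "Vacc_ts",
        "Vacc_ts_F", "TAAAGCCTGCCACTGCGATT",
        "Vacc_ts_pR", "CCAATCGCCACGAGTAACTAAC",
        55, 838,
    ),
}


def _matches_at(template: str, pos: int, primer: str, max_mismatches: int) -> int | None:
    """Mismatch count if *primer* anneals at 0-based *pos*, else None.

    Template ambiguity codes match permissively (any covered base); the
    primer's 3'-terminal base must match exactly regardless of the budget.
    """
    if pos < 0 or pos + len(primer) > len(template):
        return None
    mism = 0
    last = len(primer) - 1
    for i, base in enumerate(primer):
        t = template[pos + i]
        if t == "-":
            return None
        ok = base in expand_iupac(t)
        if not ok:
            if i == last:
                return None
            mism += 1
            if mism > max_mismatches:
                return None
    return mism


def _primer_sites(template: str, primer: str, max_mismatches: int) -> list[tuple[int, int]]:
    sites = []
    for pos in range(len(template) - len(primer) + 1):
        m = _matches_at(template, pos, primer, max_mismatches)
        if m is not None:
            sites.append((pos, m))
    return sites


def find_amplicon(
    template: NucSequence,
    primer_pair: PrimerPair,
    max_mismatches: int = 0,
    max_length: int = 10_000,
) -> list[AmpliconHit]:
    """Predict PCR products of *primer_pair* on the + strand of *template*.

    The forward primer is matched on the + strand and the reverse primer's
    reverse complement downstream of it; the product spans the 5' end of the
    forward site through the 3' end of the reverse site, primers included.
    All pairings up to *max_length* are reported, sorted by start then
    length. More than ten hits triggers a nonspecific-primer warning.
    """
    seq = template.residues
    fwd_sites = _primer_sites(seq, primer_pair.forward.residues, max_mismatches)
    rev_rc = revcomp(primer_pair.reverse.residues)
    rev_sites = _primer_sites(seq, rev_rc, max_mismatches)

    hits = []
    for fpos, fm in fwd_sites:
        for rpos, rm in rev_sites:
            end = rpos + len(rev_rc)  # 0-based exclusive
            length = end - fpos
            if rpos >= fpos + len(primer_pair.forward) and length <= max_length:
                hits.append(AmpliconHit(template.id, fpos + 1, end, fm, rm))
    hits.sort(key=lambda h: (h.start, h.length))
    if len(hits) > 10:
        warnings.warn(
            f"{primer_pair.name}: {len(hits)} products on {template.id} "
            "(nonspecific primers?)"
        )
    return hits


_STOPS = {"TAA", "TAG", "TGA"}


def find_orf(template: NucSequence, min_length: int = 300) -> list[OrfRecord]:
    """All ATG->stop ORFs of at least *min_length* nt on both strands.

    The reported span includes the stop codon; ``protein_length`` excludes
    it. Nested ORFs (an internal in-frame ATG) are suppressed: only the
    longest ORF per stop codon and frame is reported. Results are sorted
    longest first; coordinates are always on the + strand of the template.
    """
    n = len(template)
    records = []
    for strand, seq in (("+", template.residues), ("-", revcomp(template.residues))):
        for frame in range(3):
            start_pending: int | None = None
            for pos in range(frame, len(seq) - 2, 3):
                codon = seq[pos : pos + 3]
                if codon == "ATG" and start_pending is None:
                    start_pending = pos
                elif codon in _STOPS and start_pending is not None:
                    span = pos + 3 - start_pending
                    if span >= min_length:
                        if strand == "+":
                            s, e = start_pending + 1, pos + 3
                        else:
                            s, e = n - (pos + 3) + 1, n - start_pending
                        records.append(
                            OrfRecord(template.id, s, e, strand, span // 3 - 1)
                        )
                    start_pending = None
    records.sort(key=lambda r: (-r.length, r.cds_start, r.strand))
    return records


def read_primer_table(source) -> dict[str, PrimerPair]:
    """Read primer pairs from a TSV (name, forward, reverse, tm, expected_size)."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t")
    pairs = {}
    for row in df.itertuples(index=False):
        size = None if pd.isna(getattr(row, "expected_size", None)) else int(row.expected_size)
        tm = None if pd.isna(getattr(row, "tm", None)) else float(row.tm)
        pairs[row.name] = _primer_pair(
            row.name, f"{row.name}_F", row.forward, f"{row.name}_R", row.reverse, tm, size
        )
    return pairs


def translate_span(template: NucSequence, orf: OrfRecord) -> str:
    """Translate an OrfRecord's span (standard code), stop codon trimmed."""
    sub = template.residues[orf.cds_start - 1 : orf.cds_end]
    if orf.strand == "-":
        sub = revcomp(sub)
    return str(Seq(sub).translate())[:-1]
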