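"""Sequence and alignment containers plus FASTA/TSV input-output.

Conventions used throughout the package:

* coordinates are 1-based and inclusive (reports say "nucleotides 198 to 800"
  and mean exactly those bases);
* the only gap character is ``-`` (``.`` is rejected);
* ``U`` is silently converted to ``T`` on input;
* residues are upper-cased on input and may contain the IUPAC nucleotide
  ambiguity codes, which is how a heterozygous position in a Sanger
  consensus is written.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

__all__ = [
    "IUPAC_SETS",
    "SET_CODES",
    "NucSequence",
    "Alignment",
    "SampleRecord",
    "expand_iupac",
    "iupac_code",
    "revcomp",
    "parse_fasta",
    "write_fasta",
    "read_sample_table",
    "write_sample_table",
]

#: IUPAC nucleotide ambiguity codes mapped to the base sets they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse mapping: base set -> single-letter code.
SET_CODES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

ALLOWED_CHARS = frozenset(IUPAC_SETS) | {"-"}


def expand_iupac(code: str) -> frozenset[str]:
    """Return the set of bases denoted by a single IUPAC symbol.

    ``A/C/G/T`` map to singletons, ``N`` to all four bases. Raises
    ``ValueError`` for anything that is not a valid IUPAC nucleotide symbol
    (the gap character included).
    """
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC nucleotide symbol: {code!r}") from None


def iupac_code(bases: Iterable[str]) -> str:
    """Return the IUPAC symbol for a non-empty set of bases (e.g. {A,G} -> R)."""
    key = frozenset(b.upper() for b in bases)
    try:
        return SET_CODES[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(key)}") from None


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string, IUPAC codes and gaps included."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot complement symbol {exc.args[0]!r}") from None


def _clean_residues(raw: str, *, record_id: str) -> str:
    residues = raw.upper().replace("U", "T")
    for pos, char in enumerate(residues, start=1):
        if char not in ALLOWED_CHARS:
            if char == ".":
                raise ValueError(
                    f"record {record_id!r}: '.' at position {pos}; "
                    "only '-' is accepted as a gap character"
                )
            raise ValueError(
                f"record {record_id!r}: illegal character {char!r} at position {pos}"
            )
    return residues


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over the IUPAC alphabet plus ``-``."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(
            self, "residues", _clean_residues(self.residues, record_id=self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "NucSequence":
        """Copy with all gap characters removed."""
        return NucSequence(self.id, self.residues.replace("-", ""), self.description)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, revcomp(self.residues), self.description)


@dataclass
class Alignment:
    """A list of equal-length sequences; columns addressed 1-based inclusive."""

    sequences: list[NucSequence]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment needs at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def column_count(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def column(self, i: int) -> str:
        """Residues of 1-based column *i* across all sequences."""
        if not 1 <= i <= self.column_count:
            raise IndexError(f"column {i} out of range 1..{self.column_count}")
        return "".join(s.residues[i - 1] for s in self.sequences)

    def select(self, ids: Iterable[str]) -> "Alignment":
        wanted = set(ids)
        return Alignment([s for s in self.sequences if s.id in wanted])

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """Sub-alignment of the given 1-based columns, order preserved."""
        idx = [c - 1 for c in columns]
        return Alignment(
            [
                NucSequence(s.id, "".join(s.residues[i] for i in idx), s.description)
                for s in self.sequences
            ]
        )


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced genotype: metadata plus its marker consensus sequence."""

    sample_id: str
    species: str
    location: str
    ploidy: int
    sequence: NucSequence

    def __post_init__(self) -> None:
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError(
                f"sample {self.sample_id!r}: ploidy must be an even integer >= 2, "
                f"got {self.ploidy}"
            )


PathOrStream = Union[str, Path, TextIO]


def _as_handle(source: PathOrStream):
    if isinstance(source, (str, Path)):
        return open(source), True
    return source, False


def parse_fasta(source: PathOrStream) -> list[NucSequence]:
    """Read a multi-record FASTA into :class:`NucSequence` objects.

    Residues are upper-cased, ``U`` becomes ``T``; record order is preserved.
    Raises ``ValueError`` on an empty file, a duplicate id, or an illegal
    character (the error names the record and 1-based position).
    """
    handle, close = _as_handle(source)
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(NucSequence(rec.id, str(rec.seq), desc))
    finally:
        if close:
            handle.close()
    if not records:
        raise ValueError("no records in FASTA input")
    return records


def write_fasta(
    sequences: Iterable[NucSequence], target: PathOrStream, *, width: int = 70
) -> None:
    """Write FASTA, wrapped at *width* columns."""
    if isinstance(target, (str, Path)):
        handle: TextIO = open(target, "w")
        close = True
    else:
        handle, close = target, False
    try:
        for seq in sequences:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                handle.write(seq.residues[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


_SAMPLE_COLUMNS = ["sample_id", "species", "location", "ploidy"]


def read_sample_table(
    source: PathOrStream, sequences: Mapping[str, NucSequence] | None = None
) -> list[SampleRecord] | pd.DataFrame:
    """Read the sample metadata TSV (sample_id/species/location/ploidy).

    If *sequences* (a mapping sample_id -> NucSequence) is given, full
    :class:`SampleRecord` objects are returned; otherwise the raw DataFrame.
    """
    df = pd.read_csv(source, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if sequences is None:
        return df
    records = []
    for row in df.itertuples(index=False):
        try:
            seq = sequences[row.sample_id]
        except KeyError:
            raise ValueError(
                f"sample {row.sample_id!r} has no sequence in the FASTA input"
            ) from None
        records.append(
            SampleRecord(row.sample_id, row.species, str(row.location), int(row.ploidy), seq)
        )
    return records


def write_sample_table(samples: Iterable[SampleRecord], target: PathOrStream) -> None:
    rows = [
        (s.sample_id, s.species, s.location, s.ploidy) for s in samples
    ]
    pd.DataFrame(rows, columns=_SAMPLE_COLUMNS).to_csv(target, sep="\t", index=False)
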