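"""Sequence input/output and strand primitives.

Reads plain multi-record FASTA and the dbSNP-style "rs_fastA" dialect in
which each header carries the SNP position and the sequence length
(``pos = 501|len1001``) and the sequence body carries an IUPAC ambiguity
code at the SNP site.  Also provides the reverse-complement and
IUPAC-expansion primitives every other module builds on.

Coordinates are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 4 bases plus the 11 IUPAC ambiguity codes.
ALPHABET = frozenset("ACGTRYMKWSBDHVN")

#: Ambiguity codes only (every member expands to >= 2 bases).
AMBIGUITY_CODES = frozenset("RYMKWSBDHVN")

#: IUPAC code -> alphabetically ordered base set.
IUPAC_EXPANSION: dict[str, tuple[str, ...]] = {
    "A": ("A",),
    "C": ("C",),
    "G": ("G",),
    "T": ("T",),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "M": ("A", "C"),
    "K": ("G", "T"),
    "W": ("A", "T"),
    "S": ("C", "G"),
    "B": ("C", "G", "T"),
    "D": ("A", "G", "T"),
    "H": ("A", "C", "T"),
    "V": ("A", "C", "G"),
    "N": ("A", "C", "G", "T"),
}

#: Complement map over the full 15-letter alphabet (R<->Y, M<->K, W/S/N self).
COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "M": "K", "K": "M",
    "W": "W", "S": "S", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_COMPLEMENT_TABLE = str.maketrans(COMPLEMENT)

# "pos = 501|len1001" with optional whitespace around "=".
_RS_HEADER_RE = re.compile(r"pos\s*=\s*(\d+)\|len(\d+)")


class SequenceFormatError(ValueError):
    """Malformed FASTA / rs_fastA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One input DNA sequence; the substrate for candidate scanning."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceFormatError(f"invalid record id: {self.id!r}")
        if not self.residues:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceFormatError(
                f"record {self.id!r}: illegal residue character(s) "
                f"{sorted(bad)} (allowed: A/C/G/T and IUPAC ambiguity codes)"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]

    def subsequence(self, start: int, end: int) -> str:
        """Plus-strand substring for the 1-based inclusive span [start, end]."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(
                f"span {start}..{end} outside 1..{len(self.residues)} "
                f"for record {self.id!r}"
            )
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class SnpRecord:
    """A flanking-sequence record with a single polymorphic site.

    The SNP itself is the IUPAC ambiguity code found at ``snp_position``
    (1-based) in the record body; ``alleles`` is its expansion in
    alphabetical order.
    """

    record: SequenceRecord
    snp_position: int
    declared_length: int
    iupac_code: str = field(init=False, default="")
    alleles: tuple[str, ...] = field(init=False, default=())

    def __post_init__(self) -> None:
        seq = self.record.residues
        if not 1 <= self.snp_position <= len(seq):
            raise SequenceFormatError(
                f"record {self.record.id!r}: SNP position {self.snp_position} "
                f"outside sequence of length {len(seq)}"
            )
        if self.declared_length != len(seq):
            raise SequenceFormatError(
                f"record {self.record.id!r}: declared length {self.declared_length} "
                f"!= actual sequence length {len(seq)}"
            )
        code = seq[self.snp_position - 1]
        if code not in AMBIGUITY_CODES:
            raise SequenceFormatError(
                f"record {self.record.id!r}: no ambiguity code at SNP site "
                f"(position {self.snp_position} holds {code!r})"
            )
        object.__setattr__(self, "iupac_code", code)
        object.__setattr__(self, "alleles", IUPAC_EXPANSION[code])

    @property
    def id(self) -> str:
        return self.record.id

    def __len__(self) -> int:
        return len(self.record)


def expand_iupac(code: str) -> tuple[str, ...]:
    """Bases denoted by one IUPAC letter, in alphabetical order.

    >>> expand_iupac("R")
    ('A', 'G')
    """
    try:
        return IUPAC_EXPANSION[code.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    """Antiparallel complement of a 5'->3' residue string.

    Ambiguity codes map to their IUPAC complements, so the operation is an
    involution over the full alphabet.
    """
    s = seq.upper()
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"illegal residue character(s): {sorted(bad)}")
    return s.translate(_COMPLEMENT_TABLE)[::-1]


def _iter_biopython(path: str | Path) -> Iterable[SeqRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a multi-record FASTA file in file order.

    Residues are uppercased and internal whitespace is folded away
    (Biopython's parser already joins wrapped sequence lines).  Duplicate
    ids and characters outside the 15-letter IUPAC alphabet are errors.
    """
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _iter_biopython(path):
        if rec.id in seen:
            raise SequenceFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper().replace(" ", ""),
                description=rec.description,
            )
        )
    return out


def read_rs_fasta(path: str | Path) -> list[SnpRecord]:
    """Parse a dbSNP-style flanking-sequence FASTA file.

    Each header must embed ``pos = <int>|len<int>`` (whitespace around the
    ``=`` is tolerated); the base at the declared position must be an IUPAC
    ambiguity code.  The id is the first whitespace-delimited header token;
    the full header is kept as the description.
    """
    out: list[SnpRecord] = []
    for rec in read_fasta(path):
        m = _RS_HEADER_RE.search(rec.description)
        if m is None:
            raise SequenceFormatError(
                f"record {rec.id!r}: header lacks the 'pos = <int>|len<int>' pattern"
            )
        out.append(
            SnpRecord(
                record=rec,
                snp_position=int(m.group(1)),
                declared_length=int(m.group(2)),
            )
        )
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with fixed-width sequence lines."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def to_biopython(rec: SequenceRecord) -> SeqRecord:
    """Convert to a Bio.SeqRecord (for interop with Biopython pipelines)."""
    return SeqRecord(Seq(rec.residues), id=rec.id, description=rec.description)
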