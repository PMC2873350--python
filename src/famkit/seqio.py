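"""Sequence records and FASTA input/output.

Records are plain immutable dataclasses; parsing is delegated to
:mod:`Bio.SeqIO` with validation (alphabet composition, unique ids, non-empty
sequences) layered on top.  All residue positions in the package are 1-based
inclusive, and alignment columns are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .errors import FormatError

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
GAP = "-"

#: Minimum fraction of characters that must belong to the declared alphabet.
ALPHABET_TOLERANCE = 0.95


@dataclass(frozen=True)
class SeqRecord:
    """One protein or nucleotide sequence.

    Parameters
    ----------
    id:
        Accession-like token, unique within a file's record set.
    residues:
        Upper-case ungapped sequence.
    moltype:
        ``"protein"`` or ``"nucleotide"``; must be consistent with the
        residue alphabet (at least 95% of characters in the declared
        alphabet).
    """

    id: str
    residues: str
    moltype: str = "protein"
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record must have a non-empty id")
        if not self.residues:
            raise FormatError(f"empty sequence for record {self.id!r}")
        if self.moltype not in ("protein", "nucleotide"):
            raise FormatError(f"unknown moltype {self.moltype!r}")
        alphabet = (
            PROTEIN_ALPHABET if self.moltype == "protein" else NUCLEOTIDE_ALPHABET
        )
        n_ok = sum(1 for c in self.residues if c in alphabet)
        if n_ok < ALPHABET_TOLERANCE * len(self.residues):
            raise FormatError(
                f"record {self.id!r}: more than 5% of characters fall outside "
                f"the {self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedRecord:
    """A sequence embedded in an alignment: the record plus its gapped string."""

    record: SeqRecord
    gapped: str

    def __post_init__(self):
        if self.gapped.replace(GAP, "") != self.record.residues:
            raise FormatError(
                f"gapped string for {self.record.id!r} does not reduce to "
                "the ungapped residues"
            )

    @property
    def id(self) -> str:
        return self.record.id

    def column_of_residue(self, pos: int) -> int:
        """1-based alignment column holding ungapped residue position ``pos``."""
        if not 1 <= pos <= len(self.record.residues):
            raise IndexError(f"residue position {pos} out of range")
        seen = 0
        for col, c in enumerate(self.gapped, start=1):
            if c != GAP:
                seen += 1
                if seen == pos:
                    return col
        raise AssertionError("unreachable: gapped/ungapped mismatch")

    def residue_of_column(self, col: int) -> int | None:
        """1-based residue position at alignment column ``col`` (None if gap)."""
        if not 1 <= col <= len(self.gapped):
            raise IndexError(f"column {col} out of range")
        if self.gapped[col - 1] == GAP:
            return None
        return len(self.gapped[:col].replace(GAP, ""))


def _clean(seq: str, moltype: str) -> str:
    seq = seq.upper()
    if moltype == "protein" and seq.endswith("*"):
        seq = seq[:-1]
    return seq


def read_fasta(path, moltype: str = "protein") -> list[SeqRecord]:
    """Read a (possibly line-wrapped) FASTA file into :class:`SeqRecord` s.

    Order is preserved, residues are upper-cased, a single terminal ``*``
    stop is stripped from proteins.  Raises :class:`FormatError` on empty
    files, duplicate ids, empty sequences or alphabet violations.
    """
    path = Path(path)
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if not parsed:
        raise FormatError(f"{path}: no FASTA records found")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean(str(rec.seq), moltype)
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, residues=seq, moltype=moltype,
                                 description=desc))
    return records


def write_fasta(records: Sequence[SeqRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`."""
    if not records:
        raise FormatError("refusing to write an empty FASTA file")
    if width < 1:
        raise ValueError("width must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_alignment_fasta(path, moltype: str = "protein") -> list[AlignedRecord]:
    """Read an aligned (gapped) FASTA file into :class:`AlignedRecord` s."""
    path = Path(path)
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FormatError(f"{path}: no FASTA records found")
    rows: list[AlignedRecord] = []
    seen: set[str] = set()
    length = None
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        gapped = _clean(str(rec.seq), moltype)
        if length is None:
            length = len(gapped)
        elif len(gapped) != length:
            raise FormatError(f"{path}: rows differ in aligned length")
        ungapped = gapped.replace(GAP, "")
        if not ungapped:
            raise FormatError(f"{path}: all-gap row {rec.id!r}")
        rows.append(AlignedRecord(
            record=SeqRecord(id=rec.id, residues=ungapped, moltype=moltype),
            gapped=gapped,
        ))
    return rows


def write_alignment_fasta(rows: Sequence[AlignedRecord], path,
                          width: int = 60) -> None:
    """Write aligned rows (gapped strings) as FASTA."""
    if not rows:
        raise FormatError("refusing to write an empty alignment")
    with open(path, "w") as fh:
        for row in rows:
            fh.write(f">{row.id}\n")
            for i in range(0, len(row.gapped), width):
                fh.write(row.gapped[i:i + width] + "\n")
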