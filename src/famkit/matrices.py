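"""Substitution matrices and alignment parameters.

The default scoring model is the canonical published BLOSUM62 integer matrix
(taken from Biopython's copy) over the 20 amino acids, extended with the
ambiguity character X which scores 0 against everything including itself —
translated genomic predictions (XP_ records) contain X and should neither be
rewarded nor punished at those sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .errors import AlignmentError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer scores over the 21-letter alphabet (20 aa + X)."""

    name: str
    scores: np.ndarray  # (21, 21) float array, symmetric, X row/col zero

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (21, 21):
            raise AlignmentError("substitution matrix must be 21x21")
        if not np.allclose(s, s.T):
            raise AlignmentError("substitution matrix must be symmetric")
        object.__setattr__(self, "scores", s)

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.scores[INDEX[a], INDEX[b]])
        except KeyError as exc:
            raise AlignmentError(f"unknown amino acid {exc.args[0]!r}") from exc


def blosum62() -> SubstitutionMatrix:
    """BLOSUM62 with X scored 0 against everything."""
    raw = substitution_matrices.load("BLOSUM62")
    s = np.zeros((21, 21))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = raw[a, b]
    s[INDEX["X"], :] = 0.0
    s[:, INDEX["X"]] = 0.0
    return SubstitutionMatrix(name="BLOSUM62", scores=s)


def load_matrix_file(path) -> SubstitutionMatrix:
    """Load a whitespace-delimited square matrix with a header row of letters.

    Letters absent from the file keep score 0 (like X); letters must be a
    subset of the 21-letter alphabet.
    """
    lines = [ln.split() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0]
    for aa in header:
        if aa not in INDEX:
            raise AlignmentError(f"matrix file letter {aa!r} outside alphabet")
    s = np.zeros((21, 21))
    if len(lines) - 1 != len(header):
        raise AlignmentError("matrix file is not square")
    for row in lines[1:]:
        aa, values = row[0], row[1:]
        if len(values) != len(header):
            raise AlignmentError(f"row {aa!r} has wrong number of entries")
        for bb, v in zip(header, values):
            s[INDEX[aa], INDEX[bb]] = float(v)
    return SubstitutionMatrix(name=str(Path(path).name), scores=s)


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap alignment parameters.

    A gap of length k costs ``gap_open + (k-1) * gap_extend``: opening pays
    the full penalty, every further gapped position pays the extension.
    """

    matrix: SubstitutionMatrix = field(default_factory=blosum62)
    gap_open: float = 10.0
    gap_extend: float = 0.5
    terminal_gaps_free: bool = False

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignmentError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise AlignmentError("gap_extend must not exceed gap_open")
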