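"""Percent-identity computations.

The default denominator convention emulates the BioEdit sequence identity
matrix: columns where both rows are gapped are ignored, a gap opposite a
residue counts as a mismatch, and identity is matches over all columns with
at least one residue.  Because the source tables do not state the convention,
two alternatives are available: ``pair-columns`` (only columns where both
rows have residues) and ``shorter-seq`` (matches over the shorter ungapped
length).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .align import PairwiseAlignment, global_align
from .errors import FamkitError
from .matrices import AlignParams
from .seqio import GAP, AlignedRecord, SeqRecord

DENOMINATORS = ("columns", "pair-columns", "shorter-seq")
_DENOM_ALIASES = {"min-len": "shorter-seq"}


def round1(value: float) -> float:
    """One decimal place, round half up — the convention of printed tables."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.1"),
                                                      rounding=ROUND_HALF_UP))


def _gapped(row) -> str:
    return row.gapped if isinstance(row, AlignedRecord) else str(row)


def identity_pair(row_a, row_b, denominator: str = "columns") -> float:
    """Percent identity of two equal-length gapped rows."""
    a, b = _gapped(row_a), _gapped(row_b)
    if len(a) != len(b):
        raise FamkitError("rows differ in aligned length")
    denominator = _DENOM_ALIASES.get(denominator, denominator)
    if denominator not in DENOMINATORS:
        raise FamkitError(f"unknown identity denominator {denominator!r}")
    matches = occupied = both = 0
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            continue
        occupied += 1
        if ca != GAP and cb != GAP:
            both += 1
            if ca == cb:
                matches += 1
    if occupied == 0:
        raise FamkitError("all-gap pair of rows")
    if denominator == "columns":
        denom = occupied
    elif denominator == "pair-columns":
        denom = both
    else:
        denom = min(len(a.replace(GAP, "")), len(b.replace(GAP, "")))
    if denom == 0:
        raise FamkitError("zero qualifying columns for identity")
    return 100.0 * matches / denom


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity table with a fixed label order."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels),) * 2:
            raise FamkitError("identity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise FamkitError("identity matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        rounded = np.vectorize(round1)(self.values)
        return pd.DataFrame(rounded, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "IdentityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float))


def identity_matrix(msa, denominator: str = "columns") -> IdentityMatrix:
    """All-pairs identity over the rows of a multiple alignment."""
    rows = list(msa.rows) if hasattr(msa, "rows") else list(msa)
    if len(rows) < 2:
        raise FamkitError("identity matrix needs at least two rows")
    n = len(rows)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = identity_pair(rows[i], rows[j],
                                                        denominator)
    return IdentityMatrix(labels=[r.id for r in rows], values=values)


@dataclass(frozen=True)
class DomainSpec:
    """A 1-based inclusive residue window on a named reference sequence."""

    name: str
    reference_id: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise FamkitError(f"domain {self.name!r}: invalid window "
                              f"{self.start}-{self.end}")


def domain_identity(pairwise: PairwiseAlignment, domain: DomainSpec,
                    denominator: str = "columns") -> float:
    """Identity restricted to the columns of a reference residue window."""
    ref = pairwise.row(domain.reference_id)
    other = pairwise.b if ref is pairwise.a else pairwise.a
    if domain.end > len(ref.record.residues):
        raise FamkitError(f"domain {domain.name!r} extends past the end of "
                          f"{domain.reference_id!r}")
    columns = [ref.column_of_residue(p)
               for p in range(domain.start, domain.end + 1)]
    sub_ref = "".join(ref.gapped[c - 1] for c in columns)
    sub_other = "".join(other.gapped[c - 1] for c in columns)
    return identity_pair(sub_ref, sub_other, denominator)


@dataclass(frozen=True)
class Hit:
    """One ranked result of a local best-hit search."""

    id: str
    identity: float
    score: float


def best_hit(query: SeqRecord, db: list[SeqRecord],
             params: AlignParams | None = None,
             denominator: str = "columns") -> list[Hit]:
    """Globally align the query to every database record and rank by score.

    A desk-scale stand-in for a protein database search: deterministic, with
    record id as the tie-break.
    """
    if not db:
        raise FamkitError("best_hit: empty database")
    params = params or AlignParams()
    hits = []
    for rec in db:
        pw = global_align(query, rec, params)
        hits.append(Hit(id=rec.id,
                        identity=identity_pair(pw.a, pw.b, denominator),
                        score=pw.score))
    hits.sort(key=lambda h: (-h.score, h.id))
    return hits
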