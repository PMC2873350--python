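"""Global pairwise alignment (Needleman-Wunsch with Gotoh affine gaps).

The dynamic program is shared between residue-level pairwise alignment and
the profile-profile step of the progressive aligner: :func:`gotoh_core` works
on an arbitrary pre-computed column-column score matrix.

Traceback is byte-deterministic: on ties we prefer the diagonal move, then a
gap in the second sequence, then a gap in the first.  Score comparisons in
the traceback use a tight relative tolerance: residue-level scores (integers
plus multiples of 0.5) are exact in double precision, while profile-profile
column scores are means and can carry rounding at the last bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError
from .matrices import INDEX, AlignParams
from .seqio import GAP, AlignedRecord, SeqRecord

NEG = -1.0e30  # effectively -infinity, but safe under addition


def _close(x: float, y: float) -> bool:
    return abs(x - y) <= 1e-9 * (1.0 + abs(x))

# move codes: M = both advance, X = first advances (gap in second),
# Y = second advances (gap in first)
_M, _X, _Y = 0, 1, 2


def gotoh_core(S: np.ndarray, gap_open: float, gap_extend: float,
               free_ends: bool = False) -> tuple[float, list[int]]:
    """Affine-gap global alignment over a score matrix.

    Parameters
    ----------
    S:
        ``(n, m)`` array; ``S[i, j]`` is the score of pairing item ``i`` of
        the first series with item ``j`` of the second.
    free_ends:
        When true, leading and trailing gaps cost nothing (semi-global).

    Returns
    -------
    (score, path) where path is a list of move codes from start to end.
    """
    n, m = S.shape
    open_, ext = gap_open, gap_extend

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    ii = np.arange(1, n + 1)
    jj = np.arange(1, m + 1)
    if free_ends:
        X[1:, 0] = 0.0
        Y[0, 1:] = 0.0
    else:
        X[1:, 0] = -(open_ + (ii - 1) * ext)
        Y[0, 1:] = -(open_ + (jj - 1) * ext)

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - open_,
            X[i - 1, 1:] - ext,
        )
        # Y has an in-row dependence; solve the scan via a running max of
        # T[j] = Y[i, j] + j*ext.
        Z = np.maximum(M[i], X[i])
        cand = np.empty(m + 1)
        cand[0] = Y[i, 0] + 0.0
        cand[1:] = Z[:-1] - open_ + jj * ext
        T = np.maximum.accumulate(cand)
        Y[i, 1:] = T[1:] - jj * ext

    # pick the end cell (interior corner, or any border cell when ends are free)
    end_i, end_j = n, m
    if free_ends:
        best = NEG
        for i in range(n + 1):
            v = max(M[i, m], X[i, m], Y[i, m])
            if v > best:
                best, end_i, end_j = v, i, m
        for j in range(m + 1):
            v = max(M[n, j], X[n, j], Y[n, j])
            if v > best:
                best, end_i, end_j = v, n, j
        score = best
    else:
        score = max(M[n, m], X[n, m], Y[n, m])

    # traceback
    path: list[int] = []
    # trailing free gaps
    for _ in range(end_i, n):
        path.append(_X)
    for _ in range(end_j, m):
        path.append(_Y)
    i, j = end_i, end_j
    vals = (M, X, Y)
    target = max(M[i, j], X[i, j], Y[i, j])
    state = next(s for s in (_M, _X, _Y) if _close(vals[s][i, j], target))
    while i > 0 or j > 0:
        if state == _M:
            path.append(_M)
            want = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = next(s for s in (_M, _X, _Y) if _close(vals[s][i, j], want))
        elif state == _X:
            path.append(_X)
            here = X[i, j]
            if j == 0:
                state = _X
            elif _close(here, M[i - 1, j] - open_):
                state = _M
            elif _close(here, X[i - 1, j] - ext):
                state = _X
            elif _close(here, Y[i - 1, j] - open_):
                state = _Y
            else:  # free-end border column
                state = _X
            i -= 1
            if i == 0 and j > 0:
                state = _Y
        else:
            path.append(_Y)
            here = Y[i, j]
            if i == 0:
                state = _Y
            elif _close(here, M[i, j - 1] - open_):
                state = _M
            elif _close(here, X[i, j - 1] - open_):
                state = _X
            elif _close(here, Y[i, j - 1] - ext):
                state = _Y
            else:  # free-end border row
                state = _Y
            j -= 1
            if j == 0 and i > 0:
                state = _X
    path.reverse()
    return float(score), path


@dataclass(frozen=True)
class PairwiseAlignment:
    """Result of a global alignment of two protein sequences."""

    a: AlignedRecord
    b: AlignedRecord
    score: float
    params: AlignParams

    def row(self, record_id: str) -> AlignedRecord:
        for r in (self.a, self.b):
            if r.id == record_id:
                return r
        raise KeyError(record_id)


def _indices(seq: str) -> np.ndarray:
    try:
        return np.array([INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise AlignmentError(f"residue {exc.args[0]!r} not in the amino-acid "
                             "alphabet") from exc


def global_align(a: SeqRecord, b: SeqRecord,
                 params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two protein records."""
    params = params or AlignParams()
    for rec in (a, b):
        if rec.moltype != "protein":
            raise AlignmentError(f"{rec.id!r}: global_align expects protein "
                                 "records")
        if not rec.residues:
            raise AlignmentError(f"{rec.id!r}: empty sequence")
    ia, ib = _indices(a.residues), _indices(b.residues)
    S = params.matrix.scores[np.ix_(ia, ib)]
    score, path = gotoh_core(S, params.gap_open, params.gap_extend,
                             free_ends=params.terminal_gaps_free)
    ga, gb, i, j = [], [], 0, 0
    for move in path:
        if move == _M:
            ga.append(a.residues[i]); gb.append(b.residues[j]); i += 1; j += 1
        elif move == _X:
            ga.append(a.residues[i]); gb.append(GAP); i += 1
        else:
            ga.append(GAP); gb.append(b.residues[j]); j += 1
    assert i == len(a.residues) and j == len(b.residues)
    return PairwiseAlignment(
        a=AlignedRecord(record=a, gapped="".join(ga)),
        b=AlignedRecord(record=b, gapped="".join(gb)),
        score=score,
        params=params,
    )


def score_alignment(gapped_a: str, gapped_b: str,
                    params: AlignParams | None = None) -> float:
    """Re-score an emitted pair of gapped strings under the affine model.

    Independent of the dynamic program; used for the self-consistency
    invariant that an alignment's score equals the score of its strings.
    """
    params = params or AlignParams()
    if len(gapped_a) != len(gapped_b):
        raise AlignmentError("gapped strings differ in length")
    total = 0.0
    in_gap_a = in_gap_b = False
    ncols = len(gapped_a)
    for k, (ca, cb) in enumerate(zip(gapped_a, gapped_b)):
        if ca == GAP and cb == GAP:
            raise AlignmentError("column is gap in both rows")
        if ca == GAP or cb == GAP:
            terminal = False
            if params.terminal_gaps_free:
                # gap run touching either end of the alignment
                run_start = k
                while run_start > 0 and (gapped_a[run_start - 1] == GAP) == (ca == GAP) \
                        and (gapped_a[run_start - 1] == GAP or gapped_b[run_start - 1] == GAP):
                    run_start -= 1
                run_end = k
                while run_end + 1 < ncols and (gapped_a[run_end + 1] == GAP) == (ca == GAP) \
                        and (gapped_a[run_end + 1] == GAP or gapped_b[run_end + 1] == GAP):
                    run_end += 1
                terminal = run_start == 0 or run_end == ncols - 1
            if not terminal:
                extending = in_gap_a if ca == GAP else in_gap_b
                total -= params.gap_extend if extending else params.gap_open
            in_gap_a, in_gap_b = ca == GAP, cb == GAP
        else:
            total += params.matrix.score(ca, cb)
            in_gap_a = in_gap_b = False
    return total
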