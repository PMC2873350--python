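"""Progressive multiple alignment.

The strategy mirrors the classical ClustalW scheme: all-against-all global
alignments give percent identities, identities become p-distances, a UPGMA
guide tree fixes the merge order, and profiles are merged bottom-up with a
profile-profile Gotoh pass scoring columns by the mean of all residue pairs.
Gaps, once introduced, are never removed ("once a gap, always a gap").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import _M, _X, _Y, global_align, gotoh_core
from .errors import AlignmentError, PhyloError
from .matrices import INDEX, AlignParams
from .seqio import GAP, AlignedRecord, SeqRecord
from .tree import TreeNode


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows over a shared set of columns."""

    rows: list[AlignedRecord]
    params: AlignParams | None = None

    def __post_init__(self):
        if not self.rows:
            raise AlignmentError("alignment must have at least one row")
        length = len(self.rows[0].gapped)
        for r in self.rows:
            if len(r.gapped) != length:
                raise AlignmentError("rows differ in aligned length")
        for col in range(length):
            if all(r.gapped[col] == GAP for r in self.rows):
                raise AlignmentError(f"all-gap column at position {col + 1}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].gapped)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, record_id: str) -> AlignedRecord:
        for r in self.rows:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def take_columns(self, columns: list[int]) -> "MultipleAlignment":
        """New alignment from the given 1-based columns (order preserved)."""
        rows = []
        for r in self.rows:
            gapped = "".join(r.gapped[c - 1] for c in columns)
            ungapped = gapped.replace(GAP, "")
            if not ungapped:
                raise AlignmentError(f"row {r.id!r} is all-gap after column "
                                     "selection")
            rows.append(AlignedRecord(
                record=SeqRecord(id=r.id, residues=ungapped,
                                 moltype=r.record.moltype,
                                 description=r.record.description),
                gapped=gapped))
        return MultipleAlignment(rows=rows, params=self.params)


def build_guide_tree(dm) -> TreeNode:
    """UPGMA clustering of a distance matrix into a rooted ultrametric tree.

    ``dm`` is any object with ``labels`` and a square ``values`` array.
    Ties are broken by the lexicographically smallest pair of cluster labels,
    so the tree is deterministic.
    """
    labels = list(dm.labels)
    values = np.asarray(dm.values, dtype=float)
    if len(labels) < 2:
        raise PhyloError("guide tree needs at least two taxa")
    if np.isnan(values).any():
        raise PhyloError("distance matrix contains NaN")
    if (values < 0).any():
        raise PhyloError("distance matrix contains negative entries")

    # cluster state: (sorted member labels, node, height, size)
    clusters: dict[int, tuple[tuple[str, ...], TreeNode, float, int]] = {}
    for k, lab in enumerate(labels):
        clusters[k] = ((lab,), TreeNode(label=lab), 0.0, 1)
    dist = {(i, j): values[i, j] for i in range(len(labels))
            for j in range(i + 1, len(labels))}
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        for (i, j), d in dist.items():
            if i not in clusters or j not in clusters:
                continue
            key = tuple(sorted((clusters[i][0][0], clusters[j][0][0])))
            if best is None or (d, key) < (best[0], best[1]):
                best = (d, key, i, j)
        d, _, i, j = best
        mi, ni, hi, si = clusters[i]
        mj, nj, hj, sj = clusters[j]
        height = d / 2.0
        node = TreeNode()
        ni.length = height - hi
        nj.length = height - hj
        for child in sorted((ni, nj), key=lambda c: min(
                clusters[i][0] if c is ni else clusters[j][0])):
            node.add_child(child)
        members = tuple(sorted(mi + mj))
        # average-linkage update
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dist[tuple(sorted((next_id, k)))] = (si * dik + sj * djk) / (si + sj)
        del clusters[i], clusters[j]
        clusters[next_id] = (members, node, height, si + sj)
        next_id += 1
    (_, root, _, _), = clusters.values()
    return root


class _Profile:
    """Gapped rows plus per-column residue counts for profile alignment."""

    def __init__(self, rows: list[AlignedRecord]):
        self.rows = rows
        L = len(rows[0].gapped)
        counts = np.zeros((L, 21))
        for r in rows:
            for k, c in enumerate(r.gapped):
                if c != GAP:
                    counts[k, INDEX[c]] += 1
        self.counts = counts

    def __len__(self):
        return len(self.rows[0].gapped)


def _merge(pa: _Profile, pb: _Profile, params: AlignParams) -> _Profile:
    Smat = params.matrix.scores
    # mean-of-pairs column score; gapped members contribute zero
    S = (pa.counts @ Smat @ pb.counts.T) / (len(pa.rows) * len(pb.rows))
    _, path = gotoh_core(S, params.gap_open, params.gap_extend,
                         free_ends=params.terminal_gaps_free)
    rows_a, rows_b = [], []
    a_chunks = [[] for _ in pa.rows]
    b_chunks = [[] for _ in pb.rows]
    i = j = 0
    for move in path:
        take_a = move in (_M, _X)
        take_b = move in (_M, _Y)
        for r, chunk in zip(pa.rows, a_chunks):
            chunk.append(r.gapped[i] if take_a else GAP)
        for r, chunk in zip(pb.rows, b_chunks):
            chunk.append(r.gapped[j] if take_b else GAP)
        i += take_a
        j += take_b
    for r, chunk in zip(pa.rows, a_chunks):
        rows_a.append(AlignedRecord(record=r.record, gapped="".join(chunk)))
    for r, chunk in zip(pb.rows, b_chunks):
        rows_b.append(AlignedRecord(record=r.record, gapped="".join(chunk)))
    return _Profile(rows_a + rows_b)


def pairwise_distance_matrix(records: list[SeqRecord],
                             params: AlignParams):
    """p-distances (1 - identity/100) from all-against-all global alignment."""
    from .identity import identity_pair
    from .phylo import DistanceMatrix

    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pw = global_align(records[i], records[j], params)
            d = 1.0 - identity_pair(pw.a, pw.b) / 100.0
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=[r.id for r in records], values=values)


def progressive_msa(records: list[SeqRecord],
                    params: AlignParams | None = None) -> MultipleAlignment:
    """Align ≥2 protein records progressively along a UPGMA guide tree.

    Output row order equals input order regardless of the merge order.
    """
    params = params or AlignParams()
    if len(records) < 2:
        raise AlignmentError("progressive_msa needs at least two sequences; "
                             "a single record can be used unaligned")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids in MSA input")
    dm = pairwise_distance_matrix(records, params)
    guide = build_guide_tree(dm)
    by_id = {r.id: r for r in records}

    def align_node(node: TreeNode) -> _Profile:
        if node.is_leaf:
            rec = by_id[node.label]
            return _Profile([AlignedRecord(record=rec, gapped=rec.residues)])
        profile = align_node(node.children[0])
        for child in node.children[1:]:
            profile = _merge(profile, align_node(child), params)
        return profile

    profile = align_node(guide)
    order = {rid: k for k, rid in enumerate(ids)}
    rows = sorted(profile.rows, key=lambda r: order[r.id])
    return MultipleAlignment(rows=rows, params=params)
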