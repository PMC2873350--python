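"""Distance phylogenetics: trimming, p-distances, neighbour joining,
bootstrap and majority-rule consensus, outgroup rooting.

The tree-building route is neighbour joining over p-distances (optionally
Poisson-corrected), with column-bootstrap support and a >50% majority-rule
consensus completed greedily with compatible splits.  All randomness flows
from a single integer seed; bootstrap replicate *r* draws from spawned
substream *r*, so replicates are reproducible independently of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PhyloError
from .identity import identity_pair
from .msa import MultipleAlignment
from .seqio import GAP
from .tree import TreeNode


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a fixed label order."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels),) * 2:
            raise PhyloError("distance matrix shape does not match labels")
        if not np.isfinite(v).all():
            raise PhyloError("distance matrix has non-finite entries")
        if (v < 0).any():
            raise PhyloError("distance matrix has negative entries")
        if not np.allclose(v, v.T):
            raise PhyloError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise PhyloError("distance matrix diagonal must be zero")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def trim_variable_termini(msa: MultipleAlignment, reference_id: str,
                          trim_cterm: bool = False) -> MultipleAlignment:
    """Drop alignment columns outside the reference's span.

    Removes every column left of the column holding reference residue 1
    (the variable N-terminal overhangs of longer family members), optionally
    truncates right of the reference's last residue, then drops any column
    left all-gap.
    """
    try:
        ref = msa.row(reference_id)
    except KeyError:
        raise PhyloError(f"reference id {reference_id!r} not in alignment")
    first = ref.column_of_residue(1)
    last = ref.column_of_residue(len(ref.record.residues)) if trim_cterm \
        else msa.n_columns
    keep = [c for c in range(first, last + 1)
            if any(r.gapped[c - 1] != GAP for r in msa.rows)]
    return msa.take_columns(keep)


def p_distance(msa: MultipleAlignment, poisson: bool = False,
               denominator: str = "pair-columns") -> DistanceMatrix:
    """Pairwise distances ``1 - identity/100``; optional Poisson correction
    ``-ln(1 - p)``.

    Defaults to pairwise deletion (``pair-columns``): only columns where
    both rows carry a residue are compared, the standard p-distance
    convention — an indel in one family member then cannot inflate its
    distance to every other member.  Pass ``denominator="columns"`` to
    score gap-versus-residue columns as mismatches instead.
    """
    rows = msa.rows
    n = len(rows)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = 1.0 - identity_pair(rows[i], rows[j], denominator) / 100.0
            if poisson:
                if p >= 1.0:
                    raise PhyloError("saturated pair: Poisson correction "
                                     "undefined at p = 1")
                p = -np.log(1.0 - p)
            values[i, j] = values[j, i] = p
    return DistanceMatrix(labels=[r.id for r in rows], values=values)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest pair of cluster labels.  Negative branch
    lengths are clamped to zero with the deficit moved to the sister edge.
    Returns an unrooted tree represented with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("neighbour joining needs at least three taxa")
    nodes = {k: TreeNode(label=lab) for k, lab in enumerate(dm.labels)}
    # representative label per cluster for deterministic tie-breaks
    rep = {k: lab for k, lab in enumerate(dm.labels)}
    D = {(i, j): dm.values[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_id = n

    def d(i, j):
        return D[(i, j) if i < j else (j, i)]

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = tuple(sorted((rep[i], rep[j])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        # clamp negatives, moving the deficit to the sister edge
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            D[tuple(sorted((next_id, k)))] = max(dk, 0.0)
        active -= {i, j}
        nodes[next_id] = parent
        rep[next_id] = min(rep[i], rep[j])
        active.add(next_id)
        next_id += 1
    i, j = sorted(active)
    root = TreeNode()
    inner, other = nodes[i], nodes[j]
    if inner.is_leaf and not other.is_leaf:
        inner, other = other, inner
    if not inner.is_leaf:
        # absorb one internal node to get the conventional trifurcation
        other.length = d(i, j)
        for child in inner.children:
            root.add_child(child)
        root.add_child(other)
    else:  # two taxa never reach here; n == 3 with all leaves cannot occur
        inner.length = other.length = d(i, j) / 2.0
        root.add_child(inner)
        root.add_child(other)
    return root


def bootstrap_trees(msa: MultipleAlignment, n_reps: int,
                    seed: int) -> list[TreeNode]:
    """Column bootstrap: resample columns with replacement, rebuild NJ trees.

    Fully reproducible: replicate ``r`` uses spawned random substream ``r``.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    ncols = msa.n_columns
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    trees = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = sorted(int(c) + 1 for c in rng.integers(0, ncols, size=ncols))
        replicate = _resampled(msa, cols)
        trees.append(nj_tree(p_distance(replicate)))
    return trees


def _resampled(msa: MultipleAlignment, columns: list[int]) -> MultipleAlignment:
    # a pathological draw can leave a mostly-gap row empty; take_columns
    # raises in that case rather than emitting a degenerate replicate
    return msa.take_columns(columns)


def majority_consensus(trees: list[TreeNode], threshold: float = 50.0
                       ) -> TreeNode:
    """Majority-rule consensus with greedy compatible completion.

    Includes every non-trivial bipartition occurring in strictly more than
    ``threshold`` percent of the input trees, then adds remaining observed
    bipartitions in frequency order while compatible.  Support values are
    rounded percentages.
    """
    if not trees:
        raise PhyloError("no input trees")
    taxa = frozenset(trees[0].leaf_names())
    for t in trees[1:]:
        if frozenset(t.leaf_names()) != taxa:
            raise PhyloError("input trees disagree on their leaf sets")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)

    def compatible(a: frozenset, b: frozenset) -> bool:
        return a <= b or b <= a or not (a & b)

    accepted: list[tuple[frozenset[str], int]] = []
    ordered = sorted(counts.items(),
                     key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))
    for split, c in ordered:
        if 100.0 * c / n > threshold:
            accepted.append((split, c))
    for split, c in ordered:
        if 100.0 * c / n > threshold:
            continue
        if all(compatible(split, s) for s, _ in accepted):
            accepted.append((split, c))
    return _tree_from_clusters(taxa, accepted, n)


def _tree_from_clusters(taxa: frozenset[str],
                        accepted: list[tuple[frozenset[str], int]],
                        n_trees: int) -> TreeNode:
    # clusters are oriented away from the lexicographically smallest taxon,
    # so they nest and can be built top-down by containment
    root = TreeNode()
    leaf_nodes = {t: TreeNode(label=t) for t in taxa}
    # sort big-to-small so parents are placed before children
    clusters = sorted(accepted, key=lambda kv: (-len(kv[0]),
                                                tuple(sorted(kv[0]))))
    cluster_nodes: list[tuple[frozenset[str], TreeNode]] = []
    for split, c in clusters:
        node = TreeNode(support=round(100.0 * c / n_trees))
        parent = root
        parent_set = taxa
        for s, existing in cluster_nodes:
            if split <= s and len(s) < len(parent_set):
                parent, parent_set = existing, s
        parent.add_child(node)
        cluster_nodes.append((split, node))
    for t in sorted(taxa):
        node = leaf_nodes[t]
        parent = root
        parent_set = taxa
        for s, existing in cluster_nodes:
            if t in s and len(s) < len(parent_set):
                parent, parent_set = existing, s
        parent.add_child(node)
    return root


def root_on_outgroup(tree: TreeNode, label: str) -> TreeNode:
    """Root the tree on the edge leading to the named leaf.

    The outgroup's branch length (when present) is split equally across the
    two root edges.  Re-rooting an already-rooted tree on the same label is
    the identity.
    """
    work = tree.copy()
    leaf = work.find(label)
    if leaf is None or not leaf.is_leaf:
        raise PhyloError(f"outgroup leaf {label!r} not found")
    if leaf.parent is work and len(work.children) == 2:
        return work  # already rooted here
    # re-hang the tree from the outgroup's parent edge
    old_parent = leaf.parent
    old_parent.children.remove(leaf)
    length = leaf.length
    path = []
    node = old_parent
    while node is not None:
        path.append(node)
        node = node.parent
    # reverse parent links along the path to the old root
    new_root = TreeNode()
    half = None if length is None else length / 2.0
    leaf.length = half
    new_root.add_child(leaf)
    prev = new_root
    prev_length = half
    prev_support = None
    for k, node in enumerate(path):
        upper = path[k + 1] if k + 1 < len(path) else None
        if upper is not None:
            upper.children.remove(node)
        node.parent = None
        # support and length annotate the edge above a node; reversing the
        # edge moves both annotations one step along the path
        this_length, this_support = node.length, node.support
        node.length = prev_length
        node.support = prev_support
        prev.add_child(node)
        prev = node
        prev_length, prev_support = this_length, this_support
    _suppress_unary(new_root)
    return new_root


def _suppress_unary(root: TreeNode) -> None:
    """Collapse degree-2 internal nodes created by re-rooting."""
    changed = True
    while changed:
        changed = False
        for node in list(root.walk()):
            if node is root or node.is_leaf or len(node.children) != 1:
                continue
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            if child.support is None:
                child.support = node.support
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
            changed = True
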