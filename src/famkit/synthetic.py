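"""Synthetic EF-hand protein families with known ground truth.

The generator emulates the structure of a calmodulin-derived Ca²⁺-sensor
family: a calmodulin-like ancestor whose four 12-residue coordinating loops
start as the canonical ``DKDGDGTITTKE`` loop, evolved down a gene tree by a
per-site Poisson substitution process (uniform replacement among the other
19 residues) with region-scaled rates — slow in loops, fast in the termini.
Lineage events inject the family's hallmark features deterministically:
N-terminal splice-like extensions, the calneuron C-terminal extension,
loop-degrading deletions and position-12 E↔D swaps.

Two modelling choices keep the truth table exact.  Indels occur only through
declared events, and the classification-bearing anchor residues (loop
positions 1 and 12) are invariant under the substitution process, changing
only through declared events — the biological reading is strong purifying
selection on the coordinating ligands.  Everything else is free to drift,
which is what makes the closed-form identity expectation of
:func:`expected_identity` exact for event-free configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import FamkitError
from .matrices import AMINO_ACIDS
from .seqio import SeqRecord
from .tree import TreeNode, parse_newick

CANONICAL_LOOP = "DKDGDGTITTKE"
CALMODULIN_WINDOWS = ((21, 32), (57, 68), (94, 105), (130, 141))

# per-site region codes
R_NTERM, R_CORE, R_LINKER, R_CTERM = 0, 1, 2, 3
R_LOOP = 10   # + ef index (1..4)
R_ANCHOR = 20  # + ef index; frozen coordinating positions 1 and 12
R_FLANK = 40  # frozen helix residues bracketing each loop window

EVENT_KINDS = ("nterm_insert", "cterm_append", "loop_delete", "pos12_swap")


@dataclass(frozen=True)
class Event:
    """One deterministic lineage event (applied at the branch midpoint)."""

    lineage: str
    kind: str
    ef: int | None = None
    length: int | None = None


@dataclass(frozen=True)
class Duplication:
    """Gene duplication: the subtree below ``branch`` is duplicated at
    fraction ``at`` along the branch leading to it."""

    branch: str
    at: float = 0.5


@dataclass(frozen=True)
class FamilyConfig:
    """Full specification of one synthetic family."""

    seed: int
    species_tree: str  # Newick; branch lengths in substitutions/site
    ancestor_length: int = 149
    loop_windows: tuple[tuple[int, int], ...] = CALMODULIN_WINDOWS
    rate_loops: float = 0.2
    rate_linker: float = 1.0
    rate_termini: float = 2.0
    rate_core: float = 1.0
    duplications: tuple[Duplication, ...] = ()
    events: tuple[Event, ...] = ()

    def validate(self) -> TreeNode:
        problems = []
        for name in ("rate_loops", "rate_linker", "rate_termini", "rate_core"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        try:
            tree = parse_newick(self.species_tree)
        except Exception as exc:
            problems.append(f"species_tree does not parse: {exc}")
            tree = None
        prev_end = 0
        for k, (s, e) in enumerate(self.loop_windows, start=1):
            if e - s + 1 != len(CANONICAL_LOOP):
                problems.append(f"loop window {k} is not 12 residues")
            if s <= prev_end:
                problems.append("loop windows must be ordered, non-overlapping")
            prev_end = e
        if prev_end > self.ancestor_length:
            problems.append("loop windows extend past the ancestor")
        if tree is not None:
            known = {n.label for n in tree.walk() if n.label}
            for ev in self.events:
                if ev.kind not in EVENT_KINDS:
                    problems.append(f"unknown event kind {ev.kind!r}")
                if ev.lineage not in known:
                    problems.append(f"event lineage {ev.lineage!r} not in tree")
                if ev.kind in ("loop_delete", "pos12_swap") and not ev.ef:
                    problems.append(f"{ev.kind} event needs an ef index")
                if ev.kind in ("nterm_insert", "cterm_append", "loop_delete") \
                        and not ev.length:
                    problems.append(f"{ev.kind} event needs a length")
            for dup in self.duplications:
                if dup.branch not in known:
                    problems.append(f"duplication branch {dup.branch!r} "
                                    "not in tree")
        if problems:
            raise FamkitError("invalid family config: " + "; ".join(problems))
        return tree

    @classmethod
    def from_yaml(cls, path) -> "FamilyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["loop_windows"] = tuple(tuple(w) for w in raw.get(
            "loop_windows", CALMODULIN_WINDOWS))
        raw["events"] = tuple(Event(**e) for e in raw.get("events", ()))
        raw["duplications"] = tuple(Duplication(**d) for d in raw.get(
            "duplications", ()))
        return cls(**raw)


@dataclass(frozen=True)
class LeafTruth:
    """Ground truth for one generated sequence."""

    lineage: str
    activity: tuple[bool, bool, bool, bool]
    pos12: tuple[str, str, str, str]
    nterm_extension: int
    cterm_extension: int


@dataclass(frozen=True)
class TruthTable:
    """Everything the downstream analyses should recover."""

    leaves: dict[str, LeafTruth]
    topology: str  # Newick of the gene tree (after duplications)
    ancestor: SeqRecord
    loop_windows: tuple[tuple[int, int], ...]

    def to_json(self) -> str:
        payload = {
            "topology": self.topology,
            "ancestor": self.ancestor.residues,
            "loop_windows": [list(w) for w in self.loop_windows],
            "leaves": {
                name: {
                    "lineage": t.lineage,
                    "activity": list(t.activity),
                    "pos12": list(t.pos12),
                    "nterm_extension": t.nterm_extension,
                    "cterm_extension": t.cterm_extension,
                } for name, t in self.leaves.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


class _Lineage:
    """Mutable per-lineage simulation state."""

    def __init__(self, seq: np.ndarray, region: np.ndarray,
                 truth: LeafTruth):
        self.seq = seq          # int codes into AMINO_ACIDS
        self.region = region    # region codes, same length
        self.truth = truth

    def clone(self) -> "_Lineage":
        return _Lineage(self.seq.copy(), self.region.copy(), self.truth)

    def multipliers(self, cfg: FamilyConfig) -> np.ndarray:
        m = np.empty(len(self.seq))
        r = self.region
        m[r == R_NTERM] = cfg.rate_termini
        m[r == R_CTERM] = cfg.rate_termini
        m[r == R_CORE] = cfg.rate_core
        m[r == R_LINKER] = cfg.rate_linker
        m[(r >= R_LOOP) & (r < R_ANCHOR)] = cfg.rate_loops
        m[r >= R_ANCHOR] = 0.0  # frozen anchors and loop-bracketing flanks
        return m

    def loop_positions(self, ef: int) -> np.ndarray:
        return np.nonzero((self.region == R_LOOP + ef)
                          | (self.region == R_ANCHOR + ef))[0]


def _make_gene_tree(cfg: FamilyConfig) -> TreeNode:
    tree = cfg.validate()
    for dup in cfg.duplications:
        node = tree.find(dup.branch)
        length = node.length if node.length is not None else 0.0
        parent = node.parent
        if parent is None:
            raise FamkitError("cannot duplicate at the root")
        junction = TreeNode(length=dup.at * length)
        copies = []
        for suffix in ("-a", "-b"):
            copy = node.copy()
            for sub in copy.walk():
                if sub.label:
                    sub.label = sub.label + suffix
            copy.length = (1.0 - dup.at) * length
            copies.append(copy)
        idx = parent.children.index(node)
        parent.children[idx] = junction
        junction.parent = parent
        for copy in copies:
            junction.add_child(copy)
    return tree


def _ancestor_state(cfg: FamilyConfig, rng: np.random.Generator) -> _Lineage:
    n = cfg.ancestor_length
    seq = rng.integers(0, 20, size=n).astype(np.int64)
    region = np.full(n, R_CORE, dtype=np.int64)
    (s1, e1), (s2, e2), (s3, e3), (s4, e4) = cfg.loop_windows
    region[:s1 - 1] = R_NTERM
    region[e4:] = R_CTERM
    region[e2:s3 - 1] = R_LINKER
    loop_codes = [AMINO_ACIDS.index(c) for c in CANONICAL_LOOP]
    for ef, (s, e) in enumerate(cfg.loop_windows, start=1):
        seq[s - 1:e] = loop_codes
        region[s - 1:e] = R_LOOP + ef
        region[s - 1] = R_ANCHOR + ef   # position 1
        region[e - 1] = R_ANCHOR + ef   # position 12
        # two invariant helix residues bracket each loop (entering/exiting
        # helix positions are under strong purifying selection); they anchor
        # loop projection so declared deletions are seen inside the window
        region[max(0, s - 3):s - 1] = R_FLANK
        region[e:e + 2] = R_FLANK
    truth = LeafTruth(lineage="ancestor",
                      activity=(True,) * 4,
                      pos12=(CANONICAL_LOOP[-1],) * 4,
                      nterm_extension=0, cterm_extension=0)
    return _Lineage(seq, region, truth)


def _evolve(state: _Lineage, t: float, cfg: FamilyConfig,
            rng: np.random.Generator) -> None:
    if t <= 0:
        return
    mult = state.multipliers(cfg)
    counts = rng.poisson(t * mult)
    for i in np.nonzero(counts)[0]:
        cur = state.seq[i]
        for _ in range(counts[i]):
            nxt = rng.integers(0, 19)
            if nxt >= cur:
                nxt += 1
            cur = nxt
        state.seq[i] = cur
    # guard: anchors are rate-0, so they can never have drifted
    assert not counts[state.region >= R_ANCHOR].any()


def _apply_event(state: _Lineage, ev: Event, cfg: FamilyConfig,
                 rng: np.random.Generator) -> None:
    t = state.truth
    if ev.kind == "nterm_insert":
        extra = rng.integers(0, 20, size=ev.length).astype(np.int64)
        state.seq = np.concatenate([extra, state.seq])
        state.region = np.concatenate(
            [np.full(ev.length, R_NTERM, dtype=np.int64), state.region])
        state.truth = replace(t, nterm_extension=t.nterm_extension + ev.length)
    elif ev.kind == "cterm_append":
        extra = rng.integers(0, 20, size=ev.length).astype(np.int64)
        state.seq = np.concatenate([state.seq, extra])
        state.region = np.concatenate(
            [state.region, np.full(ev.length, R_CTERM, dtype=np.int64)])
        state.truth = replace(t, cterm_extension=t.cterm_extension + ev.length)
    elif ev.kind == "loop_delete":
        pos = state.loop_positions(ev.ef)
        if len(pos) < ev.length + 2:
            raise FamkitError(f"loop {ev.ef} too degraded for a further "
                              f"{ev.length}-residue deletion")
        # delete from the loop interior, sparing the two anchors
        doomed = pos[4:4 + ev.length] if len(pos) >= 4 + ev.length + 1 \
            else pos[1:1 + ev.length]
        keep = np.ones(len(state.seq), dtype=bool)
        keep[doomed] = False
        state.seq = state.seq[keep]
        state.region = state.region[keep]
        activity = list(t.activity)
        activity[ev.ef - 1] = False
        state.truth = replace(t, activity=tuple(activity))
    elif ev.kind == "pos12_swap":
        pos = state.loop_positions(ev.ef)
        idx = pos[-1]  # position 12 anchor
        current = AMINO_ACIDS[state.seq[idx]]
        swapped = "D" if current == "E" else "E"
        state.seq[idx] = AMINO_ACIDS.index(swapped)
        pos12 = list(t.pos12)
        pos12[ev.ef - 1] = swapped
        state.truth = replace(t, pos12=tuple(pos12))
    else:
        raise FamkitError(f"unknown event kind {ev.kind!r}")


def generate_family(cfg: FamilyConfig) -> tuple[list[SeqRecord], TruthTable]:
    """Simulate the family; byte-deterministic for a given config."""
    gene_tree = _make_gene_tree(cfg)
    rng = np.random.default_rng(cfg.seed)
    root_state = _ancestor_state(cfg, rng)
    events_by_lineage: dict[str, list[Event]] = {}
    for ev in cfg.events:
        events_by_lineage.setdefault(ev.lineage, []).append(ev)

    records: list[SeqRecord] = []
    leaves: dict[str, LeafTruth] = {}

    def descend(node: TreeNode, state: _Lineage) -> None:
        for ev in events_by_lineage.get(node.label or "", []):
            pass  # events are applied mid-branch below, never at the root
        for child in node.children:
            child_state = state.clone()
            t = child.length or 0.0
            # events for lineages that were duplicated carry the suffix
            child_events = events_by_lineage.get(child.label or "", [])
            if not child_events and child.label and child.label[-2:] in ("-a", "-b"):
                child_events = events_by_lineage.get(child.label[:-2], [])
            _evolve(child_state, t / 2.0, cfg, rng)
            for ev in child_events:
                _apply_event(child_state, ev, cfg, rng)
            _evolve(child_state, t / 2.0, cfg, rng)
            if child_state.truth.lineage != (child.label or ""):
                child_state.truth = replace(child_state.truth,
                                            lineage=child.label or "")
            if child.is_leaf:
                residues = "".join(AMINO_ACIDS[c] for c in child_state.seq)
                records.append(SeqRecord(id=child.label, residues=residues,
                                         moltype="protein"))
                leaves[child.label] = child_state.truth
            else:
                descend(child, child_state)

    descend(gene_tree, root_state)
    ancestor = SeqRecord(
        id="ancestor",
        residues="".join(AMINO_ACIDS[c] for c in root_state.seq),
        moltype="protein")
    truth = TruthTable(leaves=leaves, topology=gene_tree.to_newick(),
                       ancestor=ancestor, loop_windows=cfg.loop_windows)
    return records, truth


def expected_identity(cfg: FamilyConfig, lineage_a: str,
                      lineage_b: str) -> float:
    """Closed-form expected percent identity between two leaves.

    Under the 20-state symmetric substitution chain, a site with total path
    rate r matches with probability ``1/20 + (19/20) exp(-(20/19) r)``.
    Valid for event-free configurations (indels change the site set).
    """
    for ev in cfg.events:
        if ev.kind != "pos12_swap":
            raise FamkitError("expected_identity requires an indel-free "
                              "configuration")
    gene_tree = _make_gene_tree(cfg)
    key = (lineage_a, lineage_b) if lineage_a < lineage_b \
        else (lineage_b, lineage_a)
    paths = gene_tree.path_lengths()
    if key not in paths:
        raise FamkitError(f"no leaf pair {key} in the gene tree")
    r = paths[key]
    state = _ancestor_state(cfg, np.random.default_rng(0))
    mult = state.multipliers(cfg)
    p_same = 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-(20.0 / 19.0) * r * mult)
    p_same[mult == 0.0] = 1.0
    return float(100.0 * p_same.mean())


def default_family_config(seed: int) -> FamilyConfig:
    """The package's stand-in for the study family: a calmodulin outgroup,
    a CaBP-like clade (with an inactivated EF2 and position-12 swaps) and a
    calneuron-like clade (EF3 deletion, degraded EF4, 38-residue C-terminal
    extension, N-terminal splice-like extension on one member)."""
    newick = ("(calmodulin:0.06,((CaBP1:0.10,CaBP5:0.10)cabp15:0.05,"
              "(CaBP2:0.10,CaBP4:0.10)cabp24:0.05)cabps:0.08,"
              "(calneuron1:0.12,calneuron2:0.12)calneurons:0.10);")
    events = (
        Event(lineage="cabps", kind="loop_delete", ef=2, length=2),
        Event(lineage="CaBP1", kind="pos12_swap", ef=1),
        Event(lineage="CaBP5", kind="pos12_swap", ef=1),
        Event(lineage="CaBP4", kind="nterm_insert", length=100),
        Event(lineage="calneurons", kind="loop_delete", ef=3, length=3),
        Event(lineage="calneurons", kind="loop_delete", ef=4, length=2),
        Event(lineage="calneurons", kind="cterm_append", length=38),
    )
    return FamilyConfig(seed=seed, species_tree=newick, events=events)
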