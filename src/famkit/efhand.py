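"""EF-hand annotation and cation-specificity classification.

EF-hand loops are located by global alignment of a query protein to a
calmodulin reference whose four 12-residue coordinating-loop windows are
known configuration.  Each projected loop is then classified:

* **inactive** when the loop is structurally degraded — any deletion (gap)
  inside the 12-residue window, any insertion into it, or a disallowed
  residue at coordinating position 1 (allowed: D/N/S) or position 12
  (allowed: D/E);
* otherwise **active**, with glutamate at position 12 marking a
  Ca²⁺-specific site and aspartate a site whose preference is shifted toward
  Mg²⁺ (the position-12 rule).

Every call carries machine-readable rationale codes so each
activity/specificity decision is auditable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .align import global_align
from .errors import FamkitError
from .identity import identity_pair
from .matrices import AlignParams
from .seqio import GAP, SeqRecord

LOOP_LEN = 12
EF_NAMES = ("EF1", "EF2", "EF3", "EF4")
CANONICAL_EF1 = "DKDGDGTITTKE"

# rationale codes emitted by the classifier
CODE_DELETION = "loop-deletion"
CODE_INSERTION = "loop-insertion"
CODE_POS1 = "pos1-substitution"
CODE_POS12 = "pos12-substitution"
CODE_CA = "pos12-glutamate"
CODE_MG = "pos12-aspartate"
CODE_FALLBACK = "fallback-consensus-scan"

# consensus-pattern fallback: positions 1, 3, 5 are acidic-ish ligands and
# position 6 is the canonical glycine
_CONSENSUS = re.compile("D.[DN].[DNS]G.{6}")


@dataclass(frozen=True)
class RuleConfig:
    """User-configurable classification rules."""

    pos1_allowed: tuple[str, ...] = ("D", "N", "S")
    pos12_allowed: tuple[str, ...] = ("D", "E")
    ca_pos12: str = "E"
    mg_pos12: str = "D"
    forbid_deletions: bool = True
    forbid_insertions: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RuleConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in raw.items()}
        return cls(**kwargs)


@dataclass(frozen=True)
class ReferenceLoops:
    """A reference protein plus its four EF-hand loop windows."""

    reference: SeqRecord
    loops: tuple[tuple[int, int], ...]  # ((start, end) x 4), 1-based inclusive

    def __post_init__(self):
        if len(self.loops) != 4:
            raise FamkitError("exactly four EF-hand windows are required")
        prev_end = 0
        for k, (s, e) in enumerate(self.loops, start=1):
            if e - s + 1 != LOOP_LEN:
                raise FamkitError(f"EF{k} window is not {LOOP_LEN} residues")
            if s <= prev_end:
                raise FamkitError("EF-hand windows must be ordered and "
                                  "non-overlapping")
            if e > len(self.reference.residues):
                raise FamkitError(f"EF{k} window extends past the reference")
            prev_end = e

    def loop_sequence(self, ef_index: int) -> str:
        s, e = self.loops[ef_index - 1]
        return self.reference.residues[s - 1:e]

    @property
    def linker_length(self) -> int:
        """Residues between the EF2 loop end and the EF3 loop start."""
        return self.loops[2][0] - self.loops[1][1] - 1

    @classmethod
    def from_mapping(cls, raw: dict) -> "ReferenceLoops":
        ref = raw["reference"]
        record = SeqRecord(id=ref["id"],
                           residues="".join(str(ref["residues"]).split()),
                           moltype="protein",
                           description=ref.get("description", ""))
        loops = tuple(tuple(raw["loops"][name]) for name in EF_NAMES)
        obj = cls(reference=record, loops=loops)
        if obj.loop_sequence(1) != CANONICAL_EF1:
            raise FamkitError(
                f"reference EF1 window reads {obj.loop_sequence(1)!r}, "
                f"expected the calmodulin loop {CANONICAL_EF1!r}")
        return obj

    @classmethod
    def from_yaml(cls, path) -> "ReferenceLoops":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "ReferenceLoops":
        text = (resources.files("famkit") / "data" /
                "reference_loops.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))


@dataclass(frozen=True)
class EFHandAnnotation:
    """One annotated EF-hand loop of a query protein."""

    ef_index: int
    loop_gapped: str            # 12 columns in reference loop coordinates
    insertions: int             # query residues inserted inside the window
    query_start: int | None     # 1-based query coordinates; None if deleted
    query_end: int | None
    activity: str | None = None          # "active" | "inactive"
    cation_class: str | None = None      # "Ca-specific" | "Mg-preferring" | "none"
    rationale: tuple[str, ...] = ()
    low_confidence: bool = False

    def __post_init__(self):
        if len(self.loop_gapped) != LOOP_LEN:
            raise FamkitError("loop string must have exactly 12 columns")

    @property
    def pos12(self) -> str:
        return self.loop_gapped[11]

    @property
    def pos1(self) -> str:
        return self.loop_gapped[0]

    def to_dict(self) -> dict:
        return {
            "ef": EF_NAMES[self.ef_index - 1],
            "loop": self.loop_gapped,
            "insertions": self.insertions,
            "query_start": self.query_start,
            "query_end": self.query_end,
            "pos12": self.pos12,
            "activity": self.activity,
            "cation_class": self.cation_class,
            "rationale": list(self.rationale),
            "low_confidence": self.low_confidence,
        }


@dataclass(frozen=True)
class EFHandComparison:
    """Loop-level comparison of one EF-hand between two orthologues."""

    ef_index: int
    pos12_a: str
    pos12_b: str
    conserved_pct: float
    both_inactive: bool


def annotate_efhands(query: SeqRecord, ref: ReferenceLoops | None = None,
                     params: AlignParams | None = None
                     ) -> list[EFHandAnnotation]:
    """Project the reference loop windows onto a query via global alignment.

    Deleted loop positions appear as ``-`` in the 12-column loop string;
    query residues falling between two reference loop columns are counted as
    insertions.  When the alignment leaves a window entirely empty a
    low-confidence consensus-pattern scan is attempted instead.
    """
    ref = ref or ReferenceLoops.default()
    params = params or AlignParams()
    if len(query.residues) < 30:
        raise FamkitError(f"{query.id!r}: query too short for EF-hand "
                          "annotation (< 30 aa)")
    pw = global_align(query, ref.reference, params)
    qrow, rrow = pw.a, pw.b
    annotations: list[EFHandAnnotation] = []
    used_spans: list[tuple[int, int]] = []
    for k, (s, e) in enumerate(ref.loops, start=1):
        cols = [rrow.column_of_residue(p) for p in range(s, e + 1)]
        loop_chars = [qrow.gapped[c - 1] for c in cols]
        insertions = sum(
            1 for c in range(cols[0] + 1, cols[-1])
            if c not in cols and qrow.gapped[c - 1] != GAP)
        positions = [qrow.residue_of_column(c) for c in cols]
        occupied = [p for p in positions if p is not None]
        if not occupied:
            ann = _fallback_scan(query, k, used_spans)
            if ann is not None:
                annotations.append(ann)
                used_spans.append((ann.query_start, ann.query_end))
                continue
        q_start = occupied[0] if occupied else None
        q_end = occupied[-1] if occupied else None
        if q_start is not None:
            used_spans.append((q_start, q_end))
        annotations.append(EFHandAnnotation(
            ef_index=k, loop_gapped="".join(loop_chars),
            insertions=insertions, query_start=q_start, query_end=q_end))
    return annotations


def _fallback_scan(query: SeqRecord, ef_index: int,
                   used_spans: list[tuple[int, int]]
                   ) -> EFHandAnnotation | None:
    """Low-confidence consensus scan used when a window aligns to nothing."""
    for m in _CONSENSUS.finditer(query.residues):
        start, end = m.start() + 1, m.start() + LOOP_LEN
        if any(not (end < s or start > e) for s, e in used_spans):
            continue
        return EFHandAnnotation(
            ef_index=ef_index, loop_gapped=m.group(0), insertions=0,
            query_start=start, query_end=end, low_confidence=True,
            rationale=(CODE_FALLBACK,))
    return None


def classify_efhand(ann: EFHandAnnotation,
                    rules: RuleConfig | None = None) -> EFHandAnnotation:
    """Fill activity, cation class and rationale codes on an annotation.

    A pure function of the 12-column loop string and the insertion count.
    """
    rules = rules or RuleConfig()
    codes: list[str] = [c for c in ann.rationale if c == CODE_FALLBACK]
    if rules.forbid_deletions and GAP in ann.loop_gapped:
        codes.append(CODE_DELETION)
    if rules.forbid_insertions and ann.insertions > 0:
        codes.append(CODE_INSERTION)
    if GAP not in (ann.pos1,) and ann.pos1 not in rules.pos1_allowed:
        codes.append(CODE_POS1)
    if GAP not in (ann.pos12,) and ann.pos12 not in rules.pos12_allowed:
        codes.append(CODE_POS12)
    inactive = any(c in (CODE_DELETION, CODE_INSERTION, CODE_POS1, CODE_POS12)
                   for c in codes)
    if inactive:
        return replace(ann, activity="inactive", cation_class="none",
                       rationale=tuple(codes))
    if ann.pos12 == rules.ca_pos12:
        codes.append(CODE_CA)
        cation = "Ca-specific"
    elif ann.pos12 == rules.mg_pos12:
        codes.append(CODE_MG)
        cation = "Mg-preferring"
    else:  # unreachable with default rules (pos12 already restricted)
        cation = "none"
    return replace(ann, activity="active", cation_class=cation,
                   rationale=tuple(codes))


def annotate_and_classify(query: SeqRecord, ref: ReferenceLoops | None = None,
                          params: AlignParams | None = None,
                          rules: RuleConfig | None = None
                          ) -> list[EFHandAnnotation]:
    return [classify_efhand(a, rules) for a in annotate_efhands(query, ref,
                                                                params)]


def family_ef_table(annotations: dict[str, list[EFHandAnnotation]]
                    ) -> pd.DataFrame:
    """Protein × EF1..EF4 activity/cation summary (Ca / Mg / inactive)."""
    short = {"Ca-specific": "Ca", "Mg-preferring": "Mg", "none": "inactive"}
    rows = {}
    for protein, anns in annotations.items():
        cells = {}
        for ann in anns:
            if ann.activity is None:
                raise FamkitError("annotations must be classified first")
            cells[EF_NAMES[ann.ef_index - 1]] = short[ann.cation_class]
        rows[protein] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=EF_NAMES)


def compare_efhands(anns_a: list[EFHandAnnotation],
                    anns_b: list[EFHandAnnotation]
                    ) -> list[EFHandComparison]:
    """Loop-by-loop comparison of two proteins' EF-hand annotations."""
    out = []
    for a, b in zip(anns_a, anns_b):
        if a.ef_index != b.ef_index:
            raise FamkitError("annotation lists are not aligned by EF index")
        out.append(EFHandComparison(
            ef_index=a.ef_index, pos12_a=a.pos12, pos12_b=b.pos12,
            conserved_pct=identity_pair(a.loop_gapped, b.loop_gapped),
            both_inactive=(a.activity == "inactive"
                           and b.activity == "inactive")))
    return out


def comparison_table(comparisons: dict[str, list[EFHandComparison]]
                     ) -> pd.DataFrame:
    """Serialize per-protein EF-hand comparisons in a printed-table layout."""
    rows = {}
    for protein, comps in comparisons.items():
        cells = {}
        for c in comps:
            name = EF_NAMES[c.ef_index - 1]
            pct = f"{round(c.conserved_pct):d}%"
            mark = " (N)" if c.both_inactive else ""
            cells[name] = f"{c.pos12_a} {c.pos12_b} {pct}{mark}"
        rows[protein] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=EF_NAMES)


def detect_cterm_extension(query: SeqRecord,
                           ref: ReferenceLoops | None = None,
                           params: AlignParams | None = None) -> int:
    """Query residues C-terminal to the reference's last aligned residue."""
    ref = ref or ReferenceLoops.default()
    params = params or AlignParams()
    pw = global_align(query, ref.reference, params)
    last_col = pw.b.column_of_residue(len(ref.reference.residues))
    return sum(1 for c in pw.a.gapped[last_col:] if c != GAP)


def measure_linker(query: SeqRecord, ref: ReferenceLoops | None = None,
                   params: AlignParams | None = None) -> int:
    """Length, in query residues, of the segment between EF2 and EF3 loops."""
    ref = ref or ReferenceLoops.default()
    anns = annotate_efhands(query, ref, params)
    ef2, ef3 = anns[1], anns[2]
    if ef2.query_end is None or ef3.query_start is None:
        raise FamkitError("cannot measure linker: EF2 or EF3 loop absent")
    return ef3.query_start - ef2.query_end - 1


def report_json(annotations: dict[str, list[EFHandAnnotation]]) -> str:
    """JSON EF-hand report, one entry per protein."""
    payload = {protein: [a.to_dict() for a in anns]
               for protein, anns in annotations.items()}
    return json.dumps(payload, indent=2, sort_keys=True)
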