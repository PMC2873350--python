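"""Open-reading-frame discovery and Kozak start-context scoring.

Transcripts are assumed to be oriented, so only the forward strand is
scanned.  The Kozak classification follows the two consensus-defining
positions: a purine (A/G) at -3 and a G at +4 relative to the A of the ATG
(A = +1).  Both satisfied → strong; exactly one → adequate; neither → weak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .errors import FamkitError
from .seqio import SeqRecord

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfHit:
    """One forward-strand open reading frame (ATG..stop, inclusive)."""

    start: int           # 1-based position of the A of ATG
    end: int             # 1-based position of the last stop-codon base
    frame: int           # start position modulo 3 (0|1|2)
    peptide_length: int  # codons excluding the stop

    def __post_init__(self):
        if (self.end - self.start + 1) % 3 != 0:
            raise FamkitError("ORF span must be a whole number of codons")


@dataclass(frozen=True)
class KozakReport:
    """Start-codon context of an ORF scored against the Kozak consensus."""

    orf: OrfHit
    context: str   # 10 nt covering positions -6..+4 (N-padded at the 5' end)
    minus3: str
    plus4: str
    kozak_class: str  # strong | adequate | weak

    def to_dict(self) -> dict:
        return {
            "start": self.orf.start,
            "end": self.orf.end,
            "peptide_length": self.orf.peptide_length,
            "context": self.context,
            "minus3": self.minus3,
            "plus4": self.plus4,
            "class": self.kozak_class,
        }


def find_orfs(seq: SeqRecord, min_codons: int = 50) -> list[OrfHit]:
    """All forward-strand ATG-to-stop ORFs with at least ``min_codons``
    coding codons, sorted by start position."""
    if seq.moltype != "nucleotide":
        raise FamkitError(f"{seq.id!r}: find_orfs expects a nucleotide record")
    s = seq.residues
    hits: list[OrfHit] = []
    for start in range(len(s) - 2):
        if s[start:start + 3] != "ATG":
            continue
        for stop in range(start + 3, len(s) - 2, 3):
            codon = s[stop:stop + 3]
            if codon in STOPS:
                peptide = (stop - start) // 3
                if peptide >= min_codons:
                    hits.append(OrfHit(start=start + 1, end=stop + 3,
                                       frame=start % 3,
                                       peptide_length=peptide))
                break
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def kozak_context(seq: SeqRecord, orf: OrfHit) -> KozakReport:
    """Extract the -6..+4 window around an ORF's start codon and classify it.

    The window is padded with ``N`` when the ATG sits fewer than 7 nt from
    the 5' end; ``N`` never satisfies a consensus rule.
    """
    if seq.moltype != "nucleotide":
        raise FamkitError("kozak_context expects a nucleotide record")
    s = seq.residues
    a = orf.start  # 1-based position of A (= Kozak position +1)
    if not (1 <= a and a + 2 <= len(s)) or s[a - 1:a + 2] != "ATG":
        raise FamkitError(f"ORF at {orf.start} does not start with ATG on "
                          f"{seq.id!r}")
    window = []
    for offset in list(range(-6, 0)) + [1, 2, 3, 4]:
        pos = a + offset if offset < 0 else a + offset - 1
        window.append(s[pos - 1] if 1 <= pos <= len(s) else "N")
    context = "".join(window)
    minus3, plus4 = context[3], context[9]
    strong_minus3 = minus3 in ("A", "G")
    strong_plus4 = plus4 == "G"
    if strong_minus3 and strong_plus4:
        klass = "strong"
    elif strong_minus3 or strong_plus4:
        klass = "adequate"
    else:
        klass = "weak"
    return KozakReport(orf=orf, context=context, minus3=minus3, plus4=plus4,
                       kozak_class=klass)


def scan_transcript(seq: SeqRecord, min_codons: int = 50) -> list[KozakReport]:
    """Convenience: ORFs plus Kozak classification for one transcript."""
    return [kozak_context(seq, orf) for orf in find_orfs(seq, min_codons)]


def report_json(reports: dict[str, list[KozakReport]]) -> str:
    payload = {tid: [r.to_dict() for r in reps]
               for tid, reps in reports.items()}
    return json.dumps(payload, indent=2, sort_keys=True)
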