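#!/usr/bin/env python
"""Fetch the original GenBank records behind the published comparative
analysis (network required; not part of the tested API).

Downloads the human and zebrafish CaBP/calneuron/calmodulin sequences and
the two human calneuron-1 transcript isoforms from NCBI E-utilities, renames
them to the short protein names used throughout this package, and writes

    data/paper/proteins.fasta     (17 protein sequences)
    data/paper/transcripts.fasta  (2 nucleotide transcripts)

With these files in place the published-table reproduction in
tests/test_acceptance.py becomes runnable.

Usage:  python scripts/fetch_accessions.py
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

# (our name, accession, database, rettype)
PROTEINS = [
    ("calmodulin", "AAA35635", "protein", "fasta"),
    ("caldendrin", "NM_001033677", "nuccore", "fasta_cds_aa"),
    ("CaBP1L", "NM_031205", "nuccore", "fasta_cds_aa"),
    ("CaBP1S", "NM_004276", "nuccore", "fasta_cds_aa"),
    ("CaBP2S", "NM_031204", "nuccore", "fasta_cds_aa"),
    ("CaBP2L", "NM_016366", "nuccore", "fasta_cds_aa"),
    ("CaBP4", "NM_145200", "nuccore", "fasta_cds_aa"),
    ("CaBP5", "NM_019855", "nuccore", "fasta_cds_aa"),
    ("calneuron2", "NM_182527", "nuccore", "fasta_cds_aa"),
    ("calneuron1", "AY007302", "nuccore", "fasta_cds_aa"),
    ("zcalmodulin", "NP_955864", "protein", "fasta"),
    ("zCaBP1", "NP_001002414", "protein", "fasta"),
    ("zCaBP2", "NP_001025439", "protein", "fasta"),
    ("zCaBP4", "XP_001338361", "protein", "fasta"),
    ("zCaBP5", "NP_956992", "protein", "fasta"),
    ("zcalneuron2", "XP_683885", "protein", "fasta"),
    ("zcalneuron1", "XP_690899", "protein", "fasta"),
]

TRANSCRIPTS = [
    ("calneuron1_isoform1", "NM_031468.3", "nuccore", "fasta"),
    ("calneuron1_isoform2", "NM_001017440.2", "nuccore", "fasta"),
]


def fetch(accession: str, db: str, rettype: str) -> str:
    query = urllib.parse.urlencode({
        "db": db, "id": accession, "rettype": rettype, "retmode": "text"})
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=60) as resp:
        return resp.read().decode()


def first_record(fasta_text: str, new_name: str) -> str:
    """Keep the first record, renamed; wrap at 60 columns."""
    lines = fasta_text.strip().splitlines()
    seq: list[str] = []
    seen_header = False
    for line in lines:
        if line.startswith(">"):
            if seen_header:
                break
            seen_header = True
            continue
        seq.append(line.strip())
    body = "".join(seq)
    wrapped = "\n".join(body[i:i + 60] for i in range(0, len(body), 60))
    return f">{new_name}\n{wrapped}\n"


def main() -> int:
    outdir = Path(__file__).resolve().parent.parent / "data" / "paper"
    outdir.mkdir(parents=True, exist_ok=True)
    for outfile, table in [("proteins.fasta", PROTEINS),
                           ("transcripts.fasta", TRANSCRIPTS)]:
        chunks = []
        for name, accession, db, rettype in table:
            print(f"fetching {accession} -> {name}", file=sys.stderr)
            chunks.append(first_record(fetch(accession, db, rettype), name))
            time.sleep(0.4)  # NCBI rate limit
        (outdir / outfile).write_text("".join(chunks))
        print(f"wrote {outdir / outfile}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    sys.exit(main())
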