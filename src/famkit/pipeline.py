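"""End-to-end family report: the full analysis as one orchestrated run.

Given a FASTA of family members and the id of the calmodulin reference, the
pipeline aligns, tabulates identities, annotates and classifies EF-hands,
compares orthologue pairs, builds a bootstrap-consensus tree rooted on the
reference, and (optionally) scans transcripts for Kozak contexts.  All
output files are deterministic for a fixed seed and configuration; the
timestamped plain-text log is the only non-reproducible artefact.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .efhand import (ReferenceLoops, RuleConfig, annotate_and_classify,
                     compare_efhands, comparison_table, family_ef_table,
                     report_json)
from .errors import FamkitError
from .identity import identity_matrix
from .kozak import report_json as kozak_report_json
from .kozak import scan_transcript
from .matrices import AlignParams
from .msa import progressive_msa
from .phylo import (bootstrap_trees, majority_consensus,
                    root_on_outgroup, trim_variable_termini)
from .seqio import SeqRecord, read_fasta, write_alignment_fasta
from .tree import write_newick


@dataclass(frozen=True)
class ReportConfig:
    """Configuration for one family-report run."""

    reference_id: str
    seed: int = 0
    bootstrap: int = 2000
    trim_cterm: bool = False
    identity_denominator: str = "columns"
    min_codons: int = 50
    params: AlignParams = field(default_factory=AlignParams)
    rules: RuleConfig = field(default_factory=RuleConfig)


def family_report(records: list[SeqRecord], config: ReportConfig,
                  outdir, transcripts: list[SeqRecord] | None = None,
                  orthologue_pairs: list[tuple[str, str]] | None = None,
                  reference_loops: ReferenceLoops | None = None) -> dict:
    """Run every stage and write the report bundle into ``outdir``.

    Returns a manifest dict mapping stage names to output file names
    (relative to ``outdir``, so bundles are byte-reproducible).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [r.id for r in records]
    if config.reference_id not in ids:
        raise FamkitError(f"reference id {config.reference_id!r} not among "
                          "the input sequences")
    ref = reference_loops or ReferenceLoops.default()
    manifest: dict[str, str] = {}
    log_lines: list[str] = []

    def stage(name: str, fn):
        log_lines.append(f"{datetime.datetime.now().isoformat()} {name}")
        try:
            return fn()
        except Exception as exc:
            raise FamkitError(f"stage {name!r} failed: {exc}") from exc

    msa = stage("align", lambda: progressive_msa(records, config.params))
    aln_path = outdir / "alignment.fasta"
    write_alignment_fasta(msa.rows, aln_path)
    manifest["alignment"] = aln_path.name

    im = stage("identity", lambda: identity_matrix(
        msa, config.identity_denominator))
    im_path = outdir / "identity.tsv"
    im.to_tsv(im_path)
    manifest["identity"] = im_path.name

    def run_efhand():
        return {r.id: annotate_and_classify(r, ref, config.params,
                                            config.rules) for r in records}
    annotations = stage("efhand", run_efhand)
    ef_json = outdir / "efhands.json"
    ef_json.write_text(report_json(annotations) + "\n")
    table_path = outdir / "efhand_table.tsv"
    family_ef_table(annotations).to_csv(table_path, sep="\t",
                                        index_label="protein")
    manifest["efhand"] = ef_json.name
    manifest["efhand_table"] = table_path.name

    if orthologue_pairs:
        comps = {f"{a}|{b}": compare_efhands(annotations[a], annotations[b])
                 for a, b in orthologue_pairs}
        comp_path = outdir / "efhand_comparison.tsv"
        comparison_table(comps).to_csv(comp_path, sep="\t",
                                       index_label="pair")
        manifest["efhand_comparison"] = comp_path.name

    def run_tree():
        trimmed = trim_variable_termini(msa, config.reference_id,
                                        config.trim_cterm)
        trees = bootstrap_trees(trimmed, config.bootstrap, config.seed)
        consensus = majority_consensus(trees)
        return root_on_outgroup(consensus, config.reference_id)
    rooted = stage("tree", run_tree)
    tree_path = outdir / "consensus.nwk"
    write_newick(rooted, tree_path)
    manifest["tree"] = tree_path.name

    if transcripts:
        reports = stage("kozak", lambda: {
            t.id: scan_transcript(t, config.min_codons) for t in transcripts})
        kz_path = outdir / "kozak.json"
        kz_path.write_text(kozak_report_json(reports) + "\n")
        manifest["kozak"] = kz_path.name

    sidecar = {
        "version": __version__,
        "seed": config.seed,
        "bootstrap": config.bootstrap,
        "reference_id": config.reference_id,
        "identity_denominator": config.identity_denominator,
        "gap_open": config.params.gap_open,
        "gap_extend": config.params.gap_extend,
        "matrix": config.params.matrix.name,
        "n_sequences": len(records),
        "outputs": manifest,
    }
    (outdir / "run.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return manifest


def family_report_from_fasta(fasta_path, config: ReportConfig, outdir,
                             transcripts_path=None, **kwargs) -> dict:
    records = read_fasta(fasta_path, moltype="protein")
    transcripts = (read_fasta(transcripts_path, moltype="nucleotide")
                   if transcripts_path else None)
    return family_report(records, config, outdir, transcripts=transcripts,
                         **kwargs)
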