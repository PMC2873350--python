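"""ORF discovery and Kozak start-context classification on two transcripts.

Builds one transcript whose start codon sits in an ideal Kozak context and
one whose upstream start (mimicking an N-terminally extended isoform) does
not, then prints the classification of each ORF's context.
"""

from famkit import SeqRecord, find_orfs, kozak_context

cds = "ATG" + "GCTGAAGAT" * 20 + "TAA"
good = SeqRecord(id="short_isoform", residues="GGCGCCACC" + cds,
                 moltype="nucleotide")
# upstream in-frame ATG in a pyrimidine context extends the reading frame
bad = SeqRecord(id="long_isoform",
                residues="TTTTCTATGCTTCCT" + cds, moltype="nucleotide")

for tx in (good, bad):
    print(tx.id)
    for orf in find_orfs(tx, min_codons=20):
        rep = kozak_context(tx, orf)
        print(f"  ORF {orf.start}-{orf.end} ({orf.peptide_length} aa)  "
              f"context={rep.context}  -3={rep.minus3} +4={rep.plus4}  "
              f"-> {rep.kozak_class}")
    print()
print("A purine at -3 and G at +4 (A of ATG = +1) make a strong context;")
print("one of the two makes it adequate, neither makes it weak. A weak")
print("upstream start suggests the extended isoform is poorly translated.")
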