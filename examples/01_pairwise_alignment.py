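"""Global alignment of two EF-hand loops under BLOSUM62 with affine gaps.

Aligns the canonical calmodulin EF1 coordinating loop against a variant with
a three-residue deletion and prints the score, the gapped strings and the
percent identity.
"""

from famkit import SeqRecord, global_align, identity_pair

loop = SeqRecord(id="EF1", residues="DKDGDGTITTKE")
variant = SeqRecord(id="EF1del3", residues="DKDGTTKE")

pw = global_align(loop, variant)
print(f"score          : {pw.score}")
print(f"{pw.a.id:<15}: {pw.a.gapped}")
print(f"{pw.b.id:<15}: {pw.b.gapped}")
print(f"identity       : {identity_pair(pw.a, pw.b):.1f}%")
print()
print("The score is the optimal affine-gap global alignment score; the gap")
print("run marks the deleted coordinating residues, and identity counts")
print("matching columns over all columns with at least one residue.")
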