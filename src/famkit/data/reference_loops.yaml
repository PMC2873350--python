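# Default EF-hand reference: human calmodulin (canonical 149-aa vertebrate
# calmodulin) with its four 12-residue coordinating-loop windows (1-based
# inclusive).  EF1 must read DKDGDGTITTKE; this is checked at load time.
name: human-calmodulin
reference:
  id: calmodulin
  description: human calmodulin EF-hand reference
  residues: >-
    MADQLTEEQIAEFKEAFSLFDKDGDGTITTKELGTVMRSLGQNPTEAELQDMINEVDADGNGTIDFPE
    FLTMMARKMKDTDSEEEIREAFRVFDKDGNGYISAAELRHVMTNLGEKLTDEEVDEMIREADIDGDGQ
    VNYEEFVQMMTAK
loops:
  EF1: [21, 32]
  EF2: [57, 68]
  EF3: [94, 105]
  EF4: [130, 141]
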