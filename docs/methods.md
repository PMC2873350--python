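# Methods

This note documents the models, conventions and design choices behind
`famkit`, in the spirit of a methods supplement: what each stage computes,
which knobs matter, and what the synthetic-data results do and do not show.

## Pairwise and multiple alignment

Global alignment is Needleman–Wunsch with Gotoh's affine-gap extension.
A gap of length *k* costs `gap_open + (k−1)·gap_extend`: the first gapped
position pays the full opening penalty, each further position the
extension. Defaults are `gap_open = 10.0`, `gap_extend = 0.5`,
BLOSUM62, terminal gaps penalised — common protein-alignment defaults in
the ClustalW tradition; all are configurable (YAML/CLI, or a custom
whitespace-delimited matrix file). The ambiguity character X scores 0
against everything, itself included: translated genomic predictions
(XP_ records) carry X and should be neutral, not penalised.

Traceback is deterministic: ties prefer the diagonal move, then a gap in
the second sequence, then a gap in the first, so output is byte-stable.
Residue-level scores (integers plus halves) are exact in double precision;
profile–profile column scores are means and can round at the last bit, so
traceback comparisons use a 1e-9 relative tolerance.

The progressive aligner follows the classical recipe: all-against-all
global alignments → percent identities → p-distances → UPGMA guide tree
(ties broken by smallest label pair) → profile–profile Gotoh merges in
post-order, scoring a column pair as the mean of all residue-pair scores
(gapped members contribute zero). Gaps, once inserted, are never removed;
output row order equals input order.

## Percent identity

The table convention emulates the BioEdit sequence identity matrix:
columns gapped in both rows are ignored, a gap opposite a residue counts
as a mismatch, and identity is matches over all columns with at least one
residue. Because published tables rarely state their convention, two
alternatives are selectable: `pair-columns` (only doubly-occupied columns)
and `shorter-seq` (matches over the shorter ungapped length). Printed
tables round to one decimal, half up.

Domain profiles restrict the same computation to the alignment columns
occupied by a stated residue window of a named reference sequence
(1-based, inclusive). The best-hit search ranks database records by global
alignment score with the record id as tie-break — a deterministic,
desk-scale stand-in for a database search; it reports no E-values.

## EF-hand annotation and classification

Loops are located by globally aligning the query to a calmodulin reference
whose four 12-residue loop windows are configuration (shipped default:
human calmodulin, windows 21–32, 57–68, 94–105, 130–141; the EF1 window is
validated at load time to read `DKDGDGTITTKE`). Each window's columns are
projected onto the query: deletions appear as `-`, query residues falling
between window columns are counted as insertions, and coordinates refer to
the ungapped query. When a window projects onto nothing, a low-confidence
consensus scan (`D-x-[DN]-x-[DNS]-G` over a 12-window) is attempted and
flagged.

Classification is a pure function of the 12-column loop string and the
insertion count. A hand is **inactive** when any of four rules fires: a
deletion in the window, an insertion into it, position 1 outside {D, N, S},
or position 12 outside {D, E}. Otherwise it is **active**, Ca²⁺-specific
when position 12 is E and Mg²⁺-preferring when it is D. Only positions 1
and 12 of the six coordinating positions are enforced by default — the
conservative choice, avoiding inactivation calls the loop string cannot
support; the rule set is user-configurable YAML, and every call carries the
codes of the rules that fired.

Two structural measurements round out the module: the number of query
residues C-terminal to the reference's last aligned residue (the calneuron
membrane-targeting extension), and the query-coordinate length of the
segment between the EF2 and EF3 loops (the linker that is extended in
CaBPs relative to calmodulin).

## Distance phylogeny

Tree building replaces the original maximum-likelihood search with a
distance route whose claims are the testable surface (clade composition
and support): p-distance → Saitou–Nei neighbour joining → column bootstrap
→ majority-rule consensus → outgroup rooting.

p-distances default to **pairwise deletion**: only columns where both rows
carry residues are compared, the standard p-distance convention. The
alternative (gap-versus-residue as mismatch, `denominator="columns"`)
couples every pairwise distance to indel events elsewhere in the family —
a single long splice-variant insertion then inflates its carrier's
distance to every relative and can distort the topology. An optional
Poisson correction −ln(1−p) is available.

Before tree building, columns left of the reference's first residue are
removed (the variable N-termini), and with `trim_cterm` also columns right
of its last residue. The C-terminal trim matters whenever part of the
family shares a fast-evolving extension the outgroup lacks: under pairwise
deletion those members are compared over their divergent tails while other
pairs are not, biasing the distances; trimming restores a common site set.
The default pipeline trims both ends.

Neighbour joining breaks Q-criterion ties by the smallest label pair and
clamps negative branch lengths to zero, moving the deficit to the sister
edge. Bootstrap replicate *r* resamples columns with replacement using
spawned random substream *r* of the single run seed, so runs are exactly
reproducible and replicates independent. The consensus keeps every
bipartition in strictly more than 50% of replicates (support = rounded
percentage) and completes the tree greedily with compatible
lower-frequency bipartitions. Rooting places the root on the edge to the
outgroup leaf, splitting its branch length equally; support values, which
annotate edges, are re-attached to the correct side when edges reverse.

## Kozak scanning

ORF discovery scans the forward strand only (transcripts are oriented) for
every ATG with an in-frame stop, reporting 1-based ATG..stop coordinates
and peptide length; `min_codons` (default 50) suppresses spurious short
frames. The start context is the 10-nt window −6..+4 around the A of the
ATG (A = +1), N-padded near the 5′ end. Classification uses the two
consensus-defining positions: purine at −3 and G at +4 ⇒ strong, exactly
one ⇒ adequate, neither ⇒ weak; N never satisfies a rule. The binary
"has a Kozak consensus" question maps to class == strong.

## The synthetic family generator

The generator emulates the structure of a calmodulin-derived sensor
family. The ancestor is 149 residues of uniform random sequence with the
four loop windows set to the canonical `DKDGDGTITTKE` loop. Sequences
evolve down a Newick gene tree (branch lengths in substitutions/site) by a
per-site Poisson process with uniform replacement among the other 19
residues, region-scaled: loops ×0.2, linker ×1.0, termini ×2.0, core ×1.0
by default — slow loops, fast termini, as observed across the family.
Gene duplications clone a subtree at a point on its branch (the teleost
whole-genome duplication motivates this), suffixing leaf names.

Indels and classification-relevant changes happen **only** through
declared events, applied deterministically at branch midpoints:
`nterm_insert` (splice-like extension), `cterm_append` (the calneuron
tail), `loop_delete` (interior residues of a window), `pos12_swap`
(E↔D). Two site classes are additionally held invariant under the
substitution process: the coordinating anchors (loop positions 1 and 12)
and two flanking helix residues on each side of every window. The
biological reading is strong purifying selection on the coordinating
ligands and the helix positions entering and leaving the loop; the
practical consequence is that the truth table is exact — the anchors can
only change through declared events, and the frozen flanks pin the
alignment so a declared deletion is always projected inside its window.

The per-site match probability after total path rate *r* under this chain
is `1/20 + (19/20)·exp(−(20/19)·r)`; `expected_identity` averages it over
sites (frozen sites contribute 1) and is exact for event-free
configurations, which is what the calibration tests use.

What passing these tests shows — and does not. The generator produces
equal-rate Poisson substitutions, no alignment ambiguity beyond its
declared indels, and loops whose anchors never drift. Real families add
rate heterogeneity, empirical exchangeabilities, indel churn in the
variable termini and annotation ambiguity at degraded loops; agreement on
synthetic families demonstrates the machinery is correct, not that real
identity cells will land within any particular tolerance.

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py`) and the seeded test grids
use desk-scale sizes chosen as the package's defaults: the seven-member
default family; a 50-seed grid for truth-table accuracy and identity
calibration (two-taxon family, total path 0.3 substitutions/site); 100
seeded six-taxon families (300 sites, all branch rates 0.05/site, equal
region rates) for topology recovery; 200 bootstrap replicates for the
clade-support figures. The bootstrap default elsewhere is 2000 replicates,
matching common practice for publication trees; all stages accept an
explicit seed and are byte-reproducible given one.

## Known limitations

* No maximum-likelihood or Bayesian inference; support values from NJ
  bootstrap are not comparable to likelihood-based supports, and exact
  published support figures are not targeted.
* Identity cells from progressive alignment are sensitive to gap
  parameters at the ±1 percentage-point level; the defaults are stated
  above rather than fitted.
* The EF-hand fallback scanner is pattern-based and flagged
  low-confidence; structure-based detection is out of scope.
* The simulator's uniform substitution model keeps the calibration oracle
  exact but is not an empirical amino-acid model; an empirical-matrix mode
  would lose the closed form.
* `expected_identity` requires indel-free configurations.
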