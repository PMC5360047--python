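# Methods

This note documents the models and conventions the package implements, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical/design decisions taken where the underlying
field practice is informal.

## Coordinate and naming conventions

Intron insertion sites are 1-based coordinates on an intron-free reference
cox1 CDS: "intron N" means the intron sits between reference positions N and
N+1, and N is the last exon nucleotide 5′ of the intron. The canonical sponge
site set is {387, 714, 723, 870, 966, 1141} (the first four are group I, the
last two group II; the class is user-supplied metadata here, not inferred).
All canonical group I sites are multiples of 3, i.e. codon boundaries; site
1141 has phase 1. The exon-continuous reading frame inside an intron starts
at intron position `(3 − N mod 3) mod 3 + 1`.

HEG ORF start positions are reported 1-based within the intron (the 0-based
equivalent is exposed in the `HegOrf` repr, because published per-taxon start
positions mix the two conventions and the mix is not resolvable
programmatically).

## Insertion-site mapping

Queries are globally aligned to the reference with affine gap costs
(match +2, mismatch −3, gap open −12, extension −0.5, Biopython
`PairwiseAligner`). These scores make a long random insertion cheaper as one
contiguous gap than as scattered spurious matches (expected per-column score
of aligning random sequence is −1.75, below the −0.5 extension cost), so an
intron appears as a single query-only gap run. Runs ≥ `min_intron_len`
(default 150 nt — real cox1 group I introns are several hundred nt, so this
cleanly separates introns from indel noise) become intron calls; shorter
insertions stay inside exon segments as indels.

Gap placement within an alignment-score-equivalence region is arbitrary, so
boundaries are canonicalised toward the biology: if the called intron does
not end in G, the boundary is shifted by up to 3 nt (any score-neutral shift,
i.e. one that exchanges bases with identical match/mismatch status against
the reference) to make the 3′ base the conserved terminal ωG; a warning is
logged when no shift achieves this. Orientation is auto-detected by aligning
both strands and keeping the better score. A query aligning to < 50 % of the
reference (configurable) is rejected as non-homologous rather than annotated.

Canonical labels are assigned within a tolerance (default 3 nt, for residual
alignment jitter). The tolerance is validated against half the minimal
canonical spacing (sites 714/723 are 9 nt apart, capping it at 4), which
makes label assignment provably unambiguous.

## ORF scanning and motif detection

Translation uses NCBI table 4 (TGA = Trp; stops TAA/TAG); codons containing
ambiguity letters translate to X. The ORF scan enumerates, per frame, every
(start codon … next in-frame stop) span with start ∈ {ATG, GTG, TTG, ATT}
(TTA excluded by default — there is no evidence of TTA initiation in sponge
mitochondria — but re-enable with `allow_TTA`), minimum length 100 bp counted
from the start codon through the stop codon inclusive, interior starts
included. ORFs running off the intron 3′ end are reported with
`stop_codon = None` (their length excludes any stop); they matter because a
missing in-intron stop is itself degeneration evidence.

LAGLIDADG motifs are detected as 9-mer windows within class-aware Hamming
distance ≤ 2 of the literal pattern, where substitutions within {L,I,V,M,F}
and within {A,G} are free. The published analyses located motifs by protein
BLAST, which is not reproducible without a database; the class-aware scan is
a transparent deterministic stand-in with a measured false-positive rate
(zero hits on ≥ 99 % of random 300-aa proteins at distance ≤ 1). The double
motif characteristic of these HEGs requires two hits ≥ 75 aa apart.

Among motif-bearing ORFs, the annotator prefers the 5′-most one in the
exon-continuous frame (this reproduces the "earliest potential start"
convention of published reports, e.g. ATT at position 10 for intron 723
HEGs); if no in-frame candidate exists it takes the ORF with the most motif
hits in any frame.

## Stage classification

The five-stage degeneration ladder is decided purely from evidence fields:

| stage | rule |
|---|---|
| 5 | no intron |
| 4 | no motif-bearing ORF ≥ 100 bp |
| 3 | ORF truncated (no stop inside the intron, or < `full_len_frac` × `expected_heg_aa`) or the double motif is decayed |
| 2 | full-length double-motif HEG, but out of the exon-continuous frame or preceded by an in-frame stop |
| 1 | otherwise: HEG in frame and uninterrupted from the upstream exon |

Defaults `expected_heg_aa = 250` and `full_len_frac = 0.8` are explicit knobs,
not literature constants: sponge-type HEGs run roughly 250–300 aa, and no
quantitative truncation cutoff exists in the descriptive literature. A
`degenerate_mismatch` threshold (default 3) flags individual decayed motif
hits; at the default scan distance of 2 it cannot fire, so at defaults the
operative motif-decay signal for stage 3 is the loss of the well-spaced
double motif. The stage-1/stage-2 split ("fused in frame" vs "free-standing")
is operationalised as: stage 1 requires the exon-continuous frame AND no stop
codon in that frame between intron position 1 and the ORF start.

## Conservation profile

The per-column substitution count is `max(0, distinct residues − 1)` after
excluding gaps and X — the minimum number of changes explaining the column
under any tree. (Whether the original profile scripts counted distinct
states, pairwise differences, or parsimony steps is not recoverable; this
minimum-change definition is fixed here, documented, and isolated in one
function.) The profile sums counts over an 11-column window; edge columns use
the truncated window, and a per-column mean over the actual window size is
emitted alongside for comparable plotting. Column classes follow the
PAUP-style convention: only unambiguous residues count as states; constant
means ≤ 1 state, parsimony-informative means ≥ 2 states each with count ≥ 2.

Nucleotide positions on the reference CDS project to alignment columns via
amino-acid position ⌈nt/3⌉ and a walk along the gapped reference row. Output
is a data table (column, score, mean score, annotations); plotting is left to
the caller.

## Structure bookkeeping

Exactly two bracket layers are supported — '()' for the nested core and '[]'
for pseudoknots — matching how group I core structures are curated by hand;
deeper nesting is an error, not silently accepted. The nested layer must be
non-crossing; pseudoknot pairs may cross nested ones but not each other
(otherwise the structure is not representable in this notation and
conversion raises). The ct emitter writes the common 6-column dialect
(index, base, i−1, i+1 with 0 at the ends, partner, index). ct files carry no
layer information, so `parse_ct` accepts an explicit pseudoknot pair list, or
falls back to a greedy maximal non-crossing assignment.

Helix inventories use the standard P-nomenclature (P1…P10 with suffixes such
as P6d or P9.1c); labels are supplied, never inferred — automatic helix
naming would require the reference structures themselves. The conserved-core
check requires the P, Q, R, S boxes plus the nine domain helices (P1-P2-P10
substrate, P4-P5-P6 scaffold, P3-P7-P8 catalytic; P9 is peripheral), with a
suffixed label satisfying its base helix.

## Tree congruence

The Robinson–Foulds distance is the symmetric difference of non-trivial
bipartition sets over the shared leaf set (trees are pruned to it first);
`rf_max` counts the bipartitions actually present, so polytomies lower the
ceiling rather than being penalised. Transfer candidates are ranked greedily:
repeatedly remove the leaf whose removal most reduces RF (lexicographic tie
break), stopping at congruence, at `max_k` removals, or when removal stops
helping. Greedy pruning is a heuristic (exact maximum agreement subtrees are
exponential) but resolves single-regraft conflicts exactly and is adequate at
the ≤ 100-leaf scale of these datasets. Likelihood-based significance tests
of incongruence are deliberately not implemented; the screen provides the
normalized RF and the candidate ranking.

## Synthetic data generator

The generator emulates the study conditions: a 12-taxon demo species tree, a
1554-nt random table-4-clean root CDS (cox1-sized), Jukes–Cantor
substitutions with per-site rate classes, and intron events on branches.
Defaults: background rate 1.0, conserved blocks of ±45 nt around each
canonical site at rate 0.1 (the conserved-region premise of intron homing,
by construction), HEG length 250 aa, 3′ shell 150 nt ending in a non-G run
plus the terminal ωG, HEG start at intron position phase+10 (matching the
convention that intron 723 HEGs start near position 10).

Determinism: one numpy Generator seeded from the spec drives every draw;
`generate_dataset` bundles are byte-identical for equal spec+seed.

Constructions that keep planted truth unambiguous (boundary cases are
excluded by construction rather than tolerated statistically):

- substitutions that would create an in-frame stop are rejected (purifying
  selection on the host CDS);
- the three exon bases flanking each canonical junction are invariant
  (rate 0), the root CDS keeps a non-G base immediately 5′ of each site, and
  the intron's first base differs from the exon base following the site —
  together these make the planted gap placement the strict alignment optimum,
  so mapper recovery is exact rather than merely canonical;
- intron shells are rejection-sampled against chance LAGLIDADG-like windows
  and against start codons in the exon-continuous 5′ shell, so the planted
  HEG is the unique motif-bearing call;
- the stage-3 transform inserts a premature stop after the first motif
  (truncating the ORF to 59 aa, far from the 0.8 × 250 aa threshold); stage 2
  shifts the HEG one nucleotide out of frame and plants an upstream in-frame
  stop; stage 4 replaces the ORF with a 400-nt shell.

Horizontal transfer is modeled as reinfection: the recipient tip's intron
state is replaced by a copy of the donor tip's intron (optional divergence
mutates shell positions only, preserving the planted stage; the demo uses
divergence 0, so tree regrafting is the only HGT signal). The emitted intron
"gene tree" is the species tree restricted to carriers with each HGT
recipient regrafted as the donor's sister.

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: indels within exons (alignments are trivial by
design, isolating each stage's logic from aligner behaviour), codon- or
amino-acid-level substitution models, rate variation beyond two classes,
intron sequence divergence along the tree, partially degenerate boundary
cases near the stage thresholds, and biogeography. Real sequencing artifacts
(chimeras, frameshifts from miscalled homopolymers) are also absent.

## Problem sizes in the validation run

`scripts/acceptance.py` uses: 500 random sequences of 120–5000 nt for the
ORF-scan/oracle comparison; 50 seeds × 5 stages for stage recovery; 100
synthetic taxa for the mapper round trip; 100 simulated alignments for the
conserved-vs-background comparison; 200 random alignments for the column
classes; 200 random two-layer structures; 50 random 8-leaf tree pairs; and
100 single-regraft transfer simulations on 12-leaf trees. These sizes give
stable percentages across seeds while keeping the whole run under a minute.

## Known limitations

- The mapper assumes one homologous reference; paralogy, chimeric queries and
  introns in other genes are out of scope.
- Intron class (group I vs II, IA–IE) is positional/user-supplied metadata;
  structure-based classification is not attempted.
- The motif scan is a fixed-pattern detector, not an HMM; deeply diverged
  LAGLIDADG variants beyond two class-aware mismatches will read as decayed.
- The greedy congruence screen can mis-rank when multiple overlapping
  transfers interact; it is a screen, not a test of significance.
- Published per-taxon HEG start positions mix 0- and 1-based counting between
  intron types; the package reports 1-based and logs the 0-based equivalent
  without guessing intent.
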