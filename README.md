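# cox1intron

A Python toolkit for analysing **mitochondrial group I introns in the cox1
gene**, the only mitochondrial gene known to harbour self-splicing introns in
sponges and one of the classic insertion hotspots for mobile introns across
eukaryotes. The package turns the standard desk analyses of this field —
done by hand or with one-off scripts in most studies — into a tested,
reusable pipeline:

- **Insertion-site mapping.** An intron-bearing cox1 sequence is globally
  aligned (affine gaps) to an intron-free reference CDS; maximal query-only
  insertions ≥ 150 nt are called as introns. Sites are reported as the
  1-based reference coordinate of the last exon nucleotide 5′ of the intron
  ("intron 723" sits between positions 723 and 724, following the
  *Amphimedon queenslandica* coordinate convention), snapped to the canonical
  site set {387, 714, 723, 870, 966, 1141}. Boundary ambiguity is resolved
  towards the conserved terminal ωG of group I introns.
- **Homing-endonuclease gene (HEG) annotation.** ORFs are scanned under NCBI
  translation table 4 (mold/protozoan mitochondrial: TGA = Trp, stops
  TAA/TAG) with start codons ATG, GTG, TTG and ATT (TTA excluded), minimum
  100 bp, interior starts included. LAGLIDADG motifs are found by a
  class-aware Hamming scan (L/I/V/M/F and A/G substitutions free); a
  functional HEG carries a double motif ≥ 75 aa apart.
- **Five-stage degeneration classification.** Each intron is placed on the
  degeneration ladder: (1) HEG fused in frame with the upstream exon,
  (2) free-standing HEG, (3) truncated/degenerated HEG, (4) intron without a
  conserved HEG, (5) exon without intron. The verdict is a pure function of
  machine-checkable evidence (frame, double motif, truncation, upstream
  in-frame stop).
- **Conservation profiling.** Per-column substitution counts
  (distinct residues − 1, gaps/X excluded) summed over a sliding 11-column
  window of a protein alignment, plus the constant / parsimony-uninformative
  / parsimony-informative column tally, with intron sites and primer 5′
  anchors projected onto alignment columns — the computation behind "introns
  sit in the most conserved regions of the host protein" and behind choosing
  barcoding primers that avoid intron-interrupted priming sites.
- **Secondary-structure bookkeeping.** Two-layer dot-bracket notation
  (round brackets: nested P1–P10 core; square brackets: pseudoknots) ↔ pair
  tables ↔ 6-column ct files, helix inventories in the standard
  P-nomenclature, inventory diffs (e.g. presence/absence of P6d) and a
  conserved-core check (P/Q/R/S boxes; substrate P1-P2-P10, scaffold
  P4-P5-P6, catalytic P3-P7-P8 domains).
- **Tree-congruence screening.** Unrooted Robinson–Foulds distance between
  exon and intron phylogenies over their shared leaves, with a greedy leaf
  ranking that names the taxa whose removal restores congruence — the
  combinatorial core of horizontal-vs-vertical transmission arguments.
- **Synthetic data with planted truth.** A seed-reproducible generator:
  exons evolve by Jukes–Cantor substitutions with conserved blocks around the
  canonical sites; introns with table-4-clean double-motif HEGs are gained,
  lost, degenerated and horizontally copied along a species tree; every
  bundle ships a truth table (per taxon × site: presence, stage, transmission
  mode, donor) so each pipeline stage is testable without downloads.

## Worked example

```python
import cox1intron as cx

bundle = cx.simulate(cx.demo_spec(seed=1))          # 12 taxa, 2 sites, 1 HGT
ref = cx.ReferenceCDS("REF", bundle.reference.seq)

ann = cx.map_insertion_sites(bundle.genomic_by_taxon["t01"], ref)
intr = ann.introns[0]
print(intr.insertion_pos, intr.canonical_label, intr.length, intr.terminal_ok)
# 723 723 910 True

heg = cx.annotate_heg(intr.seq, cx.exon_frame_at(intr.insertion_pos))
print(heg.start_codon, heg.start_pos, heg.stop_codon, len(heg.motif_hits))
# ATG 10 TAA 2

print(cx.stage_intron(intr.seq, 0).stage)
# 1
```

The intron lands after reference position 723 on a codon boundary, is 910 nt
long and ends in the conserved ωG. Its HEG opens at intron position 10 (the
position reported for real intron 723 HEGs), in the exon-continuous reading
frame, with two LAGLIDADG motifs and a table-4 stop — the evidence pattern of
a stage-1 (potentially active, exon-fused) intron. The `examples/` directory has one short script per
capability, including `tree_congruence_screen.py`, which recovers the
planted horizontal transfer (removing the recipient taxon drops the
exon-vs-intron Robinson–Foulds distance from 4 to 0), and
`annotate_real_intron.py` for running the same annotation on user-supplied
cox1 FASTA files.

A thin CLI mirrors the library: `cox1intron map|heg|profile|congruence|simulate`.

## Scope

Tree inference, likelihood-based topology tests (SH), thermodynamic RNA
folding, automatic helix naming, intron class (IA–IE) determination and
database homology searches are out of scope: trees, structures and class
labels are inputs. See `docs/methods.md` for the models, parameter
defaults and known limitations.
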