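"""Annotate homing-endonuclease ORFs and stage intron degeneration.

Builds one synthetic intron per degeneration stage at canonical site 723 and
runs the annotator: the ORF scan uses translation table 4 (TGA = Trp) with
start codons ATG/GTG/TTG/ATT, and the stage classifier reads the evidence
(frame, double LAGLIDADG motif, truncation, upstream in-frame stop).
"""

import numpy as np

import cox1intron as cx

rng = np.random.default_rng(1)
phase = cx.exon_frame_at(723)          # 723 sits on a codon boundary

for planted in (1, 2, 3, 4):
    intr = cx.make_intron(723, rng, stage=planted)
    heg = cx.annotate_heg(intr.seq, phase)
    call = cx.stage_intron(intr.seq, phase)
    desc = (f"ORF start {heg.start_codon}@{heg.start_pos}, "
            f"stop {heg.stop_codon or 'none'}, {heg.len_aa} aa, "
            f"{len(heg.motif_hits)} motif hit(s), "
            f"in exon frame: {heg.in_exon_frame}") if heg else "no HEG ORF"
    print(f"planted stage {planted} -> classified stage {call.stage}  ({desc})")

print(f"no intron        -> classified stage {cx.stage_intron(None, phase).stage}")
print("\nStage 1 = HEG fused in frame with the upstream exon; 2 = free-standing;")
print("3 = truncated/degenerated HEG; 4 = intron without HEG; 5 = no intron.")
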