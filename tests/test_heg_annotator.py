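import numpy as np
import pytest

import cox1intron as cx
from cox1intron import OrfScanParams, StageThresholds
from cox1intron.heg_annotator import upstream_in_frame_stop
from cox1intron.synthetic_data import make_intron


def brute_force_orfs(seq, params):
    """Independent ORF enumeration: try every codon position as a start and
    scan forward for the frame's next stop."""
    seq = seq.upper()
    found = []
    for i in range(len(seq) - 2):
        if seq[i:i + 3] not in params.effective_starts:
            continue
        stop = None
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j:j + 3] in cx.STOP_CODONS_TABLE4:
                stop = j
                break
            j += 3
        if stop is not None:
            length = stop + 3 - i
            key = (i + 1, stop + 1, seq[stop:stop + 3], i % 3)
        else:
            n_codons = (len(seq) - i) // 3
            length = 3 * n_codons
            key = (i + 1, i + 3 * n_codons + 1, None, i % 3)
        if length >= params.min_len_nt:
            found.append(key)
    return sorted(found)


class TestTranslate:
    @pytest.mark.parametrize("nt,aa", [
        ("TGA", "W"),              # table-4 reassignment
        ("ATGAAATAA", "MK*"),
        ("ATGNNN", "MX"),
        ("TTATAGTAA", "L**"),
    ])
    def test_table4_semantics(self, nt, aa):
        assert cx.translate(nt) == aa

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            cx.translate("ATGA")


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = cx.find_orfs("ATGAAATAA", OrfScanParams(min_len_nt=9, frames=(0,)))
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start_pos, o.start_codon, o.stop_codon, o.protein) \
            == (1, "ATG", "TAA", "MK")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        params = OrfScanParams(min_len_nt=100)
        got = sorted((o.start_pos, o.stop_pos,
                      o.stop_codon, o.frame) for o in cx.find_orfs(seq, params))
        assert got == brute_force_orfs(seq, params)

    def test_allow_tta_gives_superset(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
        base = {(o.start_pos, o.frame) for o in
                cx.find_orfs(seq, OrfScanParams())}
        wide = {(o.start_pos, o.frame) for o in
                cx.find_orfs(seq, OrfScanParams(allow_TTA=True))}
        assert base <= wide

    def test_interior_false_keeps_only_5prime_start(self):
        # two in-frame starts before one stop
        seq = "ATG" + "AAA" * 3 + "GTG" + "AAA" * 3 + "TAA"
        all_orfs = cx.find_orfs(seq, OrfScanParams(min_len_nt=9, frames=(0,)))
        first_only = cx.find_orfs(
            seq, OrfScanParams(min_len_nt=9, frames=(0,), interior=False))
        assert [o.start_pos for o in all_orfs] == [1, 13]
        assert [o.start_pos for o in first_only] == [1]

    def test_open_ended_orf_reported_without_stop(self):
        seq = "ATG" + "GCT" * 40      # runs off the 3' end
        (o,) = cx.find_orfs(seq, OrfScanParams(min_len_nt=60, frames=(0,)))
        assert o.stop_codon is None
        assert o.protein == "M" + "A" * 40
        assert (o.stop_pos - o.start_pos) % 3 == 0


class TestLaglidadgScan:
    def test_exact_motif(self):
        hits = cx.find_laglidadg("XXX" + cx.LAGLIDADG + "XXX")
        assert len(hits) == 1
        assert (hits[0].aa_start, hits[0].mismatches) == (4, 0)

    def test_double_motif_with_one_substitution(self):
        prot = ("Q" * 29 + "LAGLIDADG" + "Q" * 101 + "LAGLIGADG" + "Q" * 60)
        hits = cx.find_laglidadg(prot, max_mismatch=2)
        assert [(h.aa_start, h.mismatches) for h in hits] == [(30, 0), (140, 1)]
        assert cx.has_double_motif(hits, min_spacing_aa=75)

    def test_conservative_classes_cost_zero(self):
        # swap every L<->I/V and A<->G: still a perfect hit
        variant = "IGALVDGDA"
        assert cx.find_laglidadg(variant, max_mismatch=0)[0].mismatches == 0

    def test_false_positive_rate_on_random_proteins(self):
        rng = np.random.default_rng(99)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        clean = 0
        reps = 1000
        for _ in range(reps):
            prot = "".join(aas[i] for i in rng.integers(0, 20, size=300))
            if not cx.find_laglidadg(prot, max_mismatch=1):
                clean += 1
        assert clean / reps >= 0.99


class TestAnnotateHeg:
    def test_planted_heg_start_recovered(self, rng):
        intr = make_intron(723, rng, stage=1)
        heg = cx.annotate_heg(intr.seq, exon_phase=723 % 3)
        assert heg is not None
        assert heg.start_pos == intr.heg_start == 10
        assert heg.in_exon_frame
        assert len(heg.motif_hits) == 2

    def test_motifless_intron_yields_none(self, rng):
        intr = make_intron(714, rng, stage=4)     # HEG-less shell
        assert cx.annotate_heg(intr.seq, exon_phase=714 % 3) is None

    def test_exon_continuous_frame_offsets(self):
        assert cx.exon_continuous_frame(0) == 0
        assert cx.exon_continuous_frame(1) == 2   # e.g. site 1141
        assert cx.exon_continuous_frame(2) == 1


class TestClassifyStage:
    def test_absent_intron_is_stage5(self):
        call = cx.classify_stage(False, None)
        assert call.stage == 5
        assert not call.evidence.has_intron

    def test_no_orf_is_stage4(self):
        assert cx.classify_stage(True, None).stage == 4

    def test_truncated_heg_is_stage3(self, rng):
        intr = make_intron(723, rng, stage=3)
        call = cx.stage_intron(intr.seq, 0)
        assert call.stage == 3
        assert call.evidence.truncated or not call.evidence.double_motif

    def test_out_of_frame_heg_is_stage2(self, rng):
        intr = make_intron(723, rng, stage=2)
        call = cx.stage_intron(intr.seq, 0)
        assert call.stage == 2
        assert not call.evidence.orf_in_exon_frame

    def test_pure_function_of_evidence(self, rng):
        intr = make_intron(870, rng, stage=1)
        heg = cx.annotate_heg(intr.seq, 0)
        a = cx.classify_stage(True, heg)
        b = cx.classify_stage(True, heg)
        assert a == b

    def test_degradation_monotone_along_decay_path(self, rng):
        """gain -> premature stop -> delete ORF never decreases the stage."""
        intact = make_intron(723, rng, stage=1)
        stages = [cx.stage_intron(intact.seq, 0).stage]
        # truncate: premature stop inside the ORF
        i = intact.heg_start - 1 + 3 * 59
        truncated = intact.seq[:i] + "TAA" + intact.seq[i + 3:]
        stages.append(cx.stage_intron(truncated, 0).stage)
        # delete the HEG entirely
        hegless = make_intron(723, rng, stage=4)
        stages.append(cx.stage_intron(hegless.seq, 0).stage)
        stages.append(cx.stage_intron(None, 0).stage)
        assert stages == sorted(stages)
        assert stages[0] == 1 and stages[-1] == 5

    def test_stage12_stop_codons_are_table4_stops(self, rng):
        for site, stage in [(723, 1), (870, 1), (723, 2), (1141, 1)]:
            intr = make_intron(site, rng, stage=stage)
            heg = cx.annotate_heg(intr.seq, site % 3)
            call = cx.stage_intron(intr.seq, site % 3)
            if call.stage in (1, 2):
                assert heg.stop_codon in {"TAA", "TAG"}

    def test_upstream_stop_detection(self):
        # TAA sits in the exon-continuous frame before the ORF start
        seq = "TAA" + "GCT" * 3 + "ATG" + "GCT" * 40 + "TAA"
        assert upstream_in_frame_stop(seq, orf_start_pos=13, cont_frame=0)
        assert not upstream_in_frame_stop(seq[3:], orf_start_pos=10, cont_frame=0)
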