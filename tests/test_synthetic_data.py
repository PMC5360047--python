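import hashlib
from pathlib import Path

import numpy as np
import pytest

import cox1intron as cx
from cox1intron import SimSpec, IntronEvent, SimSpecError
from cox1intron.synthetic_data import (make_root_cds, _evolve_branch,
                                       DEMO_TREE)


def _dir_digest(path: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(path.iterdir())}


class TestMakeHeg:
    def test_deterministic_per_seed(self):
        assert cx.make_heg(250, 1) == cx.make_heg(250, 1)
        assert cx.make_heg(250, 1) != cx.make_heg(250, 2)

    def test_table4_clean_with_double_motif(self):
        heg = cx.make_heg(250, 5)
        assert heg[:3] in cx.DEFAULT_START_CODONS
        assert heg[-3:] in {"TAA", "TAG"}
        aa = cx.translate(heg)
        assert "*" not in aa[:-1] and aa.endswith("*")
        hits = cx.find_laglidadg(aa)
        assert cx.has_double_motif(hits, 75)

    def test_too_short_for_spaced_motifs(self):
        with pytest.raises(SimSpecError, match="160"):
            cx.make_heg(100, 1)

    def test_scanner_closure_stage1_evidence(self, rng):
        """The planted HEG comes back as stage-1 evidence from the annotator."""
        intr = cx.make_intron(723, rng, stage=1)
        call = cx.stage_intron(intr.seq, cx.exon_frame_at(723))
        assert call.stage == 1
        assert call.evidence.n_motifs >= 2 and call.evidence.double_motif


class TestEvolveExons:
    def test_zero_rates_leave_root_unchanged(self, rng):
        root = make_root_cds(300, rng)
        out = cx.evolve_exons(DEMO_TREE, root, np.zeros(300), rng)
        assert all(s == root for s in out.values())

    def test_two_taxon_divergence_matches_jukes_cantor(self):
        """Observed difference fraction ~ (3/4)(1 - e^(-4d/3)) over 10 seeds."""
        d = 0.3
        expected = 0.75 * (1 - np.exp(-4 * d / 3))
        n = 3000
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            root = make_root_cds(n, rng)
            out = cx.evolve_exons(f"(a:{d / 2},b:{d / 2});", root,
                                  np.ones(n), rng)
            a, b = out["a"], out["b"]
            diffs.append(sum(x != y for x, y in zip(a, b)) / n)
        # stop-codon avoidance slightly depresses the rate; stay within 3 SE
        se = np.sqrt(expected * (1 - expected) / (n * 10))
        assert abs(np.mean(diffs) - expected) < 3 * se + 0.01

    def test_conserved_blocks_quieter_than_background(self):
        spec = cx.demo_spec(seed=3)
        rates = cx.site_rate_profile(spec)
        rng = np.random.default_rng(3)
        root = make_root_cds(spec.root_cds_len, rng)
        out = cx.evolve_exons(spec.tree, root, rates, rng)
        seqs = list(out.values())
        cons = rates < spec.background_rate
        def diversity(mask):
            cols = [i for i in range(len(root)) if mask[i]]
            diff = sum(len({s[i] for s in seqs}) - 1 for i in cols)
            return diff / len(cols)
        assert diversity(cons) < diversity(~cons)

    def test_branch_evolution_never_creates_stops(self, rng):
        root = make_root_cds(999, rng)
        arr = np.array(list(root))
        out = _evolve_branch(arr, np.ones(999), 0.8, rng)
        aa = cx.translate("".join(out))
        assert "*" not in aa


class TestIntronHistory:
    def test_empty_event_list_all_stage5(self, rng):
        spec = SimSpec(tree=DEMO_TREE, events=[], seed=4)
        bundle = cx.simulate(spec)
        assert bundle.genomic_by_taxon == bundle.cds_by_taxon
        assert (bundle.truth.stage == 5).all()
        assert (~bundle.truth.present).all()

    def test_root_gain_reaches_every_taxon(self):
        spec = SimSpec(
            tree=DEMO_TREE, seed=5, canonical_sites=(723,),
            events=[IntronEvent("gain", 723, ("t01", "t12"), stage=1)])
        bundle = cx.simulate(spec)
        assert bundle.truth.present.all()
        assert (bundle.truth.stage == 1).all()
        ref = cx.ReferenceCDS("REF", bundle.reference.seq)
        for taxon, g in bundle.genomic_by_taxon.items():
            ann = cx.map_insertion_sites(g, ref)
            assert [i.insertion_pos for i in ann.introns] == [723]

    def test_loss_without_intron_is_spec_error(self):
        spec_kwargs = dict(tree=DEMO_TREE, seed=1, canonical_sites=(723,))
        spec = SimSpec(events=[IntronEvent("loss", 723, ("t01",))],
                       **spec_kwargs)
        with pytest.raises(SimSpecError, match="without the intron"):
            cx.simulate(spec)

    def test_degrade_must_increase_stage(self):
        spec = SimSpec(
            tree=DEMO_TREE, seed=1, canonical_sites=(723,),
            events=[IntronEvent("gain", 723, ("t01", "t12"), stage=3),
                    IntronEvent("degrade", 723, ("t01",), stage=2)])
        with pytest.raises(SimSpecError, match="never decreases"):
            cx.simulate(spec)

    def test_truth_table_schema_and_invariants(self, demo_bundle):
        truth = demo_bundle.truth
        spec = demo_bundle.spec
        taxa = set(demo_bundle.cds_by_taxon)
        assert set(truth.taxon) == taxa
        assert len(truth) == len(taxa) * len(spec.canonical_sites)
        absent = truth[~truth.present]
        assert (absent.stage == 5).all()
        assert (absent.transmission == "none").all()
        hgt = truth[truth.transmission == "hgt"]
        assert (hgt.donor != "").all()

    def test_hgt_pattern_paraphyletic_and_flagged(self, demo_bundle):
        """An HGT copy makes intron presence para-phyletic on the species tree
        and the recipient tops the transfer-candidate ranking."""
        truth = demo_bundle.truth
        carriers = set(truth[(truth.site == 723) & truth.present].taxon)
        recipient = truth[(truth.site == 723) &
                          (truth.transmission == "hgt")].taxon.iloc[0]
        # para-phyly: the recipient is outside the vertical carriers' clade
        exon = cx.parse_newick(demo_bundle.spec.tree)
        exon.is_rooted = True
        vert = carriers - {recipient}
        mrca = exon.mrca(taxa=[l.taxon for l in exon.leaf_node_iter()
                               if l.taxon.label in vert])
        below = {l.taxon.label for l in mrca.leaf_iter()}
        assert recipient not in below
        report = cx.transfer_candidates(exon, demo_bundle.intron_trees[723])
        top2 = {c.leaf for c in report.candidates[:2]}
        assert recipient in top2 or truth[(truth.site == 723) & (
            truth.transmission == "hgt")].donor.iloc[0] in top2


class TestBundleDeterminism:
    def test_same_spec_same_seed_byte_identical(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        cx.generate_dataset(cx.demo_spec(seed=11), a)
        cx.generate_dataset(cx.demo_spec(seed=11), b)
        assert _dir_digest(a) == _dir_digest(b)

    def test_seed_changes_sequences_not_schema(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        cx.generate_dataset(cx.demo_spec(seed=11), a)
        cx.generate_dataset(cx.demo_spec(seed=12), b)
        assert set(p.name for p in a.iterdir()) == set(p.name for p in b.iterdir())
        assert (a / "genomic.fasta").read_text() != (b / "genomic.fasta").read_text()
        head = (a / "truth.tsv").read_text().splitlines()[0]
        assert head == (b / "truth.tsv").read_text().splitlines()[0]

    def test_bundle_files_parse_back(self, tmp_path):
        out = tmp_path / "bundle"
        cx.generate_dataset(cx.demo_spec(seed=2), out)
        recs = cx.read_fasta(out / "genomic.fasta")
        assert len(recs) == 12
        cx.read_newick(out / "species_tree.nwk")
        cx.read_newick(out / "intron_tree_723.nwk")
        aln = cx.read_alignment(out / "protein_alignment.fasta", moltype="aa")
        assert aln.nrow == 12


class TestSpecValidation:
    def test_site_beyond_cds_rejected(self):
        with pytest.raises(SimSpecError, match="inside the CDS"):
            SimSpec(tree=DEMO_TREE, canonical_sites=(2000,), root_cds_len=1554)

    def test_event_site_must_be_canonical(self):
        with pytest.raises(SimSpecError, match="unknown site"):
            SimSpec(tree=DEMO_TREE, canonical_sites=(723,),
                    events=[IntronEvent("gain", 870, ("t01",))])

    def test_hgt_requires_donor(self):
        with pytest.raises(SimSpecError, match="donor"):
            IntronEvent("hgt_copy", 723, ("t01",))

    def test_json_roundtrip(self, tmp_path):
        spec = cx.demo_spec(seed=3)
        p = tmp_path / "spec.json"
        spec.to_json(p)
        back = SimSpec.from_json(p)
        assert back == spec
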