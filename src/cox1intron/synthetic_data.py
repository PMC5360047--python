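"""Seed-reproducible synthetic cox1/intron datasets with planted ground truth.

The generator emulates the study system: a species tree, an intron-free cox1
CDS evolving by single-nucleotide substitutions with site-heterogeneous rates
(conserved blocks around the canonical insertion sites), and group I introns
planted at canonical sites carrying a table-4-clean homing endonuclease ORF
with two LAGLIDADG motifs.  Intron histories are event lists on tree
branches: ``gain`` (vertical transmission from that branch down), ``loss``
(secondary loss), ``degrade`` (transform to a degeneration stage) and
``hgt_copy`` (replace a recipient's intron state with a copy of a donor tip's
intron — the reinfection model of horizontal transfer).  Every dataset is
emitted together with a truth table (per taxon and site: presence, stage,
transmission mode, donor) so each pipeline stage can be tested without
external data.

Exon evolution is indel-free by design: alignments are trivial, which
isolates the mapper, profile and column statistics from aligner behaviour.
All randomness flows through one numpy Generator seeded from the spec.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import dendropy
import numpy as np
import pandas as pd

from .io_formats import (SequenceRecord, AlignmentMatrix, write_fasta,
                         write_alignment, parse_newick)
from .heg_annotator import (translate, find_laglidadg, exon_continuous_frame,
                            DEFAULT_START_CODONS, STOP_CODONS_TABLE4,
                            _CODON_TO_AA, LAGLIDADG)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = sorted(_CODON_TO_AA)                       # no TAA/TAG
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon in _SENSE_CODONS:
    _AA_TO_CODONS.setdefault(_CODON_TO_AA[codon], []).append(codon)
# codons safe for filler regions: sense, not a start codon, not TTA
_SAFE_CODONS = [c for c in _SENSE_CODONS
                if c not in DEFAULT_START_CODONS and c != "TTA"]
_AA20 = sorted(_AA_TO_CODONS)


class SimSpecError(ValueError):
    pass


EventKind = Literal["gain", "loss", "degrade", "hgt_copy"]


@dataclass
class IntronEvent:
    """One event in an intron history.

    ``clade`` names the leaves whose most recent common ancestor's branch
    carries the event (for ``hgt_copy`` it is the recipient tip set, and
    ``donor`` names the donor tip).
    """

    kind: EventKind
    site: int
    clade: tuple[str, ...]
    stage: int = 1              # planted stage for gain / target for degrade
    donor: str | None = None    # hgt_copy only
    divergence: float = 0.0     # hgt_copy: per-site mutation prob, shell only

    def __post_init__(self) -> None:
        self.clade = tuple(self.clade)
        if self.kind not in ("gain", "loss", "degrade", "hgt_copy"):
            raise SimSpecError(f"unknown event kind {self.kind!r}")
        if self.kind == "hgt_copy" and not self.donor:
            raise SimSpecError("hgt_copy event needs a donor taxon")
        if self.kind in ("gain", "degrade") and self.stage not in (1, 2, 3, 4):
            raise SimSpecError(f"cannot plant stage {self.stage}")


@dataclass
class SimSpec:
    """Full description of one synthetic dataset."""

    tree: str
    events: list[IntronEvent] = field(default_factory=list)
    root_cds_len: int = 1554
    canonical_sites: tuple[int, ...] = (723, 870)
    conserved_halfwidth_nt: int = 45
    conserved_rate: float = 0.1
    background_rate: float = 1.0
    heg_len_aa: int = 250
    shell3_len: int = 150
    stage4_shell_len: int = 400
    reference_id: str = "REF"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_cds_len % 3 != 0:
            raise SimSpecError("root_cds_len must be divisible by 3")
        self.canonical_sites = tuple(sorted(self.canonical_sites))
        if any(s >= self.root_cds_len for s in self.canonical_sites):
            raise SimSpecError("canonical sites must lie inside the CDS")
        self.events = [e if isinstance(e, IntronEvent) else IntronEvent(**e)
                       for e in self.events]
        for ev in self.events:
            if ev.site not in self.canonical_sites:
                raise SimSpecError(
                    f"event references unknown site {ev.site}")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimSpec":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class IntronState:
    """The intron carried at one site along one lineage."""

    seq: str
    stage: int
    intron_id: str
    heg_start: int | None       # 1-based planted ORF start within the intron
    transmission: Literal["vgt", "hgt"] = "vgt"
    donor: str | None = None
    orf_span: tuple[int, int] | None = None   # 1-based nt span of the HEG


# ---------------------------------------------------------------------------
# sequence synthesis


def _random_codons(n: int, rng: np.random.Generator,
                   pool: list[str] | None = None) -> str:
    pool = pool or _SAFE_CODONS
    return "".join(pool[i] for i in rng.integers(0, len(pool), size=n))


def _encode_protein(protein: str, rng: np.random.Generator) -> str:
    out = []
    for aa in protein:
        codons = _AA_TO_CODONS[aa]
        out.append(codons[rng.integers(0, len(codons))])
    return "".join(out)


def make_heg(length_aa: int, seed: int | np.random.Generator,
             start_codon: str | None = None) -> str:
    """Synthesize a table-4-clean homing endonuclease ORF.

    The ORF opens with a canonical start codon, carries two exact LAGLIDADG
    motifs at least 75 aa apart, closes with TAA or TAG and contains no
    internal stop.  Deterministic for a given seed.
    """
    if length_aa < 160:
        raise SimSpecError(
            f"length_aa {length_aa} too short to fit two LAGLIDADG motifs "
            "75 aa apart with margins (need >= 160)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    starts = sorted(DEFAULT_START_CODONS)
    start = start_codon or starts[rng.integers(0, len(starts))]
    m1, m2 = 21, length_aa - 30          # 1-based motif starts, spacing >= 109
    body = [ _AA20[i] for i in rng.integers(0, 20, size=length_aa) ]
    body[m1 - 1:m1 + 8] = list(LAGLIDADG)
    body[m2 - 1:m2 + 8] = list(LAGLIDADG)
    protein = "".join(body)
    stop = ("TAA", "TAG")[rng.integers(0, 2)]
    return start + _encode_protein(protein[1:], rng) + stop


def _spurious_motif(intron: str, allowed_nt_spans: list[tuple[int, int]],
                    max_mismatch: int = 2) -> bool:
    """Any LAGLIDADG-like window outside the designed motif spans?"""
    for frame in range(3):
        n = (len(intron) - frame) // 3
        prot = translate(intron[frame:frame + 3 * n])
        for hit in find_laglidadg(prot, max_mismatch=max_mismatch):
            nt_start = frame + 3 * (hit.aa_start - 1) + 1
            nt_end = nt_start + 26
            if not any(lo <= nt_start and nt_end <= hi
                       for lo, hi in allowed_nt_spans):
                return True
    return False


def make_intron(site: int, rng: np.random.Generator, stage: int = 1,
                heg_len_aa: int = 250, shell3_len: int = 150,
                stage4_shell_len: int = 400,
                intron_id: str = "intron",
                forbidden_first: str = "") -> IntronState:
    """Build one planted intron for an insertion after reference position
    ``site``, in the requested degeneration stage.

    The intron ends in the conserved omega-G with a non-G run before it, and
    its 5' shell carries no start codon in the exon-continuous frame, so the
    planted HEG start is the 5'-most one the annotator can report.  Shells
    are rejection-sampled against chance LAGLIDADG-like windows so planted
    truth is unambiguous; ``forbidden_first`` (the exon base 3' of the site)
    keeps the 5' boundary free of alignment-shift ambiguity.
    """
    o = exon_continuous_frame(site % 3)        # 0-based cont-frame offset
    avoid_first = set(forbidden_first.upper()) | {"G"}
    for _ in range(200):
        if stage == 4:
            shell = ("".join(_BASES[i] for i in
                             rng.integers(0, 3, size=3))           # ACT only
                     + _random_codons((stage4_shell_len - 10) // 3, rng)
                     + "AAAG")
            if shell[0] in avoid_first:
                continue
            if not _spurious_motif(shell, []):
                return IntronState(seq=shell, stage=4, intron_id=intron_id,
                                   heg_start=None)
            continue

        heg = make_heg(heg_len_aa, rng)
        lead = "".join("ACT"[i] for i in rng.integers(0, 3, size=o))
        if stage == 2:
            # free-standing HEG: out of the exon-continuous frame, with an
            # upstream in-frame stop
            first = "ACT"[rng.integers(0, 3)]
            shell5 = lead + "TAA" + _random_codons(2, rng) + first  # len o+10
            heg_start = o + 11
        else:
            shell5 = lead + _random_codons(3, rng)                  # len o+9
            heg_start = o + 10
        if shell5[0] in avoid_first:
            continue
        if stage == 3:
            # premature stop after the first motif, before the second
            cut_aa = 60                        # 1-based codon index in the ORF
            i = 3 * (cut_aa - 1)
            heg = heg[:i] + "TAA" + heg[i + 3:]
        shell3 = _random_codons((shell3_len - 4) // 3, rng) + "AAAG"
        intron = shell5 + heg + shell3
        orf_span = (heg_start, heg_start + len(heg) - 1)
        if _spurious_motif(intron, [orf_span]):
            continue
        return IntronState(seq=intron, stage=stage, intron_id=intron_id,
                           heg_start=heg_start, orf_span=orf_span)
    raise SimSpecError("could not synthesize a clean intron in 200 attempts")


def _degrade_state(state: IntronState, target_stage: int, site: int,
                   rng: np.random.Generator, spec: "SimSpec",
                   intron_id: str, forbidden_first: str = "") -> IntronState:
    """Transform a carried intron to a deeper degeneration stage."""
    if target_stage <= state.stage:
        raise SimSpecError(
            f"degrade to stage {target_stage} from stage {state.stage} "
            "never decreases degeneration")
    if target_stage == 3 and state.heg_start is not None:
        # insert a premature stop inside the carried ORF, after the first motif
        i = state.heg_start - 1 + 3 * 59
        seq = state.seq[:i] + "TAA" + state.seq[i + 3:]
        return IntronState(seq=seq, stage=3, intron_id=intron_id,
                           heg_start=state.heg_start,
                           transmission=state.transmission, donor=state.donor,
                           orf_span=state.orf_span)
    # stage 2 or 4 (or 3 without a usable ORF): rebuild the intron shell
    return make_intron(site, rng, stage=target_stage,
                       heg_len_aa=spec.heg_len_aa,
                       shell3_len=spec.shell3_len,
                       stage4_shell_len=spec.stage4_shell_len,
                       intron_id=intron_id, forbidden_first=forbidden_first)


# ---------------------------------------------------------------------------
# exon evolution


def make_root_cds(length: int, rng: np.random.Generator,
                  sites: tuple[int, ...] = ()) -> str:
    """A random table-4-clean CDS (sense codons only).

    When canonical ``sites`` are given, the last exon base before each site
    is kept non-G so a planted intron's terminal omega-G can never be
    mistaken for exon sequence.
    """
    if length % 3 != 0:
        raise SimSpecError("CDS length must be divisible by 3")
    cds = list(_random_codons(length // 3, rng, pool=_SENSE_CODONS))
    for site in sites:
        i = site - 1                     # 0-based last exon base 5' of the site
        c0 = 3 * (i // 3)
        while cds[i] == "G":
            codon = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
            if codon[i - c0] != "G":
                cds[c0:c0 + 3] = list(codon)
    return "".join(cds)


def site_rate_profile(spec: SimSpec) -> np.ndarray:
    """Per-nucleotide substitution rates: conserved blocks around each
    canonical site, background elsewhere.  The three bases on either side of
    each junction are invariant — intron insertion targets the most conserved
    positions of the host gene, and fixed flanks keep planted intron
    boundaries free of alignment ambiguity."""
    rates = np.full(spec.root_cds_len, spec.background_rate, dtype=float)
    hw = spec.conserved_halfwidth_nt
    for site in spec.canonical_sites:
        lo = max(0, site - hw)
        hi = min(spec.root_cds_len, site + hw)
        rates[lo:hi] = spec.conserved_rate
    for site in spec.canonical_sites:
        rates[max(0, site - 3):min(spec.root_cds_len, site + 3)] = 0.0
    return rates


def _evolve_branch(seq: np.ndarray, rates: np.ndarray, dist: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor substitutions along one branch, avoiding new stop codons."""
    p = 0.75 * (1.0 - np.exp(-4.0 * rates * dist / 3.0))
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    # purifying selection on the reading frame: no codon may become a stop
    for c in range(0, len(out) - 2, 3):
        if "".join(out[c:c + 3]) in STOP_CODONS_TABLE4:
            out[c:c + 3] = seq[c:c + 3]
    return out


def evolve_exons(tree: dendropy.Tree | str, root_cds: str,
                 rates: np.ndarray,
                 rng: np.random.Generator) -> dict[str, str]:
    """Evolve the root CDS down the tree; returns per-taxon ungapped CDS.

    Site order is preserved (no indels), so the per-taxon sequences are also
    a trivial alignment and share the reference coordinate system.
    """
    t = tree if isinstance(tree, dendropy.Tree) else parse_newick(tree)
    if len(root_cds) != len(rates):
        raise SimSpecError("rates length must equal CDS length")
    root_arr = np.array(list(root_cds))
    out: dict[str, str] = {}

    def walk(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            d = child.edge.length or 0.0
            child_seq = _evolve_branch(seq, rates, d, rng) if d > 0 else seq
            if child.is_leaf():
                out[child.taxon.label] = "".join(child_seq)
            else:
                walk(child, child_seq)

    seed_node = t.seed_node
    if seed_node.is_leaf():
        out[seed_node.taxon.label] = root_cds
    walk(seed_node, root_arr)
    return out


def cds_alignment(cds_by_taxon: dict[str, str]) -> AlignmentMatrix:
    recs = [SequenceRecord(id=t, description=t, seq=s, moltype="nt")
            for t, s in sorted(cds_by_taxon.items())]
    return AlignmentMatrix(records=recs, moltype="nt")


def protein_alignment(cds_by_taxon: dict[str, str]) -> AlignmentMatrix:
    recs = [SequenceRecord(id=t, description=t, seq=translate(s),
                           moltype="aa")
            for t, s in sorted(cds_by_taxon.items())]
    return AlignmentMatrix(records=recs, moltype="aa")


# ---------------------------------------------------------------------------
# intron histories


def _mrca(tree: dendropy.Tree, labels: tuple[str, ...]) -> dendropy.Node:
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    missing = [x for x in labels if x not in leaves]
    if missing:
        raise SimSpecError(f"event clade references unknown taxa {missing}")
    if len(labels) == 1:
        return leaves[labels[0]]
    node = tree.mrca(taxa=[leaves[x].taxon for x in labels])
    if node is None:
        raise SimSpecError(f"no MRCA for clade {labels}")
    return node


def apply_intron_history(cds_by_taxon: dict[str, str], spec: SimSpec,
                         rng: np.random.Generator,
                         tree: dendropy.Tree | None = None
                         ) -> tuple[dict[str, str], pd.DataFrame]:
    """Insert planted introns per the event list; returns genomic sequences
    and the truth table (one row per taxon x canonical site)."""
    t = tree or parse_newick(spec.tree)
    t.is_rooted = True      # histories descend from the seed node
    taxa = sorted(l.taxon.label for l in t.leaf_node_iter())
    if set(taxa) - set(cds_by_taxon):
        raise SimSpecError("CDS missing for some tree taxa")

    vertical = [e for e in spec.events if e.kind != "hgt_copy"]
    horizontal = [e for e in spec.events if e.kind == "hgt_copy"]
    events_at: dict[int, list[IntronEvent]] = {}
    for ev in vertical:
        node = _mrca(t, ev.clade)
        events_at.setdefault(id(node), []).append(ev)

    gain_counter = 0
    tip_states: dict[str, dict[int, IntronState | None]] = {}
    # exon base immediately 3' of each junction (invariant across taxa:
    # junction flanks evolve at rate 0); the intron must not start with it
    cds0 = cds_by_taxon[taxa[0]]
    after_base = {site: cds0[site] for site in spec.canonical_sites}

    def walk(node: dendropy.Node, state: dict[int, IntronState | None]) -> None:
        nonlocal gain_counter
        state = dict(state)
        for ev in events_at.get(id(node), []):
            if ev.kind == "gain":
                if state.get(ev.site) is not None:
                    raise SimSpecError(
                        f"gain at site {ev.site} on a lineage already "
                        "carrying an intron there")
                gain_counter += 1
                state[ev.site] = make_intron(
                    ev.site, rng, stage=ev.stage,
                    heg_len_aa=spec.heg_len_aa, shell3_len=spec.shell3_len,
                    stage4_shell_len=spec.stage4_shell_len,
                    intron_id=f"intron{ev.site}_g{gain_counter}",
                    forbidden_first=after_base[ev.site])
            elif ev.kind == "loss":
                if state.get(ev.site) is None:
                    raise SimSpecError(
                        f"loss at site {ev.site} on a lineage without the intron")
                state[ev.site] = None
            elif ev.kind == "degrade":
                cur = state.get(ev.site)
                if cur is None:
                    raise SimSpecError(
                        f"degrade at site {ev.site} on a lineage without "
                        "the intron")
                state[ev.site] = _degrade_state(
                    cur, ev.stage, ev.site, rng, spec,
                    intron_id=cur.intron_id + f"_d{ev.stage}",
                    forbidden_first=after_base[ev.site])
        if node.is_leaf():
            tip_states[node.taxon.label] = state
        for child in node.child_nodes():
            walk(child, state)

    walk(t.seed_node, {site: None for site in spec.canonical_sites})

    for ev in horizontal:
        donor_state = tip_states.get(ev.donor, {}).get(ev.site)
        if donor_state is None:
            raise SimSpecError(
                f"hgt_copy donor {ev.donor!r} carries no intron at "
                f"site {ev.site}")
        for recipient in ev.clade:
            if recipient not in tip_states:
                raise SimSpecError(f"unknown hgt recipient {recipient!r}")
            seq = donor_state.seq
            if ev.divergence > 0:
                seq = _mutate_shell(donor_state, ev.divergence, rng)
            tip_states[recipient][ev.site] = IntronState(
                seq=seq, stage=donor_state.stage,
                intron_id=donor_state.intron_id, heg_start=donor_state.heg_start,
                transmission="hgt", donor=ev.donor,
                orf_span=donor_state.orf_span)

    genomic: dict[str, str] = {}
    rows = []
    for taxon in taxa:
        seq = cds_by_taxon[taxon]
        for site in sorted(spec.canonical_sites, reverse=True):
            st = tip_states[taxon].get(site)
            if st is not None:
                seq = seq[:site] + st.seq + seq[site:]
        genomic[taxon] = seq
        for site in spec.canonical_sites:
            st = tip_states[taxon].get(site)
            rows.append({
                "taxon": taxon,
                "site": site,
                "present": st is not None,
                "stage": st.stage if st is not None else 5,
                "transmission": st.transmission if st is not None else "none",
                "donor": (st.donor or "") if st is not None else "",
                "intron_id": st.intron_id if st is not None else "",
                "heg_start_offset": (st.heg_start or 0) if st is not None else 0,
                "intron_seq": st.seq if st is not None else "",
            })
    truth = pd.DataFrame(rows)
    return genomic, truth


def _mutate_shell(state: IntronState, p: float,
                  rng: np.random.Generator) -> str:
    """Mutate intron shell positions only (the HEG span and the terminal G
    are untouched, so the planted stage is preserved exactly)."""
    seq = list(state.seq)
    lo, hi = state.orf_span if state.orf_span else (1, 0)
    for i in range(len(seq) - 1):            # spare the terminal G
        if lo - 1 <= i < hi:
            continue
        if rng.random() < p:
            seq[i] = [b for b in "ACGT" if b != seq[i]][rng.integers(0, 3)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# intron gene tree (species tree with HGT regrafts)


def regraft_leaf(tree: dendropy.Tree, leaf_label: str,
                 sibling_label: str, edge_length: float = 0.01) -> dendropy.Tree:
    """Move ``leaf_label`` so it becomes the sister of ``sibling_label``."""
    tree.prune_taxa_with_labels([leaf_label], suppress_unifurcations=True)
    sib = next(l for l in tree.leaf_node_iter()
               if l.taxon.label == sibling_label)
    parent = sib.parent_node
    joint = dendropy.Node()
    joint.edge.length = max((sib.edge.length or 0.02) / 2, 0.005)
    sib_len = (sib.edge.length or 0.02) - joint.edge.length
    parent.remove_child(sib)
    parent.add_child(joint)
    joint.add_child(sib)
    sib.edge.length = max(sib_len, 0.005)
    taxon = tree.taxon_namespace.require_taxon(label=leaf_label)
    moved = dendropy.Node(taxon=taxon)
    moved.edge.length = edge_length
    joint.add_child(moved)
    return tree


def intron_gene_tree(spec: SimSpec, truth: pd.DataFrame, site: int) -> dendropy.Tree:
    """Species tree restricted to the carriers of ``site``, with every HGT
    recipient regrafted as sister to its donor."""
    carriers = truth[(truth.site == site) & truth.present]
    labels = sorted(carriers.taxon)
    if len(labels) < 3:
        raise SimSpecError(
            f"site {site} has only {len(labels)} carriers; no informative tree")
    tree = parse_newick(spec.tree)
    keep = [t for t in tree.taxon_namespace if t.label in labels]
    tree.retain_taxa(keep)
    for _, row in carriers[carriers.transmission == "hgt"].iterrows():
        if row.donor in labels and row.taxon in labels:
            regraft_leaf(tree, row.taxon, row.donor)
    return tree


def random_binary_tree(labels: list[str], rng: np.random.Generator,
                       mean_branch: float = 0.08) -> str:
    """A random binary newick over ``labels`` (random sequential joins)."""
    if len(labels) < 2:
        raise SimSpecError("need at least two labels")
    nodes = [f"{l}:{rng.exponential(mean_branch) + 0.01:.4f}" for l in labels]
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.exponential(mean_branch) + 0.01:.4f}")
    return nodes[0].rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# dataset bundles


DEMO_TREE = ("((((t01:0.05,t02:0.05):0.04,(t03:0.05,t04:0.05):0.04):0.06,"
             "((t05:0.05,t06:0.05):0.04,(t07:0.05,t08:0.05):0.04):0.06):0.05,"
             "((t09:0.06,t10:0.06):0.05,(t11:0.06,t12:0.06):0.05):0.05);")


def demo_spec(seed: int = 0) -> SimSpec:
    """The bundled demonstration history: 12 taxa, two canonical sites, one
    root-clade gain with a secondary loss, one degeneration and one HGT."""
    events = [
        IntronEvent("gain", 723, ("t01", "t08"), stage=1),
        IntronEvent("loss", 723, ("t07", "t08")),
        IntronEvent("degrade", 723, ("t04",), stage=3),
        IntronEvent("gain", 870, ("t07", "t08"), stage=1),
        IntronEvent("hgt_copy", 723, ("t10",), donor="t02"),
    ]
    return SimSpec(tree=DEMO_TREE, events=events, seed=seed)


@dataclass
class DatasetBundle:
    spec: SimSpec
    reference: SequenceRecord
    cds_by_taxon: dict[str, str]
    genomic_by_taxon: dict[str, str]
    truth: pd.DataFrame
    species_tree: dendropy.Tree
    intron_trees: dict[int, dendropy.Tree]


def simulate(spec: SimSpec) -> DatasetBundle:
    """Run the full generator in memory."""
    rng = np.random.default_rng(spec.seed)
    root_cds = make_root_cds(spec.root_cds_len, rng, sites=spec.canonical_sites)
    rates = site_rate_profile(spec)
    tree = parse_newick(spec.tree)
    cds = evolve_exons(tree, root_cds, rates, rng)
    genomic, truth = apply_intron_history(cds, spec, rng, tree)
    intron_trees: dict[int, dendropy.Tree] = {}
    for site in spec.canonical_sites:
        n_carriers = int(((truth.site == site) & truth.present).sum())
        if n_carriers >= 4:
            intron_trees[site] = intron_gene_tree(spec, truth, site)
    ref = SequenceRecord(id=spec.reference_id, description=spec.reference_id,
                         seq=root_cds, moltype="nt")
    return DatasetBundle(spec=spec, reference=ref, cds_by_taxon=cds,
                         genomic_by_taxon=genomic, truth=truth,
                         species_tree=tree, intron_trees=intron_trees)


def generate_dataset(spec: SimSpec, outdir: str | Path) -> DatasetBundle:
    """Simulate and write the file bundle (FASTA, trees, truth TSV, config)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate(spec)

    write_fasta([bundle.reference], out / "reference.fasta")
    write_fasta([SequenceRecord(id=t, description=t, seq=s)
                 for t, s in sorted(bundle.genomic_by_taxon.items())],
                out / "genomic.fasta")
    write_fasta([SequenceRecord(id=t, description=t, seq=s)
                 for t, s in sorted(bundle.cds_by_taxon.items())],
                out / "cds.fasta")
    write_alignment(protein_alignment(bundle.cds_by_taxon),
                    out / "protein_alignment.fasta")
    bundle.species_tree.write(path=str(out / "species_tree.nwk"),
                              schema="newick", suppress_rooting=True)
    for site, tr in sorted(bundle.intron_trees.items()):
        tr.write(path=str(out / f"intron_tree_{site}.nwk"),
                 schema="newick", suppress_rooting=True)
    truth = bundle.truth.drop(columns=["intron_seq"])
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    spec.to_json(out / "config.json")
    logger.info("dataset bundle written to %s (seed %d)", out, spec.seed)
    return bundle
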