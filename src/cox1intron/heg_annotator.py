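"""Homing-endonuclease ORF detection and intron degeneration staging.

Intron ORFs are scanned under the mold/protozoan mitochondrial genetic code
(NCBI translation table 4: TGA codes tryptophan, stops are TAA/TAG) with the
alternative start codons ATG, GTG, TTG and ATT; TTA is excluded by default
because there is no evidence it initiates translation in sponges.  LAGLIDADG
motifs are detected by a class-aware Hamming scan, and each intron is placed
on the five-stage degeneration ladder:

1. HEG in frame with, and uninterrupted from, the upstream exon;
2. expressed free-standing HEG (full length, both motifs, but out of the
   exon-continuous frame or preceded by an in-frame stop);
3. shortened or degenerated HEG (truncated ORF or decayed motif);
4. intron without a conserved HEG;
5. exon without intron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

TABLE4 = CodonTable.unambiguous_dna_by_id[4]
_CODON_TO_AA = dict(TABLE4.forward_table)
STOP_CODONS_TABLE4 = frozenset(TABLE4.stop_codons)   # {"TAA", "TAG"}

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG", "ATT"})
LAGLIDADG = "LAGLIDADG"

# conservative substitution classes for motif matching
_CLASSES = ({"L", "I", "V", "M", "F"}, {"A", "G"})


class HegError(ValueError):
    pass


def translate(seq: str, genetic_code: int = 4) -> str:
    """Translate a gap-free nucleotide sequence (length divisible by 3).

    Internal stops are rendered '*'; any codon containing a non-ACGT letter
    translates to 'X'.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise HegError(f"sequence length {len(seq)} not divisible by 3")
    if genetic_code == 4:
        fwd, stops = _CODON_TO_AA, STOP_CODONS_TABLE4
    else:
        table = CodonTable.unambiguous_dna_by_id[genetic_code]
        fwd, stops = table.forward_table, frozenset(table.stop_codons)
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in stops:
            out.append("*")
        else:
            out.append(fwd.get(codon, "X"))
    return "".join(out)


@dataclass
class OrfScanParams:
    """Settings of the intron ORF scan."""

    genetic_code: int = 4
    start_codons: frozenset[str] = DEFAULT_START_CODONS
    allow_TTA: bool = False
    min_len_nt: int = 100          # start through stop codon, inclusive
    frames: tuple[int, ...] = (0, 1, 2)
    interior: bool = True

    def __post_init__(self) -> None:
        self.start_codons = frozenset(c.upper() for c in self.start_codons)
        for c in self.start_codons:
            if len(c) != 3 or set(c) - set("ACGT"):
                raise HegError(f"bad start codon {c!r}")
        if self.min_len_nt < 3:
            raise HegError("min_len_nt must be >= 3")

    @property
    def effective_starts(self) -> frozenset[str]:
        return self.start_codons | ({"TTA"} if self.allow_TTA else frozenset())


@dataclass
class MotifHit:
    aa_start: int        # 1-based position in the protein
    matched: str         # the 9-residue window
    mismatches: int


@dataclass
class HegOrf:
    """An ORF call inside an intron (positions 1-based on the intron)."""

    start_pos: int
    start_codon: str
    stop_pos: int               # start of the stop codon; past-the-end if open
    stop_codon: str | None      # None when the ORF runs off the 3' end
    frame: int
    protein: str
    in_exon_frame: bool | None = None
    motif_hits: list[MotifHit] = field(default_factory=list)

    @property
    def len_aa(self) -> int:
        return len(self.protein)

    @property
    def len_nt(self) -> int:
        """ORF length including the stop codon when present."""
        return self.stop_pos - self.start_pos + (3 if self.stop_codon else 0)

    def __repr__(self) -> str:  # 0-based equivalent logged for cross-checking
        return (f"HegOrf(start={self.start_pos} [0-based {self.start_pos - 1}], "
                f"codon={self.start_codon}, stop={self.stop_codon}, "
                f"frame={self.frame}, {self.len_aa} aa, "
                f"{len(self.motif_hits)} motif hits)")


def find_orfs(seq: str, params: OrfScanParams | None = None) -> list[HegOrf]:
    """Enumerate ORFs on the forward strand of a gap-free sequence.

    Within every stop-to-stop interval of each requested frame, each start
    codon opens an ORF running to the interval's stop (or off the 3' end, in
    which case ``stop_codon`` is None).  ORFs shorter than ``min_len_nt`` are
    dropped; interior starts are reported when ``params.interior``.
    """
    params = params or OrfScanParams()
    seq = seq.upper()
    if "-" in seq:
        raise HegError("gapped sequence passed to find_orfs")
    starts = params.effective_starts
    orfs: list[HegOrf] = []
    for frame in params.frames:
        codon_starts = range(frame, len(seq) - 2, 3)
        stop_positions = [i for i in codon_starts
                          if seq[i:i + 3] in STOP_CODONS_TABLE4]
        boundaries = [frame - 3] + stop_positions + [None]
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            interval_starts = []
            begin = lo + 3
            end = hi if hi is not None else len(seq) - 2
            for i in range(begin, end, 3):
                if seq[i:i + 3] in starts:
                    interval_starts.append(i)
                    if not params.interior:
                        break
            for i in interval_starts:
                if hi is not None:
                    stop_pos, stop_codon = hi, seq[hi:hi + 3]
                    length = hi + 3 - i
                else:
                    n_codons = (len(seq) - i) // 3
                    stop_pos, stop_codon = i + 3 * n_codons, None
                    length = 3 * n_codons
                if length < params.min_len_nt:
                    continue
                protein = translate(seq[i:stop_pos], params.genetic_code)
                orfs.append(HegOrf(start_pos=i + 1, start_codon=seq[i:i + 3],
                                   stop_pos=stop_pos + 1, stop_codon=stop_codon,
                                   frame=frame, protein=protein))
    orfs.sort(key=lambda o: (o.start_pos, o.frame))
    return orfs


def _motif_cost(pattern_res: str, obs: str) -> int:
    if pattern_res == obs:
        return 0
    for cls in _CLASSES:
        if pattern_res in cls and obs in cls:
            return 0
    return 1


def find_laglidadg(protein: str, max_mismatch: int = 2,
                   min_spacing_aa: int = 75) -> list[MotifHit]:
    """Scan a protein for LAGLIDADG motif windows.

    Every 9-mer within the class-aware Hamming distance ``max_mismatch`` of
    the literal LAGLIDADG pattern is reported (L/I/V/M/F and A/G substitutions
    are free).  ``min_spacing_aa`` is not applied here; it defines the
    double-motif predicate :func:`has_double_motif`.
    """
    protein = protein.upper()
    hits: list[MotifHit] = []
    k = len(LAGLIDADG)
    for i in range(len(protein) - k + 1):
        window = protein[i:i + k]
        if "*" in window:
            continue
        mm = 0
        for p, o in zip(LAGLIDADG, window):
            mm += _motif_cost(p, o)
            if mm > max_mismatch:
                break
        if mm <= max_mismatch:
            hits.append(MotifHit(aa_start=i + 1, matched=window, mismatches=mm))
    return hits


def has_double_motif(hits: list[MotifHit], min_spacing_aa: int = 75) -> bool:
    """True when two motif hits are separated by at least ``min_spacing_aa``."""
    starts = sorted(h.aa_start for h in hits)
    return bool(starts) and starts[-1] - starts[0] >= min_spacing_aa


def exon_continuous_frame(exon_phase: int) -> int:
    """Frame (0-based offset within the intron) continuing the exon's reading.

    ``exon_phase`` is ``insertion_pos % 3``; phase 0 means the intron begins
    at a codon boundary, so its first base opens an exon-continuous codon.
    """
    return (3 - exon_phase % 3) % 3


def upstream_in_frame_stop(intron_seq: str, orf_start_pos: int,
                           cont_frame: int) -> bool:
    """Any table-4 stop in the exon-continuous frame 5' of the ORF start."""
    seq = intron_seq.upper()
    for i in range(cont_frame, orf_start_pos - 1 - 2, 3):
        if seq[i:i + 3] in STOP_CODONS_TABLE4:
            return True
    return False


def annotate_heg(intron_seq: str, exon_phase: int,
                 params: OrfScanParams | None = None,
                 max_mismatch: int = 2,
                 min_spacing_aa: int = 75) -> HegOrf | None:
    """Pick the homing-endonuclease ORF of an intron, if any.

    Preference order: in the exon-continuous frame, the 5'-most motif-bearing
    ORF (which covers every motif of its stop-to-stop interval); otherwise the
    ORF in any frame with the most motif hits (fewest total mismatches, then
    longest, then 5'-most).  Returns None when no ORF of minimum length
    carries a motif.
    """
    params = params or OrfScanParams()
    cont = exon_continuous_frame(exon_phase)
    candidates = []
    for orf in find_orfs(intron_seq, params):
        hits = find_laglidadg(orf.protein, max_mismatch=max_mismatch,
                              min_spacing_aa=min_spacing_aa)
        if hits:
            orf.motif_hits = hits
            orf.in_exon_frame = (orf.frame == cont)
            candidates.append(orf)
    if not candidates:
        return None
    in_frame = [o for o in candidates if o.in_exon_frame]
    if in_frame:
        chosen = min(in_frame, key=lambda o: o.start_pos)
    else:
        chosen = min(candidates,
                     key=lambda o: (-len(o.motif_hits),
                                    sum(h.mismatches for h in o.motif_hits),
                                    -o.len_aa, o.start_pos))
    logger.debug("annotate_heg: chose %r", chosen)
    return chosen


@dataclass
class StageThresholds:
    """Knobs of the stage classifier (none are literature-fixed values)."""

    expected_heg_aa: int = 250
    full_len_frac: float = 0.8
    degenerate_mismatch: int = 3   # a recorded hit above this is "decayed"
    min_spacing_aa: int = 75


@dataclass
class StageEvidence:
    has_intron: bool
    has_orf: bool
    orf_in_exon_frame: bool
    n_motifs: int
    double_motif: bool
    orf_len_aa: int
    truncated: bool
    degenerate_motif: bool
    upstream_in_frame_stop: bool


@dataclass
class StageCall:
    stage: int
    evidence: StageEvidence


def classify_stage(intron_present: bool, heg: HegOrf | None,
                   thresholds: StageThresholds | None = None,
                   *, upstream_stop: bool | None = None) -> StageCall:
    """Place an intron on the five-stage degeneration ladder.

    A pure function of the evidence: stage 5 without an intron; stage 4
    without a motif-bearing ORF; stage 3 when the ORF is truncated (no stop
    inside the intron or shorter than ``full_len_frac * expected_heg_aa``) or
    the double motif is decayed; stage 2 when full-length and double-motifed
    but free-standing (wrong frame, or an upstream in-frame stop); stage 1
    otherwise.
    """
    th = thresholds or StageThresholds()
    if not intron_present:
        ev = StageEvidence(False, False, False, 0, False, 0, False, False, False)
        return StageCall(stage=5, evidence=ev)
    if heg is None:
        ev = StageEvidence(True, False, False, 0, False, 0, False, False, False)
        return StageCall(stage=4, evidence=ev)

    double = has_double_motif(heg.motif_hits, th.min_spacing_aa)
    truncated = (heg.stop_codon is None
                 or heg.len_aa < th.full_len_frac * th.expected_heg_aa)
    degenerate = any(h.mismatches > th.degenerate_mismatch
                     for h in heg.motif_hits)
    if upstream_stop is None:
        upstream_stop = False
    ev = StageEvidence(
        has_intron=True, has_orf=True,
        orf_in_exon_frame=bool(heg.in_exon_frame),
        n_motifs=len(heg.motif_hits), double_motif=double,
        orf_len_aa=heg.len_aa, truncated=truncated,
        degenerate_motif=degenerate, upstream_in_frame_stop=upstream_stop)
    if truncated or degenerate or not double:
        return StageCall(stage=3, evidence=ev)
    if not heg.in_exon_frame or upstream_stop:
        return StageCall(stage=2, evidence=ev)
    return StageCall(stage=1, evidence=ev)


def stage_intron(intron_seq: str | None, exon_phase: int = 0,
                 params: OrfScanParams | None = None,
                 thresholds: StageThresholds | None = None) -> StageCall:
    """End-to-end staging of one intron sequence (None = intron absent)."""
    if intron_seq is None:
        return classify_stage(False, None, thresholds)
    th = thresholds or StageThresholds()
    heg = annotate_heg(intron_seq, exon_phase, params,
                       min_spacing_aa=th.min_spacing_aa)
    upstream = None
    if heg is not None and heg.in_exon_frame:
        upstream = upstream_in_frame_stop(
            intron_seq, heg.start_pos, exon_continuous_frame(exon_phase))
    return classify_stage(True, heg, th, upstream_stop=upstream)
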