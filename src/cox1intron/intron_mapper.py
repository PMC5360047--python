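"""Decompose intron-bearing cox1 sequences against an intron-free reference.

A query is globally aligned (affine gaps) to a reference CDS; maximal
query-only insertion runs at least ``min_intron_len`` long are called as
introns, everything else stays in the exon.  Insertion sites are reported as
1-based reference coordinates of the last exon nucleotide 5' of the intron
("intron 723" sits between reference positions 723 and 724), the convention
used for naming sponge cox1 introns after the *Amphimedon queenslandica*
coordinate system.  Boundary ambiguity is resolved in favour of a terminal G
(the conserved omega-G of group I introns) when an equivalent alignment shift
achieves it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

from .io_formats import SequenceRecord, reverse_complement
from .heg_annotator import translate

logger = logging.getLogger(__name__)

DEFAULT_MIN_INTRON_LEN = 150
DEFAULT_CANONICAL_SITES = (387, 714, 723, 870, 966, 1141)
DEFAULT_TOLERANCE = 3


class MappingError(ValueError):
    """Raised when a query cannot be mapped onto the reference."""


@dataclass
class ReferenceCDS:
    """An intron-free protein-coding reference sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if "-" in self.seq:
            raise MappingError(f"reference {self.id!r} contains gaps")
        if len(self.seq) % 3 != 0:
            raise MappingError(
                f"reference {self.id!r} length {len(self.seq)} not divisible by 3")
        aa = translate(self.seq, genetic_code=4)
        if "*" in aa[:-1]:
            logger.warning(
                "reference %r has internal stop(s) under table 4", self.id)

    @property
    def length(self) -> int:
        return len(self.seq)

    @classmethod
    def from_record(cls, rec: SequenceRecord) -> "ReferenceCDS":
        return cls(id=rec.id, seq=rec.seq)


@dataclass
class IntronRecord:
    """One intron call: insertion site, sequence and bookkeeping flags."""

    insertion_pos: int          # last exon nt 5' of the intron, 1-based on ref
    seq: str
    canonical_label: int | None = None
    intron_class: str | None = None   # user-supplied metadata (I/II), not inferred

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def terminal_ok(self) -> bool:
        """True when the 3' base is the conserved omega-G."""
        return self.seq.endswith("G")


@dataclass
class AnnotatedCox1Record:
    """A query decomposed into exon segments and introns.

    ``exon_segments`` are half-open 0-based ``(query_start, query_end,
    ref_start, ref_end)`` spans between consecutive introns; small indels are
    retained inside a segment, so query and reference extents may differ.
    """

    id: str
    query_seq: str
    exon_segments: list[tuple[int, int, int, int]]
    introns: list[IntronRecord]
    reverse_complemented: bool = False

    @property
    def spliced_cds(self) -> str:
        return "".join(self.query_seq[qs:qe] for qs, qe, _, _ in self.exon_segments)


def exon_frame_at(insertion_pos: int) -> int:
    """Reading-frame phase of the exon at an insertion site.

    0 means the intron begins exactly at a codon boundary; the
    exon-continuous frame inside the intron starts at intron position
    ``(3 - phase) % 3 + 1``.
    """
    if insertion_pos < 1:
        raise ValueError(f"insertion_pos must be >= 1, got {insertion_pos}")
    return insertion_pos % 3


def assign_canonical_label(insertion_pos: int,
                           canonical_sites=DEFAULT_CANONICAL_SITES,
                           tolerance: int = DEFAULT_TOLERANCE) -> int | None:
    """Snap an insertion site to the nearest canonical site within tolerance.

    The tolerance must be smaller than half the minimal spacing between
    canonical sites (9 nt between 714 and 723 caps it at 4), which makes the
    assignment unambiguous.
    """
    sites = sorted(canonical_sites)
    if len(sites) >= 2:
        min_gap = min(b - a for a, b in zip(sites, sites[1:]))
        if tolerance >= min_gap / 2:
            raise ValueError(
                f"tolerance {tolerance} >= half the minimal canonical spacing "
                f"({min_gap}/2); labels would be ambiguous")
    for site in sites:
        if abs(site - insertion_pos) <= tolerance:
            return site
    return None


def splice(record: AnnotatedCox1Record) -> str:
    """Concatenate the exon segments (the intron-free CDS of the query)."""
    return record.spliced_cds


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -0.5
    return aligner


def _shift_for_terminal_g(query: str, qs: int, qe: int, ref: str, r: int,
                          window: int) -> tuple[int, int, int]:
    """Shift an insertion window within its score-equivalence region so the
    intron ends in G.  A shift by k is admissible when it leaves the alignment
    score unchanged: each base moved across the gap must have the same
    match/mismatch status against the reference as the base it replaces.
    Smallest |shift| wins, left preferred on ties."""
    if query[qe - 1] == "G":
        return qs, qe, r

    def left_ok(k: int) -> bool:
        return (r - k >= 0 and qs - k >= 0 and all(
            (query[qs - 1 - i] == ref[r - 1 - i])
            == (query[qe - 1 - i] == ref[r - 1 - i]) for i in range(k)))

    def right_ok(k: int) -> bool:
        return (r + k <= len(ref) and qe + k <= len(query) and all(
            (query[qs + i] == ref[r + i])
            == (query[qe + i] == ref[r + i]) for i in range(k)))

    for k in range(1, window + 1):
        if left_ok(k) and query[qe - k - 1] == "G":
            return qs - k, qe - k, r - k
        if right_ok(k) and query[qe + k - 1] == "G":
            return qs + k, qe + k, r + k
    logger.warning(
        "no boundary shift within %d nt yields a terminal G for the insertion "
        "after reference position %d", window, r)
    return qs, qe, r


def map_insertion_sites(query: SequenceRecord | str,
                        ref: ReferenceCDS,
                        min_intron_len: int = DEFAULT_MIN_INTRON_LEN,
                        *,
                        min_ref_coverage: float = 0.5,
                        canonical_sites=DEFAULT_CANONICAL_SITES,
                        tolerance: int = DEFAULT_TOLERANCE,
                        auto_orient: bool = True,
                        omega_g_window: int = 3) -> AnnotatedCox1Record:
    """Map a (possibly intron-bearing) cox1 query onto the reference CDS.

    Every maximal query-only insertion of at least ``min_intron_len`` becomes
    an :class:`IntronRecord`; shorter insertions are treated as indel noise
    inside exon segments.  Raises :class:`MappingError` when the query covers
    less than ``min_ref_coverage`` of the reference.
    """
    if isinstance(query, SequenceRecord):
        qid, qseq = query.id, query.seq
    else:
        qid, qseq = "query", str(query).upper()

    aligner = _make_aligner()
    rseq = ref.seq
    fwd_score = aligner.score(rseq, qseq)
    revcomp = False
    if auto_orient:
        rc = reverse_complement(qseq)
        rev_score = aligner.score(rseq, rc)
        if rev_score > fwd_score:
            qseq = rc
            revcomp = True
            logger.info("query %s mapped on the reverse strand "
                        "(score %.1f > %.1f)", qid, rev_score, fwd_score)

    alignment = aligner.align(rseq, qseq)[0]
    ref_blocks, query_blocks = alignment.aligned

    aligned_ref_cols = int(sum(e - s for s, e in ref_blocks))
    if aligned_ref_cols < min_ref_coverage * len(rseq):
        raise MappingError(
            f"query {qid!r} not homologous to reference: aligns to "
            f"{aligned_ref_cols}/{len(rseq)} reference positions")

    # query-only insertion runs between consecutive aligned blocks
    raw_insertions: list[tuple[int, int, int]] = []  # (qs, qe, ref_pos)
    for i in range(len(ref_blocks) - 1):
        r_end = int(ref_blocks[i][1])
        r_next = int(ref_blocks[i + 1][0])
        q_end = int(query_blocks[i][1])
        q_next = int(query_blocks[i + 1][0])
        if q_next > q_end and r_next == r_end:
            raw_insertions.append((q_end, q_next, r_end))
        # mixed gap (both advance) or deletion: stays exon-internal

    introns: list[IntronRecord] = []
    breakpoints: list[tuple[int, int, int]] = []  # (qs, qe, ref_pos) of introns
    for qs, qe, r in raw_insertions:
        if qe - qs < min_intron_len:
            continue
        qs, qe, r = _shift_for_terminal_g(qseq, qs, qe, rseq, r, omega_g_window)
        label = assign_canonical_label(r, canonical_sites, tolerance) \
            if canonical_sites else None
        introns.append(IntronRecord(insertion_pos=r, seq=qseq[qs:qe],
                                    canonical_label=label))
        breakpoints.append((qs, qe, r))

    # exon segments between consecutive introns (query and ref coordinates)
    q_start = int(query_blocks[0][0])
    r_start = int(ref_blocks[0][0])
    q_stop = int(query_blocks[-1][1])
    r_stop = int(ref_blocks[-1][1])
    segments: list[tuple[int, int, int, int]] = []
    prev_q, prev_r = q_start, r_start
    for qs, qe, r in breakpoints:
        segments.append((prev_q, qs, prev_r, r))
        prev_q, prev_r = qe, r
    segments.append((prev_q, q_stop, prev_r, r_stop))

    return AnnotatedCox1Record(id=qid, query_seq=qseq, exon_segments=segments,
                               introns=introns, reverse_complemented=revcomp)
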