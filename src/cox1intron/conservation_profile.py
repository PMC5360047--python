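"""Windowed conservation profile of a protein alignment (host-gene view).

The per-column substitution count is the minimum number of changes explaining
the column — the number of distinct residues minus one — with gaps and 'X'
excluded.  The profile sums these counts over a sliding window (default 11
columns, truncated at the alignment edges), so lower values mean more
conserved regions.  Intron insertion sites and primer 5' anchors, given as
nucleotide positions on an ungapped reference CDS, are projected onto
alignment columns through the gapped reference row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentMatrix

_EXCLUDED = {"-", "X", "?", "."}
_NT_STATES = set("ACGTU")
_AA_STATES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProfileAnnotation:
    label: str
    column: int                     # 1-based alignment column
    kind: Literal["intron", "primer"]


@dataclass
class ConservationProfile:
    window: int
    scores: np.ndarray              # windowed sums, one per column
    mean_scores: np.ndarray         # per-column mean over the actual window
    annotations: list[ProfileAnnotation] = field(default_factory=list)

    @property
    def ncol(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: column, score, normalized score, annotations."""
        ann: dict[int, list[str]] = {}
        for a in self.annotations:
            ann.setdefault(a.column, []).append(f"{a.kind}:{a.label}")
        return pd.DataFrame({
            "column": np.arange(1, self.ncol + 1),
            "score": self.scores,
            "mean_score": self.mean_scores,
            "annotation": [";".join(ann.get(c, []))
                           for c in range(1, self.ncol + 1)],
        })


@dataclass
class ColumnClassCounts:
    constant: int
    parsimony_uninformative: int
    parsimony_informative: int

    @property
    def total(self) -> int:
        return (self.constant + self.parsimony_uninformative
                + self.parsimony_informative)

    def __add__(self, other: "ColumnClassCounts") -> "ColumnClassCounts":
        return ColumnClassCounts(
            self.constant + other.constant,
            self.parsimony_uninformative + other.parsimony_uninformative,
            self.parsimony_informative + other.parsimony_informative)


def column_substitutions(column: Iterable[str]) -> int:
    """Minimum substitutions explaining one column: distinct residues - 1.

    Gaps and 'X' are excluded before counting, so a column of only gaps or
    ambiguities scores 0.
    """
    states = {r.upper() for r in column} - _EXCLUDED
    return max(0, len(states) - 1)


def sliding_profile(alignment: AlignmentMatrix, window: int = 11) -> ConservationProfile:
    """Windowed substitution profile over all columns.

    Edge columns use the truncated window; ``mean_scores`` divides each sum by
    the number of columns actually inside the window, which keeps edge values
    comparable for plotting.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > alignment.ncol:
        raise ValueError(
            f"window {window} exceeds alignment width {alignment.ncol}")
    per_col = np.array([column_substitutions(alignment.column(i))
                        for i in range(alignment.ncol)], dtype=float)
    kernel = np.ones(window)
    scores = np.convolve(per_col, kernel, mode="same")
    coverage = np.convolve(np.ones_like(per_col), kernel, mode="same")
    return ConservationProfile(window=window,
                               scores=scores.astype(int),
                               mean_scores=scores / coverage)


def classify_columns(alignment: AlignmentMatrix) -> ColumnClassCounts:
    """Count constant / parsimony-uninformative / parsimony-informative columns.

    Only unambiguous residue states are counted (gaps and ambiguity codes are
    ignored as states).  A column is constant with at most one counted state,
    parsimony-informative when at least two states each occur at least twice,
    and otherwise variable but uninformative.
    """
    states_ok = _NT_STATES if alignment.moltype == "nt" else _AA_STATES
    constant = uninf = inf = 0
    for i in range(alignment.ncol):
        counts: dict[str, int] = {}
        for r in alignment.column(i):
            r = r.upper()
            if r in states_ok:
                counts[r] = counts.get(r, 0) + 1
        if len(counts) <= 1:
            constant += 1
        elif sum(1 for n in counts.values() if n >= 2) >= 2:
            inf += 1
        else:
            uninf += 1
    return ColumnClassCounts(constant, uninf, inf)


def project_to_profile(nt_pos: int, alignment: AlignmentMatrix,
                       reference_row_id: str) -> int:
    """Map a nucleotide position on the ungapped reference CDS to a column.

    ``nt_pos`` (1-based) becomes amino-acid position ``ceil(nt_pos / 3)``,
    then the gapped reference row is walked to find the 1-based alignment
    column holding that residue.
    """
    row = alignment.row(reference_row_id)   # KeyError if absent
    if nt_pos < 1:
        raise ValueError(f"nt_pos must be >= 1, got {nt_pos}")
    aa_pos = math.ceil(nt_pos / 3)
    ungapped_len = sum(1 for c in row.seq if c != "-")
    if aa_pos > ungapped_len:
        raise ValueError(
            f"nt position {nt_pos} (aa {aa_pos}) beyond ungapped reference "
            f"row length {ungapped_len}")
    seen = 0
    for col, c in enumerate(row.seq, start=1):
        if c != "-":
            seen += 1
            if seen == aa_pos:
                return col
    raise AssertionError("unreachable")


def annotate_profile(profile: ConservationProfile,
                     alignment: AlignmentMatrix,
                     reference_row_id: str,
                     introns: Sequence[tuple[str, int]] = (),
                     primers: Sequence[tuple[str, int]] = ()) -> ConservationProfile:
    """Project (label, nt position) intron sites and primer anchors onto the profile."""
    for label, pos in introns:
        col = project_to_profile(pos, alignment, reference_row_id)
        profile.annotations.append(ProfileAnnotation(label, col, "intron"))
    for label, pos in primers:
        col = project_to_profile(pos, alignment, reference_row_id)
        profile.annotations.append(ProfileAnnotation(label, col, "primer"))
    return profile
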