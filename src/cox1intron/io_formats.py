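"""Readers and writers for the external formats the pipeline touches.

Sequences travel as :class:`SequenceRecord` (FASTA), alignments as
:class:`AlignmentMatrix` (aligned FASTA), trees as dendropy ``Tree`` objects
(newick), primers as :class:`PrimerSpec` rows (TSV) and run configuration as
flat JSON.  All parsers validate and reject malformed input rather than
repairing it silently; sequences are upper-cased on ingest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import dendropy
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

Moltype = Literal["nt", "aa"]

# IUPAC alphabets; '-' is only legal in aligned context, '*' never in nt.
_NT_LETTERS = set("ACGTURYSWKMBDHVN")
_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

FASTA_WRAP = 70


class FormatError(ValueError):
    """Raised for any malformed external input."""


@dataclass
class SequenceRecord:
    """A single named sequence (nucleotide or protein)."""

    id: str
    description: str
    seq: str
    moltype: Moltype = "nt"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.seq = self.seq.upper()
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")

    def validate(self, aligned: bool = False) -> None:
        letters = _NT_LETTERS if self.moltype == "nt" else _AA_LETTERS
        allowed = letters | ({"-"} if aligned else set())
        bad = set(self.seq) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal {self.moltype} characters "
                f"{sorted(bad)}" + ("" if aligned else " (gaps only legal in alignments)")
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentMatrix:
    """An aligned set of equal-length rows."""

    records: list[SequenceRecord]
    moltype: Moltype = "nt"

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("empty alignment")
        ncol = len(self.records[0].seq)
        if ncol == 0:
            raise FormatError("alignment with zero columns")
        for rec in self.records:
            if len(rec.seq) != ncol:
                raise FormatError(
                    f"ragged alignment: row {rec.id!r} has length "
                    f"{len(rec.seq)}, expected {ncol}"
                )

    @property
    def ncol(self) -> int:
        return len(self.records[0].seq)

    @property
    def nrow(self) -> int:
        return len(self.records)

    def column(self, i: int) -> list[str]:
        """Residues of 0-based column *i*."""
        return [rec.seq[i] for rec in self.records]

    def row(self, row_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == row_id:
                return rec
        raise KeyError(f"row {row_id!r} not in alignment")


_ORIENTATIONS = {
    "forward": "forward",
    "f": "forward",
    "fwd": "forward",
    "reverse": "reverse",
    "r": "reverse",
    "rev": "reverse",
}


@dataclass
class PrimerSpec:
    """A PCR primer with its 5' anchor position on the reference CDS."""

    name: str
    seq: str
    orientation: Literal["forward", "reverse"]
    five_prime_ref_pos: int  # 1-based on the reference CDS

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        key = self.orientation.strip().lower()
        if key not in _ORIENTATIONS:
            raise FormatError(
                f"primer {self.name!r}: unknown orientation token {self.orientation!r}"
            )
        self.orientation = _ORIENTATIONS[key]
        if self.five_prime_ref_pos < 1:
            raise FormatError(
                f"primer {self.name!r}: 5' position must be >= 1, "
                f"got {self.five_prime_ref_pos}"
            )


@dataclass
class RunConfig:
    """Resolved run configuration (flat JSON on disk)."""

    reference_id: str = "reference"
    canonical_sites: tuple[int, ...] = (387, 714, 723, 870, 966, 1141)
    min_intron_len: int = 150
    orf_min_len_nt: int = 100
    start_codons: tuple[str, ...] = ("ATG", "GTG", "TTG", "ATT")
    window: int = 11
    canonical_tolerance: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise FormatError(f"window must be odd and >= 1, got {self.window}")
        if self.orf_min_len_nt < 3:
            raise FormatError("orf_min_len_nt must be >= 3")
        sites = tuple(self.canonical_sites)
        if any(b <= a for a, b in zip(sites, sites[1:])):
            raise FormatError("canonical_sites must be strictly increasing")
        self.canonical_sites = sites
        self.start_codons = tuple(c.upper() for c in self.start_codons)
        for c in self.start_codons:
            if len(c) != 3 or set(c) - set("ACGT"):
                raise FormatError(f"bad start codon {c!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        logger.info("resolved config from %s: %s", path, asdict(cfg))
        return cfg

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, moltype: Moltype = "nt",
               aligned: bool = False) -> list[SequenceRecord]:
    """Parse a FASTA file into validated records (order preserved).

    Duplicate ids and empty files are errors; sequences are upper-cased.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out = SequenceRecord(id=rec.id, description=rec.description,
                             seq=str(rec.seq), moltype=moltype)
        out.validate(aligned=aligned)
        records.append(out)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                wrap: int = FASTA_WRAP) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) \
                else (f"{rec.id} {rec.description}".strip())
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i:i + wrap] + "\n")


def read_alignment(path: str | Path, moltype: Moltype = "nt") -> AlignmentMatrix:
    """Read an aligned FASTA; ragged rows or an empty file raise."""
    records = read_fasta(path, moltype=moltype, aligned=True)
    return AlignmentMatrix(records=records, moltype=moltype)


def write_alignment(aln: AlignmentMatrix, path: str | Path) -> None:
    write_fasta(aln.records, path)


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a newick tree; duplicate leaf labels are an error."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()
              if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"{path}: duplicate leaf labels {dups}")
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Like :func:`read_newick` but from a string."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()
              if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels {dups}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()
            if leaf.taxon is not None}


# ---------------------------------------------------------------------------
# Primer tables


def read_primer_table(path: str | Path,
                      reference_length: int | None = None) -> list[PrimerSpec]:
    """Read a tab-separated primer table: name, seq, orientation, position.

    A header line whose first field is ``name`` is tolerated.  An empty file
    yields an empty list (a primer table is optional input).
    """
    primers: list[PrimerSpec] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "name":
                continue
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}")
            name, seq, orientation, pos_s = (f.strip() for f in fields)
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: position {pos_s!r} is not an integer"
                ) from exc
            spec = PrimerSpec(name=name, seq=seq, orientation=orientation,
                              five_prime_ref_pos=pos)
            if reference_length is not None and pos > reference_length:
                raise FormatError(
                    f"{path}:{lineno}: primer {name!r} position {pos} beyond "
                    f"reference length {reference_length}")
            primers.append(spec)
    return primers


def write_primer_table(primers: Sequence[PrimerSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tseq\torientation\tposition\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.seq}\t{p.orientation}\t{p.five_prime_ref_pos}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
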