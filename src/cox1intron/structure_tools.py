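"""Pseudoknotted secondary-structure bookkeeping for group I introns.

Structures travel as dot-bracket strings with exactly two layers: '()' for
the nested helix core and '[]' for pseudoknot pairs that may cross it (the
notation used when curating group I intron core structures by hand).  A
:class:`PairTable` can be converted to the 6-column ct connectivity table and
back.  Helix inventories follow the standard P-nomenclature (P1..P10 with
letter suffixes, e.g. P6d, P9.1c); comparing inventories between introns and
checking the conserved core (P/Q/R/S boxes, substrate P1-P2-P10, scaffold
P4-P5-P6 and catalytic P3-P7-P8 domains) mechanizes the usual
structure-difference arguments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

Layer = Literal["nested", "pseudoknot"]

#: helices required for the three-domain group I core (P9 is peripheral)
CORE_HELICES = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P10")
#: conserved sequence boxes building the catalytic core
CORE_BOXES = ("P", "Q", "R", "S")

_HELIX_RE = re.compile(r"^P(\d+)(?:\.(\d+))?([a-z]*)$")


class StructureError(ValueError):
    pass


@dataclass
class PairTable:
    """Base pairs of one sequence, each tagged nested or pseudoknot."""

    seq: str
    pairs: list[tuple[int, int]]            # 1-based, i < j
    layers: list[Layer]

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.layers):
            raise StructureError("pairs and layers differ in length")
        n = len(self.seq)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise StructureError(f"pair ({i},{j}) out of range 1..{n}")
            if i in seen or j in seen:
                raise StructureError(f"index used in more than one pair: ({i},{j})")
            seen.update((i, j))
        nested = sorted(p for p, l in zip(self.pairs, self.layers)
                        if l == "nested")
        for (i1, j1) in nested:
            for (i2, j2) in nested:
                if i1 < i2 < j1 < j2:
                    raise StructureError(
                        f"crossing pairs ({i1},{j1}) and ({i2},{j2}) in the "
                        "nested layer")

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def sorted(self) -> "PairTable":
        order = sorted(range(len(self.pairs)), key=lambda k: self.pairs[k])
        return PairTable(self.seq, [self.pairs[k] for k in order],
                         [self.layers[k] for k in order])


def parse_dotbracket(seq: str, structure: str) -> PairTable:
    """Parse a two-layer dot-bracket string against its sequence.

    '()' pairs go to the nested layer, '[]' to the pseudoknot layer; each
    layer must balance on its own.  Unbalanced brackets raise with the
    offending 1-based position.
    """
    if len(seq) != len(structure):
        raise StructureError(
            f"sequence length {len(seq)} != structure length {len(structure)}")
    bad = set(structure) - set(".()[]")
    if bad:
        raise StructureError(f"illegal structure characters {sorted(bad)}")
    stacks: dict[str, list[int]] = {"(": [], "[": []}
    closer = {")": "(", "]": "["}
    layer_of = {"(": "nested", "[": "pseudoknot"}
    pairs: list[tuple[int, int]] = []
    layers: list[Layer] = []
    for pos, ch in enumerate(structure, start=1):
        if ch in "([":
            stacks[ch].append(pos)
        elif ch in ")]":
            opener = closer[ch]
            if not stacks[opener]:
                raise StructureError(
                    f"unbalanced {ch!r} at position {pos}")
            i = stacks[opener].pop()
            pairs.append((i, pos))
            layers.append(layer_of[opener])
    for opener, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unclosed {opener!r} at position {stack[-1]}")
    return PairTable(seq=seq, pairs=pairs, layers=layers).sorted()


def to_dotbracket(pt: PairTable) -> str:
    """Render a PairTable back to two-layer dot-bracket notation."""
    chars = ["."] * len(pt.seq)
    sym = {"nested": "()", "pseudoknot": "[]"}
    for (i, j), layer in zip(pt.pairs, pt.layers):
        o, c = sym[layer]
        chars[i - 1], chars[j - 1] = o, c
    # pseudoknot layer must itself be non-crossing to be representable
    pk = sorted(p for p, l in zip(pt.pairs, pt.layers) if l == "pseudoknot")
    for (i1, j1) in pk:
        for (i2, j2) in pk:
            if i1 < i2 < j1 < j2:
                raise StructureError(
                    "pseudoknot layer crosses itself; not representable in "
                    "two-layer dot-bracket")
    return "".join(chars)


def to_ct(pt: PairTable, title: str = "") -> str:
    """Emit the 6-column ct connectivity table (header: length + title)."""
    partner = pt.partner()
    n = len(pt.seq)
    lines = [f"{n} {title}".rstrip()]
    for i in range(1, n + 1):
        lines.append(f"{i} {pt.seq[i - 1]} {i - 1} {(i + 1) if i < n else 0} "
                     f"{partner.get(i, 0)} {i}")
    return "\n".join(lines) + "\n"


def parse_ct(text: str, pseudoknot_pairs: Iterable[tuple[int, int]] = ()) -> PairTable:
    """Parse ct text back to a PairTable.

    The ct format does not distinguish layers; pairs listed in
    ``pseudoknot_pairs`` are tagged pseudoknot, all others nested.  Without
    that hint, any pair crossing the maximal non-crossing subset chosen
    greedily by 5' opening position is assigned to the pseudoknot layer.
    """
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise StructureError("empty ct text")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise StructureError(f"bad ct header {lines[0]!r}") from exc
    if len(lines) - 1 != n:
        raise StructureError(
            f"ct header declares {n} bases but {len(lines) - 1} rows follow")
    seq_chars: list[str] = []
    partner: dict[int, int] = {}
    for row in lines[1:]:
        fields = row.split()
        if len(fields) < 6:
            raise StructureError(f"short ct row {row!r}")
        idx, base, _, _, pair, _ = fields[:6]
        i, j = int(idx), int(pair)
        seq_chars.append(base)
        if j:
            partner[i] = j
    pairs = sorted((i, j) for i, j in partner.items() if i < j)
    for i, j in pairs:
        if partner.get(j) != i:
            raise StructureError(f"asymmetric ct pairing ({i},{j})")
    pk = {tuple(sorted(p)) for p in pseudoknot_pairs}
    layers: list[Layer] = []
    if pk:
        layers = ["pseudoknot" if (i, j) in pk else "nested" for i, j in pairs]
    else:
        accepted: list[tuple[int, int]] = []
        for i, j in pairs:
            crosses = any(a < i < b < j or i < a < j < b for a, b in accepted)
            layers.append("pseudoknot" if crosses else "nested")
            if not crosses:
                accepted.append((i, j))
    return PairTable(seq="".join(seq_chars), pairs=pairs, layers=layers)


# ---------------------------------------------------------------------------
# Helix inventories


def helix_base(name: str) -> str:
    """Base helix of a suffixed label: P6d -> P6, P9.1c -> P9."""
    m = _HELIX_RE.match(name)
    if not m:
        raise StructureError(f"label {name!r} not in P-nomenclature")
    return f"P{m.group(1)}"


@dataclass
class HelixInventory:
    """Named helices (P-nomenclature) and conserved core boxes of one intron."""

    name: str
    labels: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    core_boxes: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in self.labels:
            helix_base(label)       # raises for labels outside P1..P10 scheme
        for box in self.core_boxes:
            if box not in CORE_BOXES:
                raise StructureError(f"unknown core box {box!r}")

    @property
    def present(self) -> set[str]:
        return set(self.labels)

    @classmethod
    def from_names(cls, name: str, helices: Iterable[str],
                   core_boxes: Iterable[str] = ()) -> "HelixInventory":
        return cls(name=name, labels={h: [] for h in helices},
                   core_boxes={b: None for b in core_boxes})


@dataclass
class InventoryDiff:
    only_in_a: list[str]
    only_in_b: list[str]
    shared: list[str]


def compare_inventories(a: HelixInventory, b: HelixInventory) -> InventoryDiff:
    """Set differences of helix presence, deterministically ordered."""
    return InventoryDiff(
        only_in_a=sorted(a.present - b.present),
        only_in_b=sorted(b.present - a.present),
        shared=sorted(a.present & b.present))


def check_core_elements(inventory: HelixInventory) -> tuple[bool, list[str]]:
    """Check the conserved group I core: P/Q/R/S boxes plus P1-P8 and P10.

    A required helix counts as present when any label shares its base (P6d
    satisfies P6).  Returns (complete, missing-element list).
    """
    bases = {helix_base(h) for h in inventory.present}
    missing = [h for h in CORE_HELICES if h not in bases]
    missing += [b for b in CORE_BOXES if b not in inventory.core_boxes]
    return (not missing, missing)


def read_helix_table(path: str | Path, name: str | None = None) -> HelixInventory:
    """Read a helix-interval TSV: label, start, end[, layer]; 'box:' rows give
    core boxes (e.g. ``box:Q``)."""
    labels: dict[str, list[tuple[int, int]]] = {}
    boxes: dict[str, tuple[int, int] | None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() in {"name", "label"}:
                continue
            label = fields[0].strip()
            start, end = int(fields[1]), int(fields[2])
            if label.startswith("box:"):
                boxes[label[4:]] = (start, end)
            else:
                labels.setdefault(label, []).append((start, end))
    return HelixInventory(name=name or str(path), labels=labels,
                          core_boxes=boxes)
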