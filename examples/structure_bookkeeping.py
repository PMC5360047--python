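"""Pseudoknotted dot-bracket parsing, ct conversion and helix inventories.

Parses a toy two-layer structure (round brackets: nested core; square
brackets: pseudoknot), converts it to the 6-column ct table, and compares two
intron 723 helix inventories: the Scleritodermidae-style inventory lacks the
P6d helix carried by the Cinachyrella-style one.
"""

import cox1intron as cx

seq = "GGAAGGAACCAACC"
db = "((..[[..))..]]"
pt = cx.parse_dotbracket(seq, db)
print(f"dot-bracket {db!r} -> {len(pt.pairs)} pairs "
      f"({pt.layers.count('nested')} nested, "
      f"{pt.layers.count('pseudoknot')} pseudoknot)")
print(cx.to_ct(pt, "toy"))

cina = cx.HelixInventory.from_names(
    "Cinachyrella_723",
    ["P1", "P2", "P3", "P4", "P5", "P6", "P6a", "P6b", "P6d", "P7", "P8",
     "P9", "P9.1a", "P10"], core_boxes=cx.CORE_BOXES)
scler = cx.HelixInventory.from_names(
    "Scleritodermid_723",
    ["P1", "P2", "P3", "P4", "P5", "P6", "P6a", "P6b", "P7", "P8",
     "P9", "P9.1a", "P10"], core_boxes=cx.CORE_BOXES)

diff = cx.compare_inventories(cina, scler)
print(f"only in {cina.name}: {diff.only_in_a}")
print(f"only in {scler.name}: {diff.only_in_b}")
for inv in (cina, scler):
    ok, missing = cx.check_core_elements(inv)
    print(f"{inv.name}: conserved core complete = {ok}"
          + (f", missing {missing}" if missing else ""))
print("\nBoth keep the full P/Q/R/S core; the P6d peripheral helix is the")
print("diagnostic difference between the two intron 723 structure families.")
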