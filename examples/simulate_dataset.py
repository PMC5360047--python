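"""Generate the bundled demonstration dataset and inspect its planted truth.

The demo history: a 12-taxon species tree, a cox1 intron gained at canonical
site 723 in an eight-taxon clade, secondarily lost in two taxa, degenerated to
stage 3 in one, horizontally copied into an outside taxon, plus an independent
gain at site 870.
"""

from pathlib import Path

import cox1intron as cx

outdir = Path("scratch/demo_bundle")
bundle = cx.generate_dataset(cx.demo_spec(seed=1), outdir)

print(f"wrote {sorted(p.name for p in outdir.iterdir())}\n")
print(bundle.truth[["taxon", "site", "present", "stage", "transmission",
                    "donor"]].to_string(index=False))
print("\nEach row is one taxon x canonical site: presence, the planted")
print("degeneration stage (5 = no intron), and whether the intron arrived")
print("vertically (vgt) or by horizontal transfer (hgt, with its donor).")
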