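#!/usr/bin/env python
"""Materialize the two synthetic datasets the downstream analyses use.

``rosaceae_mini``: 200 gene families evolved under background
duplication-loss on the 16-species tree, with a whole-genome duplication
planted at the Maleae crown (retention probability 0.6) and a 3-state
fruit-type character.  ``filter_bench``: 200 noise-free families of
which the first 30 carry one NNI each, for exercising the hidden-paralog
screen.  Everything is written as plain text under results/simulated/.
"""

from pathlib import Path

from phylodup.simulate import build_fixture, write_bundle

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"

for name in ("rosaceae_mini", "filter_bench"):
    bundle = build_fixture(name)
    write_bundle(bundle, OUT / name)
    n_extinct = sum(f.tree is None for f in bundle.families)
    print(
        f"{name}: {len(bundle.families)} families ({n_extinct} extinct), "
        f"species tree with {len(bundle.species_tree.leaf_labels())} leaves"
        + (f", planted WGD at species node {bundle.wgd_node}" if bundle.wgd_node is not None else "")
    )
print(f"written under {OUT}")
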