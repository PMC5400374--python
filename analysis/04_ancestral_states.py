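#!/usr/bin/env python
"""Parsimony reconstruction of the fruit-type character.

Collapses each genus to a single unit on the species tree (after
checking genus monophyly), then traces the simulated 3-state fruit-type
character with Fitch parsimony and reports the most-parsimonious root
states.
"""

from pathlib import Path

import pandas as pd

from phylodup.asr import CharacterMatrix, collapse_to_units, reconstruct_all
from phylodup.taxonomy import TaxonomyTable
from phylodup.trees import parse_newick

BASE = Path(__file__).resolve().parents[1] / "results"
SIM = BASE / "simulated" / "rosaceae_mini"
OUT = BASE / "ancestral_states"
OUT.mkdir(parents=True, exist_ok=True)

species_tree = parse_newick((SIM / "species_tree.nwk").read_text())
taxonomy = TaxonomyTable.from_tsv(SIM / "taxonomy.tsv")

unit_tree, report = collapse_to_units(species_tree, taxonomy)
report.to_csv(OUT / "units.tsv", sep="\t", index=False)
print(f"{len(species_tree.leaf_labels())} species collapsed to "
      f"{len(unit_tree.leaf_labels())} genus units")

matrix = pd.read_csv(SIM / "characters.tsv", sep="\t", index_col=0, dtype=str)
rep_to_unit = dict(zip(report.representative, report.unit))
matrix.index = [rep_to_unit.get(i, i) for i in matrix.index]
matrix = matrix.loc[sorted(set(matrix.index) & set(unit_tree.leaf_labels()))]

table, results = reconstruct_all(unit_tree, CharacterMatrix(matrix))
table.to_csv(OUT / "asr.tsv", sep="\t", index=False)
for char, res in results.items():
    root = "/".join(sorted(res.root_states(unit_tree)))
    print(f"{char}: parsimony score {res.score}, root MPR states {{{root}}}")
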