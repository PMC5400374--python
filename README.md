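# phylodup

Ortholog curation against hidden paralogs, whole-genome-duplication
(WGD) detection by gene-tree/species-tree mapping, and parsimony
ancestral-state reconstruction — the three bespoke computational steps
of a transcriptome-scale plant phylogenomics study, reimplemented as a
tested Python pipeline and exercised end-to-end on simulated gene
families.

## The problem

Plant nuclear phylogenies are built from hundreds of putatively
single-copy genes, but polyploid ancestry creates **hidden
paralogs**: duplicated genes that return to single copy through
differential loss in different lineages. They look like orthologs yet
carry the topology of the duplication, not the speciation history.
Conversely, the duplications themselves are signal: a burst of gene
families all duplicating at the same species-tree node is the classic
phylogenomic signature of a **whole-genome duplication**.

`phylodup` implements both sides of that coin, plus the character-level
follow-up (tracing fruit-type evolution on the resulting tree):

1. **Marker filtering** (`phylodup.filters`). Families pass length
   (≥ 1000 bp in reference genomes), taxon-coverage (e.g. ≥ 6 of a
   10-species panel, or ≥ 85% of all taxa), and copy-number caps
   (≤ 2 copies in recently polyploid species), then a *hierarchical
   topology screen*: at successively finer ranks (order → subfamily →
   tribe), a family is removed when its gene tree contradicts group
   monophyly — either by any supported conflicting clade
   (`conflict_reject`, support threshold strict `>`) or by failing to
   group the rank's members at all (`clade_require`). Near-single-copy
   families can be reduced to one copy per species, keeping the
   species-richer paralog clade at the basal duplication split.

2. **WGD mapping** (`phylodup.wgd`). A gene-tree node is a duplication
   candidate when its bootstrap support exceeds 50 and its two child
   subtrees share at least two species. Writing L₁, L₂ for the
   species-tree LCAs of the two subclade species sets and depth(·) for
   edge steps from the root, the event is accepted when
   |depth(L₁) − depth(L₂)| ≤ 1 and mapped to the shallower LCA. Mapped
   events are classified by paralog retention across the node's two
   descendant lineages (big/small by species count): **type I** keeps
   both copies in both lineages (strongest WGD evidence), **type II**
   lacks duplicates for the small lineage, **type III** for the large
   one. Per node, the pipeline reports the percentage of duplicated
   families among *informative* families — those containing genes from
   both child lineages.

3. **Ancestral states** (`phylodup.asr`). Monophyletic genera collapse
   to units on the species tree; discrete characters are traced with
   Fitch parsimony (Sankoff dynamic programming for weighted costs),
   reporting full MPR state sets per internal node.

4. **Simulation** (`phylodup.simulate`). Gene families evolve down a
   known species tree under a duplication–loss branching process (rates
   λ, μ per lineage per unit branch length) with WGDs planted at chosen
   nodes (per-lineage retention probability *r*), bootstrap-like
   supports from a two-point mixture, and optional single-NNI
   perturbations that mimic hidden-paralog noise. Truth records make
   recovery measurable.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_filter_markers.py
python analysis/03_map_duplications.py
python analysis/04_ancestral_states.py
```

The drivers print (abridged):

```
rosaceae_mini: 200 families (0 extinct), species tree with 16 leaves, planted WGD at species node 25
200 families in; per-stage removals: {'order': 1, 'subfamily': 3, 'tribe': 10}; 186 retained
subfamily-topology tally (bootstrap > 50): {'Dryadoideae_basal': 197, 'Rosoideae_basal': 0, 'Amygdaloideae_basal': 0, 'unresolved': 3}
202 accepted duplication events; skipped families: {'no_tree': 0, 'no_outgroup': 0, 'unrootable': 0}
 node  depth  n_species  n_informative  n_dup_families   pct  n_pairs  type_I  type_II  type_III  type_NA
   25      5          3            191             108 56.54      121     119        2         0        0
16 species collapsed to 13 genus units
fruit_type: parsimony score 3, root MPR states {achenetum/drupetum}
```

Reading this: the staged screen removed 14 of the 30 deliberately
perturbed families (the others are rearrangements consistent with the
taxonomy, hence invisible to any monophyly-based screen) and none of the
170 clean ones; 197 of 200 gene trees support the generating
subfamily topology at bootstrap > 50; the planted WGD node (25, the
Maleae crown) is the clear percentage peak — 56.5% of the 191
informative families duplicated there, 119 of 121 paralog pairs type I —
against a background of ≤ 8% elsewhere, matching the retention
probability 0.6 minus losses plus a small background-duplication
contribution; and the fruit-type character reconstructs with three
changes and an ambiguous root, as expected at the simulated rate.

A CLI mirrors the drivers for ad-hoc use:
`phylodup simulate|filter|tally|mapdups|asr --help`.

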