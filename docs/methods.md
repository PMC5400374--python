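# Methods

This note records the models, rules and numerical choices behind
`phylodup`, and what the synthetic experiments do and do not establish.

## Tree model and support semantics

Trees are rooted, with optional branch lengths, leaf labels unique per
tree, and support values on internal nodes interpreted as bootstrap
percentages on the node's parent-edge bipartition. Supports are stored
on a 0–100 scale; an input tree whose maximum support is ≤ 1 is assumed
to be on the 0–1 scale and rescaled. Every support comparison in the
package is strict (`support > threshold`): a node at exactly 50 does not
pass a 50 threshold. Node identifiers are assigned by deterministic
post-order numbering, so identical inputs give byte-identical outputs.

Gene trees may contain polytomies; they are treated as unresolved and
never counted as duplication nodes. The species tree must be fully
bifurcating — depth "steps" (edge counts from the root) are only well
defined on a resolved organismal tree — and a polytomous species tree is
rejected with a validation error.

Gene-tree leaves are `species|gene` tokens. When gene trees arrive
unrooted (or rooted arbitrarily), they can be re-rooted on a declared
outgroup species set; a family whose outgroup is absent or not separable
on the unrooted topology is skipped and logged rather than
midpoint-rooted, because a wrong root manufactures spurious deep
duplications. Rerooting preserves the unrooted bipartition set and keeps
each support attached to its bipartition.

## Duplication–loss simulation

One ancestral lineage enters the species-tree root. Along each branch of
length *t*, each lineage duplicates as a Poisson process at rate λ and
dies with exponential hazard μ (survival probability e^(−μt) per
branch). At a species-tree node carrying a planted WGD, every surviving
lineage independently duplicates with retention probability *r* — the
per-family probability that the WGD leaves a detectable duplicate. At
speciation, each lineage continues into both daughter branches. Extinct
subtrees are pruned and pass-through nodes spliced out; a fully extinct
family is flagged rather than resampled, so indices stay aligned with
seeds.

Defaults used by the canned datasets: λ = 0.05 duplications per lineage
per unit branch length and μ = 0.01 (a low-retention background giving a
few-percent duplicated-family rate per node, comparable to the
background level a transcriptome-scale scan shows away from WGD nodes),
one WGD at the Maleae-crown node with r = 0.6, and 200 families.
Supports come from a two-point mixture (low value with probability
p_low, else high), emulating bootstrap heterogeneity without simulating
alignments. A perturbed family undergoes exactly one random
nearest-neighbour interchange and the rearranged node's support is set
to the model's low value — one poorly supported wrong edge per noisy
family, enough to break group monophyly without destroying the rest of
the signal.

Family *i* draws from an independent substream seeded by `(seed, i)`
(numpy `SeedSequence`), so any family is individually reproducible and
the set is order-independent.

Discrete characters evolve root-to-tips under a symmetric k-state Markov
chain: the number of substitutions on a branch is Poisson(rate × length)
and each substitution jumps uniformly to one of the other k − 1 states;
the root state is uniform unless fixed. This is exact for the symmetric
model (no matrix exponentials needed).

What the generator does **not** model: incomplete lineage sorting (no
coalescent layer — the WGD detector treats duplication/loss as the
signal source, and ILS robustness is out of scope), sequence evolution
and real bootstrap resampling, gene conversion, and allopolyploid
subgenome structure. Passing tests therefore show the *procedures* are
correct under duplication-loss assumptions, not that real transcriptome
data satisfy those assumptions.

## Marker filtering

The per-family filters follow fixed rules: length (every copy of every
required species ≥ the cutoff, with the boundary counting as a pass; a
family missing a required species is dropped with its own reason code),
panel coverage (≥ *k* species, or ≥ ⌈fraction × panel⌉ in fraction
mode), and copy-number caps (absent species count zero and pass).

The topology screen runs ordered stages, coarse to fine. In
`conflict_reject` mode a family fails when some internal node with
support strictly above the stage threshold subtends a clade that
partially overlaps a group sampled with ≥ 2 species (neither contains
nor is contained in it). In `clade_require` mode it fails when such a
group is simply not monophyletic. Monophyly is always evaluated relative
to the species actually sampled in that family; groups with ≤ 1 sampled
member pass vacuously. Retained sets are nested by construction and a
family failing several stages is charged to the first.

A structural point worth recording: a single NNI changes exactly one
bipartition, and when that edge carries low support — as the noise model
deliberately arranges — no *supported*-conflict screen at threshold 50
can see it. The benchmark therefore screens with monophyly requirements
(`clade_require`) at order, subfamily and tribe, which is also how a
"fails to group the subfamily's members" criterion reads. Supported
conflicts are exercised separately with constructed high-support
contradictions. NNIs that rearrange *within* a group (e.g. inside one
tribe, or rotations near the root) contradict no rank and are correctly
invisible; that is why the benchmark screen catches about half of the
perturbed families and all of its removals are true positives.

Alternative-topology tallies assign each gene tree to at most one
alternative: the one whose defining clade (union of the named groups'
sampled members) is monophyletic and subtended by a node with support
strictly above the threshold (default 50; the analysis of
within-subfamily placements used 70, so the threshold is a flag). Trees
matching nothing are `unresolved`; counts always partition the input.

Copy reduction keeps a family intact when a strict majority of its
(ingroup) species are single-copy, collapsing species-specific
duplicates to the lexicographically smallest gene id — deterministic and
biologically arbitrary, flagged in the result. Otherwise it keeps the
child clade with more species at the basal-most paralog split (the
shallowest node whose children share a species); ties go to the clade
with the lexicographically smaller species list and are flagged.

## WGD mapping

Candidate duplication nodes: binary gene-tree nodes with support
strictly above `min_support` (default 50) whose two child subtrees share
at least `min_shared_species` (default 2) species. The literal reading
"the same two species in each subclade" (identical species pairs) would
exclude most genuine events, so shared-count ≥ 2 is the default, with 1
available. The root of a gene tree carries no bootstrap value (it is not
a bipartition); it is treated as maximally supported and flagged.

Placement: with L₁, L₂ the species-tree LCAs of the two subclade species
sets, an event is accepted iff |depth(L₁) − depth(L₂)| ≤
`depth_tolerance` and mapped to the shallower LCA — equivalently the LCA
of the union — i.e. the species ancestor in which both paralog lineages
existed. The source description of the depth rule is internally
inconsistent ("same or close depth", "differences smaller than one
step"); the default here is tolerance 1 (≤ 1 step), which the type II/III
definitions require to be reachable at all, with 0 available for the
stricter reading.

Type classification needs a mapped node with ≥ 3 species. Its two child
lineages are ordered big/small by species count (tie: lexicographically
smaller sorted species list is "big"; this affects only the II vs III
label and is logged). Type I: both paralog subclades intersect both
lineages. Type II: the small lineage occurs in only one subclade. Type
III: the large lineage occurs in only one. Given ≥ 1 shared species the
three cases are exhaustive and mutually exclusive.

Summaries count, per species-tree internal node, the families containing
genes from both child lineages (the informative denominator), the
families with ≥ 1 accepted event there (each family counted once per
node by default), all paralog pairs, and the type distribution; all
percentages share the informative-family denominator. A family may
contribute events to several nodes (nested duplications are accepted
independently); deduplication happens within a node only.

The mapper is verified against an independent exhaustive implementation
(from-scratch node scan, parent-path LCAs and set arithmetic) on
hundreds of simulated families across the full threshold grid, and obeys
monotonicity: relaxing any threshold can only grow the accepted-event
set.

## Parsimony reconstruction

Units are monophyletic genera (or explicit clade-level splits of
non-monophyletic genera); collapsing verifies monophyly and errors with
the interdigitating taxa otherwise. Missing cells contribute the full
alphabet; polymorphic cells the listed subset.

Unordered parsimony uses Fitch's intersection/union bottom-up pass for
the score. MPR sets come from a top-down pass phrased as Hartigan-style
majority counting over the children's preliminary sets plus an "outside"
set per node. The textbook three-case up-pass assumes fixed single-state
tips; ambiguity sets and missing data are *hard constraints* under which
it returns wrong sets, while with unit costs every edge message is
two-valued (optimum or optimum + 1), so exact MPR sets reduce to the set
arithmetic implemented here — confirmed exhaustively against brute-force
enumeration on all random trees ≤ 8 leaves tested. Weighted/ordered
characters go through Sankoff dynamic programming (explicit cost matrix,
zero diagonal), whose unit-cost specialization reproduces Fitch scores
and MPR sets exactly and serves as an independent cross-check, not a
shared code path. Reported node states are always full MPR sets; the
method deliberately does not pick single resolutions, and
likelihood/Bayesian reconstruction is out of scope.

## Problem sizes and numerical choices

The canned analyses use a 16-species tree (14 rosaceous species across
three subfamilies and six tribes, two outgroups), 200–500 families, and
thresholds at their defaults; these sizes keep every experiment exact
(brute-force comparable) while leaving the binomial recovery checks
well-powered. Floating-point ties in Sankoff MPR extraction use an
absolute 1e-9 slack; everything else is integer or set arithmetic.
Deterministic tie-breaks (lexicographic gene ids and species lists,
first-in-post-order duplication splits) are flagged in outputs wherever
they decide anything.

## Known limitations

- No coalescent/ILS layer in the simulator, so discordance from deep
  coalescence is indistinguishable from noise here.
- The hierarchical screen can only see noise that contradicts the
  supplied taxonomy; rearrangements within a group pass silently.
- Outgroup rooting refuses non-separable outgroups instead of falling
  back to midpoint rooting; such families are excluded from mapping.
- The copy-reduction representative choice (smallest gene id) is a
  convention, not a biological statement.
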