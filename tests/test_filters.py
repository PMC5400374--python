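"""Marker curation: per-family filters, hierarchical topology screening,
alternative-topology tallies, and copy reduction."""

import math

import pytest

from phylodup.families import GeneFamily, GeneMember
from phylodup.filters import (
    FilterStage,
    TopologyAlternative,
    filter_copy_number,
    filter_coverage,
    filter_length,
    reduce_to_single_copy,
    run_hierarchical_filter,
    tally_alternatives,
    topology_stage,
)
from phylodup.taxonomy import TaxonomyTable
from phylodup.trees import parse_newick


def fam(fid, lengths: dict, tree=None):
    members = [
        GeneMember(sp, f"g{i+1}", ln)
        for sp, lns in lengths.items()
        for i, ln in enumerate(lns if isinstance(lns, list) else [lns])
    ]
    return GeneFamily(fid, members, tree)


REQUIRED = ["apple", "pear", "peach", "strawberry", "medicago"]


class TestLengthFilter:
    def test_boundary_length_counts_as_pass(self):
        f = fam("a", {"apple": 1200, "pear": 1500, "peach": 1000, "strawberry": 1001,
                      "medicago": 2000})
        out = filter_length([f], 1000, REQUIRED)
        assert [g.family_id for g in out.retained] == ["a"]

    def test_one_short_copy_drops_family(self):
        f = fam("a", {"apple": [1200, 999], "pear": 1500, "peach": 1000,
                      "strawberry": 1001, "medicago": 2000})
        out = filter_length([f], 1000, REQUIRED)
        assert out.retained == [] and out.removed == [("a", "short_sequence")]

    def test_missing_required_species_drops_with_reason(self):
        f = fam("a", {"apple": 1200})
        out = filter_length([f], 1000, REQUIRED)
        assert out.removed == [("a", "missing_required")]

    def test_idempotent(self):
        fams = [
            fam("a", {sp: 1500 for sp in REQUIRED}),
            fam("b", {sp: 900 for sp in REQUIRED}),
        ]
        once = filter_length(fams, 1000, REQUIRED)
        twice = filter_length(once.retained, 1000, REQUIRED)
        assert twice.retained == once.retained and not twice.removed


class TestCoverageFilter:
    PANEL = [f"s{i}" for i in range(10)]

    def test_six_of_ten_kept_five_dropped(self):
        f6 = fam("six", {s: 1000 for s in self.PANEL[:6]})
        f5 = fam("five", {s: 1000 for s in self.PANEL[:5]})
        out = filter_coverage([f6, f5], self.PANEL, min_present=6)
        assert [g.family_id for g in out.retained] == ["six"]
        assert out.removed == [("five", "low_coverage")]

    def test_fraction_mode_threshold_is_ceiling(self):
        panel = [f"t{i}" for i in range(148)]
        want = math.ceil(0.85 * 148)  # arithmetic oracle: 126 species
        ok = fam("ok", {s: 1000 for s in panel[:want]})
        just_below = fam("lo", {s: 1000 for s in panel[: want - 1]})
        out = filter_coverage([ok, just_below], panel, min_fraction=0.85)
        assert [g.family_id for g in out.retained] == ["ok"]


class TestCopyNumberFilter:
    def test_within_caps_kept(self):
        f = fam("a", {"apple": [1000, 1000], "pear": 1000})
        out = filter_copy_number([f], {"apple": 2, "pear": 2})
        assert out.retained == [f]

    def test_over_cap_dropped_and_absent_passes(self):
        f = fam("a", {"apple": [1, 1, 1]})
        assert filter_copy_number([f], {"apple": 2}).removed == [("a", "copy_number")]
        assert filter_copy_number([f], {"pear": 2}).retained == [f]

    def test_empty_caps_identity(self):
        fams = [fam("a", {"apple": [1, 1, 1]}), fam("b", {"pear": 1})]
        assert filter_copy_number(fams, {}).retained == fams


class TestTopologyStage:
    def test_congruent_families_pass_every_rank(self, bench):
        tax = bench.taxonomy
        clean = [f.to_gene_family() for f in bench.families if not f.perturbed][:20]
        for rank in ("order", "subfamily", "tribe"):
            for mode in ("conflict_reject", "clade_require"):
                stage = FilterStage(rank, mode=mode, rank=rank)
                for family in clean:
                    passed, offending = topology_stage(family, tax, stage)
                    assert passed, (rank, mode, family.family_id, offending)

    def test_supported_outgroup_intrusion_fails_order_stage(self, mini):
        # an outgroup gene nested inside Rosales with support 95
        tree = parse_newick(
            "((Cucumis_sativus|g1:1,(Rosa_a|g1:1,Medicago_truncatula|g1:1)95:1)90:1,"
            "(Malus_a|g1:1,Prunus_a|g1:1)95:1)90;"
        )
        family = GeneFamily.from_tree("bad", tree)
        stage = FilterStage("order", mode="conflict_reject", rank="order", min_support=50)
        passed, offending = topology_stage(family, mini.taxonomy, stage)
        assert not passed and "Rosales" in offending

    def test_same_conflict_invisible_below_threshold(self, mini):
        tree = parse_newick(
            "((Cucumis_sativus|g1:1,(Rosa_a|g1:1,Medicago_truncatula|g1:1)30:1)30:1,"
            "(Malus_a|g1:1,Prunus_a|g1:1)30:1)30;"
        )
        family = GeneFamily.from_tree("bad", tree)
        stage = FilterStage("order", mode="conflict_reject", rank="order", min_support=50)
        passed, _ = topology_stage(family, mini.taxonomy, stage)
        assert passed

    def test_singleton_group_vacuously_passes(self, mini):
        tree = parse_newick("((Rosa_a|g1,Cucumis_sativus|g1)99,Malus_a|g1)99;")
        family = GeneFamily.from_tree("single", tree)
        stage = FilterStage("tribe", mode="clade_require", rank="tribe")
        passed, _ = topology_stage(family, mini.taxonomy, stage)
        assert passed


BENCH_STAGES = [
    FilterStage("order", mode="clade_require", rank="order"),
    FilterStage("subfamily", mode="clade_require", rank="subfamily"),
    FilterStage("tribe", mode="clade_require", rank="tribe"),
]


class TestHierarchicalFilter:
    def test_empty_stage_list_is_identity(self, bench):
        fams = [f.to_gene_family() for f in bench.families[:10]]
        res = run_hierarchical_filter(fams, bench.taxonomy, [])
        assert res.final == fams and res.removals.empty

    def test_retained_sets_nested_and_only_perturbed_removed(self, bench):
        fams = [f.to_gene_family() for f in bench.families]
        res = run_hierarchical_filter(fams, bench.taxonomy, BENCH_STAGES)
        ids = [set(f.family_id for f in s) for s in res.retained_sets]
        for coarse, fine in zip(ids, ids[1:]):
            assert fine <= coarse
        perturbed = {f.family_id for f in bench.families if f.perturbed}
        assert set(res.removals["family_id"]) <= perturbed
        assert len(res.final) < len(fams)  # the screen actually removes noise

    def test_rerun_on_retained_removes_nothing(self, bench):
        fams = [f.to_gene_family() for f in bench.families]
        res = run_hierarchical_filter(fams, bench.taxonomy, BENCH_STAGES)
        again = run_hierarchical_filter(res.final, bench.taxonomy, BENCH_STAGES)
        assert [f.family_id for f in again.final] == [f.family_id for f in res.final]
        assert again.removals.empty

    def test_raising_min_support_never_removes_more(self, mini):
        fams = [f.to_gene_family() for f in mini.families if f.tree is not None]
        stages_of = lambda s: [
            FilterStage(r, mode="conflict_reject", rank=r, min_support=s)
            for r in ("order", "subfamily", "tribe")
        ]
        removed = {
            s: len(run_hierarchical_filter(fams, mini.taxonomy, stages_of(s)).removals)
            for s in (0.0, 50.0, 97.0)
        }
        assert removed[97.0] <= removed[50.0] <= removed[0.0]


SUBFAMILY_ALTS = [
    TopologyAlternative("Dryadoideae_basal", ("Rosoideae", "Amygdaloideae")),
    TopologyAlternative("Rosoideae_basal", ("Dryadoideae", "Amygdaloideae")),
    TopologyAlternative("Amygdaloideae_basal", ("Dryadoideae", "Rosoideae")),
]


class TestTallies:
    def tax3(self):
        return TaxonomyTable.from_records(
            [
                {"species_id": s, "genus": s, "tribe": "", "subfamily": sf,
                 "family": "Rosaceae", "order": "Rosales"}
                for s, sf in [("D", "Dryadoideae"), ("R", "Rosoideae"), ("A", "Amygdaloideae")]
            ]
        )

    def test_forced_assignment_and_threshold(self):
        tax = self.tax3()
        strong = parse_newick("(D,(R,A)100);")
        weak = parse_newick("(D,(R,A)40);")
        counts = tally_alternatives([strong, weak], SUBFAMILY_ALTS, tax, min_support=50)
        assert counts["Dryadoideae_basal"] == 1
        assert counts["unresolved"] == 1
        assert sum(counts.values()) == 2

    def test_counts_partition_simulated_trees(self, bench):
        trees = [f.tree for f in bench.families if f.tree is not None][:300]
        counts = tally_alternatives(trees, SUBFAMILY_ALTS, bench.taxonomy, min_support=50)
        assert sum(counts.values()) == len(trees)
        # trees were generated on a Dryadoideae-basal species tree
        best = max((c, k) for k, c in counts.items() if k != "unresolved")[1]
        assert best == "Dryadoideae_basal"
        assert counts["Dryadoideae_basal"] > len(trees) / 2


class TestCopyReduction:
    def test_all_single_copy_unchanged(self):
        t = parse_newick("((A|1,B|1)90,C|1)90;")
        res = reduce_to_single_copy(GeneFamily.from_tree("f", t))
        assert res.rule == "single_copy_majority"
        assert res.family.tree.leaf_labels() == t.leaf_labels()

    def test_majority_duplicated_retains_larger_clade(self):
        t = parse_newick("((A|1,(B|1,C|1)90)90,(A|2,B|2)90)90;")
        res = reduce_to_single_copy(GeneFamily.from_tree("f", t))
        assert res.rule == "clade_retained" and not res.tie
        assert res.family.species == {"A", "B", "C"}
        assert res.family.tree.leaf_labels() == {"A|1", "B|1", "C|1"}

    def test_species_specific_pair_collapsed_to_smallest_gene(self):
        t = parse_newick("(((A|1,A|2)99,B|1)90,(C|1,D|1)90)90;")
        res = reduce_to_single_copy(GeneFamily.from_tree("f", t))
        assert res.rule == "single_copy_majority"
        assert res.family.tree.leaf_labels() == {"A|1", "B|1", "C|1", "D|1"}
        assert "A|2" in res.dropped_genes

    def test_tie_between_clades_is_deterministic_and_flagged(self):
        t = parse_newick("((A|1,B|1)90,(A|2,B|2)90)90;")
        res = reduce_to_single_copy(GeneFamily.from_tree("f", t))
        assert res.rule == "clade_retained" and res.tie
        # equal species counts: first clade under the deterministic tie-break
        assert res.family.tree.leaf_labels() == {"A|1", "B|1"}

    def test_at_most_one_copy_per_species_always(self, mini):
        for f in mini.families[:60]:
            if f.tree is None:
                continue
            res = reduce_to_single_copy(f.to_gene_family())
            counts = res.family.copy_numbers()
            assert all(c == 1 for c in counts.values())
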