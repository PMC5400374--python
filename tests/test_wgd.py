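"""Duplication detection, species-tree placement, type classification,
and per-node summaries."""

import numpy as np
import pytest

from helpers import brute_force_events
from phylodup.families import GeneFamily
from phylodup.simulate import SimulationConfig, SupportModel, simulate_family
from phylodup.simulate import mini_species_tree
from phylodup.trees import lca, parse_newick
from phylodup.wgd import (
    MappingConfig,
    classify_type,
    detect_duplication_nodes,
    map_duplication,
    map_family,
    run_mapping,
    summarize_per_node,
)


SP4 = parse_newick("((A,B),(C,D));")
SP_LADDER = parse_newick("(O,(A,(B,C)));")


def candidates(newick, **kw):
    tree = parse_newick(newick)
    return tree, detect_duplication_nodes(tree, MappingConfig(**kw))


class TestDetect:
    def test_root_with_shared_species_is_candidate(self):
        tree, cands = candidates("((A|1,B|1)100,(A|2,B|2)100);")
        assert len(cands) == 1
        only = cands[0]
        assert only.is_root and only.support == 100.0 and only.shared == {"A", "B"}

    def test_support_exactly_at_threshold_is_not_candidate(self):
        # strict ">": a node at exactly 50 does not qualify (and the root
        # shares no species between its subclades here)
        _, cands = candidates("(((A|1,B|1)50,(A|2,B|2)50)50,C|1)100;")
        assert cands == []
        _, above = candidates("(((A|1,B|1)51,(A|2,B|2)51)51,C|1)100;")
        assert len(above) == 1 and not above[0].is_root

    def test_min_shared_species_respected(self):
        nwk = "((A|1,B|1)100,(A|2,C|1)100);"  # subclades share only A
        _, at2 = candidates(nwk, min_shared_species=2)
        _, at1 = candidates(nwk, min_shared_species=1)
        assert not at2 and len(at1) == 1

    def test_polytomies_are_never_duplication_nodes(self):
        tree = parse_newick("((A|1,A|2,B|1)100,C|1)100;")
        assert detect_duplication_nodes(tree, MappingConfig(min_shared_species=1)) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_exhaustive_scan(self, seed):
        sp = mini_species_tree()
        cfg = SimulationConfig(
            species_tree=sp, n_families=1, dup_rate=0.15, loss_rate=0.05, seed=seed,
            support_model=SupportModel("two_point", p_low=0.4, low_value=40.0, high_value=95.0),
        )
        fam = simulate_family(cfg, 0)
        if fam.tree is None:
            pytest.skip("family extinct at this seed")
        mc = MappingConfig(min_support=50, min_shared_species=1, depth_tolerance=100)
        got = sorted(
            (e.gene_node, e.mapped_node, e.topology_type)
            for e in map_family(fam.to_gene_family(), sp, mc)[0]
        )
        want = brute_force_events(fam.tree, sp, 50, 1, 100)
        assert got == want


class TestMapping:
    def test_equal_depth_subclades_map_to_shared_ancestor(self):
        tree, cands = candidates("((A|1,B|1)100,(A|2,B|2)100);")
        event, reason = map_duplication("f", cands[0], SP4, MappingConfig())
        assert reason is None
        assert event.mapped_node == lca(SP4, ["A", "B"])
        assert event.depth_left == event.depth_right

    def test_one_step_depth_difference_needs_tolerance(self):
        tree, cands = candidates("((A|1,(B|1,C|1)100)100,(B|2,C|2)100);")
        root_cand = [c for c in cands if c.is_root][0]
        ok, reason = map_duplication("f", root_cand, SP_LADDER, MappingConfig(depth_tolerance=1))
        assert reason is None and ok.mapped_node == lca(SP_LADDER, ["A", "B", "C"])
        rej, reason = map_duplication("f", root_cand, SP_LADDER, MappingConfig(depth_tolerance=0))
        assert rej is None and reason == "depth_mismatch"

    def test_two_step_difference_rejected_at_default_tolerance(self):
        sp = parse_newick("((((A,B),C),D),E);")
        tree, cands = candidates("((A|1,B|1)100,(A|2,(D|1,E|1)100)100);",
                                 min_shared_species=1)
        root_cand = [c for c in cands if c.is_root][0]
        rejected, reason = map_duplication("f", root_cand, sp, MappingConfig(
            min_shared_species=1, depth_tolerance=1))
        assert rejected is None and reason == "depth_mismatch"

    def test_unknown_species_raises(self):
        tree, cands = candidates("((A|1,Z|1)100,(A|2,Z|2)100);")
        with pytest.raises(KeyError, match="Z"):
            map_duplication("f", cands[0], SP4, MappingConfig())


class TestTypes:
    def test_type_I_retains_both_lineages_in_both_copies(self):
        tree, cands = candidates("((A|1,(B|1,C|1)100)100,(A|2,(B|2,C|2)100)100);")
        event, _ = map_duplication("f", [c for c in cands if c.is_root][0],
                                   SP_LADDER, MappingConfig())
        assert classify_type(event, SP_LADDER) == "I"

    def test_type_II_small_lineage_in_one_copy_only(self):
        tree, cands = candidates("((A|1,(B|1,C|1)100)100,(B|2,C|2)100);")
        event, _ = map_duplication("f", [c for c in cands if c.is_root][0],
                                   SP_LADDER, MappingConfig())
        assert classify_type(event, SP_LADDER) == "II"

    def test_type_III_large_lineage_in_one_copy_only(self):
        # the large lineage {B,C} survives in only the first paralog copy
        tree, cands = candidates("((A|1,(B|1,C|1)100)100,A|2);",
                                 min_shared_species=1)
        event, _ = map_duplication("f", [c for c in cands if c.is_root][0],
                                   SP_LADDER, MappingConfig(min_shared_species=1))
        assert classify_type(event, SP_LADDER) == "III"

    def test_two_species_node_is_NA(self):
        tree, cands = candidates("((A|1,B|1)100,(A|2,B|2)100);")
        event, _ = map_duplication("f", cands[0], SP4, MappingConfig())
        assert classify_type(event, SP4) == "NA"


class TestSummaries:
    def test_no_events_zero_percent_full_denominators(self):
        fams = [GeneFamily.from_tree("f1", parse_newick("((A|1,B|1)100,(C|1,D|1)100);"))]
        summaries = summarize_per_node([], fams, SP4)
        for s in summaries.values():
            assert s.n_dup_families == 0 and s.pct == 0.0
        root_summary = summaries[SP4.root.node_id]
        assert root_summary.n_informative == 1

    def test_type_counts_sum_to_pairs_and_dup_le_informative(self, mini):
        fams = [f.to_gene_family() for f in mini.families if f.tree is not None]
        ev, summ, _ = run_mapping(fams, mini.species_tree)
        for _, row in summ.iterrows():
            assert row.type_I + row.type_II + row.type_III + row.type_NA == row.n_pairs
            assert row.n_dup_families <= row.n_informative

    def test_planted_node_is_argmax(self, mini):
        fams = [f.to_gene_family() for f in mini.families if f.tree is not None]
        _, summ, _ = run_mapping(fams, mini.species_tree)
        top = summ.sort_values("pct", ascending=False).iloc[0]
        assert top.node == mini.wgd_node

    def test_empty_family_list_gives_empty_tables(self):
        ev, summ, skipped = run_mapping([], SP4)
        assert ev.empty and (summ.n_pairs == 0).all()

    def test_rerun_outputs_byte_identical(self, mini, tmp_path):
        fams = [f.to_gene_family() for f in mini.families if f.tree is not None][:50]
        run_mapping(fams, mini.species_tree, out_dir=tmp_path / "a")
        run_mapping(fams, mini.species_tree, out_dir=tmp_path / "b")
        for name in ("events.tsv", "node_summary.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_unrootable_families_are_skipped_not_fatal(self, mini):
        fams = [f.to_gene_family() for f in mini.families if f.tree is not None][:20]
        ev, summ, skipped = run_mapping(
            fams, mini.species_tree, outgroup=["Cucumis_sativus", "Medicago_truncatula"]
        )
        assert sum(skipped.values()) + len(set(ev.family_id)) <= 20


class TestMonotonicity:
    def event_keys(self, fams, sp, cfg):
        out = set()
        for fam in fams:
            for e in map_family(fam, sp, cfg)[0]:
                out.add((e.family_id, e.gene_node))
        return out

    def test_relaxing_each_threshold_grows_event_set(self, mini):
        sp = mini.species_tree
        fams = [f.to_gene_family() for f in mini.families if f.tree is not None][:80]
        base = MappingConfig(min_support=50, min_shared_species=2, depth_tolerance=1)
        e0 = self.event_keys(fams, sp, base)
        assert e0 <= self.event_keys(fams, sp, MappingConfig(0, 2, 1))
        assert e0 <= self.event_keys(fams, sp, MappingConfig(50, 1, 1))
        assert e0 <= self.event_keys(fams, sp, MappingConfig(50, 2, 5))
        e_strict = self.event_keys(fams, sp, MappingConfig(70, 2, 0))
        assert e_strict <= e0
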