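import collections

import pytest

from cladeforge import redcore, synthetic, treeio
from cladeforge.delineate import (
    UNGROUPED,
    DelineationParams,
    delineate_subgroups,
    map_to_16s_clusters,
)


def _annotate(text):
    return redcore.red_annotate(treeio.read_newick(text))


def _true_partition(truth):
    part = collections.defaultdict(set)
    for lf, lab in truth.items():
        if lab != UNGROUPED:
            part[lab].add(lf)
    return {frozenset(v) for v in part.values()}


class TestQualification:
    def test_well_supported_deep_clade_selected(self, small_cfg):
        cfg = small_cfg(
            11,
            planted_clades=(synthetic.PlantedClade(6, 0.5, 0.55, 96, 85),
                            synthetic.PlantedClade(6, 0.5, 0.55, 100, 100)),
            n_outliers=0,
        )
        text, truth, info = synthetic.sim_tree_with_clades(cfg)
        asg = delineate_subgroups(_annotate(text), outgroup=info["outgroup"])
        assert asg.partition() == _true_partition(truth)

    def test_failing_ufboot_leaves_members_ungrouped(self, small_cfg):
        # identical construction, but one clade at UFBOOT 90 (< 95)
        cfg = small_cfg(
            11,
            planted_clades=(synthetic.PlantedClade(6, 0.5, 0.55, 90, 85),
                            synthetic.PlantedClade(6, 0.5, 0.55, 100, 100)),
            n_outliers=0,
        )
        text, truth, info = synthetic.sim_tree_with_clades(cfg)
        asg = delineate_subgroups(_annotate(text), outgroup=info["outgroup"])
        weak = next(l for l in truth.values() if not info["passes_default"].get(l, True))
        weak_leaves = {lf for lf, lab in truth.items() if lab == weak}
        # the failing crown is not selected, but its strongly supported
        # internal sub-clades may be: none may equal the planted leaf set
        assert weak_leaves not in asg.partition()

    def test_red_and_stem_exactly_at_threshold_rejected(self):
        # "exceeded 0.4" is strict: RED = 0.40 fails, 0.41 passes
        at = _annotate("((A:0.6,B:0.6)100/100:0.4,C:1);")
        assert delineate_subgroups(at).subgroups == []
        above = _annotate("((A:0.59,B:0.59)100/100:0.41,C:1);")
        assert len(delineate_subgroups(above).subgroups) == 1

    def test_stem_at_threshold_rejected_even_with_deep_red(self):
        # crown at depth 0.6 (RED 0.6) but stem exactly 0.4
        at = _annotate("(((A:0.4,B:0.4)100/100:0.4,X:0.8)100/100:0.2,C:1);")
        labels = {sg.leaves for sg in delineate_subgroups(at).subgroups}
        assert frozenset({"A", "B"}) not in labels

    def test_nodes_without_supports_fail(self):
        at = _annotate("((A:0.5,B:0.5):0.5,C:1);")
        assert delineate_subgroups(at).subgroups == []

    def test_ingroup_root_qualifying_yields_single_subgroup(self):
        text = "((A:0.4,(B:0.2,C:0.2)100/100:0.2)100/100:0.6,(P1:0.5,P2:0.5)100/100:0.5);"
        asg = delineate_subgroups(_annotate(text), outgroup={"P1", "P2"})
        assert [sg.leaves for sg in asg.subgroups] == [frozenset({"A", "B", "C"})]
        assert asg.ungrouped() == set()

    def test_override_relaxes_red_threshold_for_anchored_clade(self):
        # deep-rooted lineage: RED 0.3/(0.3+0.5) = 0.375 fails the default
        # 0.4 gate but its ultrametric stem (0.9-0.5)/0.9 = 0.444 passes;
        # a 0.3 RED override anchored on one of its leaves admits it
        text = "((A1:0.5,A2:0.5)100/100:0.3,(B1:0.3,B2:0.3)100/100:0.7);"
        rt = _annotate(text)
        default = delineate_subgroups(rt)
        assert frozenset({"A1", "A2"}) not in default.partition()
        params = DelineationParams(overrides={frozenset({"A1"}): 0.3})
        relaxed = delineate_subgroups(rt, params)
        assert frozenset({"A1", "A2"}) in relaxed.partition()


class TestMaximalityAndOrder:
    def test_selected_clades_disjoint_and_non_nested(self, small_cfg):
        for seed in range(5):
            text, _, info = synthetic.sim_tree_with_clades(small_cfg(seed))
            asg = delineate_subgroups(_annotate(text), outgroup=info["outgroup"])
            seen = set()
            for sg in asg.subgroups:
                assert not (sg.leaves & seen)
                seen |= sg.leaves
            for a in asg.subgroups:
                for b in asg.subgroups:
                    assert a is b or not (a.leaves < b.leaves)

    def test_labels_are_preorder_alphabetical(self, small_cfg):
        text, _, info = synthetic.sim_tree_with_clades(small_cfg(3))
        asg = delineate_subgroups(_annotate(text), outgroup=info["outgroup"])
        assert asg.labels() == [chr(ord("A") + i) for i in range(len(asg.subgroups))]

    def test_raising_thresholds_never_adds_subgroups(self, small_cfg):
        text, _, info = synthetic.sim_tree_with_clades(small_cfg(4))
        rt = _annotate(text)
        base = len(delineate_subgroups(rt, outgroup=info["outgroup"]).subgroups)
        for params in (
            DelineationParams(red_min=0.6),
            DelineationParams(stem_min=0.6),
            DelineationParams(ufboot_min=100.0, shalrt_min=100.0),
        ):
            n = len(delineate_subgroups(rt, params, outgroup=info["outgroup"]).subgroups)
            assert n <= base


@pytest.mark.parametrize("seed", range(10))
def test_planted_partition_recovery_with_outliers(seed, small_cfg):
    text, truth, info = synthetic.sim_tree_with_clades(small_cfg(seed))
    asg = delineate_subgroups(_annotate(text), outgroup=info["outgroup"])
    assert asg.partition() == _true_partition(truth)
    assert asg.ungrouped() == {lf for lf, lab in truth.items() if lab == UNGROUPED}


class TestErrors:
    def test_missing_red_annotation(self, small_cfg):
        text, _, info = synthetic.sim_tree_with_clades(small_cfg(0))
        rt = _annotate(text)
        rt.red = {}
        with pytest.raises(ValueError, match="RED annotation"):
            delineate_subgroups(rt, outgroup=info["outgroup"])

    def test_empty_ingroup(self):
        rt = _annotate("((A:0.5,B:0.5)100/100:0.5,C:1);")
        with pytest.raises(ValueError, match="empty ingroup"):
            delineate_subgroups(rt, outgroup={"A", "B", "C"})


class TestMap16S:
    def _assignment(self):
        text = "((x:0.5,y:0.5)100/100:0.5,(P1:0.5,P2:0.5)100/100:0.5);"
        return delineate_subgroups(_annotate(text), outgroup={"P1", "P2"})

    def test_partial_mapping_counts_shared_leaves(self):
        asg = self._assignment()
        table = map_to_16s_clusters(asg, {"x": "Woese-4"})
        assert table.to_dict("records") == [
            {"subgroup": "A", "cluster": "Woese-4", "n_shared_leaves": 1}
        ]

    def test_empty_mapping_gives_empty_table(self):
        assert map_to_16s_clusters(self._assignment(), {}).empty

    def test_double_mapping_rejected(self):
        with pytest.raises(ValueError, match="single-valued"):
            map_to_16s_clusters(self._assignment(), [("x", "Woese-4"), ("x", "Woese-8")])
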