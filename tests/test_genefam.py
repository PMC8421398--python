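import numpy as np
import pandas as pd
import pytest

from cladeforge import synthetic
from cladeforge.delineate import SubgroupAssignment
from cladeforge.genefam import (
    category_composition,
    filter_families_min_size,
    filter_single_copy_orthologs,
    occurrence_by_subgroup,
    pairwise_distance_matrix,
    select_medoid,
)
from oracles import medoid_brute_force, random_protein


def _fm(rows, fams=None):
    fams = fams or [f"F{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame.from_dict(rows, orient="index", columns=fams)


class TestFamilySizeFilter:
    def test_boundary_at_four_sequences(self):
        fm = _fm({"g1": [1, 2], "g2": [2, 2]})  # totals 3 and 4
        kept = filter_families_min_size(fm)
        assert list(kept.columns) == ["F1"]

    def test_min_one_is_identity_without_empty_families(self):
        fm = _fm({"g1": [1, 1], "g2": [0, 1]})
        assert filter_families_min_size(fm, min_seqs=1).equals(fm)

    def test_all_below_threshold_warns(self):
        fm = _fm({"g1": [1, 1]})
        with pytest.warns(UserWarning, match="below the size threshold"):
            assert filter_families_min_size(fm, min_seqs=4).shape[1] == 0


class TestSingleCopyOrthologs:
    def test_85_percent_occupancy_boundary(self):
        # 17/20 genomes = 85% occupancy, all single-copy: kept
        rows = {f"g{i}": [1 if i < 17 else 0] for i in range(20)}
        assert filter_single_copy_orthologs(_fm(rows, ["F0"])) == ["F0"]
        rows16 = {f"g{i}": [1 if i < 16 else 0] for i in range(20)}
        assert filter_single_copy_orthologs(_fm(rows16, ["F0"])) == []

    def test_multicopy_in_disallowed_genome_excluded(self):
        rows = {f"g{i}": [2 if i == 0 else (1 if i < 17 else 0)] for i in range(20)}
        fm = _fm(rows, ["F0"])
        assert filter_single_copy_orthologs(fm) == []
        assert filter_single_copy_orthologs(fm, allow_multicopy_in={"g0"}) == ["F0"]

    def test_full_occupancy_requires_every_genome(self):
        rows = {"g1": [1], "g2": [0]}
        assert filter_single_copy_orthologs(_fm(rows, ["F0"]), occupancy=1.0) == []

    def test_antitone_in_occupancy(self, small_cfg):
        cfg = small_cfg(6)
        _, truth, _ = synthetic.sim_tree_with_clades(cfg)
        fm, _, _ = synthetic.sim_family_matrix(cfg, synthetic.truth_assignment(truth))
        prev = None
        for occ in (0.2, 0.4, 0.6, 0.8, 1.0):
            kept = set(filter_single_copy_orthologs(fm, occupancy=occ))
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestOccurrence:
    def _assignment(self):
        return SubgroupAssignment(
            leaf_to_label={"g1": "A", "g2": "A", "g3": "A", "g4": "A", "g5": "UNGROUPED"},
            subgroups=[],
        )

    def test_percentages_exact(self):
        fm = _fm({"g1": [1], "g2": [2], "g3": [1], "g4": [0], "g5": [1]}, ["F0"])
        occ, sizes = occurrence_by_subgroup(fm, self._assignment())
        assert occ.loc["F0", "A"] == 75.0
        assert sizes["A"] == 4  # UNGROUPED genome not counted

    def test_absent_and_universal_genes(self):
        fm = _fm({f"g{i}": [0, 1] for i in range(1, 6)}, ["F0", "F1"])
        occ, _ = occurrence_by_subgroup(fm, self._assignment())
        assert (occ["A"] == [0.0, 100.0]).all()

    def test_unassigned_genome_rejected(self):
        fm = _fm({"gX": [1]}, ["F0"])
        with pytest.raises(ValueError, match="without a subgroup assignment"):
            occurrence_by_subgroup(fm, self._assignment())

    def test_planted_enrichment_direction_recovered(self, small_cfg):
        # planted families occur more often inside their subgroup than among
        # all non-member genomes pooled, in every trial
        hits = 0
        for seed in range(20):
            cfg = small_cfg(seed, n_families=60)
            _, truth, _ = synthetic.sim_tree_with_clades(cfg)
            asg = synthetic.truth_assignment(truth)
            fm, _, ftruth = synthetic.sim_family_matrix(cfg, asg)
            occ, _ = occurrence_by_subgroup(fm, asg, list(ftruth))
            ok = True
            for fam, sub in ftruth.items():
                outside = [g for g in fm.index if asg.leaf_to_label[g] != sub]
                pooled = 100.0 * (fm.loc[outside, fam] >= 1).mean()
                ok &= occ.loc[fam, sub] > pooled
            hits += ok
        assert hits == 20


class TestMedoid:
    def test_single_sequence_is_its_own_medoid(self):
        assert select_medoid({"only": "MKV"}) == "only"

    def test_tie_between_identical_sequences_breaks_lexicographically(self):
        seqs = {"s2": "MKVLHAG", "s1": "MKVLHAG", "s3": "WWWWCCC"}
        assert select_medoid(seqs) == "s1"

    def test_distances_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        seqs = {f"s{i}": random_protein(rng) for i in range(4)}
        d = pairwise_distance_matrix(seqs)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no sequences"):
            select_medoid({})

    def test_non_amino_acid_rejected_with_name(self):
        with pytest.raises(ValueError, match="sXX"):
            select_medoid({"sXX": "MKVB2"})

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        seqs = {f"s{i:02d}": random_protein(rng, 25, 45) for i in range(n)}
        assert select_medoid(seqs) == medoid_brute_force(seqs)


class TestCategoryComposition:
    def test_simple_fraction(self):
        ann = pd.Series({f"F{i}": "E" if i < 4 else "NA" for i in range(10)})
        comp = category_composition(ann.index, ann)
        assert comp["E"] == pytest.approx(0.4)
        assert comp["NA"] == pytest.approx(0.6)

    def test_all_na(self):
        comp = category_composition(["F0", "F1"], {})
        assert comp.to_dict() == {"NA": 1.0}

    def test_multi_letter_category_split_fractionally(self):
        ann = pd.Series({"F0": "EH", **{f"F{i}": "NA" for i in range(1, 10)}})
        comp = category_composition(ann.index, ann)
        assert comp["E"] == pytest.approx(0.05)
        assert comp["H"] == pytest.approx(0.05)
        assert comp.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_sums_to_one_on_random_annotations(self, seed, small_cfg):
        cfg = small_cfg(seed)
        _, truth, _ = synthetic.sim_tree_with_clades(cfg)
        _, ann, _ = synthetic.sim_family_matrix(cfg, synthetic.truth_assignment(truth))
        comp = category_composition(ann.index[:50], ann)
        assert comp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_gives_empty_series(self):
        assert category_composition([], {}).empty
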