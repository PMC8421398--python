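import textwrap

import pandas as pd
import pytest

from cladeforge import synthetic
from cladeforge.reconcile import (
    gain_composition,
    parse_reconciliation,
    summarize_gains,
    threshold_events,
)


SIMPLE = textwrap.dedent(
    """\
    family\tbranch\tD\tT\tL\tO\tcopies
    f1\tb1\t0.0\t0.5\t0.0\t0.31\t1.0
    f1\tb2\t0.0\t0.0\t0.9\t0.0\t0.0
    f2\tb1\t0.45\t0.0\t0.0\t0.30\t0.2
    f2\tb3\t0.0\t0.0\t0.0\t0.0\t0.8
    """
)

ALE_UML = textwrap.dedent(
    """\
    #ALEml_undated-style reconciliation summary (synthetic fixture)
    rate of duplications 0.01 transfers 0.02 losses 0.05
    S_internal_branch\t82\t0.10\t0.45\t0.00\t0.62\t1.10
    S_terminal_branch\tleafX\t0.00\t0.00\t0.80\t0.00\t0.95
    """
)


class TestParse:
    def test_simple_tsv_round_values(self, tmp_path):
        p = tmp_path / "rec.tsv"
        p.write_text(SIMPLE)
        rt = parse_reconciliation(p)
        assert rt.families == ["f1", "f2"]
        assert rt.branches == ["b1", "b2", "b3"]
        row = rt.freq.set_index(["family", "branch"]).loc[("f1", "b1")]
        assert (row["T"], row["O"]) == (0.5, 0.31)

    def test_malformed_line_cites_line_number(self, tmp_path):
        p = tmp_path / "rec.tsv"
        p.write_text(SIMPLE + "f3\tb1\t0.1\n")
        with pytest.raises(ValueError, match="line 6"):
            parse_reconciliation(p)

    def test_unknown_branch_cites_line_number(self, tmp_path):
        p = tmp_path / "rec.tsv"
        p.write_text(SIMPLE)
        with pytest.raises(ValueError, match="line 2.*unknown branch"):
            parse_reconciliation(p, branches=["b2", "b3"])

    def test_negative_frequency_rejected(self, tmp_path):
        p = tmp_path / "rec.tsv"
        p.write_text("family\tbranch\tD\tT\tL\tO\tcopies\nf1\tb1\t-0.1\t0\t0\t0\t0\n")
        with pytest.raises(ValueError, match="negative"):
            parse_reconciliation(p)

    def test_ale_uml_fixture_matches_hand_built_expectation(self, tmp_path):
        p = tmp_path / "fam42.uml_rec"
        p.write_text(ALE_UML)
        rt = parse_reconciliation(p, dialect="ale_uml")
        expected = pd.DataFrame(
            [
                ["fam42", "82", 0.10, 0.45, 0.00, 0.62, 1.10],
                ["fam42", "leafX", 0.00, 0.00, 0.80, 0.00, 0.95],
            ],
            columns=["family", "branch", "D", "T", "L", "O", "copies"],
        )
        pd.testing.assert_frame_equal(rt.freq.reset_index(drop=True), expected)

    def test_ale_uml_directory_of_families(self, tmp_path):
        d = tmp_path / "recs"
        d.mkdir()
        (d / "famA.uml_rec").write_text(ALE_UML)
        (d / "famB.uml_rec").write_text(ALE_UML)
        rt = parse_reconciliation(d, dialect="ale_uml")
        assert rt.families == ["famA", "famB"]


class TestThreshold:
    def _table(self, tmp_path):
        p = tmp_path / "rec.tsv"
        p.write_text(SIMPLE)
        return parse_reconciliation(p)

    def test_strictly_over_tau(self, tmp_path):
        es = threshold_events(self._table(tmp_path), tau=0.3)
        b1 = es.branch("b1")
        # O=0.31 counted, O=0.30 not; T=0.5 and D=0.45 counted
        assert (b1["n_O"], b1["n_T"], b1["n_D"]) == (1, 1, 1)
        assert es.gained["b1"] == ["f1", "f2"]

    def test_inclusive_flag_counts_boundary(self, tmp_path):
        es = threshold_events(self._table(tmp_path), tau=0.3, inclusive=True)
        assert es.branch("b1")["n_O"] == 2

    def test_tau_zero_counts_every_positive_frequency(self, tmp_path):
        es = threshold_events(self._table(tmp_path), tau=0.0)
        assert int(es.events[["n_D", "n_T", "n_L", "n_O"]].sum().sum()) == 5

    def test_monotone_in_tau(self, small_cfg):
        rt, _ = synthetic.sim_reconciliation(small_cfg(3), [f"b{i}" for i in range(10)])
        totals = [
            int(threshold_events(rt, tau=t).events["n_gain"].sum())
            for t in (0.0, 0.2, 0.3, 0.5, 0.9)
        ]
        assert totals == sorted(totals, reverse=True)

    def test_tau_one_yields_no_events(self, small_cfg):
        rt, _ = synthetic.sim_reconciliation(small_cfg(3), ["b0", "b1"])
        es = threshold_events(rt, tau=1.0)
        assert int(es.events[["n_D", "n_T", "n_L", "n_O"]].sum().sum()) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_reproduces_generator_ground_truth(self, seed, small_cfg):
        cfg = small_cfg(seed)
        rt, truth = synthetic.sim_reconciliation(cfg, [f"b{i}" for i in range(12)])
        es = threshold_events(rt, tau=cfg.tau)
        pd.testing.assert_frame_equal(es.events, truth.events)
        pd.testing.assert_series_equal(es.copies, truth.copies)
        assert es.gained == truth.gained

    def test_gain_decomposition_identity(self, small_cfg):
        rt, _ = synthetic.sim_reconciliation(small_cfg(1), [f"b{i}" for i in range(8)])
        es = threshold_events(rt)
        assert (es.events["n_gain"] ==
                es.events["n_D"] + es.events["n_T"] + es.events["n_O"]).all()


class TestSummarizeGains:
    def _summary(self, d, t, o):
        df = pd.DataFrame(
            {"n_D": [d], "n_T": [t], "n_L": [0], "n_O": [o], "n_gain": [d + t + o]},
            index=pd.Index(["b"], name="branch"),
        )
        from cladeforge.reconcile import EventSummary

        return EventSummary(events=df, copies=pd.Series(dtype=int), gained={"b": []})

    def test_node82_style_shares(self):
        # 110/256 ~ 43%, 83/256 ~ 32% of gains
        out = summarize_gains(self._summary(63, 83, 110), "b")
        assert out["n_gain"] == 256
        assert out["share_O"] == 43
        assert out["share_T"] == 32

    def test_single_origination_full_share(self):
        out = summarize_gains(self._summary(0, 0, 1), "b")
        assert out["share_O"] == 100

    def test_empty_branch_gives_na_shares(self):
        out = summarize_gains(self._summary(0, 0, 0), "b")
        assert out["share_O"] is None and out["n_gain"] == 0

    def test_unknown_branch_rejected(self):
        with pytest.raises(KeyError):
            summarize_gains(self._summary(1, 0, 0), "nope")


class TestGainComposition:
    def test_fraction_matches_annotations(self, tmp_path):
        p = tmp_path / "rec.tsv"
        header = "family\tbranch\tD\tT\tL\tO\tcopies\n"
        lines = [f"f{i}\tb1\t0\t0\t0\t0.9\t0\n" for i in range(50)]
        p.write_text(header + "".join(lines))
        es = threshold_events(parse_reconciliation(p))
        ann = {f"f{i}": ("E" if i < 8 else "NA") for i in range(50)}
        comp = gain_composition(es, "b1", ann)
        assert comp["E"] == pytest.approx(0.16)

    def test_no_gains_empty_composition(self, tmp_path):
        p = tmp_path / "rec.tsv"
        p.write_text("family\tbranch\tD\tT\tL\tO\tcopies\nf1\tb1\t0\t0\t0.9\t0\t0\n")
        es = threshold_events(parse_reconciliation(p))
        assert gain_composition(es, "b1", {}).empty

    def test_unannotated_gains_are_all_na(self, tmp_path):
        p = tmp_path / "rec.tsv"
        p.write_text("family\tbranch\tD\tT\tL\tO\tcopies\nf1\tb1\t0\t0\t0\t0.9\t0\n")
        es = threshold_events(parse_reconciliation(p))
        assert gain_composition(es, "b1", {}).to_dict() == {"NA": 1.0}
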