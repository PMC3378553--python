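"""Deregulation calls, pathway lists, validation, stroma filter,
specificity."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import rabscreen as rs
from rabscreen.expression import PATHWAY_GROUPS, TUMOR_GROUPS
from rabscreen.screen import PathwayLists, ScreenError

from conftest import reference_calls

STROMAL = {"MICAL1", "RABAC1", "SDC1"}


def _fcq(rows):
    df = pd.DataFrame(rows, columns=["gene", "fc", "q_percent"])
    return df.set_index("gene")


class TestCallDeregulated:
    def test_rab27_t24_nonmut_column(self, rab27_reference):
        calls = reference_calls(rab27_reference, "T24_nonmut")
        down = set(calls.loc[calls.direction == "down", "gene"])
        assert down == {"GCC2", "MLPH", "RPH3AL", "SYTL1", "SYTL2"}
        assert (calls.direction == "up").sum() == 0

    def test_rab27_counts_across_all_groups(self, rab27_reference):
        counts = [
            (reference_calls(rab27_reference, g).direction != "none").sum()
            for g in ("TaG3_nonmut", "T1_nonmut", "T24_nonmut",
                      "TaG1G2_mut", "T1_mut", "T24_mut")]
        assert counts == [2, 3, 5, 4, 2, 4]

    def test_boundaries_are_strict(self):
        table = _fcq([("up_at_limit", 1.5, 0.0),
                      ("down_at_limit", 0.667, 0.0),
                      ("q_at_limit", 2.0, 5.0),
                      ("passes_up", 1.51, 4.99),
                      ("passes_down", 0.666, 4.99)])
        calls = rs.call_deregulated(table).set_index("gene")
        assert calls.loc["up_at_limit", "direction"] == "none"
        assert calls.loc["down_at_limit", "direction"] == "none"
        assert calls.loc["q_at_limit", "direction"] == "none"
        assert calls.loc["passes_up", "direction"] == "up"
        assert calls.loc["passes_down", "direction"] == "down"

    def test_rab27b_fails_on_q(self, rab27_reference):
        calls = reference_calls(rab27_reference, "T24_nonmut")
        row = calls.set_index("gene").loc["RAB27B"]
        assert row.fc == pytest.approx(0.506)
        assert row.direction == "none"  # q = 5.43 fails q < 5

    @given(st.integers(0, 2 ** 31 - 1))
    def test_relaxing_thresholds_never_removes_calls(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({
            "fc": np.exp2(rng.normal(0, 1, 50)),
            "q_percent": rng.uniform(0, 100, 50),
        }, index=[f"G{i}" for i in range(50)])
        strict = rs.call_deregulated(table, q_max=5)
        loose = rs.call_deregulated(table, fc_up=1.2, fc_down=0.8, q_max=20)
        called_strict = set(strict.loc[strict.direction != "none", "gene"])
        called_loose = set(loose.loc[loose.direction != "none", "gene"])
        assert called_strict <= called_loose


def _pathway_calls(pathway_references):
    calls = {}
    for pathway, groups in PATHWAY_GROUPS.items():
        ref = pathway_references[pathway]
        for g in groups:
            calls[g] = reference_calls(ref, g)
    return calls


class TestPathwayUnion:
    def test_published_per_pathway_totals(self, pathway_references):
        lists = rs.pathway_union(_pathway_calls(pathway_references),
                                 PATHWAY_GROUPS)
        assert len(lists.down["non_mutated"]) == 19
        assert len(lists.up["non_mutated"]) == 12
        assert len(lists.down["mutated"]) == 21
        assert len(lists.up["mutated"]) == 4

    def test_union_and_intersection(self, pathway_references):
        lists = rs.pathway_union(_pathway_calls(pathway_references),
                                 PATHWAY_GROUPS)
        down, up = lists.union()
        assert len(down) == 30 and len(up) == 13
        c_down, c_up = lists.intersection()
        assert len(c_down | c_up) == 13
        assert c_down == {"EEA1", "ICA1", "MLPH", "MYO5B", "MYO5C", "PIGR",
                          "RAB14", "RPH3AL", "SYTL2", "TBC1D30"}
        assert c_up == {"CAV1", "ITGA5", "MICAL1"}

    def test_group_order_invariant(self, pathway_references):
        calls = _pathway_calls(pathway_references)
        a = rs.pathway_union(calls, PATHWAY_GROUPS)
        reversed_groups = {p: tuple(reversed(g))
                           for p, g in PATHWAY_GROUPS.items()}
        b = rs.pathway_union(calls, reversed_groups)
        assert a.up == b.up and a.down == b.down

    def test_conflicting_directions_rejected(self):
        up = rs.call_deregulated(_fcq([("G1", 2.0, 1.0)]), group="a")
        down = rs.call_deregulated(_fcq([("G1", 0.4, 1.0)]), group="b")
        with pytest.raises(ScreenError, match="G1"):
            rs.pathway_union({"a": up, "b": down}, {"p": ("a", "b")})


class TestCrossDatasetValidate:
    @pytest.mark.parametrize("fc2,q2,expected", [
        (0.60, 20.0, "validated"),        # FC criterion alone
        (0.90, 2.0, "validated"),         # q passes, FC on same side of 1
        (0.90, 50.0, "not_significant"),  # neither criterion
        (1.80, 2.0, "discordant"),        # both pass in reverse
        (1.20, 2.0, "not_significant"),   # q passes but FC on wrong side
    ])
    def test_down_call_against_second_dataset(self, fc2, q2, expected):
        calls = rs.call_deregulated(_fcq([("G1", 0.4, 1.0)]), group="g")
        sam2 = _fcq([("G1", fc2, q2)])
        out = rs.cross_dataset_validate(calls, sam2, {"G1"})
        assert out.loc[0, "validation"] == expected

    def test_absent_gene_untested(self):
        calls = rs.call_deregulated(_fcq([("G1", 0.4, 1.0)]), group="g")
        out = rs.cross_dataset_validate(calls, _fcq([("G2", 1.0, 50.0)]),
                                        {"G2"})
        assert out.loc[0, "validation"] == "untested"


class TestStromaFilter:
    @pytest.fixture
    def panel(self):
        # 13 up-regulated genes; three of them rise only with stroma
        genes = ["CAV1", "ITGA5", "KIF20A", "LEPRE1", "MICAL2", "RAB23",
                 "RAB31", "STXBP1", "TMEM22", "ZWINT",
                 "MICAL1", "RABAC1", "SDC1"]
        rng = np.random.default_rng(0)
        nhu = pd.DataFrame(rng.normal(8, 0.1, size=(13, 3)), index=genes,
                           columns=["NHU_1", "NHU_2", "NHU_3"])
        lines = pd.DataFrame(rng.normal(8, 0.1, size=(13, 7)), index=genes,
                             columns=list("ABCDEFG"))
        for g in genes[:10]:
            lines.loc[g, "C"] = 10.5  # well above 2x NHU in one line
        return genes, lines, nhu

    def test_stromal_genes_flagged(self, panel):
        genes, lines, nhu = panel
        out = rs.stroma_filter(genes, lines, nhu).set_index("gene")
        flagged = set(out.index[out.status == "stromal_flagged"])
        assert flagged == STROMAL
        assert (out.loc[genes[:10], "status"] == "retained").all()

    def test_exact_twofold_is_retained(self):
        nhu = pd.DataFrame({"NHU_1": [8.0], "NHU_2": [8.0]}, index=["G1"])
        lines = pd.DataFrame({"L1": [9.0], "L2": [7.0]}, index=["G1"])
        out = rs.stroma_filter(["G1"], lines, nhu)
        assert out.loc[0, "status"] == "retained"

    def test_all_lines_below_nhu_flagged(self):
        nhu = pd.DataFrame({"NHU_1": [8.0]}, index=["G1"])
        lines = pd.DataFrame({"L1": [7.0], "L2": [6.5]}, index=["G1"])
        out = rs.stroma_filter(["G1"], lines, nhu)
        assert out.loc[0, "status"] == "stromal_flagged"

    def test_missing_gene_named(self, panel):
        genes, lines, nhu = panel
        with pytest.raises(KeyError, match="NOT_THERE"):
            rs.stroma_filter(["NOT_THERE"], lines, nhu)

    def test_dominated_extra_line_changes_nothing(self, panel):
        genes, lines, nhu = panel
        base = rs.stroma_filter(genes, lines, nhu)
        extra = lines.copy()
        extra["H"] = lines.min(axis=1) - 1.0
        again = rs.stroma_filter(genes, extra, nhu)
        assert base.status.equals(again.status)


class TestPathwaySpecific:
    def _lists(self, pathway_references):
        lists = rs.pathway_union(_pathway_calls(pathway_references),
                                 PATHWAY_GROUPS)
        for p in lists.up:  # stroma filter precedes specificity
            lists.up[p] -= STROMAL
        return lists

    def test_published_specific_genes(self, pathway_references,
                                      specificity_reference):
        lists = self._lists(pathway_references)
        cross = specificity_reference[["fc_cross", "q_cross"]].copy()
        cross.columns = ["fc", "q_percent"]
        specific = rs.pathway_specific(
            lists, {"T24_nonmut": cross}, {"T24_nonmut": "non_mutated"})
        assert specific["non_mutated"]["down"] == {"SYTL1"}
        assert specific["non_mutated"]["up"] == \
            {"LEPRE1", "MICAL2", "RAB23", "STXBP1"}
        assert specific["mutated"]["up"] == set()
        assert specific["mutated"]["down"] == set()

    def test_failing_cross_comparison_gives_empty_set(self,
                                                      pathway_references):
        lists = self._lists(pathway_references)
        null_cross = pd.DataFrame(
            {"fc": 1.0, "q_percent": 90.0},
            index=sorted(lists.pathway_genes("mutated")))
        specific = rs.pathway_specific(
            lists, {"TaG1G2_mut": null_cross}, {"TaG1G2_mut": "mutated"})
        assert specific["mutated"] == {"up": set(), "down": set()}

    def test_shared_gene_excluded_at_step_one(self, pathway_references):
        lists = self._lists(pathway_references)
        # MLPH is down in both pathways: even a passing cross-comparison
        # must not make it "specific"
        cross = pd.DataFrame({"fc": 0.3, "q_percent": 0.1}, index=["MLPH"])
        specific = rs.pathway_specific(
            lists, {"T24_nonmut": cross}, {"T24_nonmut": "non_mutated"})
        assert "MLPH" not in specific["non_mutated"]["down"]
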