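"""Interaction score arithmetic, filters, aggregation and network export."""

import numpy as np
import pandas as pd
import pytest

from kinlink import io
from kinlink.errors import ValidationError
from kinlink.netscore import (add_biogrid, add_psp_evidence, base_kls,
                              build_network, filter_top_per_site,
                              final_interaction_score, interaction_scores,
                              kinase_substrate_scores,
                              pathway_interaction_score,
                              pathway_interaction_table, protein_score_sums)


class TestScoreArithmetic:
    def test_base_kls_uses_absolute_activity(self):
        assert base_kls(1.0, -3.0) == pytest.approx(3.0)
        assert base_kls(0.0, 5.0) == 0.0
        assert base_kls(0.8, 2.5) == pytest.approx(2.0)

    def test_base_kls_requires_unit_scale_percentile(self):
        with pytest.raises(ValidationError):
            base_kls(80.0, 1.0)

    def test_psp_increment_per_evidence_level(self):
        assert add_psp_evidence(2.0, True, False) == pytest.approx(2.5)
        assert add_psp_evidence(2.0, True, True) == pytest.approx(3.0)
        assert add_psp_evidence(2.0, False, False) == pytest.approx(2.0)

    @pytest.mark.parametrize("n,expected", [(0, 0.0), (1, 0.5), (3, 0.75),
                                            (9, 0.9)])
    def test_biogrid_reference_scaling(self, n, expected):
        assert add_biogrid(0.0, n) == pytest.approx(expected)

    def test_final_score_carries_regulation_sign(self):
        assert final_interaction_score(2.5, 2.0) == pytest.approx(5.0)
        assert final_interaction_score(2.5, -2.0) == pytest.approx(-5.0)
        assert final_interaction_score(2.5, 0.0) == 0.0


def _score_frame(rows):
    return pd.DataFrame(rows, columns=["site", "protein", "kinase",
                                       "augmented_kls", "final_score"])


class TestTopPerSiteFilter:
    def test_retains_k_by_absolute_score(self):
        rows = [("s1", "P1", f"K{i}", 1.0, float(i - 5)) for i in range(10)]
        out = filter_top_per_site(_score_frame(rows), 3)
        assert len(out) == 3
        assert set(out["kinase"]) == {"K0", "K1", "K9"}  # abs scores 5, 4, 4

    def test_fewer_candidates_than_k(self):
        rows = [("s1", "P1", "KA", 1.0, 2.0), ("s1", "P1", "KB", 1.0, 1.0)]
        assert len(filter_top_per_site(_score_frame(rows), 3)) == 2

    def test_tie_broken_by_augmented_kls_then_name(self):
        rows = [("s1", "P1", "KB", 2.0, 1.0), ("s1", "P1", "KA", 1.0, 1.0),
                ("s1", "P1", "KC", 2.0, 1.0)]
        out = filter_top_per_site(_score_frame(rows), 2)
        assert out["kinase"].tolist() == ["KB", "KC"]  # KLS first, then name


class TestAggregation:
    def test_kinase_substrate_signed_sum(self):
        rows = [("s1", "P1", "KA", 1.0, 5.0), ("s2", "P1", "KA", 1.0, -1.0),
                ("s3", "P2", "KA", 1.0, 2.0)]
        pairs = kinase_substrate_scores(_score_frame(rows))
        by = pairs.set_index(["kinase", "protein"])["score"]
        assert by[("KA", "P1")] == pytest.approx(4.0)
        assert by[("KA", "P2")] == pytest.approx(2.0)

    def test_pathway_score_fraction_convention(self):
        sums = pd.Series({"A": 3.0, "B": 1.0})
        result = pathway_interaction_score({"A", "B", "C", "D"}, sums)
        assert result["pathway_score"] == pytest.approx((3 + 1) * 0.5)
        assert result["fraction"] == pytest.approx(0.5)

    def test_pathway_score_zero_when_no_member_scored(self):
        result = pathway_interaction_score({"X", "Y"}, pd.Series(dtype=float))
        assert result["pathway_score"] == 0.0

    def test_pathway_score_all_members_scored_is_plain_sum(self):
        sums = pd.Series({"A": 2.0, "B": -1.0})
        result = pathway_interaction_score({"A", "B"}, sums)
        assert result["pathway_score"] == pytest.approx(1.0)

    def test_pathway_score_invariant_to_duplicates_and_order(self):
        sums = pd.Series({"A": 2.0, "B": -1.0, "C": 0.5})
        a = pathway_interaction_score(["A", "B", "C"], sums)
        b = pathway_interaction_score(["C", "B", "A", "A", "B"], sums)
        assert a == b

    def test_percent_scale_is_pure_rescaling(self):
        sums = pd.Series({"A": 3.0})
        frac = pathway_interaction_score({"A", "B"}, sums)
        percent = pathway_interaction_score({"A", "B"}, sums, as_percent=True)
        assert percent["pathway_score"] == pytest.approx(
            100 * frac["pathway_score"])

    def test_undetected_pathway_omitted(self):
        retained = _score_frame([("s1", "P1", "KA", 1.0, 2.0)])
        table = pathway_interaction_table(
            {"GOOD": {"P1", "P2"}, "GHOST": {"Z1", "Z2"}},
            retained, detected_proteins={"P1", "P2"})
        assert table["pathway"].tolist() == ["GOOD"]


class TestEvidenceResolution:
    def _inputs(self):
        calls = pd.DataFrame({
            "site": ["P1_S10"], "protein": ["P1"], "position": [10],
            "comparison": ["c1"], "direction": ["up"], "score": [2.0],
        })
        percentiles = pd.DataFrame({"KA": [80.0]}, index=[0])
        top_sets = {0: frozenset({"KA"})}
        activities = pd.DataFrame({"kinase": ["KA"], "activity": [2.0]})
        return calls, percentiles, top_sets, activities

    def test_site_level_match_preferred_over_protein_level(self):
        calls, perc, tops, act = self._inputs()
        evidence = pd.DataFrame({
            "kinase": ["KA", "KA"], "protein": ["P1", "P1"],
            "position": [10, np.nan], "in_vitro": [1, 1], "in_vivo": [1, 0],
        })
        out = interaction_scores(calls, perc, None, tops, act,
                                 evidence=evidence)
        assert out.loc[0, "psp_increment"] == pytest.approx(1.0)  # site row wins

    def test_protein_level_fallback(self):
        calls, perc, tops, act = self._inputs()
        evidence = pd.DataFrame({
            "kinase": ["KA"], "protein": ["P1"], "position": [np.nan],
            "in_vitro": [1], "in_vivo": [0],
        })
        out = interaction_scores(calls, perc, None, tops, act,
                                 evidence=evidence)
        assert out.loc[0, "psp_increment"] == pytest.approx(0.5)

    def test_absent_record_adds_nothing(self):
        calls, perc, tops, act = self._inputs()
        out = interaction_scores(calls, perc, None, tops, act)
        assert out.loc[0, "psp_increment"] == 0.0
        assert out.loc[0, "biogrid_increment"] == 0.0

    def test_increment_decomposition_invariant(self):
        calls, perc, tops, act = self._inputs()
        evidence = pd.DataFrame({"kinase": ["KA"], "protein": ["P1"],
                                 "position": [10], "in_vitro": [1],
                                 "in_vivo": [1]})
        interactions = pd.DataFrame({"kinase": ["KA"], "protein": ["P1"],
                                     "n_refs": [4]})
        out = interaction_scores(calls, perc, None, tops, act,
                                 evidence=evidence, interactions=interactions)
        row = out.iloc[0]
        assert row["psp_increment"] in (0.0, 0.5, 1.0)
        assert 0.0 <= row["biogrid_increment"] < 1.0
        assert row["augmented_kls"] == pytest.approx(
            row["base_kls"] + row["psp_increment"] + row["biogrid_increment"])

    def test_evidence_outranks_no_evidence_at_equal_inputs(self):
        calls = pd.DataFrame({
            "site": ["P1_S10", "P2_S10"], "protein": ["P1", "P2"],
            "position": [10, 10], "comparison": ["c1", "c1"],
            "direction": ["up", "up"], "score": [2.0, 2.0],
        })
        perc = pd.DataFrame({"KA": [80.0, 80.0]}, index=[0, 1])
        tops = {0: frozenset({"KA"}), 1: frozenset({"KA"})}
        act = pd.DataFrame({"kinase": ["KA"], "activity": [2.0]})
        evidence = pd.DataFrame({"kinase": ["KA"], "protein": ["P1"],
                                 "position": [10], "in_vitro": [1],
                                 "in_vivo": [0]})
        out = interaction_scores(calls, perc, None, tops, act,
                                 evidence=evidence).set_index("protein")
        assert out.loc["P1", "final_score"] > out.loc["P2", "final_score"]


class TestNetwork:
    def _pairs(self):
        return pd.DataFrame({"kinase": ["KA", "KA", "KB"],
                             "protein": ["P1", "P2", "P1"],
                             "score": [4.0, -2.0, 1.0],
                             "n_sites": [2, 1, 1]})

    def test_node_and_edge_counts(self):
        graph = build_network(self._pairs())
        assert graph.number_of_nodes() == 4
        assert graph.number_of_edges() == 3

    def test_essentiality_annotation(self):
        dependency = pd.DataFrame({"gene": ["P1", "P2"],
                                   "chronos": [-0.7, 0.1]})
        graph = build_network(self._pairs(), dependency)
        assert graph.nodes["P1"]["essential"] is True
        assert graph.nodes["P2"]["essential"] is False

    def test_graphml_round_trip_preserves_weights(self, tmp_path):
        graph = build_network(self._pairs())
        path = tmp_path / "net.graphml"
        io.write_network(graph, path, "graphml")
        back = io.read_network(path, "graphml")
        assert set(back.nodes) == set(graph.nodes)
        for u, v, data in graph.edges(data=True):
            assert back.edges[u, v]["weight"] == pytest.approx(data["weight"])

    def test_sif_round_trip_preserves_identity(self, tmp_path):
        graph = build_network(self._pairs())
        graph.add_node("LONELY", kind="kinase")
        path = tmp_path / "net.sif"
        io.write_network(graph, path, "sif")
        back = io.read_network(path, "sif")
        assert set(back.nodes) == set(graph.nodes)
        assert set(back.edges) == set(graph.edges)

    def test_unknown_format_rejected(self, tmp_path):
        from kinlink.errors import FormatError
        with pytest.raises(FormatError):
            io.write_network(build_network(self._pairs()),
                             tmp_path / "x.bad", "xml")
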