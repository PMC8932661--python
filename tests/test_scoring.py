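"""Subpopulation projection, prognostic/cross-talk scores, influence score."""

import numpy as np
import pandas as pd
import pytest

from lrnet.graph import LIGAND, LRNode, RECEPTOR
from lrnet.interactome import EdgeRecord, Interactome
from lrnet.scoring import (ProjectedEdge, SubpopulationProfile,
                           autocrine_conversion_stats,
                           average_by_subpopulation, crosstalk_matrix,
                           downstream_influence, filter_pairs_by_prognosis,
                           prognostic_score, project_to_subpopulations,
                           _power_iteration)


def edge(lct, lg, rct, rg):
    return (LRNode(lct, lg, LIGAND), LRNode(rct, rg, RECEPTOR))


def profile_from_rows(rows):
    return SubpopulationProfile(pd.DataFrame(
        rows, columns=["subpop", "parent", "gene", "avg_expr", "scaled_avg",
                       "de_flag", "secreted"]))


def coarse(edges):
    return Interactome(edges={e: EdgeRecord(0.5, 0.3, "wc0", "within")
                              for e in edges})


class TestAverageBySubpopulation:
    def test_simple_mean(self):
        cells = pd.DataFrame({"g": [1.0, 3.0]}, index=["c1", "c2"])
        out = average_by_subpopulation(cells, {"c1": "A", "c2": "A"})
        assert out.loc["A", "g"] == pytest.approx(2.0)

    def test_patient_balanced(self):
        cells = pd.DataFrame({"g": [1.0, 1.0, 1.0, 3.0]},
                             index=["c1", "c2", "c3", "c4"])
        labels = {c: "A" for c in cells.index}
        patients = {"c1": "p1", "c2": "p1", "c3": "p1", "c4": "p2"}
        out = average_by_subpopulation(cells, labels, patients)
        assert out.loc["A", "g"] == pytest.approx(2.0)  # (1 + 3) / 2

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame(rng.normal(size=(12, 4)),
                             index=[f"c{i}" for i in range(12)],
                             columns=[f"g{j}" for j in range(4)])
        labels = pd.Series([f"S{i % 3}" for i in range(12)], index=cells.index)
        out = average_by_subpopulation(cells, labels)
        for s in ("S0", "S1", "S2"):
            expected = cells[labels == s].to_numpy().mean(axis=0)
            np.testing.assert_allclose(out.loc[s].to_numpy(), expected)

    def test_unlabeled_cell_rejected(self):
        cells = pd.DataFrame({"g": [1.0, 2.0]}, index=["c1", "c2"])
        with pytest.raises(ValueError):
            average_by_subpopulation(cells, {"c1": "A"})


class TestProjection:
    def test_product_rule(self):
        inter = coarse([edge("F", "L1", "M", "R1")])
        prof = profile_from_rows([
            ("F1", "F", "L1", 0.9, 1.0, True, True),
            ("F2", "F", "L1", 0.8, 1.0, True, True),
            ("M1", "M", "R1", 0.7, 1.0, False, False),
            ("M2", "M", "R1", 0.1, 1.0, False, False),
        ])
        projected = project_to_subpopulations(inter, prof)
        assert len(projected.edges) == 2
        assert {pe.edge[0].cell_type for pe in projected.edges} == {"F1", "F2"}

    def test_below_threshold_dropped(self):
        inter = coarse([edge("F", "L1", "M", "R1")])
        prof = profile_from_rows([
            ("F1", "F", "L1", 0.3, 1.0, True, True),
            ("M1", "M", "R1", 0.7, 1.0, False, False),
        ])
        assert project_to_subpopulations(inter, prof).edges == []

    def test_non_de_ligand_dropped(self):
        inter = coarse([edge("F", "L1", "M", "R1")])
        prof = profile_from_rows([
            ("F1", "F", "L1", 0.9, 1.0, False, True),
            ("M1", "M", "R1", 0.7, 1.0, False, False),
        ])
        assert project_to_subpopulations(inter, prof).edges == []

    def test_autocrine_becomes_paracrine_across_subpops(self):
        inter = coarse([edge("F", "CYR61", "F", "ITGB5")])
        prof = profile_from_rows([
            ("F2", "F", "CYR61", 0.9, 1.0, True, True),
            ("F4", "F", "ITGB5", 0.8, 1.0, False, False),
        ])
        projected = project_to_subpopulations(inter, prof)
        (pe,) = projected.edges
        assert pe.edge[0].cell_type == "F2" and pe.edge[1].cell_type == "F4"
        stats = autocrine_conversion_stats(inter, projected)
        assert stats["any"] == stats["all"] == 1.0

    def test_unknown_parent_rejected(self):
        inter = coarse([edge("F", "L1", "M", "R1")])
        prof = profile_from_rows([("X1", "X", "L1", 0.9, 1.0, True, True)])
        with pytest.raises(ValueError, match="parents"):
            project_to_subpopulations(inter, prof)


class TestConversionStats:
    def test_same_subpop_projection_scores_zero(self):
        inter = coarse([edge("F", "L1", "F", "R1")])
        prof = profile_from_rows([
            ("F1", "F", "L1", 0.9, 1.0, True, True),
            ("F1", "F", "R1", 0.8, 1.0, False, False),
        ])
        projected = project_to_subpopulations(inter, prof)
        stats = autocrine_conversion_stats(inter, projected)
        assert stats["any"] == stats["all"] == 0.0

    def test_mixed_fixture_matches_enumeration(self):
        edges = [edge("F", f"L{i}", "F", f"R{i}") for i in range(5)]
        inter = coarse(edges)
        rows = []
        # edges 0,1: cross-subpop only; 2: same only; 3: both; 4: no projection
        for i, (senders, receivers) in enumerate([
            (["Fa"], ["Fb"]), (["Fa"], ["Fb"]), (["Fa"], ["Fa"]),
            (["Fa"], ["Fa", "Fb"]), ([], []),
        ]):
            for s in senders:
                rows.append((s, "F", f"L{i}", 0.9, 1.0, True, True))
            for r in receivers:
                rows.append((r, "F", f"R{i}", 0.9, 1.0, False, False))
        prof = profile_from_rows(rows)
        projected = project_to_subpopulations(inter, prof)
        stats = autocrine_conversion_stats(inter, projected)
        assert stats["n_autocrine"] == 4
        assert stats["any"] == pytest.approx(3 / 4)
        assert stats["all"] == pytest.approx(2 / 4)


class TestPrognosticScore:
    def _profile(self, n_ligands, expr=None, subpop="S1"):
        rows = [(subpop, "F", f"L{i}", 1.0 if expr is None else expr[i],
                 1.0, True, True) for i in range(n_ligands)]
        return profile_from_rows(rows)

    def test_constant_z_gives_constant_score(self):
        prof = self._profile(4)
        table = prognostic_score(prof, {f"L{i}": 2.5 for i in range(4)})
        assert table.scores["S1"] == pytest.approx(2.5)

    def test_hand_weighted_average(self):
        prof = self._profile(3, expr=[2.0, 1.0, 1.0])
        z = {"L0": 1.0, "L1": -2.0, "L2": 0.0}
        table = prognostic_score(prof, z)
        assert table.scores["S1"] == pytest.approx((2 - 2 + 0) / 4)

    def test_too_few_ligands_excluded(self):
        prof = self._profile(2)
        table = prognostic_score(prof, {"L0": 1.0, "L1": 1.0})
        assert table.excluded["S1"] == "min_ligands"
        assert "S1" not in table.scores

    def test_convexity_bound_fuzzed(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            k = int(rng.integers(3, 8))
            expr = rng.uniform(0.1, 5, k)
            z = {f"L{i}": float(rng.normal()) for i in range(k)}
            prof = self._profile(k, expr=list(expr))
            score = prognostic_score(prof, z).scores["S1"]
            assert min(z.values()) - 1e-12 <= score <= max(z.values()) + 1e-12


class TestFilterPairs:
    def _projected(self, specs):
        return [ProjectedEdge(edge=edge(*s), parent_edge=edge(*s)) for s in specs]

    def test_negative_receptor_expression_removed(self):
        pes = self._projected([("Fa", "L1", "Fb", "R1")])
        prof = profile_from_rows([
            ("Fa", "F", "L1", 0.9, 1.0, True, True),
            ("Fb", "F", "R1", 0.8, -0.2, False, False),
        ])
        from lrnet.scoring import PrognosticTable, ProjectedInteractome
        table = PrognosticTable(scores={"Fa": 0.1, "Fb": 0.2}, excluded={})
        kept, dropped = filter_pairs_by_prognosis(
            ProjectedInteractome(edges=pes, expr_threshold=0.4), table, prof)
        assert kept == [] and dropped["receptor_expression"] == 1

    def test_closest_score_pair_selected(self):
        from lrnet.scoring import PrognosticTable, ProjectedInteractome
        pes = self._projected([("Fa", "L1", "Fb", "R1"),
                               ("Fc", "L1", "Fb", "R1")])
        prof = profile_from_rows([
            ("Fb", "F", "R1", 0.8, 0.5, False, False)])
        table = PrognosticTable(
            scores={"Fa": 0.7, "Fb": 0.2, "Fc": 0.3}, excluded={})
        kept, dropped = filter_pairs_by_prognosis(
            ProjectedInteractome(edges=pes, expr_threshold=0.4), table, prof)
        assert len(kept) == 1
        assert kept[0].edge[0].cell_type == "Fc"  # gap 0.1 beats 0.5
        assert dropped["not_argmin"] == 1

    def test_argmin_groups_match_enumeration(self):
        from lrnet.scoring import PrognosticTable, ProjectedInteractome
        rng = np.random.default_rng(5)
        subpops = [f"S{i}" for i in range(5)]
        scores = {s: float(rng.normal()) for s in subpops}
        prof = profile_from_rows(
            [(s, "F", g, 0.9, 0.5, True, True)
             for s in subpops for g in ("L0", "L1", "R0", "R1")])
        specs = []
        for g in range(2):
            for _ in range(4):
                a, b = rng.choice(subpops, 2, replace=False)
                specs.append((a, f"L{g}", b, f"R{g}"))
        pes = self._projected(specs)
        table = PrognosticTable(scores=scores, excluded={})
        kept, _ = filter_pairs_by_prognosis(
            ProjectedInteractome(edges=pes, expr_threshold=0.4), table, prof)
        # brute-force argmin per (ligand gene, receptor gene) group
        for g in range(2):
            members = [pe for pe in pes if pe.edge[0].gene == f"L{g}"]
            gaps = [abs(scores[pe.edge[0].cell_type] - scores[pe.edge[1].cell_type])
                    for pe in members]
            winners = {pe.edge for pe, gap in zip(members, gaps)
                       if gap == min(gaps)}
            assert {pe.edge for pe in kept if pe.edge[0].gene == f"L{g}"} == winners


class TestCrosstalk:
    def test_sample_sd_zscore(self):
        edges = ([edge("A", "L", "X", "R")] * 2 + [edge("A", "L", "Y", "R")] * 4
                 + [edge("A", "L", "Z", "R")] * 6)
        ct = crosstalk_matrix(edges)
        np.testing.assert_allclose(ct.standardized.loc["A"].to_numpy(),
                                   [-1.0, 0.0, 1.0])

    def test_constant_row_flagged_zero(self):
        edges = [edge("A", "L", "X", "R"), edge("A", "L", "Y", "R")]
        ct = crosstalk_matrix(edges)
        np.testing.assert_array_equal(ct.standardized.loc["A"].to_numpy(), 0.0)
        assert ct.constant_senders == ["A"]

    def test_proportion_mode(self):
        edges = [edge("A", "L", "X", "R")] * 3 + [edge("A", "L", "Y", "R")]
        ct = crosstalk_matrix(edges, mode="proportion")
        np.testing.assert_allclose(ct.standardized.loc["A"].to_numpy(),
                                   [0.75, 0.25])

    def test_single_receiver_rejected(self):
        with pytest.raises(ValueError):
            crosstalk_matrix([edge("A", "L", "X", "R")])


class TestDownstreamInfluence:
    def test_complete_graph_equal_weights_scores_one(self):
        v = np.array([1.0, -1.0, 2.0, 0.0])
        expr = pd.DataFrame([v, 2 * v, -v], index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(4)])
        ppi = [("a", "b"), ("b", "c"), ("a", "c")]
        score, info = downstream_influence("b", ["a", "b", "c"], ppi, expr)
        assert score == pytest.approx(1.0)

    def test_path_graph_centrality_ratio(self):
        g1 = np.array([1.0, -1, 1, -1])
        g2 = np.array([1.0, 1, -1, -1])
        g3 = np.array([1.0, -1, -1, 1])
        expr = pd.DataFrame([g1 + g2, g1, g1 + g3], index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(4)])
        ppi = [("a", "b"), ("b", "c")]
        score, info = downstream_influence("a", ["a", "b", "c"], ppi, expr)
        # path eigenvector is (1, sqrt(2), 1)/..; ends get c = 1/sqrt(2)
        assert info["centrality"] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert score == pytest.approx(np.log2(1 + 1 / np.sqrt(2)), abs=1e-9)

    def test_receptor_absent_scores_zero(self):
        expr = pd.DataFrame([[1.0, 2, 3]], index=["a"], columns=["s1", "s2", "s3"])
        score, info = downstream_influence("zzz", ["a"], [], expr)
        assert score == 0.0 and info["flag"] == "receptor_absent"

    def test_power_iteration_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(8)
        p = 40
        A = np.abs(rng.normal(size=(p, p)))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        x = _power_iteration(A)
        w, V = np.linalg.eigh(A)
        lead = np.abs(V[:, -1])
        cos = np.abs(x @ lead) / (np.linalg.norm(x) * np.linalg.norm(lead))
        assert cos > 1 - 1e-8
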