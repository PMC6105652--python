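"""Candidate-gene intersection, stagewise chi-square and enrichment tests."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from tristage.expression import SUBSET_LABELS
from tristage.fixtures import (
    load_table1,
    load_table2,
    table1_candidates,
    table1_patterns,
    table1_summary,
)
from tristage.integrate import (
    ContingencyTable2x2,
    build_subset_networks,
    emit_candidate_table,
    enrichment_test,
    intersect_candidates,
    parse_candidate_table,
    pattern_to_subsets,
    stagewise_hub_chisq,
)
from tristage.profiles import ModelProfile, ProfileAssignment


class TestPatternToSubsets:
    @pytest.mark.parametrize(
        "levels,expected",
        [
            ((0, 1, 1), {"MvCup", "EvCup"}),
            ((0, 0, 0), set()),
            ((0, -1, -2), {"MvCdown", "EvCdown", "EvMdown"}),
            ((0, 2, 1), {"MvCup", "EvCup", "EvMdown"}),
            ((0, -2, -1), {"MvCdown", "EvCdown", "EvMup"}),
            ((0, 0, 1), {"EvCup", "EvMup"}),
        ],
    )
    def test_sign_logic(self, levels, expected):
        assert pattern_to_subsets(levels) == expected

    def test_non_three_point_design_rejected(self):
        with pytest.raises(ValueError):
            pattern_to_subsets((0, 1))


class TestBuildSubsetNetworks:
    def test_induced_subgraphs(self):
        graph = nx.complete_graph(["a", "b", "c"])
        nets = build_subset_networks(
            graph, {"MvCup": {"a", "b"}, "EvCup": set(), "EvMdown": set(graph.nodes)}
        )
        assert set(map(frozenset, nets["MvCup"].edges)) == {frozenset("ab")}
        assert nets["EvCup"].number_of_nodes() == 0
        assert nets["EvMdown"].number_of_edges() == 3


def _toy_layers():
    profiles = [ModelProfile(0, (0, 0, 0)), ModelProfile(1, (0, 1, 1))]
    assignments = [
        ProfileAssignment("hub_deg", 1, 0.0),
        ProfileAssignment("weak_hub", 1, 0.0),
        ProfileAssignment("not_hub", 1, 0.0),
        ProfileAssignment("flat", 0, 0.0),
    ]
    hub_scores = {
        "MvCup": {"hub_deg": 24, "weak_hub": 9},
        "EvCup": {"hub_deg": 24},
    }
    deg_sets = {label: set() for label in SUBSET_LABELS}
    deg_sets["MvCup"] = {"hub_deg", "weak_hub", "not_hub"}
    deg_sets["EvCup"] = {"hub_deg"}
    return profiles, assignments, hub_scores, deg_sets


class TestIntersectCandidates:
    def test_requires_hub_and_deg_in_a_concordant_subset(self):
        profiles, assignments, hub_scores, deg_sets = _toy_layers()
        cands = intersect_candidates(assignments, [1], profiles, hub_scores, deg_sets)
        assert {c.gene for c in cands} == {"hub_deg"}
        (c,) = cands
        assert c.subset_scores == [("MvCup", 24), ("EvCup", 24)]

    def test_mcc_boundary_excludes_nine(self):
        profiles, assignments, hub_scores, deg_sets = _toy_layers()
        cands = intersect_candidates(assignments, [1], profiles, hub_scores, deg_sets, min_mcc=10)
        assert "weak_hub" not in {c.gene for c in cands}
        cands9 = intersect_candidates(assignments, [1], profiles, hub_scores, deg_sets, min_mcc=9)
        assert "weak_hub" in {c.gene for c in cands9}

    def test_lowering_min_mcc_is_monotone(self):
        profiles, assignments, hub_scores, deg_sets = _toy_layers()
        strict = {c.gene for c in intersect_candidates(assignments, [1], profiles, hub_scores, deg_sets, min_mcc=20)}
        loose = {c.gene for c in intersect_candidates(assignments, [1], profiles, hub_scores, deg_sets, min_mcc=5)}
        assert strict <= loose

    def test_require_all_mode_demands_every_concordant_subset(self):
        profiles, assignments, hub_scores, deg_sets = _toy_layers()
        deg_sets["EvCup"] = set()  # hub_deg no longer a DEG in EvCup
        any_mode = intersect_candidates(assignments, [1], profiles, hub_scores, deg_sets)
        all_mode = intersect_candidates(
            assignments, [1], profiles, hub_scores, deg_sets, require_all=True
        )
        assert {c.gene for c in any_mode} == {"hub_deg"}
        assert all_mode == []

    def test_hub_without_score_is_a_consistency_error(self):
        profiles, assignments, hub_scores, deg_sets = _toy_layers()
        with pytest.raises(ValueError, match="without MCC"):
            intersect_candidates(
                assignments, [1], profiles, hub_scores, deg_sets,
                hub_sets={"MvCup": {"ghost"}},
            )


class TestCandidateTable:
    def test_empty_candidates_give_header_only(self, tmp_path):
        frame = emit_candidate_table([], tmp_path / "cands.tsv")
        assert frame.empty
        assert (tmp_path / "cands.tsv").read_text().startswith("gene\t")

    def test_fixture_round_trip_is_identity(self, tmp_path):
        candidates = table1_candidates()
        for c in candidates:  # drop fixture-only annotation before comparing
            c.go_terms = c.pathways = None
        path = tmp_path / "table.tsv"
        emit_candidate_table(candidates, path)
        back = parse_candidate_table(path)
        assert sorted(back, key=lambda c: c.gene) == sorted(candidates, key=lambda c: c.gene)

    def test_rows_sorted_by_max_mcc_within_profile(self):
        frame = emit_candidate_table(table1_candidates())
        for _, group in frame.groupby("profile"):
            maxima = [max(int(x) for x in s.split(",")) for s in group["mcc_scores"]]
            assert maxima == sorted(maxima, reverse=True)


class TestTable1Fixture:
    def test_bookkeeping_counts(self):
        summary = table1_summary()
        assert summary["total"] == 63
        assert summary["profile_11"] == 24
        assert summary["mvc_entries"] == 35
        assert summary["evm_entries"] == 19
        assert summary["without_evc"] == 19
        assert summary["without_evc_pct"] == pytest.approx(30.16, abs=0.01)
        assert summary["drmp_significant"] == 7

    def test_every_row_concordant_with_its_profile_pattern(self):
        patterns = table1_patterns()
        for c in table1_candidates():
            concordant = pattern_to_subsets(patterns[c.profile_id])
            assert set(c.subsets) <= concordant, c.gene

    def test_all_mcc_scores_at_least_ten(self):
        assert all(
            mcc >= 10 for c in table1_candidates() for _, mcc in c.subset_scores
        )

    def test_unique_genes_and_seven_profiles(self):
        frame = load_table1()
        assert frame["gene"].is_unique
        assert frame["profile"].nunique() == 7


class TestTable2Fixture:
    def test_pathways_in_cancer_leads_with_13_genes(self):
        frame = load_table2()
        top = frame.loc[frame["n_genes"].idxmax()]
        assert top["definition"] == "Pathways in cancer"
        assert top["n_genes"] == 13
        assert len(top["genes"].split(",")) == 13

    def test_listed_genes_are_candidate_genes(self):
        candidates = {c.gene for c in table1_candidates()}
        frame = load_table2()
        for genes in frame["genes"]:
            assert set(genes.split(",")) <= candidates


class TestStagewiseChisq:
    def test_reproduces_printed_early_vs_advanced_contrast(self):
        chi2, p = stagewise_hub_chisq(ContingencyTable2x2(35, 2339, 19, 2539))
        assert round(chi2, 2) == 6.08
        assert p < 0.025

    def test_identical_proportions_give_zero(self):
        chi2, p = stagewise_hub_chisq(ContingencyTable2x2(10, 100, 10, 100))
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        a, b, c, d = 20, 100, 5, 100
        chi2, _ = stagewise_hub_chisq(ContingencyTable2x2(a, b, c, d))
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(expected)

    def test_row_and_column_swap_invariance(self):
        base, _ = stagewise_hub_chisq(ContingencyTable2x2(35, 2339, 19, 2539))
        swapped, _ = stagewise_hub_chisq(ContingencyTable2x2(2539, 19, 2339, 35))
        assert swapped == pytest.approx(base)

    def test_zero_marginal_is_an_error(self):
        with pytest.raises(ValueError, match="marginal"):
            stagewise_hub_chisq(ContingencyTable2x2(0, 0, 5, 5))

    def test_yates_correction_shrinks_the_statistic(self):
        table = ContingencyTable2x2(35, 2339, 19, 2539)
        assert stagewise_hub_chisq(table, yates=True)[0] < stagewise_hub_chisq(table)[0]


class TestEnrichment:
    BACKGROUND = {f"g{i}" for i in range(20)}
    TERM = {f"g{i}" for i in range(5)}
    QUERY = {"g0", "g1", "g2", "g3", "g10", "g11"}  # overlap 4

    def test_zero_overlap_gives_one_for_all_methods(self):
        query = {"g10", "g11"}
        for method in ("fisher", "hypergeometric", "ease"):
            p = enrichment_test(query, {"t": self.TERM}, self.BACKGROUND, method)["t"]
            assert p == pytest.approx(1.0)

    def test_ease_with_single_overlap_equals_no_overlap(self):
        query = {"g0", "g10"}
        p = enrichment_test(query, {"t": self.TERM}, self.BACKGROUND, "ease")["t"]
        assert p == pytest.approx(1.0)

    def test_hypergeometric_matches_exhaustive_enumeration(self):
        p = enrichment_test(self.QUERY, {"t": self.TERM}, self.BACKGROUND, "hypergeometric")["t"]
        # oracle: count 6-subsets of the 20-gene background with overlap >= 4
        hits = total = 0
        for subset in combinations(sorted(self.BACKGROUND), 6):
            total += 1
            if len(set(subset) & self.TERM) >= 4:
                hits += 1
        assert p == pytest.approx(hits / total)

    def test_fisher_matches_scipy_direct_call(self):
        p = enrichment_test(self.QUERY, {"t": self.TERM}, self.BACKGROUND, "fisher")["t"]
        expected = stats.fisher_exact([[4, 1], [2, 13]], alternative="greater")[1]
        assert p == pytest.approx(expected)

    def test_ease_never_smaller_than_fisher(self, rng):
        genes = [f"g{i}" for i in range(30)]
        background = set(genes)
        annotation = {
            f"t{j}": set(rng.choice(genes, size=rng.integers(3, 12), replace=False))
            for j in range(10)
        }
        query = set(rng.choice(genes, size=8, replace=False))
        fisher = enrichment_test(query, annotation, background, "fisher")
        ease = enrichment_test(query, annotation, background, "ease")
        for term in annotation:
            assert ease[term] >= fisher[term] - 1e-12

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test({"zz"}, {"t": self.TERM}, self.BACKGROUND)
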