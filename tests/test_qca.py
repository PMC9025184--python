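"""The fsQCA engine: set measures, truth table, Quine-McCluskey, the three
solutions and their structural relations."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest

import helpers
from likertqca.qca import (ABSENT, FREE, PRESENT, Implicant, QCAError,
                           Solution, analyze_outcome, build_truth_table,
                           complex_solution, consistency, coverage,
                           intermediate_solution, parsimonious_solution,
                           quine_mccluskey, recipe_membership,
                           reverse_expectations, solution_matrix_text,
                           solution_statistics)

ABC = ("A", "B", "C")


def imp(label, conds=ABC):
    return Implicant.from_label(label, conds)


def states(implicants):
    return sorted(r.states for r in implicants)


def make_solution(cover, stype="complex", outcome="USE", conds=ABC):
    s = Solution(stype, outcome, conds)
    s.recipes = list(cover)
    return s


class TestImplicant:
    @pytest.mark.parametrize("label", ["A", "~A", "A*~B", "~A*B*~C", "1"])
    def test_label_round_trip(self, label):
        assert imp(label).label == label

    def test_tautology(self):
        t = imp("1")
        assert t.is_tautology and t.n_literals == 0

    def test_subsumption(self):
        assert imp("A").subsumes(imp("A*~B"))
        assert not imp("A*~B").subsumes(imp("A"))
        assert imp("1").subsumes(imp("A*B*C"))

    def test_unknown_condition_rejected(self):
        with pytest.raises(QCAError, match="unknown condition"):
            imp("A*Z")


class TestRecipeMembership:
    def setup_method(self):
        self.m = pd.DataFrame({"A": [0.3], "B": [0.8], "C": [0.6]})

    def test_conjunction_takes_min(self):
        assert recipe_membership(imp("A*B"), self.m)[0] == pytest.approx(0.3)

    def test_negated_literal_complements_first(self):
        assert recipe_membership(imp("~A*B"), self.m)[0] == pytest.approx(0.7)

    def test_tautology_scores_one(self):
        assert recipe_membership(imp("1"), self.m)[0] == 1.0


class TestConsistencyCoverage:
    def test_fuzzy_subset_is_fully_consistent(self):
        assert consistency([0.2, 0.4], [0.5, 0.4]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # sum min = 0.4 + 0.6 = 1.0; sum mZ = 1.4; sum mY = 1.0
        assert consistency([0.8, 0.6], [0.4, 0.6]) == pytest.approx(1.0 / 1.4)
        assert coverage([0.8, 0.6], [0.4, 0.6]) == pytest.approx(1.0)

    def test_zero_vectors(self):
        assert consistency([0.5, 0.5], [0.0, 0.0]) == 0.0
        assert coverage([0.0, 0.0], [0.5, 0.5]) == 0.0
        with pytest.raises(QCAError, match="undefined"):
            consistency([0.0, 0.0], [0.5, 0.5])
        with pytest.raises(QCAError, match="undefined"):
            coverage([0.5, 0.5], [0.0, 0.0])

    def test_duality_consistency_is_swapped_coverage(self, rng):
        for _ in range(25):
            mz, my = rng.random(30), rng.random(30)
            assert consistency(mz, my) == coverage(my, mz)

    def test_matches_direct_summation(self, rng):
        mz, my = rng.random(50), rng.random(50)
        assert consistency(mz, my) == pytest.approx(
            helpers.direct_consistency(mz, my), abs=1e-15)
        assert coverage(mz, my) == pytest.approx(
            helpers.direct_coverage(mz, my), abs=1e-15)


class TestTruthTable:
    def test_seven_conditions_enumerate_128_rows(self, rng):
        m = pd.DataFrame(rng.random((40, 7)),
                         columns=[f"X{i}" for i in range(7)])
        table = build_truth_table(m, rng.random(40))
        assert len(table.rows) == 128

    def test_crisp_case_lands_in_its_own_corner(self):
        m = pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0]})
        table = build_truth_table(m, np.array([1.0, 0.0]))
        counts = {r.configuration: r.n_best_fit for r in table.rows}
        assert counts == {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 0}

    def test_crossover_case_counts_nowhere(self):
        m = pd.DataFrame({"A": [0.5, 0.9], "B": [0.8, 0.9]})
        table = build_truth_table(m, np.array([1.0, 1.0]))
        assert table.n_ambiguous == 1
        assert sum(r.n_best_fit for r in table.rows) == 1

    def test_perfectly_planted_rows_reach_full_consistency(self, rng):
        # crisp conditions; outcome = 1 exactly on ~A rows
        A = (rng.random(200) > 0.5).astype(float)
        B = (rng.random(200) > 0.5).astype(float)
        m = pd.DataFrame({"A": A, "B": B})
        y = 1.0 - A
        table = build_truth_table(m, y)
        for row in table.rows:
            if row.configuration[0] == 0 and row.n_best_fit > 0:
                assert row.row_consistency == pytest.approx(1.0)
                assert row.status == "positive"

    def test_contradictory_observed_rows_are_negative(self):
        m = pd.DataFrame({"A": [0.9] * 10, "B": [0.9] * 10})
        y = np.array([1.0] * 5 + [0.0] * 5)  # half the cases contradict
        table = build_truth_table(m, y, consistency_cutoff=0.8)
        row = {r.configuration: r for r in table.rows}[(1, 1)]
        assert row.status == "negative"


class TestQuineMcCluskey:
    def test_single_merge(self):
        _, cover = quine_mccluskey([(1, 1), (1, 0)], conditions=("A", "B"))
        assert [r.label for r in cover] == ["A"]

    def test_complete_function_collapses_to_tautology(self):
        mts = list(itertools.product((0, 1), repeat=3))
        _, cover = quine_mccluskey(mts, conditions=ABC)
        assert [r.label for r in cover] == ["1"]

    def test_overlapping_dont_cares_rejected(self):
        with pytest.raises(QCAError, match="overlap"):
            quine_mccluskey([(1, 0)], [(1, 0)], ("A", "B"))

    def test_four_condition_instance_matches_exhaustive_search(self):
        conds = ("A", "B", "C", "D")
        mts = [(1, 1, 0, 0), (1, 1, 0, 1), (0, 1, 1, 0), (1, 0, 0, 0)]
        dcs = [(1, 1, 1, 0), (0, 1, 1, 1), (1, 0, 0, 1)]
        _, cover = quine_mccluskey(mts, dcs, conds)
        (_, oracle) = helpers.brute_force_min_cover(mts, dcs, 4)
        assert states(cover) == sorted(tuple(c) for c in oracle)

    def test_random_tables_match_exhaustive_optimum(self):
        r = random.Random(2024)
        for _ in range(40):
            k = r.randint(2, 4)
            mts, dcs = helpers.random_truth_table(r, k)
            if not mts:
                continue
            _, cover = quine_mccluskey(mts, dcs)
            cost, oracle = helpers.brute_force_min_cover(mts, dcs, k)
            got = (len(cover), sum(c.n_literals for c in cover),
                   tuple(sorted(helpers.cube_key(c.states) for c in cover)))
            assert got == cost

    def test_cover_never_touches_forbidden_configurations(self):
        r = random.Random(7)
        for _ in range(30):
            k = 5
            mts, dcs = helpers.random_truth_table(r, k)
            if not mts:
                continue
            _, cover = quine_mccluskey(mts, dcs)
            allowed = set(mts) | set(dcs)
            for config in itertools.product((0, 1), repeat=k):
                covered = any(c.covers(config) for c in cover)
                if config in mts:
                    assert covered
                elif config not in allowed:
                    assert not covered


class TestSolutions:
    def _table(self, positives, remainders, conds=ABC):
        rows = {c: "negative" for c in itertools.product((0, 1), repeat=len(conds))}
        rows.update({c: "positive" for c in positives})
        rows.update({c: "remainder" for c in remainders})
        from likertqca.qca import TruthTable, TruthTableRow
        return TruthTable(
            conds,
            [TruthTableRow(c, 1 if s == "positive" else 0,
                           1.0 if s == "positive" else 0.0, s)
             for c, s in rows.items()],
            n_cases=10, n_ambiguous=0, frequency_cutoff=1,
            consistency_cutoff=0.8)

    def test_single_positive_row_is_its_own_complex_solution(self):
        table = self._table([(1, 0, 1)], [])
        cs = complex_solution(table)
        assert cs.labels == ["A*~B*C"]

    def test_adjacent_positive_rows_merge(self):
        table = self._table([(1, 1, 0), (1, 1, 1)], [])
        cs = complex_solution(table)
        assert cs.labels == ["A*B"]

    def test_without_remainders_parsimonious_equals_complex(self):
        table = self._table([(1, 1, 0), (0, 1, 0)], [])
        assert states(parsimonious_solution(table).recipes) == states(
            complex_solution(table).recipes)

    def test_every_complex_recipe_is_subsumed_by_a_parsimonious_one(self):
        r = random.Random(5)
        for _ in range(30):
            mts, dcs = helpers.random_truth_table(r, 3)
            if not mts:
                continue
            table = self._table(mts, dcs)
            cs, ps = complex_solution(table), parsimonious_solution(table)
            for c in cs.recipes:
                assert any(p.subsumes(c) for p in ps.recipes)

    def test_no_positive_rows_yield_empty_solution(self):
        table = self._table([], [(0, 0, 0)])
        assert complex_solution(table).is_empty
        assert parsimonious_solution(table).is_empty


class TestIntermediateSolution:
    def test_worked_three_condition_example(self):
        """Complex recipe A*B*~C generalized to parsimonious A; with B's
        presence expected to contribute and C unconstrained, only B is
        added back: the intermediate recipe is A*B."""
        cs = make_solution([imp("A*B*~C")])
        ps = make_solution([imp("A")], "parsimonious")
        inter = intermediate_solution(
            cs, ps, {"A": "present", "B": "present", "C": "either"})
        assert inter.labels == ["A*B"]

    def test_all_either_expectations_reduce_to_parsimonious(self):
        cs = make_solution([imp("A*B*~C")])
        ps = make_solution([imp("A")], "parsimonious")
        inter = intermediate_solution(cs, ps, dict.fromkeys(ABC, "either"))
        assert states(inter.recipes) == states(ps.recipes)

    def test_no_remainders_used_means_intermediate_equals_complex(self):
        cover = [imp("A*B"), imp("~A*~C")]
        cs = make_solution(cover)
        ps = make_solution(cover, "parsimonious")
        inter = intermediate_solution(cs, ps, dict.fromkeys(ABC, "present"))
        assert states(inter.recipes) == states(cover)

    def test_contradicting_literal_stays_dropped(self):
        cs = make_solution([imp("A*~B")])
        ps = make_solution([imp("A")], "parsimonious")
        inter = intermediate_solution(
            cs, ps, {"A": "present", "B": "present", "C": "either"})
        assert inter.labels == ["A"]

    def test_missing_expectation_for_used_condition_rejected(self):
        cs = make_solution([imp("A*~B")])
        ps = make_solution([imp("A")], "parsimonious")
        with pytest.raises(QCAError, match="expectation missing"):
            intermediate_solution(cs, ps, {"A": "present"})

    def test_reverse_expectations_flips_directions(self):
        exp = {"A": "present", "B": "absent", "C": "either"}
        assert reverse_expectations(exp) == {
            "A": "absent", "B": "present", "C": "either"}

    def test_recipes_sit_between_complex_and_parsimonious(self):
        r = random.Random(11)
        for _ in range(40):
            mts, dcs = helpers.random_truth_table(r, 3)
            if not mts:
                continue
            table = TestSolutions()._table(mts, dcs)
            cs, ps = complex_solution(table), parsimonious_solution(table)
            exp = {c: r.choice(["present", "absent", "either"]) for c in ABC}
            inter = intermediate_solution(cs, ps, exp)
            for i_rec in inter.recipes:
                assert any(p.subsumes(i_rec) for p in ps.recipes)
                assert any(i_rec.subsumes(c) for c in cs.recipes) or any(
                    p.states == i_rec.states for p in ps.recipes)


class TestSolutionStatistics:
    def test_single_recipe_solution_inherits_its_stats(self, rng):
        m = pd.DataFrame({"A": rng.random(40), "B": rng.random(40),
                          "C": rng.random(40)})
        y = rng.random(40)
        sol = make_solution([imp("A*~B")])
        solution_statistics(sol, m, y)
        assert sol.solution_consistency == pytest.approx(sol.recipe_consistency[0])
        assert sol.solution_coverage == pytest.approx(sol.recipe_coverage[0])

    def test_disjoint_crisp_recipes_add_their_coverages(self):
        m = pd.DataFrame({
            "A": [1.0, 1.0, 0.0, 0.0, 0.0],
            "B": [0.0, 0.0, 1.0, 0.0, 0.0],
            "C": [0.0] * 5,
        })
        y = np.array([1.0, 1.0, 1.0, 1.0, 0.0])
        sol = make_solution([imp("A"), imp("B")])
        solution_statistics(sol, m, y)
        assert sol.solution_coverage == pytest.approx(
            sum(sol.recipe_coverage))

    def test_union_dominates_every_recipe_coverage(self, rng):
        m = pd.DataFrame({"A": rng.random(60), "B": rng.random(60),
                          "C": rng.random(60)})
        y = rng.random(60)
        sol = make_solution([imp("A"), imp("~B*C")])
        solution_statistics(sol, m, y)
        assert sol.solution_coverage >= max(sol.recipe_coverage) - 1e-12


class TestAnalyzeOutcome:
    def test_mirrored_crisp_data_yield_mirrored_solutions(self, rng):
        n = 300
        m = pd.DataFrame({
            "A": (rng.random(n) > 0.5).astype(float),
            "B": (rng.random(n) > 0.5).astype(float),
        })
        y = m["A"].to_numpy()  # USE exactly when A present
        exp = {"A": "present", "B": "either"}
        use = analyze_outcome(m, y, "USE", exp)
        nonuse = analyze_outcome(m, y, "~USE", exp)
        assert use.parsimonious.labels == ["A"]
        assert nonuse.parsimonious.labels == ["~A"]

    def test_all_zero_outcome_gives_empty_solutions(self, rng):
        m = pd.DataFrame({"A": rng.random(50), "B": rng.random(50)})
        res = analyze_outcome(m, np.zeros(50), "USE",
                              {"A": "either", "B": "either"})
        assert res.complex.is_empty and res.parsimonious.is_empty

    def test_core_conditions_come_from_parsimonious_solution(self, rng):
        n = 400
        A = (rng.random(n) > 0.5).astype(float)
        B = (rng.random(n) > 0.5).astype(float)
        m = pd.DataFrame({"A": A, "B": B})
        y = A  # driven by A only
        res = analyze_outcome(m, y, "USE", {"A": "present", "B": "either"})
        assert "A" in res.core_conditions
        assert "B" not in res.core_conditions

    def test_solution_matrix_rendering(self, rng):
        m = pd.DataFrame({"A": (rng.random(99) > 0.5).astype(float),
                          "B": (rng.random(99) > 0.5).astype(float)})
        res = analyze_outcome(m, m["A"].to_numpy(), "USE",
                              {"A": "present", "B": "either"})
        text = solution_matrix_text(res.parsimonious)
        assert "•" in text and "cons" in text and "cov" in text
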