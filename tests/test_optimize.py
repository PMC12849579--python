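import dataclasses

import numpy as np
import pytest

from qpmsi import (
    RelationshipMatrix,
    SelectionSpec,
    StandardizedTraits,
    brute_force_select,
    build_problem,
    solve_lpmsi,
    solve_qpmsi,
)
from qpmsi.errors import CapExceeded
from qpmsi.optimize import CONSTRAINT_TOL

from conftest import random_instance, random_psd_grm, random_scores


def _problem(y_vals, G, s, k=1.0, R=None):
    y_vals = np.atleast_2d(np.asarray(y_vals, dtype=float))
    if y_vals.shape[0] == 1:
        y_vals = y_vals.T
    n, p0 = y_vals.shape
    ids = tuple(f"g{i}" for i in range(n))
    y = StandardizedTraits(ids, y_vals, tuple(f"T{j}" for j in range(p0)))
    spec = SelectionSpec(s=s, k=k, R=tuple(R) if R else ())
    return build_problem(y, RelationshipMatrix(ids, np.asarray(G, float)), spec)


class TestSolveQpmsi:
    def test_identity_grm_reduces_to_top_s(self):
        # constant penalty: x'Ix = s for every subset
        prob = _problem([1.0, 0.9, 0.1], np.eye(3), s=2, k=1.0)
        res = solve_qpmsi(prob)
        assert res.selected_ids == ("g0", "g1")
        assert res.objective == pytest.approx(1.9 - 2.0)
        assert res.merit_term == pytest.approx(1.9)
        assert res.penalty_term == pytest.approx(2.0)

    def test_relatedness_penalty_flips_choice(self):
        G = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        prob = _problem([1.0, 0.9, 0.1], G, s=2, k=1.0)
        res = solve_qpmsi(prob)
        assert res.selected_ids == ("g0", "g2")
        assert res.objective == pytest.approx(1.1 - 2.0)

    def test_unsatisfiable_gain_constraint_reports_infeasible(self):
        prob = _problem([0.0, 0.0, 0.0], np.eye(3), s=2, R=(50.0,))
        res = solve_qpmsi(prob)
        assert res.status == "infeasible"
        assert "T0" in res.message
        assert res.selected_ids == ()

    @pytest.mark.parametrize("method", ["exact_milp", "exact_milp_mccormick"])
    def test_result_invariants_on_random_instances(self, rng, method):
        for _ in range(15):
            prob = random_instance(rng)
            res = solve_qpmsi(prob, method)
            if res.status == "infeasible":
                continue
            assert res.x.sum() == prob.spec.s
            sums = prob.constraint_matrix[res.selected_indices].sum(axis=0)
            assert np.all(sums >= prob.l.l - CONSTRAINT_TOL)
            assert res.objective == pytest.approx(
                res.merit_term - prob.spec.k * res.penalty_term, abs=1e-6
            )

    def test_local_search_feasible_and_labeled_heuristic(self, rng):
        prob = random_instance(rng, n=20, s=5, k=1.0, p0=2, R=(0.0, 0.0))
        res = solve_qpmsi(prob, "local_search", seed=7)
        assert res.status == "heuristic"
        assert res.x.sum() == 5
        exact = solve_qpmsi(prob)
        assert res.objective <= exact.objective + 1e-9

    def test_local_search_seed_determinism(self, rng):
        prob = random_instance(rng, n=15, s=4)
        a = solve_qpmsi(prob, "local_search", seed=3)
        b = solve_qpmsi(prob, "local_search", seed=3)
        assert a.selected_ids == b.selected_ids


class TestSolveLpmsi:
    def test_top_s_fast_path(self):
        y = np.array([[1.0, 0.9], [0.6, 0.6], [0.2, 0.1]])
        prob = _problem(y, np.eye(3), s=2, R=(0.0, 0.0))
        res = solve_lpmsi(prob)
        assert res.solver == "top-s"
        assert res.selected_ids == ("g0", "g1")
        assert res.objective == pytest.approx(3.1)

    def test_gain_constraint_overrides_top_s(self):
        # subset {g0,g1} maximizes merit but violates the trait-2 gain
        y = np.array([[1.0, 0.0], [0.9, 0.0], [0.1, 2.0]])
        prob = _problem(y, np.eye(3), s=2, R=(0.0, 50.0))  # l = (0, 1)
        res = solve_lpmsi(prob)
        assert res.selected_ids == ("g0", "g2")
        assert res.objective == pytest.approx(3.1)

    def test_k_plays_no_role(self, rng):
        y = random_scores(rng, 10, 2)
        G = random_psd_grm(rng, 10)
        results = [
            solve_lpmsi(build_problem(y, G, SelectionSpec(s=3, k=k, R=(0.0, 0.0))))
            for k in (0.0, 1.0, 5.0)
        ]
        assert len({r.selected_ids for r in results}) == 1

    def test_fast_path_agrees_with_explicit_lp(self, rng):
        for _ in range(10):
            prob = random_instance(rng, R=(0.0,), p0=1)
            fast = solve_lpmsi(prob)
            lp = brute_force_select(prob, "lpmsi")
            if fast.status == "optimal" and lp.status == "optimal":
                assert fast.objective == pytest.approx(lp.objective, abs=1e-9)


class TestBruteForce:
    def test_subset_count_matches_binomial(self, rng):
        # C(5,2) = 10 subsets; verified indirectly: the maximizer over an
        # injective objective equals the max over all 10 enumerated values
        merit = np.array([5.0, 3.0, 2.0, 1.0, 0.5])
        prob = _problem(merit, np.eye(5), s=2, k=0.0)
        res = brute_force_select(prob, "lpmsi")
        assert res.selected_ids == ("g0", "g1")

    def test_matches_exact_milp_on_flip_example(self):
        G = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        prob = _problem([1.0, 0.9, 0.1], G, s=2, k=1.0)
        assert brute_force_select(prob).objective == pytest.approx(
            solve_qpmsi(prob).objective
        )

    def test_all_subsets_infeasible(self):
        prob = _problem([0.1, 0.2, 0.3], np.eye(3), s=2, R=(100.0,))
        assert brute_force_select(prob).status == "infeasible"

    def test_cap_exceeded(self, rng):
        prob = random_instance(rng, n=15, s=5)
        with pytest.raises(CapExceeded):
            brute_force_select(prob, cap=10)

    def test_lexicographic_tie_break(self):
        # two optimal sets {g0,g1} and {g0,g2}; lexicographically smaller wins
        prob = _problem([1.0, 0.5, 0.5], np.eye(3), s=2, k=0.0)
        assert brute_force_select(prob, "lpmsi").selected_ids == ("g0", "g1")


class TestStructuralProperties:
    def test_k_zero_qpmsi_equals_lpmsi_objective(self, rng):
        for _ in range(10):
            prob = random_instance(rng, k=0.0)
            q = solve_qpmsi(prob)
            l = solve_lpmsi(prob)
            assert q.status == l.status
            if q.status == "optimal":
                assert q.merit_term == pytest.approx(l.merit_term, abs=1e-6)

    def test_constant_penalty_collapse(self, rng):
        # G = cI makes the penalty c*s for every subset: same set as LPMSI
        for c in (0.5, 2.0):
            prob = random_instance(rng, n=10, s=3, k=1.5, p0=2, R=(0.0, 0.0))
            prob = dataclasses.replace(
                prob, G=RelationshipMatrix(prob.G.genotype_ids, c * np.eye(10))
            )
            q = brute_force_select(prob, "qpmsi")
            l = brute_force_select(prob, "lpmsi")
            if q.status == l.status == "optimal":
                assert q.merit_term == pytest.approx(l.merit_term, abs=1e-9)

    def test_scalarization_penalty_and_merit_ordering(self, rng):
        # LPMSI's set is QPMSI-feasible, hence pen_Q <= pen_L and merit_Q <= merit_L
        checked = 0
        while checked < 20:
            prob = random_instance(rng)
            if prob.spec.k == 0.0:
                continue
            q, l = solve_qpmsi(prob), solve_lpmsi(prob)
            if q.status != "optimal" or l.status != "optimal":
                continue
            assert q.penalty_term <= l.penalty_term + 1e-6
            assert q.merit_term <= l.merit_term + 1e-6
            checked += 1

    def test_k_monotonicity(self, rng):
        for _ in range(5):
            base = random_instance(rng, n=12, s=4, k=0.0)
            pens, merits = [], []
            for k in (0.0, 0.25, 0.5, 1.0, 2.0, 4.0):
                prob = dataclasses.replace(
                    base, spec=dataclasses.replace(base.spec, k=k)
                )
                res = solve_qpmsi(prob)
                if res.status != "optimal":
                    break
                pens.append(res.penalty_term)
                merits.append(res.merit_term)
            for a, b in zip(pens, pens[1:]):
                assert b <= a + 1e-6
            for a, b in zip(merits, merits[1:]):
                assert b <= a + 1e-6
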