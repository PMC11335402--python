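import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import jawscape as jw
from oracles import brute_goldberg, brute_pareto_front

TOY = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0], [1.0, 1.0]])


class TestParetoFront:
    def test_toy_front_by_inspection(self):
        obj = jw.ObjectiveSet(TOY, senses=("max", "max"))
        mask = jw.pareto_front(obj)
        np.testing.assert_array_equal(mask, [True, True, True, False])

    def test_all_identical_share_front(self):
        obj = jw.ObjectiveSet(np.ones((5, 2)), senses=("max", "min"))
        assert jw.pareto_front(obj).all()

    def test_min_sense_orientation(self):
        obj = jw.ObjectiveSet(TOY, senses=("min", "min"))
        mask = jw.pareto_front(obj)
        np.testing.assert_array_equal(mask, [False, False, False, True])

    @pytest.mark.parametrize("k", [2, 3])
    def test_agrees_with_brute_oracle(self, k):
        """20 seeded random instances per dimensionality: exact agreement
        with the O(n^2) pairwise-dominance oracle."""
        rng = np.random.default_rng(100 + k)
        for _ in range(20):
            n = int(rng.integers(20, 201))
            pts = rng.uniform(size=(n, k))
            if rng.random() < 0.3:  # force ties sometimes
                pts = np.round(pts, 1)
            obj = jw.ObjectiveSet(pts, senses=("max",) * k)
            np.testing.assert_array_equal(jw.pareto_front(obj), brute_pareto_front(pts))


class TestGoldbergRank:
    def test_hand_peeled_five_points(self):
        """Fronts {(1,3),(2,2),(3,1)}, {(1,1)}, {(0,0)} rank 1, 0.5, 0."""
        pts = np.vstack([TOY, [0.0, 0.0]])
        surf = jw.goldberg_rank(jw.ObjectiveSet(pts, senses=("max", "max")))
        np.testing.assert_array_equal(surf.front_index, [1, 1, 1, 2, 3])
        np.testing.assert_allclose(surf.rank, [1.0, 1.0, 1.0, 0.5, 0.0])

    def test_single_point(self):
        surf = jw.goldberg_rank(jw.ObjectiveSet(np.array([[1.0, 2.0]]), senses=("max", "max")))
        assert surf.rank[0] == 1.0 and surf.front_index[0] == 1

    def test_adding_dominated_point_preserves_fronts(self):
        base = jw.goldberg_rank(jw.ObjectiveSet(TOY, senses=("max", "max")))
        extended = jw.goldberg_rank(
            jw.ObjectiveSet(np.vstack([TOY, [-1.0, -1.0]]), senses=("max", "max"))
        )
        np.testing.assert_array_equal(extended.front_index[:4], base.front_index)

    def test_invalid_cells_excluded(self):
        valid = np.array([True, True, False, True])
        surf = jw.goldberg_rank(jw.ObjectiveSet(TOY, senses=("max", "max"), valid_mask=valid))
        assert surf.front_index[2] == 0
        assert np.isnan(surf.rank[2])
        assert surf.front_index[3] == 2  # (1,1) now peels second

    @pytest.mark.parametrize("k", [2, 3])
    def test_full_equality_with_brute_peeling(self, k):
        """Random instances up to 500 points: front indices and ranks match
        the brute-force iterative-peeling oracle exactly."""
        rng = np.random.default_rng(7 * k)
        for _ in range(6):
            n = int(rng.integers(50, 501))
            pts = np.round(rng.uniform(size=(n, k)), 2)
            surf = jw.goldberg_rank(jw.ObjectiveSet(pts, senses=("max",) * k))
            fi, rk = brute_goldberg(pts)
            np.testing.assert_array_equal(surf.front_index, fi)
            np.testing.assert_allclose(surf.rank, rk)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=2,
            max_size=30,
        ),
        st.sampled_from(["cube", "exp", "affine"]),
    )
    def test_monotone_transform_invariance(self, points, transform):
        """Strictly increasing transforms of one objective leave all fronts
        unchanged.  (Values drawn on a lattice so the transforms stay
        strictly monotone in floating point.)"""
        pts = np.array(points, dtype=float) / 10.0
        f = {"cube": lambda x: x**3, "exp": np.exp, "affine": lambda x: 2 * x + 1}[transform]
        t = pts.copy()
        t[:, 0] = f(t[:, 0])
        s0 = jw.goldberg_rank(jw.ObjectiveSet(pts, senses=("max", "max")))
        s1 = jw.goldberg_rank(jw.ObjectiveSet(t, senses=("max", "max")))
        np.testing.assert_array_equal(s0.front_index, s1.front_index)


class TestOptimalitySurface:
    def test_constant_objective_reduces_to_sorting(self):
        rng = np.random.default_rng(0)
        other = rng.uniform(size=40)
        surfaces = {"a": np.full(40, 2.0), "b": other}
        out = jw.optimality_surface(surfaces, {"a": "min", "b": "max"})
        ranks = out[("a", "b")].rank
        order = np.argsort(other)
        assert np.all(np.diff(ranks[order]) >= 0)  # monotone in objective b

    def test_objective_order_symmetry(self):
        rng = np.random.default_rng(1)
        vals = {m: rng.uniform(size=60) for m in ("x", "y", "z")}
        senses = {"x": "min", "y": "max", "z": "min"}
        s1 = jw.optimality_surface(vals, senses)
        rev = {m: vals[m] for m in ("z", "y", "x")}
        s2 = jw.optimality_surface(rev, senses)
        np.testing.assert_array_equal(
            s1[("x", "y", "z")].rank, s2[("z", "y", "x")].rank
        )

    def test_three_way_front_members_undominated(self):
        rng = np.random.default_rng(2)
        vals = {m: rng.uniform(size=80) for m in ("x", "y", "z")}
        senses = {m: "max" for m in vals}
        out = jw.optimality_surface(vals, senses)
        combined = out[("x", "y", "z")]
        pts = np.column_stack([vals[m] for m in ("x", "y", "z")])
        oracle_front = brute_pareto_front(pts)
        np.testing.assert_array_equal(combined.front_index == 1, oracle_front)

    def test_emits_all_pairwise_and_combined(self):
        rng = np.random.default_rng(3)
        vals = {m: rng.uniform(size=20) for m in ("x", "y", "z")}
        out = jw.optimality_surface(vals, {m: "max" for m in vals})
        assert set(out) == {("x", "y"), ("x", "z"), ("y", "z"), ("x", "y", "z")}

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            jw.optimality_surface(
                {"a": np.ones(5), "b": np.ones(6)}, {"a": "max", "b": "max"}
            )
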