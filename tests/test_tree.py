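import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vascgen import tree as T
from tests.conftest import random_forest


def simple_root() -> T.VascularForest:
    f = T.VascularForest()
    f.add_vessel((0, 0, 0), (1, 0, 0), radius=0.1, inflow=1.0)
    return f


def forest_state(f: T.VascularForest):
    n = f.n
    return (
        n, f.xp[:n].tobytes(), f.xd[:n].tobytes(), f.radius[:n].tobytes(),
        f.flow[:n].tobytes(), f.parent[:n].tobytes(), f.level[:n].tobytes(),
        tuple(tuple(c) for c in f.children), tuple(f.roots),
    )


class TestInsertTerminal:
    def test_split_makes_three_vessels_two_terminals(self):
        f = simple_root()
        f.insert_terminal(0, (0.5, 0, 0), (0.5, 0.5, 0))
        assert f.n == 3
        assert len(f.terminals()) == 2
        f.validate()

    def test_insert_then_rollback_is_identity(self):
        f = simple_root()
        before = forest_state(f)
        snap, k, p = f.insert_terminal(0, (0.5, 0, 0), (0.5, 0.5, 0))
        assert forest_state(f) != before
        f.restore(snap)
        assert forest_state(f) == before

    def test_distal_attachment_adds_single_child(self):
        f = simple_root()
        f.behaviour[0] = T.DISTAL
        snap, k, j = f.insert_terminal(0, f.xd[0], (1.5, 0.5, 0))
        assert f.n == 2
        assert f.children[0] == [k]
        assert j == 0
        f.validate()

    def test_split_preserves_children_roles_on_distal_half(self):
        f = simple_root()
        f.role[0] = T.TRANSPORT
        f.insert_terminal(0, (0.4, 0, 0), (0.4, 0.4, 0))
        # vessel 0 is now the distal half and keeps its role; the new
        # proximal half inherited the role too
        assert int(f.role[0]) == T.TRANSPORT
        p = int(f.parent[0])
        assert int(f.role[p]) == T.TRANSPORT

    def test_root_split_moves_root_status(self):
        f = simple_root()
        f.insert_terminal(0, (0.5, 0, 0), (0.5, 0.5, 0))
        (r,) = f.roots
        assert f.parent[r] == -1
        assert f.root_inflow[r] == 1.0

    def test_unknown_vessel_rejected(self):
        f = simple_root()
        with pytest.raises(ValueError):
            f.insert_terminal(5, (0.5, 0, 0), (0.5, 0.5, 0))


class TestBifurcationLevel:
    def test_root_is_level_zero(self):
        f = simple_root()
        assert f.bifurcation_level(0) == 0

    def test_child_of_first_true_bifurcation(self):
        f = simple_root()
        _, k, p = f.insert_terminal(0, (0.5, 0, 0), (0.5, 0.5, 0))
        assert f.bifurcation_level(p) == 0
        assert f.bifurcation_level(k) == 1
        assert f.bifurcation_level(0) == 1  # distal half sits below the new junction

    def test_unary_chain_does_not_increment_level(self):
        f = T.VascularForest()
        a = f.add_vessel((0, 0, 0), (1, 0, 0), radius=0.1, inflow=1.0)
        b = f.add_vessel((1, 0, 0), (2, 0.1, 0), radius=0.1, parent=a)
        c = f.add_vessel((2, 0.1, 0), (3, 0, 0), radius=0.1, parent=b)
        d = f.add_vessel((3, 0, 0), (4, 1, 0), radius=0.08, parent=c)
        e = f.add_vessel((3, 0, 0), (4, -1, 0), radius=0.08, parent=c)
        assert f.bifurcation_level(b) == 0
        assert f.bifurcation_level(c) == 0
        assert f.bifurcation_level(d) == 1
        assert f.bifurcation_level(e) == 1


class TestSpatialQueries:
    def test_point_on_segment_has_zero_distance(self):
        f = simple_root()
        d, _ = f.min_point_distance((0.25, 0, 0))
        assert d == pytest.approx(0.0, abs=1e-14)

    def test_perpendicular_foot(self):
        f = T.VascularForest()
        f.add_vessel((0, 0, 0), (0, 1, 0), radius=0.1, inflow=1.0)
        d, closest = f.min_point_distance((1, 0.5, 0))
        assert d == pytest.approx(1.0, rel=1e-12)
        assert np.allclose(closest, (0, 0.5, 0))

    def test_huge_radius_returns_all(self, rng):
        f, _ = random_forest(rng, n_terminals=8)
        assert len(f.neighbourhood((0.2, 0.2, 0), 1e9)) == f.n

    def test_tiny_radius_returns_none(self, rng):
        f, _ = random_forest(rng, n_terminals=5)
        assert len(f.neighbourhood((50.0, 50.0, 0.0), 1e-8)) == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), qx=st.floats(-1, 1), qy=st.floats(-1, 1))
    def test_min_distance_matches_bruteforce(self, seed, qx, qy, disc_tree_40):
        forest = disc_tree_40[0]
        x = np.array([qx, qy, 0.0])
        d, _ = forest.min_point_distance(x)
        brute = min(
            _point_seg(x, forest.xp[i], forest.xd[i]) for i in range(forest.n)
        )
        assert d == pytest.approx(brute, rel=1e-12, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(qx=st.floats(-1.2, 1.2), qy=st.floats(-1.2, 1.2), r=st.floats(0.01, 0.8))
    def test_neighbourhood_matches_bruteforce(self, qx, qy, r, disc_tree_40):
        forest = disc_tree_40[0]
        x = np.array([qx, qy, 0.0])
        got = set(int(i) for i in forest.neighbourhood(x, r))
        want = {
            i for i in range(forest.n)
            if _point_seg(x, forest.xp[i], forest.xd[i]) <= r
        }
        assert got == want


def _point_seg(x, a, b):
    d = b - a
    l2 = float(np.dot(d, d))
    t = 0.0 if l2 == 0 else float(np.clip(np.dot(x - a, d) / l2, 0, 1))
    return float(np.linalg.norm(a + t * d - x))


class TestSegmentDistances:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**30))
    def test_batch_matches_single(self, seed):
        rng = np.random.default_rng(seed)
        p1, q1 = rng.uniform(-1, 1, 3), rng.uniform(-1, 1, 3)
        p2 = rng.uniform(-1, 1, (7, 3))
        q2 = rng.uniform(-1, 1, (7, 3))
        one = T.segment_segment_distance(p1, q1, p2, q2)
        batch = T.segment_segment_distance_batch(p1, q1, p2, q2)[0]
        assert np.allclose(one, batch, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**30))
    def test_distance_bounded_by_sampled_points(self, seed):
        # the true minimum can never exceed a dense pointwise sampling
        rng = np.random.default_rng(seed)
        p1, q1 = rng.uniform(-1, 1, 3), rng.uniform(-1, 1, 3)
        p2 = rng.uniform(-1, 1, (1, 3))
        q2 = rng.uniform(-1, 1, (1, 3))
        d = float(T.segment_segment_distance(p1, q1, p2, q2)[0])
        ts = np.linspace(0, 1, 40)
        pts1 = p1 + ts[:, None] * (q1 - p1)
        pts2 = p2[0] + ts[:, None] * (q2[0] - p2[0])
        sampled = np.linalg.norm(pts1[:, None, :] - pts2[None, :, :], axis=2).min()
        assert d <= sampled + 1e-9
        assert d >= 0

    def test_symmetry(self, rng):
        p1, q1 = rng.uniform(-1, 1, 3), rng.uniform(-1, 1, 3)
        p2, q2 = rng.uniform(-1, 1, 3), rng.uniform(-1, 1, 3)
        a = float(T.segment_segment_distance(p1, q1, p2[None], q2[None])[0])
        b = float(T.segment_segment_distance(p2, q2, p1[None], q1[None])[0])
        assert a == pytest.approx(b, rel=1e-10, abs=1e-12)


class TestIntegrity:
    def test_validate_passes_on_grown_tree(self, disc_tree_40):
        disc_tree_40[0].validate()

    def test_repeated_insert_rollback_is_identity(self, rng):
        f, _ = random_forest(rng, n_terminals=6)
        before = forest_state(f)
        for _ in range(10):
            j = int(rng.integers(f.n))
            if f.behaviour[j] == T.DISTAL or f.length[j] < 1e-6:
                continue
            x_b = 0.5 * (f.xp[j] + f.xd[j])
            snap, _, _ = f.insert_terminal(j, x_b, x_b + np.array([0.05, 0.07, 0.0]))
            f.restore(snap)
        assert forest_state(f) == before
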