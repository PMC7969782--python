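import numpy as np
import pytest

from vascgen import costs, domains as D, engine, fixtures, hemo, io as vio, tree as T


class TestDistanceThreshold:
    def test_unity_factors(self):
        assert engine.distance_threshold(0, 1.0, 2, 1.0) == pytest.approx(1.0)

    def test_3d_inverse_cuberoot(self):
        # nu=1, 7 existing terminals: (1/8)^(1/3) = 0.5
        assert engine.distance_threshold(7, 1.0, 3, 1.0) == pytest.approx(0.5)

    def test_relaxation_compounds(self):
        base = engine.distance_threshold(10, 1.0, 2, 1.5)
        relaxed = engine.distance_threshold(10, 1.0, 2, 1.5, relaxation=0.9 * 0.9)
        assert relaxed == pytest.approx(0.81 * base)


class TestCandidateLattice:
    def make_vessel(self, behaviour=T.VERSATILE):
        f = T.VascularForest()
        f.add_vessel((0, 0, 0), (1, 0, 0), radius=0.1, inflow=1.0, behaviour=behaviour)
        return f

    @pytest.mark.parametrize("delta_v,count", [(6, 18), (7, 25)])
    def test_lattice_size_formula(self, delta_v, count):
        # Dv(Dv+1)/2 - 3 points (triangle lattice minus the vertices)
        f = self.make_vessel()
        pts, distal = engine.candidate_lattice(f, 0, np.array([0.5, 0.7, 0.0]), delta_v)
        assert len(pts) == count and not distal

    def test_fixed_behaviour_restricted_to_axis(self):
        f = self.make_vessel(T.FIXED)
        pts, _ = engine.candidate_lattice(f, 0, np.array([0.5, 0.7, 0.0]), 7)
        assert len(pts) == 5  # delta_v - 2 interior points on the axis
        assert np.allclose(pts[:, 1:], 0.0)

    def test_distal_behaviour_single_point(self):
        f = self.make_vessel(T.DISTAL)
        pts, distal = engine.candidate_lattice(f, 0, np.array([0.5, 0.7, 0.0]), 7)
        assert distal and len(pts) == 1 and np.allclose(pts[0], (1, 0, 0))

    def test_degenerate_triangle_falls_back_to_axis(self):
        f = self.make_vessel()
        pts, _ = engine.candidate_lattice(f, 0, np.array([2.0, 0.0, 0.0]), 7)
        assert np.allclose(pts[:, 1:], 0.0)

    def test_lattice_points_lie_in_triangle(self):
        f = self.make_vessel()
        A = np.array([0.5, 0.7, 0.0])
        pts, _ = engine.candidate_lattice(f, 0, A, 7)
        # barycentric coordinates wrt (A, xp, xd) must be in [0, 1]
        M = np.stack([A - f.xd[0], f.xp[0] - f.xd[0]], axis=1)[:2]
        for p in pts:
            lam = np.linalg.solve(M, (p - f.xd[0])[:2])
            assert -1e-12 <= lam[0] <= 1 and -1e-12 <= lam[1] <= 1
            assert lam.sum() <= 1 + 1e-12


class TestGrowth:
    def test_budget_one_adds_one_terminal(self):
        fx = fixtures.build("disc_uniform", n_terminals=1)
        forest, per = engine.run_stages(fx["stages"], seed=5)
        assert forest.n_free_terminals() == 2  # root tip + the new terminal
        assert len(per[0]) in (3, 4)  # root + split pair + new vessel

    def test_budget_zero_is_identity(self):
        f = T.VascularForest()
        f.add_vessel((-1, 0, 0), (0, 0, 0), radius=0.05, inflow=10.0)
        stage = engine.Stage(domain=D.Disc(), n_terminals=0)
        forest, per = engine.run_stages([stage], seed=5, initial_forest=f)
        assert forest.n == 1 and per[0] == []

    def test_same_seed_reproduces_bitwise(self):
        runs = []
        for _ in range(2):
            fx = fixtures.build("disc_uniform", n_terminals=15)
            forest, _ = engine.run_stages(fx["stages"], seed=77)
            runs.append(vio.forest_to_table(forest))
        assert runs[0].equals(runs[1])

    def test_stage_budgets_met_exactly(self):
        fx = fixtures.build("two_inlets_twostage", budgets=(5, 10))
        forest, per = engine.run_stages(fx["stages"], seed=2, initial_forest=fx["initial_forest"])
        new_terms_1 = sum(1 for i in per[0] if forest.stage[i] == 1 and not forest.children[i])
        new_terms_2 = sum(1 for i in per[1] if forest.stage[i] == 2 and not forest.children[i])
        assert new_terms_1 == 5
        assert new_terms_2 == 10

    def test_relaxation_event_logged_when_threshold_infeasible(self):
        # tiny domain relative to nu forces Eq.-14 relaxations before any
        # terminal can be placed
        f = T.VascularForest()
        f.add_vessel((-1, 0, 0), (0, 0, 0), radius=0.02, inflow=10.0)
        stage = engine.Stage(
            domain=D.Disc(),
            n_terminals=1,
            opt=engine.OptParams(nu=30.0, n_fail=10),
        )
        state = engine.EngineState(forest=f, rng=np.random.default_rng(4))
        hemo.solve(f)
        engine.grow_stage(state, stage)
        assert any(e["event"] == "relaxation" for e in state.log)

    def test_degenerate_density_aborts(self):
        stage = engine.Stage(
            domain=D.Disc(),
            n_terminals=1,
            density=D.CallableDensity(lambda p: np.zeros(len(p)), p_max=1.0),
            inlets=(engine.RootSpec(position=(-1, 0, 0), radius=0.05, inflow=1.0),),
        )
        with pytest.raises(D.DegenerateDensityError):
            engine.run_stages([stage], seed=1)

    def test_domain_too_small_for_root_aborts(self):
        stage = engine.Stage(
            domain=D.Disc(radius=0.05),
            n_terminals=1,
            opt=engine.OptParams(max_total_attempts=2000),
            inlets=(engine.RootSpec(position=(-0.05, 0, 0), radius=0.04, inflow=1.0),),
        )
        with pytest.raises(engine.StageAbort):
            engine.run_stages([stage], seed=1)


class TestBestConnectionOracle:
    def exhaustive_best(self, state, stage, x_new):
        """Full-recompute exhaustive search over all (vessel, point) pairs."""
        forest = state.forest
        dist_all, _ = forest._seg_point_distance(np.asarray(x_new, float))
        best = None
        for j in range(forest.n):
            if forest.behaviour[j] == T.NON_BRANCHING or forest.outlet_fraction[j] > 0:
                continue
            pts, distal = engine.candidate_lattice(forest, j, x_new, stage.opt.delta_v)
            for p in pts:
                if int(forest.role[j]) in (T.DISTRIBUTION, T.PERFORATOR) and not stage.domain.contains(p):
                    continue
                if stage.new_role == T.DISTRIBUTION and not stage.domain.segment_in_domain(p, np.asarray(x_new, float), n_checks=12):
                    continue
                c = engine._exact_evaluate(
                    state, stage, j, p, np.asarray(x_new, float), distal, 1,
                    signal_distance=float(dist_all[j]),
                )
                if c is not None and (best is None or c < best[0] - 1e-15):
                    best = (c, j, p)
        return best

    def test_matches_exhaustive_search_on_micro_forests(self):
        """best_connection equals brute force on small random instances."""
        rng = np.random.default_rng(2024)
        agree = 0
        total = 0
        while total < 12:
            n_t = int(rng.integers(2, 5))
            fx = fixtures.build("disc_uniform", n_terminals=n_t)
            forest, _ = engine.run_stages(fx["stages"], seed=int(rng.integers(2**31 - 1)))
            stage = fx["stages"][0]
            hemo.solve(forest)
            state = engine.EngineState(forest=forest, rng=rng)
            x = engine.sample_terminal(state, stage)
            want = self.exhaustive_best(state, stage, x)
            got = engine.best_connection(state, stage, x)
            total += 1
            if want is None:
                assert got is None
                agree += 1
                continue
            assert got is not None
            assert got.cost == pytest.approx(want[0], rel=1e-9)
            if got.j == want[1] and np.allclose(got.x_b, want[2]):
                agree += 1
        assert agree == total
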