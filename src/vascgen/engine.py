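"""Staged constructive growth of vascular trees.

One growth iteration: draw a terminal location from the stage's placement
density, rejecting points closer to the existing forest than a shrinking
perfusion-distance threshold; enumerate trial bifurcation sites on a
barycentric lattice over the connection triangles of nearby vessels;
evaluate each trial with an incremental hemodynamic update; gate by the
geometric/role/behaviour rules; commit the cheapest admissible connection
and re-converge all radii.  A *stage* repeats this until its terminal
budget is met; a run is an ordered sequence of stages, possibly with
different domains, parameters, costs and vessel types.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import costs as C
from . import hemo
from . import rules
from . import tree as T
from .domains import Domain, PlacementDensity, UniformDensity, sample_point


#: creation-time slenderness headroom: new vessels must clear the l/r > 2
#: bound with this factor so that later radius re-convergence (which grows
#: trunk radii by a few percent as their subtrees capture terminals) cannot
#: drag them below the bound; the whole-tree re-check remains the arbiter.
ASPECT_HEADROOM = 1.05

#: creation-time cylinder-clearance headroom, same drift rationale
CLASH_HEADROOM = 1.10


class StageAbort(RuntimeError):
    """Raised when a stage exhausts its attempt budget."""


@dataclass
class OptParams:
    """Optimisation parameters of a growth stage.

    nu: slender-domain tuning of the perfusion-distance threshold
    f_r: threshold relaxation factor applied after n_fail failures
    f_n: neighbourhood radius factor (radius = f_n · l_c)
    delta_v: lattice points per triangle side (>= 3)
    n_fail: consecutive failures before one relaxation step
    max_total_attempts: hard abort guard per stage
    n_nearest: cap on the number of closest neighbour vessels examined per
        terminal (keeps the brute-force search tractable on large trees)
    """

    nu: float = 1.0
    f_r: float = 0.9
    f_n: float = 8.0
    delta_v: int = 7
    n_fail: int = 100
    max_total_attempts: int = 1_000_000
    n_nearest: int = 30

    def __post_init__(self):
        if not 0 < self.f_r < 1:
            raise ValueError("f_r must lie in (0, 1)")
        if self.f_n <= 0 or self.nu <= 0:
            raise ValueError("f_n and nu must be positive")
        if self.delta_v < 3:
            raise ValueError("delta_v must be >= 3")


@dataclass
class RootSpec:
    """Inlet of a new tree: proximal position, fixed radius, nominal inflow."""

    position: tuple
    radius: float
    inflow: float
    role: int = T.DISTRIBUTION
    behaviour: int = T.VERSATILE


@dataclass
class Stage:
    """One growth phase: domain, parameters, budget, cost and vessel type."""

    domain: Domain
    n_terminals: int
    geo: rules.GeoParams = field(default_factory=rules.GeoParams)
    opt: OptParams = field(default_factory=OptParams)
    angles: rules.AngleParams = field(default_factory=rules.AngleParams)
    cost: str = "vol"                       # "vol" | "sprout"
    sprout: tuple = (0.0, 0.0, 0.0)         # (c_v, c_p, c_d) when cost == "sprout"
    density: PlacementDensity = field(default_factory=UniformDensity)
    new_role: int = T.DISTRIBUTION
    new_behaviour: int = T.VERSATILE
    parent_stages: tuple | None = None      # stage ids eligible as parents (None = all)
    inlets: tuple = ()                      # RootSpecs creating new trees at stage start
    label: str = ""

    def __post_init__(self):
        if self.n_terminals < 0:
            raise ValueError("terminal budget must be >= 0")
        if self.cost not in ("vol", "sprout"):
            raise ValueError(f"unknown cost functional {self.cost!r}")


@dataclass
class EngineState:
    """Mutable growth state shared across the stages of one run."""

    forest: T.VascularForest
    rng: np.random.Generator
    relaxation: float = 1.0
    fails: int = 0
    attempts: int = 0
    log: list = field(default_factory=list)
    solve_tol: float = 1e-6

    def note(self, event: str, **data):
        self.log.append({"event": event, **data})


def distance_threshold(n_terminals: int, l_c: float, D: int, nu: float, relaxation: float = 1.0) -> float:
    """Minimum admissible distance between a new terminal and the forest.

    l_lim = relaxation · l_c · (ν/(N_T+1))^(1/D): the equivalent perfusion
    radius a terminal would claim if the N_T+1 territories tiled the domain.
    """
    return relaxation * l_c * (nu / (n_terminals + 1)) ** (1.0 / D)


_BARY_CACHE: dict[int, tuple] = {}


def _bary_weights(delta_v: int):
    """Barycentric integer weights of the triangle lattice, vertices removed."""
    got = _BARY_CACHE.get(delta_v)
    if got is not None:
        return got
    k = delta_v - 1
    ii, jj = np.meshgrid(np.arange(delta_v), np.arange(delta_v), indexing="ij")
    sel = ii + jj <= k
    ii, jj = ii[sel], jj[sel]
    kk = k - ii - jj
    vertex = ((ii == k) & (jj == 0)) | ((jj == k) & (ii == 0)) | ((kk == k) & (ii == 0))
    out = (ii[~vertex], jj[~vertex], kk[~vertex])
    _BARY_CACHE[delta_v] = out
    return out


def candidate_lattice(forest: T.VascularForest, j: int, x_d_new, delta_v: int):
    """Trial bifurcation points for connecting a terminal to vessel j.

    Versatile vessels expose the barycentric lattice of the triangle
    (x_d_new, x_p_j, x_d_j) with ``delta_v`` points per side, vertices
    removed; fixed vessels only the lattice points on their own axis;
    distal vessels the single distal point; non-branching vessels none.
    Degenerate (collinear) triangles fall back to the axis points.

    Returns ``(points (m, 3), distal_flag)``.
    """
    beh = int(forest.behaviour[j])
    if beh == T.NON_BRANCHING:
        return np.empty((0, 3)), False
    if beh == T.DISTAL:
        return forest.xd[j][None, :].copy(), True

    A = np.asarray(x_d_new, dtype=float)
    B = forest.xp[j]
    Cc = forest.xd[j]
    k = delta_v - 1
    ii, jj, kk = _bary_weights(delta_v)

    u = B - A
    v = Cc - A
    cx = u[1] * v[2] - u[2] * v[1]
    cy = u[2] * v[0] - u[0] * v[2]
    cz = u[0] * v[1] - u[1] * v[0]
    area2 = math.sqrt(cx * cx + cy * cy + cz * cz)
    lbc = math.dist(B, Cc)
    degenerate = area2 < 1e-12 * max(lbc, 1.0) ** 2
    if beh == T.FIXED or degenerate:
        on_axis = ii == 0
        ii, jj, kk = ii[on_axis], jj[on_axis], kk[on_axis]
    pts = (ii[:, None] * A[None, :] + jj[:, None] * B[None, :] + kk[:, None] * Cc[None, :]) / k
    return pts, False


_LINSPACE_CACHE: dict[int, np.ndarray] = {}


def _segments_inside(domain: Domain, A: np.ndarray, B: np.ndarray, n_checks: int) -> np.ndarray:
    """Vectorised whole-segment containment for m segments A[i] -> B[i]."""
    m = len(A)
    if m == 0:
        return np.empty(0, dtype=bool)
    t = _LINSPACE_CACHE.get(n_checks)
    if t is None:
        t = np.linspace(0.0, 1.0, n_checks)
        _LINSPACE_CACHE[n_checks] = t
    pts = A[:, None, :] + t[None, :, None] * (B - A)[:, None, :]
    ok = domain.contains(pts.reshape(-1, 3)).reshape(m, n_checks)
    return np.all(ok, axis=1)


@dataclass
class Candidate:
    """A committed-quality evaluation of one trial connection."""

    j: int
    x_b: np.ndarray
    distal: bool
    cost: float
    enum: int


def _sprout_coeffs(stage: Stage, forest: T.VascularForest, j: int,
                   V_ref: float | None = None) -> C.SproutCoeffs:
    root = forest.root_of(j)
    return C.SproutCoeffs.for_forest(
        *stage.sprout, forest=forest, r_root=float(forest.radius[root]), V_ref=V_ref
    )


def _exact_evaluate(state: EngineState, stage: Stage, j: int, x_b, x_new, distal: bool,
                    stage_id: int = 1, signal_distance: float | None = None):
    """Insert, fully converge, audit with exact radii, measure cost, roll back.

    Returns the exact cost or None if the candidate is infeasible.
    """
    forest = state.forest
    vol_before = C.tree_volume(forest)
    snap, k, p = forest.insert_terminal(
        j, x_b, x_new, stage=stage_id, role=stage.new_role, behaviour=stage.new_behaviour
    )
    try:
        try:
            hemo.solve(forest, gamma=stage.geo.gamma, tol=state.solve_tol)
        except hemo.ConvergenceError:
            return None

        # constraint re-check with converged radii, over the whole reshaped tree
        new_ids = [k] if distal else [k, p, j]
        for i in new_ids:
            if forest.length[i] <= 2.0 * ASPECT_HEADROOM * forest.radius[i]:
                return None
        ch = forest.children[p]
        if len(ch) >= 2:
            rc = forest.radius[ch]
            if float(rc.min()) / float(rc.max()) <= stage.geo.delta_at(int(forest.level[p])):
                return None
        if not rules.whole_tree_ok(forest, stage.geo):
            return None
        # cylinder clash of each new segment against non-adjacent vessels
        for i in new_ids:
            exempt = rules.junction_exempt(forest, i, hops=2)
            if rules.segments_clash(forest, forest.xp[i], forest.xd[i], float(forest.radius[i]),
                                    exempt, headroom=CLASH_HEADROOM):
                return None

        dvol = C.tree_volume(forest) - vol_before
        if stage.cost == "vol":
            return dvol
        coeffs = _sprout_coeffs(stage, forest, p, V_ref=vol_before)
        if signal_distance is None:
            # distance from the terminal to the target vessel's original axis
            signal_distance = float(
                T.segment_segment_distance(x_new, x_new, forest.xp[p][None, :], forest.xd[j][None, :])[0]
            )
        return float(C.sprout_cost(dvol, float(forest.radius[p]), signal_distance, coeffs))
    finally:
        forest.restore(snap)


def best_connection(state: EngineState, stage: Stage, x_new, stage_id: int = 1) -> Candidate | None:
    """Cheapest admissible connection of a terminal point to the forest.

    Enumerates (neighbour vessel, lattice point) pairs, ranks them by the
    incremental cost, then re-evaluates the short-list of best candidates
    with a full insert/converge/rollback so the returned connection is the
    exact-cost argmin (ties resolved by enumeration order).
    """
    forest = state.forest
    x_new = np.asarray(x_new, dtype=float)
    opt, geo = stage.opt, stage.geo
    l_c = stage.domain.characteristic_length()

    dist_all, _ = forest._seg_point_distance(x_new)
    neigh = np.argsort(dist_all, kind="stable")
    neigh = neigh[dist_all[neigh] <= opt.f_n * l_c]
    elig = []
    for j in neigh:
        j = int(j)
        if forest.behaviour[j] == T.NON_BRANCHING or forest.outlet_fraction[j] > 0:
            continue
        if stage.parent_stages is not None and int(forest.stage[j]) not in stage.parent_stages:
            continue
        elig.append(j)
        if len(elig) >= opt.n_nearest:
            break
    if not elig:
        return None

    # perforator stages only require the (fixed) terminal point to lie in Ω
    if stage.new_role == T.PERFORATOR and not bool(stage.domain.contains(x_new)):
        return None
    vol_now = C.tree_volume(forest) if stage.cost == "sprout" else 0.0

    all_cost: list[np.ndarray] = []
    all_meta: list[tuple] = []
    enum = 0
    for j in elig:
        pts_full, distal = candidate_lattice(forest, j, x_new, opt.delta_v)
        m_full = len(pts_full)
        if m_full == 0:
            continue
        mask = np.ones(m_full, dtype=bool)

        # (2) bifurcation-site containment by the target vessel's role
        if int(forest.role[j]) in (T.DISTRIBUTION, T.PERFORATOR):
            mask &= np.asarray(stage.domain.contains(pts_full), dtype=bool)

        # (6) angle windows (geometry only, radius-independent)
        if stage.angles.theta_enabled:
            ref = forest.xd[j] if not distal else forest.xd[j] + (forest.xd[j] - forest.xp[j])
            th = rules.bifurcation_angle(pts_full, ref, x_new)
            mask &= (th > stage.angles.theta_min) & (th < stage.angles.theta_max)
        if stage.angles.phi_enabled and not distal:
            phi = rules.opening_angle(pts_full, forest.xp[j], forest.xd[j], x_new)
            mask &= np.isnan(phi) | ((phi > stage.angles.phi_min) & (phi < stage.angles.phi_max))

        keep = np.nonzero(mask)[0]
        if len(keep) == 0:
            enum += m_full
            continue
        pts = pts_full[keep]

        # (3) containment of the new/split segments, sampled at the
        # perfusion-scale resolution
        reach = max(
            float(np.linalg.norm(forest.xp[j] - x_new)),
            float(np.linalg.norm(forest.xd[j] - x_new)),
            float(forest.length[j]),
        )
        n_chk = max(3, min(24, int(math.ceil(reach / (0.1 * l_c))) + 1))
        sub = np.ones(len(keep), dtype=bool)
        if stage.new_role == T.DISTRIBUTION:
            sub &= _segments_inside(stage.domain, pts, np.broadcast_to(x_new, pts.shape), n_chk)
        if not distal and int(forest.role[j]) == T.DISTRIBUTION:
            sub &= _segments_inside(stage.domain, np.broadcast_to(forest.xp[j], pts.shape), pts, n_chk)
            sub &= _segments_inside(stage.domain, pts, np.broadcast_to(forest.xd[j], pts.shape), n_chk)
        keep = keep[sub]
        if len(keep) == 0:
            enum += m_full
            continue
        pts = pts_full[keep]

        ev = hemo.evaluate_candidates(
            forest, j, pts, x_new, gamma=geo.gamma, distal=distal
        )
        # (5) aspect and symmetry with incrementally updated radii
        mask2 = ev.l_vnew > 2.0 * ASPECT_HEADROOM * ev.r_vnew
        if not distal:
            mask2 &= (ev.l_vp > 2.0 * ASPECT_HEADROOM * ev.r_vp) & (ev.l_vs > 2.0 * ASPECT_HEADROOM * ev.r_vs)
            delta_eff = geo.delta_at(int(forest.level[j]))
            ratio = np.minimum(ev.beta_s, ev.beta_new) / np.maximum(ev.beta_s, ev.beta_new)
            mask2 &= ratio > delta_eff
        else:
            ch = forest.children[j]
            if ch:
                rc = forest.radius[ch]
                lo = np.minimum(ev.r_vnew, float(rc.min()))
                hi = np.maximum(ev.r_vnew, float(rc.max()))
                mask2 &= lo / hi > geo.delta_at(int(forest.level[j]))

        # (4) cylinder clearance against non-adjacent vessels
        if mask2.any():
            live = np.nonzero(mask2)[0]
            sub = _clash_mask(
                forest, j, pts[live], x_new, distal,
                CandidateEvalView(ev, live), dist_all,
            )
            mask2[live[~sub]] = False

        idx = np.nonzero(mask2)[0]
        if len(idx):
            if stage.cost == "vol":
                cost = ev.dvol[idx]
            else:
                coeffs = _sprout_coeffs(stage, forest, j, V_ref=vol_now)
                cost = C.sprout_cost(ev.dvol[idx], ev.r_vp[idx], float(dist_all[j]), coeffs)
            all_cost.append(np.atleast_1d(cost))
            for i in idx:
                all_meta.append((j, pts[i], distal, enum + int(keep[i])))
        enum += m_full

    if not all_cost:
        return None
    cost = np.concatenate(all_cost)
    order = np.argsort(cost, kind="stable")
    # The incremental evaluation freezes off-path viscosities, so its cost
    # deviates from the exact re-evaluation.  The candidate-to-candidate
    # spread of that deviation is bounded (measured across tree sizes) by
    # ~0.3·V/N_free — one terminal's share of the tree volume, which is
    # the amount of reshaping a single insertion causes.  Candidates whose
    # incremental cost lies within that band of the best exact cost are
    # re-evaluated exactly, so the returned argmin matches an exhaustive
    # full-recompute search.
    n_free = max(forest.n_free_terminals(), 1)
    vol_margin = 0.4 * C.tree_volume(forest) / n_free
    if stage.cost == "vol":
        margin = vol_margin
    else:
        # the volume term dominates the sprout-cost error (V_ref is the
        # forest volume, so the c_v term's error band is c_v·0.4/N_free)
        margin = stage.sprout[0] * 0.4 / n_free + 1e-3

    best: Candidate | None = None
    for oi in order:
        c_inc = float(cost[oi])
        if best is not None and c_inc > best.cost + margin + 1e-12:
            break
        j, pt, distal, en = all_meta[int(oi)]
        c_exact = _exact_evaluate(state, stage, j, pt, x_new, distal, stage_id,
                                  signal_distance=float(dist_all[j]))
        if c_exact is None:
            continue
        if best is None or c_exact < best.cost or (c_exact == best.cost and en < best.enum):
            best = Candidate(j=j, x_b=pt, distal=distal, cost=c_exact, enum=en)
    return best


class CandidateEvalView:
    """Row-subset view of a CandidateEval (for masked lattice points)."""

    def __init__(self, ev, rows):
        self.r_vp = ev.r_vp[rows]
        self.r_vs = ev.r_vs[rows]
        self.r_vnew = ev.r_vnew[rows]


def _clash_mask(forest, j, pts, x_new, distal, ev, dist_to_xnew) -> np.ndarray:
    """Vectorised pre-insertion cylinder-clash mask (True = clear).

    Checks the prospective segments of every lattice point against all
    vessels outside the junction neighbourhood of j, pruned to those near
    enough to possibly touch; radii are the incremental estimates.  The
    authoritative check with converged radii runs after the full
    re-evaluation of the winning candidates.
    """
    m = len(pts)
    n = forest.n
    # family-specific exemptions mirroring the two-hop neighbourhoods the
    # three prospective vessels will have after insertion, so the mask
    # agrees with the authoritative post-insertion check
    par = int(forest.parent[j])
    ex_new = {j, par}
    ex_p = {j, par, *forest.children[j]}
    ex_s = {j, par, *forest.children[j]}
    if par >= 0:
        ex_p.update(forest.children[par])
        g = int(forest.parent[par])
        if g >= 0:
            ex_p.add(g)
    for c in forest.children[j]:
        ex_s.update(forest.children[c])

    # every prospective segment lies in the triangle hull around x_new;
    # a vessel further away than the hull diameter plus the largest
    # possible radii sum cannot clash
    diam = max(float(np.linalg.norm(forest.xp[j] - x_new)), float(np.linalg.norm(forest.xd[j] - x_new)))
    r_slack = (float(forest.radius[:n].max()) + float(np.max(ev.r_vp if not distal else ev.r_vnew))) * 1.5
    near = dist_to_xnew[:n] <= diam + r_slack
    idx_all = np.nonzero(near)[0]
    clear = np.ones(m, dtype=bool)
    if len(idx_all) == 0:
        return clear
    exempt = np.zeros((3, n), dtype=np.bool_)
    for f, ex in enumerate((ex_new, ex_p, ex_s)):
        for e in ex:
            if 0 <= e < n:
                exempt[f, e] = True
    T._clash_mask_kernel(
        pts, np.asarray(x_new, float), forest.xp[j], forest.xd[j],
        ev.r_vp, ev.r_vs, ev.r_vnew, distal,
        forest.xp[:n], forest.xd[:n], forest.radius[:n],
        idx_all.astype(np.int64), exempt, CLASH_HEADROOM, clear,
    )
    return clear


def sample_terminal(state: EngineState, stage: Stage, budget_guard: bool = True):
    """Draw a terminal point obeying the minimum-distance rule.

    Rejections count as failures; every ``n_fail`` consecutive failures
    shrink the threshold by f_r.  The relaxation accumulator is reset by
    the caller once a terminal is successfully *connected*.
    """
    forest = state.forest
    opt = stage.opt
    l_c = stage.domain.characteristic_length()
    D = stage.domain.D
    while True:
        if budget_guard and state.attempts >= opt.max_total_attempts:
            raise StageAbort(
                f"stage {stage.label!r}: attempt budget {opt.max_total_attempts} exhausted "
                f"(fails={state.fails}, relaxation={state.relaxation:.3g})"
            )
        state.attempts += 1
        x = sample_point(stage.domain, stage.density, state.rng)
        n_t = forest.n_free_terminals() if forest.n else 0
        l_lim = distance_threshold(n_t, l_c, D, opt.nu, state.relaxation)
        if forest.n == 0:
            return x
        d, _ = forest.min_point_distance(x)
        if d >= l_lim:
            return x
        _register_failure(state, stage)


def _register_failure(state: EngineState, stage: Stage):
    state.fails += 1
    if state.fails % stage.opt.n_fail == 0:
        state.relaxation *= stage.opt.f_r
        state.note("relaxation", stage=stage.label, relaxation=state.relaxation)


def create_root(state: EngineState, stage: Stage, spec: RootSpec, stage_id: int = 1) -> int:
    """Create a root segment for a new tree at the given inlet.

    Terminal points are sampled until one yields a root segment inside the
    stage domain with an admissible aspect ratio and, when other trees
    exist, an admissible distance from them.
    """
    forest = state.forest
    pos = np.asarray(spec.position, dtype=float)
    l_c = stage.domain.characteristic_length()
    opt = stage.opt
    while True:
        if state.attempts >= opt.max_total_attempts:
            raise StageAbort(f"stage {stage.label!r}: no admissible root segment found")
        state.attempts += 1
        x = sample_point(stage.domain, stage.density, state.rng)
        # the first terminal must lie at the empty-domain perfusion distance:
        # a root shorter than that could never be split under the aspect
        # bound (its fixed radius makes the proximal half too dumpy) and the
        # tree would be unable to accept any connection
        l_min = max(
            2.0 * spec.radius,
            distance_threshold(0, l_c, stage.domain.D, opt.nu, state.relaxation),
        )
        if np.linalg.norm(x - pos) <= l_min:
            _register_failure(state, stage)
            continue
        if spec.role == T.DISTRIBUTION and not stage.domain.segment_in_domain(pos, x):
            _register_failure(state, stage)
            continue
        if forest.n:
            l_lim = distance_threshold(forest.n_free_terminals(), l_c, stage.domain.D, opt.nu, state.relaxation)
            d, _ = forest.min_point_distance(x)
            if d < l_lim:
                _register_failure(state, stage)
                continue
        i = forest.add_vessel(
            pos, x, radius=spec.radius, parent=-1, role=spec.role,
            behaviour=spec.behaviour, stage=stage_id, inflow=spec.inflow,
        )
        state.fails = 0
        state.note("root", stage=stage.label, vessel=i)
        return i


def grow_stage(state: EngineState, stage: Stage, stage_id: int = 1) -> list[int]:
    """Run one stage to its terminal budget; returns the vessels it created."""
    forest = state.forest
    n_before = forest.n

    for spec in stage.inlets:
        create_root(state, stage, spec, stage_id)
    if forest.n == 0:
        raise ValueError("stage has no initial forest and declares no inlets")
    hemo.solve(forest, gamma=stage.geo.gamma, tol=state.solve_tol)

    committed = 0
    state.relaxation = 1.0
    state.fails = 0
    while committed < stage.n_terminals:
        x = sample_terminal(state, stage)
        cand = best_connection(state, stage, x, stage_id)
        if cand is None:
            _register_failure(state, stage)
            if state.attempts >= stage.opt.max_total_attempts:
                raise StageAbort(f"stage {stage.label!r}: attempt budget exhausted")
            continue
        forest.insert_terminal(
            cand.j, cand.x_b, x, stage=stage_id,
            role=stage.new_role, behaviour=stage.new_behaviour,
        )
        hemo.solve(forest, gamma=stage.geo.gamma, tol=state.solve_tol)
        committed += 1
        state.fails = 0
        state.relaxation = 1.0
    state.note("stage-done", stage=stage.label, committed=committed)
    return list(range(n_before, forest.n))


def run_stages(
    stages,
    seed: int | np.random.Generator = 0,
    initial_forest: T.VascularForest | None = None,
    solve_tol: float = 1e-6,
    event_log: list | None = None,
) -> tuple[T.VascularForest, list[list[int]]]:
    """Execute stages in order; reproducible bit-for-bit given (config, seed).

    Returns the final forest and the list of vessel ids created per stage.
    Vessels carry the 1-based index of their creating stage; pre-existing
    vessels keep stage 0.  Pass a list as ``event_log`` to receive the
    relaxation/root/stage events and attempt counts of the run.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    forest = initial_forest if initial_forest is not None else T.VascularForest()
    state = EngineState(forest=forest, rng=rng, solve_tol=solve_tol)
    if event_log is not None:
        state.log = event_log
    per_stage = []
    for t, stage in enumerate(stages, start=1):
        n_attempts = state.attempts
        per_stage.append(grow_stage(state, stage, stage_id=t))
        state.note("stage-attempts", stage=stage.label, attempts=state.attempts - n_attempts)
    return forest, per_stage
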