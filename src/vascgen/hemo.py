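"""Steady-state Poiseuille hemodynamics of a vascular forest.

Model: Newtonian blood in straight cylindrical segments at low Reynolds
number, so each vessel obeys Δp = R·q with the Poiseuille resistance
R = 8·η(r)·l/(π·r⁴).  The viscosity η(r) follows the Fåhræus–Lindqvist
effect: apparent viscosity drops steeply for sub-millimetre radii.

Boundary conditions close the system as: fixed root radius r₁ and root
inflow Q per tree; every free terminal discharges the same outflow
q_f = (Q − Σ q_out)/N_free, with constrained outlets carrying prescribed
fractions of Q.  Radii are then the unknowns.  They are found by a fixed
point over two rules applied at every junction:

* sibling ratio  r₁/r₂ = (q₁·R*₁ / (q₂·R*₂))^(1/4), which equalises the
  pressure drop across the sibling subtrees (hence across all terminals),
  where R* is the *reduced resistance*: the subtree-equivalent resistance
  scaled by the local radius to the fourth power, so that
  R_subtree = R*/r⁴;
* Murray's law  r_p^γ = Σ_c r_c^γ for the magnitude relative to the parent.

Together these give, at a junction with children c:

    β_c = w_c / (Σ_k w_k^γ)^(1/γ),   w_c = (q_c · R*_c)^(1/4),

with β_c = r_c/r_p.  Unary links get β = 1.  Since η depends on the
absolute radius, the ratio recursion is wrapped in an outer fixed point
that re-evaluates η(r) after each radius pass; η is a mild contraction in
r so a handful of iterations suffice.

Units: lengths mm, flows mm³/s, η in cP converted once (×10⁻³) to Pa·s,
making resistances Pa·s/mm³ and pressures Pa.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .tree import VascularForest

#: conversion from cP to the internal Pa·s viscosity unit
CP_TO_PAS = 1e-3
#: pole of the Fåhræus–Lindqvist κ factor (mm)
R_POLE = 5.5e-4

_K8PI = 8.0 / math.pi


class ConvergenceError(RuntimeError):
    def __init__(self, msg, residual=None, iterations=None):
        super().__init__(msg)
        self.residual = residual
        self.iterations = iterations


def viscosity(r):
    """Apparent blood viscosity in cP for a vessel radius r in mm.

    η = 1.125·(κ + κ²·(6·e^(−170 r) − 2.44·e^(−8.09·r^0.64) + 2.2)),
    κ = (r/(r − 5.5e−4))².  Singular at r = 5.5e-4 mm.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= R_POLE):
        raise ValueError(f"viscosity undefined for r <= {R_POLE} mm")
    kappa = (r / (r - R_POLE)) ** 2
    eta = 1.125 * (kappa + kappa**2 * (6.0 * np.exp(-170.0 * r) - 2.44 * np.exp(-8.09 * r**0.64) + 2.2))
    return float(eta) if eta.ndim == 0 else eta


def resistance(r, l, eta):
    """Poiseuille resistance 8·η·l/(π·r⁴) in the units of its arguments."""
    r = np.asarray(r, dtype=float)
    l = np.asarray(l, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(r <= 0) or np.any(l <= 0) or np.any(eta <= 0):
        raise ValueError("resistance requires positive radius, length and viscosity")
    out = _K8PI * eta * l / r**4
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# flow specification
# ---------------------------------------------------------------------------


@dataclass
class FlowSpec:
    """Inflow and outlet-flow closure of a forest.

    ``inflow``: total root inflow Q over all trees (mm³/s); if None, the sum
    of the per-root inflows recorded on the forest is used.
    ``outlet_fractions``: optional {vessel id: fraction of Q} written onto
    the forest's constrained-outlet bookkeeping before assignment.
    """

    inflow: float | None = None
    outlet_fractions: dict = field(default_factory=dict)


@dataclass
class HemoState:
    """Converged hemodynamic state of a forest."""

    forest: VascularForest
    Q: float
    q_f: float
    iterations: int = 0
    residual: float = 0.0

    def resistances(self) -> np.ndarray:
        f = self.forest
        n = f.n
        return resistance(f.radius[:n], f.length[:n], f.eta[:n] * CP_TO_PAS)

    def pressure_drops(self) -> np.ndarray:
        """Per-vessel Δp = R·q (Pa)."""
        f = self.forest
        return self.resistances() * f.flow[: f.n]

    def terminal_path_drops(self) -> np.ndarray:
        """Total root-to-terminal pressure drop for every free terminal."""
        f = self.forest
        dp = self.pressure_drops()
        out = []
        for t in f.free_terminals():
            out.append(sum(dp[k] for k in f.path_to_root(int(t))))
        return np.asarray(out)


# ---------------------------------------------------------------------------
# topology helpers (CSR children + topological orders)
# ---------------------------------------------------------------------------


def _topology(forest: VascularForest):
    n = forest.n
    parent = forest.parent[:n]
    depth = forest.depth[:n]
    order_desc = np.argsort(-depth, kind="stable").astype(np.int64)
    nonroot = np.nonzero(parent >= 0)[0]
    counts = np.bincount(parent[nonroot], minlength=n)
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    child_idx = nonroot[np.argsort(parent[nonroot], kind="stable")].astype(np.int64)
    return order_desc, ptr, child_idx


@njit(cache=True)
def _aggregate_pass(order_desc, child_ptr, child_idx, is_free_term, frac, nterm, qfrac):
    for oi in range(order_desc.shape[0]):
        i = order_desc[oi]
        c0, c1 = child_ptr[i], child_ptr[i + 1]
        if c1 == c0:
            nterm[i] = 1 if is_free_term[i] else 0
            qfrac[i] = frac[i]
        else:
            nt = 0
            qf = 0.0
            for ci in range(c0, c1):
                ch = child_idx[ci]
                nt += nterm[ch]
                qf += qfrac[ch]
            nterm[i] = nt
            qfrac[i] = qf


@njit(cache=True)
def _bottom_up_pass(order_desc, child_ptr, child_idx, a, length, q, gamma, rstar, vstar, beta, w):
    for oi in range(order_desc.shape[0]):
        i = order_desc[oi]
        c0, c1 = child_ptr[i], child_ptr[i + 1]
        if c1 == c0:
            rstar[i] = a[i]
            vstar[i] = length[i]
        else:
            S = 0.0
            for ci in range(c0, c1):
                S += w[child_idx[ci]] ** gamma
            Sg = S ** (1.0 / gamma)
            P = 0.0
            V = 0.0
            for ci in range(c0, c1):
                ch = child_idx[ci]
                b = w[ch] / Sg
                beta[ch] = b
                P += b**4 / rstar[ch]
                V += b * b * vstar[ch]
            rstar[i] = a[i] + 1.0 / P
            vstar[i] = length[i] + V
        w[i] = (q[i] * rstar[i]) ** 0.25


@njit(cache=True)
def _top_down_pass(order_desc, parent, beta, radius):
    # ascending depth = reversed descending order
    for oi in range(order_desc.shape[0] - 1, -1, -1):
        i = order_desc[oi]
        p = parent[i]
        if p >= 0:
            radius[i] = beta[i] * radius[p]


# ---------------------------------------------------------------------------
# flow assignment and radius update
# ---------------------------------------------------------------------------


def assign_flows(forest: VascularForest, spec: FlowSpec | None = None) -> HemoState:
    """Distribute the root inflow over terminals and propagate upwards.

    Constrained outlets carry their prescribed fraction of Q; the remaining
    flow splits equally over free terminals (q_f each); internal flows are
    subtree sums, so conservation at junctions is exact by construction.
    """
    spec = spec or FlowSpec()
    n = forest.n
    if n == 0:
        raise ValueError("empty forest")
    for vid, fr in spec.outlet_fractions.items():
        if not forest.is_terminal(vid):
            raise ValueError(f"constrained outlet {vid} is not a terminal vessel")
        forest.outlet_fraction[vid] = fr

    Q = spec.inflow if spec.inflow is not None else sum(forest.root_inflow.values())
    if Q <= 0:
        raise ValueError("total inflow must be positive")

    outlets = forest.constrained_outlets()
    fracs = forest.outlet_fraction[outlets]
    if np.any((fracs <= 0) | (fracs >= 1)):
        raise ValueError("outlet fractions must lie in (0, 1)")
    fsum = float(fracs.sum())
    n_free = forest.n_free_terminals()
    if n_free > 0:
        if fsum >= 1.0:
            raise ValueError(f"outlet fractions sum to {fsum} >= 1 with free terminals present")
        q_f = Q * (1.0 - fsum) / n_free
    else:
        if abs(fsum - 1.0) > 1e-9:
            raise ValueError("no free terminals: outlet fractions must sum to 1")
        q_f = 0.0

    order_desc, ptr, child_idx = _topology(forest)
    is_free = np.array(
        [forest.is_terminal(i) and forest.outlet_fraction[i] == 0.0 for i in range(n)],
        dtype=np.bool_,
    )
    nterm = np.zeros(n, dtype=np.int64)
    qfrac = np.zeros(n, dtype=np.float64)
    _aggregate_pass(order_desc, ptr, child_idx, is_free, forest.outlet_fraction[:n], nterm, qfrac)
    forest.flow[:n] = nterm * q_f + Q * qfrac
    # cache subtree terminal bookkeeping for incremental candidate evaluation
    forest._nterm = nterm
    forest._qfrac = qfrac
    forest._agg_version = forest._version
    return HemoState(forest, Q=Q, q_f=q_f)


def update_radii(
    forest: VascularForest,
    state: HemoState | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    gamma: float = 3.0,
    constant_viscosity: float | None = None,
) -> HemoState:
    """Fixed-point radius update with flows held fixed (Karch-style scheme).

    Alternates (a) a bottom-up pass computing reduced resistances R*,
    relative subtree volumes V* and radius ratios β at every junction with
    the current viscosities, and (b) a top-down pass rebuilding absolute
    radii from the fixed root radii, then refreshes η(r); stops when the
    largest relative radius change drops below ``tol``.

    ``constant_viscosity`` (cP) freezes η for closed-form checks.
    """
    if state is None:
        state = assign_flows(forest)
    n = forest.n
    order_desc, ptr, child_idx = _topology(forest)
    length = forest.length[:n]
    q = forest.flow[:n]
    radius = forest.radius[:n]
    if np.any(q < 0):
        raise ValueError("flows must be assigned and non-negative")

    rstar = forest.rstar[:n]
    vstar = forest.vstar[:n]
    beta = forest.beta[:n]
    w = np.empty(n)
    parent = forest.parent[:n]

    for it in range(1, max_iter + 1):
        if constant_viscosity is not None:
            forest.eta[:n] = constant_viscosity
        else:
            forest.eta[:n] = viscosity(np.maximum(radius, 2.0 * R_POLE))
        a = _K8PI * (forest.eta[:n] * CP_TO_PAS) * length
        _bottom_up_pass(order_desc, ptr, child_idx, a, length, q, gamma, rstar, vstar, beta, w)
        r_old = radius.copy()
        _top_down_pass(order_desc, parent, beta, radius)
        residual = float(np.max(np.abs(radius - r_old) / r_old))
        if residual < tol:
            state.iterations = it
            state.residual = residual
            return state
    raise ConvergenceError(
        f"radius fixed point did not converge in {max_iter} iterations",
        residual=residual,
        iterations=max_iter,
    )


def solve(forest: VascularForest, spec: FlowSpec | None = None, **kw) -> HemoState:
    """Convenience: assign flows then converge radii."""
    state = assign_flows(forest, spec)
    return update_radii(forest, state, **kw)


# ---------------------------------------------------------------------------
# incremental candidate evaluation
# ---------------------------------------------------------------------------


@dataclass
class CandidateEval:
    """Vectorised evaluation of trial bifurcations on one target vessel."""

    dvol: np.ndarray      # tree volume increment (mm³) per trial point
    r_vp: np.ndarray      # radius of the proximal half v_p
    r_vs: np.ndarray      # radius of the distal half v_s
    r_vnew: np.ndarray    # radius of the new terminal vessel
    l_vp: np.ndarray
    l_vs: np.ndarray
    l_vnew: np.ndarray
    beta_s: np.ndarray
    beta_new: np.ndarray


@njit(cache=True, fastmath=False)
def _visc_cp(r):
    """Scalar Fåhræus–Lindqvist viscosity (cP), floored away from the pole."""
    if r < 2.0 * R_POLE:
        r = 2.0 * R_POLE
    kappa = (r / (r - R_POLE)) ** 2
    return 1.125 * (kappa + kappa * kappa * (6.0 * np.exp(-170.0 * r) - 2.44 * np.exp(-8.09 * r**0.64) + 2.2))


@njit(cache=True)
def _eval_kernel(
    l_p, l_s, l_n,                       # (m,) prospective segment lengths
    path, sib_ptr, sib_idx,              # path j..root; off-path children per ancestor step
    sib0_idx,                            # children of j (distal mode junction siblings)
    rstar, vstar, eta, length, nterm, qfrac,
    radius_root, q_f, Q, gamma, n_iter, distal, eta_const,
    dvol, r_vp, r_vs, r_vn, beta_s, beta_n,
):
    cpas = CP_TO_PAS
    k8pi = _K8PI
    j = path[0]
    P = path.shape[0]
    eta_j = eta[j]
    a_j_cur = k8pi * (eta_j * cpas) * length[j]
    par_j = rstar[j] - a_j_cur
    if par_j < 0.0:
        par_j = 0.0
    vchild_j = vstar[j] - length[j]
    vstar_root_old = vstar[path[P - 1]]

    for i in range(l_n.shape[0]):
        e_p = eta_j if eta_const <= 0.0 else eta_const
        e_s = e_p
        e_n = e_p
        bs = 1.0
        bn = 1.0
        R_cur = 0.0
        V_cur = 0.0
        bprod = 1.0
        for _ in range(n_iter):
            a_n = k8pi * (e_n * cpas) * l_n[i]
            Rn = a_n
            Vn = l_n[i]
            wn = (q_f * Rn) ** 0.25

            if distal:
                S = wn**gamma
                for ci in range(sib0_idx.shape[0]):
                    c = sib0_idx[ci]
                    q_c = nterm[c] * q_f + Q * qfrac[c]
                    S += ((q_c * rstar[c]) ** 0.25) ** gamma
                Sg = S ** (1.0 / gamma)
                bn = wn / Sg
                Pp = bn**4 / Rn
                V = bn * bn * Vn
                for ci in range(sib0_idx.shape[0]):
                    c = sib0_idx[ci]
                    q_c = nterm[c] * q_f + Q * qfrac[c]
                    wc = (q_c * rstar[c]) ** 0.25
                    bc = wc / Sg
                    Pp += bc**4 / rstar[c]
                    V += bc * bc * vstar[c]
                a_p = k8pi * (e_p * cpas) * l_p[i]
                R_cur = a_p + 1.0 / Pp
                V_cur = l_p[i] + V
                q_cur = (nterm[j] + 1) * q_f + Q * qfrac[j]
                bs = 1.0
            else:
                a_s = k8pi * (e_s * cpas) * l_s[i]
                a_p = k8pi * (e_p * cpas) * l_p[i]
                Rs = a_s + par_j
                Vs = vchild_j + l_s[i]
                q_s = nterm[j] * q_f + Q * qfrac[j]
                ws = (q_s * Rs) ** 0.25
                S = ws**gamma + wn**gamma
                Sg = S ** (1.0 / gamma)
                bs = ws / Sg
                bn = wn / Sg
                Pp = bs**4 / Rs + bn**4 / Rn
                V = bs * bs * Vs + bn * bn * Vn
                R_cur = a_p + 1.0 / Pp
                V_cur = l_p[i] + V
                q_cur = q_s + q_f

            w_cur = (q_cur * R_cur) ** 0.25
            bprod = 1.0
            prev = j
            for t in range(1, P):
                anc = path[t]
                S = w_cur**gamma
                for ci in range(sib_ptr[t], sib_ptr[t + 1]):
                    c = sib_idx[ci]
                    q_c = nterm[c] * q_f + Q * qfrac[c]
                    S += ((q_c * rstar[c]) ** 0.25) ** gamma
                Sg = S ** (1.0 / gamma)
                b_cur = w_cur / Sg
                Pp = b_cur**4 / R_cur
                V = b_cur * b_cur * V_cur
                for ci in range(sib_ptr[t], sib_ptr[t + 1]):
                    c = sib_idx[ci]
                    q_c = nterm[c] * q_f + Q * qfrac[c]
                    wc = (q_c * rstar[c]) ** 0.25
                    bc = wc / Sg
                    Pp += bc**4 / rstar[c]
                    V += bc * bc * vstar[c]
                a_anc = k8pi * (eta[anc] * cpas) * length[anc]
                R_cur = a_anc + 1.0 / Pp
                V_cur = length[anc] + V
                q_cur = (nterm[anc] + 1) * q_f + Q * qfrac[anc]
                w_cur = (q_cur * R_cur) ** 0.25
                bprod *= b_cur
                prev = anc

            if eta_const <= 0.0:
                rp = radius_root * bprod
                e_p = _visc_cp(rp)
                e_s = _visc_cp(bs * rp)
                e_n = _visc_cp(bn * rp)

        r_vp[i] = radius_root * bprod
        r_vs[i] = bs * r_vp[i] if not distal else r_vp[i]
        r_vn[i] = bn * r_vp[i]
        beta_s[i] = bs
        beta_n[i] = bn
        dvol[i] = np.pi * radius_root**2 * (V_cur - vstar_root_old)


def evaluate_candidates(
    forest: VascularForest,
    j: int,
    xb: np.ndarray,
    x_new: np.ndarray,
    gamma: float = 3.0,
    n_iter: int = 2,
    distal: bool = False,
    constant_viscosity: float | None = None,
) -> CandidateEval:
    """Path-to-root update of R*/V* for trial bifurcation points on vessel j.

    Off the root path nothing changes: subtree ratio structures depend only
    on flow *ratios*, which the global q_f rescaling preserves, and off-path
    viscosities are frozen.  The evaluation is therefore exact (up to the
    inner fixed point) in the absence of constrained outlets and a close
    approximation otherwise; the engine re-evaluates its short-list of best
    candidates with a full recomputation before committing.

    ``distal=True`` evaluates a distal attachment (v_new appended as an
    extra child of j, no split); ``xb`` must then be the single distal
    point of j.
    """
    n = forest.n
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    m = len(xb)
    x_new = np.asarray(x_new, dtype=float)

    nterm = forest._nterm
    qfrac = forest._qfrac
    ver = forest._version
    if getattr(forest, "_eval_cache_ver", -1) != ver:
        Q = sum(forest.root_inflow.values())
        fsum = float(sum(forest.outlet_fraction[forest.constrained_outlets()]))
        n_free = int(sum(nterm[r] for r in forest.roots))
        forest._eval_glob = (Q, fsum, n_free)
        forest._eval_cache = {}
        forest._eval_cache_ver = ver
    Q, fsum, n_free = forest._eval_glob
    q_f = Q * (1.0 - fsum) / (n_free + 1)

    ent = forest._eval_cache.get(j)
    if ent is None:
        path = np.asarray(forest.path_to_root(j), dtype=np.int64)
        sib_lists = [[]]
        prev = j
        for anc in path[1:]:
            sib_lists.append([c for c in forest.children[int(anc)] if c != prev])
            prev = int(anc)
        sib_ptr = np.zeros(len(path) + 1, dtype=np.int64)
        np.cumsum([len(s) for s in sib_lists], out=sib_ptr[1:])
        sib_idx = np.array([c for s in sib_lists for c in s], dtype=np.int64)
        sib0_idx = np.array(forest.children[j], dtype=np.int64)
        ent = (path, sib_ptr, sib_idx, sib0_idx)
        forest._eval_cache[j] = ent
    path, sib_ptr, sib_idx, sib0_idx = ent
    root = int(path[-1])
    r_root = float(forest.radius[root])

    l_n = np.linalg.norm(x_new[None, :] - xb, axis=1)
    if distal:
        l_p = np.full(m, float(forest.length[j]))
        l_s = np.zeros(m)
    else:
        l_p = np.linalg.norm(xb - forest.xp[j][None, :], axis=1)
        l_s = np.linalg.norm(forest.xd[j][None, :] - xb, axis=1)

    dvol = np.empty(m)
    r_vp = np.empty(m)
    r_vs = np.empty(m)
    r_vn = np.empty(m)
    beta_s = np.empty(m)
    beta_n = np.empty(m)
    _eval_kernel(
        l_p, l_s, l_n, path, sib_ptr, sib_idx, sib0_idx,
        forest.rstar[:n], forest.vstar[:n], forest.eta[:n], forest.length[:n],
        nterm, qfrac, r_root, q_f, Q, gamma, max(1, n_iter), distal,
        -1.0 if constant_viscosity is None else float(constant_viscosity),
        dvol, r_vp, r_vs, r_vn, beta_s, beta_n,
    )
    return CandidateEval(
        dvol=dvol, r_vp=r_vp, r_vs=r_vs, r_vnew=r_vn,
        l_vp=l_p, l_vs=l_s, l_vnew=l_n, beta_s=beta_s, beta_new=beta_n,
    )
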