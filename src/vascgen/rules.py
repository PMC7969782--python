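"""Feasibility rules for candidate bifurcations.

A trial connection is admissible only if it simultaneously satisfies the
branching-behaviour eligibility of the target vessel, role-dependent
containment of the bifurcation site and of the new segment, cylinder
non-intersection against non-adjacent vessels, and the geometric
constraints: Murray's law (enforced by construction in the radius solver),
the sibling symmetry ratio, the slenderness (aspect) bound l/r > 2, and
optional bifurcation/opening angle windows.

All constraints are hard rejects; the gate returns reason codes rather
than raising.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tree as T

_DEG = 180.0 / np.pi


@dataclass
class GeoParams:
    """Murray exponent γ and symmetry ratio δ.

    δ may be a constant or a step over the parent's bifurcation level:
    ``delta=(threshold, below, at_or_above)`` applies ``below`` when
    l_bif < threshold and ``at_or_above`` otherwise.
    """

    gamma: float = 3.0
    delta: float | tuple = 0.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        values = self.delta[1:] if isinstance(self.delta, tuple) else (self.delta,)
        for d in values:
            if not 0.0 <= d < 1.0:
                raise ValueError("delta must lie in [0, 1)")

    def delta_at(self, level: int) -> float:
        """Effective δ at the given parent bifurcation level."""
        if isinstance(self.delta, tuple):
            thr, below, above = self.delta
            return below if level < thr else above
        return float(self.delta)


@dataclass
class AngleParams:
    """Bifurcation angle θ and opening angle φ windows, degrees."""

    theta_min: float = 0.0
    theta_max: float = 180.0
    phi_min: float = 0.0
    phi_max: float = 180.0
    theta_enabled: bool = False
    phi_enabled: bool = False

    def __post_init__(self):
        for lo, hi in ((self.theta_min, self.theta_max), (self.phi_min, self.phi_max)):
            if not 0.0 <= lo <= hi <= 180.0:
                raise ValueError("angle windows must satisfy 0 <= min <= max <= 180")


def check_murray(r_p, r_s1, r_s2, gamma, tol: float = 1e-6):
    """Residual test of r_p^γ = r_s1^γ + r_s2^γ. Returns (ok, residual)."""
    res = abs(r_p**gamma - r_s1**gamma - r_s2**gamma) / r_p**gamma
    return res < tol, res


def check_symmetry(r_s1, r_s2, delta_effective):
    """min/max sibling radius ratio must exceed δ."""
    r_s1 = np.asarray(r_s1, float)
    r_s2 = np.asarray(r_s2, float)
    ratio = np.minimum(r_s1, r_s2) / np.maximum(r_s1, r_s2)
    out = ratio > delta_effective
    return bool(out) if out.ndim == 0 else out


def check_aspect(l, r):
    """Slenderness bound l/r > 2 (strict)."""
    out = np.asarray(l, float) > 2.0 * np.asarray(r, float)
    return bool(out) if out.ndim == 0 else out


def bifurcation_angle(x_b, x_d_j, x_d_i):
    """Angle θ between the distal sibling arm and the new vessel, degrees.

    Vectorised over x_b (m, 3); the arccos argument is clamped to [-1, 1].
    """
    scalar = np.asarray(x_b).ndim == 1
    x_b = np.atleast_2d(np.asarray(x_b, float))
    u = np.asarray(x_d_j, float)[None, :] - x_b
    v = np.asarray(x_d_i, float)[None, :] - x_b
    lu = np.linalg.norm(u, axis=1)
    lv = np.linalg.norm(v, axis=1)
    if np.any(lu == 0) or np.any(lv == 0):
        raise ValueError("zero-length bifurcation arm")
    c = np.clip(np.einsum("ij,ij->i", u, v) / (lu * lv), -1.0, 1.0)
    ang = np.arccos(c) * _DEG
    return float(ang[0]) if scalar else ang


def opening_angle(x_b, x_p_j, x_d_j, x_d_i):
    """Angle φ between the new vessel and the v_p–v_s bifurcation plane.

    φ = 90° − arccos(|⟨n, x_d_i − x_b⟩| / (‖n‖·l_new)) with
    n = (x_d_j − x_b) × (x_p_j − x_b).  Returns NaN where the plane is
    degenerate (collinear v_p and v_s); the caller treats that as
    constraint-satisfied.
    """
    scalar = np.asarray(x_b).ndim == 1
    x_b = np.atleast_2d(np.asarray(x_b, float))
    n = np.cross(np.asarray(x_d_j, float)[None, :] - x_b, np.asarray(x_p_j, float)[None, :] - x_b)
    v = np.asarray(x_d_i, float)[None, :] - x_b
    nn = np.linalg.norm(n, axis=1)
    lv = np.linalg.norm(v, axis=1)
    if np.any(lv == 0):
        raise ValueError("zero-length new vessel")
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.clip(np.abs(np.einsum("ij,ij->i", n, v)) / (nn * lv), -1.0, 1.0)
        phi = 90.0 - np.arccos(c) * _DEG
    phi = np.where(nn == 0, np.nan, phi)
    return float(phi[0]) if scalar else phi


# ---------------------------------------------------------------------------
# intersection test
# ---------------------------------------------------------------------------


def junction_exempt(forest: T.VascularForest, i: int, hops: int = 3) -> set[int]:
    """Vessels within ``hops`` parent/child links of i, exempt from clash tests.

    Adjacent cylinders necessarily overlap around their shared junction,
    and the aspect bound only guarantees segment lengths above 2r, so
    vessels joined through one or two short intermediate segments sit on
    overlapping junction clusters: contact there is junction geometry,
    not inter-penetration of distant branches.  Distant pairs (more than
    ``hops`` links apart) are always checked strictly.
    """
    out = {i}
    frontier = [i]
    for _ in range(hops):
        nxt = []
        for k in frontier:
            nb = list(forest.children[k])
            p = int(forest.parent[k])
            if p >= 0:
                nb.append(p)
            for m in nb:
                if m not in out:
                    out.add(m)
                    nxt.append(m)
        frontier = nxt
    return out


def segments_clash(forest: T.VascularForest, a, b, r_new: float, exempt: set[int],
                   headroom: float = 1.0) -> bool:
    """True if cylinder (a, b, r_new) clashes with any non-exempt vessel.

    Clash = minimum distance between segment axes < (r_a + r_b)·headroom;
    vessels around the shared junction are exempt.  The growth gate uses a
    headroom > 1 so that the few-percent radius drift of later
    re-convergences cannot turn an accepted configuration into a clash;
    the post-hoc audit uses the strict bound.
    """
    n = forest.n
    if n == 0:
        return False
    mask = np.ones(n, dtype=bool)
    for e in exempt:
        if 0 <= e < n:
            mask[e] = False
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return False
    d = T.segment_segment_distance(a, b, forest.xp[idx], forest.xd[idx])
    return bool(np.any(d < (r_new + forest.radius[idx]) * headroom))


def whole_tree_ok(forest: T.VascularForest, geo: GeoParams) -> bool:
    """Fast whole-tree re-check of the radius-dependent constraints.

    Adding a vessel reshapes every radius in the tree (the terminal
    outflow and all ratio products change), so the admissible set demands
    that the *reshaped* tree still satisfies the aspect and symmetry
    bounds everywhere, not just at the new bifurcation.  Pre-existing
    (stage 0) vessels are exempt: imported anatomy is taken as given.

    Murray's law and flow conservation hold by construction of the radius
    solver, and angle/containment constraints are pure geometry that never
    drifts, so only aspect and symmetry need the global check.
    """
    n = forest.n
    gen = forest.stage[:n] > 0
    if np.any(forest.length[:n][gen] <= 2.0 * forest.radius[:n][gen]):
        return False

    # symmetry: per-junction min/max sibling radius ratio (vectorised)
    has_delta = geo.delta_at(0) > 0 or (isinstance(geo.delta, tuple) and max(geo.delta[1:]) > 0)
    if not has_delta:
        return True
    parent = forest.parent[:n]
    child = np.nonzero(parent >= 0)[0]
    if len(child) == 0:
        return True
    par = parent[child]
    rmin = np.full(n, np.inf)
    rmax = np.zeros(n)
    np.minimum.at(rmin, par, forest.radius[child])
    np.maximum.at(rmax, par, forest.radius[child])
    counts = np.bincount(par, minlength=n)
    junc = np.nonzero(counts >= 2)[0]
    # only junctions with at least one generated child are constrained
    gen_child = np.zeros(n, dtype=bool)
    np.logical_or.at(gen_child, par, gen[child])
    junc = junc[gen_child[junc]]
    if len(junc) == 0:
        return True
    deltas = np.array([geo.delta_at(int(forest.level[i])) for i in junc])
    return bool(np.all(rmin[junc] / rmax[junc] > deltas))


# ---------------------------------------------------------------------------
# post-hoc audit
# ---------------------------------------------------------------------------


def audit_tree(
    forest: T.VascularForest,
    domain,
    geo: GeoParams,
    angles: AngleParams | None = None,
    murray_tol: float = 1e-6,
    generated_only: bool = True,
    check_intersections: bool = True,
) -> list[str]:
    """Re-check every (generated) vessel and bifurcation of a finished tree.

    Returns a list of human-readable violations (empty = clean audit).
    Pre-existing (stage 0) vessels are skipped unless ``generated_only`` is
    False, since imported anatomy need not satisfy the constructive rules.
    """
    problems = []
    n = forest.n
    gen = forest.stage[:n] > 0

    for i in range(n):
        if generated_only and not gen[i]:
            continue
        # aspect
        if not check_aspect(forest.length[i], forest.radius[i]):
            problems.append(f"vessel {i}: aspect l/r = {forest.length[i]/forest.radius[i]:.4f} <= 2")
        # role containment
        role = int(forest.role[i])
        if role == T.DISTRIBUTION:
            if not domain.segment_in_domain(forest.xp[i], forest.xd[i]):
                problems.append(f"vessel {i}: distribution vessel leaves the domain")
        elif role == T.PERFORATOR:
            if forest.is_terminal(i) and not domain.contains(forest.xd[i]):
                problems.append(f"vessel {i}: perforator terminal outside the domain")

    # bifurcation-level checks
    for i in range(n):
        ch = forest.children[i]
        if len(ch) < 2:
            continue
        if generated_only and not any(gen[c] for c in ch):
            continue
        r_p = float(forest.radius[i])
        rc = forest.radius[ch]
        # Murray (generalised to N children)
        res = abs(r_p**geo.gamma - float(np.sum(rc**geo.gamma))) / r_p**geo.gamma
        if res >= murray_tol:
            problems.append(f"junction {i}: Murray residual {res:.2e}")
        # symmetry over the sibling set
        if float(rc.min()) / float(rc.max()) <= geo.delta_at(int(forest.level[i])) and geo.delta_at(int(forest.level[i])) > 0:
            problems.append(f"junction {i}: symmetry ratio {rc.min()/rc.max():.3f}")
        # bifurcation-site containment by the parent's role
        if int(forest.role[i]) in (T.DISTRIBUTION, T.PERFORATOR) and not domain.contains(forest.xd[i]):
            problems.append(f"junction {i}: bifurcation site outside the domain")
        # flow conservation
        if abs(forest.flow[i] - float(np.sum(forest.flow[ch]))) > 1e-9 * max(forest.flow[i], 1e-30):
            problems.append(f"junction {i}: flow not conserved")
        if angles is not None and angles.theta_enabled and len(ch) == 2:
            th = bifurcation_angle(forest.xd[i], forest.xd[ch[0]], forest.xd[ch[1]])
            if not (angles.theta_min < th < angles.theta_max):
                problems.append(f"junction {i}: bifurcation angle {th:.1f} outside window")

    if check_intersections:
        for i in range(n):
            if generated_only and not gen[i]:
                continue
            exempt = junction_exempt(forest, i)
            if segments_clash(forest, forest.xp[i], forest.xd[i], float(forest.radius[i]), exempt):
                problems.append(f"vessel {i}: cylinder intersection")
    return problems
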