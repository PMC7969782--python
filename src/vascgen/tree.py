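"""N-ary vascular forest: rooted trees of straight cylindrical segments.

The forest is stored struct-of-arrays for fast vectorised geometry and
hemodynamics.  Each vessel has a proximal point ``xp``, distal point ``xd``,
radius, flow, a *role* (where it may lie / host bifurcations relative to the
perfusion domain), a *branching behaviour* (which bifurcation sites it
offers), a stage id and parent/children links.  Junctions may have any
number of children: unary chains represent tortuous vessels, binary
junctions are true bifurcations and higher multiplicities model
trifurcations and beyond.

Mutating operations (terminal insertion) support rollback through full
state snapshots, which is how tentative candidate evaluations are undone.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# vessel roles
DISTRIBUTION, TRANSPORT, PERFORATOR = 0, 1, 2
ROLE_NAMES = {DISTRIBUTION: "distribution", TRANSPORT: "transport", PERFORATOR: "perforator"}
ROLE_CODES = {v: k for k, v in ROLE_NAMES.items()}

# branching behaviours
NON_BRANCHING, DISTAL, FIXED, VERSATILE = 0, 1, 2, 3
BEHAVIOUR_NAMES = {NON_BRANCHING: "non-branching", DISTAL: "distal", FIXED: "fixed", VERSATILE: "versatile"}
BEHAVIOUR_CODES = {v: k for k, v in BEHAVIOUR_NAMES.items()}

_FLOAT_FIELDS = ("radius", "flow", "eta", "rstar", "vstar", "beta", "length", "outlet_fraction")
_INT_FIELDS = ("parent", "depth", "level", "role", "behaviour", "stage")


@dataclass
class Snapshot:
    """Opaque rollback handle: full copy of the mutable forest state."""

    n: int
    xp: np.ndarray
    xd: np.ndarray
    floats: dict
    ints: dict
    children: list
    roots: list
    root_inflow: dict


class VascularForest:
    """One or more rooted N-ary vascular trees sharing a perfusion domain."""

    def __init__(self, capacity: int = 64):
        cap = max(capacity, 8)
        self.n = 0
        self.xp = np.zeros((cap, 3))
        self.xd = np.zeros((cap, 3))
        for f in _FLOAT_FIELDS:
            setattr(self, f, np.zeros(cap))
        for f in _INT_FIELDS:
            setattr(self, f, np.zeros(cap, dtype=np.int64))
        self.children: list[list[int]] = []
        self.roots: list[int] = []
        self.root_inflow: dict[int, float] = {}
        self._version = 0      # bumped on every topology mutation
        self._agg_version = -1  # version at which flow aggregates were built

    # -- bookkeeping ------------------------------------------------------
    def _grow(self, need: int):
        cap = len(self.radius)
        if self.n + need <= cap:
            return
        new_cap = max(cap * 2, self.n + need)
        self.xp = np.resize(self.xp, (new_cap, 3))
        self.xd = np.resize(self.xd, (new_cap, 3))
        for f in _FLOAT_FIELDS:
            setattr(self, f, np.resize(getattr(self, f), new_cap))
        for f in _INT_FIELDS:
            setattr(self, f, np.resize(getattr(self, f), new_cap))

    def _new_slot(self) -> int:
        self._version += 1
        self._grow(1)
        i = self.n
        self.n += 1
        self.children.append([])
        # defaults
        self.parent[i] = -1
        self.outlet_fraction[i] = 0.0
        self.beta[i] = 1.0
        return i

    def __len__(self):
        return self.n

    # -- queries ----------------------------------------------------------
    def is_terminal(self, i: int) -> bool:
        return len(self.children[i]) == 0

    def terminals(self) -> np.ndarray:
        return np.array([i for i in range(self.n) if not self.children[i]], dtype=np.int64)

    def free_terminals(self) -> np.ndarray:
        t = self.terminals()
        return t[self.outlet_fraction[t] == 0.0]

    def constrained_outlets(self) -> np.ndarray:
        idx = np.arange(self.n)
        return idx[self.outlet_fraction[: self.n] > 0.0]

    def n_free_terminals(self) -> int:
        if self._agg_version == self._version and self.roots:
            return int(sum(self._nterm[r] for r in self.roots))
        return int(len(self.free_terminals()))

    def bifurcation_level(self, i: int) -> int:
        """Number of true (>= 2 children) junctions on the path from the root."""
        return int(self.level[i])

    def subtree(self, i: int) -> list[int]:
        out = []
        stack = [i]
        while stack:
            k = stack.pop()
            out.append(k)
            stack.extend(self.children[k])
        return out

    def root_of(self, i: int) -> int:
        while self.parent[i] >= 0:
            i = int(self.parent[i])
        return i

    def path_to_root(self, i: int) -> list[int]:
        """Vessel indices from i (inclusive) up to its root (inclusive)."""
        out = [i]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    # -- construction -----------------------------------------------------
    def add_vessel(
        self,
        xp,
        xd,
        radius: float,
        parent: int = -1,
        role: int = DISTRIBUTION,
        behaviour: int = VERSATILE,
        stage: int = 0,
        inflow: float = 0.0,
        outlet_fraction: float = 0.0,
    ) -> int:
        """Append a vessel; roots (parent=-1) carry a fixed radius and inflow."""
        i = self._new_slot()
        self.xp[i] = np.asarray(xp, dtype=float)
        self.xd[i] = np.asarray(xd, dtype=float)
        self.length[i] = float(np.linalg.norm(self.xd[i] - self.xp[i]))
        self.radius[i] = float(radius)
        self.role[i] = role
        self.behaviour[i] = behaviour
        self.stage[i] = stage
        self.outlet_fraction[i] = outlet_fraction
        self.parent[i] = parent
        if parent < 0:
            self.roots.append(i)
            self.root_inflow[i] = float(inflow)
            self.depth[i] = 0
            self.level[i] = 0
        else:
            if not np.allclose(self.xp[i], self.xd[parent]):
                raise ValueError("child proximal point must coincide with parent distal point")
            self.children[parent].append(i)
            self._refresh_subtree_meta(parent)
        return i

    def _refresh_subtree_meta(self, top: int):
        """Recompute depth and bifurcation level below (and including) ``top``."""
        p = int(self.parent[top])
        stack = [top]
        while stack:
            k = stack.pop()
            q = int(self.parent[k])
            if q < 0:
                self.depth[k] = 0
                self.level[k] = 0
            else:
                self.depth[k] = self.depth[q] + 1
                self.level[k] = self.level[q] + (1 if len(self.children[q]) >= 2 else 0)
            stack.extend(self.children[k])

    # -- snapshot / rollback ---------------------------------------------
    def snapshot(self) -> Snapshot:
        n = self.n
        return Snapshot(
            n=n,
            xp=self.xp[:n].copy(),
            xd=self.xd[:n].copy(),
            floats={f: getattr(self, f)[:n].copy() for f in _FLOAT_FIELDS},
            ints={f: getattr(self, f)[:n].copy() for f in _INT_FIELDS},
            children=[list(c) for c in self.children],
            roots=list(self.roots),
            root_inflow=dict(self.root_inflow),
        )

    def restore(self, snap: Snapshot):
        self._version += 1
        n = snap.n
        self._grow(max(0, n - self.n))
        self.n = n
        self.xp[:n] = snap.xp
        self.xd[:n] = snap.xd
        for f in _FLOAT_FIELDS:
            getattr(self, f)[:n] = snap.floats[f]
        for f in _INT_FIELDS:
            getattr(self, f)[:n] = snap.ints[f]
        self.children = [list(c) for c in snap.children]
        self.roots = list(snap.roots)
        self.root_inflow = dict(snap.root_inflow)

    # -- terminal insertion ----------------------------------------------
    def insert_terminal(
        self,
        j: int,
        x_b,
        x_d_new,
        stage: int = 0,
        role: int = DISTRIBUTION,
        behaviour: int = VERSATILE,
    ) -> tuple[Snapshot, int, int]:
        """Connect a new terminal at bifurcation point ``x_b`` on vessel ``j``.

        If ``x_b`` is interior to ``j``, the vessel is split into a proximal
        half ``v_p`` and distal half ``v_s`` (which keeps j's index, children,
        role and behaviour) and the new terminal becomes a sibling of
        ``v_s``.  If ``x_b`` coincides with j's distal point (distal
        behaviour), the terminal is appended as an additional child of j.

        Returns ``(rollback handle, index of v_new, index of v_p or j)``.
        """
        if not 0 <= j < self.n:
            raise ValueError(f"vessel {j} not in forest")
        x_b = np.asarray(x_b, dtype=float)
        x_d_new = np.asarray(x_d_new, dtype=float)
        snap = self.snapshot()

        if np.array_equal(x_b, self.xd[j]) or np.linalg.norm(x_b - self.xd[j]) < 1e-14:
            # distal attachment: no split
            k = self.add_vessel(
                self.xd[j], x_d_new, radius=self.radius[j], parent=j,
                role=role, behaviour=behaviour, stage=stage,
            )
            return snap, k, j

        if self.behaviour[j] == DISTAL:
            raise ValueError("distal-behaviour vessel only accepts its distal point as x_b")

        # split: p takes j's parent link and proximal half; j becomes v_s
        p = self._new_slot()
        self.xp[p] = self.xp[j]
        self.xd[p] = x_b
        self.length[p] = float(np.linalg.norm(x_b - self.xp[j]))
        self.radius[p] = self.radius[j]
        self.role[p] = self.role[j]  # proximal half keeps the parent's role
        self.behaviour[p] = NON_BRANCHING if self.behaviour[j] == NON_BRANCHING else VERSATILE
        self.stage[p] = self.stage[j]
        self.outlet_fraction[p] = 0.0
        self.eta[p] = self.eta[j]

        old_parent = int(self.parent[j])
        self.parent[p] = old_parent
        if old_parent < 0:
            # j was a root: p inherits root status, fixed radius and inflow
            self.roots[self.roots.index(j)] = p
            self.root_inflow[p] = self.root_inflow.pop(j)
        else:
            pc = self.children[old_parent]
            pc[pc.index(j)] = p

        self.parent[j] = p
        self.xp[j] = x_b
        self.length[j] = float(np.linalg.norm(self.xd[j] - x_b))

        k = self.add_vessel(x_b, x_d_new, radius=self.radius[j], parent=p,
                            role=role, behaviour=behaviour, stage=stage)
        self.children[p] = [j, k]
        self._refresh_subtree_meta(p)
        return snap, k, p

    # -- spatial queries --------------------------------------------------
    def _seg_point_distance(self, x: np.ndarray) -> np.ndarray:
        """Distance from point x to every vessel segment (vectorised)."""
        n = self.n
        a = self.xp[:n]
        d = self.xd[:n] - a
        l2 = np.einsum("ij,ij->i", d, d)
        t = np.einsum("ij,ij->i", x[None, :] - a, d) / np.where(l2 > 0, l2, 1.0)
        t = np.clip(t, 0.0, 1.0)
        closest = a + t[:, None] * d
        return np.linalg.norm(closest - x[None, :], axis=1), closest

    def min_point_distance(self, x) -> tuple[float, np.ndarray]:
        """Distance from x to the closest point on any vessel segment."""
        if self.n == 0:
            raise ValueError("empty forest")
        dist, closest = self._seg_point_distance(np.asarray(x, dtype=float))
        i = int(np.argmin(dist))
        return float(dist[i]), closest[i]

    def neighbourhood(self, x, radius: float) -> np.ndarray:
        """Vessels whose segment lies within ``radius`` of x, sorted by distance."""
        if radius <= 0:
            raise ValueError("radius must be positive")
        if self.n == 0:
            return np.empty(0, dtype=np.int64)
        dist, _ = self._seg_point_distance(np.asarray(x, dtype=float))
        idx = np.nonzero(dist <= radius)[0]
        return idx[np.argsort(dist[idx], kind="stable")]

    # -- integrity --------------------------------------------------------
    def validate(self):
        """Check the forest is a set of rooted trees with consistent links."""
        seen = np.zeros(self.n, dtype=bool)
        for r in self.roots:
            if self.parent[r] >= 0:
                raise AssertionError("root with a parent")
            for k in self.subtree(r):
                if seen[k]:
                    raise AssertionError("cycle or shared vessel detected")
                seen[k] = True
        if not seen.all():
            raise AssertionError("orphan vessels outside any root's tree")
        for i in range(self.n):
            for c in self.children[i]:
                if int(self.parent[c]) != i:
                    raise AssertionError("parent/child link mismatch")
                if not np.array_equal(self.xp[c], self.xd[i]):
                    raise AssertionError("child proximal point != parent distal point")


def segment_segment_distance(p1, q1, p2, q2) -> np.ndarray:
    """Minimum distance between segment (p1,q1) and each segment (p2[i], q2[i]).

    Standard clamped closest-point computation, vectorised over the second
    argument.
    """
    p1 = np.asarray(p1, float)
    q1 = np.asarray(q1, float)
    p2 = np.atleast_2d(np.asarray(p2, float))
    q2 = np.atleast_2d(np.asarray(q2, float))
    d1 = q1 - p1                       # (3,)
    d2 = q2 - p2                       # (n,3)
    r = p1[None, :] - p2               # (n,3)
    a = float(np.dot(d1, d1))
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = d2 @ d1                        # (n,)  d1·d2 per pair
    g = r @ d1                         # (n,)  d1·r  per pair
    eps = 1e-300

    denom = a * e - c * c
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > eps, np.clip((c * f - g * e) / np.where(denom > eps, denom, 1.0), 0.0, 1.0), 0.0)
        t = np.where(e > eps, (c * s + f) / np.where(e > eps, e, 1.0), 0.0)
        # clamp t, then recompute s for clamped t
        t_cl = np.clip(t, 0.0, 1.0)
        if a > eps:
            s = np.where(t != t_cl, np.clip((c * t_cl - g) / a, 0.0, 1.0), s)
        else:
            s = np.zeros_like(s)
    c1 = p1[None, :] + s[:, None] * d1[None, :]
    c2 = p2 + t_cl[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1)


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


if _njit is not None:

    @_njit(cache=True)
    def _clash_mask_kernel(pts, x_new, xp_j, xd_j, r_vp, r_vs, r_vn, distal,
                           xp, xd, radius, idx, exempt, headroom, clear):
        """clear[i] = False where any prospective segment of candidate i
        comes within the clash distance of a non-exempt nearby vessel.

        Families per candidate: the new terminal vessel x_b→x_new and, for
        split candidates, the proximal and distal halves of the split
        vessel; exempt is a (3, n) flag table per family.
        """
        n_f = 1 if distal else 3
        for i in range(pts.shape[0]):
            clear[i] = True
            for f in range(n_f):
                if f == 0:
                    ax, ay, az = pts[i, 0], pts[i, 1], pts[i, 2]
                    bx, by, bz = x_new[0], x_new[1], x_new[2]
                    rf = r_vn[i]
                elif f == 1:
                    ax, ay, az = xp_j[0], xp_j[1], xp_j[2]
                    bx, by, bz = pts[i, 0], pts[i, 1], pts[i, 2]
                    rf = r_vp[i]
                else:
                    ax, ay, az = pts[i, 0], pts[i, 1], pts[i, 2]
                    bx, by, bz = xd_j[0], xd_j[1], xd_j[2]
                    rf = r_vs[i]
                d1x, d1y, d1z = bx - ax, by - ay, bz - az
                a = d1x * d1x + d1y * d1y + d1z * d1z
                for ki in range(idx.shape[0]):
                    k = idx[ki]
                    if exempt[f, k]:
                        continue
                    px, py, pz = xp[k, 0], xp[k, 1], xp[k, 2]
                    d2x, d2y, d2z = xd[k, 0] - px, xd[k, 1] - py, xd[k, 2] - pz
                    rx, ry, rz = ax - px, ay - py, az - pz
                    e = d2x * d2x + d2y * d2y + d2z * d2z
                    ff = d2x * rx + d2y * ry + d2z * rz
                    c = d1x * d2x + d1y * d2y + d1z * d2z
                    g = d1x * rx + d1y * ry + d1z * rz
                    denom = a * e - c * c
                    if denom > 1e-300:
                        s = (c * ff - g * e) / denom
                        if s < 0.0:
                            s = 0.0
                        elif s > 1.0:
                            s = 1.0
                    else:
                        s = 0.0
                    if e > 1e-300:
                        t = (c * s + ff) / e
                    else:
                        t = 0.0
                    if t < 0.0 or t > 1.0:
                        t = 0.0 if t < 0.0 else 1.0
                        if a > 1e-300:
                            s = (c * t - g) / a
                            if s < 0.0:
                                s = 0.0
                            elif s > 1.0:
                                s = 1.0
                    ex = ax + s * d1x - (px + t * d2x)
                    ey = ay + s * d1y - (py + t * d2y)
                    ez = az + s * d1z - (pz + t * d2z)
                    lim = (rf + radius[k]) * headroom
                    if ex * ex + ey * ey + ez * ez < lim * lim:
                        clear[i] = False
                        break
                if not clear[i]:
                    break


def segment_segment_distance_batch(p1, q1, p2, q2) -> np.ndarray:
    """Pairwise minimum distances between m segments and k segments, (m, k).

    Same clamped closest-point computation as
    :func:`segment_segment_distance`, broadcast over both families.
    """
    p1 = np.atleast_2d(np.asarray(p1, float))[:, None, :]   # (m,1,3)
    q1 = np.atleast_2d(np.asarray(q1, float))[:, None, :]
    p2 = np.atleast_2d(np.asarray(p2, float))[None, :, :]   # (1,k,3)
    q2 = np.atleast_2d(np.asarray(q2, float))[None, :, :]
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2                                             # (m,k,3)
    a = np.einsum("mij,mij->mi", d1, d1)                    # (m,1)
    e = np.einsum("ikj,ikj->ik", d2, d2)                    # (1,k)
    f = np.einsum("ikj,mkj->mk", d2, r)
    c = np.einsum("mij,ikj->mk", d1, d2)
    g = np.einsum("mij,mkj->mk", d1, r)
    eps = 1e-300
    denom = a * e - c * c
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > eps, np.clip((c * f - g * e) / np.where(denom > eps, denom, 1.0), 0.0, 1.0), 0.0)
        t = np.where(e > eps, (c * s + f) / np.where(e > eps, e, 1.0), 0.0)
        t_cl = np.clip(t, 0.0, 1.0)
        s = np.where((t != t_cl) & (a > eps), np.clip((c * t_cl - g) / np.where(a > eps, a, 1.0), 0.0, 1.0), s)
    c1 = p1 + s[:, :, None] * d1
    c2 = p2 + t_cl[:, :, None] * d2
    return np.linalg.norm(c1 - c2, axis=2)
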