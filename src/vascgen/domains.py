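"""Perfusion domains: implicit shapes, watertight surface meshes, and
terminal-placement densities.

A domain is the region of tissue a vascular tree must supply.  All domains
live in 3D coordinates (mm); planar (D=2) domains occupy the z=0 plane so a
single vessel representation serves both cases.  The dimension only enters
the characteristic perfusion length

    l_c = sqrt(area/pi)          (D = 2)
    l_c = (3*volume/(4*pi))**(1/3)  (D = 3)

i.e. the radius of the disc/sphere with the same measure, interpreted as the
expected perfusion radius of a terminal vessel.

Boundary points count as inside (closed region): near-boundary rejection is
the job of the segment and geometric-constraint checks, not of membership.
"""
from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

_Z_TOL = 1e-9  # planar domains: tolerated off-plane distance (mm)


def _as_points(x) -> np.ndarray:
    """Coerce a point or an (n, 3) stack of points to a 2-D float array."""
    p = np.asarray(x, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if p.shape[-1] != 3:
        raise ValueError(f"points must have 3 coordinates, got shape {p.shape}")
    return p


class Domain:
    """Base class for perfusion regions Ω.

    Subclasses provide :meth:`contains_many`, :meth:`measure` and
    :meth:`bounds`; everything else derives from those.
    """

    D: int = 3
    label: str = ""

    # -- abstract ---------------------------------------------------------
    def contains_many(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def measure(self) -> float:
        """Area (mm^2) for D=2, volume (mm^3) for D=3."""
        raise NotImplementedError

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi), each shape (3,)."""
        raise NotImplementedError

    # -- derived ----------------------------------------------------------
    def contains(self, x) -> bool | np.ndarray:
        """Membership test, boundary inclusive. Accepts one point or a stack."""
        p = _as_points(x)
        inside = self.contains_many(p)
        if self.D == 2:
            inside = inside & (np.abs(p[:, 2]) <= _Z_TOL)
        return bool(inside[0]) if np.asarray(x).ndim == 1 else inside

    def characteristic_length(self) -> float:
        """Equivalent disc/sphere radius of the domain (mm)."""
        m = self.measure()
        if m <= 0:
            raise ValueError("domain has non-positive measure")
        if self.D == 2:
            return math.sqrt(m / math.pi)
        return (3.0 * m / (4.0 * math.pi)) ** (1.0 / 3.0)

    def default_n_checks(self, length: float) -> int:
        # resolution tied to the perfusion scale
        return max(2, int(math.ceil(length / (0.1 * self.characteristic_length()))) + 1)

    def segment_in_domain(self, a, b, n_checks: int | None = None) -> bool:
        """True iff both endpoints and equally spaced interior points lie in Ω."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != (3,) or b.shape != (3,):
            raise ValueError("segment endpoints must be 3-vectors")
        if n_checks is None:
            n_checks = self.default_n_checks(float(np.linalg.norm(b - a)))
        if n_checks < 2:
            raise ValueError("n_checks must be >= 2")
        t = np.linspace(0.0, 1.0, n_checks)
        pts = a[None, :] + t[:, None] * (b - a)[None, :]
        return bool(np.all(self.contains(pts)))


class Disc(Domain):
    """Closed disc of given radius in the z=0 plane."""

    D = 2

    def __init__(self, radius: float = 1.0, center=(0.0, 0.0, 0.0), label: str = ""):
        if radius <= 0:
            raise ValueError("radius must be positive")
        self.radius = float(radius)
        self.center = np.asarray(center, dtype=float)
        self.label = label

    def contains_many(self, points):
        d = points[:, :2] - self.center[None, :2]
        return np.einsum("ij,ij->i", d, d) <= self.radius**2

    def measure(self):
        return math.pi * self.radius**2

    def bounds(self):
        r = self.radius
        return self.center - (r, r, 0.0), self.center + (r, r, 0.0)


class Annulus(Domain):
    """Closed ring r_inner <= |x - c| <= r_outer in the z=0 plane."""

    D = 2

    def __init__(self, r_inner: float, r_outer: float, center=(0.0, 0.0, 0.0), label: str = ""):
        if not 0 < r_inner < r_outer:
            raise ValueError("need 0 < r_inner < r_outer")
        self.r_inner = float(r_inner)
        self.r_outer = float(r_outer)
        self.center = np.asarray(center, dtype=float)
        self.label = label

    def contains_many(self, points):
        d = points[:, :2] - self.center[None, :2]
        r2 = np.einsum("ij,ij->i", d, d)
        return (r2 >= self.r_inner**2) & (r2 <= self.r_outer**2)

    def measure(self):
        return math.pi * (self.r_outer**2 - self.r_inner**2)

    def bounds(self):
        r = self.r_outer
        return self.center - (r, r, 0.0), self.center + (r, r, 0.0)


class Sphere(Domain):
    """Closed ball of given radius."""

    D = 3

    def __init__(self, radius: float = 1.0, center=(0.0, 0.0, 0.0), label: str = ""):
        if radius <= 0:
            raise ValueError("radius must be positive")
        self.radius = float(radius)
        self.center = np.asarray(center, dtype=float)
        self.label = label

    def contains_many(self, points):
        d = points - self.center[None, :]
        return np.einsum("ij,ij->i", d, d) <= self.radius**2

    def measure(self):
        return 4.0 / 3.0 * math.pi * self.radius**3

    def bounds(self):
        r = self.radius
        return self.center - r, self.center + r


class SphericalShell(Domain):
    """Closed shell r_inner <= |x - c| <= r_outer."""

    D = 3

    def __init__(self, r_inner: float, r_outer: float, center=(0.0, 0.0, 0.0), label: str = ""):
        if not 0 < r_inner < r_outer:
            raise ValueError("need 0 < r_inner < r_outer")
        self.r_inner = float(r_inner)
        self.r_outer = float(r_outer)
        self.center = np.asarray(center, dtype=float)
        self.label = label

    def contains_many(self, points):
        d = points - self.center[None, :]
        r2 = np.einsum("ij,ij->i", d, d)
        return (r2 >= self.r_inner**2) & (r2 <= self.r_outer**2)

    def measure(self):
        return 4.0 / 3.0 * math.pi * (self.r_outer**3 - self.r_inner**3)

    def bounds(self):
        r = self.r_outer
        return self.center - r, self.center + r


class Box(Domain):
    """Axis-aligned box [lo, hi]; D=2 boxes must be flat in z (lo_z = hi_z = 0)."""

    def __init__(self, lo, hi, D: int = 3, label: str = ""):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        if self.lo.shape != (3,) or self.hi.shape != (3,):
            raise ValueError("lo/hi must be 3-vectors")
        if D == 2 and (self.lo[2] != 0.0 or self.hi[2] != 0.0):
            raise ValueError("planar boxes must have lo_z = hi_z = 0")
        if np.any(self.hi[: D] <= self.lo[: D]):
            raise ValueError("need hi > lo on every in-plane axis")
        self.D = D
        self.label = label

    def contains_many(self, points):
        return np.all((points >= self.lo[None, :]) & (points <= self.hi[None, :]), axis=1)

    def measure(self):
        ext = self.hi - self.lo
        return float(np.prod(ext[: self.D]))

    def bounds(self):
        return self.lo.copy(), self.hi.copy()


class UnionDomain(Domain):
    """Union of pairwise-disjoint subdomains (measure is additive)."""

    def __init__(self, parts: Sequence[Domain], label: str = ""):
        if not parts:
            raise ValueError("union of zero domains")
        dims = {p.D for p in parts}
        if len(dims) != 1:
            raise ValueError("all parts must share the dimension")
        self.parts = list(parts)
        self.D = parts[0].D
        self.label = label

    def contains_many(self, points):
        inside = np.zeros(len(points), dtype=bool)
        for p in self.parts:
            inside |= p.contains_many(points)
        return inside

    def measure(self):
        return sum(p.measure() for p in self.parts)

    def bounds(self):
        los, his = zip(*(p.bounds() for p in self.parts))
        return np.min(los, axis=0), np.max(his, axis=0)


def winding_number_inside(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray,
                          chunk: int = 128) -> np.ndarray:
    """Membership of points in a watertight triangle mesh by solid angle.

    The generalised winding number sums the signed solid angle each
    triangle subtends at the query point (van Oosterom–Strackee); for a
    closed surface it is 4π inside and 0 outside.  Points are accepted at
    winding > 1/2, which keeps boundary points inside up to round-off.
    """
    tri = vertices[faces]  # (m, 3, 3)
    inside = np.empty(len(points), dtype=bool)
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        A = tri[None, :, 0, :] - p[:, None, :]
        B = tri[None, :, 1, :] - p[:, None, :]
        C = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(A, axis=2)
        lb = np.linalg.norm(B, axis=2)
        lc = np.linalg.norm(C, axis=2)
        num = np.einsum("pmi,pmi->pm", A, np.cross(B, C))
        den = (
            la * lb * lc
            + np.einsum("pmi,pmi->pm", A, B) * lc
            + np.einsum("pmi,pmi->pm", B, C) * la
            + np.einsum("pmi,pmi->pm", C, A) * lb
        )
        omega = 2.0 * np.arctan2(num, den)
        inside[s:s + chunk] = omega.sum(axis=1) > 2.0 * math.pi
    return inside


class MeshDomain(Domain):
    """Watertight closed surface mesh (STL/PLY/OBJ via trimesh).

    Membership uses the generalised winding number of the closed surface
    and the measure comes from the divergence theorem on the mesh.
    """

    D = 3

    def __init__(self, mesh, label: str = ""):
        import trimesh

        if isinstance(mesh, (str,)) or hasattr(mesh, "__fspath__"):
            mesh = trimesh.load_mesh(str(mesh))
        if not mesh.is_watertight:
            raise ValueError("mesh domain requires a watertight closed surface")
        self.mesh = mesh
        self.label = label

    def contains_many(self, points):
        return winding_number_inside(
            np.asarray(points, float),
            np.asarray(self.mesh.vertices, float),
            np.asarray(self.mesh.faces),
        )

    def measure(self):
        return float(abs(self.mesh.volume))

    def bounds(self):
        lo, hi = self.mesh.bounds
        return np.asarray(lo, float), np.asarray(hi, float)


class ExtrudedShell(Domain):
    """Thin shell built by offsetting a closed surface along vertex normals.

    Emulates growing vessels over an organ surface: the shell between the
    outward offset (+outward mm) and inward offset (-inward mm) of the base
    surface is the perfusion region.
    """

    D = 3

    def __init__(self, mesh, outward: float, inward: float, label: str = ""):
        import trimesh

        if isinstance(mesh, (str,)) or hasattr(mesh, "__fspath__"):
            mesh = trimesh.load_mesh(str(mesh))
        if outward + inward <= 0:
            raise ValueError("shell thickness must be positive")
        n = mesh.vertex_normals
        outer = trimesh.Trimesh(mesh.vertices + outward * n, mesh.faces, process=False)
        inner = trimesh.Trimesh(mesh.vertices - inward * n, mesh.faces, process=False)
        self.outer = outer
        self.inner = inner
        self.label = label

    def contains_many(self, points):
        points = np.asarray(points, float)
        in_outer = winding_number_inside(
            points, np.asarray(self.outer.vertices, float), np.asarray(self.outer.faces)
        )
        in_inner = winding_number_inside(
            points, np.asarray(self.inner.vertices, float), np.asarray(self.inner.faces)
        )
        return in_outer & ~in_inner

    def measure(self):
        return float(abs(self.outer.volume) - abs(self.inner.volume))

    def bounds(self):
        lo, hi = self.outer.bounds
        return np.asarray(lo, float), np.asarray(hi, float)


# ---------------------------------------------------------------------------
# Terminal-placement densities
# ---------------------------------------------------------------------------


class PlacementDensity:
    """Unnormalised spatial density p(x) >= 0 shaping where terminals appear.

    ``propose`` draws candidate points already distributed proportionally to
    p on free space; restriction to Ω is done by rejection in
    :func:`sample_point`.
    """

    def propose(self, rng: np.random.Generator, n: int, domain: Domain) -> np.ndarray:
        raise NotImplementedError

    def pdf(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class UniformDensity(PlacementDensity):
    def propose(self, rng, n, domain):
        lo, hi = domain.bounds()
        pts = rng.uniform(lo, hi, size=(n, 3))
        if domain.D == 2:
            pts[:, 2] = 0.0
        return pts

    def pdf(self, points):
        return np.ones(len(points))


class GaussianDensity(PlacementDensity):
    """Axis-aligned Gaussian N(mu, diag(sigma^2)); planar if mu/sigma are 2-vectors."""

    def __init__(self, mu, sigma):
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if mu.shape not in ((2,), (3,)) or sigma.shape != mu.shape:
            raise ValueError("mu and sigma must both be 2- or 3-vectors")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        self.planar = mu.shape == (2,)
        self.mu = np.append(mu, 0.0) if self.planar else mu
        self.sigma = np.append(sigma, 0.0) if self.planar else sigma

    def propose(self, rng, n, domain):
        pts = self.mu[None, :] + rng.standard_normal((n, 3)) * self.sigma[None, :]
        if self.planar:
            pts[:, 2] = 0.0
        return pts

    def pdf(self, points):
        d = (points - self.mu[None, :]) ** 2
        sig2 = np.where(self.sigma > 0, self.sigma**2, 1.0)
        k = 2 if self.planar else 3
        return np.exp(-0.5 * np.sum(d[:, :k] / sig2[None, :k], axis=1))


class MixtureDensity(PlacementDensity):
    """Finite mixture of placement densities with given weights."""

    def __init__(self, components: Sequence[PlacementDensity], weights: Sequence[float]):
        w = np.asarray(weights, dtype=float)
        if len(components) != len(w) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative and sum to > 0")
        self.components = list(components)
        self.weights = w / w.sum()

    def propose(self, rng, n, domain):
        counts = rng.multinomial(n, self.weights)
        parts = [c.propose(rng, k, domain) for c, k in zip(self.components, counts) if k > 0]
        pts = np.concatenate(parts, axis=0)
        rng.shuffle(pts, axis=0)
        return pts

    def pdf(self, points):
        return sum(w * c.pdf(points) for c, w in zip(self.components, self.weights))


class CallableDensity(PlacementDensity):
    """User-supplied density function, sampled by thinning uniform proposals.

    ``p_max`` must bound p(x) from above on the domain bounding box.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], p_max: float):
        if p_max <= 0:
            raise ValueError("p_max must be positive")
        self.fn = fn
        self.p_max = float(p_max)

    def propose(self, rng, n, domain):
        lo, hi = domain.bounds()
        pts = rng.uniform(lo, hi, size=(n, 3))
        if domain.D == 2:
            pts[:, 2] = 0.0
        u = rng.uniform(0.0, self.p_max, size=n)
        return pts[u < self.pdf(pts)]

    def pdf(self, points):
        return np.asarray(self.fn(points), dtype=float)


class DegenerateDensityError(RuntimeError):
    """Raised when the density/domain pair yields (almost) no admissible points."""


def sample_point(
    domain: Domain,
    density: PlacementDensity,
    rng: np.random.Generator,
    acceptance_floor: float = 1e-6,
    chunk: int = 256,
) -> np.ndarray:
    """Draw one point x in Ω distributed proportionally to the density.

    Rejection sampling: proposals from the density's free-space sampler are
    kept if they fall inside Ω.  If the empirical acceptance rate stays below
    ``acceptance_floor`` the pair is declared degenerate.
    """
    draws = 0
    while True:
        pts = density.propose(rng, chunk, domain)
        draws += chunk
        if len(pts):
            inside = domain.contains(pts)
            if np.any(inside):
                return pts[int(np.argmax(inside))]
        if draws >= 10_000 and draws * acceptance_floor >= 1.0:
            raise DegenerateDensityError(
                f"acceptance rate below {acceptance_floor:g} after {draws} draws"
            )
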