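"""Cost functionals driving per-vessel optimisation.

Two criteria are provided:

* the classic volumetric criterion — the increment of the total tree
  volume Σ l_i·π·r_i² caused by adding the trial vessel; and
* the sprouting criterion, a dimensionless mixture of (i) the scaled
  volume increment, (ii) a parent-wall degradation term proportional to
  the parent radius (wall thickness scales with radius, and degrading the
  wall is what exposes endothelium and triggers a sprout), and (iii) a
  growth-signal diffusion term quadratic in the distance the signal must
  travel from the new terminal point to the closest point of the vessel
  being sprouted from (Fick's second law makes the arrival time quadratic
  in distance):

      F_sprout = c_v·ΔF_vol/V_ref + c_p·r_p/r_ref + c_d·(d_sig/l_ref)²

  The diffusion distance is a property of the terminal/target-vessel pair,
  not of the trial bifurcation point: otherwise placing the bifurcation
  next to the terminal would hide an arbitrarily long connection from the
  diffusion penalty.

  with V_ref the currently vascularised volume (the total volume of the
  forest at the moment of evaluation), l_ref = (3·V_ref/4π)^(1/3) its
  equivalent-sphere radius and r_ref the root radius of the tree being
  joined.  Normalising by the vasculature's own volume keeps the three
  terms dimensionless in 2D and 3D alike (vessels are cylinders either
  way) and gives the diffusion term a length scale of the same order as
  the vessels themselves, so proximity dominates any tie between distant
  alternatives — which is what keeps multi-inlet growth balanced.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import hemo
from .tree import VascularForest


@dataclass
class SproutCoeffs:
    """Mixture coefficients and normalising references of the sprouting cost."""

    c_v: float = 0.0
    c_p: float = 0.0
    c_d: float = 0.0
    V_ref: float = 1.0   # stage domain measure (mm^D)
    l_ref: float = 1.0   # equivalent disc/sphere radius of V_ref (mm)
    r_ref: float = 1.0   # root radius of the tree being connected (mm)

    def __post_init__(self):
        if min(self.c_v, self.c_p, self.c_d) < 0 or max(self.c_v, self.c_p, self.c_d) == 0:
            raise ValueError("coefficients must be non-negative and not all zero")
        if min(self.V_ref, self.l_ref, self.r_ref) <= 0:
            raise ValueError("reference quantities must be positive")

    @classmethod
    def for_forest(cls, c_v, c_p, c_d, forest, r_root, V_ref=None):
        """Build references from the current vasculature and connected root.

        ``V_ref`` may be passed to avoid recomputing the forest volume.
        """
        V = tree_volume(forest) if V_ref is None else V_ref
        l_ref = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
        return cls(c_v=c_v, c_p=c_p, c_d=c_d, V_ref=V, l_ref=l_ref, r_ref=r_root)


def tree_volume(forest: VascularForest) -> float:
    """Total intravascular volume Σ l_i·π·r_i² (mm³)."""
    n = forest.n
    return float(np.sum(forest.length[:n] * math.pi * forest.radius[:n] ** 2))


def delta_volume(forest: VascularForest, j: int, x_b, x_d_new, gamma: float = 3.0, **solve_kw) -> float:
    """Exact volume increment of tentatively inserting a terminal.

    Inserts, re-converges radii, measures, and restores the forest.  Raises
    :class:`~vascgen.hemo.ConvergenceError` through to the caller if the
    radius update fails, in which case the candidate is infeasible.
    """
    before = tree_volume(forest)
    snap, _, _ = forest.insert_terminal(j, x_b, x_d_new)
    try:
        hemo.solve(forest, gamma=gamma, **solve_kw)
        after = tree_volume(forest)
    finally:
        forest.restore(snap)
    return after - before


def sprout_cost(dvol, r_p, signal_distance, coeffs: SproutCoeffs):
    """Sprouting cost from the volume increment, parent radius and the
    growth-signal diffusion distance (terminal point to target vessel).

    Vectorised over its array arguments.
    """
    dvol = np.asarray(dvol, float)
    r_p = np.asarray(r_p, float)
    signal_distance = np.asarray(signal_distance, float)
    out = (
        coeffs.c_v * dvol / coeffs.V_ref
        + coeffs.c_p * r_p / coeffs.r_ref
        + coeffs.c_d * (signal_distance / coeffs.l_ref) ** 2
    )
    return float(out) if out.ndim == 0 else out
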