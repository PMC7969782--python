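"""Packaged academic experiment setups.

Each fixture builds, programmatically, the domain(s), stage sequence and
(where needed) a small pre-existing tree for one of the canonical
benchmark scenarios: uniform disc growth, sequential two-territory
growth, hierarchical annulus-then-disc perfusion, scale-specific
staging with decreasing symmetry ratio, concurrent growth from two
opposite equiradial inlets (volumetric vs sprouting cost), heterogeneous
terminal-placement densities, and constrained-outlet flow diversion.

Exact inlet positions and radii of the pre-existing trees in the
literature are not published; the fixtures use symmetric constructions
(inlets on the boundary, root radius 0.1 mm, total inflow 10 mm³/s for
the unit disc/sphere) that preserve every structural property the
scenarios are meant to exhibit.
"""
from __future__ import annotations

from . import tree as T
from .domains import Annulus, Disc, GaussianDensity, MixtureDensity, Sphere, UnionDomain
from .engine import OptParams, RootSpec, Stage
from .rules import GeoParams

R1 = 0.05      # root radius of academic fixtures (mm); well below the
               # domain's characteristic length so that early segments stay
               # splittable under the aspect bound
Q_TOTAL = 10.0  # total inflow of academic fixtures (mm³/s)


def disc_uniform(n_terminals: int = 200, delta: float = 0.0, nu: float = 1.0, **opt_kw):
    """Classic single-stage growth in the unit disc from one boundary inlet."""
    stage = Stage(
        domain=Disc(),
        n_terminals=n_terminals,
        geo=GeoParams(gamma=3.0, delta=delta),
        opt=OptParams(nu=nu, **opt_kw),
        inlets=(RootSpec(position=(-1.0, 0.0, 0.0), radius=R1, inflow=Q_TOTAL),),
        label="disc-uniform",
    )
    return {"stages": [stage], "initial": None, "outlets": {}}


def _two_territory_tree() -> T.VascularForest:
    """Pre-existing carriage tree feeding two disjoint territories."""
    f = T.VascularForest()
    root = f.add_vessel((0.0, -2.6, 0.0), (0.0, -1.8, 0.0), radius=0.15, parent=-1,
                        role=T.TRANSPORT, behaviour=T.NON_BRANCHING, stage=0, inflow=Q_TOTAL)
    f.add_vessel((0.0, -1.8, 0.0), (-1.5, -1.0, 0.0), radius=0.12, parent=root,
                 role=T.TRANSPORT, behaviour=T.DISTAL, stage=0)
    f.add_vessel((0.0, -1.8, 0.0), (1.5, -1.0, 0.0), radius=0.12, parent=root,
                 role=T.TRANSPORT, behaviour=T.DISTAL, stage=0)
    return f


def sequential_two_territories(budgets=(800, 1200)):
    """Sequential growth: territory Ω₁ first, then Ω₂, off one carriage tree."""
    omega1 = Disc(radius=1.0, center=(-1.5, 0.0, 0.0), label="omega1")
    omega2 = Disc(radius=1.0, center=(1.5, 0.0, 0.0), label="omega2")
    opt = OptParams(nu=1.5, f_r=0.9, f_n=8, delta_v=7)
    geo = GeoParams(gamma=3.0, delta=0.0)
    stages = [
        Stage(domain=omega1, n_terminals=budgets[0], geo=geo, opt=opt, label="omega1"),
        Stage(domain=omega2, n_terminals=budgets[1], geo=geo, opt=opt, label="omega2"),
    ]
    return {"stages": stages, "initial": _two_territory_tree, "outlets": {}}


def hierarchical_annulus(budgets=(50, 1950)):
    """Hierarchical perfusion: annulus parent domain, then the full disc."""
    ring = Annulus(0.5, 1.0, label="ring")
    full = UnionDomain([ring, Disc(radius=0.5)], label="full")
    opt = OptParams(nu=1.0, f_r=0.9, f_n=8, delta_v=7)
    geo = GeoParams(gamma=3.0, delta=0.0)
    stages = [
        Stage(domain=ring, n_terminals=budgets[0], geo=geo, opt=opt,
              inlets=(RootSpec(position=(-1.0, 0.0, 0.0), radius=R1, inflow=Q_TOTAL),),
              label="ring"),
        Stage(domain=full, n_terminals=budgets[1], geo=geo, opt=opt, label="full"),
    ]
    return {"stages": stages, "initial": None, "outlets": {}}


def scale_specific(budgets=(50, 450, 1500), deltas=(0.7, 0.5, 0.2)):
    """Scale-specific staging: same disc, decreasing symmetry ratio δ."""
    opt = OptParams(nu=1.5, f_r=0.9, f_n=8, delta_v=7)
    stages = []
    for i, (b, d) in enumerate(zip(budgets, deltas)):
        inlets = (RootSpec(position=(-1.0, 0.0, 0.0), radius=R1, inflow=Q_TOTAL),) if i == 0 else ()
        stages.append(Stage(domain=Disc(), n_terminals=b, geo=GeoParams(3.0, d), opt=opt,
                            inlets=inlets, label=f"delta-{d}"))
    return {"stages": stages, "initial": None, "outlets": {}}


_SPROUT_2D = (0.5e2, 0.5, 1.0)
_SPROUT_3D = (1.0e4, 0.5, 1.0)


def _two_inlet_tree() -> T.VascularForest:
    """Symmetric initialisation: two equiradial inlets, each already carrying
    a first bifurcation.

    Starting both trees past their first split keeps the parent-wall
    degradation term comparable between the inlets from the outset; an
    unsplit root is much thicker than any split tip, which would bias
    every early sprouting decision toward whichever side happened to
    split first.
    """
    f = T.VascularForest()
    for s in (-1.0, 1.0):
        root = f.add_vessel((s, 0.0, 0.0), (s * 0.6, 0.0, 0.0), radius=R1, parent=-1,
                            role=T.DISTRIBUTION, behaviour=T.VERSATILE, stage=0,
                            inflow=Q_TOTAL / 2)
        for dy in (0.3, -0.3):
            f.add_vessel((s * 0.6, 0.0, 0.0), (s * 0.3, dy, 0.0), radius=0.8 * R1,
                         parent=root, role=T.DISTRIBUTION, behaviour=T.VERSATILE, stage=0)
    return f


def _two_inlet_stages(domain, plan, sprout):
    opt = OptParams(nu=1.0, f_r=0.9, f_n=8, delta_v=7)
    geo = GeoParams(gamma=3.0, delta=0.0)
    stages = []
    for budget, cost in plan:
        stages.append(Stage(domain=domain, n_terminals=budget, geo=geo, opt=opt,
                            cost=cost, sprout=sprout if cost == "sprout" else (0, 0, 0),
                            label=f"{cost}-{budget}"))
    return {"stages": stages, "initial": _two_inlet_tree, "outlets": {}}


def two_inlets_vol(n_terminals: int = 1000):
    """Concurrent vascularisation of the disc, volumetric cost."""
    return _two_inlet_stages(Disc(), [(n_terminals, "vol")], _SPROUT_2D)


def two_inlets_sprout(n_terminals: int = 1000):
    """Concurrent vascularisation of the disc, sprouting cost (c_v=50, c_p=0.5, c_d=1)."""
    return _two_inlet_stages(Disc(), [(n_terminals, "sprout")], _SPROUT_2D)


def two_inlets_twostage(budgets=(25, 975)):
    """Two-stage multi-criteria growth: short sprouting stage, volumetric rest."""
    return _two_inlet_stages(Disc(), [(budgets[0], "sprout"), (budgets[1], "vol")], _SPROUT_2D)


def two_inlets_sphere_sprout(n_terminals: int = 1000):
    """3D concurrent vascularisation of the unit sphere, sprouting cost."""
    return _two_inlet_stages(Sphere(), [(n_terminals, "sprout")], _SPROUT_3D)


def gaussian_disc(n_terminals: int = 500):
    """Heterogeneous flow delivery: centred Gaussian terminal density."""
    fx = disc_uniform(n_terminals)
    fx["stages"][0].density = GaussianDensity((0.0, 0.0), (0.25, 0.25))
    fx["stages"][0].label = "gaussian"
    return fx


def gaussian_mixture_disc(n_terminals: int = 500):
    """Two-lobe Gaussian-mixture terminal density (0.5/0.5 weights)."""
    fx = disc_uniform(n_terminals)
    fx["stages"][0].density = MixtureDensity(
        [GaussianDensity((0.0, 0.5), (0.25, 0.25)), GaussianDensity((0.0, -0.5), (0.10, 0.10))],
        [0.5, 0.5],
    )
    fx["stages"][0].label = "gaussian-mixture"
    return fx


def _outlet_tree(fraction: float | None) -> T.VascularForest:
    """Small initial tree with one distal artery leaving the disc."""
    f = T.VascularForest()
    root = f.add_vessel((-1.0, 0.0, 0.0), (-0.2, 0.0, 0.0), radius=R1, parent=-1,
                        role=T.DISTRIBUTION, behaviour=T.VERSATILE, stage=0, inflow=Q_TOTAL)
    f.add_vessel((-0.2, 0.0, 0.0), (0.9, 0.9, 0.0), radius=0.035, parent=root,
                 role=T.TRANSPORT, behaviour=T.NON_BRANCHING, stage=0,
                 outlet_fraction=fraction or 0.0)
    f.add_vessel((-0.2, 0.0, 0.0), (0.1, -0.35, 0.0), radius=0.035, parent=root,
                 role=T.DISTRIBUTION, behaviour=T.VERSATILE, stage=0)
    return f


def _outlet_fixture(fraction: float | None, n_terminals: int):
    stage = Stage(
        domain=Disc(),
        n_terminals=n_terminals,
        geo=GeoParams(3.0, 0.0),
        opt=OptParams(nu=1.0, f_r=0.9, f_n=8, delta_v=7),
        label=f"outlet-{fraction}",
    )
    outlets = {1: fraction} if fraction else {}
    return {"stages": [stage], "initial": lambda: _outlet_tree(fraction), "outlets": outlets}


def outlet_unconstrained(n_terminals: int = 200):
    """Distal artery present but unconstrained: it behaves as a free terminal."""
    return _outlet_fixture(None, n_terminals)


def outlet_half(n_terminals: int = 200):
    """Distal artery constrained to divert 0.5·Q out of the domain."""
    return _outlet_fixture(0.5, n_terminals)


def outlet_extreme(n_terminals: int = 200):
    """Distal artery constrained to divert 0.99·Q out of the domain."""
    return _outlet_fixture(0.99, n_terminals)


REGISTRY = {
    "disc_uniform": disc_uniform,
    "sequential_two_territories": sequential_two_territories,
    "hierarchical_annulus": hierarchical_annulus,
    "scale_specific": scale_specific,
    "two_inlets_vol": two_inlets_vol,
    "two_inlets_sprout": two_inlets_sprout,
    "two_inlets_twostage": two_inlets_twostage,
    "two_inlets_sphere_sprout": two_inlets_sphere_sprout,
    "gaussian_disc": gaussian_disc,
    "gaussian_mixture_disc": gaussian_mixture_disc,
    "outlet_unconstrained": outlet_unconstrained,
    "outlet_half": outlet_half,
    "outlet_extreme": outlet_extreme,
}


def fixtures() -> dict:
    """Registry of packaged setups: name -> builder()."""
    return dict(REGISTRY)


def build(name: str, **kw) -> dict:
    """Materialise a fixture: {'stages', 'initial_forest', 'outlets'}."""
    fx = REGISTRY[name](**kw)
    init = fx.pop("initial", None)
    fx["initial_forest"] = init() if init else None
    return fx
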