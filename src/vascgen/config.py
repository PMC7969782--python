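"""Stage-sequence configuration: YAML/JSON files to Stage objects.

A configuration declares named domains, an optional initial tree
(interchange table, inline or by path), optional constrained outlets, and
an ordered stage list.  Every stage column of a typical parameter table is
representable: domain, (γ, δ — constant or a piecewise level map),
(ν, f_r, f_n, Δv), initial-tree/parent selector, terminal budget, cost
functional with sprouting coefficients, generated-vessel type, and angle
windows (a supplementary maximum is assumed when only a minimum is given).
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import domains as D
from . import io as vio
from . import tree as T
from .engine import OptParams, RootSpec, Stage
from .rules import AngleParams, GeoParams


class ConfigError(ValueError):
    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))


_SHAPES = {
    "disc": lambda p: D.Disc(radius=p.get("radius", 1.0), center=p.get("center", (0, 0, 0))),
    "annulus": lambda p: D.Annulus(p["r_inner"], p["r_outer"], center=p.get("center", (0, 0, 0))),
    "sphere": lambda p: D.Sphere(radius=p.get("radius", 1.0), center=p.get("center", (0, 0, 0))),
    "spherical_shell": lambda p: D.SphericalShell(p["r_inner"], p["r_outer"], center=p.get("center", (0, 0, 0))),
    "box": lambda p: D.Box(p["lo"], p["hi"], D=p.get("dimension", 3)),
    "mesh": lambda p: D.MeshDomain(p["path"]),
    "extruded_shell": lambda p: D.ExtrudedShell(p["path"], p.get("outward", 1.0), p.get("inward", 0.0)),
}


def build_domain(spec, named: dict | None = None) -> D.Domain:
    """Build a domain from a config mapping, a named reference, or pass through."""
    if isinstance(spec, D.Domain):
        return spec
    if isinstance(spec, str):
        if named and spec in named:
            return named[spec]
        raise KeyError(f"unknown domain name {spec!r}")
    spec = dict(spec)
    shape = spec.pop("shape")
    if shape == "union":
        return D.UnionDomain([build_domain(s, named) for s in spec["parts"]])
    if shape not in _SHAPES:
        raise KeyError(f"unknown domain shape {shape!r}")
    return _SHAPES[shape](spec)


def build_density(spec) -> D.PlacementDensity:
    if spec is None:
        return D.UniformDensity()
    if isinstance(spec, D.PlacementDensity):
        return spec
    kind = spec.get("type", "uniform")
    if kind == "uniform":
        return D.UniformDensity()
    if kind == "gaussian":
        return D.GaussianDensity(spec["mu"], spec["sigma"])
    if kind == "mixture":
        comps = [build_density(c) for c in spec["components"]]
        return D.MixtureDensity(comps, spec["weights"])
    raise KeyError(f"unknown density type {kind!r}")


def _build_delta(spec):
    if isinstance(spec, dict):
        return (spec["below_level"], spec["value"], spec["else"])
    return float(spec)


def _build_angles(spec) -> AngleParams:
    if not spec:
        return AngleParams()
    th_min = spec.get("theta_min")
    ph_min = spec.get("phi_min")
    ap = AngleParams()
    if th_min is not None:
        ap.theta_min = float(th_min)
        ap.theta_max = float(spec.get("theta_max", 180.0 - float(th_min)))
        ap.theta_enabled = True
    if ph_min is not None and float(ph_min) > 0:
        ap.phi_min = float(ph_min)
        ap.phi_max = float(spec.get("phi_max", 180.0 - float(ph_min)))
        ap.phi_enabled = True
    ap.__post_init__()
    return ap


def build_stage(spec, named_domains: dict | None = None, problems: list | None = None) -> Stage:
    """One stage from its config mapping."""
    own = [] if problems is None else problems
    try:
        domain = build_domain(spec["domain"], named_domains)
    except Exception as e:  # collect, keep validating the rest
        own.append(f"stage {spec.get('label', '?')}: domain: {e}")
        domain = D.Disc()

    cost_spec = spec.get("cost", {"name": "vol"})
    if isinstance(cost_spec, str):
        cost_spec = {"name": cost_spec}
    sprout = (cost_spec.get("c_v", 0.0), cost_spec.get("c_p", 0.0), cost_spec.get("c_d", 0.0))

    vessel = spec.get("vessel", {})
    inlets = tuple(
        RootSpec(
            position=tuple(i["position"]),
            radius=float(i["radius"]),
            inflow=float(i.get("inflow", 0.0)),
            role=T.ROLE_CODES[i.get("role", "distribution")],
            behaviour=T.BEHAVIOUR_CODES[i.get("behaviour", "versatile")],
        )
        for i in spec.get("inlets", ())
    )

    def _try(build, label):
        try:
            return build()
        except Exception as e:
            own.append(f"stage {spec.get('label', '?')}: {label}: {e}")
            return None

    geo = _try(lambda: GeoParams(gamma=float(spec.get("gamma", 3.0)), delta=_build_delta(spec.get("delta", 0.0))), "geometry") or GeoParams()
    opt = _try(lambda: OptParams(
        nu=float(spec.get("nu", 1.0)),
        f_r=float(spec.get("f_r", 0.9)),
        f_n=float(spec.get("f_n", 8.0)),
        delta_v=int(spec.get("delta_v", 7)),
        n_fail=int(spec.get("n_fail", 100)),
        max_total_attempts=int(spec.get("max_total_attempts", 1_000_000)),
        n_nearest=int(spec.get("n_nearest", 30)),
    ), "optimisation") or OptParams()
    angles = _try(lambda: _build_angles(spec.get("angles")), "angles") or AngleParams()
    stage = _try(lambda: Stage(
        domain=domain,
        n_terminals=int(spec["n_terminals"]),
        geo=geo,
        opt=opt,
        angles=angles,
        cost=cost_spec.get("name", "vol"),
        sprout=sprout,
        density=build_density(spec.get("density")),
        new_role=T.ROLE_CODES[vessel.get("role", "distribution")],
        new_behaviour=T.BEHAVIOUR_CODES[vessel.get("behaviour", "versatile")],
        parent_stages=tuple(spec["parent_stages"]) if spec.get("parent_stages") is not None else None,
        inlets=inlets,
        label=str(spec.get("label", "")),
    ), "stage")
    if problems is None and own:
        raise ConfigError(own)
    return stage


_KNOWN_TOP = {"domains", "stages", "initial_tree", "outlets", "label", "seed"}


def load_config(source) -> dict:
    """Load a YAML/JSON config into {stages, initial_forest, outlets, ...}.

    ``source`` may be a path or an already-parsed mapping.  All violations
    are collected and reported together.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text)
    else:
        raw = source
    problems: list[str] = []
    for k in raw:
        if k not in _KNOWN_TOP:
            problems.append(f"unknown top-level key {k!r}")

    named = {}
    for name, dspec in (raw.get("domains") or {}).items():
        try:
            named[name] = build_domain(dspec)
        except Exception as e:
            problems.append(f"domain {name!r}: {e}")

    stages = []
    for sspec in raw.get("stages") or []:
        stages.append(build_stage(sspec, named, problems))
    if not stages:
        problems.append("config declares no stages")

    forest = None
    init = raw.get("initial_tree")
    if init is not None:
        try:
            if isinstance(init, (str, Path)):
                forest = vio.read_tree(init)
            else:
                forest = vio.table_to_forest(pd.DataFrame(init))
        except Exception as e:
            problems.append(f"initial_tree: {e}")

    outlets = {}
    for o in raw.get("outlets") or []:
        fr = float(o["fraction"])
        if not 0 < fr < 1:
            problems.append(f"outlet {o.get('vessel')}: fraction {fr} outside (0, 1)")
        outlets[int(o["vessel"])] = fr

    if problems:
        raise ConfigError(problems)
    return {
        "stages": stages,
        "initial_forest": forest,
        "outlets": outlets,
        "label": raw.get("label", ""),
        "seed": raw.get("seed"),
    }
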