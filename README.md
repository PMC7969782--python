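# vascgen

Staged constrained constructive optimisation of synthetic arterial trees.

Peripheral vascular beds — arterioles down to pre-capillary vessels — are
below the resolution of in-vivo imaging, yet hemodynamic and
tissue-perfusion models need their geometry. `vascgen` generates
anatomically plausible arterial trees inside a 2D or 3D perfusion domain,
either from scratch or by extending a pre-existing (e.g. image-derived)
network, for researchers building organ-scale blood-flow models and
boundary-condition closures.

## The algorithm

A tree 𝒯 = {v_i = (r_i, x_i^p, x_i^d)} of straight cylindrical segments
is built one terminal at a time. Each step draws a terminal location x
from a placement density on Ω (rejecting draws closer to the tree than
the perfusion distance l_lim = l_c·(ν/(N_T+1))^{1/D}), prices every
admissible bifurcation site on a Δv-per-side triangle lattice between x
and each nearby vessel, and commits the connection minimising the stage's
cost functional — the tree-volume increment ΔΣ l_i π r_i², or a sprouting
cost c_v·ΔF_vol/V_ref + c_p·r_p/r_ref + c_d·(d/l_ref)² mixing volume,
parent-wall degradation and growth-signal diffusion.

Constraints are hard: Murray's law r_p^γ = r_{s1}^γ + r_{s2}^γ,
sibling symmetry min(r)/max(r) > δ, slenderness l/r > 2, cylinder
non-intersection, role-based containment (distribution / transport /
perforator vessels) and per-vessel branching behaviour (non-branching /
distal / fixed / versatile) for integrating pre-existing anatomy, plus
optional bifurcation- and opening-angle windows.

Hemodynamics close the system with fixed root radius r₁ and inflow Q per
tree: Poiseuille resistances with Fåhræus–Lindqvist viscosity η(r), equal
outflow q_f at free terminals, prescribed fractions of Q at constrained
outlets, and radii from a fixed point that equalises terminal pressure
drops via reduced-resistance ratios while enforcing Murray's law.

Growth is organised in *stages* — each with its own domain, parameters
(γ, δ, ν, f_r, f_n, Δv), terminal budget, cost functional and vessel
type — so hierarchical, sequential, scale-specific and multi-criteria
vascularisation processes compose from the same primitive.
See `docs/methods.md` for the full model description.

## Worked example

Grow a 100-terminal tree in the unit disc (radius in mm) from a single
boundary inlet with fixed root radius 0.05 mm and inflow 10 mm³/s:

```python
from vascgen import engine, fixtures, hemo, morphometry

fx = fixtures.build("disc_uniform", n_terminals=100)
forest, per_stage = engine.run_stages(fx["stages"], seed=42)
state = hemo.solve(forest)
print(f"vessels: {forest.n}, free terminals: {forest.n_free_terminals()}")
print(f"terminal outflow q_f: {state.q_f:.4f} mm^3/s")
print(morphometry.morphometry_report(forest).to_string(index=False))
```

```
vessels: 201, free terminals: 101
terminal outflow q_f: 0.0990 mm^3/s
stage  n_vessels  n_terminals  radius_min  radius_mean  radius_max  length_total   volume  level_max  multimodal_radius
    1        201          101    0.008517     0.016232        0.05      24.22423 0.024138         20              False
total        201          101    0.008517     0.016232        0.05      24.22423 0.024138         20              False
```

Each of the 100 insertions splits one vessel, so the single root becomes
201 segments with 101 free terminals (the root tip counts as one).  Every
terminal discharges q_f = 10/101 ≈ 0.099 mm³/s; radii taper from the
fixed 0.05 mm root to ≈ 8.5 µm terminals over up to 20 bifurcation
levels, and the whole tree holds ≈ 0.024 mm³ of blood.

The same pipeline runs from the shell:

```sh
vascgen fixtures                                   # list packaged setups
vascgen grow --fixture disc_uniform --seed 42 --out run   # -> run.csv, run.vtk
vascgen audit --fixture disc_uniform --tree run.csv
vascgen report --tree run.csv --plot radii.png
```

`grow` also accepts a YAML stage configuration (`--config`); trees are
exchanged as flat parent-pointer CSV/JSON tables and legacy-VTK polydata
for ParaView.

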