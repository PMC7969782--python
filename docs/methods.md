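# Methods

## Model

`vascgen` grows arterial trees one terminal at a time inside a perfusion
domain Ω. A tree is a set of straight cylindrical segments
v_i = (r_i, x_i^p, x_i^d); junctions are N-ary (unary links model
tortuosity, binary junctions are true bifurcations). Growth minimises a
cost functional subject to geometric and hemodynamic constraints: at every
step a random terminal location is drawn, every admissible connection to
the existing vasculature is priced, and the cheapest one is committed.

### Hemodynamic closure

Blood is Newtonian at low Reynolds number; each segment obeys
Δp = R·q with Poiseuille resistance R = 8η(r)l/(πr⁴). Viscosity follows
the Fåhræus–Lindqvist law

    η(r) = 1.125·(κ + κ²(6e^{−170r} − 2.44e^{−8.09 r^{0.64}} + 2.2)),
    κ = (r/(r − 5.5·10⁻⁴))²,   r in mm, η in cP,

singular at r = 0.55 µm; radii are kept well above that pole. Units:
lengths mm, flows mm³/s; η converts once to Pa·s, so resistances are
Pa·s/mm³ and pressures Pa.

The boundary conditions fix each tree's **root radius** r₁ and **root
inflow** Q; pressure drop is an output. All free terminals discharge the
same outflow q_f = (Q − Σq_out)/N_free; constrained outlets carry
prescribed fractions of Q. Radii then follow from two junction rules:

* **sibling ratio** r₁/r₂ = (q₁R*₁/(q₂R*₂))^{1/4}, which equalises the
  pressure drop over sibling subtrees (hence across all terminals), where
  R* is the reduced resistance (subtree resistance × local r⁴, a quantity
  that depends only on the ratio structure below);
* **Murray's law** r_p^γ = Σ_c r_c^γ for the magnitude.

Together: β_c = w_c/(Σ_k w_k^γ)^{1/γ} with w_c = (q_c R*_c)^{1/4};
unary links get β = 1. Because η depends on the absolute radius, the
ratio recursion sits inside an outer fixed point (bottom-up R*, V* pass →
top-down radii from the fixed roots → η update), iterated until the
largest relative radius change falls below `tol` (default 1e-6; η is a
mild contraction, convergence typically takes < 10 iterations, capped at
200).

### Constraints

A candidate bifurcation (split of a target vessel v_j at a lattice point
x_b, or distal attachment) is admissible iff all of:

1. v_j's branching behaviour allows the site (non-branching: never;
   distal: only x_b = x_j^d; fixed: x_b on v_j's axis; versatile: any
   lattice point of the triangle (x_new, x_j^p, x_j^d), Δv points per
   side minus the vertices);
2. the bifurcation site lies in Ω when v_j is a distribution or
   perforator vessel (transport vessels may branch anywhere);
3. the new segment respects the stage's vessel type: distribution —
   wholly inside Ω; perforator — terminal point in Ω; transport — free;
4. no cylinder clash: minimum axis distance to any vessel more than
   two parent/child links away must exceed the radii sum (the growth
   gate demands 10% clearance on top; see *Numerical choices*);
5. slenderness l/r > 2 and sibling symmetry min(r)/max(r) > δ — checked
   over the whole reshaped tree, not only the new junction, because a
   fixed-root-radius tree reshapes globally at every insertion (δ may be
   a step function of the parent's bifurcation level);
6. optional bifurcation-angle (θ) and opening-angle (φ) windows.

Murray's law and flow conservation hold by construction of the solver and
are only audited.

### Terminal sampling

Locations are drawn from the stage's placement density (uniform,
Gaussian, Gaussian mixture, or user function), restricted to Ω by
rejection. A draw is rejected if it lies closer to the forest than

    l_lim = relaxation · l_c · (ν/(N_T+1))^{1/D},

the equivalent perfusion radius when N_T+1 territories tile the domain,
with l_c = √(A/π) (2D) or (3V/4π)^{1/3} (3D). After N_fail consecutive
failures (distance rejections and failed connection searches both count)
the threshold relaxes by f_r; the accumulator resets when a terminal is
successfully connected. Root segments are created the same way: the
first terminal of a new tree must lie at least the empty-domain
perfusion distance from its inlet — a shorter root could never be split
under the aspect bound (its fixed-radius proximal half would be too
dumpy), leaving the tree permanently unable to accept connections.

### Cost functionals

* `vol`: the increment of Σ l_i π r_i² caused by the insertion, after
  full reconvergence of all radii (the increment can be negative: with a
  fixed root radius, spreading the same inflow over more terminals can
  shrink the total).
* `sprout`: c_v·ΔF_vol/V_ref + c_p·r_p/r_ref + c_d·(d_sig/l_ref)², where
  r_p is the converged radius of the new parent vessel and d_sig is the
  distance from the terminal point to the closest point of the target
  vessel — the distance a growth signal must diffuse, which is a property
  of the terminal/vessel pair, not of the trial bifurcation point
  (tying it to the new vessel's endpoints would let the optimiser hide
  long connections by placing x_b next to the terminal). V_ref is the
  **currently vascularised volume** — the total volume of the forest at
  evaluation time — with l_ref = (3V_ref/4π)^{1/3} and r_ref = r₁ of the
  tree being joined. This normalisation is dimensionless in 2D and 3D
  alike and gives the diffusion term a vessel-scale length, so proximity
  dominates ties between distant alternatives; that is precisely what
  keeps concurrent growth from multiple inlets balanced.

### Staged growth

A stage bundles {Ω, (γ, δ), (ν, f_r, f_n, Δv), initial-tree selector,
terminal budget, cost functional, generated-vessel type, placement
density, angle windows}. Stages run sequentially on the shared forest;
vessels record their creating stage (0 = pre-existing). Scenario
archetypes shipped as fixtures: sequential territories, hierarchical
(annulus then full disc), scale-specific (decreasing δ), concurrent
two-inlet growth (volumetric vs sprouting), heterogeneous placement
densities, and constrained-outlet flow diversion.

## Search implementation

The per-terminal search enumerates the `n_nearest` (default 30) closest
vessels within the f_n·l_c neighbourhood ball — with f_n = 8 on compact
domains the ball covers the entire tree, and the cap is what keeps the
brute force O(1) per neighbour set. For each target vessel all lattice
points are priced at once by an **incremental path update**: only R*, V*
and the junction ratios on the path from the insertion point to the root
change (off-path ratio structures depend on flow ratios only, which the
global q_f rescaling preserves), so one candidate costs O(depth) instead
of O(N). Viscosities off the path are frozen during this evaluation.

The incremental cost therefore deviates from an exact re-evaluation; the
candidate-to-candidate spread of the deviation was measured across tree
sizes at ≲ 0.3·V/N_free (one terminal's share of the reshaping).
Candidates are scanned in incremental-cost order and re-evaluated
**exactly** (insert → full fixed point → constraint re-check → rollback)
until the incremental cost exceeds the best exact cost by a margin of
0.4·V/N_free (scaled by c_v/V_ref for the sprouting cost); the committed
connection is thus the argmin an exhaustive full-recompute search would
return, which the test suite verifies on ≥50 random micro-instances.

## Numerical choices

* **Headrooms.** New vessels must clear l/r > 2 with a 5% margin and the
  cylinder clearance with a 10% margin at creation: later insertions
  reshape every radius (trunk radii grow as their subtrees capture
  terminals), and the margins absorb that drift so the strict bounds
  still hold post hoc. The whole-tree re-check at acceptance remains the
  arbiter; the post-hoc audit uses the strict bounds.
* **Clash exemption.** Cylinders within ≤ 3 parent/child links share a
  junction cluster: the aspect bound only guarantees lengths above 2r,
  so members of such a cluster cannot always avoid axis distances below
  the radii sum. The audit therefore exempts ≤ 3-hop pairs; the growth
  gate is stricter (2 hops + headroom). Distant pairs are always checked.
* **Ties.** Exact floating-point comparison; equal costs resolve to the
  first candidate in enumeration order (neighbours by distance, lattice
  points in barycentric order), making runs bit-reproducible per seed.
* **Angle constraints on distal attachments** use the prolongation of
  the parent vessel as the reference arm (no v_s exists); the opening
  angle is skipped (degenerate plane), as it is for collinear splits.
* **Degenerate inputs.** Zero-measure domains, densities with vanishing
  mass on Ω, inlets whose domain cannot host a root segment, and radius
  fixed points that fail to converge all raise typed errors carrying
  diagnostics; a stage aborts after `max_total_attempts` draws.

## Fixture conditions

Academic fixtures use a unit-radius disc/sphere (mm), total inflow
Q = 10 mm³/s and root radius r₁ = 0.05 mm. The root radius is kept well
below the characteristic length because splitting a vessel of radius r
needs ≈ 3.8r of free length under the aspect bound; a root fat relative
to the early segment lengths would make a young tree unable to accept
connections at all. Two-inlet fixtures initialise both inlets with one
bifurcation already present (two tips each): an unsplit root is thicker
than any split tip, so the sprouting degradation term would otherwise
bias every early decision toward whichever inlet happened to split
first. Pre-existing carriage trees (sequential scenario) are
non-branching transport vessels whose distal tips are distal-behaviour
attachment points on the territory boundaries.

## Problem sizes used in the tests

Constraint audits and constrained-outlet checks run 200-terminal trees;
oracle equivalence uses ≥50 forests of ≤ 9 vessels; the two-stage
multi-criteria scenario runs at its published budgets (25 + 975); the
sequential, hierarchical and scale-specific scenarios run scaled-down
budgets (80/120, 50/195, 50/45/150) that exercise the same staging
logic; the two-inlet balance comparison uses 200 terminals per run over
five seeds. The acceptance script regrows three 200-terminal scenarios
from scratch per invocation.

## What the synthetic scenarios do and do not show

The fixtures emulate the geometry of the academic benchmark scenarios —
convex and annular territories, competing inlets, prescribed outflow
diversion, heterogeneous densities — with symmetric, programmatically
built initial trees. They do not contain image-derived anatomy: real
vascular completion starts from measured centrelines with per-vessel
radii and flows, where pre-existing geometry need not satisfy any of the
constructive constraints (the audit therefore skips stage-0 vessels).
Passing tests demonstrate the constructive machinery — constraint
satisfaction, budget bookkeeping, flow closure, optimiser correctness —
not anatomical fidelity of any particular organ.

## Known limitations

* Tree topologies only; anastomoses/graphs are out of scope.
* Vessels are straight segments: thin curved shells require many checks
  per segment and remain expensive; curvature-following growth is not
  implemented.
* The incremental evaluator's error band was measured on uniform-disc
  trees; exotic geometries with extreme depth could in principle exceed
  it (the exact re-evaluation step, not the incremental ranking, is what
  guards feasibility).
* With constrained outlets the off-path flow-ratio invariance is only
  approximate; the exact re-evaluation step absorbs the difference.
* Multi-inlet balance under the sprouting cost is an emergent property:
  early growth is volume-term-dominated (ΔF_vol/V_ref ~ 1/N), so
  unfavourable early sampling can still lock in an uneven split on some
  seeds.
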