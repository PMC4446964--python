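# Methods

## The energy model

A single cell is described by two geometric observables — perimeter `p` and
area `a` in 2D, surface `s` and volume `v` in 3D — and an energy

    E(p, a) = J p + λ_p (p − P)² + λ_a (a − A)²          (2D)
    E(s, v) = J s + λ_s (s − S)² + λ_v (v − V)²          (3D)

`J` is the adhesion energy per unit contact length (sign free: adhesion can
be effectively attractive or repulsive relative to the medium), `P` the
membrane rest length, `A` the target area, and the λ's weigh the cortical
and size constraints.  Interfacial tension is γ = ∂E/∂p and pressure
Π = −∂E/∂a.  The constraint weights must be non-negative (λ_a, λ_v
strictly positive) and targets non-negative; these are enforced at
construction.

### Shape classes

Equilibrium analysis restricts the cell to a one-parameter shape family
`p = k_p l`, `a = k_a l²` (2D) or `s = k_s l²`, `v = k_v l³` (3D).  Built-in
families:

| family | constants |
|---|---|
| circle | k_p = 2π, k_a = π (l = radius) |
| hexagon | k_p = 6, k_a = 3√3/2 (l = side length) |
| sphere | k_s = 4π, k_v = 4π/3 |
| rhombic dodecahedron | k_s = 8√2, k_v = 16/(3√3) |

The hexagon and rhombic dodecahedron are the space-filling shapes of packed
2D and 3D tissue; custom (k_p, k_a) pairs model anything in between.

### 2D equilibria and regions

On the shape manifold, dE/dl = k_p (τ + β l (l² − 3ε)) with the aggregates

    τ = J − 2 k_p λ_p L_p       (L_p = P/k_p)
    ε = L_a²/3 − k_p² λ_p / (6 k_a² λ_a)    (L_a = √(A/k_a))
    β = 4 k_a² λ_a / k_p,   α = −8 k_a² λ_a ε^{3/2}  (real for ε ≥ 0)

Two numbers, τ and ε, fully determine the qualitative behaviour:

* **Region I** (τ < −2 k_p λ_p L_a): tension at the regular-shape
  equilibrium is negative; the regular shape is unstable and the cell
  satisfies both constraints independently in a ruffled shape with
  a* = A and p* = P − J/(2λ_p).  For λ_p = 0 this off-manifold perimeter
  diverges and is reported as NaN.
* **Region II** (−2 k_p λ_p L_a < τ < 0): one stable regular equilibrium
  with positive tension.
* **Region III** (0 < τ < 2βε^{3/2}, needs ε > 0): bistable; a stable
  positive root coexists with the stable trivial root l* = 0, separated by
  an unstable root.
* **Region IV** (otherwise, τ > 0): only l* = 0 is stable; cells vanish.

The non-trivial roots of the depressed cubic are evaluated in closed form:
the cos form for the stable branch, switched to the algebraically identical
cosh form when τ k_p/α > 1 so no complex intermediates arise; the sin form
for the unstable branch; and the real Cardano form (via ζ = −(α/k_p)² > 0)
for ε < 0.  arccos/arcsin arguments within 1e−12 of ±1 are clamped (they
occur exactly at bifurcations through floating-point overshoot); larger
excursions raise, as they indicate an internal inconsistency.  Stability is
the sign of d²E/dl² = 3 k_p β (l² − ε).

Boundary classification is tolerance-based: τ is compared to each
bifurcation value at 1e−9 relative, and |τ| below 1e−9 of its own
constituent-term scale counts as τ = 0 (τ is a difference of large terms,
so an exact-zero test would be meaningless at reference magnitudes).

### The normalised vertex-model plane

With a zero rest length (P = 0, τ = J) the parameters map onto the
normalised tension/contractility coordinates used in vertex models of
epithelial packing:

    Λ̄ = J/(k_a^{3/2} λ_a L_a³),   Γ̄ = λ_p/(k_a λ_a L_a²).

The three bifurcation lines become Γ̄ = −(√k_a/2k_p) Λ̄, Λ̄ = 0, and
Γ̄ = (4k_a − 3(k_a k_p Λ̄)^{2/3})/(2k_p²); region IV lies above the fold
curve.  The map refuses P ≠ 0 rather than silently mis-normalising.

### 3D equilibria

dE/dl = 2k_s(a l⁵ + b l³ − c l² + τ l) with a = 3k_v²λ_v/k_s, b = 2k_sλ_s,
c = a L_v³, τ = J − 2k_sλ_sL_s².  The gradient vanishes at l = 0 for every
parameter choice (small 3D cells change size ever more slowly — a genuine
difference from 2D, where the rate at zero is τ).  Closed-form quintic
roots are uninformative; positive roots are bracketed on a combined
linear+geometric grid of ~5000 points and refined by Brent's method to
1e−12 relative.  The search interval is bounded by
10·max(L_v, √φ, (2|τ|/a)^{1/4}, 1): any root obeys a l⁴ ≤ c l + |τ|, so the
three scales cover it (the τ term matters when both constraints are weak
and τ is strongly negative).  τ < 0 guarantees exactly one positive root
(stable); τ > 0 gives zero or two (lower unstable, upper stable); parameters
on the fold give a double root, detected via the reduced coordinates.

Regions live in the reduced plane built from φ = b/(6a), ψ = c/(8a):
ν = τ/(12aφ²), μ = ψ/φ^{3/2} for λ_s > 0, with the fold at
ν = f(μ)(μ − f(μ)), f(μ) = sinh(arcsinh(μ)/3).  For λ_s = 0 the branch
switch is exact (λ_s is user input, not a computed quantity): ν′ = τ/(12a),
μ′ = ψ, the tension-sign boundary collapses onto ν′ = 0 (no separate
region II) and the fold is ν′ = μ′^{4/3}/2^{2/3}.

## The lattice simulator

The Cellular Potts model realises the same energetics on an integer label
grid.  Energy: every unordered pair of neighbouring sites with distinct
labels contributes J[type_i, type_j]; each cell adds λ_p(p_CPM − P)² +
λ_a(n − A)².  This pairwise-once convention makes a cell–cell interface
cost J once per site pair while each of the two abutting cells "feels" half
of it — which is why the geometric adhesion parameter is ξJ_CPM for
cell–medium but (ξ/2)J_CPM for cell–cell interfaces.

The perimeter proxy counts, for every cell site, all foreign sites within
the chosen radial neighbourhood (multiplicity-weighted).  The same
neighbourhood is used for the adhesion term; mixing neighbourhoods would
break the ξ bridge.  Dynamics follow the modified Metropolis rule
p = 1 if ΔE < −Y, else exp(−(ΔE+Y)/T); the boundary case ΔE = −Y falls in
the exponential branch (probability 1).  One MCS visits each site once in
a fresh random permutation and draws one copy source from the copy
neighbourhood.  Design choices where the convention is genuinely open:

* **Copy-source neighbourhood**: level 2 (Moore) in 2D, level 3 in 3D by
  default, independent of the (typically larger) perimeter neighbourhood;
  configurable.  Standard practice, keeps proposals local.
* **Boundary conditions**: default is a fixed frame of immutable medium
  (out-of-lattice reads are medium); periodic is available.
* **Connectivity**: cells may fragment; no connectivity constraint.
* **Temperature**: T > 0 enforced; the zero-temperature limit produces
  lattice-anisotropy artefacts.
* **Medium**: label 0, its own row/column in J, no size constraints.
* **RNG order**: per MCS — site permutation, then copy-source indices,
  then acceptance uniforms, drawn from a single seeded generator.  An
  acceptance uniform is consumed for every heterotypic visit whether or
  not the deterministic branch applies, keeping the stream positionally
  fixed.

The per-MCS sweep is numba-compiled; a pure-Python reference path performs
the identical update with the identical stream, and the suite asserts
bitwise-equal trajectories between the two.  ΔE is computed locally in one
pass over the neighbourhood (adhesion change plus the foreign-site counts
that give the perimeter-proxy changes of the losing and gaining cells); the
suite verifies it against a global Hamiltonian recompute to 1e−9 absolute,
which is the double-precision cancellation floor at total energies of
~10⁶ — the oracle test therefore uses tissue-like random states with
moderate weights, where that comparison is numerically meaningful.

## Parameter bridges

* **ξ (perimeter scaling)**: the proxy has dimension L⁴ (2D) / L⁶ (3D);
  ξ = p_CPM/p converges to (2/3)r³ and (π/4)r⁴ for large radial
  neighbourhoods.  For the small neighbourhoods used in practice the exact
  flat-interface count is computed instead (half-space cell, one boundary
  column, offsets with last component ≥ depth+1 summed over depths) and is
  the default everywhere; the continuum formula is opt-in.  The exact count
  is verified against an independent oracle: a slab spanning a periodic
  lattice has proxy exactly 2·width·ξ.  Note the exact counts deviate from
  the continuum formula by more than 6% at isolated shell-entry radii even
  above radius 5 (e.g. 12% at r = √26, where the (±1, 5)-type offsets
  enter); between those spikes the error decays as expected.
* **Resolution**: J′ = J/k, λ_p′ = λ_p/k², λ_a′ = λ_a/k⁴, P′ = kP,
  A′ = k²A (2D; one power higher in 3D), exact for any cell shape and
  multiplicative in k.  T is left untouched: it does not enter the
  force-balance derivation, and the reference resolution comparisons hold
  T fixed.  Trajectory tables convert measurements back to reference
  units (areas by k², perimeters by k, 3D surfaces by k²).
* **Adhesion ↔ rest length**: shifting every cell–cell J by ΔJ, every
  cell–medium J by ΔJ/2 and every rest perimeter by ΔJ/(4λ_p) changes every
  ΔE by exactly zero — same-seed runs are bitwise identical.  Requires
  λ_p > 0 (no compensation through λ_p exists); for non-uniform shifts only
  the instantaneous contact-weighted diagnostic is provided, since no
  static one-to-one mapping exists.

## Synthetic initial conditions and desk-scale experiments

`make_disc` (discs/balls by exact lattice membership) and `make_tissue`
(uniform random non-colliding seeds, nearest-seed Voronoi assignment,
types drawn from given fractions) are pure functions of arguments and
seed.  They emulate the initial conditions of the reference experiments —
isolated cells and dense multi-type blobs — not real microscopy data: real
tissues have curved boundaries, size dispersion and correlated types, so
green tests certify the model implementation, not biological realism.

The region suite runs the reference single-cell parameter set (λ_p = 25,
P = 2000, λ_a = 0.0625, A = 31416, T = 20000, 6th-level neighbourhood,
J ∈ {0, 80k, 200k, 300k} for regions I–IV) rescaled to k = 0.25 on 96²
lattices — the package's own resolution mapping makes this a faithful,
exactly-parameter-equivalent miniature of the published 256²-scale sweeps
(~100× fewer site-updates than the 10 000-run original).  A run counts as
"persisted" only if the cell is alive at the final MCS and over the whole
last 10% of the run.  Observed behaviour matches the analytics: region II
converges to the stable area within a few percent (the equilibrium
perimeter runs high, as expected from membrane fluctuations at
near-zero tension); region III cells below/above the unstable radius
vanish/grow; region IV cells vanish.

## Known limitations

* Equilibrium analysis only; no analytic time courses.
* The flat-interface ξ applied to a curved boundary over-/under-counts by
  a few percent (a disc of radius 30 measures within ~10%); this is
  intrinsic to the proxy, not to the implementation.
* No chemotaxis, persistence, connectivity constraint or GPU path.
* Monte Carlo time is not rescaled across resolutions; only parameters are.
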