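# Methods

`rangefront` models a population front crossing a habitat that contains
compact growth-free regions ("obstacles", the lake scenario): a planar wave
of a dispersing, logistically growing population meets one or more obstacles,
wraps around them, and heals the resulting perturbation downstream.  Three
engines describe this at different levels of detail, and a measurement layer
compares them on a common footing.

## Constant-speed (eikonal) model

**Model.** The front advances at a fixed speed v normal to itself; an
obstacle deletes the front segments that overlap it and contributes nothing
else.  This is a Huygens construction: the front at time t is the envelope of
circular wavelets, equivalently the level set T(x) = t of the first-arrival
time solving |grad T| = 1/v outside obstacles.

**Closed forms.** For a rhombus of half-width w and half-height h centered on
the propagation axis, the front behind the obstacle consists of straight
outer segments plus circular arcs of radius d centered on the two widest
points, where d is the unperturbed front's distance past the widest row.
The arcs meet the obstacle edges at exactly 90 degrees (the arc radius runs
along the edge), collide on the axis at d_kink = sqrt(w^2 + h^2), and the
indent — the lag of the most retarded point behind the unperturbed front —
heals as

    Delta(d) = d * (1 - sqrt(1 - w^2/d^2))  ->  w^2 / (2 d)    (d >> w),

independent of h.  Rescaling all lengths by w collapses every rhombus onto
one master curve; rescaling by h does not, which the tests use as a negative
control.  For a circular obstacle of radius r the most-lagging axis point is
reached by the shortest grazing path (tangent, arc, tangent), giving
d = r asin(r/y_f) + sqrt(y_f^2 - r^2) with Delta = d - y_f; the kink is born
as a cusp (opening angle zero) at d = pi r / 2 and obeys the same far-field
healing law with w = r — the far-field perturbation depends on the obstacle's
width only.  For a thin bar of projected half-width L tilted by angle
arctan(h/L), intersecting the two endpoint-centered arcs gives the kink tip
at x_tip = (h/L) * L^2 (d - sqrt(d^2 - L^2 - h^2)) / (L^2 + h^2), which
approaches the bisecting normal monotonically.

**Grid solver.** Arbitrary environments use an upwind discretization of
|grad T| = 1/v on a square grid (default spacing a_eik = w_half/100, obstacle
cells excluded by the cell-center rule), solved by Gauss–Seidel fast sweeping
in four orderings.  Two accuracy measures beyond the textbook first-order
scheme matter here:

* an 8-neighbour *multistencil* (the upwind quadratic is solved on the axis
  pair and on the diagonal pair with spacing a*sqrt(2), taking the minimum),
  which cuts the anisotropy error of diagonal characteristics;
* *second-order one-sided differences* (3T - 4T1 + T2)/(2a) wherever the
  second upwind neighbour is available and causal, falling back to first
  order at walls and sources.

Sweeping (rather than heap-based marching) was chosen because the kernel is
a tight numba loop with no priority queue; both solve the same discrete
system.  With these choices the measured indent agrees with the closed form
to about half a grid cell over d in [1.5w, 10w], and planar regions are exact
to rounding because the founder row is frozen at its planar arrival values.

A known artifact remains: along slanted obstacle walls the scheme drops to
first order and drags a numerical boundary layer of roughly ten cells.  The
contact-angle estimator therefore discards contour vertices within 12 cells
of the obstacle, fits an algebraic (Kasa) circle to the next ~60 cells of
front — the constant-speed front *is* locally a circle — and evaluates the
tangent where the fitted circle crosses the edge line.  At the default
resolution this recovers 90 degrees to within ~1 degree for d not too small;
for d < ~0.6 w_half the arc is shorter than the excluded layer and the
estimate degrades, so angle measurements are taken at mid-range d.

**Marker paths.** Geodesics ("virtual marker" trajectories) are discrete
steepest-descent backtraces on the arrival grid: from a cell, move to the
8-neighbour with the largest descent rate per unit length; exact ties resolve
toward the column of the query point.  Path lengths therefore carry the
8-direction chamfer excess (up to ~8% on oblique legs), which is ample for
the qualitative uses here (single bend at a convex corner; a second obstacle
lengthens the path).

## Reaction-diffusion (FKPP) model

**Model.**

    du/dt = D_eff * lap u + k_eff(x) * u * (1 - u),

with k_eff = k_hat outside obstacles and 0 inside; the diffusion coefficient
is unchanged inside obstacles (a config override exists), so obstacles act as
partially absorbing sinks with a boundary layer of width ~xi.  Carrying
capacity is 1 after rescaling.  The pulled-front speed is
v = 2 sqrt(D_eff k_hat) and the front width parameter xi = sqrt(D_eff/k_hat).

**Default parameters** (units mm, hours): D_eff = 0.0144 mm^2/h (the
literature diffusion coefficient for a ~60 nm phage particle in soft agar;
the Stokes–Einstein value in water, ~0.04 mm^2/h, is about a factor three
larger and serves as an upper bound) and k_hat = 0.7/h, obtained by inverting
v = 2 sqrt(D k) for the measured front speed v ≈ 0.2 mm/h.  These give
xi ≈ 0.143 mm.  The front threshold is u_thresh = 0.05 (0.5 as alternate);
both thresholds show the same qualitative lag.

**Discretization.** Nine-point Laplacian, exactly

    lap u ≈ [-20 u + (corner sum) + 4 (edge sum)] / (6 a^2),

on a square grid of spacing a_grid = 0.15 xi (exact on quadratics; checked
against direct arithmetic).  Periodic boundaries along x; the first and last
rows are Dirichlet rows held at their initial values (1 behind, 0 ahead) and
must be at least 10 xi from any obstacle.  The initial condition is u = 1
behind the founder line with a linear ramp of width 2 xi (the ramp width and
founder-obstacle distance are package choices; the profile relaxes to the
Fisher wave within a few growth times and the tests verify insensitivity).
Time integration is adaptive method-of-lines (SciPy RK45,
rtol = atol = 1e-6); the reference implementation's specific solver is not
reproduced — the contract is that halving tolerances moves reported front
positions by less than 0.1 a_grid, which is tested.  Density bounds are
enforced at 100*atol: long adaptive integrations accumulate excursions of
order ten atol at the wave tail and the saturated state (solver noise),
while real instabilities grow to order one, so the threshold separates the
two cleanly.  The
right-hand side is a fused numba kernel (identical to the stencil above to
machine precision).

**Measurements.** The front is the marching-squares contour of u at
u_thresh with obstacle cells masked; the front position d is read from the
two lateral edge columns (far from the obstacle), matching the convention of
the other engines, with d = 0 when the unperturbed front passes the
obstacle's widest row.  The comoving profile approximation

    u(z) ≈ s + (1/4) e^{z/c} s^2 ln(4 e^{z/c} s^2),  s = (1+e^{z/c})^{-1},  c = 2,

(u(0) = 1/2 exactly) matches the measured obstacle-free profile to sup-norm
~0.013 after 10–15 growth times; the test tolerance 0.03 acknowledges that
the formula itself is approximate.

**Known behavior.** The PDE front always lags the constant-speed prediction:
the obstacle absorbs density near its boundary (a xi-wide lagging layer), and
the freshly created arc of radius < xi at the widest point propagates slower
than a planar front.  Both effects scale with xi while the geometric
perturbation scales with w, so the lag shrinks as D_eff decreases at fixed v
(tested: D -> D/3 strictly reduces the lag at matched d).

## Stochastic lattice (Eden) model

One individual per site on a lattice with hexagonal (6-neighbour) topology:
rows are spaced one unit apart with odd rows offset by half a site, so the
site density is one per unit area and a disk of radius R rasterizes to
~pi R^2 sites.  (A true equilateral metric would change site counts by
2/sqrt(3); only the topology matters for the model.)  The founder row holds
W unique genotypes; obstacle disks and the lateral boundary columns are
blocked (no periodic wrap, which keeps genealogies planar).  Each event picks
a frontier site (occupied, with an empty neighbour) uniformly, copies its
genotype into a uniformly chosen empty neighbour, and advances time by an
exponential increment of mean 1/|frontier| (frontier size taken before the
event).  Blocked sites are excluded from the frontier; including them as
choosable-but-sterile would only rescale time.  Individuals never die.

Defaults follow the printed scale: W = 600, R = 80, obstacle center one third
of the system width ahead of the founder row, laterally centered; the
two-obstacle configuration offsets the second disk by (5/3 R, 5/2 R).  The
run stops when every column's front has passed the top of the highest
obstacle by 3R (the stop depth and lattice depth are package choices).
Frontier bookkeeping is incremental (swap-pop array with a position map), and
random draws are consumed from buffered blocks of a seeded PCG64 generator,
so printed-scale runs take seconds and identical seeds reproduce bit for bit.

**Genealogy and sector statistics.**  Every site records its parent and birth
time, so the lineage forest of any frontier (current or at a past time —
occupancy at time t is simply birth-time <= t because sites never vacate) is
reconstructed exactly; tests verify equality with a brute-force replay of the
event log.  Newick export uses an in-repo iterative writer because lineage
paths reach thousands of nodes.  Sector boundaries are adjacent occupied
pairs with different genotypes, grouped by proximity.  A *pinned* boundary at
an obstacle top is detected as a boundary pair in the first R/4 rows above
the top whose two flanks trace (via parent pointers) to opposite lateral
sides of the obstacle's widest row.  The default search window is +-R/8
around the obstacle axis; for the staggered two-obstacle configuration the
tests widen it to +-0.35R because the kink over the second obstacle is
asymmetric — its wake-facing side is reached later, shifting the meeting
point about R/4 toward the wake.  Lineage routes are labeled left/right by
the ancestry's lateral position at each obstacle's widest row, with a
"graze-" prefix when the path comes within 2 lattice units of the obstacle;
with the positive lateral offset used here the between-obstacle route is
(first: right, second: left) — the mirror image of the same geometry with the
offset flipped.

## What the synthetic configurations do and do not emulate

All inputs are generated geometry — there is no external data.  The standard
inventory (four rhombi with half-sizes in {0.9, 1.2} mm, the two staggered
configurations, the lattice defaults, and quarter-scale miniatures) spans the
printed study conditions; random obstacle fields (N square features of side L
at growth fraction rho) emulate disordered habitats.  The engines capture
front geometry, absorption, and neutral drift, but none of the biology
underneath: no explicit infection cycle (adsorption, latency, burst), no
selection, no death behind the front, no front-roughness instabilities, and
no experimental imaging noise.  Agreement of the three engines on the
geometric observables therefore supports the geometric theory, not any
particular microbial mechanism.

## Problem sizes used by the test suite

Chosen so the full suite and the acceptance script each run comfortably on a
single CPU: arrival grids at a_eik = w/100 (~1.6 M cells per rhombus);
PDE lag runs for the wide rhombus on ~0.2 M cells (D_eff default) and ~1.5 M
cells (D_eff/3), sampling d in [1.6, 2.6] mm past the kink at 1.5 mm;
planar-speed and profile runs quasi-1D; lattice runs at the printed scale
(W = 600, R = 80, ten seeds) for the drift statistics and at W ~ 100–150 for
unit-scale checks.

## Limitations

* The contact-angle estimator needs an arc several tens of cells long; very
  small d (or very coarse grids) degrade it.
* Marker paths are 8-direction chamfer paths, not exact geodesics (exact
  visibility-graph geodesics are out of scope).
* The random-field generator requires (rho, N, L, domain) to be mutually
  consistent (within 2%) rather than adjusting one to fit the others.
* Delta measurements clamp at zero; fronts that overshoot the unperturbed
  position (possible at PDE resolution limits) are reported as zero indent.
* The FKPP engine assumes equal diffusion inside obstacles; the config
  override covers the unequal case but it is untested against any reference.
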