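# Methods

## Model overview

A tissue voxel is modelled in two dimensions as a square of side
L = 250 µm containing three compartments: circular vessel cross sections
(plasma fraction v_p), packed elliptical cells (intracellular fraction
1 − v_e − v_p, impermeable to gadolinium chelates), and the extracellular
extracellular space (EES, fraction v_e) between them.  Contrast agent
enters the EES only across vessel walls and then spreads by Fickian
diffusion:

    dC/dt = D lap(C)                     in the EES,
    D dC/dn = P (C_p(t) − C)             on vessel boundaries,
    dC/dn = 0                            on cell boundaries and the outer edge,

with C_p(t) the arterial input function, uniform within every vessel at
all times (no flow modelling: K^trans here is a permeability–surface-area
product, the permeability-limited regime).  The wall transfer coefficient
is calibrated as P = (K^trans/60) · V / S, with S the total vessel
boundary length in one voxel and V = L² its area, so that the *total*
influx equals K^trans V (C_p − C).  In the limit of fast diffusion the EES
is well mixed and the voxel obeys the standard two-compartment (Kety/Tofts)
model with the nominal K^trans exactly; at finite D it does not, and that
difference is the quantity of interest.

To avoid artificial no-flux conditions at the voxel edge, the voxel is
surrounded by eight identical copies (a 3×3 tiling, 750 µm across); the
outer boundary of the *extended* domain is sealed, and all reported voxel
quantities are computed on the central tile only.

## Voxel geometry generation

Vessels are discs of fixed 8 µm diameter; their count is
round(v_p L² / vessel area) and their centres are placed by greedy
farthest-point sampling, giving a spaced (unclustered) vasculature.

Cells are ellipses constructed in four steps: (1) a Lloyd-relaxed Voronoi
partition of the voxel (vessel centres are additional fixed sites) sets
one region per prospective cell, with the cell count chosen from the
nominal 14 µm mean diameter; (2) the largest ellipse with moment-derived
orientation/axis ratio is inscribed in each region (for a fixed shape this
reduces to a largest-inscribed-circle problem in an affinely stretched
polygon, solved by pole-of-inaccessibility); (3) cells iteratively
re-inscribe against the *current* shapes of their neighbours, absorbing
the corner space the polygonal partition wastes; (4) remaining pockets are
filled greedily with small round cells, and a final uniform scaling trims
the total to the exact target fraction.  Every step preserves a minimum
inter-shape clearance (default 2 µm), so the interstitial channel network
is always resolvable by a boundary-conforming mesh.  Plain random
sequential addition of 14 µm ellipses was tried first and jams near 55 %
coverage — short of the 58 % intracellular fraction of the reference
voxel — and what it does reach is laced with sub-micron channels that
explode the mesh size; the Voronoi construction is the package's answer to
that constraint.

Consequences worth knowing: the achieved mean cell diameter is ~12.4 µm
(slightly below the 14 µm nominal, because pocket-filling cells are
small), and an intracellular fraction of 0.72 (the v_e = 0.25
configuration of the full grid) is not reachable with mesh-resolvable
clearances — the grid runner logs and skips that configuration.  The
generator is deterministic given its seed; achieved fractions land within
±0.01 (v_e) and ±0.005 (v_p) of their targets.

## Meshing

Only the EES is triangulated; cells and vessels are voids.  Hole
boundaries are polygonized with vertex spacing ~target edge length and
then inflated radially so each polygon's area equals the analytic
ellipse/disc area — this keeps the triangulated EES area within 0.5 % of
the exact geometric fraction even at coarse boundary resolution.  The
mesher is a distmesh-style smoothed Delaunay scheme: fixed boundary
vertices, hexagonal interior seeding thinned to a graded size field
(channels narrower than the target edge are meshed finer), repulsive-edge
relaxation with Delaunay retriangulation, carving of triangles whose
centroid falls in a hole, and a refinement loop that splits boundary
segments or retires crowded nodes where skinny triangles remain.  Boundary
edges are tagged vessel / cell / outer with the owning shape recorded.

The default test-suite target edge is 6 µm to keep runtimes sensible; the
high-fidelity setting used for the headline numbers is 2 µm, where the
mean edge length is 2.0 µm and the minimum triangle angle exceeds 20°.  At
targets coarser than the channel width (e.g. 6 µm on 2–4 µm channels) a
small tail (<1 % of triangles, all ≥10°) of flatter triangles remains in
channel junctions; P1 accuracy is insensitive to this, and the
cross-solver validation below bounds the practical effect.

## Discretization and time stepping

Linear (P1) Lagrange elements with a consistent mass matrix; the Robin
term adds an edge mass matrix and a load vector on vessel-tagged edges
only.  Time stepping is the theta scheme with theta = 0.5
(Crank–Nicolson): unconditionally stable, second order, with the constant
left-hand-side matrix factorized once (sparse LU) and reused.  Small
Crank–Nicolson undershoots are tolerated to 1e-6 mM.  Measured
convergence orders on a separable analytic solution are 2.0 in h and 2.1
in dt; sealed-domain mass is conserved to machine precision.

`choose_time_step` implements the conservative rule
dt = clamp(h²/D, 1e-3 s, 0.1 s) (additionally capped at 0.25 s to resolve
the arterial bolus).  For the experiment grid the default is a fixed
dt = 0.05 s: a refinement study at the stiffest setting (D = 3×10⁻³ mm²/s,
dt from 0.005 to 0.1 s) changes the voxel-mean curve by less than 10⁻⁴ %
of its peak, because the implicit scheme's accuracy is governed by the
smooth forcing, not by the mesh-diffusion scale.

In the pipeline, S in the P calibration is taken from the *mesh* (total
vessel-tagged edge length per tile) rather than the analytic perimeter, so
the discrete total influx matches the nominal K^trans exactly and the
well-mixed limit is recovered without geometric bias.

## Arterial input function

The measured population input that motivates the simulations is not
publicly tabulated, so the package ships a parametric stand-in with the
features that matter here: a gamma-variate first pass
A (t/t_p)^a exp(a(1 − t/t_p)) with the peak calibrated to t_p = 0.88 min,
peak amplitude 3.0 mM (a typical preclinical bolus), shape a = 3, and a
smoothly ramped biexponential washout (time constants 2 min and 50 min).
C_p(0) = 0, the curve is non-negative with a single interior maximum, and
the simulated duration is 11 min.  All parameters are exposed, and a
measured curve can be loaded from CSV (minutes, mM).  Because the true
amplitude and shape are surrogate choices, quantitative error *ranges*
from the simulation should be read as indicative; the qualitative
structure (bias growing as D falls, χ² falling as D grows) is
AIF-independent and is what the acceptance checks pin down.

## Signal synthesis and fitting

A fast exchange limit is assumed: the voxel R1 is the area-weighted sum of
compartment rates, each linear in its local concentration with
r1 = 4.7 mM⁻¹s⁻¹ and all baselines at 0.5 s⁻¹.  Because of this
linearity, the weighted elemental sum collapses to
R1(t) = 0.5 + r1 [v_e C̄_e(t) + v_p C_p(t)], which is evaluated at every
solver step; the explicit per-element route is kept and tested for
equality.  Signal is the SPGR steady state (TR 5 ms, flip 25°, S0 = 1,
TE ≪ T2*), point-sampled at the scan interval (1.6–25.6 s) starting at
t = 0, then inverted back to concentration and fitted with the extended
Tofts model by bounded trust-region least squares from the standard
initial guess (0.1 min⁻¹, 0.1, 0.01).  v_e + v_p ≤ 1 is deliberately not
enforced, so the fit can express the over-estimates of v_p that the
physics produces.

The model convolution inside the fit is evaluated on a grid ten times
finer than the data and subsampled (the AIF is available continuously).
With the convolution restricted to the data grid instead, the trapezoidal
quadrature error of the *model* dominates χ² at 12.8–25.6 s sampling and
even reverses the χ²-vs-D trend; supersampling keeps χ² a measure of the
physics mismatch, and it decreases monotonically in D at every sampling
interval, as it should.

## Validation strategy

* analytic: cosine-mode decay on a hole-free square (error <1 %, orders
  ~2/~2), exact mass conservation with sealed walls, exact equilibrium
  when C matches a constant C_p, exact 4-fold symmetry on a symmetric
  fixture mesh;
* cross-solver: an independent masked-grid finite-difference solver
  (1 µm pixels, 5-point stencil, flux faces at vessel-adjacent pixels,
  reflecting outer wall, its *own* discrete vessel-interface length in the
  P calibration) agrees with the FEM voxel mean to within 2 % of peak over
  three domain configurations and D from 1×10⁻⁴ to 1×10⁻³ mm²/s;
* limiting case: at D = 3×10⁻³ mm²/s the simulated voxel matches the
  closed-form well-mixed solution within 3 % of peak and the full
  signal-fit pipeline returns all three parameters within 5 % (measured:
  <0.2 %).

The synthetic study emulates geometry, delivery, diffusion, relaxation and
sampling; it does not emulate noise (a noiseless analysis isolates the
diffusion bias), water-exchange effects beyond the fast exchange limit,
T2*/susceptibility effects, flow-limited delivery, vessel clustering, or
3-D connectivity of the interstitium (a 2-D EES percolates differently
than 3-D).  Passing tests therefore demonstrate the *mechanism* and its
scaling, not patient-level error magnitudes.

## Problem sizes used by the test suite

Reference voxel ~280 cells / 37 vessels; single-tile test mesh ~4.6k
nodes (6 µm), high-fidelity tile mesh ~10k nodes (2 µm); extended-domain
mesh ~39k nodes; reduced grid = one domain × K^trans 0.4 min⁻¹ ×
D ∈ {1, 2, 4, 30}×10⁻⁴ mm²/s × five sampling intervals, 11 simulated
minutes each; finite-difference oracle at 1 µm pixels (~24k unknowns),
compared over 5–6 simulated minutes.
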