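# Methods

`pinchflow` simulates size-dependent sorting of deformable cells in an
asymmetric pinched-flow-fractionation (AsPFF) microchannel with a
two-dimensional immersed boundary-lattice Boltzmann method (IB-LBM).
This note records the model, the numerical choices, and the reasoning
behind parameters the design left open.

## Fluid solver

The carrier fluid is evolved with the D2Q9 single-relaxation-time (BGK)
lattice Boltzmann equation with Guo's forcing discretization.  Nine
populations g_i relax toward the second-order Maxwellian at rate 1/tau;
body forces enter both as a source term G_i with prefactor (1 - 1/(2
tau)) and as a half-step shift in the macroscopic velocity
u = (sum_i e_i g_i + f dt/2) / rho.  The kinematic viscosity is
nu = (tau - 1/2) c_s^2 dt with c_s = h/(sqrt(3) dt).  The implementation
is a fused collide + pull-stream pair of numba kernels, single-threaded
so results are bit-reproducible; mass is conserved to round-off on
closed and periodic domains.

Validation oracles (in the test suite): body-force-driven plane
Poiseuille flow reproduces the analytic parabola to < 1% L2 error at 32
nodes across the gap, and the Taylor-Green vortex decay recovers the
nominal viscosity within 0.1%.

Boundary handling:

* channel walls: halfway bounce-back (the no-slip plane sits half a node
  outside the last fluid node);
* free-slip walls: specular reflection (used optionally by the cylinder
  benchmark);
* open ports: non-equilibrium extrapolation of a target velocity
  (inlets) or a target density (outlets); an equilibrium-only velocity
  variant is available and is the default for the benchmark's far-field
  boundaries.

All port fluxes are audited as *mass* fluxes through the link plane
between the port nodes and the first interior nodes, the quantity the
scheme conserves exactly.  Volumetric fluxes differ between ports by the
O(Ma^2) density variation that drives the flow; at the default flow
scale this is a ~2-5% effect and mass flux is the meaningful bookkeeping
unit.

## Immersed boundaries

Lagrangian point sets (cell membranes, the benchmark cylinder) couple to
the lattice through the four-point smoothed delta kernel: velocities are
interpolated onto the points, point forces are spread back with the same
kernel (the two operators are exact adjoints; spreading conserves total
force to round-off).  Points advect by forward Euler, one update per
lattice step.  Point spacing is kept at or below ~0.7 lattice units.

Rigid boundaries are enforced by feedback (penalty) forcing: a force
alpha_1 * integral of the slip velocity + alpha_2 * slip velocity, with
alpha_1, alpha_2 large and negative.  Defaults alpha_1 = -0.05,
alpha_2 = -2.0 (lattice units) keep the coupled system stable for
tau >= 0.54 and drive the boundary slip RMS below 10^-3 of the free
stream; both are exposed in the benchmark configuration.

### Effective boundary position

A boundary represented through a smoothed kernel is hydrodynamically
wider than its Lagrangian radius.  We measure this offset with an
independent oracle: two straight feedback-held wall lines in a periodic
box, with Poiseuille flow driven between them; extrapolating the
parabolic profile to zero locates the effective no-slip planes.  For the
four-point kernel at the benchmark's feedback constants the effective
wall sits delta_k ~ 0.79 lattice units outside the Lagrangian line,
essentially independent of tau and point spacing (`ib_wall_offset`
recomputes this).  A front-stagnation-point measurement on the cylinder
confirms that retracting the Lagrangian circle by delta_k places the
effective surface at the nominal radius.

The cylinder benchmark is defined at full scale (domain 1000 x 800,
D = 40) where the standard practice — and the only construction the
original description admits — places the Lagrangian points on the
nominal circle, so the *effective* diameter at full scale is
D + 2 delta_k.  Reduced-resolution runs therefore retract the circle by
delta_k (1 - s) at resolution scale s: this preserves the full-scale
ratio of effective to nominal diameter, and with it the effective
Reynolds number of the full-scale setup being emulated.  The default
desk-scale benchmark runs at s = 0.5.

## Cylinder benchmark

Flow past a stationary cylinder at Re = U_inf D / nu of 40 (steady twin
vortices) and 100 (periodic vortex street).  U_inf = 0.08 lattice units
(Mach 0.14; halving it changes drag by < 0.2%), tau set from Re.  The
domain starts in the uniform free stream — an impulsive equilibrium
start excites far less of the slow acoustic ringing of the open box than
ramping the whole column.  The lateral boundaries are *open* (held at
the reference pressure so the wake can displace fluid sideways): at the
domain's 5% blockage, walls that forbid lateral outflow — free-slip or
imposed-velocity alike — confine the wake and measurably raise drag and
Strouhal number and inflate the lift amplitude toward classic
confined-cylinder values; the open condition recovers far-field
behaviour.  Free-slip and imposed-velocity variants remain available.
At Re = 100 a transient inflow tilt (8% of U_inf for 2500 steps) seeds
the instability so shedding saturates within ~15 periods.

Measurements: drag and lift coefficients from the negated sum of the
spread feedback forces, Cd = F_D / (0.5 rho U_inf^2 D) with D the
*nominal* diameter; the Strouhal number from the dominant spectral peak
of Cl(t) (Hann window, parabolic peak interpolation) over at least ten
shedding periods; the recirculation length from the sign change of the
streamwise velocity on the wake centerline, computed from a
time-averaged profile (a few thousand steps) because the crossing sits
where u ~ 0 and instantaneous profiles carry acoustic noise of ~ +-0.1
diameters.  The steady (Re = 40) run stops when two-chunk means of Cd
agree within 0.15%; the wake length saturates later than the drag, which
the averaging window absorbs.

## Cell model

A cell is a closed counterclockwise chain of Lagrangian points with four
force densities: tension restoring unit local stretch (evaluated as a
difference of segment tensions, so the closed-chain sum telescopes to
zero), bending (periodic fourth arclength difference, entering the total
with a minus sign), an area penalty K_s (S - S_0)/S_0 along the membrane
normal with the sign arranged to restore the reference area from either
side, and a short-range wall repulsion K_e / d^2 cut off at r_c with the
gap clamped at 0.1 lattice units.  Wall distances are measured against
the analytic wall polylines of the device, not the rasterized mask, for
sub-lattice accuracy in the 30 um pinch.

Stiffness defaults (lattice units): K_l = 5, K_b = 0.1, K_s = 2,
K_e = 0.003 with r_c = 2 um.  The elastic coefficients are not reported
for the original study and are calibrated against its sorting outcomes
— the only data that constrain them.  The calibration is strongly
informative: soft membranes (K_l below ~1 at the default flow scale)
elongate in the pinched segment until every diameter exits at the same
transverse height, destroying size discrimination altogether, while the
quasi-rigid defaults preserve the center-height-equals-radius mapping
that pinched-flow fractionation relies on.  Enclosed area drifts by
less than 1% over a device transit (the membrane advects with the
interpolated fluid velocity, so area is conserved by the flow itself to
within kernel slip; the penalty corrects the residual).

The wall repulsion acts along the into-fluid normal of the nearest wall
segment with a signed distance, so a point pressed onto (or numerically
through) a wall always receives a restoring push; segments are oriented
automatically against the analytic region test at construction.

## Device geometry and flow control

The device (458 x 400 um) comprises two 70.71 um U-branches meeting at
45 degrees into a 30 um pinched segment of length 2 w_0, a circular
buffer (radius 50 um), and four 26 um D-branches whose mouths sit on the
buffer circle.  Branch 1 (adjacent to the alignment sidewall) and branch
4 run straight to the bottom/top domain edges at +-60 degrees from the
axis; branches 2 and 3 run to the right edge at +-20 degrees.  The
published schematic dimensions neither the fan angles nor the buffer.
The buffer radius matters more than it looks: with a large buffer the
outlet fan is long and cells drift across the dividing streamlines
(away from the wall-side branches) before committing, which scrambles
the branch pattern; the compact buffer keeps the fan short so cells
commit near where the pinch releases them.  The fan angles were chosen
so the resistance calibration below has room on both sides.

The "folded" parts of branches 2/3 are realized as an inline narrowed
segment of width w_e = 23 um whose length is the calibration parameter —
at low Reynolds number only the added resistance (~ length / width^3) of
the fold matters, not its routing.  `equalize_resistance` adjusts this
length by a secant iteration until, with equal outlet pressures, the
four outlet fluxes agree within 2% (then beta = 1/4 within 0.02).  The
calibrated length and the measured linear response d(beta)/d(rho_4) are
cached in a packaged JSON file keyed by the geometry parameters; the
linearity of beta in the outlet-4 pressure offset is exact for a Stokes
network and holds well here.

Two ways of realizing a target outflow fraction beta:

* pressure mode: outlets 1-3 at the reference density, outlet 4 offset
  by (beta - 1/4) / slope using the cached linear response;
* flux mode: outlets 1-3 impose outflow profiles; a small controller
  rescales them every 200 steps so each carries (1 - beta)/3 of the
  *measured inlet mass flux*, and the free pressure outlet 4 absorbs the
  remainder.  This realizes beta within ~0.005 independent of the
  compressibility of the flow and is what the sorting experiments use.

Inlets impose parabolic profiles whose means are split alpha : 1; the
flow rate (sum of inlet means, default 0.01 lattice units) keeps the
peak pinch velocity below 0.1 c_s.  Runs ramp the inlets over 2000 steps
and are declared stationary when port fluxes change by < 10^-5 of the
total inflow over 1000 steps.

## Experiments

Cells are released at seeded-random non-overlapping positions in
U-branch 2 (the lower inlet branch).  The alpha sweep records each
cell's transverse position when its centroid leaves the pinched segment
(2 um inside the segment: at the buffer junction itself the fan already
deflects trajectories), as height above the lower sidewall; alignment
improves (heights drop) with increasing alpha and saturates once the
sheath flow pins cells at roughly a cell radius from the wall, which is
why alpha = 6 and alpha = 10 differ by little.  Sorting runs converge
the carrier flow without cells first, then insert one cell per diameter
and advect until every centroid crosses a D-branch mouth (at >= 3 um
depth), removing each cell as it classifies; cells still in transit at
the step budget are reported unresolved rather than dropped.

Sorting demonstrations run at the lowest flow rate that completes in
reasonable time (inlet mean-speed sum 0.006 lattice units): branch
capture near band edges is Reynolds-sensitive, and the slow,
quasi-Stokes operation matches the regime the physical device targets.
Flux-mode runs realize the requested beta exactly (the outlet targets
are closed-loop-controlled against the same exact link-plane mass-flux
audit the flux reports use).

Two of the published sorting cases sit exactly on band edges of the
closed-form rule and are razor-edge cases for any reconstruction:

* at beta = 0.6, D = 8 um lies exactly on the branch-1/2 edge
  (2 w0 (1 - beta)/3 = 8), and 16/24 um on the 2/3 and 3/4 edges.  Our
  simulation resolves the 16/20/24 assignments as published but sends
  the 8 um cell to branch 2 at exactly-realized beta = 0.600; a
  finite-size flux argument shows its capture there is marginal even
  at full resolution (the cell's flux footprint spans about twice
  branch 1's 13.3% share).  Requesting 1.7% less outlet-4 flow
  (beta = 0.59) separates all four diameters into four distinct
  branches — the knife-edge the original work itself observes in its
  transition cases.
* at beta = 0.4, the rule places a rigid 20 um particle in branch 2
  (D/2 = 10 < 12), so the published {8, 16, 20} three-way split relies
  on the flexible cell riding above its rigid band; in this geometry
  the 20 um cell follows the rigid-rule branch.

The 8-vs-20 um two-way separation at beta = 0.1 is reproduced exactly
as published.

Why sorting works where the rigid band rule struggles: with a parabolic
pinch profile the wall-adjacent band that feeds branch N ends where the
cumulative flux fraction 3 eta^2 - 2 eta^3 (eta = y/w_0) reaches
N (1 - beta)/3.  At beta = 0.6 these edges sit at 6.8, 10.0 and 12.6 um
above the wall, so cell centres riding at radius-plus-gap heights of
roughly 5, 9, 11 and 13 um (for 8/16/20/24 um cells) fall into four
different bands — the uniform-profile rule instead places three of the
four exactly on band edges.

## Problem sizes

Desk-scale defaults: cylinder benchmark at resolution scale 0.5
(500 x 400 nodes, D = 20, both Reynolds cases in about eight minutes on
one core); device studies at 0.5 (229 x 200 nodes, 1 node = 2 um) with
the full-scale device available.  A sorting run (stationary carrier
flow plus four cells through the device) takes one to two minutes at
0.5x; the inlet-ratio sweep about six minutes for its four alpha
values.  These sizes resolve the smallest (8 um) cell with ~4 nodes
across, sufficient for branch-choice statistics though not detailed
deformation; the effective hydrodynamic size of such a cell exceeds
nominal by about one node of kernel smoothing, which tightens the
band-edge cases discussed above.

## Known limitations

* 2D: no out-of-plane curvature, depth effects or 3D lift.
* Cell-cell interactions are hydrodynamic only; the short-range
  repulsion acts between membrane and wall, not between two membranes.
* The weakly compressible solver carries O(Ma^2) density gradients;
  flux bookkeeping uses mass fluxes for this reason.
* The branch predictor is a rigid-particle band rule; flexible-cell
  deviations near band edges are expected and are the point of the
  simulations.
* Benchmark values at reduced scale carry the discretization of the
  emulated full-scale setup (see "Effective boundary position"); drag
  at the short 7.5 D inlet-to-cylinder distance of the prescribed
  domain is a few percent above unbounded-domain references regardless
  of boundary scheme.
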