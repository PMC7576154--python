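# Methods

This note documents the models implemented in `paddlepress`, the
numerical choices behind them, what the synthetic benchmark scenes do and
do not emulate, and the package's known limitations.

## Pressure from planar velocimetry

The pressure gradient follows from the incompressible planar momentum
balance

    ∇p = −ρ (∂u/∂t + (u·∇)u) + μ ∇²u ,

with all terms evaluated on the measurement grid: spatial derivatives by
second-order central differences, falling back to one-sided stencils at
the domain edge and beside masked nodes (so vectors contaminated by the
body surface never enter a stencil); the temporal derivative by central
differences over adjacent frames (one-sided at the sequence ends, hence
the three-frame minimum). The viscous term is retained in full — at
appendage Reynolds numbers of 10–100 it is not negligible.

### Eight-path median integration

Each unmasked node casts eight straight rays (4 axis-aligned, 4 diagonal)
to the edge of the field of view. Along each ray, ∇p·dl is integrated by
the composite trapezoidal rule with a sample step of min(Δx, Δy) and
bilinear interpolation of the gradient at off-node sample points (for
axis-aligned rays the interpolation is linear between nodes, so the rule
is exact at any sub-sampling). Rays whose path touches an undefined
(masked or invalid) node are excluded; the node's pressure is the median
of the surviving ray results (mean of the central two for an even count).
Nodes with no surviving rays are reported undefined, not filled — filling
would invent data exactly where masking is meant to prevent artefacts.
The median makes the estimate robust to locally corrupted gradients: on
the vortex-lattice benchmark, blocking three of a node's eight rays with
a mask changes its pressure by ≈0.3% of the field range.

**Boundary anchoring.** A ray integral yields p(node) − p(ray start), so
the boundary pressures fix the field. The conventional choice — ambient
p = 0 everywhere on the boundary — is only correct when the field of view
extends into quiescent fluid. This package instead derives the boundary
values from the same momentum data: the tangential component of ∇p is
integrated around the closed field-of-view loop (trapezoidal rule along
the edge nodes), and the loop's closure residual — zero for an exact
gradient field, small otherwise — is distributed uniformly in arc length.
Rays are anchored at these values, and the final field is shifted so the
mean over unmasked boundary nodes is zero (the ambient gauge; pressure
from planar velocimetry is determined only up to a constant). When the
boundary is genuinely far-field the loop values are near-constant and the
scheme reduces to the ambient anchor, which remains available as
`boundary="ambient"`. The difference matters on periodic benchmarks: with
ambient anchors the recovered lattice field is attenuated by roughly half
(≈12% RMS of range), because the true boundary pressure spans the full
field range; with loop anchors the error is 0.69/0.19/0.06% RMS at
32²/64²/128² — second-order convergence.

Straight rays were chosen over grid-following staircase paths; with the
bilinear-interpolated trapezoidal rule both are second-order consistent,
and straight rays make the blocked-ray geometry unambiguous.

### Reference solver

An independent pressure-Poisson solver provides reference fields where no
closed form exists: the staggered forward-difference gradient operator G
gives the least-squares problem min‖Gp − g‖, whose normal equations are
exactly the 5-point Neumann Poisson discretization of ∇²p = ∇·g with
∂p/∂n = g·n. The singular constant mode is removed by anchoring one node
during the sparse solve (the right-hand side is compatible by
construction) and re-gauging to zero boundary mean. Against the lattice
closed form the solver is accurate to 0.03% RMS of range at 128².

## Surface forces and the pull/push decomposition

The body outline is resampled into segments of equal arc length
(Δs = perimeter/n); outward unit normals come from rotating each chord
tangent by −90°, with orientation fixed against the polygon interior (or,
for open surfaces, against a supplied leeward reference point). The force
per unit depth is F = Σ(−pᵢ n̂ᵢ)Δs and the torque about a pivot
τ = Σ(rᵢ − r₀)×(−pᵢ n̂ᵢ Δs); only pressure is integrated — viscous skin
friction on the surface is out of scope.

Because pressure is undefined inside the dilated mask, each segment
samples the field at midpoint + (probe offset)·min(Δx, Δy)·n̂. The default
probe offset is 3 cells: with the default paddle half-width (0.75 cell)
and 1-cell mask dilation the masked band reaches about 2.2 cells from the
centerline, and a 3-cell probe is the nearest position whose bilinear
stencil is reliably defined. Segments whose probe still lands undefined
inherit the nearest defined segment's value and are flagged; more than
50% undefined raises an error. The offset is config-exposed for
sensitivity checks.

Pull and push partition the thrust-axis force by the *sign of the local
surface pressure*: tᵢ = (−pᵢ n̂ᵢ Δs)·â, pull = Σ{pᵢ<0} tᵢ,
push = Σ{pᵢ>0} tᵢ. The partition is exact (total = pull + push to the
last bit) and matches the physical reading: negative pressure on a
surface element pulls the body toward it. The stroke-averaged ratio
|mean pull|/|mean push| is flagged undefined when the mean push is zero.
Both components are stored as signed thrust-axis values; plotting with
pull as (−) and push as (+) is a display convention applied only in the
figure helpers.

## Bending kinematics

Centerlines are resampled to equal arc-length spacing (the arc coordinate
is measured along the *original* polyline, so total length is preserved
exactly). The bend model is a continuous two-segment piecewise-linear
fit: every interior node with arc fraction in [0.2, 0.9] is tried as the
breakpoint (end segments with fewer points are ill-posed); the points on
each side get a free total-least-squares line; the candidate minimizing
the summed squared perpendicular residual wins, with ties toward the
smaller fraction. Continuity is enforced by placing the vertex at the
intersection of the two fitted lines, whose arc-length position (divided
by L) is the inflexion fraction; the bend angle is the angle between the
base→tip oriented directions. Putting the vertex at the intersection
rather than at a data node removes the node-quantization bias: noiseless
two-segment polylines are recovered to <0.1° and <0.001 in fraction, and
with point noise of 1% of L the mean errors over 100 draws stay well
within 3° and 0.05. The fit is invariant to rigid motions and to
reversing the point order (with the orientation flag). Centerlines whose
single-line residual is below 0.5% of L — below plausible digitization
noise — are declared straight: bend angle 0, fraction flagged unreliable.

The mid-power-stroke frame is the temporal midpoint of the stroke window
(ties toward the earlier frame); the window is either supplied or
detected as the longest monotone run of the base-to-tip orientation
angle. Appendage Reynolds number is Re = U L/ν with U the tip speed by
central differences of digitized tip positions.

## Flow profiles

Offset curves displace each centerline sample by ±δ along the local
normal (central-difference tangents averaged over a 7-point window, so
samples wrap smoothly around the bend). The flowward side is the one
whose mid-arc normal points along the paddle's motion. Offset validity is
judged on the geometric offset curve (round joins): a naive per-point
offset of a polyline with a corner self-intersects at any δ, which is a
discretization artifact, not a geometry failure. The default δ is 4 grid
cells — the nearest distance at which pressure sampling clears the
dilated mask; speed-only profiles can use smaller offsets. Metrics:
peak-flow arc fraction (maximum of |u| over the union of both sides, ties
toward the base), leeward/flowward mean-speed ratio, and
|mean negative leeward pressure| / mean positive flowward pressure with
sign-filtered means (the most direct reading of a leeward-suction /
flowward-push asymmetry). Samples are bilinear; more than 25% undefined
on either side marks the profile unreliable.

## Body masking

Segmentation thresholds on image contrast (Otsu's inter-class-variance
criterion by default, dark-on-bright polarity with an invert flag),
keeps connected regions above a minimum area, and extracts the sub-pixel
boundary of the largest survivor by contouring the grayscale image at the
threshold level (falling back to the binary region boundary). Contours
are smoothed by a circular moving average (window config-exposed;
smoothing that induces self-intersection raises an error suggesting a
smaller window). Masks are rasterized by a node-in-polygon test with
boundary nodes counted inside, then dilated with a 3×3 structuring
element (1 cell by default) to exclude velocimetry vectors contaminated
by the surface. On synthetic ellipse images with noise sd 0.05 the
pipeline recovers area within 0.2% and centroid within 0.04 px — far
inside the 2% / 1 px targets.

## Cohort statistics

`one_way_anova` implements the classical decomposition
F = (SSB/(k−1)) / (SSW/(n−k)) with the p-value from the upper F tail; it
is verified against an independent oracle on 1,000 random designs and its
null rejection rate at α = 0.05 is calibrated on 2,000 simulated
6-species × 3-individual designs (the df = 5, 12 shape). `holm_sidak`
applies the step-down adjustment p̃₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^(m−i+1) with a
running maximum for monotonicity, rejecting while p̃ < α. The source of
raw pairwise p-values is selectable (Welch t, Mann–Whitney, or paired
t / Wilcoxon when paired by individual — paired-by-individual is the
default for side-to-side comparisons on the same animals). Unbalanced
designs warn rather than fail.

## Synthetic scenes: what they emulate, and what they do not

All generators write the same on-disk formats as real data, are
deterministic given a seed, and (at zero noise) are *discretely*
divergence-free: velocity is obtained by central-differencing a
streamfunction sampled on a one-node-padded grid, so the
central-difference divergence vanishes to round-off.

* **Uniform flow** — degenerate benchmark; zero pressure.
* **Decaying vortex lattice** — the doubly periodic decaying-vortex
  solution of the unsteady viscous equations, with closed-form pressure;
  exercises every term in the gradient and both integrators.
* **Line vortex** — Lamb–Oseen azimuthal profile; reference pressure by
  quadrature of the radial momentum balance dp/dr = ρu_θ²/r from the
  domain boundary inward.
* **Bending paddle** — a two-segment centerline (default 27° bend at
  0.59 L, L = 3 mm) sweeping 40° about its base in 48 ms (tip speed
  ≈0.04 m/s, Re ≈ 94 in 10–12 °C seawater: ρ = 1025 kg/m³,
  ν = 1.35×10⁻⁶ m²/s — all config-overridable); a counter-rotating
  Lamb–Oseen pair (Γ = 1.5×10⁻⁴ m²/s, core 0.07 L) anchored just off the
  leeward surface, straddling the bend symmetrically along the bend
  bisector and advected with the paddle; plus a weak entrained-fluid
  cell co-moving with the paddle (windowed streamfunction, velocity
  scale 0.1·L·|θ̇|). Reference pressure comes from the Poisson solver
  applied to the noise-free field (validated first on the lattice closed
  form); optional Gaussian noise is scaled to the peak speed. Masks are
  the thickened centerline (half-width 0.75 cell) rasterized with the
  1-cell dilation.

The paddle scene is a *kinematically prescribed idealization*, not a
fluid–structure simulation. Because the velocity is prescribed, its
momentum residual is not exactly a gradient field; the pair placement and
the weak background were chosen so the residual's rotational part stays
small (eight-path and Poisson reconstructions agree to ≲5% RMS across the
stroke — a strongly inconsistent background drove them 50–90% apart and
moved the global pressure minimum away from the leeward pair, so those
designs were rejected when the scene was built). What passing tests on
this scene show is that the pipeline correctly recovers the pressure
topology and force regime *implied by the flow it is given*: leeward
suction concentrated at the bend (minimum within 0.15 L, leeward side),
leeward speeds above flowward, and a pull-dominated stroke (ratio ≈19,
inside the 2–34 pull/push range reported for real metachronal paddlers).
They do not show that real limb flows look like this scene: real μPIV
data add out-of-plane motion, correlated PIV noise, vector dropouts and
imperfect masks, of which only uncorrelated noise and masking are
emulated.

## Numerical details and degenerate inputs

* Floats are written with shortest-round-trip `repr`; all writer/reader
  pairs are bit-exact, and closure of contours travels in a header flag,
  never as a duplicated point.
* Grid convention: x rightward, y upward, node-centered, 0-based, meters;
  image row 0 is the top of the frame, so image import flips the
  vertical axis and "swimming up" is +y.
* Eight-path details: even-count medians average the central two;
  boundary nodes are their own (zero-length) ray for the direction that
  starts there; a fully masked field or an all-masked boundary raises.
* The Lamb–Oseen streamfunction is regular at the origin
  (ln r² + E₁(r²/r_c²) → ln r_c² − γ); the limit value is substituted
  inside r < 10⁻¹² r_c.
* Duplicate centerline points are dropped before resampling; zero-length
  polylines, empty masks, non-unit thrust axes, empty stroke windows and
  misaligned frame sequences raise typed errors
  (`paddlepress.errors`).
* Pipeline caching is keyed by SHA-256 of inputs and the relevant config
  section, never by timestamps; re-runs are byte-identical and deleting
  any cached stage output reproduces it.

## Problem sizes

The shipped validation uses 32²–128² grids, 9-frame strokes, 100
kinematics draws, 50 segmentation seeds, and 1,000 + 2,000 statistical
designs; the full test suite runs in well under a minute and
`scripts/acceptance.py` in a few seconds on one CPU. Larger grids and
frame counts only tighten the discretization-limited results
(grid-refinement convergence is itself one of the checks).

## Known limitations

* 2D only: no out-of-plane pressure correction; forces are per unit
  depth and sum over a single imaged propulsor, not the whole animal.
* Pressure integration assumes the field-of-view boundary is either far
  field or at least momentum-consistent along its edge; a boundary cut
  through a strongly masked region degrades the loop anchor.
* The two-segment bend model reports a single angle and a single
  inflexion point by design; propulsors with distributed curvature are
  summarized, not resolved.
* Shear forces, deformable-template masking, and tracking beyond
  nearest-centroid association are out of scope.
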