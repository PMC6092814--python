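# Methods

This note documents the models, defaults and numerical choices behind
`swirlwell`, and what its synthetic benchmarks do and do not demonstrate
about real data.

## The swirling-well system

A well of a 6-well plate (radius 17.4 mm, height 10 mm) containing a 2 mm
layer of culture medium (density 1003 kg/m³, dynamic viscosity
0.78 × 10⁻³ Pa·s — note the sign of the exponent: 0.78 × 10³ Pa·s, a value
sometimes quoted, is physically impossible for an aqueous medium) is
orbited horizontally with a 5 mm orbital radius at 150 rpm
(ω = 15.71 rad/s, period T = 0.4 s).  In the co-moving frame of the well
the orbit appears as a rotating horizontal body force

    a(t) = [A ω² cos(ωt),  A ω² sin(ωt),  −9.81]   (m/s², A in metres)

whose horizontal magnitude A ω² ≈ 1.23 m/s² is constant in time.
Convention, used in all file outputs: right-handed coordinates, origin at
the well centre, θ counter-clockwise from +x, orbit phase advancing
counter-clockwise.  The rotation sense of the physical shaker is not
constrained by any quantity computed here; all metrics are invariant to
reflecting the orbit.

Cells are seeded either in a centre disc (r ≤ 10.5 mm) or an edge annulus
(13.5 mm ≤ r ≤ 17.4 mm).  These radii make the two areas nearly equal
(346 vs 379 mm²; relative difference 9.3% with the disc as denominator,
8.5% with the annulus, 8.9% with the mean — the convention is recorded in
the output).

## Shear metrics

TAWSS, OSI and transWSS are computed from the instantaneous WSS vectors of
exactly one forcing cycle.  Numerical choices:

* **Quadrature** — trapezoidal rule with periodic closure.  Series sampled
  half-open (t = 0 … T−Δt) are closed by re-using the first sample; series
  longer than one period are windowed to the final full period.
  For smooth waveforms the error is O(Δt²): at 64 samples/cycle the
  rotating-vector transWSS is accurate to ~8 × 10⁻⁴ relative, and the test
  suite checks agreement with a 10⁵-sample Riemann oracle to < 10⁻³.
* **τz** — included in the magnitude |τ| = √(τx²+τy²+τz²) as the metric
  definitions are usually written, although a true wall shear has no
  wall-normal traction; on the base τz ≈ 0 and the inclusion is inert.
* **Degenerate mean** — transWSS projects onto n × τ_mean/|τ_mean|, which
  is undefined for zero-mean (e.g. perfectly rotating) shear.  When
  |τ_mean| < 10⁻⁶ × TAWSS, the reference direction falls back to the
  principal eigenvector of the in-plane second-moment matrix of the
  vectors; if that matrix is isotropic (rotating flow) an arbitrary fixed
  axis is used — the integral of |τ·ê| is then axis-independent — and the
  point is flagged `degenerate_mean`.
* **Bounds** — 0 ≤ OSI ≤ 0.5 and 0 ≤ transWSS ≤ TAWSS are enforced up to
  round-off (tiny overshoots are clipped).

## Flow models

**Surrogate field** (the quantitative workhorse).  The local waveform in
the (radial, circumferential) basis with suppression s(r) and phase
ψ = ωt − θ is

    w_r = (1−s) cos ψ,    w_θ = (1−s) sin ψ + s (1 + a sin ψ)

— the unit rotating vector where s = 0 and a non-reversing fluctuating
circumferential vector where s = 1.  Each point's waveform is rescaled so
its cycle-mean magnitude equals M(r), a smoothstep between the centre and
edge magnitudes; TAWSS(r) = M(r) by construction, OSI falls monotonically
from 0.5 at r = 0, and the whole pattern advances in phase with the orbit.
Defaults: centre 0.3 Pa, edge 0.6 Pa (the LMMF/HMUF magnitudes typical of
this configuration), fluctuation amplitude a = 0.5, suppression smoothstep
0 → 1, 64 samples/cycle (the polar-plot sampling of such data, ~10 ms at
150 rpm, is ≈ 40/cycle; 64 gives quadrature headroom).  The smoothstep
magnitude profile is a deliberate minimal choice: only the monotone
centre-to-edge increase is empirically constrained, not its shape.

**Coarse solver** (qualitative).  A strict rigid-flat-lid model admits the
exact solution u ≡ 0 — a uniform horizontal body force in a closed rigid
container is balanced identically by pressure — so base shear requires the
free-surface response.  The coarse solver keeps exactly that physics:
linearized depth-averaged shallow-water equations on a staggered grid
masked to the circular well (no-penetration walls), forced by the rotating
body force, with an oscillatory Stokes-layer closure for the base stress
(τ = ρ√(νω) U, and the matching bottom friction √(νω)/h).  The first
azimuthal sloshing mode of the 2 mm layer (≈ 14.9 rad/s) lies close to the
150 rpm forcing, so the model reproduces the near-resonant swirl that
makes orbital shakers effective, converging to a periodic limit cycle
monitored through the cycle-max base WSS (tolerance 1% per cycle;
halving the grid spacing moves the converged cycle-max by ~2%).  Its
limits are equally clear: the depth-averaged rotating response yields
OSI ≈ 0.5 at every radius and a TAWSS profile peaking at the *centre*,
whereas resolved free-surface CFD of this system shows higher, nearly
uniaxial shear at the edge.  Capturing that contrast requires the 3-D
free-surface physics (wave shape, vertical structure, nonlinearity) that
this desk-scale model deliberately omits — which is why the surrogate
field, not the solver, encodes the edge/centre structure used everywhere
else.  The solver rejects time steps violating the gravity-wave CFL limit
and reports the smallest stable samples-per-cycle.

## Nuclear morphometry

* **Segmentation** — global Otsu threshold (original analysis thresholds
  for such data are typically unpublished; an absolute override is
  accepted), floored at the robust background level + 5 median-based
  sigmas so that images with few or no objects do not have their noise
  split; connected components filtered to 20–500 µm² (typical nuclear
  areas).  An optional distance-transform watershed can split touching
  nuclei; it is off by default.
* **Ellipse fit** — moment-equivalent ellipse (semi-axes 2√eigenvalue of
  the pixel covariance, + 1/12 px² footprint correction); regions under
  5 px or collinear are excluded.  Before fitting, each nucleus is
  re-thresholded at half its (95th-percentile) peak above background:
  for a blurred object the half-maximum contour tracks the true boundary,
  removing most of the dilation bias of the global threshold (binned axis
  ratios recover generator truth to ~1%).
* **Shape index** — SI = 4πA/P² with A and P of the *fitted ellipse*
  (area πab; perimeter 4aE(1−b²/a²) by the complete elliptic integral,
  Ramanujan-II only as a degenerate-input fallback).  SI is scale
  invariant and equals 1 for a circle.
* **Signed radial orientation** — the axial angle in (−90°, +90°] between
  the long axis and the centre-to-centroid reference vector, positive when
  the nucleus end nearest the well centre lies to the *right* of that
  vector.  Image arrays are y-down; the sign is evaluated in the physical
  (y-up) frame.  With the axis angle φ and the reference angle ψ both in
  the physical frame the signed orientation is simply φ − ψ wrapped to
  (−90°, 90°].  Ties: exactly circumferential nuclei report +90°, exactly
  radial ones 0°.  A centroid coinciding with the well centre is flagged
  undefined.
* **Radial binning** — half-open 1 mm bins [k, k+1), the last closed at
  the wall; densities divide by the imaged (centroid-admissible) area per
  bin, and empty or zero-area bins are reported missing, not zero.  The
  modal orientation of a bin is the doubled-angle axial mean.  SEM across
  independent wells is computed from per-well means
  (`aggregate_profiles`); the per-well SEM over nuclei is also reported.
* **Orientation-vs-radius summaries** — least-squares degree-7 polynomial
  through the per-bin means with the per-bin SEM band; the degree is
  reduced (with a warning) when fewer than degree+2 bins are populated.

## Adhesion assay

THP-1 spots are counted with the same intensity/area operator as nuclei
with a 10–200 µm² window.  The THP-1:HUVEC ratio is computed from counts
pooled per well by default (a per-field option exists; with equal field
sizes the two differ only in weighting), then summarized as mean ± SEM
across wells per (region × treatment × segmentation) condition.  A single
well reports SEM as missing.  Hypothesis testing is intentionally not
included: the module emits tidy per-well tables for any stats package.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis assumes:
nucleus density and elongation rising centre → edge, circumferential
alignment where shear is uniaxial, isotropy at the centre, a second
channel of adhered-monocyte spots with region- and condition-dependent
ratios, z-stacks where only the maximum projection recovers every nucleus,
and analytic WSS waveforms with known metrics.  Defaults (chosen once as
realistic orders of magnitude for a confluent sheared HUVEC monolayer;
effect sizes in published figures of such experiments are graphical only):
density 300 → 600 cells/mm², axis ratio 1.05 → 2.5 (area-preserving,
120 µm² nuclei), orientation mean 90° with wrapped-normal concentration
κ: 0 → 8 (σ = 1/√κ; κ = 0 is uniform — orientations are axial, not
directional), SNR 20 (peak over background σ = √(background + read²),
Poisson shot + Gaussian read noise), 0.65 µm/px, hard-core gap 4 µm,
adhesion base ratios centre 0.12 / edge 0.04, TNF-α multiplier 3,
centre-only segmentation effect ×1.5 under TNF-α.

Placement is an inhomogeneous Poisson process with hard-core
non-overlap, *stratified in narrow radial bands*: each band's count is an
exact Poisson draw and collisions are re-drawn within the band, so binned
densities are unbiased at any feasible packing fraction; infeasible
densities are rejected with a packing estimate.  Radial profiles are
rendered as centre-to-edge strip images (the tile-scan geometry; a full
17.4 mm disc at 0.65 µm/px would be ~2.9 Gpx), full discs being available
for small wells.  Identical seeds give bit-identical images and truth
tables.

What passing these benchmarks shows: the pipeline recovers known density,
elongation and orientation structure essentially exactly at SNR ≥ 10 with
non-overlapping nuclei, and detects a configured centre-only adhesion
effect at its true size.  What it does not show: robustness to confluent
*touching* nuclei, debris, uneven illumination, stitching artifacts or
focus drift — real images fail in ways the generator does not emulate, and
thresholds/area windows should be revisited per dataset.

## Problem sizes

The test suite runs the full pipeline on ten synthetic strip wells
(strip height 0.7 mm, ~5 × 10³ nuclei per well) and 240 adhesion fields
(512 px, ten per region per well, six wells per arm); the coarse solver
runs 14 cycles at nx = 48. These sizes give per-bin SEMs of a few percent,
comfortably inside the recovery tolerances, while keeping the whole suite
desk-scale.
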