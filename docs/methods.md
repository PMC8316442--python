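# Methods

`jamscope` quantifies collective epithelial dynamics the way the
monolayer-jamming literature does: velocity fields from particle image
velocimetry (PIV) on phase-contrast time-lapse movies, grid-seeded
trajectories integrated through those fields, mean-squared displacement
(MSD), the self-overlap order parameter Q, the instantaneous
root-mean-squared speed V_RMS, and per-cell shape morphometry compared
against the vertex-model jamming threshold.  Because this kind of raw
movie data is rarely shareable, the package also contains a synthetic
monolayer generator whose ground truth makes every downstream stage
testable.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data does and does not show
about real tissue.

## Synthetic monolayer model

Cells are overdamped **active Brownian disks with soft harmonic
repulsion** in a square periodic box.  Per Euler–Maruyama step `dt`:

    dr_i     = v0 dt (cos θ_i, sin θ_i) + dt Σ_j k (2R − |r_ij|) r̂_ij   (|r_ij| < 2R)
    dθ_i     = sqrt(2 D_r dt) ξ,   ξ ~ N(0, 1)

Mobility is absorbed into the stiffness `k` (units 1/min: a 1 µm overlap
produces a 1 µm/min push).  A single free cell obeys the closed form

    MSD(t) = (2 v0² / D_r²) (D_r t − 1 + e^(−D_r t)),

ballistic below the persistence time 1/D_r and diffusive above it; the
test suite uses this as an independent oracle for the integrator.

This is deliberately *not* a vertex or self-propelled-Voronoi model: no
T1 topology dynamics, no cell division or differentiation, no junctional
tension.  It is the simplest model in which one knob (`v0`) moves the
layer between caged, near-crystalline dynamics and a flowing, disordered
liquid — the two regimes the measurement pipeline must tell apart.

Defaults (chosen once, as representative imaging conditions): 320 cells
of radius 12 µm in a 400 µm box (packing fraction 0.90, ≈ 300 cells per
field of view at 40×-like calibration), frames every 5 min for 200 min,
`k = 1/min`, `dt = 0.5 min` with the stability guard
`dt ≤ cell_radius / (10 v0)`.  Initial positions are a jittered hexagonal
lattice (5% of the spacing), which realises confluent packing without
rejection sampling; densities above the hexagonal disk-packing bound
(π/(2√3) ≈ 0.907) raise a packing error unless repulsion is disabled.

A `collective_headings` mode makes all cells share one diffusing
polarity — the plug-flow limit of collective migration.  Its single-cell
MSD still follows the closed form above, but the motion is spatially
coherent, which matters for end-to-end validation (below).

## Rendering

Frames are rasterised at 0.75488 µm/px (the calibration constant of the
targeted acquisition setup), 512×512 px by default, as an interior crop
of the periodic box so PIV never sees wrap seams.  Each cell is painted
as a **soft-edged disk of its physical radius filled with frozen
high-contrast speckle** (seeded per cell, constant over time, stamped at
subpixel positions with cubic interpolation), plus per-frame Gaussian
sensor noise.  Two rendering choices are load-bearing for velocimetry
and were made for that reason:

* speckle correlation length ≈ 0.8 px and contrast ≈ 40% of amplitude:
  if the texture is too smooth, the circular-correlation peak is set by
  the slowly varying cell envelope and small displacements become
  ambiguous (the wrap-around penalty of circular correlation exceeds the
  autocorrelation decay per pixel);
* cubic (not linear) interpolation for fractional-pixel stamping, which
  preserves the speckle spectrum and keeps peak-locking bias small.

Label masks come from the **periodic Voronoi tessellation** of the cell
centres (nearest-centre rasterisation under the periodic metric),
space-filling with no background by default; an option draws ≈ 1-px
zero-valued boundary lines.  Morphometry masks can be rasterised at a
finer pixel size than the movie so cells are ~100 px across, inside the
perimeter estimator's unbiased regime.

## Velocimetry

Standard two-pass PIV: 64×64 px interrogation windows at 50% overlap,
validated, bilinearly interpolated onto the 32×32 px grid as window-offset
predictors for the second pass.  Correlation is mean-subtracted circular
cross-correlation without zero padding (windows are texture-filled);
sub-pixel refinement is the 3-point Gaussian fit per axis, falling back
to a parabolic fit when a neighbour sample is non-positive.  Constant
windows yield invalid vectors, not exceptions.  Near image borders the
predictor offset is split between the two frames' windows so edge tiles
keep the full predictor benefit.  Displacement sign convention: motion of
frame b relative to frame a, +x along columns, +y along rows, origin
top-left.

Validation is the normalized median test against the 8-neighbourhood
(ε = 0.1 px, threshold 2.0 — the source workflows do not state their
settings, so these common defaults are fixed here and logged); flagged
vectors are replaced by the neighbourhood median.  A field with fewer
than 80% originally-valid vectors is marked low quality and surfaces as
a warning (CLI exit code 3), never a silent drop.  Calibration is
`pixel_size / frame_interval` (px/frame → µm/min).

Measured on rendered fixtures: integer circular shifts recover to
< 0.05 px; spectral sub-pixel shifts to < 0.2 px; a 1 px/frame drift
movie calibrates to 0.1510 µm/min within 2% on every vector; a static
movie stays below 0.02 µm/min.

## Trajectories and statistics

Tracers are seeded on the final PIV grid (one per independent velocity
estimate) and advanced by explicit Euler with bilinear velocity
interpolation; tracers leaving the gridded region are frozen, flagged,
and excluded from statistics thereafter (fields of view are bounded, so
wrap-around would be fiction).  The statistics:

* `MSD(Δt) = ⟨|r_i(t+Δt) − r_i(t)|²⟩`, averaged over tracks and, by
  default, sliding time origins ("zero"-origin mode is kept for strict
  replication; the source workflows do not say which they used).
* `Q(Δt) = N⁻¹ Σ_i w_i` with `w_i = 1` iff `|r_i(t+Δt) − r_i(t)| < d_c`.
  The indicator is not spelled out in the source workflows; the
  displacement-below-cutoff form used throughout the self-overlap
  literature is the only reading consistent with Q ∈ [0, 1], and is what
  is implemented.  `d_c` defaults to one final-pass PIV grid spacing in
  µm (≈ 12.1 µm at default calibration) and is exposed everywhere.
* `V_RMS(t) = sqrt(M⁻¹ Σ_j |v_j(t)|²)` over the M valid grid vectors of
  one field; fields with no valid vectors report NaN with a warning.

**What end-to-end recovery does and does not show.**  PIV fields are
coarse-grained over ~24 µm windows, and grid-seeded tracers therefore
measure *collective* displacement.  For spatially coherent motion
(uniform drift; the `collective_headings` mode) the pipeline reproduces
ground-truth MSD to within a few percent.  For spatially *uncorrelated*
single-cell motion at confluent density, the coarse-grained MSD
systematically underestimates the single-cell MSD (by roughly 2× in our
fixtures) — an inherent property of field-based tracking, not a bug.
Real unjammed epithelia move in swirls with correlation lengths well
above the window size, which is the regime where this measurement chain
is meaningful.

## Morphometry and the jamming call

Per label: area = pixel count · pixel_size²; aspect ratio from the
second-moment best-fit ellipse; shape index q = perimeter / √area.  The
perimeter is a **multi-directional Crofton estimator** written for this
package: the indicator is lightly smoothed, rotated to 16 directions in
[0, π), and 0.5-level crossings are counted along scan lines at 0.5 px
effective spacing; P = (π/2)·⟨intercepts⟩·spacing.  The smoothing scale
grows with the object (max(0.8, 0.007 √area) px), which makes the
estimator scale-invariant under resampling; scan-line oversampling
averages subpixel alignment jitter.  Rationale: naive boundary-pixel
counting overestimates perimeters by 5–10% (a disk measures as ~4/π too
long), and few-direction Crofton approximations bias axis-aligned edges
by several percent — either error would systematically distort q at the
jamming threshold.  Reference shapes pin the estimator within 1%:
square q = 4.000, regular hexagon q = 3.722, disk q = 2√π ≈ 3.545.
Small or sliver objects (≲ 20 px across) are below the estimator's
reliable regime; labels under 9 px are excluded with a warning.

Border-touching cells are flagged and excluded by default (truncation
biases q upward).  The jamming call compares mean q with the threshold
p₀ (default 3.813; the value is also printed as 3.81 in some summaries
of the vertex-model literature, and the parameter is exposed): strictly
below ⇒ jammed, ties ⇒ unjammed (at the critical point the tissue is
marginally rigid; the call errs on the motile side).  Whether mean q
should be pooled over all cells or averaged per field first is a
reporting choice; the table output supports both aggregations.

Segmentation of membrane/F-actin images is a seeded watershed on the
smoothed signal (seeds = supplied nuclei points, else regional minima
after h-minima suppression at 10% of the intensity range).  It is a
pragmatic stand-in for interactive segmentation tools; masks from any
tool are accepted as first-class input.

## Assays

Exactly specified arithmetic: TEER = (raw − 100 Ω) · 0.33 cm², replicates
averaged; readings below the blank stay negative and **flagged** (never
clipped — the audit trail of suspect wells is preserved).  Fluorescence
per cell = field mean gray value / cell count; positive fraction =
positive count / total count.  Elastic modulus from rubber elasticity,
E = 2(1 + ν)G′; at ν = 0.5 (incompressible hydrogel) E = 3G′, which is
why a G′ = 1 kPa gel is called a "3 kPa" substrate.

## Benchmark and problem sizes

The end-to-end benchmark contrasts two conditions differing only in
motility: `v0 = 0.1 µm/min, D_r = 0.05/min` (caged, near-crystalline)
versus `v0 = 4 µm/min, D_r = 0.1/min, dt = 0.25 min` (flowing,
disordered; time-averaged speeds ~0.5–2 µm/min, in the range reported
for unjammed epithelia).  Both run the complete chain on 41-frame,
200-min movies; morphometry masks are rasterised at 0.25 µm/px so cells
are ~100 px across.  The low-motility arm must be called jammed and the
high-motility arm unjammed, with strictly larger terminal MSD and lower
terminal Q in the fast arm.  Typical outcomes: mean q ≈ 3.73 vs ≈ 3.86,
V_RMS ≈ 0.03 vs ≈ 1.7–2 µm/min, terminal Q ≈ 1.0 vs ≈ 0.04.

Problem sizes throughout (500-cell oracle ensembles, 41-frame movies,
24 shift fixtures, 3 benchmark seeds) were chosen so the entire
validation runs comfortably on a laptop-class single core while keeping
sampling error well inside each stated tolerance.

## Known limitations

* The simulator produces isotropic disks; Voronoi shape disorder is the
  only source of cell elongation, so aspect ratios are milder than in
  elongated real unjammed cells.
* No T1-resolved tissue rheology: the jammed/unjammed contrast is
  emergent from packing and motility, not from junctional mechanics.
* PIV-based trajectories cannot recover spatially uncorrelated
  single-cell motion (see above); nuclei tracking would be required.
* The watershed segmenter is not a replacement for curated interactive
  segmentation on hard images; it is validated on synthetic boundary
  images and simple fixtures.
* All randomness flows through named integer seeds; re-runs are
  bit-identical on the same platform, but floating-point determinism
  across BLAS/OS variants is not guaranteed.
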