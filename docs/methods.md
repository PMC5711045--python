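# Methods

## The physical picture

A linac on-board imager acquires cone-beam projections over 30–60 s while
the couch is stationary. Respiratory motion moves thoracic targets along
the superior–inferior (SI) axis through several full cycles per scan, so
the reconstruction images the *time-averaged* target. For a rigid target of
stationary SI length L₀ this yields two closed-form apparent lengths:

* constant speed V_P in view for time T: `L = L0 + Vp*T`;
* sinusoidal motion `Z(t) = Zo + A sin(2*pi*f*t + phi)` with the scan
  longer than one period: every target voxel sweeps the full excursion
  (−A, A), so the maximal apparent length is `L_max = L0 + 2A`, independent
  of f and phi. The instantaneous form `L(t) = L0 + [wA cos(wt+phi)]*t` is
  exposed unclamped for inspection only — it is unbounded in t, and all
  pipeline comparisons anchor on `L0 + 2A` (cyclic) or `L0 + Vp*T`
  (constant speed).

The simulator verifies these laws by running the whole imaging chain on
synthetic data and measuring apparent lengths from the reconstructions.

## Digital phantom

Three water-equivalent cuboid targets sit in a lung-equivalent foam slab
between solid-water slabs (stacked along the anterior–posterior axis):

| target | x × y × z extent (mm) | center (mm) | L₀ (mm) |
| --- | --- | --- | --- |
| small | 50 × 30 × 10 | (50, 12, 50) | 10 |
| medium | 50 × 30 × 20 | (50, −12, −50) | 20 |
| large | 50 × 30 × 40 | (−45, 0, 0) | 40 |

Attenuations (1/mm): targets and solid water 0.020, foam 0.005, air 0 —
strong target/foam contrast, no spectral physics (kVp/mAs are metadata).
The grid is 96³ at 2 mm isotropic; 2 mm is both the voxel size and the
nominal slice thickness, and it bounds the length-measurement resolution.

Placement rationale: all three targets are laterally offset from the
rotation axis so they stay fully inside both fan geometries at the largest
ROM (40 mm), and they are separated in x *and* y so that no target's
measurement column crosses another target — or the in-plane streaks a
large moving structure throws — even when maximally blurred. The foam/slab
stack spans the whole grid along z (a "long object", as real anatomy
extends beyond the axial field of view): axial profiles then have a
uniform foam baseline, and no artificial phantom end moves through the
image. The projector implements this by edge-clamping its z sampling; the
occupancy blur uses nearest-edge extension for the same reason.

Voxelization is center-sampling on half-open boxes (deterministic,
bit-reproducible); a `supersample` factor averages sub-voxel samples when
smoother boundaries are wanted. Worst-case voxelization error of any
extent is one voxel and halves when the grid is refined twofold.

## Motion

The platform moves rigidly along z; every voxel shares one trajectory.
Default frequency 0.25 Hz (15 cycles/min, period 4 s). Sweeps draw the
phase from a seeded uniform [0, 2π) because the phase is uncontrolled in
the workflow this mirrors; within `run_rom_sweep` one phase is drawn per
ROM and shared between scan modes, so the half-fan/full-fan comparison
sees identical motion.

The time-occupancy (dwell) density of the sinusoid is the arcsine law
`p(u) = 1/(pi*sqrt(A^2 - u^2))` on (−A, A). It is discretized by
integrating the exact CDF over voxel-wide bins — this matches the
histogram of uniformly time-sampled displacements (the independent oracle
in the tests) and conserves mass to machine precision.

## Acquisition and reconstruction

Geometry mimics a generic on-board imager at desk scale: SAD 1000 mm,
SDD 1500 mm, 128×128 flat panel at 3 mm pitch. Protocols:

* **half-fan** — 360° arc, 60 s, 360 projections, panel shifted 143 mm
  laterally (enlarged field of view);
* **full-fan** — 200° short-scan arc, 30 s, 200 projections, centered
  panel.

`desk_scale()` halves the projection counts; all study results here use
the desk-scale presets. The projector marches each source→pixel ray at
half the voxel spacing with trilinear interpolation; motion enters as a
z-shift of the sampling grid per projection timestamp — exact for rigid
1-D translation. Poisson noise (transmission domain, re-logged) is
available but off by default: the elongation analysis is geometric.

FDK reconstruction: detector coordinates are rescaled to a virtual panel
through the isocenter; cosine pre-weighting, then angular redundancy
weights — Parker weights for the short scan (effective half fan angle
taken from the arc itself), a raised-cosine displaced-detector ramp for
the half-fan full circle (conjugate weights sum to one; the duplicated
closing direction of the 360° schedule is half-weighted) — then a
zero-padded Ram-Lak ramp filter per row (optional Hann apodization), and
voxel-driven backprojection with inverse-square distance weighting. No
motion correction anywhere: the artifact under study must be preserved.

The **occupancy-blur surrogate** is the long-scan limit in closed form:
convolve the static volume along z with the dwell density. It bypasses
projection physics, is exact about the support arithmetic
(support dilates by exactly [−A, A]), and runs in milliseconds. The test
suite cross-validates the two routes: lengths from FDK of the moving
acquisition agree with lengths from the blurred static FDK reconstruction
within one slice thickness once the scan covers ≥ 3 periods.

## Length measurement

The measurement emulates reading target extents off coronal views with the
display window opened until the faint smeared ends are visible:

1. average the z-profile over in-plane columns at the target's static
   position — either a (2h+1)² patch or, for the experiment routes, the
   target's full in-plane **footprint** (streak-like reconstruction
   artifacts alternate sign across the footprint and cancel; the target
   signal does not);
2. background = median of the profile's outer tails; plateau = profile
   maximum; threshold level = background + fraction × (plateau −
   background);
3. length = distance between the sub-voxel linear-interpolation crossings
   that bound the **connected above-level region containing the profile
   peak**. Growing from the peak, rather than taking outermost crossings,
   is the automated analogue of outlining *the* visible target: real FDK
   volumes carry ~10 %-of-contrast baseline structure (cone shadows,
   motion streaks), and an outermost rule latches onto any detached shelf
   in the 190 mm profile. For clean unimodal profiles the two rules
   coincide, as all closed-form cases do.

Flags mark unmeasurable (low-contrast) and edge-clipped profiles.

Threshold fractions. The arcsine density piles intensity at the excursion
extremes, while the level halfway up the edge-spread sits near the
*static* boundary — FWHM on a strongly blurred flat-topped target recovers
≈ L₀, not L₀ + 2A. The support is tracked by a low fraction. Defaults:

* **0.5** (`measure_length` default) — FWHM, unbiased for sharp/static
  targets;
* **0.08** (surrogate route) — minimizes the worst-case closed-form bias
  over the study's L₀ × ROM grid at 2 mm sampling, balancing the outward
  chord-interpolation error at sharp edges (≈ 2 − 4·fraction mm) against
  arcsine support shrinkage (≈ 2A(1 − cos π·fraction) mm);
* **0.15** (FDK route) — high enough that the crossing search clears
  reconstruction baseline artifacts; the induced shrinkage is common mode
  in the mode/frequency/phase comparisons made on that route.

`sweep_thresholds` ships the sensitivity analysis for this choice.

## What the tests do and do not show

The suite verifies, at desk scale (96³ grid, 2 mm slices, halved
projection counts):

* static targets are recovered within 2 mm through the full
  build → project → FDK → measure chain (in practice within ≈ 0.1 mm);
* surrogate-measured lengths match L₀ + ROM within one slice thickness
  over ROM 0–40 mm, with regression slope within [0.9, 1.1] per target;
* measured maximal lengths vary by ≤ 2 mm across breathing frequencies
  {0.2, 0.25, 1/3} Hz and phases {0, π/2, π} at A = 15 mm;
* half-fan and full-fan lengths for identical motion agree within 2 mm at
  every ROM;
* the projector matches a 0.05 mm brute-force ray sum to 0.5 %, the ramp
  filter's impulse response is the band-limited kernel, the blur conserves
  mass and dilates supports by exactly 2A, and velocity is the derivative
  of displacement.

The generator emulates the *geometry* of the problem, not full CBCT
physics: monochromatic line integrals, no scatter, beam hardening, bow-tie
filtration, detector lag or gantry flex, rigid 1-D motion only,
homogeneous targets, and a phantom whose only moving z-structure is the
targets. Passing tests therefore validate the elongation model and its
measurement under ideal-but-complete tomographic imaging of a moving
object; they do not bound the behavior of any particular clinical scanner.
A specific honest artifact of the idealization: with the half-fan 60 s
scan at exactly 0.25 Hz, conjugate rays are sampled exactly half a cycle
apart (15.0 cycles per rotation), a resonance a real scan would miss by
jitter; the footprint averaging and the 0.15 fraction keep length readings
stable through it.

## Numerical choices and degenerate inputs

* Ray-march step: spacing/2 (midpoint rule); rays outside the x/y hull
  contribute zero.
* Ramp filtering via FFT with power-of-two zero padding; the returned
  'same' window is scaled by the pitch so it approximates the continuous
  filtered projection.
* Short-scan reconstruction requires arc ≥ 180° + fan angle (error
  otherwise); half-fan reconstruction requires a full circle.
* A = 0 motion is the identity everywhere (delta dwell density, blur is a
  copy, projector reduces bit-exactly to the static path).
* `length_max_cyclic` warns (but still evaluates) when told the scan is
  shorter than one period.
* Tie-breaking: voxelization uses half-open [lo, hi) boxes; the profile
  peak takes the first maximum; sub-voxel crossings interpolate linearly
  between the bracketing samples.

## Limitations

* The elongation laws assume the target stays inside the imaging view for
  the whole scan; the in-view check only warns.
* Measured lengths are quoted with the slice thickness (2 mm) as their
  resolution; sub-voxel digits are not physically meaningful.
* The constant-speed law is validated at one operating point by
  simulation (`simulate_constant_speed_length`); its full curve is
  analytic.
* A centrally placed target in half-fan mode (partially imaged in some
  projections) produces artifacts outside this model's scope; the default
  layout keeps targets off-axis.
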