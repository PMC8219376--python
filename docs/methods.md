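# Methods

## Scalar diffraction model

All propagation is monochromatic, paraxial and scalar. Fields are square
`N×N` complex arrays sampled at pixel centres with an explicit physical
pitch; the optical axis is at index `(N/2, N/2)` and the row index
increases downward. Two primitives cover everything the two architectures
need:

* **Lens (Fraunhofer) transform.** A centred, orthonormal FFT
  (shift–transform–shift) with the output pitch set by the lens scaling
  `Δ_out = λf / (N·Δ_in)`. Orthonormality makes Parseval exact, so energy
  bookkeeping is an assertion rather than a convention, and the inverse
  transform is the exact numerical inverse.
* **Fresnel propagation** over distance `z`, in two regimes split at the
  critical distance `z_crit = N·Δx²/λ`. At or below `z_crit` the
  transfer-function (convolutional) method multiplies the spectrum by the
  unimodular kernel `exp(−iπλz(f_x²+f_y²))`; the grid and energy are
  preserved. Above `z_crit` the quadratic-phase (single-transform) method
  is used, rescaling the pitch to `λz/(N·Δx)`. The `1/i` prefactor of the
  Fresnel integral is kept as a global `−i` so the two branches agree in
  phase; at `z = z_crit` they are the same discrete operator to machine
  precision. The piston `exp(ikz)` is dropped in both.

Backward propagation applies the conjugated kernels, so
`backward(forward(E))` is exact — the property the round-trip calibration
and the corrected retrieval rely on. Automatic regime dispatch uses the
input grid's `z_crit`; inverting a quadratic-phase step requires an
explicit `method="single_ft"` override because, seen from the coarse
far-plane grid, the step distance always lies below that grid's critical
distance and the two regimes cannot be told apart. A sampling guard raises
(rather than aliasing silently) if the quadratic-phase branch would produce
a far-plane pitch finer than the near-plane pitch.

Negative axial offsets propagate backward by `|dz|`; for the convolutional
branch this is identical to propagation over a negative distance.

## Study scenes (the synthetic data)

The instruments are simulated on **matched-pitch grids**,
`Δx = sqrt(λf/N)`, so the Fourier-plane pitch equals the native pitch.
This is the same condition under which a short-focal-length build could use
identical sensors at both planes (for a 2464² array of 1.12 µm pixels at
632.8 nm it gives f = 4.9 mm), and it keeps `z_crit = f`, so axial offsets
up to 50% of f stay within the convolutional regime. Defaults: 4f system
f = 100 mm, N = 512 (acceptance) or 256 (tests); plate system f = 10 mm,
N = 256, object-to-plate distance d = 1 mm.

**Two-sensor (4f) scene.** A two-level phase digit (step π/2, the packaged
"five" mask) band-limited by a 2 px Gaussian blur, inside a hard-edged
illumination disc of radius 0.2 of the array side. Both features matter
for retrieval, not just realism: the finite beam keeps the field's
autocorrelation inside the grid (otherwise the sampled Fourier magnitude
aliases and GS stagnates around MSE ≈ 0.4) and provides the amplitude
support that phase retrieval needs; pixel-sharp phase steps would put
target energy beyond the simulated sensor band. With a uniform-amplitude
object every circular translate satisfies both intensity constraints, so
retrieval is only defined up to translation — the finite beam removes
that degeneracy.

**Single-sensor (plate) scene.** The multi-level crest glyph (levels 0,
π/3, 2π/3, π; 2 px edge blur) under uniform illumination, plus fine
surface roughness: 0.07 rad RMS of phase noise confined to spatial
frequencies beyond 0.375·N — outside the recovery band and outside the
first- and second-order spectral replicas introduced by plate-pixel
quantisation. The roughness emulates the fine texture of a physical
printed target, and it sets the resolution-constrained recovery floor at a
realistic level (≈5×10⁻³): a perfectly band-limited synthetic target has a
floor two orders lower, which would make relative comparisons between
plate variants (the "within 2× of baseline" criteria) meaningless tests of
numerical noise. Quantisation crosstalk adds a roughly constant ≈4×10⁻³
regardless of the target, so the floor must sit at or above that scale for
ratios to reflect the physics.

**Axial-misalignment scene (plate).** A compact sharp-edged crest
(glyph scale 0.13) inside a narrow beam (radius 0.08 of the side). An
unmodelled axial sensor offset `dz` multiplies the recovered plate-plane
field by the defocus chirp `exp(−iπ·dz·r²/(λf²))`, whose local spatial
frequency grows linearly with radius: at matched pitch the chirp shift in
replay pixels at radius r is `(dz/f)·(r/Δx)` — independent of f. The
tolerance to sensor offset is therefore a function of the object's extent,
not of the focal length; the compact scene keeps the chirp representable
within the resolution window at offsets up to 0.5 f, which is the regime
in which the single-sensor architecture is robust. For larger objects the
tolerance shrinks correspondingly.

What the scenes do **not** model: sensor noise and quantisation of the
detected intensity (16-bit I/O is provided but studies run on exact
intensities), partially coherent or broadband illumination, lens
aberrations, reflections, and the physical substrate of the birefringent
target (its retardance and polariser angles are free parameters). Passing
studies therefore demonstrate algorithmic robustness to the modelled
geometric and fabrication errors, not end-to-end performance on real
captures.

## Retrieval algorithms

**Plain GS (two sensors).** Alternating amplitude projections between the
4f and 2f planes (one lens transform apart), zero initial phase by default
(deterministic; seeded-random optional). The tracked sensor-amplitude
error at the 4f plane is non-increasing. Stopping: relative error change
below `tolerance` (default 1e-6) or `max_iterations` (default 200).

**Misalignment-corrected GS.** The calibrated Fresnel steps are inserted
between each nominal plane and its sensor, with the assumed distance dz′
following a hold–ramp–hold schedule: 0 for the first 40% of iterations
(plain GS converges first), then linear growth to the true dz over the
next 30%, then held. A ramp starting at iteration 1 is bistable against
the conjugate-twin attractor (observed MSE 0.12 vs 0.002 depending on
schedule); letting the well-conditioned Fourier-pair problem converge
before switching on the Fresnel constraint is robust. With dz = 0 the
procedure reduces bit-for-bit to plain GS. The returned estimate is the
final sensor projection propagated back to the nominal 4f plane.

**Round-trip calibration.** For a known calibration field at the 4f plane
(the image of a pinhole): propagate to the 4f sensor with the candidate
offset, replace the amplitude with the measurement, propagate back;
transform to the 2f plane and repeat with the second candidate; transform
back and sum the squared error against the input. At the true offsets
every amplitude replacement is a no-op and the error vanishes exactly.
The search runs over dz ≥ 0 — the ±dz cases differ only by a global
parabolic phase and are degenerate. Because the fine-sampled ε(dz) curve
carries few-percent Fresnel ripples (its envelope is unimodal but shallow
minima can hide between ripples), the minimiser first brackets the global
basin on a 33-point grid over the bounds and then refines with scipy's
bounded Brent (golden-section with parabolic steps) inside the bracket, to
a tolerance of 1e-4·f; "both sensors" runs three alternating 1-D passes.

**Single-sensor recovery.** Iterates: enforce `sqrt(I)` at the sensor →
exact inverse of the assumed propagation to the plate plane → divide out
the assumed plate phase → keep the central K×K spatial-frequency support
(K = N/4 by default) → re-apply the plate phase → forward propagation.
Because the algorithm's internal propagation is exactly self-inverse,
unmodelled sensor-axial error appears only as the defocus chirp described
above — the mechanism behind the architecture's axial robustness. The
global phase (and, for sensor-axial studies, the analytically known
defocus chirp) is removed before MSE scoring; both are physically
unobservable in phase contrast.

**MSE.** `field_mse` is the plain per-pixel mean squared field error with
optional global-phase alignment (`e^{−iθ*}`, θ* from the inner product).
`recovery_mse` additionally rescales the recovered field to the reference
energy, since resolution constraints discard out-of-band energy that would
otherwise dominate the comparison.

## Study parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `dz_2f`, `dz_4f` | 0 | axial sensor offsets, signed fractions of f (studied to ±0.1) |
| `ramp_fraction`, `hold_fraction` | 0.3, 0.4 | dz′ schedule of corrected GS |
| `resolution_k` | N/4 | kept spatial-frequency support of plate recovery |
| quantisation `k` | 1 | plate-pixel block size (circular-mean averaging) |
| plate noise σ | — | Gaussian phase noise (rad); phasor MSE = 2(1−e^{−σ²/2}) |
| `plate_lateral` | 0 | plate shift as fraction of f; pixels = frac·f/Δx, applied wrapped |
| `plate_axial`, `sensor_axial` | 0 | fractions of f (studied to 0.1 and 0.5) |
| quantisation iteration cap | 6500 | enough for the holographic k = 8 run to plateau; the random k = 8 run is still far from convergence there |

Quantisation uses the circular mean (argument of the block-mean phasor;
arithmetic mean available for sensitivity analysis; a zero resultant gets
phase 0). Note that 8×8 averaging erases any blaze grating whose period
(4 px for quadrant-centre offsets) is below the block size — coarse plate
pixels cost the composite design some of its structure, which is visible
as the growth of its convergence time with k.

## Numerical choices and edge cases

* Ties at `z = z_crit` take the convolutional branch (the operators agree
  there anyway).
* GS/recovery error traces use relative sensor-amplitude error; an exact
  zero (plane-wave input) stops at iteration 1.
* Alternating projections stagnate at an MSE floor of order 10⁻³ under
  these scenes; comparisons between near-converged runs use an absolute
  tie tolerance of 0.005, two orders below the 0.2–0.4 scale at which
  retrievals differ visibly.
* Intensity writes refuse to clip: exceeding the declared 16-bit scale
  raises instead of saturating.
* The pinhole edge is binary by default; an area-weighted (4×4 subpixel)
  edge is available and is what the Airy-pattern comparison uses, since a
  staircase edge alone costs ~1% RMS at N = 256.
* Bayer extraction returns the red-site subarray unsmoothed by default
  (linear samples for retrieval); nearest-neighbour demosaic is opt-in.

## Known limitations

* The corrected-GS schedule removes most but not all stagnation: at
  offsets where plain GS is already near its floor, the corrected result
  can tie within the 0.005 floor rather than strictly improve.
* Convergence budgets are scene-dependent: the quantisation study's cap
  was chosen for the packaged scenes at N = 256; sharper or larger targets
  need proportionally more iterations.
* Lateral plate shifts are modelled as wrapped (circular); physical plates
  shift content in and out of the aperture instead. The "% of focal
  length" convention for lateral offsets has no unique pixel conversion;
  the adopted one (`pixels = frac·f/Δx`, wrapped) is stated in the
  geometry type.
* The birefringent scene treats retardance and polariser angles as free
  parameters and ignores wavelength dependence.
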