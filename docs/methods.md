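# Methods

This note documents the models, conventions and numerical choices behind
`mrsimqa`, and what the synthetic phantoms do and do not emulate.

## Coordinate and phase conventions

All modules share one physical frame: millimetres, origin at the magnet
isocenter, axes x = right–left, y = anterior–posterior, z = foot–head,
voxel-center convention with 0-based indices (position = origin +
index·spacing).  Distortion is defined radially about the isocenter, so
the shared isocentric frame is load-bearing, not cosmetic.  Phase is
wrapped to [−π, π) everywhere; any acquisition normalized to [0, 2π) is an
affine relabeling of the same information.

## Synthetic phantoms

The generator renders each QA object with known ground truth so every
analysis chain can be validated as a round trip.

**Capsule grid.**  Markers are solid capsules (12 mm long, 6 mm diameter,
axis in-plane) on a lattice with 25 mm in-plane and 27 mm z spacing over a
40 cm cube, trimmed to an ellipsoid with the scanner acquisition FOV
semi-axes (225, 225, 200 mm); the trim yields 2448 control points, the
practical marker count of such a phantom.  Rendering is anti-aliased: edge
voxels receive partial-volume weights from the signed distance to the
capsule surface, which is what makes sub-voxel centroid recovery
meaningful.  The default rendering voxel is 2 mm isotropic — coarse enough
to keep a full 40 cm volume at ~10⁷ voxels, fine enough that centroid
errors stay below 0.1 mm.  The distortion model is a smooth polynomial
(total degree ≤ 5) per output axis plus a pure radial cubic d(r) = a·r³,
the leading behavior of gradient-nonlinearity distortion; displacement at
the isocenter is exactly zero by construction.

**B0 sphere.**  A 31 cm sphere inside a 35 cm reconstruction FOV with a
programmed ppm field; the dual-echo images carry
φₖ = wrap(2π f₀ · ppm·10⁻⁶ · TEₖ + φ₀).  The parabolic field
ppm(r) = c·r² has closed-form moments over a ball of radius R: mean
(3/5)cR², mean-removed RMS cR²√(12/175) — used to program a field with an
exact target volume RMS.  The generator refuses fields that violate the
Itoh condition (adjacent-voxel phase-difference steps ≥ π), for which
unwrapping is ill-posed.

**Tissue phantom.**  Water / fat / cortical bone / air compartments with
complex signal s(TE) = ρ[(1−ff) + ff·e^{i2πΔf TE}]·e^{−TE/T2*},
Δf = 3.4 ppm × f₀.  T2* defaults: water 40 ms, fat 30 ms, bone 0.4 ms —
standard literature magnitudes; only their ordering matters to the tests.
The compartment amplitudes ρ are *effective* signal amplitudes, not
literal proton densities: the generator has no T1 weighting, so the
short-T1 boost that makes cortical bone bright on short-TR UTE
acquisitions is folded into the bone amplitude (0.7 vs 1.0 for water).
Bone and fat stop short of the z faces so they are enclosed by soft
tissue in 3D, as anatomy would be.

**Motion phantom.**  A cube (default 55 mm) translating along z as
position(t) = excursion·a(t)/peak-to-peak, with a round static reference
object in the same FOV.  Drive-train transmission loss is modelled simply
by passing a reduced realized excursion (e.g. 30 mm programmed × 0.6).
Waveforms are sinusoids a(t) = (pp/2)·sin(2πt/T) with optional drift,
spike, or period-jitter anomalies, sampled at dt ≤ T/50.

What the phantoms do **not** emulate: coil sensitivity, k-space /
radial-acquisition artifacts (the UTE "halo" is handled only by surface
masking), susceptibility or chemical-shift distortion, full Bloch
dynamics, realistic noise spectra.  Passing tests therefore demonstrate
the correctness of the *analysis* chains on idealized but geometrically
faithful inputs, not robustness to every artifact of real acquisitions.

## Distortion analysis

Markers are detected as connected components above a threshold (default
50 % of the intensity range) with at least 4 voxels; the centroid is the
intensity-weighted center of mass with each component grown by one voxel
so the anti-aliased skirt contributes (without this the threshold cut
biases centroids by ~0.1 mm).  Matching is greedy one-to-one by ascending
pair distance within a capture radius (default 12 mm, safely under half
the lattice spacing), ties broken by lattice-index lexicographic order.
Rigid pre-alignment (Kabsch) uses only markers within 5 cm of the
isocenter so the radially growing system distortion is not absorbed into
the rigid fit.  Dense in-plane maps are linear interpolations of marker
displacements — displacements are computed directly from matched
centroids rather than from deformable registration, which is exact where
markers exist and avoids registration boundary artifacts.  Shell
statistics use the population SD (n); the convention is recorded in the
output.  The 2D compliant rectangle is axis-aligned, centered on the
isocenter, grown alternately per axis by one lattice step (clamped to the
marker hull) while ≥ 75 % of enclosed control points distort < 2 mm; the
vendor's own algorithm is undisclosed, so this fully specified rule is
fixed instead.  Both point-based and interpolated-map outputs are
available because shell statistics can be defined over either.

## B0 homogeneity

The ppm map is referenced to the masked mean — volume-RMS homogeneity is
conventionally a deviation about the mean; the absolute frequency offset
is tracked separately by the QA module.  Unwrapping delegates to
reliability-sorted (quality-guided) unwrapping from scikit-image;
disconnected mask components unwrap independently, each with its own
2πk ambiguity, and the component count is flagged in the output.  The DSV
RMS is computed over the centered sphere inside the mask; slice-wise (2D)
and volumetric inputs are both accepted since the dual-echo protocol is
acquired per plane.

## 4D MRI simulation

Trigger levels are placed at amplitude-bin centers of the min–max range
observed in the first two breathing cycles: level_k = min +
(k+½)(max−min)/N.  Falling (inhale→exhale) phases take the odd-stepped
levels from the top down and rising phases the remainder from the bottom
up, so every bin-center level is used exactly once and the two limbs of
the cycle map to distinct phases; phase 0 % is end-inhale.  This fully
specified open scheme stands in for the vendor's proprietary triggering.

Acquisition is slice-major: the current slice collects all N phase images
before the next slice starts.  Each trigger occupies one TR window, and
the trigger re-arms only at the start of the next breathing cycle — the
relaxation constraint that separates samplings of one slice into distinct
respiratory cycles.  This makes the simulator *cycle-limited*: one
slice-phase per breath, hence duty cycle ≈ TR/T (0.67 at T = 3 s and 0.40
at T = 5 s for TR = 2 s), overall time ∝ N·n_slices·T, and a tenfold vs
twofold phase study scaling scan time ~4–5×.  An earlier variant that
allowed any still-needed phase to fire after the TR block inverts the
duty-cycle ordering between 3 s and 5 s breathing at small N and was
rejected.  Whether a real scanner acquires several phases from a single
breathing limb is vendor-internal; absolute duty cycles from this
simulator are therefore indicative, while the orderings and scalings are
robust.

With bin-center triggering the sampled object positions span
excursion·(N−1)/N, so the MIP S-I extent follows
object size + excursion·(N−1)/N — the analytic oracle the simulator must
match within one voxel.

## UTE/Dixon

Practical Dixon echo pairs are generally not exactly in/out of phase, so
the solver is a flexible-TE least-squares inversion of the two complex
Dixon echoes for non-negative (ρ_w, ρ_f); the classic (IP±OP)/2 formula
is its special case at 0/π angles.  Negative components are clamped and
the other component refit (water-only: mean of real parts; fat-only:
projection on the fat phasor).  Near-colinear echo phasors raise with the
system's condition number.  The model ignores T2* decay — a round trip
therefore recovers the compartment amplitude decayed to the mean Dixon
TE, not ρ itself; on pure compartments the discrepancy is ~0.1 %.
Magnitude-only input is accepted with the phase-sign ambiguity flagged.
The bone-enhanced image is scale·UTE − in-phase clipped at zero
(scale 1.3 default, exposed as a parameter); the halo outside the body is
removed by masking with the largest connected component of a reference
anatomy above half maximum, morphologically closed (border value 1 so a
body touching the array edge is not eroded) and hole-filled.

## Routine QA metrics

Frequency drift is day-to-day: drift_ppm = |f − f_prev|/f_prev·10⁶
against a 1.5 ppm limit (≈ 64 Hz at 42,587,276 Hz) plus the
manufacturer's absolute band; a post-service baseline reset is handled by
supplying the new baseline.  Slice thickness is FWHM × tan(ramp angle)
with the FWHM located by linear interpolation at half maximum on the
band-perpendicular profile; a missing band yields a failing entry with a
diagnostic rather than an exception.  Laser bookkeeping compares
crosshair offsets against 2 mm and individual 200 mm / ±100 mm laser
moves against 1 mm.  The default tolerance table carries each limit
exactly once with its source.  Transmitter gain and low-contrast
detectability are recorded as pass-through values — they come from vendor
software with no published algorithm.

## Numerical choices and limitations

- Line profiles are sampled by cubic-spline interpolation at half-voxel
  steps; peaks are refined with a 3-point fit on log-intensities
  (Gaussian interpolation) falling back to a plain parabola.  Linear
  profile sampling plus a plain parabola biases sub-voxel peaks by
  ~0.2 mm and was rejected.
- Threshold segmentation defaults to half of the intensity range; for
  anti-aliased objects any threshold in 0.4–0.6 moves the measured volume
  by less than one voxel shell.
- Generators are bit-reproducible given parameters and a seed; noise is
  optional and off by default in the recovery analyses.
- Problem sizes default to the phantom-scale conditions (2 mm rendering
  voxel for the 40 cm grid, 2.5 mm for the B0 sphere, 25 slices × up to
  10 phases for the 4D studies); all analyses run in seconds to a couple
  of minutes on one CPU.
- The matcher assumes displacements below half the lattice spacing
  (larger fields are flagged ambiguous by the generator); the B0 chain
  assumes the Itoh condition holds; the 4D simulator assumes an external
  surrogate that actually crosses its trigger levels every cycle.
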