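# Methods

`pabrain` simulates photoacoustic (PA) imaging of a simplified human
head: pulsed light deposits energy in tissue, the local pressure rise
propagates as ultrasound through (optionally) the skull, a linear
array records it, and delay-and-sum (DAS) beamforming forms the image.
The pipeline has five stages — phantom, optical sources, photon
transport, acoustic propagation, reconstruction — plus the ranking
analysis built on top. This note records the model in each stage, the
parameters that matter, the numerical choices, and the limits of what
the synthetic setup can show.

## Head phantom

A 14 × 14 × 14 mm³ cube of 140³ cubic voxels (0.1 mm edge). Voxel
(i, j, k) spans the half-open cell `[i·Δ, (i+1)·Δ)`; its center sits at
`(i + 0.5)·Δ`, and physical positions map to indices by `floor(p/Δ)`
(so the 7 mm analysis line is index 70, and 11/12/13 mm are
110/120/130). Four layers stack along +Z by voxel-center z: scalp
[0, 3) mm, skull [3, 8) mm, cerebrospinal fluid [8, 10) mm, gray
matter [10, 14) mm. Because centers sit at half-spacing offsets,
boundary ties cannot occur. A 2 mm-diameter cylindrical blood vessel
is centered in the gray-matter layer at (x, z) = (7, 12) mm; its axis
runs along Y across the full domain so the circular cross-section lies
in the x–z analysis plane, and the X-profiles at z = 11/12/13 mm cut
its top boundary, center, and bottom boundary. Voxel membership is
decided at the voxel center; the cross-section then contains 316
voxels per Y slice (vs. the continuum value π r²/Δ² ≈ 314).

Optical properties at 800 nm (μa, μs in mm⁻¹; g; n):

| tissue | μa | μs | g | n |
|---|---|---|---|---|
| scalp | 0.018 | 19.0 | 0.9 | 1.37 |
| skull | 0.016 | 16.0 | 0.9 | 1.43 |
| CSF | 0.004 | 2.4 | 0.9 | 1.33 |
| gray matter | 0.036 | 22.0 | 0.9 | 1.37 |
| blood vessel | 0.223 | 50.0 | 0.99 | 1.4 |

Acoustically all soft tissue is water (1500 m/s, 1000 kg/m³); in the
heterogeneous ("with skull") mode the skull band carries 2190 m/s and
1800 kg/m³. The acoustic skull region is defined by the z band
[3, 8) mm, identical to the label band on the analysis plane.

## Optical source types

Sixteen source kinds launch from (7, 7, 0) mm into +Z. All
characteristic lengths (aperture, diameter, slit length, array pitch)
are 1 mm and the characteristic angle is π/6. The per-kind launch
distributions are this package's own declared definitions (the kinds'
fine parameters are not uniquely fixed by their names, and several
reasonable conventions exist — every parameter below is configurable
through `SourceSpec`):

* **pencil** — delta in position and direction.
* **isotropic** — point source, direction uniform in solid angle over
  the downward hemisphere (upward draws re-sampled).
* **arcsine** — point source, polar angle uniform on [0, π/2] (cos θ
  arcsine-distributed).
* **cone** — uniform in solid angle within half-angle π/6.
* **angular Gaussian** — half-normal polar angle, σ = π/6, truncated
  at π/2.
* **slit / line** — positions uniform on a 1 mm X-aligned segment;
  slit collimated, line with hemispheric (isotropic) directions.
* **collimated Gaussian** — transverse Gaussian, 1/e² diameter 1 mm
  (σ = 0.25 mm), collimated.
* **hyperboloid Gaussian** — focused Gaussian-beam ray bundle: waist
  1/e² diameter 1 mm at 7 mm depth; waist offsets and ray angles are
  independent Gaussians with the Rayleigh-range parameter set equal to
  the focal depth, so the surface spot is √2 × the waist and the beam
  converges toward the focus. This geometric (not diffraction-limited)
  convergence is what distinguishes the kind from the collimated
  Gaussian at depth.
* **planar** — uniform 1 × 1 mm square, collimated.
* **disk / ring** — uniform 1 mm-diameter disk / annulus with inner
  diameter 0.5 mm, collimated.
* **pencil array** — 3 × 3 grid of pencil beams at 1 mm pitch,
  photons assigned to beams uniformly.
* **Fourier kinds (sf / 1D / 2D)** — uniform square modulated by
  `(1 + cos 2π(kx·u + ky·v + φ))/2` with (kx, ky, φ) = (1,1,0),
  (1,0,0), (1,1,0). The modulation is applied as launch *weight*, not
  by rejection, so the launched photon count is deterministic; the
  kinds' mean launched weight is ½.

## Photon transport

Steady-state voxel Monte Carlo. Free paths are sampled in optical
depth τ ~ Exp(1) and consumed voxel-by-voxel with boundary-aware ray
stepping, so layer interfaces are honored exactly. At each collision
the packet deposits the fraction μa/μt of its weight and scatters by
Henyey–Greenstein with the local g; packets below weight 10⁻⁴ enter
Russian roulette with survival probability 0.1 (survivors boosted
10×, keeping the estimator unbiased). With index mismatch enabled
(default — the property table lists n per tissue), Snell refraction /
Fresnel reflection (unpolarized average, with total internal
reflection) occurs at voxel faces where n changes, including specular
reflection at the illuminated surface and the external boundary
(ambient n = 1). A voxel with μt = 0 is traversed ballistically.

Fluence uses the track-length estimator: Σ(weight × path) per voxel,
divided by voxel volume and launched photon count — units mm⁻² per
launched photon. This is lower-variance than a collision estimator in
the low-μa CSF. Absorbed energy density is A = μa·F per voxel and
inherits the per-photon arbitrary-unit scale; the Grüneisen factor is
taken as 1, so A is also the initial acoustic pressure. Time-resolved
transport is integrated out: only total fluence feeds A.

Validation: Beer–Lambert recovery of μa within 2% in the
non-scattering limit; absorbed + escaped weight equal to launched
weight to better than 10⁻³; agreement with diffusion theory
(exp(−μeff r)/(4πDr)) within 10% beyond three transport mean free
paths for an interior isotropic source; seed-for-seed bit determinism.

## Acoustic propagation

The absorption plane through y = 7 mm (y index 70 — the plane holding
the source axis and the vessel cross-section) is the 2D initial
pressure. Propagation uses a first-order k-space pseudo-spectral
scheme: spectral gradients on spatially staggered grids, a leapfrog in
time with pressure at integer and velocity at half-integer steps, and
the dispersion-correcting factor sinc(c_ref·k·Δt/2) applied inside
every gradient, referenced to the *minimum* sound speed. The first
velocity half-step is taken with Δt/2 through the same corrected
gradient, which makes the scheme *exact* for a homogeneous medium at
c_ref — the test suite exploits this by comparing a disc-source trace
against the closed-form spectral evolution `p̂(k, t) = p̂₀(k)·cos(ckt)`
(agreement at machine precision; the acceptance check allows 3% RMS).
Heterogeneous density enters through face-averaged staggered maps.
The discrete operator is self-adjoint under the 1/(ρc²) inner
product, so source/receiver reciprocity holds to round-off (tested to
1% in the skull medium).

Time step = sensor sampling interval (12.5 ns). Stability is checked
against the k-space bound `c_ref·k_max·Δt/2 < asin(c_ref/c_max)`
(CFL ≈ 0.27 here). A 10-pixel perfectly matched layer with a
quadratic absorption ramp (strength 2·c_max/Δx at the outer edge,
applied split-field per axis) surrounds the domain; the grid is
expanded by the PML thickness with edge-replicated medium maps so the
layer never overlaps tissue. With the PML off the scheme conserves
acoustic energy to < 0.5% over 1000 steps (periodic wrap).

The sensor is a linear array of 140 point elements, one per grid
column, on the illuminated (z = 0) side — consistent with the
"moved up" uncorrected-reconstruction artifact, which requires the
skull between array and target to shorten arrival times. Each element
records every time step (sample 0 = p₀ itself), 4096 samples. The
transducer response — Gaussian amplitude, centered at 5 MHz, −6 dB
full width 5 MHz (100% fractional bandwidth, ultrasound convention) —
is applied to the recorded traces zero-phase, post hoc rather than
inside the forward solver. Acoustic absorption is zero (only speed
and density are specified for the media).

## Delay-and-sum reconstruction

`I(x,z) = Σᵢ pᵢ(Δtᵢ(x,z))` over the 140 elements: a bare sum — no
apodization, no element normalization, no envelope detection — which
fixes the arbitrary-unit scale of reconstructed values. Traces are
linearly interpolated between samples; delays beyond the record
contribute zero. The homogeneous model charges the whole straight
pixel–element path at 1500 m/s; the layered model splits the same
straight ray at the skull-band planes and charges the in-band segment
at 2190 m/s (no refraction — a pure distance/speed correction; e.g. a
pixel at z = 8 mm directly beneath its element: 3 mm/1500 + 5 mm/2190
= 4.283 μs). The reported image is |I|; the signed map is retained.
Reconstructions of the with-skull simulation use the layered model,
without-skull the homogeneous model.

End-to-end, a point target at (7, 10) mm localizes within 0.2 mm in
the homogeneous pipeline; simulated through the skull, the
homogeneous-delay reconstruction pulls it ~1.4 mm toward the array
and the layered model restores it to within 0.3 mm.

## Sweep, profiles, rankings

The experiment driver runs every (source, skull mode) cell —
per-source seeds are SHA-256 hashes of (master seed, source name), so
sweep order and subsetting never change results — and extracts, for
three stages (initial PA, reconstruction without skull, with skull),
the Z-profile at x = 7 mm and X-profiles at z = 11/12/13 mm. At each
position the sixteen sources are ranked by amplitude, ties broken by
the canonical listing order; the top-3 maxima/minima tables are the
analysis deliverable. A failing cell is logged and skipped without
aborting the sweep.

## Problem sizes

Defaults: 10⁶ photons per source for the headline amplitude
computation (`scripts/acceptance.py`), where the single-voxel
track-length estimate at 11–13 mm depth still carries a ~10% relative
standard error; the deterministic acoustic stage (140² grid + PML,
4096 steps) is exact to solver precision. The test suite runs the
sixteen-source sweep at 2 × 10⁴ photons per source and the physics
validations at 2 × 10⁴–2 × 10⁵ photons — sizes chosen so the full
suite completes in minutes while each assertion stays well above its
noise floor (statistical tests use standard-error-scaled tolerances).

## What the synthetic setup does and does not show

The phantom is the study condition itself (flat layers, literature
constants, one straight vessel), not a stand-in for patient anatomy:
passing tests demonstrate the correctness of the transport, wave
propagation, and beamforming machinery and the qualitative transcranial
effects (skull speedup of arrivals, aberration, depth mis-localization
and its delay-model correction, limited-view arcs), but say nothing
about curved skulls, heterogeneous bone, white matter, or realistic
vasculature.

Two quantitative caveats matter when comparing with published
amplitude tables for this geometry. First, PA amplitudes here are in
declared per-photon units; printed "a.u." values from other
implementations depend on their (often unstated) photon counts and
normalizations, so only orderings — not absolute values — are
comparable, and this package's absolute values at the analysis depths
are ~10³ smaller than the published prints. Second, under per-photon
normalization the superficial absorption peak exceeds the vessel-depth
signal by 10³–10⁴; its limited-view arcs and skull reverberations then
dominate the reconstructed amplitude at deep pixels in *both* acoustic
modes, so pixel-level source orderings and with/without-skull
comparisons at depth measure artifact interference rather than the
vessel signal. Isolated-source tests (a vessel-only initial pressure)
do show the expected skull attenuation cleanly. Between equal-energy
source kinds, the physical spread of deep fluence is only a few
percent (1–2 mm apertures blur within one transport mean free path of
the surface), which is below the single-voxel Monte Carlo noise at
10⁶ photons; per-kind energy conventions, not deep-tissue physics,
dominate published per-source spreads.

## Known limitations

2D acoustics on the analysis plane (out-of-plane spreading ignored);
no shear waves or frequency-dependent attenuation in bone; point
elements without directivity; no pulse temporal profile, polarization,
or wavelength sweep; straight-ray (non-refracting) layered delays; CW
photon transport.
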