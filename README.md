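# pabrain

Photoacoustic (PA) imaging simulation of a simplified human head, for
researchers studying how the skull and the choice of optical source
shape transcranial PA images.

Pulsed light absorbed in tissue launches an ultrasound wave
(`p0 = Γ·μa·F`, Grüneisen Γ ≡ 1 here); the wave crosses the skull —
which is both optically scattering and acoustically fast and dense —
and a linear transducer array records it for beamforming. `pabrain`
implements that chain end to end:

1. **Phantom** — 14 mm cube, 140³ voxels at 0.1 mm: scalp 3 mm /
   skull 5 mm / CSF 2 mm / gray matter 4 mm along +Z, with a
   2 mm-diameter blood vessel centered in the gray matter at
   (x, z) = (7, 12) mm (axis along Y). Literature optical constants at
   800 nm; acoustically water everywhere except (optionally) the skull
   band at 2190 m/s, 1800 kg/m³.
2. **Optical sources** — sixteen launch distributions (pencil,
   isotropic, arcsine, cone, slit, line, collimated/angular/hyperboloid
   Gaussian, planar, disk, ring, pencil array, three Fourier patterns),
   all 1 mm-scale, characteristic angle π/6.
3. **Photon transport** — voxel Monte Carlo: exponential free paths,
   Henyey–Greenstein scattering, weight absorption μa/μt per collision,
   Russian roulette, Snell/Fresnel at refractive-index steps;
   track-length fluence estimator, F in mm⁻² per launched photon.
4. **Acoustics** — the absorption plane through y = 7 mm is the 2D
   initial pressure; a first-order k-space pseudo-spectral solver
   (staggered grids, k-space dispersion correction, quadratic-ramp PML)
   propagates it to a 140-element line array at z = 0; traces are
   filtered by the transducer's 5 MHz / 100%-bandwidth Gaussian
   response (4096 samples, 12.5 ns).
5. **Reconstruction** — delay-and-sum, `I(x,z) = Σᵢ pᵢ(Δtᵢ)`, bare sum
   with linear interpolation; homogeneous (1500 m/s) or layered
   straight-ray delays (2190 m/s inside the skull band).
6. **Analysis** — Z/X profiles at x = 7 mm and z = 11/12/13 mm, and
   per-position rankings of the sixteen sources for three stages:
   initial PA, reconstruction without skull, reconstruction with skull.

See `docs/methods.md` for the model details, conventions, and
limitations.

## Worked example

```python
import numpy as np
from pabrain import (
    build_phantom, source_spec, McConfig, run_mc, absorption_from_fluence,
    slice_initial_pressure, Medium2D, SensorArraySpec, simulate_propagation,
    apply_bandwidth, DelayModel, das_reconstruct,
)

phantom = build_phantom()
fluence = run_mc(phantom, source_spec("pencil"),
                 McConfig(photon_count=100_000, seed=2))
A = absorption_from_fluence(fluence, phantom)
print(f"A at vessel top/center/bottom rows (x=7mm): "
      f"{A.values[70,70,110]:.3e} {A.values[70,70,120]:.3e} {A.values[70,70,130]:.3e}")

p0 = slice_initial_pressure(A)
sensor = SensorArraySpec()
for mode, delays in (("homogeneous", "homogeneous"), ("heterogeneous", "layered")):
    traces = apply_bandwidth(simulate_propagation(
        p0, Medium2D.for_phantom(skull_mode=mode), sensor))
    img = das_reconstruct(traces, DelayModel(mode=delays))
    print(f"{mode:>13}: recon amplitude at vessel center = {img.amplitude[70,120]:.3e}")
```

prints (seed 2):

```
A at vessel top/center/bottom rows (x=7mm): 3.088e-04 9.011e-05 5.228e-06
  homogeneous: recon amplitude at vessel center = 6.093e-03
heterogeneous: recon amplitude at vessel center = 5.849e-03
```

The absorption values are per launched photon: the vessel rows at
11–13 mm depth carry ~10⁻⁴–10⁻⁶ of a photon's energy per mm³ voxel
after 11+ mm of scattering tissue, falling steeply across the vessel
(μ_eff ≈ 0.7 mm⁻¹ in blood). The reconstructed amplitudes are bare
140-element DAS sums at the vessel-center pixel; here the with-skull
image is ~4% weaker than the without-skull one. Note that at this
depth the deep pixels also collect limited-view arcs from the much
brighter superficial layers, so single-pixel reconstructed values mix
vessel signal with artifact energy (quantified in `docs/methods.md`).

The staged analysis scripts run the same chain over all sixteen
sources and write tables under `results/`:

```
python analysis/01_build_phantom.py
python analysis/02_optical_simulation.py --photons 100000 --seed 1
python analysis/03_acoustic_reconstruction.py
python analysis/04_rank_and_report.py
```

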