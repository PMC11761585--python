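"""k-space solver: time of flight, exact-evolution oracle, energy,
reciprocity, bandwidth model, skull heterogeneity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import fft as sp_fft

from pabrain.acoustics import (
    KSpaceSolver2D,
    Medium2D,
    PressureField2D,
    SensorArraySpec,
    SensorData,
    apply_bandwidth,
    simulate_propagation,
    slice_initial_pressure,
)
from pabrain.phantom import build_phantom
from pabrain.transport import AbsorptionVolume, FluenceVolume, absorption_from_fluence

DT = 12.5e-9
DX = 1e-4


def point_p0(ix, iz, shape=(140, 140)):
    p = np.zeros(shape)
    p[ix, iz] = 1.0
    return PressureField2D(p)


class TestSlice:
    def test_all_zero_volume(self, phantom):
        A = AbsorptionVolume(phantom.geometry, np.zeros(phantom.geometry.shape))
        assert np.all(slice_initial_pressure(A).values == 0.0)

    def test_plane_selection_and_total(self, phantom):
        vals = np.random.default_rng(0).random(phantom.geometry.shape)
        A = AbsorptionVolume(phantom.geometry, vals)
        sl = slice_initial_pressure(A)
        assert np.array_equal(sl.values, vals[:, 70, :])
        assert sl.values.sum() == pytest.approx(vals[:, 70, :].sum())

    def test_vessel_disc_elevated(self, phantom):
        """With uniform fluence the absorption slice shows the vessel disc
        (mu_a 0.223) far above the surrounding gray matter (0.036)."""
        F = FluenceVolume(phantom.geometry, np.ones(phantom.geometry.shape))
        sl = slice_initial_pressure(absorption_from_fluence(F, phantom))
        assert sl.values[70, 120] == pytest.approx(0.223)
        assert sl.values[30, 120] == pytest.approx(0.036)
        assert sl.values[70, 120] / sl.values[30, 120] > 6


class TestPropagation:
    def test_zero_pressure_zero_traces(self):
        sd = simulate_propagation(
            PressureField2D(np.zeros((140, 140))),
            Medium2D.for_phantom(),
            SensorArraySpec(n_samples=64),
        )
        assert np.all(sd.values == 0.0)

    def test_time_of_flight_single_pixel(self):
        """Bright pixel at (7, 10) mm: central element peaks at
        10 mm / 1500 m/s = 6.67 us (sample 533) within +/- 2 samples."""
        sd = simulate_propagation(
            point_p0(70, 100), Medium2D.for_phantom(), SensorArraySpec(n_samples=700)
        )
        peak = int(np.argmax(np.abs(sd.values[70])))
        assert abs(peak - 533) <= 2

    def test_disc_source_matches_exact_evolution(self):
        """Uniform disc p0 in water: the recorded trace matches the exact
        band-limited initial-value solution (spectral cosine evolution)
        within 3% relative RMS before boundary influence."""
        N, nt, c = 200, 600, 1500.0
        x = (np.arange(N) + 0.5) * 0.1
        X, Z = np.meshgrid(x, x, indexing="ij")
        p0 = (((X - 10.0) ** 2 + (Z - 10.0) ** 2) <= 1.0).astype(float)
        cmap = np.full((N, N), c)
        rho = np.full((N, N), 1000.0)
        solver = KSpaceSolver2D(p0.copy(), cmap, rho, DT, DX, pml_size=0)
        rec = solver.run_recording((np.array([100]), np.array([30])), nt)[0]

        kx = 2 * np.pi * sp_fft.fftfreq(N, DX)[:, None]
        kz = 2 * np.pi * sp_fft.rfftfreq(N, DX)[None, :]
        K = np.sqrt(kx**2 + kz**2)
        P0 = sp_fft.rfft2(p0)
        oracle = np.array(
            [
                sp_fft.irfft2(P0 * np.cos(c * K * m * DT), s=(N, N))[100, 30]
                for m in range(nt)
            ]
        )
        rms = np.sqrt(np.mean((rec - oracle) ** 2) / np.mean(oracle**2))
        assert rms < 0.03

    def test_energy_conserved_without_pml(self):
        """Lossless homogeneous medium, periodic wrap: total acoustic
        energy constant within 0.5% over 1000 steps."""
        N = 128
        x = (np.arange(N) + 0.5) * 0.1
        X, Z = np.meshgrid(x, x, indexing="ij")
        p0 = np.exp(-(((X - 6.4) ** 2 + (Z - 6.4) ** 2) / 0.5))
        solver = KSpaceSolver2D(
            p0, np.full((N, N), 1500.0), np.full((N, N), 1000.0), DT, DX, pml_size=0
        )
        e0 = solver.acoustic_energy()
        for _ in range(1000):
            solver.step()
        assert abs(solver.acoustic_energy() - e0) / e0 < 0.005

    def test_reciprocity_in_heterogeneous_medium(self):
        """Swapping a point source and receiver (both in the water
        region) across the skull band leaves the trace unchanged."""
        med = Medium2D.for_phantom(skull_mode="heterogeneous")

        def trace(src, rec, nt=600):
            q = np.zeros((140, 140))
            q[src] = 1.0
            s = KSpaceSolver2D(
                np.pad(q, 10),
                np.pad(med.sound_speed, 10, mode="edge"),
                np.pad(med.density, 10, mode="edge"),
                DT,
                DX,
                pml_size=10,
            )
            return s.run_recording((np.array([rec[0] + 10]), np.array([rec[1] + 10])), nt)[0]

        a = trace((70, 120), (40, 10))
        b = trace((40, 10), (70, 120))
        assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 0.01

    def test_skull_advances_first_arrival(self):
        """For p0 below the skull the heterogeneous arrival leads the
        homogeneous one by ~ 5 mm (1/1500 - 1/2190) s (84 samples)."""
        p0 = point_p0(70, 120)
        sens = SensorArraySpec(n_samples=900)
        hom = simulate_propagation(p0, Medium2D.for_phantom(), sens)
        het = simulate_propagation(p0, Medium2D.for_phantom(skull_mode="heterogeneous"), sens)
        peak_hom = int(np.argmax(np.abs(hom.values[70])))
        peak_het = int(np.argmax(np.abs(het.values[70])))
        expected = 5e-3 * (1 / 1500 - 1 / 2190) / DT
        assert peak_het < peak_hom
        assert peak_hom - peak_het == pytest.approx(expected, abs=12)

    def test_cfl_violation_rejected(self):
        with pytest.raises(ValueError, match="stability"):
            KSpaceSolver2D(
                np.zeros((64, 64)),
                np.full((64, 64), 1500.0),
                np.full((64, 64), 1000.0),
                dt=1e-7,
                dx=DX,
            )

    def test_medium_modes_differ_only_on_skull_band(self):
        hom = Medium2D.for_phantom()
        het = Medium2D.for_phantom(skull_mode="heterogeneous")
        diff = hom.sound_speed != het.sound_speed
        zc = (np.arange(140) + 0.5) * 0.1
        band = (zc >= 3.0) & (zc < 8.0)
        assert np.array_equal(np.any(diff, axis=0), band)


class TestBandwidth:
    def test_center_frequency_unit_gain(self):
        sens = SensorArraySpec()
        t = sens.times
        tone = np.sin(2 * np.pi * 5e6 * t)
        sd = SensorData(np.tile(tone, (140, 1)), sens)
        out = apply_bandwidth(sd).values[0]
        mid = slice(1000, 3000)
        assert np.abs(out[mid]).max() == pytest.approx(np.abs(tone[mid]).max(), rel=1e-3)

    def test_gain_monotone_up_to_center(self):
        sens = SensorArraySpec()
        freqs = sp_fft.rfftfreq(sens.n_samples, sens.dt)
        gains = []
        for f in (0.0, 2.5e6, 5e6):
            tone = np.cos(2 * np.pi * f * sens.times)
            sd = SensorData(np.tile(tone, (140, 1)), sens)
            out = apply_bandwidth(sd).values[0]
            gains.append(np.abs(out[1000:3000]).max())
        assert 0.0 < gains[0] < gains[1] < gains[2]

    def test_linearity(self, rng):
        sens = SensorArraySpec(n_samples=512)
        a = SensorData(rng.standard_normal((140, 512)), sens)
        b = SensorData(rng.standard_normal((140, 512)), sens)
        ab = SensorData(a.values + b.values, sens)
        lhs = apply_bandwidth(ab).values
        rhs = apply_bandwidth(a).values + apply_bandwidth(b).values
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_zero_phase(self):
        """A symmetric pulse stays symmetric about its centre."""
        sens = SensorArraySpec(n_samples=1024)
        t = sens.times - sens.times[512]
        pulse = np.exp(-((t / 0.2e-6) ** 2))
        sd = SensorData(np.tile(pulse, (140, 1)), sens)
        out = apply_bandwidth(sd).values[0]
        assert np.allclose(out[1:512], out[-1:512:-1], atol=1e-9 * np.abs(out).max())


@given(st.integers(0, 139), st.integers(0, 139))
def test_sensor_trace_finiteness_invariant(ix, iz):
    """SensorData rejects non-finite traces regardless of content shape."""
    sens = SensorArraySpec(n_samples=8)
    vals = np.zeros((140, 8))
    vals[ix % 140, iz % 8] = np.inf
    with pytest.raises(FloatingPointError):
        SensorData(vals, sens)
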