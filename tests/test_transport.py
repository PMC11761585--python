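"""Monte Carlo transport: Beer-Lambert limit, conservation, diffusion
theory, estimator behaviour."""

import numpy as np
import pytest

from pabrain.geometry import GridGeometry
from pabrain.phantom import LabelVolume, TissueProperties, build_phantom
from pabrain.sources import source_spec
from pabrain.transport import (
    AbsorptionVolume,
    FluenceVolume,
    McConfig,
    absorption_from_fluence,
    mc_std_error,
    run_mc,
    run_mc_launches,
)


def uniform_medium(shape, spacing, mu_a, mu_s, g=0.0, n=1.0):
    geom = GridGeometry(shape, spacing)
    labels = np.zeros(geom.shape, np.uint8)
    table = {"medium": TissueProperties(mu_a, mu_s, g, n)}
    return LabelVolume(geom, labels, ("medium",), table)


class TestBeerLambert:
    def test_absorbing_only_recovers_mu_a(self):
        """Pencil beam in a non-scattering absorber: log-fluence slope = -mu_a."""
        mu_a = 0.5
        ph = uniform_medium((20, 20, 100), 0.1, mu_a, 0.0)
        cfg = McConfig(photon_count=200_000, seed=11, mismatch=False)
        F = run_mc(ph, source_spec("pencil", position=(1.0, 1.0, 0.0)), cfg)
        prof = F.values[10, 10, :]
        z = (np.arange(100) + 0.5) * 0.1
        sel = slice(2, 90)
        slope = np.polyfit(z[sel], np.log(prof[sel]), 1)[0]
        assert slope == pytest.approx(-mu_a, rel=0.02)


class TestConservation:
    def test_weight_conservation_layered_phantom(self, phantom):
        cfg = McConfig(photon_count=100_000, seed=5)
        F = run_mc(phantom, source_spec("pencil"), cfg)
        total = F.absorbed_weight + F.escaped_weight
        assert abs(total - F.launched_weight) / F.launched_weight < 1e-3

    def test_fluence_nonnegative_and_finite(self, phantom):
        cfg = McConfig(photon_count=5_000, seed=8)
        F = run_mc(phantom, source_spec("isotropic"), cfg)
        assert np.all(F.values >= 0.0)
        assert np.all(np.isfinite(F.values))


class TestDeterminism:
    def test_same_seed_bit_identical(self, phantom):
        cfg = McConfig(photon_count=3_000, seed=21)
        a = run_mc(phantom, source_spec("planar"), cfg)
        b = run_mc(phantom, source_spec("planar"), cfg)
        assert np.array_equal(a.values, b.values)
        assert a.absorbed_weight == b.absorbed_weight

    def test_different_seed_differs(self, phantom):
        a = run_mc(phantom, source_spec("planar"), McConfig(photon_count=3_000, seed=21))
        b = run_mc(phantom, source_spec("planar"), McConfig(photon_count=3_000, seed=22))
        assert not np.array_equal(a.values, b.values)


class TestSeedAgreement:
    def test_independent_seeds_agree_within_3_sigma(self, phantom):
        """Two independent seed groups agree at the vessel-centre voxel
        within three combined standard errors, and fluence falls from
        the scalp surface to the CSF entry."""
        cfg = lambda s: McConfig(photon_count=50_000, seed=s)
        spec = source_spec("pencil")
        group_a = [run_mc(phantom, spec, cfg(s)) for s in (101, 102, 103)]
        group_b = [run_mc(phantom, spec, cfg(s)) for s in (201, 202, 203)]
        idx = (70, 70, 120)  # (7, 7, 12) mm, vessel centre
        mean_a = np.mean([r.values[idx] for r in group_a])
        mean_b = np.mean([r.values[idx] for r in group_b])
        se_a = mc_std_error(group_a)[idx]
        se_b = mc_std_error(group_b)[idx]
        assert abs(mean_a - mean_b) <= 3 * np.hypot(se_a, se_b)
        mean_vol = np.mean([r.values for r in group_a + group_b], axis=0)
        assert mean_vol[70, 70, 80] < mean_vol[70, 70, 0]  # CSF entry < surface


class TestDiffusionLimit:
    def test_isotropic_point_source_matches_diffusion_theory(self):
        """Interior isotropic point source in a homogeneous scattering
        medium: fluence vs radius follows exp(-mu_eff r)/(4 pi D r)
        beyond three transport mean free paths."""
        mu_a, mu_s = 0.01, 2.0
        ph = uniform_medium((90, 90, 90), 0.5, mu_a, mu_s, g=0.0, n=1.0)
        n_ph = 200_000
        rng = np.random.default_rng(17)
        u = rng.normal(size=(n_ph, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos = np.full((n_ph, 3), 22.5)
        F = run_mc_launches(ph, pos, u, np.ones(n_ph), McConfig(seed=31, mismatch=False))

        c = (np.arange(90) + 0.5) * 0.5 - 22.5
        R = np.sqrt(c[:, None, None] ** 2 + c[None, :, None] ** 2 + c[None, None, :] ** 2)
        mu_t_prime = mu_a + mu_s  # g = 0
        D = 1.0 / (3.0 * mu_t_prime)
        mu_eff = np.sqrt(3.0 * mu_a * mu_t_prime)
        lstar = 1.0 / mu_t_prime
        for r_lo, r_hi in [(3, 5), (5, 8), (8, 12)]:
            shell = (R >= r_lo * lstar) & (R < r_hi * lstar)
            sim = F.values[shell].mean()
            theory = (np.exp(-mu_eff * R[shell]) / (4 * np.pi * D * R[shell])).mean()
            assert sim == pytest.approx(theory, rel=0.10)


class TestAbsorption:
    def test_zero_mu_a_gives_zero(self, phantom):
        geom = phantom.geometry
        table = dict(phantom.table)
        table["csf"] = TissueProperties(0.0, 2.4, 0.9, 1.33)
        ph0 = LabelVolume(geom, phantom.labels, phantom.tissues, table)
        F = FluenceVolume(geom, np.ones(geom.shape))
        A = absorption_from_fluence(F, ph0)
        csf = ph0.labels == ph0.label_of("csf")
        assert np.all(A.values[csf] == 0.0)

    def test_gray_matter_coefficient(self, phantom):
        F = FluenceVolume(phantom.geometry, np.ones(phantom.geometry.shape))
        A = absorption_from_fluence(F, phantom)
        assert A.values[70, 70, 100] == pytest.approx(0.036)  # gray, F = 1
        assert A.values[70, 70, 120] == pytest.approx(0.223)  # vessel

    def test_linearity_in_fluence(self, phantom):
        vals = np.random.default_rng(3).random(phantom.geometry.shape)
        F1 = FluenceVolume(phantom.geometry, vals)
        F2 = FluenceVolume(phantom.geometry, 2.0 * vals)
        A1 = absorption_from_fluence(F1, phantom)
        A2 = absorption_from_fluence(F2, phantom)
        assert np.allclose(A2.values, 2.0 * A1.values)

    def test_geometry_mismatch_raises(self, phantom):
        other = GridGeometry((10, 10, 10), 0.1)
        F = FluenceVolume(other, np.zeros(other.shape))
        with pytest.raises(ValueError):
            absorption_from_fluence(F, phantom)


class TestStdError:
    def test_duplicated_runs_give_zero(self, phantom):
        F = run_mc(phantom, source_spec("pencil"), McConfig(photon_count=1_000, seed=4))
        assert np.all(mc_std_error([F, F]) == 0.0)

    def test_requires_two_runs(self, phantom):
        F = FluenceVolume(phantom.geometry, np.zeros(phantom.geometry.shape))
        with pytest.raises(ValueError):
            mc_std_error([F])

    def test_positive_where_runs_differ(self, phantom):
        geom = phantom.geometry
        a = FluenceVolume(geom, np.zeros(geom.shape))
        vals = np.zeros(geom.shape)
        vals[1, 2, 3] = 1.0
        b = FluenceVolume(geom, vals)
        se = mc_std_error([a, b])
        assert se[1, 2, 3] > 0.0
        assert se[0, 0, 0] == 0.0

    def test_scaling_with_photon_count(self):
        """Standard error scales as 1/sqrt(photons) within 20%."""
        ph = uniform_medium((30, 30, 30), 0.5, 0.05, 1.0)
        spec = source_spec("pencil", position=(7.5, 7.5, 0.0))
        runs_small = [
            run_mc(ph, spec, McConfig(photon_count=2_000, seed=s)) for s in range(301, 307)
        ]
        runs_big = [
            run_mc(ph, spec, McConfig(photon_count=8_000, seed=s)) for s in range(401, 407)
        ]
        core = (slice(10, 20), slice(10, 20), slice(5, 25))
        se_small = mc_std_error(runs_small)[core].mean()
        se_big = mc_std_error(runs_big)[core].mean()
        assert se_small / se_big == pytest.approx(2.0, rel=0.20)


class TestConfigValidation:
    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            McConfig(photon_count=0)
        with pytest.raises(ValueError):
            McConfig(weight_threshold=0.0)
        with pytest.raises(ValueError):
            McConfig(roulette_survival=1.5)
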