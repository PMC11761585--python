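"""Shared fixtures.

The expensive sixteen-source sweep is run once per session at a
reduced photon count (2e4/source) so the ranking and skull-attenuation
checks can share it; physics-accuracy tests use their own dedicated
configurations.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pabrain.phantom import build_phantom
from pabrain.pipeline import RunConfig, run_experiment

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: photons per source for the shared sweep (keeps the suite fast; the
#: acceptance script runs the full-scale configuration)
SWEEP_PHOTONS = 20_000
SWEEP_SEED = 1


@pytest.fixture(scope="session")
def phantom():
    return build_phantom()


@pytest.fixture(scope="session")
def full_sweep(phantom):
    """All sixteen sources, both skull modes, reduced photon count."""
    cfg = RunConfig(photon_count=SWEEP_PHOTONS, master_seed=SWEEP_SEED)
    bundle = run_experiment(cfg, phantom=phantom)
    assert not bundle.failures, f"sweep cells failed: {bundle.failures}"
    return bundle


@pytest.fixture(scope="session")
def small_bundle(phantom):
    """Two-source, two-mode bundle for plumbing and serialization tests."""
    cfg = RunConfig(
        sources=("pencil", "planar"), photon_count=2_000, master_seed=3
    )
    return run_experiment(cfg, phantom=phantom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
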