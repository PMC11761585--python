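#!/usr/bin/env python
"""Acoustic stage: propagate each initial-PA slice and beamform it.

Every absorption slice from results/initial_pa.npz is propagated to
the 140-element / 5 MHz linear array twice — through uniform water and
with the skull band at bone speed and density — band-filtered, and
reconstructed by delay-and-sum with the matching delay model
(homogeneous water delays vs straight-ray layered delays).  Writes
results/recon.npz with both amplitude maps per source and prints the
vessel-centre amplitudes.
"""

import argparse
from pathlib import Path

import numpy as np

from pabrain.acoustics import (
    Medium2D,
    PressureField2D,
    SensorArraySpec,
    apply_bandwidth,
    simulate_propagation,
)
from pabrain.beamform import DelayModel, das_reconstruct


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--slices", type=Path, default=Path("results/initial_pa.npz"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    data = np.load(args.slices)
    sources = [k for k in data.files if k not in ("seed", "photons")]
    sensor = SensorArraySpec()
    media = {
        "recon_homo": (Medium2D.for_phantom(), DelayModel()),
        "recon_hetero": (
            Medium2D.for_phantom(skull_mode="heterogeneous"),
            DelayModel(mode="layered"),
        ),
    }
    out: dict[str, np.ndarray] = {}
    print(f"{'source':<22} I_noskull(7,12)  I_skull(7,12)")
    for kind in sources:
        p0 = PressureField2D(data[kind])
        row = {}
        for stage, (medium, delays) in media.items():
            traces = apply_bandwidth(simulate_propagation(p0, medium, sensor))
            image = das_reconstruct(traces, delays)
            out[f"{kind}:{stage}"] = image.amplitude
            row[stage] = image.amplitude[70, 120]
        print(f"{kind:<22} {row['recon_homo']:.4e}       {row['recon_hetero']:.4e}")
    np.savez_compressed(args.out / "recon.npz", **out)
    print(f"wrote {args.out / 'recon.npz'}")


if __name__ == "__main__":
    main()
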