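#!/usr/bin/env python
"""Transient-pocket screening across the five states.

Runs the grid-based cavity scan (1 Å spacing, 1.4 Å probe, six-direction
buriedness) on strided frames of every state and tracks the component
seeded at the pocket-lining residues (R460-S524 set).  The gated cryptic
pocket should open intermittently in the non-phosphorylated state only.
Writes volume time series under results/pocket/.
"""

from pathlib import Path

import pandas as pd

from kinastate.cavity import track_pocket
from kinastate.io import STATE_LABELS, read_structure, read_trajectory
from kinastate.synthetic import GeneratorConfig, build_topology

SRC = Path("results/synthetic")
OUT = Path("results/pocket")
STRIDE = 10


def main() -> None:
    if not (SRC / "topology.pdb").exists():
        raise SystemExit("run analysis/01_simulate_panel.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    top, _ = read_structure(SRC / "topology.pdb")
    _, roles, _ = build_topology(GeneratorConfig(n_frames=2))

    print(f"{'state':7s} {'open fraction':14s} {'max volume (A^3)':16s}")
    for state in STATE_LABELS:
        traj = read_trajectory(SRC / f"{state}.dcd", top)
        track = track_pocket(traj, top, roles, stride=STRIDE)
        pd.DataFrame({
            "time_ns": track.times,
            "volume_A3": track.volumes,
            "open": track.open_series.astype(int),
        }).to_csv(OUT / f"pocket_{state}.csv", index=False,
                  float_format="%.4f")
        print(f"{state:7s} {track.open_fraction:14.2f} {track.max_volume:16.0f}")


if __name__ == "__main__":
    main()
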