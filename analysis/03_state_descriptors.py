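#!/usr/bin/env python
"""Geometric descriptor panel and activation-state fingerprints.

Computes, per state: DFG cyclization distance, αC-helix-to-C-lobe COM
distance, the K369-E386 salt bridge and the remaining named contacts; then
classifies every frame into the three-state DFG scheme (closed ≈3 Å /
semi-closed ≈6 Å / open ≈8 Å) and the αC positioning states.  Writes tidy
CSVs and fingerprint JSONs under results/descriptors/ and prints the
qualitative state table.
"""

import json
from pathlib import Path

from kinastate.descriptors import descriptor_panel, write_series_csv
from kinastate.fingerprint import fingerprint_trajectory
from kinastate.io import STATE_LABELS, read_structure, read_trajectory
from kinastate.synthetic import GeneratorConfig, build_topology

SRC = Path("results/synthetic")
OUT = Path("results/descriptors")


def main() -> None:
    if not (SRC / "topology.pdb").exists():
        raise SystemExit("run analysis/01_simulate_panel.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    top, _ = read_structure(SRC / "topology.pdb")
    _, roles, _ = build_topology(GeneratorConfig(n_frames=2))

    print(f"{'state':7s} {'DFG':12s} {'alphaC':13s} {'bridge':6s}")
    for state in STATE_LABELS:
        traj = read_trajectory(SRC / f"{state}.dcd", top)
        traj.state_label = state
        panel = descriptor_panel(traj, top, roles)
        write_series_csv(panel, OUT / f"descriptors_{state}.csv")
        fp = fingerprint_trajectory(panel, state_label=state)
        (OUT / f"fingerprint_{state}.json").write_text(
            json.dumps(fp.to_dict(), indent=2, sort_keys=True))
        print(f"{state:7s} {fp.dominant_dfg:12s} {fp.dominant_alphac:13s} "
              f"{fp.saltbridge_occupancy:.2f}")


if __name__ == "__main__":
    main()
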