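"""Per-frame conformational-state classification from the descriptor panel.

The DFG motif is scored on the D479-carboxylate-carbon-to-G481-amide-H
distance against the three reference levels reported for kinase domains —
closed ≈ 3 Å, semi-closed ≈ 6 Å, open ≈ 8 Å — using midpoint decision
boundaries (4.5 and 7.0 Å by default).  The αC helix is scored on its
C-lobe centre-of-mass distance against the buried (≈13.5 Å), intermediate
(≈14.5–15 Å) and displaced (≈15.5 Å) levels with midpoint boundaries 14.25
and 15.25 Å.  Boundaries are a stated convention (the underlying study
reports state centres, not decision rules) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorSeries

__all__ = [
    "DFG_STATES",
    "ALPHAC_STATES",
    "FingerprintConfig",
    "Fingerprint",
    "classify_dfg",
    "classify_alphac",
    "fingerprint_trajectory",
]

DFG_STATES = ("closed", "semi_closed", "open")
ALPHAC_STATES = ("buried", "intermediate", "displaced")


@dataclass(frozen=True)
class FingerprintConfig:
    """Classification thresholds (Å).  Intervals are left-closed on the
    upper side: a distance exactly on a boundary belongs to the upper state."""

    dfg_closed_max: float = 4.5
    dfg_semi_max: float = 7.0
    alphac_buried_max: float = 14.25
    alphac_intermediate_max: float = 15.25
    saltbridge_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.dfg_closed_max < self.dfg_semi_max):
            raise ValueError("DFG boundaries must satisfy 0 < closed < semi")
        if not (0 < self.alphac_buried_max < self.alphac_intermediate_max):
            raise ValueError("αC boundaries must satisfy 0 < buried < intermediate")


def classify_dfg(
    distance, config: FingerprintConfig = FingerprintConfig()
):
    """Classify DFG cyclization distance(s) into closed / semi_closed / open."""
    d = np.asarray(distance, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("DFG distance must be >= 0")
    out = np.where(
        d < config.dfg_closed_max, "closed",
        np.where(d < config.dfg_semi_max, "semi_closed", "open"),
    )
    return out.item() if np.isscalar(distance) else out


def classify_alphac(
    distance, config: FingerprintConfig = FingerprintConfig()
):
    """Classify αC-to-C-lobe distance(s) into buried / intermediate / displaced."""
    d = np.asarray(distance, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("αC distance must be >= 0")
    out = np.where(
        d < config.alphac_buried_max, "buried",
        np.where(d < config.alphac_intermediate_max, "intermediate", "displaced"),
    )
    return out.item() if np.isscalar(distance) else out


@dataclass
class Fingerprint:
    """Per-frame classifications plus trajectory-level summaries."""

    state_label: str
    dfg_states: np.ndarray
    alphac_states: np.ndarray
    saltbridge: np.ndarray
    dfg_occupancy: dict
    alphac_occupancy: dict
    dominant_dfg: str
    dominant_alphac: str
    saltbridge_occupancy: float
    mean_alphac: float
    mean_dfg: float
    config: FingerprintConfig = field(default_factory=FingerprintConfig)

    def to_dict(self) -> dict:
        return {
            "state_label": self.state_label,
            "dfg_occupancy": self.dfg_occupancy,
            "alphac_occupancy": self.alphac_occupancy,
            "dominant_dfg": self.dominant_dfg,
            "dominant_alphac": self.dominant_alphac,
            "saltbridge_occupancy": self.saltbridge_occupancy,
            "mean_alphac": self.mean_alphac,
            "mean_dfg": self.mean_dfg,
            "n_frames": int(len(self.dfg_states)),
            "thresholds": {
                "dfg": [self.config.dfg_closed_max, self.config.dfg_semi_max],
                "alphac": [self.config.alphac_buried_max,
                           self.config.alphac_intermediate_max],
                "saltbridge_cutoff": self.config.saltbridge_cutoff,
            },
        }


def _occupancy(states: np.ndarray, order: tuple) -> dict:
    n = len(states)
    return {s: float(np.count_nonzero(states == s)) / n for s in order}


def _dominant(occ: dict, order: tuple) -> str:
    # ties broken toward the more closed/buried state (earlier in order)
    best = max(occ.values())
    for s in order:
        if occ[s] == best:
            return s
    raise AssertionError("unreachable")


def fingerprint_trajectory(
    panel: list[DescriptorSeries],
    config: FingerprintConfig = FingerprintConfig(),
    state_label: str = "custom",
) -> Fingerprint:
    """Classify every frame of a descriptor panel and summarise.

    Requires the ``dfg_cyclization``, ``alphaC_clobe`` and ``sb_K369_E386``
    series.  DFG occupancy fractions form an exact partition (they sum to 1).
    """
    by_name = {s.name: s for s in panel}
    for required in ("dfg_cyclization", "alphaC_clobe", "sb_K369_E386"):
        if required not in by_name:
            raise ValueError(f"descriptor panel is missing series {required!r}")
    dfg = by_name["dfg_cyclization"].values
    ac = by_name["alphaC_clobe"].values
    sb = by_name["sb_K369_E386"].values
    dfg_states = classify_dfg(dfg, config)
    ac_states = classify_alphac(ac, config)
    bridge = sb < config.saltbridge_cutoff
    dfg_occ = _occupancy(dfg_states, DFG_STATES)
    ac_occ = _occupancy(ac_states, ALPHAC_STATES)
    return Fingerprint(
        state_label=state_label,
        dfg_states=dfg_states,
        alphac_states=ac_states,
        saltbridge=bridge,
        dfg_occupancy=dfg_occ,
        alphac_occupancy=ac_occ,
        dominant_dfg=_dominant(dfg_occ, DFG_STATES),
        dominant_alphac=_dominant(ac_occ, ALPHAC_STATES),
        saltbridge_occupancy=float(bridge.mean()),
        mean_alphac=float(ac.mean()),
        mean_dfg=float(dfg.mean()),
        config=config,
    )
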