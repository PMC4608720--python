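"""Synthetic kinase-domain ensembles with planted, analytically known structure.

The generator builds a schematic two-lobe Cα scaffold (author numbering
336–600, the ZAP-70 kinase-domain convention) decorated with pseudo
side-chain atoms for every functional role, and simulates seeded
trajectories in which the quantities the analysis stack measures are planted
exactly:

* the DFG cyclization distance (D479 carboxylate carbon → G481 amide H) and
  the αC-helix-to-C-lobe centre-of-mass distance follow mean-reverting
  Ornstein–Uhlenbeck processes around state-specific targets, optionally
  with a scheduled mean shift (the mono-phosphorylated YP_Y0 transition);
* the K369–E386 salt bridge follows a two-state telegraph process whose
  stationary occupancy equals the profile value, realised as formed (3.0 Å)
  / broken (8.0 Å) geometries;
* collective motions displace Cα atoms along fixed orthonormal direction
  vectors with sinusoid-plus-noise amplitudes;
* a sealed cubic pocket of analytically known volume (5×5×5 Å by default)
  on the C-lobe surface is filled or vacated by the W505 gate pseudo-atom,
  toggled by a dwell-time telegraph process (non-phosphorylated state only
  by default).

Everything is a pure function of (profile, config): identical seeds give
bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import NamedTuple

import numpy as np

from .io import (
    ResidueRoles,
    RoleSpec,
    STATE_LABELS,
    Topology,
    Trajectory,
    default_role_map,
)

__all__ = [
    "Schedule",
    "StateProfile",
    "GeneratorConfig",
    "default_profiles",
    "build_topology",
    "reference_frame",
    "planted_mode_directions",
    "simulate_state",
    "simulate_panel",
    "CAVITY_EDGE",
]

FIRST_RESID = 336
LAST_RESID = 600
MIN_RESIDUES = LAST_RESID - FIRST_RESID + 1  # all roles must be hosted

HELIX_RANGE = (379, 392)
LOOP_RANGE = (479, 500)          # DFG through seven residues past Y493
FLAP_RANGE = (537, 569)
LOBE_SPLIT = 459                 # N-lobe 336–458, C-lobe 459–600

LATTICE = 3.8                    # Cα–Cα lattice constant of the blobs, Å
CAVITY_EDGE = 5.0                # edge of the planted cubic pocket, Å
_BOX_CENTER = np.array([0.0, 19.0, 0.0])
_WALL_OFFSET = CAVITY_EDGE / 2 + 3.1   # wall plane tangent to the void
_GATE_IN = _BOX_CENTER
_GATE_OUT = _BOX_CENTER + np.array([0.0, 0.0, -10.5])
# W505 side chain as a rigid indole-like heavy-atom cluster: one central
# nitrogen plus ring carbons toward the corners of the planted cube, so the
# "in" position fully occludes the void at any grid alignment
_GATE_CLUSTER = [("NE1", np.zeros(3))] + [
    (name, 1.3 * np.array(sgn, dtype=float))
    for name, sgn in zip(
        ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
        [(sx, sy, sz) for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    )
]
_ANCHOR = np.array([0.0, 14.0, 6.0])   # pseudo ATP-site anchor
_NLOBE_CENTER = np.array([0.0, 0.0, 30.0])

SB_FORMED = 3.0                  # Å, NZ–OE1 when the salt bridge is formed
SB_BROKEN = 8.0                  # Å, when broken
MODE_PERIODS = (4.0, 5.0, 6.0, 7.0)   # ns, planted collective-mode periods
MODE_NOISE_SD = 0.3              # Å, noise on planted mode amplitudes
_MODE_SEED = 982451653           # fixed: mode directions shared across states

_ELEMENT_OF = {
    "CA": "C", "CG": "C", "CZ": "C", "N": "N", "H": "H", "NZ": "N",
    "OE1": "O", "OE2": "O", "ND2": "N", "OG": "O", "NH1": "N", "OH": "O",
    "NE1": "N", "OD1": "O", "C1": "C",
}

_ROLE_RESNAMES = {
    348: "ASN", 369: "LYS", 379: "ASP", 386: "GLU", 390: "MET", 460: "ARG",
    461: "ASP", 462: "LEU", 463: "ALA", 479: "ASP", 480: "PHE", 481: "GLY",
    492: "TYR", 493: "TYR", 496: "ARG", 497: "SER", 500: "LYS", 501: "TRP",
    502: "PRO", 505: "TRP", 506: "TYR", 514: "ARG", 524: "SER",
}


class Schedule(NamedTuple):
    """Piecewise-constant mean: ``start`` before fraction ``at``, then ``end``."""

    start: float
    end: float
    at: float


@dataclass(frozen=True)
class StateProfile:
    """Target descriptor statistics of one kinase conformational state."""

    name: str
    dfg_mean: float | Schedule = 5.0
    dfg_sd: float = 0.3
    alphaC_mean: float | Schedule = 14.5
    alphaC_sd: float = 0.3
    saltbridge_occupancy: float = 0.5
    switching_rate: float = 20.0         # 1/ns, inverse correlation time
    loop_flex_scale: float = 1.0
    mode_amplitudes: tuple = ()          # ((mode id, amplitude Å), ...)
    pocket_gating: str = "off"           # "off" | "gated"
    gate_open_dwell: float = 2.0         # ns
    gate_close_dwell: float = 2.0        # ns

    def __post_init__(self) -> None:
        if not 0.0 <= self.saltbridge_occupancy <= 1.0:
            raise ValueError("saltbridge_occupancy must lie in [0, 1]")
        if self.dfg_sd < 0 or self.alphaC_sd < 0:
            raise ValueError("profile standard deviations must be >= 0")
        if any(a < 0 for _, a in self.mode_amplitudes):
            raise ValueError("mode amplitudes must be >= 0")
        if self.pocket_gating not in ("off", "gated"):
            raise ValueError("pocket_gating must be 'off' or 'gated'")
        for sched in (self.dfg_mean, self.alphaC_mean):
            if isinstance(sched, Schedule) and not 0.0 <= sched.at <= 1.0:
                raise ValueError(
                    f"schedule transition time {sched.at} outside [0, 1]"
                )


@dataclass(frozen=True)
class GeneratorConfig:
    """Size, timestep and noise of a generated ensemble."""

    n_frames: int = 15000
    dt: float = 0.1       # ns per frame (100 ps saving interval)
    seed: int = 0
    n_residues: int = MIN_RESIDUES
    noise_sd: float = 0.3  # Å, baseline thermal jitter
    ou_tau: float = 1.0    # ns, relaxation time of the OU descriptors

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_profiles() -> dict:
    """The five canonical phosphorylation-state profiles.

    Descriptor targets follow the reported per-state traces: the inhibited
    complex holds a closed DFG (3 Å) with a permanent K369–E386 bridge and
    the αC helix at 15 Å from the C-lobe; the non-phosphorylated ATP state
    sits semi-closed (5 Å) with a ~50% intermittent bridge; YP_Y0 opens
    (5→8 Å) at 0.4 of the run with the αC shifting 13.5→14.5 Å at one
    third; Y493-containing states lose the bridge and displace the αC helix
    to 15.5 Å, with YP_YP fully open at 8 Å.  Only the non-phosphorylated
    state gates the cryptic pocket.
    """
    return {
        "STA": StateProfile(
            "STA", dfg_mean=3.0, alphaC_mean=15.0, saltbridge_occupancy=1.0,
            loop_flex_scale=1.0, mode_amplitudes=(),
        ),
        "Y0Y0": StateProfile(
            "Y0Y0", dfg_mean=5.0, alphaC_mean=14.5, saltbridge_occupancy=0.5,
            loop_flex_scale=1.2, mode_amplitudes=((3, 2.0),),
            pocket_gating="gated",
        ),
        "YP_Y0": StateProfile(
            "YP_Y0", dfg_mean=Schedule(5.0, 8.0, 0.4),
            alphaC_mean=Schedule(13.5, 14.5, 1 / 3),
            saltbridge_occupancy=0.1, loop_flex_scale=2.0,
            mode_amplitudes=((0, 3.0), (2, 2.0)),
        ),
        "Y0_YP": StateProfile(
            "Y0_YP", dfg_mean=5.0, alphaC_mean=15.5, saltbridge_occupancy=0.0,
            loop_flex_scale=2.5, mode_amplitudes=((0, 3.0), (1, 2.0)),
        ),
        "YP_YP": StateProfile(
            "YP_YP", dfg_mean=8.0, alphaC_mean=15.5, saltbridge_occupancy=0.0,
            loop_flex_scale=3.0, mode_amplitudes=((0, 1.5), (1, 1.5)),
        ),
    }


# ---------------------------------------------------------------------------
# scaffold construction


def _lattice_blob(center: np.ndarray, n_sites: int) -> np.ndarray:
    """Deterministic compact blob: the ``n_sites`` cubic-lattice points
    closest to ``center``.  Sphere coverage at this lattice constant leaves
    no interior voids at a 1.4 Å probe."""
    g = np.arange(-7, 8)
    pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts * LATTICE
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], np.linalg.norm(pts, axis=1)))
    return pts[order[:n_sites]] + center


def _wall_atoms() -> np.ndarray:
    """Atom centres of the six sealed faces around the planted cubic void."""
    lat = np.array([-4.0, -2.0, 0.0, 2.0, 4.0])
    walls = []
    for axis in range(3):
        for sign in (-1.0, 1.0):
            for a in lat:
                for b in lat:
                    p = np.zeros(3)
                    p[axis] = sign * _WALL_OFFSET
                    p[(axis + 1) % 3] = a
                    p[(axis + 2) % 3] = b
                    walls.append(_BOX_CENTER + p)
    return np.asarray(walls)


class _Scaffold(NamedTuple):
    topology: Topology
    roles: ResidueRoles
    ref: np.ndarray                 # (n_atoms, 3) gate-in reference
    ca_indices: np.ndarray
    noise_scale_tag: np.ndarray     # 0 = rigid, 1 = baseline, 2 = loop/flap
    helix_atoms: np.ndarray         # all atoms of helix residues
    helix_ca: np.ndarray
    clobe_ca: np.ndarray
    idx: dict                       # role atom index shortcuts
    dfg_dir: np.ndarray
    gate_indices: np.ndarray        # the W505 side-chain cluster atoms
    gate_offsets: np.ndarray        # cluster offsets from the gate centre
    gate_in: np.ndarray
    gate_out: np.ndarray


@lru_cache(maxsize=4)
def _scaffold(n_residues: int) -> _Scaffold:
    if n_residues < MIN_RESIDUES:
        raise ValueError(
            f"n_residues={n_residues} too small to host all functional "
            f"roles; minimum is {MIN_RESIDUES} (residues {FIRST_RESID}-"
            f"{LAST_RESID} in author numbering)"
        )
    resid_list = list(range(FIRST_RESID, FIRST_RESID + n_residues))
    helix = set(range(HELIX_RANGE[0], HELIX_RANGE[1] + 1))
    loop = set(range(LOOP_RANGE[0], LOOP_RANGE[1] + 1))
    flap = set(range(FLAP_RANGE[0], FLAP_RANGE[1] + 1))
    nlobe = [r for r in resid_list if r < LOBE_SPLIT and r not in helix]
    clobe = [r for r in resid_list
             if r >= LOBE_SPLIT and r not in loop and r != 505]

    ca_pos: dict[int, np.ndarray] = {}
    for r, p in zip(nlobe, _lattice_blob(_NLOBE_CENTER, len(nlobe))):
        ca_pos[r] = p
    for r, p in zip(clobe, _lattice_blob(np.zeros(3), len(clobe))):
        ca_pos[r] = p
    ca_pos[505] = np.array([0.0, 10.5, -2.0])  # gate residue, near the box

    # αC helix: straight 1.5 Å-rise segment along x in the inter-lobe gap
    helix_ids = sorted(helix)
    for k, r in enumerate(helix_ids):
        ca_pos[r] = np.array([1.5 * (k - len(helix_ids) / 2), 0.0, 14.5])

    # activation loop: arc on the C-lobe surface ending at the pocket box
    loop_ids = sorted(loop)
    t = np.linspace(0.0, 1.0, len(loop_ids))
    theta = np.deg2rad(20.0 + 70.0 * t)
    phi = np.deg2rad(80.0 + 20.0 * t)
    arc = 12.8 * np.stack([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ], axis=1)
    for r, p in zip(loop_ids, arc):
        ca_pos[r] = p

    def outward(r: int) -> np.ndarray:
        center = _NLOBE_CENTER if r < LOBE_SPLIT else np.zeros(3)
        v = ca_pos[r] - center
        n = np.linalg.norm(v)
        return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])

    # per-residue extra atoms (appended after CA, in listed order)
    g481 = ca_pos[481]
    g481_n = g481 + 1.2 * outward(481)
    dfg_dir = (g481_n - np.zeros(3))
    dfg_dir = dfg_dir / np.linalg.norm(dfg_dir)
    g481_h = g481_n + 1.0 * dfg_dir
    oe1 = ca_pos[386] + np.array([0.0, -1.5, 0.0])
    extras: dict[int, list[tuple[str, np.ndarray]]] = {
        479: [("CG", g481_h + 5.0 * dfg_dir)],
        480: [("CZ", ca_pos[480] + 1.5 * outward(480))],
        481: [("N", g481_n), ("H", g481_h)],
        369: [("NZ", oe1 + SB_FORMED * np.array([0.0, 0.0, 1.0]))],
        386: [("OE1", oe1), ("OE2", oe1 + np.array([2.2, 0.0, 0.0]))],
        390: [("N", ca_pos[390] + np.array([0.0, 1.2, 0.0]))],
        379: [("OD1", ca_pos[379] + np.array([0.0, -1.8, 0.0]))],
        496: [("NH1", ca_pos[496] + 1.8 * outward(496))],
        348: [("ND2", ca_pos[348] + 1.5 * outward(348))],
        497: [("OG", ca_pos[497] + 1.4 * outward(497))],
        514: [("NH1", ca_pos[514] + 1.8 * outward(514))],
        492: [("OH", ca_pos[492] + 1.6 * outward(492))],
        493: [("OH", ca_pos[493] + 1.6 * outward(493))],
        505: [(name, _GATE_IN + off) for name, off in _GATE_CLUSTER],
    }
    walls = _wall_atoms()
    pocket = (460, 461, 462, 463, 500, 501, 502, 505, 506, 524)
    per_res = len(walls) // len(pocket)
    for k, r in enumerate(pocket):
        chunk = walls[k * per_res:(k + 1) * per_res]
        extras.setdefault(r, [])
        extras[r].extend((f"CW{j + 1}", c) for j, c in enumerate(chunk))

    names, resnames, resids, elements, coords, tags = [], [], [], [], [], []
    for r in resid_list:
        resname = _ROLE_RESNAMES.get(r, "ALA")
        atoms = [("CA", ca_pos[r])] + extras.get(r, [])
        for name, pos in atoms:
            names.append(name)
            resnames.append(resname)
            resids.append(r)
            el = _ELEMENT_OF.get(name, "C")
            elements.append(el)
            coords.append(pos)
            if name.startswith("CW") or (r == 505 and name != "CA"):
                tags.append(0)          # rigid pocket scaffold / gate
            elif r in loop or r in flap:
                tags.append(2)          # flexible segments
            else:
                tags.append(1)
    # pseudo ATP-site anchor, a single carbon "ligand"
    names.append("C1")
    resnames.append("LIG")
    resids.append(700)
    elements.append("C")
    coords.append(_ANCHOR.copy())
    tags.append(0)

    from .io import default_element_table

    table = default_element_table()
    topology = Topology(
        names=np.asarray(names, dtype=object),
        resnames=np.asarray(resnames, dtype=object),
        resids=np.asarray(resids, dtype=np.int64),
        elements=np.asarray(elements, dtype=object),
        masses=np.asarray([table["masses"][e] for e in elements]),
        vdw_radii=np.asarray([table["radii"][e] for e in elements]),
    )
    ref = np.asarray(coords, dtype=np.float64)
    roles = default_role_map()
    roles = ResidueRoles({**roles.roles, "ATP_ANCHOR": RoleSpec((700,), ("C1",))})
    roles.validate(topology)

    resids_arr = topology.resids
    names_arr = topology.names
    ca_indices = topology.ca_indices()
    helix_mask = np.isin(resids_arr, sorted(helix))
    idx = {
        "dfg_cg": topology.atom_index(479, "CG"),
        "g481_h": topology.atom_index(481, "H"),
        "nz": topology.atom_index(369, "NZ"),
        "oe1": topology.atom_index(386, "OE1"),
    }
    gate_indices = np.array(
        [topology.atom_index(505, name) for name, _ in _GATE_CLUSTER]
    )
    gate_offsets = np.stack([off for _, off in _GATE_CLUSTER])
    clobe_ca = np.flatnonzero(
        (resids_arr >= 463) & (resids_arr <= 600) & (names_arr == "CA")
    )
    helix_ca = np.flatnonzero(helix_mask & (names_arr == "CA"))
    return _Scaffold(
        topology=topology,
        roles=roles,
        ref=ref,
        ca_indices=ca_indices,
        noise_scale_tag=np.asarray(tags, dtype=np.int8),
        helix_atoms=np.flatnonzero(helix_mask),
        helix_ca=helix_ca,
        clobe_ca=clobe_ca,
        idx=idx,
        dfg_dir=dfg_dir,
        gate_indices=gate_indices,
        gate_offsets=gate_offsets,
        gate_in=_GATE_IN.copy(),
        gate_out=_GATE_OUT.copy(),
    )


def build_topology(config: GeneratorConfig) -> tuple[Topology, ResidueRoles, np.ndarray]:
    """Build the coarse kinase-domain scaffold.

    Returns the topology, a fully resolvable role map, and the reference
    frame (gate atom in its "in" position, filling the planted pocket).
    """
    s = _scaffold(config.n_residues)
    return s.topology, s.roles, s.ref.copy()


def reference_frame(n_residues: int = MIN_RESIDUES, gate: str = "in") -> np.ndarray:
    """Reference coordinates with the gate residue "in" (pocket filled) or
    "out" (pocket vacated, exposing the planted 5×5×5 Å void)."""
    s = _scaffold(n_residues)
    ref = s.ref.copy()
    if gate == "out":
        ref[s.gate_indices] = s.gate_out + s.gate_offsets
    elif gate != "in":
        raise ValueError("gate must be 'in' or 'out'")
    return ref


def planted_mode_directions(n_residues: int = MIN_RESIDUES, k: int = 4) -> np.ndarray:
    """The ``k`` fixed orthonormal Cα-space mode directions (k, n_ca, 3).

    Deterministic per topology and shared by all states; orthogonalised
    against the six rigid-body motions of the reference so alignment does
    not mix them.
    """
    s = _scaffold(n_residues)
    ca = s.ref[s.ca_indices]
    n_ca = len(ca)
    rng = np.random.default_rng(_MODE_SEED + n_ca)
    # rigid-body basis: 3 translations + 3 rotations about the Cα centroid
    centered = ca - ca.mean(axis=0)
    rigid = []
    for ax in range(3):
        t = np.zeros((n_ca, 3))
        t[:, ax] = 1.0
        rigid.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        rigid.append(np.cross(centered, e).ravel())
    basis = np.stack(rigid, axis=1)
    q, _ = np.linalg.qr(basis)
    # draw direction-by-direction so direction j is identical no matter how
    # many directions are requested (states share the same mode basis)
    raw = rng.standard_normal((k, 3 * n_ca)).T
    raw -= q @ (q.T @ raw)
    vecs, _ = np.linalg.qr(raw)
    return vecs.T.reshape(k, n_ca, 3)


# ---------------------------------------------------------------------------
# stochastic processes


def _ou_series(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: float,
    dt: float,
    tau: float,
) -> np.ndarray:
    """Ornstein–Uhlenbeck path with stationary sd ``sd``, tracking ``mean``."""
    n = len(mean)
    if sd == 0.0:
        return mean.copy()
    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1.0 - a * a)
    shocks = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = mean[0] + sd * shocks[0]
    for i in range(1, n):
        x[i] = mean[i] + a * (x[i - 1] - mean[i]) + b * shocks[i]
    return x


def _telegraph(
    rng: np.random.Generator,
    n: int,
    dt: float,
    occupancy: float,
    rate: float,
    start: bool | None = None,
) -> np.ndarray:
    """Two-state telegraph path with stationary P(on) = ``occupancy``.

    Rates are ``k_on = rate * occupancy`` (off→on) and ``k_off = rate *
    (1 - occupancy)``, so ``rate`` is the inverse correlation time.
    """
    if occupancy <= 0.0:
        return np.zeros(n, dtype=bool)
    if occupancy >= 1.0:
        return np.ones(n, dtype=bool)
    # exact CTMC propagator over one frame interval: preserves the
    # stationary law at any dt (naive 1-exp(-k dt) hazards do not)
    decay = np.exp(-rate * dt)
    p_up = occupancy * (1.0 - decay)
    p_dn = (1.0 - occupancy) * (1.0 - decay)
    u = rng.random(n)
    out = np.empty(n, dtype=bool)
    state = bool(u[0] < occupancy) if start is None else start
    out[0] = state
    for i in range(1, n):
        if state:
            state = not (u[i] < p_dn)
        else:
            state = bool(u[i] < p_up)
        out[i] = state
    return out


def _dwell_telegraph(
    rng: np.random.Generator,
    n: int,
    dt: float,
    open_dwell: float,
    close_dwell: float,
) -> np.ndarray:
    """Open/closed telegraph with given mean dwell times (ns); starts closed."""
    k_open = 1.0 / close_dwell
    k_close = 1.0 / open_dwell
    pi_open = k_open / (k_open + k_close)
    decay = np.exp(-(k_open + k_close) * dt)
    p_open = pi_open * (1.0 - decay)
    p_close = (1.0 - pi_open) * (1.0 - decay)
    u = rng.random(n)
    out = np.empty(n, dtype=bool)
    state = False
    out[0] = state
    for i in range(1, n):
        state = (not (u[i] < p_close)) if state else bool(u[i] < p_open)
        out[i] = state
    return out


def _mean_array(target: float | Schedule, n: int) -> np.ndarray:
    if isinstance(target, Schedule):
        frac = np.arange(n) / max(n - 1, 1)
        return np.where(frac < target.at, target.start, target.end)
    return np.full(n, float(target))


# ---------------------------------------------------------------------------
# simulation


def simulate_state(profile: StateProfile, config: GeneratorConfig) -> Trajectory:
    """Simulate one state; a pure function of (profile, config)."""
    s = _scaffold(config.n_residues)
    n, dt = config.n_frames, config.dt
    rng = np.random.default_rng(config.seed)
    times = np.arange(n) * dt

    # planted scalar processes (drawn first, in fixed order)
    dfg = _ou_series(rng, _mean_array(profile.dfg_mean, n), profile.dfg_sd,
                     dt, config.ou_tau)
    dfg = np.abs(dfg)  # distances cannot go negative
    alphac = _ou_series(rng, _mean_array(profile.alphaC_mean, n),
                        profile.alphaC_sd, dt, config.ou_tau)
    bridge = _telegraph(rng, n, dt, profile.saltbridge_occupancy,
                        profile.switching_rate)
    if profile.pocket_gating == "gated":
        gate_open = _dwell_telegraph(rng, n, dt, profile.gate_open_dwell,
                                     profile.gate_close_dwell)
    else:
        gate_open = np.zeros(n, dtype=bool)

    # thermal noise; the pocket scaffold, gate and anchor stay rigid
    sd_per_atom = np.where(
        s.noise_scale_tag == 0, 0.0,
        np.where(s.noise_scale_tag == 2,
                 config.noise_sd * profile.loop_flex_scale, config.noise_sd),
    )
    coords = np.empty((n, s.topology.n_atoms, 3))
    coords[:] = s.ref
    coords += rng.standard_normal(coords.shape) * sd_per_atom[None, :, None]

    # planted collective modes on Cα atoms
    amplitudes: dict[int, np.ndarray] = {}
    if profile.mode_amplitudes:
        dirs = planted_mode_directions(config.n_residues,
                                       k=max(m for m, _ in profile.mode_amplitudes) + 1)
        for mode_id, amp in profile.mode_amplitudes:
            period = MODE_PERIODS[mode_id % len(MODE_PERIODS)]
            phase = rng.uniform(0.0, 2.0 * np.pi)
            a = amp * np.sin(2.0 * np.pi * times / period + phase)
            a = a + MODE_NOISE_SD * rng.standard_normal(n)
            amplitudes[mode_id] = a
            coords[:, s.ca_indices, :] += a[:, None, None] * dirs[mode_id][None]

    # αC helix: rigidly translate so its Cα COM sits at the planted distance
    # from the C-lobe Cα COM, along +z (the inter-lobe axis)
    clobe_com = coords[:, s.clobe_ca, :].mean(axis=1)
    helix_com = coords[:, s.helix_ca, :].mean(axis=1)
    target = clobe_com + alphac[:, None] * np.array([0.0, 0.0, 1.0])
    shift = target - helix_com
    coords[:, s.helix_atoms, :] += shift[:, None, :]

    # exact role-atom placements (after the helix has moved)
    coords[:, s.idx["dfg_cg"], :] = (
        coords[:, s.idx["g481_h"], :] + dfg[:, None] * s.dfg_dir
    )
    sb_dist = np.where(bridge, SB_FORMED, SB_BROKEN)
    coords[:, s.idx["nz"], :] = (
        coords[:, s.idx["oe1"], :] + sb_dist[:, None] * np.array([0.0, 0.0, 1.0])
    )
    centers = np.where(gate_open[:, None], s.gate_out[None, :],
                       s.gate_in[None, :])
    coords[:, s.gate_indices, :] = (
        centers[:, None, :] + s.gate_offsets[None, :, :]
    )

    return Trajectory(
        coords, times, state_label=profile.name,
        aux={
            "dfg": dfg, "alphaC": alphac, "bridge": bridge,
            "gate_open": gate_open, "mode_amplitudes": amplitudes,
            "seed": config.seed,
        },
    )


def simulate_panel(
    config: GeneratorConfig, profiles: dict | None = None
) -> dict:
    """Simulate the five default states with seeds ``seed + 0..4``.

    Returns a mapping ``state label -> Trajectory`` in canonical order.
    """
    profiles = profiles if profiles is not None else default_profiles()
    out = {}
    for i, (label, profile) in enumerate(profiles.items()):
        out[label] = simulate_state(profile, replace(config, seed=config.seed + i))
    return out
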