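"""Structure / trajectory I/O and atom selection.

In-memory conventions used across the package:

* coordinates are Angstrom, float64, shaped ``(n_frames, n_atoms, 3)``;
* times are nanoseconds and strictly increasing;
* residue numbering is the author (crystallographic) numbering of the input
  and is preserved end-to-end — atom *indices* are 0-based.

File formats are handled by MDAnalysis (PDB v3 coordinate records, CHARMM/
NAMD DCD, Gromacs XTC with nm→Å conversion, multi-model PDB as plain-text
trajectory fallback); this module owns the domain types, the validation
contracts and the minimal selection grammar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

__all__ = [
    "Topology",
    "Trajectory",
    "Selection",
    "RoleSpec",
    "ResidueRoles",
    "SelectionError",
    "StructureParseError",
    "TrajectoryFormatError",
    "default_element_table",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select_atoms",
    "subset_topology",
    "default_role_map",
    "STATE_LABELS",
]

#: canonical state labels of the five simulated kinase-domain systems
STATE_LABELS = ("STA", "Y0Y0", "YP_Y0", "Y0_YP", "YP_YP")

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL", "PTR", "SEP", "TPO",
}


class StructureParseError(ValueError):
    """A coordinate file could not be parsed."""


class SelectionError(ValueError):
    """A selection expression is invalid or references unknown roles."""


class TrajectoryFormatError(ValueError):
    """A trajectory file is inconsistent with the supplied topology."""


def default_element_table() -> dict:
    """Bundled per-element vdW radii (Å) and masses (Da)."""
    text = resources.files("kinastate.data").joinpath("vdw_radii.json").read_text()
    return json.loads(text)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Topology:
    """Atom-level topology with author residue numbering.

    All arrays have length ``n_atoms``.  ``(residue_id, atom_name)`` pairs are
    unique and residue ids are non-decreasing in atom order.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    vdw_radii: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("resnames", "resids", "elements", "masses", "vdw_radii"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology field {attr!r} has wrong length")
        if n == 0:
            raise ValueError("topology must contain at least one atom")
        if np.any(self.masses <= 0):
            raise ValueError("all atomic masses must be positive")
        if np.any(self.vdw_radii <= 0):
            raise ValueError("all vdW radii must be positive")
        if np.any(np.diff(self.resids) < 0):
            raise ValueError("residue ids must be non-decreasing in atom order")
        pairs = set(zip(self.resids.tolist(), self.names.tolist()))
        if len(pairs) != n:
            raise ValueError("(residue_id, atom_name) pairs must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue ids, in order of first appearance."""
        _, idx = np.unique(self.resids, return_index=True)
        return self.resids[np.sort(idx)]

    def ca_indices(self) -> np.ndarray:
        return np.flatnonzero(self.names == "CA")

    def atom_index(self, resid: int, name: str) -> int:
        hits = np.flatnonzero((self.resids == resid) & (self.names == name))
        if hits.size == 0:
            raise KeyError(f"no atom {name!r} in residue {resid}")
        return int(hits[0])


@dataclass
class Trajectory:
    """Cartesian trajectory (Å, ns) with a conformational-state label.

    ``aux`` carries optional per-frame ground-truth series attached by the
    synthetic generator (planted distances, telegraph/gate booleans); analysis
    code never reads it.
    """

    coordinates: np.ndarray
    times: np.ndarray
    state_label: str = "custom"
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if self.times.shape != (self.coordinates.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def check_topology(self, topology: Topology) -> None:
        if self.n_atoms != topology.n_atoms:
            raise TrajectoryFormatError(
                f"trajectory has {self.n_atoms} atoms but topology has "
                f"{topology.n_atoms}"
            )

    def slice_frames(self, sl: slice) -> "Trajectory":
        return Trajectory(
            self.coordinates[sl], self.times[sl], self.state_label,
            {k: (v[sl] if np.ndim(v) >= 1 and len(v) == self.n_frames else v)
             for k, v in self.aux.items()},
        )


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: expression plus sorted unique indices."""

    expression: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError("selection indices must be sorted, unique, non-negative")
        object.__setattr__(self, "indices", idx)

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_selected


# ---------------------------------------------------------------------------
# selection grammar
#
# expression := clause ('and' clause)*
# clause     := 'name' NAME+ | 'resid' (ID | ID-ID)+ | 'role' ROLE
#             | 'protein' | 'all'


def _parse_resid_token(tok: str, pos: int) -> tuple[int, int]:
    try:
        if "-" in tok.lstrip("-"):
            lo, hi = tok.split("-", 1) if not tok.startswith("-") else tok.rsplit("-", 1)
            return int(lo), int(hi)
        return int(tok), int(tok)
    except ValueError:
        raise SelectionError(
            f"invalid residue token {tok!r} at position {pos}"
        ) from None


def select_atoms(
    topology: Topology,
    expression: str,
    roles: "ResidueRoles | None" = None,
    allow_empty: bool = True,
) -> Selection:
    """Resolve a selection expression against a topology.

    The grammar is deliberately minimal: atom names, residue ids and ranges,
    named roles, ``protein``, ``all``, combined with ``and``.  Resolution is
    deterministic; an empty match is allowed but flagged with a warning.
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = np.ones(topology.n_atoms, dtype=bool)
    i = 0
    first = True
    while i < len(tokens):
        if not first:
            if tokens[i] != "and":
                raise SelectionError(
                    f"expected 'and' at token {i} ({tokens[i]!r}) in {expression!r}"
                )
            i += 1
            if i >= len(tokens):
                raise SelectionError("dangling 'and' at end of expression")
        first = False
        kw = tokens[i]
        if kw == "name":
            i += 1
            vals = []
            while i < len(tokens) and tokens[i] not in ("and",):
                vals.append(tokens[i])
                i += 1
            if not vals:
                raise SelectionError(f"'name' with no values at token {i}")
            mask &= np.isin(topology.names, vals)
        elif kw == "resid":
            i += 1
            sub = np.zeros(topology.n_atoms, dtype=bool)
            got = False
            while i < len(tokens) and tokens[i] not in ("and",):
                lo, hi = _parse_resid_token(tokens[i], i)
                sub |= (topology.resids >= lo) & (topology.resids <= hi)
                got = True
                i += 1
            if not got:
                raise SelectionError(f"'resid' with no values at token {i}")
            mask &= sub
        elif kw == "role":
            i += 1
            if i >= len(tokens):
                raise SelectionError("'role' with no role name")
            if roles is None:
                raise SelectionError("expression uses 'role' but no role map given")
            role_sel = roles.selection(topology, tokens[i])
            sub = np.zeros(topology.n_atoms, dtype=bool)
            sub[role_sel.indices] = True
            mask &= sub
            i += 1
        elif kw == "protein":
            mask &= np.isin(topology.resnames, sorted(_PROTEIN_RESNAMES))
            i += 1
        elif kw == "all":
            i += 1
        else:
            raise SelectionError(
                f"unknown keyword {kw!r} at token {i} in {expression!r}"
            )
    idx = np.flatnonzero(mask)
    if idx.size == 0 and allow_empty:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    elif idx.size == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return Selection(expression, idx)


# ---------------------------------------------------------------------------
# residue-role map


@dataclass(frozen=True)
class RoleSpec:
    """One functional role: residue id(s), optionally restricted to atoms."""

    resids: tuple[int, ...]
    atoms: tuple[str, ...] | None = None

    @classmethod
    def parse(cls, value) -> "RoleSpec":
        if isinstance(value, RoleSpec):
            return value
        if isinstance(value, int):
            return cls((value,))
        if isinstance(value, str) and "-" in value:
            lo, hi = value.split("-")
            return cls(tuple(range(int(lo), int(hi) + 1)))
        if isinstance(value, Mapping):
            spec = cls.parse(value["resid"])
            atoms = value.get("atoms") or value.get("atom")
            if atoms is not None:
                atoms = (atoms,) if isinstance(atoms, str) else tuple(atoms)
            return cls(spec.resids, atoms)
        if isinstance(value, Iterable):
            return cls(tuple(int(v) for v in value))
        raise SelectionError(f"cannot parse role spec {value!r}")


REQUIRED_ROLES = (
    "DFG_D", "DFG_F", "DFG_G", "SB_K", "SB_E", "HELIX_C", "CLOBE",
    "STA_SB_D", "STA_SB_R", "HB_N", "HB_S", "LOOP_R", "PY1", "PY2",
    "GATE_W", "FLAP", "POCKET",
)

#: the ten pocket-lining residues of the cryptic pocket
POCKET_RESIDUES = (460, 461, 462, 463, 500, 501, 502, 505, 506, 524)


def default_role_map() -> "ResidueRoles":
    """Role map for the ZAP-70 kinase domain in author numbering.

    DFG triad D479/F480/G481; regulatory salt bridge K369–E386; αC helix
    D379–Q392; inhibited-state contacts D379–R496, N348–S497, R514–Y493;
    phosphorylation sites Y492/Y493; gate residue W505; flap 537–569; the
    ten pocket-lining residues of the cryptic pocket.
    """
    return ResidueRoles({
        "DFG_D": RoleSpec((479,), ("CG",)),     # carboxylate carbon
        "DFG_F": RoleSpec((480,), ("CZ",)),
        "DFG_G": RoleSpec((481,), ("N", "H")),  # amide N and H
        "SB_K": RoleSpec((369,), ("NZ",)),
        "SB_E": RoleSpec((386,), ("OE1", "OE2")),
        "HELIX_C": RoleSpec(tuple(range(379, 393))),
        "CLOBE": RoleSpec(tuple(range(463, 601))),
        "STA_SB_D": RoleSpec((379,)),
        "STA_SB_R": RoleSpec((496,)),
        "HB_N": RoleSpec((348,)),
        "HB_S": RoleSpec((497,)),
        "LOOP_R": RoleSpec((514,)),
        "PY1": RoleSpec((492,)),
        "PY2": RoleSpec((493,)),
        "GATE_W": RoleSpec((505,)),
        "FLAP": RoleSpec(tuple(range(537, 570))),
        "POCKET": RoleSpec(POCKET_RESIDUES),
        "ALPHAC_M": RoleSpec((390,), ("N",)),   # backbone amide N of M390
    })


@dataclass(frozen=True)
class ResidueRoles:
    """Mapping from functional-role names to residues (and optional atoms)."""

    roles: dict

    def __post_init__(self) -> None:
        parsed = {k: RoleSpec.parse(v) for k, v in self.roles.items()}
        object.__setattr__(self, "roles", parsed)

    def __contains__(self, name: str) -> bool:
        return name in self.roles

    def __getitem__(self, name: str) -> RoleSpec:
        if name not in self.roles:
            raise SelectionError(
                f"unknown role {name!r}; known roles: {sorted(self.roles)}"
            )
        return self.roles[name]

    def selection(self, topology: Topology, name: str) -> Selection:
        spec = self[name]
        mask = np.isin(topology.resids, spec.resids)
        if spec.atoms is not None:
            mask &= np.isin(topology.names, spec.atoms)
        idx = np.flatnonzero(mask)
        return Selection(f"role {name}", idx)

    def validate(self, topology: Topology, required=REQUIRED_ROLES) -> None:
        """Check that every required role is present and resolves to atoms."""
        missing = [r for r in required if r not in self.roles]
        if missing:
            raise SelectionError(f"role map missing required roles: {missing}")
        for r in required:
            if self.selection(topology, r).n_selected == 0:
                raise SelectionError(f"role {r!r} resolves to no atoms")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ResidueRoles":
        return cls(dict(d))


# ---------------------------------------------------------------------------
# readers / writers


def _element_from_record(name: str, element_col: str) -> str:
    el = element_col.strip().upper()
    if el:
        return el
    # PDB convention: columns 13-14 hold the element, digits/primes stripped
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise StructureParseError(f"cannot infer element for atom name {name!r}")
    if stripped[0] in "H123456789":
        return "H"
    two = stripped[:2].upper()
    if two in ("CL", "BR", "MG", "ZN", "FE", "MN", "NA", "SE") and len(name.strip()) > 1:
        # only trust two-letter elements when the name is not a common
        # protein atom like CA/CB/CD (calcium vs alpha carbon ambiguity)
        if two not in ("CA", "CB", "CD", "CE", "CG", "CZ", "ND", "NE", "NH", "NZ", "OD", "OE", "OG", "OH", "SD", "SG"):
            return two
    return stripped[0].upper()


def _prescan_pdb(path: Path) -> None:
    """Light syntactic validation so parse errors can name the line."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureParseError(
                f"{path}: line {lineno}: coordinate record too short"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise StructureParseError(
                    f"{path}: line {lineno}: malformed {what} coordinate "
                    f"field {line[lo:hi]!r}"
                ) from None
        try:
            int(line[22:26])
        except ValueError:
            raise StructureParseError(
                f"{path}: line {lineno}: malformed residue number {line[22:26]!r}"
            ) from None


def read_structure(
    path, format: str = "pdb", element_table: dict | None = None
) -> tuple[Topology, Trajectory]:
    """Read a PDB file into a Topology plus its (first-model) coordinates.

    Keeps the first altloc of each atom (with a warning when alternates are
    dropped); assigns vdW radii and masses from the bundled element table;
    preserves author residue numbering verbatim.
    """
    path = Path(path)
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    table = element_table or default_element_table()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    altlocs = (
        atoms.altLocs if hasattr(atoms, "altLocs") else np.array([""] * len(atoms))
    )
    elements_col = (
        atoms.elements if hasattr(atoms, "elements") else np.array([""] * len(atoms))
    )
    keep, seen, dropped = [], set(), 0
    for i in range(len(atoms)):
        key = (int(atoms.resids[i]), atoms.names[i])
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        keep.append(i)
    if dropped:
        warnings.warn(
            f"{path.name}: kept first altloc only ({dropped} alternate "
            "location records dropped)", stacklevel=2,
        )
    keep = np.asarray(keep, dtype=np.intp)
    names = atoms.names[keep]
    elements, radii, masses = [], [], []
    for i, j in enumerate(keep):
        el = _element_from_record(names[i], str(elements_col[j]))
        if el not in table["radii"]:
            raise StructureParseError(
                f"unknown element {el!r} for atom {names[i]!r} in residue "
                f"{int(atoms.resids[j])} (no entry in the element table)"
            )
        elements.append(el)
        radii.append(table["radii"][el])
        masses.append(table["masses"][el])
    top = Topology(
        names=np.asarray(names, dtype=object),
        resnames=np.asarray(atoms.resnames[keep], dtype=object),
        resids=np.asarray(atoms.resids[keep], dtype=np.int64),
        elements=np.asarray(elements, dtype=object),
        masses=np.asarray(masses, dtype=np.float64),
        vdw_radii=np.asarray(radii, dtype=np.float64),
    )
    coords = atoms.positions[keep][None, :, :].astype(np.float64)
    traj = Trajectory(coords, np.array([0.0]))
    return top, traj


def _infer_format(path: Path, format: str | None) -> str:
    if format:
        return format.lower()
    suf = path.suffix.lower().lstrip(".")
    return {"pdb": "pdb", "dcd": "dcd", "xtc": "xtc"}.get(suf, suf)


def read_trajectory(
    path, topology: Topology, format: str | None = None, dt: float = 0.1
) -> Trajectory:
    """Read a DCD/XTC/multi-model-PDB trajectory against a known topology.

    Coordinates come back in Å regardless of on-disk units (XTC is stored in
    nm and converted).  Times are taken from file metadata when present and
    strictly increasing, otherwise synthesised as ``i * dt`` ns.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("pdb", "dcd", "xtc"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    frames, times = [], []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path), format=fmt.upper())
            for ts in u.trajectory:
                if ts.positions.shape[0] != topology.n_atoms:
                    raise TrajectoryFormatError(
                        f"{path.name}: frame has {ts.positions.shape[0]} atoms "
                        f"but topology has {topology.n_atoms}"
                    )
                frames.append(ts.positions.astype(np.float64).copy())
                times.append(float(ts.time))
    except (OSError, EOFError, ValueError, IndexError) as exc:
        if isinstance(exc, TrajectoryFormatError):
            raise
        if "incorrect number of atoms" in str(exc) or "Supplied" in str(exc):
            raise TrajectoryFormatError(
                f"{path.name}: atom count does not match topology "
                f"({topology.n_atoms} expected): {exc}"
            ) from exc
        raise TrajectoryFormatError(
            f"{path.name}: truncated or unreadable after frame "
            f"{len(frames) - 1}: {exc}"
        ) from exc
    if not frames:
        raise TrajectoryFormatError(f"{path.name}: no frames read")
    coords = np.stack(frames)
    times = np.asarray(times) / 1000.0  # MDAnalysis times are ps
    # PDB carries no time metadata; synthesise from the supplied stride
    if fmt == "pdb" or (times.size > 1 and not np.all(np.diff(times) > 0)):
        times = np.arange(len(frames)) * dt
    return Trajectory(coords, times)


def _make_universe(topology: Topology, coordinates: np.ndarray) -> "mda.Universe":
    resids_unique, resindex = np.unique(topology.resids, return_inverse=True)
    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=len(resids_unique),
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in topology.names])
    resnames = [""] * len(resids_unique)
    for i, ri in enumerate(resindex):
        resnames[ri] = str(topology.resnames[i])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids_unique)
    u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
    u.add_TopologyAttr("masses", topology.masses)
    u.atoms.positions = coordinates
    return u


def write_trajectory(
    traj: Trajectory, topology: Topology, path, format: str | None = None
) -> Path:
    """Write a trajectory as multi-model PDB, DCD, or XTC.

    Round-trips through :func:`read_trajectory` within format precision
    (PDB 1e-3 Å fixed-point, DCD float32, XTC ~1e-3 Å lossy compression).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("pdb", "dcd", "xtc"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty (0-frame) trajectory")
    traj.check_topology(topology)
    u = _make_universe(topology, traj.coordinates[0])
    dt_ps = float(np.median(np.diff(traj.times)) * 1000.0) if traj.n_frames > 1 else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            kwargs = {"multiframe": True}
        elif fmt == "xtc":
            # 10^4 fixed-point (1e-4 nm) ⇒ 1e-3 Å round-trip precision
            kwargs = {"dt": dt_ps, "precision": 4}
        else:
            kwargs = {"dt": dt_ps}
        with mda.Writer(str(path), n_atoms=topology.n_atoms, **kwargs) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[i]
                u.trajectory.ts.time = traj.times[i] * 1000.0
                u.trajectory.ts.frame = i
                u.trajectory.ts.dt = dt_ps
                w.write(u.atoms)
    return path


def subset_topology(topology: Topology, indices: np.ndarray) -> Topology:
    """Restrict a topology to the given (sorted) atom indices."""
    idx = np.asarray(indices, dtype=np.intp)
    return Topology(
        names=topology.names[idx],
        resnames=topology.resnames[idx],
        resids=topology.resids[idx],
        elements=topology.elements[idx],
        masses=topology.masses[idx],
        vdw_radii=topology.vdw_radii[idx],
    )


def write_structure(topology: Topology, coordinates: np.ndarray, path) -> Path:
    """Write a single frame as a PDB file."""
    traj = Trajectory(np.asarray(coordinates)[None, ...], np.array([0.0]))
    return write_trajectory(traj, topology, path, format="pdb")
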