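"""Trajectory and thermodynamic-table I/O.

Containers for MD trajectories of amorphous organic systems (frames of
Cartesian coordinates in an orthogonal periodic box), the system topology
(atom types, masses, charges, molecule membership and hydrogen-bond site
roles), and per-state-point thermodynamic time series.

Units in the analysis layer are Å, fs, K, kPa and kJ/mol throughout;
reduced-unit toy-simulator output is converted at the boundary by a
declared unit system (see :mod:`glassmd.synthetic`).

Supported on-disk formats are the LAMMPS text dump (``ITEM:`` blocks with
``id type x y z`` or scaled ``xs ys zs`` columns) and extended XYZ with an
orthogonal ``Lattice``.  Triclinic cells are rejected explicitly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "ThermoSeries",
    "TrajectoryError",
    "ParseError",
    "read_lammps_dump",
    "write_lammps_dump",
    "read_extxyz",
    "write_extxyz",
    "read_thermo_table",
    "read_topology",
    "write_topology",
]


class TrajectoryError(ValueError):
    """Structural problem with a trajectory or topology."""


class ParseError(TrajectoryError):
    """Malformed input file; carries the offending line or row where known."""


@dataclass
class Topology:
    """Per-atom static attributes and molecule membership.

    ``atom_type`` follows site-label conventions such as ``"O_Z"`` or
    ``"H_A/C1"`` so that reported contact pairs carry recognisable names.
    ``donor_flag`` marks hydrogen atoms that can donate a hydrogen bond;
    ``acceptor_flag`` marks acceptor heavy atoms (carbonyl O, ring N, ...).
    Masses are unified atomic mass units, charges elementary charges.
    """

    atom_type: np.ndarray          # (n,) str
    mass: np.ndarray               # (n,) float, u
    charge: np.ndarray             # (n,) float, e
    molecule_id: np.ndarray        # (n,) int
    molecule_name: np.ndarray      # (n,) str
    donor_flag: np.ndarray | None = None      # (n,) bool
    acceptor_flag: np.ndarray | None = None   # (n,) bool

    def __post_init__(self) -> None:
        n = len(self.mass)
        self.atom_type = np.asarray(self.atom_type, dtype=object)
        self.mass = np.asarray(self.mass, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.molecule_name = np.asarray(self.molecule_name, dtype=object)
        if self.donor_flag is None:
            self.donor_flag = np.zeros(n, dtype=bool)
        if self.acceptor_flag is None:
            self.acceptor_flag = np.zeros(n, dtype=bool)
        self.donor_flag = np.asarray(self.donor_flag, dtype=bool)
        self.acceptor_flag = np.asarray(self.acceptor_flag, dtype=bool)
        for arr in (self.atom_type, self.charge, self.molecule_id,
                    self.molecule_name, self.donor_flag, self.acceptor_flag):
            if len(arr) != n:
                raise TrajectoryError("topology arrays must share one length")
        if np.any(self.mass < 0):
            raise TrajectoryError("negative atomic mass")

    @property
    def n_atoms(self) -> int:
        return len(self.mass)

    def molar_masses(self) -> dict[str, float]:
        """Molar mass (g/mol) per molecule *name*, summed over one molecule.

        Raises if two molecules sharing a name disagree by more than 1e-6 u.
        """
        out: dict[str, float] = {}
        for mol in np.unique(self.molecule_id):
            sel = self.molecule_id == mol
            name = str(self.molecule_name[sel][0])
            m = float(self.mass[sel].sum())
            if name in out and abs(out[name] - m) > 1e-6:
                raise TrajectoryError(
                    f"inconsistent molar mass for molecule {name!r}")
            out[name] = m
        return out


@dataclass
class Frame:
    """One trajectory frame: time (fs), orthogonal box edges (Å), positions (Å)."""

    time: float
    box: np.ndarray          # (3,) edge lengths
    positions: np.ndarray    # (n, 3)
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.box.shape != (3,):
            raise TrajectoryError("box must be three orthogonal edge lengths")
        if np.any(self.box <= 0):
            raise TrajectoryError("box edges must be strictly positive")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrajectoryError("positions must be (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        """Box volume in Å³."""
        return float(np.prod(self.box))


@dataclass
class Trajectory:
    """Time-ordered frames plus optional topology and generator ground truth.

    ``ground_truth`` is a free-form record attached by the synthetic-data
    generators (e.g. the true diffusivity and the true unwrapped coordinates)
    so that estimators can be validated against known answers.
    """

    frames: list[Frame]
    topology: Topology | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory must contain at least one frame")
        n = self.frames[0].n_atoms
        times = [f.time for f in self.frames]
        if any(f.n_atoms != n for f in self.frames):
            raise TrajectoryError("atom count varies across frames")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrajectoryError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.positions for f in self.frames])

    def boxes_array(self) -> np.ndarray:
        return np.stack([f.box for f in self.frames])


@dataclass
class ThermoSeries:
    """Per-record thermodynamic series for one state point.

    Columns are temperature (K), pressure (kPa), volume (Å³), potential
    energy U and total enthalpy H (kJ/mol per simulation box).  Optional
    columns are ``None`` rather than silently zero.
    """

    time: np.ndarray
    temperature: np.ndarray | None = None
    pressure: np.ndarray | None = None
    volume: np.ndarray | None = None
    potential_energy: np.ndarray | None = None
    enthalpy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = len(self.time)
        for name in ("temperature", "pressure", "volume",
                     "potential_energy", "enthalpy"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != n:
                    raise TrajectoryError(f"column {name} length mismatch")
                setattr(self, name, v)
        if self.volume is not None and np.any(self.volume <= 0):
            raise TrajectoryError("volume must be positive")

    def __len__(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# LAMMPS text dump

_DUMP_COORD_SETS = (("x", "y", "z"), ("xs", "ys", "zs"),
                    ("xu", "yu", "zu"))


def read_lammps_dump(path: str | Path) -> Trajectory:
    """Read a LAMMPS text dump into a :class:`Trajectory`.

    Supports orthogonal boxes and unscaled (``x y z``), scaled (``xs ys zs``)
    or unwrapped (``xu yu zu``) coordinate columns; scaled coordinates are
    converted to Å via the box edges.  Atoms are re-ordered by id so the
    result is invariant to the on-file atom ordering.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    n_expect: int | None = None
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("ITEM: TIMESTEP"):
            raise ParseError(f"line {i + 1}: expected 'ITEM: TIMESTEP', got {line!r}")
        timestep = float(lines[i + 1].strip())
        i += 2
        if not lines[i].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError(f"line {i + 1}: expected 'ITEM: NUMBER OF ATOMS'")
        n_atoms = int(lines[i + 1].strip())
        i += 2
        if not lines[i].startswith("ITEM: BOX BOUNDS"):
            raise ParseError(f"line {i + 1}: expected 'ITEM: BOX BOUNDS'")
        if any(tag in lines[i] for tag in ("xy", "xz", "yz")):
            raise TrajectoryError("triclinic boxes are not supported")
        bounds = np.array([[float(v) for v in lines[i + 1 + k].split()[:2]]
                           for k in range(3)])
        box = bounds[:, 1] - bounds[:, 0]
        origin = bounds[:, 0]
        i += 4
        header = lines[i].split()
        if header[:2] != ["ITEM:", "ATOMS"]:
            raise ParseError(f"line {i + 1}: expected 'ITEM: ATOMS'")
        cols = header[2:]
        coord_cols = None
        for cset in _DUMP_COORD_SETS:
            if all(c in cols for c in cset):
                coord_cols = cset
                break
        if coord_cols is None or "id" not in cols:
            raise ParseError(f"line {i + 1}: dump must carry id and x/xs/xu columns")
        i += 1
        rows = lines[i:i + n_atoms]
        if len(rows) < n_atoms:
            raise ParseError(f"line {i}: truncated ATOMS block")
        data = np.array([r.split() for r in rows], dtype=object)
        try:
            ids = data[:, cols.index("id")].astype(int)
            xyz = data[:, [cols.index(c) for c in coord_cols]].astype(float)
        except ValueError as exc:
            raise ParseError(f"non-numeric atom record near line {i + 1}: {exc}")
        order = np.argsort(ids)
        xyz = xyz[order]
        if coord_cols[0] == "xs":
            xyz = origin + xyz * box
        wrapped = coord_cols[0] != "xu"
        if n_expect is None:
            n_expect = n_atoms
        elif n_atoms != n_expect:
            raise TrajectoryError("atom count varies across dump frames")
        frames.append(Frame(time=timestep, box=box, positions=xyz,
                            wrapped=wrapped))
        i += n_atoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(frames=frames)


def write_lammps_dump(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a LAMMPS text dump (id type x y z, origin 0)."""
    buf = io.StringIO()
    types = (traj.topology.atom_type if traj.topology is not None
             else np.ones(traj.n_atoms, dtype=int))
    type_ids = {t: k + 1 for k, t in enumerate(dict.fromkeys(types))}
    for fr in traj.frames:
        buf.write("ITEM: TIMESTEP\n%d\n" % int(fr.time))
        buf.write("ITEM: NUMBER OF ATOMS\n%d\n" % fr.n_atoms)
        buf.write("ITEM: BOX BOUNDS pp pp pp\n")
        for L in fr.box:
            buf.write("0.0 %.10g\n" % L)
        buf.write("ITEM: ATOMS id type x y z\n")
        for k in range(fr.n_atoms):
            x, y, z = fr.positions[k]
            buf.write("%d %d %.10g %.10g %.10g\n"
                      % (k + 1, type_ids[types[k]], x, y, z))
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# extended XYZ

def _parse_extxyz_comment(comment: str) -> dict[str, str]:
    """Parse key=value pairs of an extxyz comment line (quoted values allowed)."""
    out: dict[str, str] = {}
    i = 0
    n = len(comment)
    while i < n:
        while i < n and comment[i].isspace():
            i += 1
        j = i
        while j < n and comment[j] not in "= \t":
            j += 1
        if j >= n or comment[j] != "=":
            break
        key = comment[i:j]
        j += 1
        if j < n and comment[j] == '"':
            k = comment.index('"', j + 1)
            out[key] = comment[j + 1:k]
            i = k + 1
        else:
            k = j
            while k < n and not comment[k].isspace():
                k += 1
            out[key] = comment[j:k]
            i = k
    return out


def read_extxyz(path: str | Path) -> Trajectory:
    """Read an extended-XYZ file with an orthogonal ``Lattice``."""
    lines = Path(path).read_text().splitlines()
    if not any(ln.strip() for ln in lines):
        raise ParseError(f"{path}: empty extended-XYZ file")
    frames: list[Frame] = []
    species_ref: np.ndarray | None = None
    i = 0
    t = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_atoms = int(lines[i].strip())
        meta = _parse_extxyz_comment(lines[i + 1])
        if "Lattice" not in meta:
            raise ParseError(f"line {i + 2}: missing Lattice field")
        cell = np.array(meta["Lattice"].split(), dtype=float).reshape(3, 3)
        off_diag = cell - np.diag(np.diag(cell))
        if np.any(np.abs(off_diag) > 1e-12):
            raise TrajectoryError("non-orthogonal lattice is not supported")
        box = np.diag(cell).copy()
        time = float(meta.get("Time", t))
        rows = [lines[i + 2 + k].split() for k in range(n_atoms)]
        species = np.array([r[0] for r in rows], dtype=object)
        xyz = np.array([r[1:4] for r in rows], dtype=float)
        if species_ref is None:
            species_ref = species
        frames.append(Frame(time=time, box=box, positions=xyz))
        i += 2 + n_atoms
        t += 1
    topo = Topology(
        atom_type=species_ref,
        mass=np.zeros(len(species_ref)),
        charge=np.zeros(len(species_ref)),
        molecule_id=np.arange(len(species_ref)),
        molecule_name=species_ref.copy(),
    )
    return Trajectory(frames=frames, topology=topo)


def write_extxyz(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as extended XYZ (orthogonal lattice, species labels)."""
    species = (traj.topology.atom_type if traj.topology is not None
               else np.array(["X"] * traj.n_atoms, dtype=object))
    buf = io.StringIO()
    for fr in traj.frames:
        lat = "%.10g 0 0 0 %.10g 0 0 0 %.10g" % tuple(fr.box)
        buf.write("%d\n" % fr.n_atoms)
        buf.write('Lattice="%s" Properties=species:S:1:pos:R:3 Time=%.10g\n'
                  % (lat, fr.time))
        for s, (x, y, z) in zip(species, fr.positions):
            buf.write("%s %.10g %.10g %.10g\n" % (s, x, y, z))
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# thermodynamic tables and topology files

_THERMO_ALIASES = {
    "time": ("time", "t_fs", "step", "Time"),
    "temperature": ("temperature", "temp", "T", "Temp"),
    "pressure": ("pressure", "press", "P"),
    "volume": ("volume", "vol", "V"),
    "potential_energy": ("potential_energy", "poteng", "U", "pe"),
    "enthalpy": ("enthalpy", "H", "etotal_plus_pv"),
}


def read_thermo_table(path: str | Path,
                      column_map: dict[str, str] | None = None,
                      sep: str | None = None) -> ThermoSeries:
    """Read a delimited thermodynamic table into a :class:`ThermoSeries`.

    Column names are resolved case-sensitively through a built-in alias
    table (``T``/``Temp``/``temperature`` ...), overridable via
    ``column_map`` mapping canonical field -> file column.  A table without
    a recognisable temperature column is rejected; other missing columns
    yield absent (``None``) fields.
    """
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    cols: dict[str, str] = {}
    for canon, aliases in _THERMO_ALIASES.items():
        if column_map and canon in column_map:
            if column_map[canon] in df.columns:
                cols[canon] = column_map[canon]
            continue
        for a in aliases:
            if a in df.columns:
                cols[canon] = a
                break
    if "temperature" not in cols:
        raise ParseError(f"{path}: no recognizable temperature column "
                         f"(have {list(df.columns)})")
    out: dict[str, np.ndarray | None] = {}
    for canon in _THERMO_ALIASES:
        if canon not in cols:
            continue
        col = df[cols[canon]]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() & col.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path}: non-numeric value in column "
                             f"{cols[canon]!r} at data row {row}")
        out[canon] = numeric.to_numpy(dtype=float)
    time = out.pop("time", None)
    if time is None:
        time = np.arange(len(df), dtype=float)
    return ThermoSeries(time=time, **out)


def read_topology(path: str | Path) -> Topology:
    """Read a topology from the package's JSON schema.

    The schema is a JSON object with per-atom parallel lists
    ``atom_type, mass, charge, molecule_id, molecule_name`` and optional
    boolean lists ``donor_flag, acceptor_flag``.
    """
    raw = json.loads(Path(path).read_text())
    return Topology(
        atom_type=np.array(raw["atom_type"], dtype=object),
        mass=np.array(raw["mass"], dtype=float),
        charge=np.array(raw["charge"], dtype=float),
        molecule_id=np.array(raw["molecule_id"], dtype=int),
        molecule_name=np.array(raw["molecule_name"], dtype=object),
        donor_flag=np.array(raw["donor_flag"], dtype=bool)
        if "donor_flag" in raw else None,
        acceptor_flag=np.array(raw["acceptor_flag"], dtype=bool)
        if "acceptor_flag" in raw else None,
    )


def write_topology(topo: Topology, path: str | Path) -> None:
    obj = {
        "atom_type": [str(t) for t in topo.atom_type],
        "mass": topo.mass.tolist(),
        "charge": topo.charge.tolist(),
        "molecule_id": topo.molecule_id.tolist(),
        "molecule_name": [str(m) for m in topo.molecule_name],
        "donor_flag": topo.donor_flag.tolist(),
        "acceptor_flag": topo.acceptor_flag.tolist(),
    }
    Path(path).write_text(json.dumps(obj, indent=1))
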