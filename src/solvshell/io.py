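"""Trajectory and topology file I/O.

Two multi-frame coordinate formats are supported:

* extended XYZ — comment line carries ``Lattice="Lx 0 0 0 Ly 0 0 0 Lz"``
  (orthorhombic required) and ``Time=<ps>``; rows are ``element x y z``.
* multi-MODEL PDB — MODEL/ENDMDL records with a CRYST1 box.

The per-atom chemistry travels in a sidecar TSV with columns
``atom_id name element mass charge epsilon rmin_half molecule_id
molecule_kind roles`` (roles comma-joined, empty allowed).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Atom, Frame, Topology, Trajectory
from .errors import AtomCountMismatchError, TrajectoryFormatError

_TOPOLOGY_COLUMNS = [
    "atom_id", "name", "element", "mass", "charge", "epsilon",
    "rmin_half", "molecule_id", "molecule_kind", "roles",
]


# ---------------------------------------------------------------------------
# topology sidecar
# ---------------------------------------------------------------------------

def write_topology(topology: Topology, path) -> None:
    rows = [
        (a.atom_id, a.name, a.element, a.mass, a.charge, a.lj_epsilon,
         a.lj_rmin_half, a.molecule_id, a.molecule_kind, ",".join(sorted(a.roles)))
        for a in topology.atoms
    ]
    df = pd.DataFrame(rows, columns=_TOPOLOGY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_topology(path) -> Topology:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"roles": str})
    missing = [c for c in _TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"topology file missing columns: {missing}")
    atoms = [
        Atom(
            atom_id=int(r.atom_id),
            name=str(r.name_col),
            element=str(r.element),
            mass=float(r.mass),
            charge=float(r.charge),
            lj_epsilon=float(r.epsilon),
            lj_rmin_half=float(r.rmin_half),
            molecule_id=int(r.molecule_id),
            molecule_kind=str(r.molecule_kind),
            roles=frozenset(x for x in str(r.roles).split(",") if x),
        )
        # 'name' clashes with the namedtuple field, rename before iterating
        for r in df.rename(columns={"name": "name_col"}).itertuples(index=False)
    ]
    return Topology(atoms)


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([0-9eE+.\-]+)")


def _write_xyz(trajectory: Trajectory, path) -> None:
    top = trajectory.topology
    with open(path, "w") as fh:
        for frame in trajectory:
            lx, ly, lz = frame.box
            fh.write(f"{frame.n_atoms}\n")
            fh.write(
                f'Lattice="{lx:.6f} 0.0 0.0 0.0 {ly:.6f} 0.0 0.0 0.0 {lz:.6f}" '
                f"Time={frame.time:.6f}\n"
            )
            for el, (x, y, z) in zip(top.elements, frame.positions):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_xyz_frames(path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_expected = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(f"bad atom-count line {i + 1}: {lines[i]!r}") from exc
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise AtomCountMismatchError(
                f"frame {len(frames)} has {n} atoms, expected {n_expected}"
            )
        comment = lines[i + 1]
        m = _LATTICE_RE.search(comment)
        if not m:
            raise TrajectoryFormatError(f"frame {len(frames)}: missing Lattice record")
        lat = np.array([float(x) for x in m.group(1).split()])
        if lat.size != 9:
            raise TrajectoryFormatError("Lattice must hold 9 numbers")
        lat = lat.reshape(3, 3)
        off = lat - np.diag(np.diag(lat))
        if np.any(np.abs(off) > 1e-8):
            raise TrajectoryFormatError("only orthorhombic lattices are supported")
        tm = _TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else float(len(frames))
        rows = lines[i + 2 : i + 2 + n]
        if len(rows) < n:
            raise AtomCountMismatchError(
                f"frame {len(frames)}: expected {n} atom rows, file ended after {len(rows)}"
            )
        pos = np.array([[float(v) for v in r.split()[1:4]] for r in rows])
        frames.append(Frame(positions=pos, box=np.diag(lat), time=time))
        i += 2 + n
    if not frames:
        raise TrajectoryFormatError(f"no frames found in {path}")
    return frames


# ---------------------------------------------------------------------------
# multi-MODEL PDB
# ---------------------------------------------------------------------------

def _write_pdb(trajectory: Trajectory, path) -> None:
    top = trajectory.topology
    with open(path, "w") as fh:
        lx, ly, lz = trajectory[0].box
        fh.write(
            f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}  90.00  90.00  90.00 P 1           1\n"
        )
        for imodel, frame in enumerate(trajectory, start=1):
            fh.write(f"MODEL     {imodel:4d}\n")
            for a, (x, y, z) in zip(top.atoms, frame.positions):
                resname = {"solute": "SOL", "urea": "URE", "water": "HOH"}[a.molecule_kind]
                serial = (a.atom_id % 99999) + 1
                resseq = (a.molecule_id % 9999) + 1
                fh.write(
                    f"ATOM  {serial:5d} {a.name[:4]:<4s} {resname:<4s}{resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _read_pdb_frames(path) -> list[Frame]:
    box = None
    frames: list[Frame] = []
    current: list[list[float]] | None = None
    n_expected = None
    t_index = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                box = np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                )
            elif rec == "MODEL ":
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:  # single-MODEL file without MODEL records
                    current = []
                current.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            elif rec == "ENDMDL":
                if current is None:
                    raise TrajectoryFormatError("ENDMDL without MODEL")
                if box is None:
                    raise TrajectoryFormatError("missing CRYST1 box record")
                if n_expected is None:
                    n_expected = len(current)
                elif len(current) != n_expected:
                    raise AtomCountMismatchError(
                        f"frame {len(frames)} has {len(current)} atoms, expected {n_expected}"
                    )
                frames.append(Frame(np.array(current), box, time=float(t_index)))
                t_index += 1
                current = None
    if current:  # trailing model without ENDMDL
        if box is None:
            raise TrajectoryFormatError("missing CRYST1 box record")
        if n_expected is not None and len(current) != n_expected:
            raise AtomCountMismatchError(
                f"trailing frame has {len(current)} atoms, expected {n_expected}"
            )
        frames.append(Frame(np.array(current), box, time=float(t_index)))
    if not frames:
        raise TrajectoryFormatError(f"no frames found in {path}")
    return frames


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def read_trajectory(path, topology_path, dt: float | None = None) -> Trajectory:
    """Read a trajectory plus sidecar topology.

    Format chosen by extension: ``.xyz``/``.extxyz`` or ``.pdb``. The PDB
    format carries no time metadata, so frame times are 0, 1, 2, ... in
    units of ``dt`` (default 1 ps) when given.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".xyz", ".extxyz", ".pdb"):
        raise TrajectoryFormatError(f"unknown trajectory extension {suffix!r}")
    topology = read_topology(topology_path)
    if suffix in (".xyz", ".extxyz"):
        frames = _read_xyz_frames(path)
    elif suffix == ".pdb":
        frames = _read_pdb_frames(path)
        if dt is not None:
            for i, f in enumerate(frames):
                f.time = i * dt
    else:
        raise TrajectoryFormatError(f"unknown trajectory extension {suffix!r}")
    if frames[0].n_atoms != topology.n_atoms:
        raise AtomCountMismatchError(
            f"trajectory has {frames[0].n_atoms} atoms/frame, topology {topology.n_atoms}"
        )
    return Trajectory(topology, frames)


def write_trajectory(trajectory: Trajectory, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".xyz", ".extxyz"):
        _write_xyz(trajectory, path)
    elif suffix == ".pdb":
        _write_pdb(trajectory, path)
    else:
        raise TrajectoryFormatError(f"unknown trajectory extension {suffix!r}")
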