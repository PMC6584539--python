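"""Domain types and periodic geometry shared by all analyses.

Units follow the CHARMM convention throughout the package: coordinates in
Angstrom, times in picoseconds, energies in kcal/mol, charges in units of
the elementary charge, angles in degrees. Boxes are orthorhombic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegeneratePlaneError,
    EmptySelectionError,
    InvalidBoxError,
    TopologyError,
)

MOLECULE_KINDS = ("solute", "urea", "water")

#: roles an atom may carry in addition to its element/parameters
ATOM_ROLES = frozenset(
    {
        "ring_atom",
        "donor_hydrogen",
        "donor_heavy",
        "acceptor",
        "urea_C",
        "urea_N",
        "urea_O",
        "urea_H",
        "water_O",
    }
)


@dataclass(frozen=True)
class Atom:
    atom_id: int
    name: str
    element: str
    mass: float            # amu
    charge: float          # e
    lj_epsilon: float      # kcal/mol (well depth, stored positive)
    lj_rmin_half: float    # Angstrom (Rmin/2)
    molecule_id: int
    molecule_kind: str
    roles: frozenset = field(default_factory=frozenset)


class Topology:
    """Per-atom chemistry plus molecule bookkeeping.

    Validates the composition invariants on construction: exactly one
    solute molecule with >= 3 ring atoms, urea molecules with the
    C/O/N2/H4 role pattern, water molecules with one water_O.
    """

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms = list(atoms)
        self._validate()
        # cached numpy views used by the numeric code paths
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.charges = np.array([a.charge for a in self.atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in self.atoms], dtype=float)
        self.molecule_ids = np.array([a.molecule_id for a in self.atoms], dtype=int)
        self.elements = np.array([a.element for a in self.atoms])

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        if not self.atoms:
            raise TopologyError("topology has no atoms")
        kind_by_mol: dict[int, str] = {}
        atoms_by_mol: dict[int, list[Atom]] = {}
        for a in self.atoms:
            if a.molecule_kind not in MOLECULE_KINDS:
                raise TopologyError(f"unknown molecule kind {a.molecule_kind!r}")
            bad = set(a.roles) - ATOM_ROLES
            if bad:
                raise TopologyError(f"unknown roles {bad} on atom {a.atom_id}")
            prev = kind_by_mol.setdefault(a.molecule_id, a.molecule_kind)
            if prev != a.molecule_kind:
                raise TopologyError(
                    f"molecule {a.molecule_id} has mixed kinds {prev}/{a.molecule_kind}"
                )
            atoms_by_mol.setdefault(a.molecule_id, []).append(a)
        solutes = [m for m, k in kind_by_mol.items() if k == "solute"]
        if len(solutes) != 1:
            raise TopologyError(f"expected exactly one solute molecule, got {len(solutes)}")
        n_ring = sum(
            1 for a in atoms_by_mol[solutes[0]] if "ring_atom" in a.roles
        )
        if n_ring < 3:
            raise TopologyError(f"solute has {n_ring} ring atoms; need >= 3")
        for mol, kind in kind_by_mol.items():
            if kind == "urea":
                counts = {r: 0 for r in ("urea_C", "urea_O", "urea_N", "urea_H")}
                for a in atoms_by_mol[mol]:
                    for r in counts:
                        if r in a.roles:
                            counts[r] += 1
                if (counts["urea_C"], counts["urea_O"], counts["urea_N"], counts["urea_H"]) != (
                    1, 1, 2, 4,
                ):
                    raise TopologyError(f"urea molecule {mol} role counts {counts}")
            elif kind == "water":
                n_o = sum(1 for a in atoms_by_mol[mol] if "water_O" in a.roles)
                if n_o != 1:
                    raise TopologyError(f"water molecule {mol} has {n_o} water_O atoms")

    # -- selections ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def indices_where(self, predicate) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int)

    def kind_indices(self, kind: str) -> np.ndarray:
        return self.indices_where(lambda a: a.molecule_kind == kind)

    def role_indices(self, role: str) -> np.ndarray:
        return self.indices_where(lambda a: role in a.roles)

    @property
    def solute_indices(self) -> np.ndarray:
        return self.kind_indices("solute")

    @property
    def solute_molecule_id(self) -> int:
        return self.atoms[int(self.solute_indices[0])].molecule_id

    def solute_heavy_indices(self) -> np.ndarray:
        return self.indices_where(
            lambda a: a.molecule_kind == "solute" and a.element != "H"
        )

    def ring_indices(self) -> np.ndarray:
        return self.indices_where(
            lambda a: a.molecule_kind == "solute" and "ring_atom" in a.roles
        )

    def molecule_ids_of_kind(self, kind: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.molecule_kind == kind and a.molecule_id not in seen:
                seen[a.molecule_id] = None
        return list(seen)

    def molecule_indices(self, molecule_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_ids == molecule_id)

    def is_purine_like(self) -> bool:
        """Fused-ring solutes (>= 7 ring atoms) are treated as purines."""
        return len(self.ring_indices()) >= 7


@dataclass
class Frame:
    """One time-ordered configuration: positions (n,3) A, box edges A, time ps."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        if np.any(self.box <= 0):
            raise InvalidBoxError(f"box edges must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


class Trajectory:
    """Topology plus a time-ordered sequence of frames with constant spacing."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        for f in frames:
            if f.n_atoms != topology.n_atoms:
                raise TopologyError(
                    f"frame has {f.n_atoms} atoms, topology has {topology.n_atoms}"
                )
        times = np.array([f.time for f in frames])
        if len(frames) > 1:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame spacing must be constant")
            self.dt = float(dts[0])
        else:
            self.dt = 0.0
        self.topology = topology
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vector(s) into the primary image.

    Each component of the result lies in [-L/2, L/2); the half-box tie
    maps to the negative end so the convention is deterministic.
    Broadcasts over leading axes of ``delta``.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise InvalidBoxError(f"box edges must be positive, got {box}")
    delta = np.asarray(delta, dtype=float)
    return delta - box * np.floor(delta / box + 0.5)


def periodic_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shortest periodic-image distance between points (broadcasting)."""
    d = minimum_image(np.asarray(a) - np.asarray(b), box)
    return np.sqrt(np.sum(d * d, axis=-1))


def center_of_mass(atom_ids: Iterable[int], frame: Frame, topology: Topology) -> np.ndarray:
    """Mass-weighted mean position of a selection.

    The selection is assumed whole (not split across a periodic seam);
    generators and readers in this package store molecules whole.
    """
    idx = np.asarray(list(atom_ids), dtype=int)
    if idx.size == 0:
        raise EmptySelectionError("center_of_mass of empty selection")
    m = topology.masses[idx]
    return np.asarray(m @ frame.positions[idx] / m.sum())


def solute_center_of_mass(frame: Frame, topology: Topology) -> np.ndarray:
    return center_of_mass(topology.solute_indices, frame, topology)


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points``.

    The normal is the smallest principal axis of the centered point
    cloud. Sign convention: the component along the laboratory axis of
    largest magnitude is made positive, so the result is reproducible.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegeneratePlaneError("plane fit needs >= 3 points")
    centered = pts - pts.mean(axis=0)
    # SVD of the centered cloud: last right-singular vector = normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear points: two near-zero singular values
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise DegeneratePlaneError("points are collinear; plane undefined")
    n = vt[2]
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return n / np.linalg.norm(n)


def base_plane_normal(frame: Frame, topology: Topology) -> np.ndarray:
    """Least-squares plane normal of the solute's ring atoms."""
    idx = topology.ring_indices()
    if idx.size < 3:
        raise DegeneratePlaneError("solute has fewer than 3 ring atoms")
    return plane_normal(frame.positions[idx])


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
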