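"""Idealized rigid molecule templates used by the synthetic generators.

All templates are planar (z = 0), built from standard bond lengths and
sp2 angles, with CHARMM-style per-element Lennard-Jones parameters and
plausible partial charges normalized to exact neutrality. The analysis
code never assumes these geometries; they exist so synthetic systems
have known, reproducible structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Atom, Topology

_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}
# generic well depth (kcal/mol) and Rmin/2 (A) per element
_LJ = {
    "H": (0.046, 0.2245),
    "C": (0.070, 1.9924),
    "N": (0.200, 1.8500),
    "O": (0.120, 1.7000),
}


@dataclass
class MoleculeTemplate:
    kind: str                      # solute | urea | water
    names: list[str]
    elements: list[str]
    charges: np.ndarray
    roles: list[frozenset]
    coords: np.ndarray             # (n, 3), centered at the center of mass

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        masses = np.array([_MASS[e] for e in self.elements])
        com = masses @ self.coords / masses.sum()
        self.coords = self.coords - com

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([_MASS[e] for e in self.elements])

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def make_atoms(self, molecule_id: int, first_atom_id: int) -> list[Atom]:
        out = []
        for i in range(self.n_atoms):
            el = self.elements[i]
            eps, rmin2 = _LJ[el]
            out.append(
                Atom(
                    atom_id=first_atom_id + i,
                    name=self.names[i],
                    element=el,
                    mass=_MASS[el],
                    charge=float(self.charges[i]),
                    lj_epsilon=eps,
                    lj_rmin_half=rmin2,
                    molecule_id=molecule_id,
                    molecule_kind=self.kind,
                    roles=self.roles[i],
                )
            )
        return out


def _rot2d(deg: float) -> np.ndarray:
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _neutralize(q: list[float]) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q - q.sum() / q.size


def urea_template() -> MoleculeTemplate:
    """Planar urea: C=O 1.23 A, C-N 1.36 A, N-C-N 120 deg, N-H 1.01 A."""
    c = np.array([0.0, 0.0])
    o = np.array([0.0, 1.23])
    n1 = 1.36 * np.array([np.sin(np.radians(60)), -np.cos(np.radians(60))])
    n2 = n1 * np.array([-1.0, 1.0])
    coords2d = [c, o, n1, n2]
    names = ["C", "O", "N1", "N2"]
    elements = ["C", "O", "N", "N"]
    roles = [
        frozenset({"urea_C"}),
        frozenset({"urea_O", "acceptor"}),
        frozenset({"urea_N", "donor_heavy"}),
        frozenset({"urea_N", "donor_heavy"}),
    ]
    for tag, n in (("1", n1), ("2", n2)):
        away = (n - c) / np.linalg.norm(n - c)
        for j, ang in enumerate((60.0, -60.0)):
            h = n + 1.01 * (_rot2d(ang) @ away)
            coords2d.append(h)
            names.append(f"H{tag}{j + 1}")
            elements.append("H")
            roles.append(frozenset({"urea_H", "donor_hydrogen"}))
    charges = _neutralize([0.142, -0.390, -0.542, -0.542, 0.333, 0.333, 0.333, 0.333])
    coords = np.column_stack([np.array(coords2d), np.zeros(len(coords2d))])
    return MoleculeTemplate("urea", names, elements, charges, roles, coords)


def water_template() -> MoleculeTemplate:
    """TIP3P-like rigid water: O-H 0.9572 A, H-O-H 104.52 deg."""
    half = np.radians(104.52 / 2)
    o = np.array([0.0, 0.0])
    h1 = 0.9572 * np.array([np.sin(half), np.cos(half)])
    h2 = h1 * np.array([-1.0, 1.0])
    coords = np.column_stack([np.array([o, h1, h2]), np.zeros(3)])
    return MoleculeTemplate(
        "water",
        ["OW", "HW1", "HW2"],
        ["O", "H", "H"],
        _neutralize([-0.834, 0.417, 0.417]),
        [
            frozenset({"water_O", "acceptor", "donor_heavy"}),
            frozenset({"donor_hydrogen"}),
            frozenset({"donor_hydrogen"}),
        ],
        coords,
    )


def _fused_rings(side: float = 1.39):
    """Regular hexagon fused with a regular pentagon sharing one edge."""
    hexagon = np.array(
        [side * np.array([np.cos(a), np.sin(a)]) for a in np.radians(np.arange(0, 360, 60))]
    )
    # shared edge: vertices 3 and 4
    a, b = hexagon[3], hexagon[4]
    mid = (a + b) / 2
    out_dir = mid / np.linalg.norm(mid)  # hexagon centered at origin
    apothem = side / (2 * np.tan(np.pi / 5))
    circum = side / (2 * np.sin(np.pi / 5))
    center = mid + apothem * out_dir
    ang_a = np.arctan2(*(a - center)[::-1])
    ang_b = np.arctan2(*(b - center)[::-1])
    # three remaining vertices, evenly spaced from b to a the long way
    # around the pentagon circumcircle
    d = (ang_a - ang_b) % (2 * np.pi)
    angs = [ang_b - (k + 1) * (2 * np.pi - d) / 4 for k in range(3)]
    penta = [center + circum * np.array([np.cos(t), np.sin(t)]) for t in angs]
    return hexagon, np.array(penta)


def purine_template() -> MoleculeTemplate:
    """Adenine-like purine: fused 6+5 ring, amino group, ring N acceptors."""
    hexagon, penta = _fused_rings()
    # hexagon: N1 C2 N3 C4 C5 C6 ; pentagon adds N7 C8 N9 (C4-C5 shared)
    ring_names = ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"]
    ring_elems = ["N", "C", "N", "C", "C", "C", "N", "C", "N"]
    coords2d = list(hexagon[[0, 1, 2, 3, 4, 5]]) + list(penta)
    names = list(ring_names)
    elements = list(ring_elems)
    roles: list[frozenset] = []
    for nm, el in zip(ring_names, ring_elems):
        r = {"ring_atom"}
        if nm in ("N1", "N3", "N7"):
            r.add("acceptor")
        if nm == "N9":
            r.add("donor_heavy")
        roles.append(frozenset(r))
    charges = [-0.74, 0.50, -0.75, 0.43, 0.28, 0.46, -0.71, 0.34, -0.05]

    def outward(p):
        return p / np.linalg.norm(p)

    # exocyclic amino N6 on C6, two H on N6
    c6 = hexagon[5]
    n6 = c6 + 1.34 * outward(c6)
    coords2d.append(n6)
    names.append("N6")
    elements.append("N")
    roles.append(frozenset({"donor_heavy"}))
    charges.append(-0.77)
    away = outward(n6 - c6)
    for j, ang in enumerate((60.0, -60.0)):
        coords2d.append(n6 + 1.01 * (_rot2d(ang) @ away))
        names.append(f"H6{j + 1}")
        elements.append("H")
        roles.append(frozenset({"donor_hydrogen"}))
        charges.append(0.38)
    # ring hydrogens: H2 on C2, H8 on C8, H9 on N9
    for nm, base_idx, blen in (("H2", 1, 1.08), ("H8", 7, 1.08), ("H9", 8, 1.01)):
        p = coords2d[base_idx]
        coords2d.append(p + blen * outward(p))
        names.append(nm)
        elements.append("H")
        roles.append(
            frozenset({"donor_hydrogen"}) if nm == "H9" else frozenset()
        )
        charges.append(0.12 if nm != "H9" else 0.34)
    coords = np.column_stack([np.array(coords2d), np.zeros(len(coords2d))])
    return MoleculeTemplate(
        "solute", names, elements, _neutralize(charges), roles, coords
    )


def pyrimidine_template() -> MoleculeTemplate:
    """Uracil-like pyrimidine: six-ring with two carbonyl O and two N-H."""
    hexagon = np.array(
        [1.39 * np.array([np.cos(a), np.sin(a)]) for a in np.radians(np.arange(0, 360, 60))]
    )
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    elements = ["N", "C", "N", "C", "C", "C"]
    coords2d = list(hexagon)
    roles = [
        frozenset({"ring_atom", "donor_heavy"}),
        frozenset({"ring_atom"}),
        frozenset({"ring_atom", "donor_heavy"}),
        frozenset({"ring_atom"}),
        frozenset({"ring_atom"}),
        frozenset({"ring_atom"}),
    ]
    charges = [-0.46, 0.53, -0.48, 0.52, -0.23, 0.03]

    def outward(p):
        return p / np.linalg.norm(p)

    extra = [
        ("O2", "O", 1, 1.23, frozenset({"acceptor"}), -0.48),
        ("O4", "O", 3, 1.23, frozenset({"acceptor"}), -0.47),
        ("H1", "H", 0, 1.01, frozenset({"donor_hydrogen"}), 0.36),
        ("H3", "H", 2, 1.01, frozenset({"donor_hydrogen"}), 0.36),
        ("H5", "H", 4, 1.08, frozenset(), 0.11),
        ("H6", "H", 5, 1.08, frozenset(), 0.21),
    ]
    for nm, el, idx, blen, rl, q in extra:
        p = hexagon[idx]
        coords2d.append(p + blen * outward(p))
        names.append(nm)
        elements.append(el)
        roles.append(rl)
        charges.append(q)
    coords = np.column_stack([np.array(coords2d), np.zeros(len(coords2d))])
    return MoleculeTemplate(
        "solute", names, elements, _neutralize(charges), roles, coords
    )


def solute_only_topology(template: MoleculeTemplate) -> Topology:
    """Topology containing just the solute molecule (id 0)."""
    return Topology(template.make_atoms(molecule_id=0, first_atom_id=0))
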