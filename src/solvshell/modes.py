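"""Geometric classification of urea-nucleobase interaction modes.

Three modes are quantified from pure geometry, frame by frame:

* pi-pi stacking — urea face-to-face over the aromatic base plane,
  gated by the COM-COM distance d <= 4.5 A, the plane-normal angle
  theta1 (< 40 deg or > 140 deg) and the normal/COM-COM-vector angle
  theta2 (< 70 deg or >= 110 deg);
* NH-pi — a urea N-H directed at the base's pi face, gated by the
  COM-to-N distance (< 4.5 A), the base-normal/COM->H angle theta4
  (> 150 deg or < 30 deg) and the N-H...COM linearity angle theta3
  (> 150 deg);
* hydrogen bonding — donor-acceptor heavy-atom distance <= 3.5 A and
  donor-H...acceptor angle >= 150 deg, both base->urea and urea->base.

Spatial density maps histogram urea C/N/O positions in the solute's
body-fixed frame on a 75^3 grid covering a sphere of 7.75 A (purines)
or 7.05 A (pyrimidines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    Frame,
    Topology,
    Trajectory,
    angle_between_deg,
    minimum_image,
    plane_normal,
    solute_center_of_mass,
)
from .errors import InvalidBinningError

# default gates, configurable at every call site
STACK_D_MAX = 4.5
STACK_THETA1 = 40.0
STACK_THETA2_LO = 70.0
STACK_THETA2_HI = 110.0
NHPI_D_MAX = 4.5
NHPI_THETA4 = (150.0, 30.0)
NHPI_THETA3_MIN = 150.0
HBOND_HEAVY_MAX = 3.5
HBOND_ANGLE_MIN = 150.0
REGION_RADIUS_PURINE = 7.75
REGION_RADIUS_PYRIMIDINE = 7.05
GRID_BINS = 75


@dataclass
class InteractionGeometry:
    """Distances and angles describing one urea molecule's pose."""

    d_com: float      # base COM - urea COM, A
    d_comN: float     # base COM - nearest urea N, A
    theta1: float     # base normal vs urea normal, deg
    theta2: float     # base normal vs COM-COM vector, deg
    theta3: float     # N-H...base-COM angle at H, deg
    theta4: float     # base normal vs base-COM -> H vector, deg
    frame_index: int = 0
    urea_molecule_id: int = -1


def measure_geometry(
    frame: Frame,
    topology: Topology,
    urea_molecule_id: int,
    frame_index: int = 0,
) -> InteractionGeometry:
    """All mode-relevant distances/angles for one urea molecule.

    Vectors use the minimum image relative to the base COM; the H
    entering theta3/theta4 is the urea hydrogen closest to the base
    COM, and theta3 uses that H's own nitrogen.
    """
    box = frame.box
    base_com = solute_center_of_mass(frame, topology)
    n_base = plane_normal(frame.positions[topology.ring_indices()])

    mol = topology.molecule_indices(urea_molecule_id)
    # rebuild the urea near the base COM so plane/COM math is seam-free
    rel = minimum_image(frame.positions[mol] - base_com, box)
    masses = topology.masses[mol]
    urea_com_rel = masses @ rel / masses.sum()

    heavy = np.array([topology.atoms[int(i)].element != "H" for i in mol])
    n_urea = plane_normal(rel[heavy])

    is_n = np.array(["urea_N" in topology.atoms[int(i)].roles for i in mol])
    is_h = np.array(["urea_H" in topology.atoms[int(i)].roles for i in mol])
    dist_n = np.linalg.norm(rel[is_n], axis=1)
    d_comN = float(dist_n.min())

    h_rel = rel[is_h]
    hd = np.linalg.norm(h_rel, axis=1)
    hi = int(np.argmin(hd))
    h = h_rel[hi]
    # nitrogen bonded to that hydrogen = nearest urea N to it
    n_rel = rel[is_n]
    nn = n_rel[int(np.argmin(np.linalg.norm(n_rel - h, axis=1)))]

    d_com = float(np.linalg.norm(urea_com_rel))
    theta1 = angle_between_deg(n_base, n_urea)
    theta2 = angle_between_deg(n_base, urea_com_rel)
    theta3 = angle_between_deg(nn - h, -h)  # at H: towards N vs towards base COM
    theta4 = angle_between_deg(n_base, h)
    return InteractionGeometry(
        d_com=d_com, d_comN=d_comN,
        theta1=theta1, theta2=theta2, theta3=theta3, theta4=theta4,
        frame_index=frame_index, urea_molecule_id=urea_molecule_id,
    )


def classify_stacking(
    g: InteractionGeometry,
    d_max: float = STACK_D_MAX,
    theta1_gate: float = STACK_THETA1,
    theta2_lo: float = STACK_THETA2_LO,
    theta2_hi: float = STACK_THETA2_HI,
) -> bool:
    """Face-to-face stacking gate (boundaries as printed: <=, strict, >=)."""
    return bool(
        g.d_com <= d_max
        and (g.theta1 < theta1_gate or g.theta1 > 180.0 - theta1_gate)
        and (g.theta2 < theta2_lo or g.theta2 >= theta2_hi)
    )


def classify_nh_pi(
    g: InteractionGeometry,
    d_max: float = NHPI_D_MAX,
    theta4_gate: tuple = NHPI_THETA4,
    theta3_min: float = NHPI_THETA3_MIN,
) -> bool:
    """NH-pi gate: N close to the pi face, H aligned, N-H...COM linear."""
    hi, lo = theta4_gate
    return bool(
        g.d_comN < d_max
        and (g.theta4 > hi or g.theta4 < lo)
        and g.theta3 > theta3_min
    )


def classify_hbond(
    frame: Frame,
    topology: Topology,
    urea_molecule_id: int,
    heavy_max: float = HBOND_HEAVY_MAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> bool:
    """True iff any base/urea donor->acceptor pair forms a hydrogen bond.

    Criterion: donor-heavy to acceptor distance <= 3.5 A and
    donor-H...acceptor angle >= 150 deg, evaluated in both directions
    (base N-H -> urea O, urea N-H -> base acceptor).
    """
    box = frame.box
    mol = set(int(i) for i in topology.molecule_indices(urea_molecule_id))
    base = [int(i) for i in topology.solute_indices]

    def atoms_with(indices, role):
        return [i for i in indices if role in topology.atoms[int(i)].roles]

    def bonded_h(heavy_idx, candidates):
        p = frame.positions[heavy_idx]
        out = []
        for h in candidates:
            d = np.linalg.norm(minimum_image(frame.positions[h] - p, box))
            if d < 1.25:
                out.append(h)
        return out

    def check(donor_heavies, donor_hs, acceptors):
        for dh in donor_heavies:
            hs = bonded_h(dh, donor_hs)
            for acc in acceptors:
                dda = np.linalg.norm(
                    minimum_image(frame.positions[acc] - frame.positions[dh], box)
                )
                if dda > heavy_max:
                    continue
                for h in hs:
                    v_d = minimum_image(frame.positions[dh] - frame.positions[h], box)
                    v_a = minimum_image(frame.positions[acc] - frame.positions[h], box)
                    if angle_between_deg(v_d, v_a) >= angle_min:
                        return True
        return False

    urea = sorted(mol)
    base_dh = atoms_with(base, "donor_heavy")
    base_h = atoms_with(base, "donor_hydrogen")
    base_acc = atoms_with(base, "acceptor")
    urea_dh = atoms_with(urea, "donor_heavy")
    urea_h = atoms_with(urea, "donor_hydrogen")
    urea_acc = atoms_with(urea, "acceptor")
    return check(base_dh, base_h, urea_acc) or check(urea_dh, urea_h, base_acc)


MODE_NAMES = ("stacking", "nh_pi", "hbond")


def classify_mode(frame: Frame, topology: Topology, urea_molecule_id: int,
                  mode: str, frame_index: int = 0) -> bool:
    if mode == "hbond":
        return classify_hbond(frame, topology, urea_molecule_id)
    g = measure_geometry(frame, topology, urea_molecule_id, frame_index)
    if mode == "stacking":
        return classify_stacking(g)
    if mode == "nh_pi":
        return classify_nh_pi(g)
    raise ValueError(f"unknown mode {mode!r}; valid: {MODE_NAMES}")


# ---------------------------------------------------------------------------
# spatial density
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Body-frame occupancy histogram of one urea atom kind."""

    counts: np.ndarray          # (75, 75, 75) int
    origin: np.ndarray          # lower corner in the body frame, A
    spacing: float              # voxel edge, A
    region_radius: float        # A
    atom_kind: str              # element binned (C, N or O)
    frames: int = 0
    inclusion_cutoff: float = 4.5

    def probability(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)


def region_radius_for(topology: Topology) -> float:
    return REGION_RADIUS_PURINE if topology.is_purine_like() else REGION_RADIUS_PYRIMIDINE


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares superposition: returns rotation R and rmsd.

    Both point sets must be centered by the caller. ``R @ mobile_i``
    best matches ``reference_i``.
    """
    h = mobile.T @ reference
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = (rot @ mobile.T).T
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return rot, rmsd


def spatial_density(
    trajectory: Trajectory,
    atom_kind: str = "C",
    region_radius: float | None = None,
    n_bins: int = GRID_BINS,
    inclusion_cutoff: float = 4.5,
    rmsd_warn: float = 1.0,
) -> DensityGrid:
    """Histogram urea C/N/O positions in the solute's body frame.

    Each frame's solute heavy atoms are superposed on the first frame's
    (Kabsch); urea atoms of ``atom_kind`` within ``inclusion_cutoff`` of
    any solute atom are transformed into the body frame and binned into
    the n_bins^3 grid spanning the cube of edge 2 x region_radius
    centered on the reference solute COM. Half-open voxel intervals;
    atoms exactly on the cube boundary are excluded.
    """
    top = trajectory.topology
    if region_radius is None:
        region_radius = region_radius_for(top)
    role = {"C": "urea_C", "N": "urea_N", "O": "urea_O"}.get(atom_kind)
    if role is None:
        raise ValueError(f"atom_kind must be C, N or O, got {atom_kind!r}")
    tgt = top.role_indices(role)
    sol = top.solute_indices
    heavy = top.solute_heavy_indices()

    ref_frame = trajectory[0]
    ref_com = solute_center_of_mass(ref_frame, top)
    ref_heavy = ref_frame.positions[heavy] - ref_com
    edge = 2.0 * region_radius
    spacing = edge / n_bins
    origin = -region_radius * np.ones(3)

    counts = np.zeros((n_bins, n_bins, n_bins), dtype=np.int64)
    for i, frame in enumerate(trajectory):
        com = solute_center_of_mass(frame, top)
        mob = frame.positions[heavy] - com
        rot, rmsd = _kabsch(mob, ref_heavy)
        if rmsd > rmsd_warn:
            warnings.warn(
                f"frame {i}: solute alignment RMSD {rmsd:.2f} A exceeds "
                f"{rmsd_warn} A; solute may not be rigid", stacklevel=2
            )
        # inclusion: target within cutoff of any solute atom (min image)
        d = minimum_image(
            frame.positions[tgt][:, None, :] - frame.positions[sol][None, :, :],
            frame.box,
        )
        near = np.sqrt((d * d).sum(axis=-1)).min(axis=1) <= inclusion_cutoff
        rel = minimum_image(frame.positions[tgt][near] - com, frame.box)
        body = (rot @ rel.T).T
        ijk = np.floor((body - origin) / spacing).astype(int)
        ok = np.all((ijk >= 0) & (ijk < n_bins), axis=1)
        np.add.at(counts, tuple(ijk[ok].T), 1)
    return DensityGrid(
        counts=counts, origin=origin, spacing=spacing,
        region_radius=region_radius, atom_kind=atom_kind,
        frames=len(trajectory), inclusion_cutoff=inclusion_cutoff,
    )


_BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


def write_cube(grid: DensityGrid, path, frame: Frame | None = None,
               topology: Topology | None = None, normalize: bool = True) -> None:
    """Write a density grid as a Gaussian cube file (z-fastest ordering)."""
    n = grid.counts.shape[0]
    data = grid.probability() if normalize else grid.counts.astype(float)
    org = grid.origin * _BOHR_PER_ANGSTROM
    step = grid.spacing * _BOHR_PER_ANGSTROM
    atoms = []
    if frame is not None and topology is not None:
        znum = {"H": 1, "C": 6, "N": 7, "O": 8}
        com = solute_center_of_mass(frame, topology)
        for i in topology.solute_indices:
            el = topology.atoms[int(i)].element
            p = (frame.positions[int(i)] - com) * _BOHR_PER_ANGSTROM
            atoms.append((znum.get(el, 0), p))
    with open(path, "w") as fh:
        fh.write(f"solvshell spatial density: urea {grid.atom_kind}\n")
        fh.write(f"region radius {grid.region_radius} A, {grid.frames} frames\n")
        fh.write(f"{len(atoms):5d}{org[0]:12.6f}{org[1]:12.6f}{org[2]:12.6f}\n")
        for k in range(3):
            axis = [0.0, 0.0, 0.0]
            axis[k] = step
            fh.write(f"{n:5d}{axis[0]:12.6f}{axis[1]:12.6f}{axis[2]:12.6f}\n")
        for z, p in atoms:
            fh.write(f"{z:5d}{float(z):12.6f}{p[0]:12.6f}{p[1]:12.6f}{p[2]:12.6f}\n")
        flat = data.reshape(n * n, n)
        for row in flat:
            for start in range(0, n, 6):
                chunk = row[start : start + 6]
                fh.write("".join(f"{v:13.5E}" for v in chunk) + "\n")


# ---------------------------------------------------------------------------
# mode distributions
# ---------------------------------------------------------------------------

def mode_distribution(
    geometries: list,
    mode: str,
    distance_bin: float = 0.1,
    angle_bin: float = 2.0,
    distance_range: tuple = (0.0, 6.0),
    angle_range: tuple = (0.0, 180.0),
):
    """Normalized 2D histogram over (distance, angle) for one mode.

    Stacking uses (d_com, theta2); NH-pi uses (d_comN, theta4).
    Returns (hist, distance_edges, angle_edges) with hist summing to 1.
    """
    if distance_bin <= 0 or angle_bin <= 0:
        raise InvalidBinningError("bin widths must be positive")
    if mode == "stacking":
        d = np.array([g.d_com for g in geometries])
        a = np.array([g.theta2 for g in geometries])
    elif mode == "nh_pi":
        d = np.array([g.d_comN for g in geometries])
        a = np.array([g.theta4 for g in geometries])
    else:
        raise ValueError(f"mode_distribution supports stacking/nh_pi, got {mode!r}")
    d_edges = np.arange(distance_range[0], distance_range[1] + distance_bin, distance_bin)
    a_edges = np.arange(angle_range[0], angle_range[1] + angle_bin, angle_bin)
    hist, _, _ = np.histogram2d(d, a, bins=[d_edges, a_edges])
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist, d_edges, a_edges
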