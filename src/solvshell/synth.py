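"""Synthetic inputs with analytically known ground truth.

Every analysis in the package can be exercised without an MD engine:

* :func:`build_solvent_box` packs urea/water mixtures around a rigid
  planar solute with hard-core exclusion rules (2.4 A to solute
  non-hydrogens, 1.8 A between solvent non-hydrogens) and an optional
  enrichment factor f applied to urea placement inside a shell around
  the solute — giving a constructed two-domain Gamma expectation;
* :func:`simulate_two_state` draws bound/unbound contact series from a
  discrete Markov chain with known on/off rates (mean lifetime 1/k_off);
* :func:`simulate_brownian` translates the solute along a Gaussian
  random walk with known diffusion coefficient;
* :func:`pose_urea` places a rigid urea at prescribed (d, theta)
  geometry for classifier round-trips;
* :func:`synthesize_rdf` evaluates the damped-sinusoid tail model with
  known parameters plus optional noise.

Frames from the box builder are i.i.d. configurations, not dynamics:
the static estimators only need configurational sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    Atom,
    Frame,
    Topology,
    Trajectory,
    base_plane_normal,
    minimum_image,
    solute_center_of_mass,
)
from .dynamics import ContactSeries
from .errors import GeometryError, PackingFailureError
from .solvation import RDFProfile, long_range_model
from .templates import (
    MoleculeTemplate,
    purine_template,
    urea_template,
    water_template,
)

SOLUTE_EXCLUSION = 2.4   # A, solvent non-H to solute non-H
SOLVENT_EXCLUSION = 1.8  # A, solvent non-H to solvent non-H


@dataclass
class MixtureSpec:
    """Composition and enrichment of a synthetic solvent box."""

    box: float = 32.0          # cubic edge, A
    n_urea: int = 156          # ~8 M in a 32 A cube
    n_water: int = 700
    enrichment: float = 1.0    # urea placement-density factor in the shell
    shell_radius: float = 10.0  # A, around the solute COM
    seed: int = 0

    def __post_init__(self):
        if self.n_urea < 0 or self.n_water < 0:
            raise ValueError("molecule counts must be >= 0")
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")
        if self.shell_radius >= self.box / 2:
            raise ValueError("shell_radius must be < half the box edge")


@dataclass
class TwoStateSpec:
    """Markov on/off kinetics for synthetic contact series."""

    k_on: float                # 1/ps
    k_off: float               # 1/ps
    dt: float = 1.0            # ps
    n_frames: int = 1000
    n_molecules: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k_on <= 0 or self.k_off < 0:
            raise ValueError("k_on must be positive and k_off non-negative")
        if self.k_off * self.dt > 0.1 or self.k_on * self.dt > 0.1:
            warnings.warn(
                "rate * dt exceeds 0.1; discrete-time approximation is coarse",
                stacklevel=2,
            )


@dataclass
class BoxBookkeeping:
    """The generator's own record of where it placed each molecule.

    Shell membership is molecule-COM within ``shell_radius`` of the box
    center (= solute COM); the closed-form Gamma expectation follows
    from these counts without running any analysis code.
    """

    shell_radius: float
    urea_in: np.ndarray        # per frame
    urea_out: np.ndarray
    water_in: np.ndarray
    water_out: np.ndarray

    def gamma_per_frame(self) -> np.ndarray:
        return self.urea_in - self.urea_out / self.water_out * self.water_in

    def gamma_realized(self) -> float:
        return float(self.gamma_per_frame().mean())


def expected_gamma_uniform_shell(spec: MixtureSpec) -> float:
    """Closed-form expected two-domain Gamma for the COM-shell region.

    Urea lands in the shell with probability f v / (f v + 1 - v) where
    v is the shell volume fraction; water with probability v. The
    builder fixes region membership by exact Bernoulli draws, so these
    are the true expected counts even with hard-core exclusion.
    """
    v = (4.0 / 3.0) * np.pi * spec.shell_radius**3 / spec.box**3
    f = spec.enrichment
    pu = f * v / (f * v + 1.0 - v)
    nu_in = spec.n_urea * pu
    nu_out = spec.n_urea * (1.0 - pu)
    nw_in = spec.n_water * v
    nw_out = spec.n_water * (1.0 - v)
    return float(nu_in - nu_out / nw_out * nw_in)


def _random_rotation(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Uniform random rotation matrices from normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    mats = np.empty((n, 3, 3))
    mats[:, 0, 0] = 1 - 2 * (y * y + z * z)
    mats[:, 0, 1] = 2 * (x * y - w * z)
    mats[:, 0, 2] = 2 * (x * z + w * y)
    mats[:, 1, 0] = 2 * (x * y + w * z)
    mats[:, 1, 1] = 1 - 2 * (x * x + z * z)
    mats[:, 1, 2] = 2 * (y * z - w * x)
    mats[:, 2, 0] = 2 * (x * z - w * y)
    mats[:, 2, 1] = 2 * (y * z + w * x)
    mats[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return mats[0] if n == 1 else mats


def _assemble_topology(
    solute: MoleculeTemplate, n_urea: int, n_water: int
) -> tuple[Topology, list[MoleculeTemplate]]:
    urea = urea_template()
    water = water_template()
    atoms: list[Atom] = list(solute.make_atoms(0, 0))
    order: list[MoleculeTemplate] = []
    mol_id = 1
    for _ in range(n_urea):
        atoms.extend(urea.make_atoms(mol_id, len(atoms)))
        order.append(urea)
        mol_id += 1
    for _ in range(n_water):
        atoms.extend(water.make_atoms(mol_id, len(atoms)))
        order.append(water)
        mol_id += 1
    return Topology(atoms), order


def shell_membership_probability(spec: MixtureSpec, kind: str) -> float:
    """Probability a molecule of ``kind`` is assigned to the shell.

    With shell volume fraction v, water lands in the shell with
    probability v (uniform); urea with probability f v / (f v + 1 - v),
    i.e. its placement density in the shell is f times the outside
    density.
    """
    v = (4.0 / 3.0) * np.pi * spec.shell_radius**3 / spec.box**3
    if kind == "urea":
        f = spec.enrichment
        return f * v / (f * v + 1.0 - v)
    return v


def _sample_in_sphere(rng, n, center, radius):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return center + v * r[:, None]


def _sample_outside_sphere(rng, n, box, center, radius):
    out = np.empty((n, 3))
    todo = np.arange(n)
    while todo.size:
        cand = rng.uniform(0.0, box, size=(todo.size, 3))
        d = cand - center
        keep = (d * d).sum(axis=1) > radius**2
        out[todo[keep]] = cand[keep]
        todo = todo[~keep]
    return out


def _propose_positions(rng, n, box, center, shell_radius, in_shell):
    """Positions uniform within each molecule's assigned region.

    ``in_shell`` is a fixed boolean per molecule: membership is decided
    once (by an exact Bernoulli draw) and re-proposals stay inside the
    assigned region, so expected region counts are unaffected by
    hard-core rejection.
    """
    in_shell = np.atleast_1d(in_shell)
    out = np.empty((n, 3))
    k = int(in_shell.sum())
    if k:
        out[in_shell] = _sample_in_sphere(rng, k, center, shell_radius)
    if n - k:
        out[~in_shell] = _sample_outside_sphere(rng, n - k, box, center, shell_radius)
    return out


def build_solvent_box(
    spec: MixtureSpec,
    solute_template: MoleculeTemplate | None = None,
    n_frames: int = 1,
    max_attempts: int = 500,
    ideal: bool = False,
) -> tuple[Trajectory, BoxBookkeeping]:
    """Pack i.i.d. solvent configurations around a centered solute.

    Each molecule is first assigned to the enrichment shell or to the
    remainder of the box by an exact Bernoulli draw (water with the
    shell's volume fraction v, urea with f v / (f v + 1 - v), so urea
    placement density in the shell is f times the outside density);
    its position is then uniform within the assigned region and its
    orientation uniform. Placements clashing with the solute (non-H
    within 2.4 A of a solute non-H) or other solvent (non-H within
    1.8 A) are re-proposed within the same region, so the expected
    region counts — and hence the constructed two-domain Gamma — are
    exactly the closed-form values even with hard-core exclusion.

    With ``ideal=True`` all exclusion rules are skipped: molecules are
    non-interacting points with orientations, the strict ideal-mixture
    reference for which every solvent-composition statistic has its
    textbook null value.
    """
    from scipy.spatial import cKDTree

    solute = solute_template if solute_template is not None else purine_template()
    topology, order = _assemble_topology(solute, spec.n_urea, spec.n_water)
    rng = np.random.default_rng(spec.seed)
    box = float(spec.box)
    box3 = np.full(3, box)
    center = box3 / 2.0
    solute_pos = solute.coords + center
    solute_heavy = solute_pos[solute.heavy_mask()]

    n_mol = len(order)
    is_urea = np.array([tpl.kind == "urea" for tpl in order])
    urea_tpl = urea_template()
    water_tpl = water_template()
    n_heavy = np.where(is_urea, int(urea_tpl.heavy_mask().sum()),
                       int(water_tpl.heavy_mask().sum()))
    offsets = np.r_[0, np.cumsum(n_heavy)]
    heavy_mol = np.repeat(np.arange(n_mol), n_heavy)
    heavy_rows = {
        m: np.arange(offsets[m], offsets[m + 1]) for m in range(n_mol)
    }

    frames = []
    uin = np.zeros(n_frames)
    uout = np.zeros(n_frames)
    win = np.zeros(n_frames)
    wout = np.zeros(n_frames)
    p_shell = np.where(
        is_urea,
        shell_membership_probability(spec, "urea"),
        shell_membership_probability(spec, "water"),
    )
    for fr in range(n_frames):
        pos = np.zeros((n_mol, 3))
        rot = np.zeros((n_mol, 3, 3))
        heavy_flat = np.zeros((int(offsets[-1]), 3))
        membership = rng.random(n_mol) < p_shell
        need = np.ones(n_mol, dtype=bool)
        if ideal:
            for species, tpl in ((True, urea_tpl), (False, water_tpl)):
                sel = np.flatnonzero(is_urea == species)
                if sel.size == 0:
                    continue
                pos[sel] = _propose_positions(
                    rng, sel.size, box, center, spec.shell_radius,
                    membership[sel],
                )
                rot[sel] = _random_rotation(rng, sel.size).reshape(-1, 3, 3)
            need[:] = False
        for _ in range(max_attempts):
            idx = np.flatnonzero(need)
            if idx.size == 0:
                break
            if idx.size <= 32:
                # few stragglers left: place them one by one against the
                # full heavy-atom set instead of paying for global passes
                self_rows = np.concatenate([heavy_rows[m] for m in idx])
                occupied = np.ones(int(offsets[-1]), dtype=bool)
                occupied[self_rows] = False
                keeper_tree = cKDTree(heavy_flat[occupied] % box, boxsize=box)
                tail: list[np.ndarray] = []
                for m in idx:
                    tpl = urea_tpl if is_urea[m] else water_tpl
                    hc = tpl.coords[tpl.heavy_mask()]
                    done = False
                    for _ in range(max_attempts * 40):
                        p = _propose_positions(
                            rng, 1, box, center, spec.shell_radius,
                            membership[m],
                        )[0]
                        r1 = _random_rotation(rng)
                        cand = hc @ r1.T + p
                        d = minimum_image(
                            cand[:, None, :] - solute_heavy[None, :, :], box3
                        )
                        if np.any((d * d).sum(-1) < SOLUTE_EXCLUSION**2):
                            continue
                        hits = keeper_tree.query_ball_point(
                            cand % box, SOLVENT_EXCLUSION, return_length=True
                        )
                        if np.any(np.asarray(hits) > 0):
                            continue
                        if tail:
                            prev = np.vstack(tail)
                            d = minimum_image(
                                cand[:, None, :] - prev[None, :, :], box3
                            )
                            if np.any((d * d).sum(-1) < SOLVENT_EXCLUSION**2):
                                continue
                        pos[m], rot[m] = p, r1
                        heavy_flat[heavy_rows[m]] = cand
                        tail.append(cand)
                        need[m] = False
                        done = True
                        break
                    if not done:
                        raise PackingFailureError(
                            f"could not place a molecule after repeated "
                            f"attempts (frame {fr})"
                        )
                continue
            for species, tpl in ((True, urea_tpl), (False, water_tpl)):
                sel = idx[is_urea[idx] == species]
                if sel.size == 0:
                    continue
                pos[sel] = _propose_positions(
                    rng, sel.size, box, center, spec.shell_radius,
                    membership[sel],
                )
                rots = _random_rotation(rng, sel.size).reshape(-1, 3, 3)
                rot[sel] = rots
                hc = tpl.coords[tpl.heavy_mask()]
                new = np.einsum("mij,kj->mki", rots, hc) + pos[sel][:, None, :]
                rows = np.concatenate([heavy_rows[m] for m in sel])
                heavy_flat[rows] = new.reshape(-1, 3)
            wrapped = heavy_flat % box
            # clash with the solute
            d = minimum_image(wrapped[:, None, :] - solute_heavy[None, :, :], box3)
            bad_solute = (d * d).sum(axis=-1).min(axis=1) < SOLUTE_EXCLUSION**2
            reject = np.zeros(n_mol, dtype=bool)
            reject[np.unique(heavy_mol[bad_solute])] = True
            # solvent-solvent clashes (periodic tree)
            tree = cKDTree(wrapped, boxsize=box)
            pairs = tree.query_pairs(SOLVENT_EXCLUSION, output_type="ndarray")
            if pairs.size:
                ma = heavy_mol[pairs[:, 0]]
                mb = heavy_mol[pairs[:, 1]]
                inter = ma != mb
                for a, b in zip(ma[inter], mb[inter]):
                    # keepers always win; among fresh proposals the
                    # higher index yields
                    if need[a] and need[b]:
                        reject[max(a, b)] = True
                    elif need[a]:
                        reject[a] = True
                    elif need[b]:
                        reject[b] = True
            # keepers passed both checks when accepted, so reject <= need
            need = reject
        else:
            raise PackingFailureError(
                f"could not pack {int(need.sum())} molecule(s) after "
                f"{max_attempts} batched attempts (frame {fr})"
            )
        d = minimum_image(pos - center, box3)
        in_shell = (d * d).sum(axis=1) <= spec.shell_radius**2
        uin[fr] = int((in_shell & is_urea).sum())
        uout[fr] = int((~in_shell & is_urea).sum())
        win[fr] = int((in_shell & ~is_urea).sum())
        wout[fr] = int((~in_shell & ~is_urea).sum())
        blocks = [solute_pos]
        for species, tpl in ((True, urea_tpl), (False, water_tpl)):
            sel = np.flatnonzero(is_urea == species)
            if sel.size:
                full = np.einsum("mij,kj->mki", rot[sel], tpl.coords) + pos[sel][:, None, :]
                blocks.append(full.reshape(-1, 3))
        frames.append(Frame(np.vstack(blocks), box3, time=float(fr)))
    bookkeeping = BoxBookkeeping(
        shell_radius=spec.shell_radius,
        urea_in=uin, urea_out=uout, water_in=win, water_out=wout,
    )
    return Trajectory(topology, frames), bookkeeping


# ---------------------------------------------------------------------------
# two-state kinetics
# ---------------------------------------------------------------------------

def simulate_two_state(spec: TwoStateSpec) -> tuple[ContactSeries, float]:
    """Discrete-time Markov contact series; returns (series, 1/k_off).

    P(off -> on) = k_on dt, P(on -> off) = k_off dt per step; the
    initial state is drawn from the stationary occupancy
    k_on / (k_on + k_off). The analytic mean bound duration is 1/k_off
    (infinite in the absorbing k_off = 0 limit, where an initially
    bound molecule yields one unbroken dwell).
    """
    rng = np.random.default_rng(spec.seed)
    p_on = min(spec.k_on * spec.dt, 1.0)
    p_off = min(spec.k_off * spec.dt, 1.0)
    occ = spec.k_on / (spec.k_on + spec.k_off)
    state = rng.random(spec.n_molecules) < occ
    data = np.empty((spec.n_molecules, spec.n_frames), dtype=bool)
    for t in range(spec.n_frames):
        data[:, t] = state
        u = rng.random(spec.n_molecules)
        state = np.where(state, u >= p_off, u < p_on)
    true_lifetime = 1.0 / spec.k_off if spec.k_off > 0 else float("inf")
    return ContactSeries(data=data, dt=spec.dt, mode="two_state"), true_lifetime


# ---------------------------------------------------------------------------
# Brownian motion
# ---------------------------------------------------------------------------

def simulate_brownian(
    D: float,
    dt: float,
    n_frames: int,
    seed: int = 0,
    solute_template: MoleculeTemplate | None = None,
    box: float = 1e6,
) -> Trajectory:
    """Rigid solute translated along a Gaussian random walk.

    Per-step displacement variance is 2 D dt per dimension (Einstein
    relation); the box is huge so coordinates are effectively
    unwrapped.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    tpl = solute_template if solute_template is not None else purine_template()
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, 3))
    path = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]) + box / 2.0
    topology = Topology(tpl.make_atoms(0, 0))
    frames = [
        Frame(tpl.coords + path[i], np.full(3, box), time=i * dt)
        for i in range(n_frames)
    ]
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# posed urea geometries
# ---------------------------------------------------------------------------

def _unit(v):
    return v / np.linalg.norm(v)


def _perp(u):
    """A deterministic unit vector perpendicular to u."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(_unit(u), ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, ref))


def _rotation_between(a, b) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    a, b = _unit(np.asarray(a, float)), _unit(np.asarray(b, float))
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1.0 + 1e-12:  # antiparallel: rotate pi about any perpendicular
        p = _perp(a)
        return _axis_rotation(p, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_rotation(axis, angle) -> np.ndarray:
    axis = _unit(np.asarray(axis, float))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def pose_urea(
    base_frame: Frame,
    base_topology: Topology,
    mode: str,
    d: float,
    theta1: float | None = None,
    theta2: float | None = None,
    theta3: float | None = None,
    theta4: float | None = None,
    azimuth: float = 0.0,
) -> Trajectory:
    """Place one rigid urea at prescribed geometry around the base.

    ``mode="stacking"`` uses (d = COM-COM distance, theta1, theta2);
    ``mode="nh_pi"`` uses (d = base-COM to N distance, theta3, theta4);
    ``mode="hbond"`` uses d as the donor-acceptor heavy distance along
    the first base N-H direction. Angles in degrees; theta1 is
    reproduced up to its intrinsic 180-degree normal-sign ambiguity.
    """
    if d < 0:
        raise GeometryError("distance must be >= 0")
    tpl = urea_template()
    u = base_plane_normal(base_frame, base_topology)
    com = solute_center_of_mass(base_frame, base_topology)
    e1 = _axis_rotation(u, np.radians(azimuth)) @ _perp(u)

    if mode == "stacking":
        if theta1 is None or theta2 is None:
            raise GeometryError("stacking pose needs theta1 and theta2")
        t1, t2 = np.radians(theta1), np.radians(theta2)
        w = np.cos(t2) * u + np.sin(t2) * e1
        v = np.cos(t1) * u + np.sin(t1) * e1
        rot = _rotation_between(np.array([0.0, 0.0, 1.0]), v)
        coords = tpl.coords @ rot.T + (com + d * w)
    elif mode == "nh_pi":
        if theta3 is None or theta4 is None:
            raise GeometryError("nh_pi pose needs theta3 and theta4")
        t3, t4 = np.radians(theta3), np.radians(theta4)
        bond = 1.01  # template N-H length
        disc = d * d - (bond * np.sin(t3)) ** 2
        if disc < 0:
            raise GeometryError(
                f"no H position satisfies d={d}, theta3={theta3}"
            )
        r_h = bond * np.cos(t3) + np.sqrt(disc)
        if r_h <= 0:
            raise GeometryError("requested geometry puts H behind the base COM")
        w = np.cos(t4) * u + np.sin(t4) * e1
        p = _unit(np.cross(np.cross(w, u), w)) if abs(np.dot(w, u)) < 1 - 1e-9 else _perp(w)
        n_dir = np.cos(np.pi - t3) * w + np.sin(np.pi - t3) * p
        h_star = com + r_h * w
        n_star = h_star + bond * n_dir
        # rigid-map the template N1-H11 bond onto (n_star, h_star)
        n_t, h_t = tpl.coords[2], tpl.coords[4]
        rot0 = _rotation_between(h_t - n_t, h_star - n_star)
        # spin about the N-H axis: keep the other hydrogens farther from
        # the base COM than the posed one, so theta3/theta4 refer to it
        axis = _unit(h_star - n_star)
        best, best_margin = None, -np.inf
        h_idx = [i for i, r in enumerate(tpl.roles) if "urea_H" in r]
        other_h = [i for i in h_idx if i != 4]
        for phi in np.linspace(0.0, 2 * np.pi, 72, endpoint=False):
            rot = _axis_rotation(axis, phi) @ rot0
            coords = (tpl.coords - n_t) @ rot.T + n_star
            # margins by which the posed H stays the nearest hydrogen
            # and the posed N the nearest nitrogen to the base COM
            m_h = min(np.linalg.norm(coords[i] - com) for i in other_h) - r_h
            m_n = np.linalg.norm(coords[3] - com) - d
            margin = min(m_h, m_n)
            if margin > best_margin:
                best_margin, best = margin, coords
        coords = best
        if best_margin <= 0:
            raise GeometryError(
                "another urea H or N ends up closer to the base COM than the "
                "posed pair; geometry unrealizable"
            )
    elif mode == "hbond":
        donors = [
            i for i in base_topology.solute_indices
            if "donor_heavy" in base_topology.atoms[int(i)].roles
        ]
        hydros = [
            i for i in base_topology.solute_indices
            if "donor_hydrogen" in base_topology.atoms[int(i)].roles
        ]
        if not donors or not hydros:
            raise GeometryError("base has no donor for an hbond pose")
        dh = None
        for heavy in donors:
            for h in hydros:
                if np.linalg.norm(
                    base_frame.positions[int(h)] - base_frame.positions[int(heavy)]
                ) < 1.25:
                    dh = (int(heavy), int(h))
                    break
            if dh:
                break
        if dh is None:
            raise GeometryError("no bonded donor H found on the base")
        heavy, h = dh
        w = _unit(base_frame.positions[h] - base_frame.positions[heavy])
        o_star = base_frame.positions[heavy] + d * w
        o_t, c_t = tpl.coords[1], tpl.coords[0]
        rot0 = _rotation_between(c_t - o_t, -w)  # C points away from the base
        # spin about the donor axis so the urea's own N-H hydrogens stay
        # clear of the base: the posed contact is the only close approach
        base_pos = base_frame.positions[base_topology.solute_indices]
        best, best_min = None, -np.inf
        for phi in np.linspace(0.0, 2 * np.pi, 36, endpoint=False):
            rot = _axis_rotation(-w, phi) @ rot0
            cand = (tpl.coords - o_t) @ rot.T + o_star
            dmin = float(
                np.linalg.norm(
                    cand[2:, None, :] - base_pos[None, :, :], axis=-1
                ).min()
            )
            if dmin > best_min:
                best_min, best = dmin, cand
        coords = best
    else:
        raise GeometryError(f"unknown pose mode {mode!r}")

    atoms = [a for a in base_topology.atoms]
    next_mol = int(max(a.molecule_id for a in atoms)) + 1
    atoms.extend(tpl.make_atoms(next_mol, len(atoms)))
    frame = Frame(
        np.vstack([base_frame.positions, coords]), base_frame.box,
        time=base_frame.time,
    )
    return Trajectory(Topology(atoms), [frame])


# ---------------------------------------------------------------------------
# synthetic RDF curves
# ---------------------------------------------------------------------------

def synthesize_rdf(
    a: float, b: float, c: float, d: float, e: float,
    r_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    rho: float = 0.01,
) -> RDFProfile:
    """Damped-sinusoid RDF with known parameters plus optional noise."""
    r = np.asarray(r_grid, dtype=float)
    g = long_range_model(r, a, b, c, d, e)
    if noise_sd > 0:
        g = g + np.random.default_rng(seed).normal(0.0, noise_sd, size=r.size)
    return RDFProfile(
        r=r, g=g, bin_width=float(r[1] - r[0]), target="synthetic",
        reference="synthetic", n_frames=1, rho=rho,
    )
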