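"""Geometry measurement, mode classifiers, spatial density grids."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare, kstest

from solvshell.core import Frame, Topology, Trajectory, angle_between_deg
from solvshell.modes import (
    InteractionGeometry,
    classify_hbond,
    classify_nh_pi,
    classify_stacking,
    measure_geometry,
    mode_distribution,
    region_radius_for,
    spatial_density,
    write_cube,
)
from solvshell.synth import _axis_rotation, _rotation_between, pose_urea
from solvshell.templates import (
    pyrimidine_template,
    solute_only_topology,
    urea_template,
)


def reference_stacking(d, t1, t2):
    """Independently coded stacking predicate (interval logic)."""
    in_d = d <= 4.5
    in_t1 = (0 <= t1 < 40) or (140 < t1 <= 180)
    in_t2 = (0 <= t2 < 70) or (110 <= t2 <= 180)
    return in_d and in_t1 and in_t2


def reference_nh_pi(dn, t3, t4):
    in_d = dn < 4.5
    in_t4 = (t4 > 150) or (t4 < 30)
    return in_d and in_t4 and (t3 > 150)


def _geom(**kw):
    base = dict(d_com=3.0, d_comN=3.0, theta1=10.0, theta2=30.0,
                theta3=160.0, theta4=160.0)
    base.update(kw)
    return InteractionGeometry(**base)


class TestClassifiers:
    def test_observed_high_density_geometries(self):
        assert classify_stacking(_geom(d_com=3.4, theta1=10, theta2=35))
        assert classify_nh_pi(_geom(d_comN=3.8, theta4=157, theta3=160))

    def test_distance_gates(self):
        assert not classify_stacking(_geom(d_com=4.6))
        assert not classify_nh_pi(_geom(d_comN=4.5))

    def test_linearity_gate(self):
        assert not classify_nh_pi(_geom(theta3=120.0))

    def test_agreement_with_reference_predicates(self):
        rng = np.random.default_rng(99)
        n = 10_000
        d = rng.uniform(0, 6, n)
        dn = rng.uniform(0, 6, n)
        t1, t2, t3, t4 = rng.uniform(0, 180, (4, n))
        for i in range(n):
            g = InteractionGeometry(d[i], dn[i], t1[i], t2[i], t3[i], t4[i])
            assert classify_stacking(g) == reference_stacking(d[i], t1[i], t2[i])
            assert classify_nh_pi(g) == reference_nh_pi(dn[i], t3[i], t4[i])

    def test_stacking_impossible_beyond_distance_gate(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            g = _geom(d_com=rng.uniform(4.5001, 10),
                      theta1=rng.uniform(0, 180), theta2=rng.uniform(0, 180))
            assert not classify_stacking(g)


class TestMeasureGeometry:
    def test_coaxial_parallel_pose(self, purine_frame, purine_topology):
        traj = pose_urea(purine_frame, purine_topology, "stacking",
                         d=3.4, theta1=0.0, theta2=0.0)
        g = measure_geometry(traj[0], traj.topology, 1)
        assert g.d_com == pytest.approx(3.4, abs=1e-6)
        assert min(g.theta1, 180 - g.theta1) == pytest.approx(0.0, abs=1e-6)
        assert min(g.theta2, 180 - g.theta2) == pytest.approx(0.0, abs=1e-6)

    def test_in_plane_pose_theta2_90(self, purine_frame, purine_topology):
        traj = pose_urea(purine_frame, purine_topology, "stacking",
                         d=4.0, theta1=0.0, theta2=90.0)
        g = measure_geometry(traj[0], traj.topology, 1)
        assert g.theta2 == pytest.approx(90.0, abs=1e-6)

    def test_angles_in_valid_range(self, purine_frame, purine_topology):
        rng = np.random.default_rng(12)
        for _ in range(20):
            traj = pose_urea(
                purine_frame, purine_topology, "stacking",
                d=rng.uniform(3, 6), theta1=rng.uniform(0, 180),
                theta2=rng.uniform(0, 180), azimuth=rng.uniform(0, 360),
            )
            g = measure_geometry(traj[0], traj.topology, 1)
            for ang in (g.theta1, g.theta2, g.theta3, g.theta4):
                assert 0.0 <= ang <= 180.0
            assert g.d_com >= 0 and g.d_comN >= 0

    def test_rigid_motion_invariance(self, purine_frame, purine_topology):
        rng = np.random.default_rng(31)
        traj = pose_urea(purine_frame, purine_topology, "stacking",
                         d=3.6, theta1=20.0, theta2=40.0)
        g0 = measure_geometry(traj[0], traj.topology, 1)
        for i in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-5, 5, 3)
            center = traj[0].box / 2
            pos = (traj[0].positions - center) @ rot.T + center + shift
            moved = Frame(pos % traj[0].box, traj[0].box)
            g1 = measure_geometry(moved, traj.topology, 1)
            assert g1.d_com == pytest.approx(g0.d_com, abs=1e-8)
            assert min(g1.theta1, 180 - g1.theta1) == pytest.approx(
                min(g0.theta1, 180 - g0.theta1), abs=1e-6
            )
            assert g1.theta3 == pytest.approx(g0.theta3, abs=1e-6)
            assert classify_stacking(g1) == classify_stacking(g0)

    def test_periodic_wrapping_invariance(self, purine, purine_topology):
        # translate whole molecules by lattice vectors (molecules are
        # stored whole, so wrapping acts per molecule, not per atom)
        frame = Frame(purine.coords + 1.0, np.full(3, 30.0))
        top = purine_topology
        traj = pose_urea(frame, top, "stacking", d=3.5, theta1=5.0, theta2=20.0)
        rng = np.random.default_rng(6)
        pos = traj[0].positions.copy()
        for mid in (0, 1):
            idx = traj.topology.molecule_indices(mid)
            pos[idx] += rng.integers(-2, 3, 3) * 30.0
        wrapped = Frame(pos, traj[0].box)
        g0 = measure_geometry(traj[0], traj.topology, 1)
        g1 = measure_geometry(wrapped, traj.topology, 1)
        assert g1.d_com == pytest.approx(g0.d_com, abs=1e-8)
        assert g1.theta2 == pytest.approx(g0.theta2, abs=1e-6)


class TestHbond:
    def test_canonical_geometry(self, purine_frame, purine_topology):
        traj = pose_urea(purine_frame, purine_topology, "hbond", d=2.9)
        assert classify_hbond(traj[0], traj.topology, 1)

    def test_distance_gate(self, purine_frame, purine_topology):
        traj = pose_urea(purine_frame, purine_topology, "hbond", d=3.6)
        assert not classify_hbond(traj[0], traj.topology, 1)

    def test_matches_brute_force_predicate(self, purine_frame, purine_topology):
        rng = np.random.default_rng(55)
        urea = urea_template()
        hits = 0
        for _ in range(150):
            rot = Rotation.random(rng=rng).as_matrix()
            offset = rng.normal(size=3)
            offset *= rng.uniform(3.0, 6.0) / np.linalg.norm(offset)
            coords = urea.coords @ rot.T + purine_frame.positions.mean(axis=0) + offset
            atoms = list(purine_topology.atoms) + urea.make_atoms(1, len(purine_topology))
            top = Topology(atoms)
            frame = Frame(np.vstack([purine_frame.positions, coords]), purine_frame.box)
            got = classify_hbond(frame, top, 1)
            expect = self._brute_force_hbond(frame, top)
            assert got == expect
            hits += got
        assert hits > 0  # the sweep must actually exercise the true branch

    @staticmethod
    def _brute_force_hbond(frame, top, dmax=3.5, amin=150.0):
        """Triple loop over donors/hydrogens/acceptors, both directions."""
        def sets(kind):
            idx = [i for i, a in enumerate(top.atoms) if a.molecule_kind == kind]
            return (
                [i for i in idx if "donor_heavy" in top.atoms[i].roles],
                [i for i in idx if "donor_hydrogen" in top.atoms[i].roles],
                [i for i in idx if "acceptor" in top.atoms[i].roles],
            )

        b_dh, b_h, b_acc = sets("solute")
        u_dh, u_h, u_acc = sets("urea")
        p = frame.positions
        for dh_list, h_list, acc_list in ((b_dh, b_h, u_acc), (u_dh, u_h, b_acc)):
            for dd in dh_list:
                for h in h_list:
                    if np.linalg.norm(p[h] - p[dd]) >= 1.25:
                        continue
                    for acc in acc_list:
                        if np.linalg.norm(p[acc] - p[dd]) > dmax:
                            continue
                        ang = angle_between_deg(p[dd] - p[h], p[acc] - p[h])
                        if ang >= amin:
                            return True
        return False


class TestModeOverlap:
    def test_stacking_and_nh_pi_can_coincide(self, purine_frame, purine_topology):
        """The gates are not mutually exclusive: a tilted urea whose N-H
        points down at the ring COM can satisfy both mode definitions."""
        tpl = urea_template()
        u = np.array([0.0, 0.0, 1.0])
        e1 = np.array([1.0, 0.0, 0.0])
        com = purine_frame.positions.mean(axis=0)
        from solvshell.core import solute_center_of_mass

        com = solute_center_of_mass(purine_frame, purine_topology)
        bond = 1.01
        found = False
        for t4 in (22.0, 26.0, 28.0):
            for t3 in (152.0, 155.0, 158.0):
                for dist in (3.6, 3.9):
                    t3r, t4r = np.radians(t3), np.radians(t4)
                    disc = dist**2 - (bond * np.sin(t3r)) ** 2
                    r_h = bond * np.cos(t3r) + np.sqrt(disc)
                    w = np.cos(t4r) * u + np.sin(t4r) * e1
                    p = -(u - np.dot(u, w) * w)
                    p /= np.linalg.norm(p)
                    n_dir = np.cos(np.pi - t3r) * w + np.sin(np.pi - t3r) * p
                    h_star = com + r_h * w
                    n_star = h_star + bond * n_dir
                    n_t, h_t = tpl.coords[2], tpl.coords[4]
                    rot0 = _rotation_between(h_t - n_t, h_star - n_star)
                    axis = (h_star - n_star) / bond
                    for phi in np.linspace(0, 2 * np.pi, 90, endpoint=False):
                        rot = _axis_rotation(axis, phi) @ rot0
                        coords = (tpl.coords - n_t) @ rot.T + n_star
                        atoms = list(purine_topology.atoms) + tpl.make_atoms(
                            1, len(purine_topology)
                        )
                        top = Topology(atoms)
                        frame = Frame(
                            np.vstack([purine_frame.positions, coords]),
                            purine_frame.box,
                        )
                        g = measure_geometry(frame, top, 1)
                        if classify_stacking(g) and classify_nh_pi(g):
                            found = True
                            break
                    if found:
                        break
                if found:
                    break
            if found:
                break
        assert found


@pytest.fixture()
def frozen_pose_trajectory(purine_frame, purine_topology):
    posed = pose_urea(purine_frame, purine_topology, "stacking",
                      d=3.4, theta1=5.0, theta2=10.0)
    frames = [Frame(posed[0].positions.copy(), posed[0].box, time=float(t))
              for t in range(50)]
    return Trajectory(posed.topology, frames)


class TestSpatialDensity:
    def test_frozen_pose_occupies_one_voxel(self, frozen_pose_trajectory):
        grid = spatial_density(frozen_pose_trajectory, "C")
        assert grid.counts.sum() == 50
        assert (grid.counts > 0).sum() == 1

    def test_count_conservation(self, frozen_pose_trajectory):
        for kind, n_atoms in (("C", 1), ("N", 2), ("O", 1)):
            grid = spatial_density(frozen_pose_trajectory, kind)
            assert grid.counts.sum() == 50 * n_atoms

    def test_region_radius_by_solute_class(self, purine_topology):
        assert region_radius_for(purine_topology) == pytest.approx(7.75)
        pyr = solute_only_topology(pyrimidine_template())
        assert region_radius_for(pyr) == pytest.approx(7.05)

    def test_grid_edge_is_twice_region_radius(self, frozen_pose_trajectory):
        grid = spatial_density(frozen_pose_trajectory, "C")
        assert grid.spacing * grid.counts.shape[0] == pytest.approx(2 * 7.75)

    def test_uniform_sphere_passes_uniformity_checks(self, purine, purine_topology):
        # points drawn uniformly in the region sphere, binned via the
        # density machinery with inclusion clipping disabled
        rng = np.random.default_rng(77)
        urea = urea_template()
        n_urea = 30
        atoms = list(purine_topology.atoms)
        for j in range(n_urea):
            atoms.extend(urea.make_atoms(1 + j, len(atoms)))
        top = Topology(atoms)
        frames = []
        radius = 7.75 * 0.98
        for t in range(60):
            coords = [purine.coords + 30.0]
            for _ in range(n_urea):
                v = rng.normal(size=3)
                v *= radius * rng.random() ** (1 / 3) / np.linalg.norm(v)
                rot = Rotation.random(rng=rng).as_matrix()
                coords.append(urea.coords @ rot.T * 0.0 + 30.0 + v)
            frames.append(Frame(np.vstack(coords), np.full(3, 60.0), time=float(t)))
        traj = Trajectory(top, frames)
        grid = spatial_density(traj, "C", inclusion_cutoff=np.inf)
        n = grid.counts.shape[0]
        centers = (np.arange(n) + 0.5) * grid.spacing + grid.origin[0]
        x, y, z = np.meshgrid(centers, centers, centers, indexing="ij")
        # octant chi-square: equal expected mass in each octant
        octant = (x > 0).astype(int) * 4 + (y > 0).astype(int) * 2 + (z > 0)
        counts = np.array([grid.counts[octant == k].sum() for k in range(8)])
        assert counts.sum() == 60 * n_urea
        _, p = chisquare(counts)
        assert p > 0.01
        # radial mass follows r^3 for a uniform ball
        r = np.sqrt(x**2 + y**2 + z**2)
        w = grid.counts.ravel()
        sample = np.repeat(r.ravel(), w)
        _, p_r = kstest((sample / radius) ** 3, "uniform")
        assert p_r > 0.001

    def test_cube_export_round_trips_counts(self, frozen_pose_trajectory, tmp_path):
        grid = spatial_density(frozen_pose_trajectory, "C")
        path = tmp_path / "density.cube"
        write_cube(grid, path, frozen_pose_trajectory[0],
                   frozen_pose_trajectory.topology, normalize=False)
        lines = path.read_text().splitlines()
        n_atoms = int(lines[2].split()[0])
        values = []
        for line in lines[6 + n_atoms:]:
            values.extend(float(v) for v in line.split())
        assert sum(values) == pytest.approx(grid.counts.sum())


class TestModeDistribution:
    def test_identical_geometries_single_bin(self):
        geoms = [_geom() for _ in range(25)]
        hist, _, _ = mode_distribution(geoms, "stacking")
        assert hist.sum() == pytest.approx(1.0)
        assert (hist > 0).sum() == 1
        assert hist.max() == pytest.approx(1.0)

    def test_normalization_always(self):
        rng = np.random.default_rng(2)
        geoms = [
            _geom(d_com=rng.uniform(0.2, 5.8), theta2=rng.uniform(0, 180))
            for _ in range(500)
        ]
        hist, _, _ = mode_distribution(geoms, "stacking")
        assert hist.sum() == pytest.approx(1.0)

    def test_marginal_means_match_generator(self):
        rng = np.random.default_rng(3)
        d = rng.normal(3.5, 0.2, 4000).clip(0.1, 5.9)
        a = rng.normal(40.0, 5.0, 4000).clip(0, 179.9)
        geoms = [_geom(d_comN=di, theta4=ai) for di, ai in zip(d, a)]
        hist, d_edges, a_edges = mode_distribution(geoms, "nh_pi")
        d_mid = 0.5 * (d_edges[:-1] + d_edges[1:])
        a_mid = 0.5 * (a_edges[:-1] + a_edges[1:])
        mean_d = (hist.sum(axis=1) * d_mid).sum()
        mean_a = (hist.sum(axis=0) * a_mid).sum()
        assert mean_d == pytest.approx(d.mean(), abs=0.05)
        assert mean_a == pytest.approx(a.mean(), abs=1.0)
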