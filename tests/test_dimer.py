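"""Dimer hinge geometry, H-bond counting, moving averages and RMSF."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from membind import (
    BindingMode,
    EncounterParams,
    HBondCriterion,
    build_bilayer,
    build_synthetic_dimer,
    count_hbonds,
    hinge_angle_series,
    moving_average,
    rmsf,
    simulate_dimer_encounter,
    subunit_distance_series,
)
from membind.core import Frame, Topology, Trajectory
from membind.dimer import UndefinedAngleError
from membind.geometry import min_image_displacement


def point_system(points, names=None, box=(50.0, 50.0, 50.0), n_frames=1,
                 coords_per_frame=None):
    n = len(points)
    names = np.array(names if names is not None else ["CA"] * n)
    topology = Topology(
        names=names,
        residue_indices=np.arange(1, n + 1),
        residue_names=np.array(["ALA"] * n),
        subunits=np.array(["A"] * n),
        masses=np.full(n, 12.0),
        species=np.array(["protein"] * n),
        headgroup=np.zeros(n, dtype=bool))
    if coords_per_frame is None:
        coords_per_frame = [np.asarray(points, float)] * n_frames
    frames = [Frame(time=float(i), coordinates=np.asarray(c, float),
                    box=np.asarray(box, float))
              for i, c in enumerate(coords_per_frame)]
    return Trajectory(topology=topology, frames=frames)


class TestHingeAngle:
    def test_collinear_points_give_180(self):
        traj = point_system([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        s = hinge_angle_series(traj, "resid 1", "resid 2", "resid 3")
        assert s.theta[0] == pytest.approx(180.0)

    def test_right_angle(self):
        traj = point_system([[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        s = hinge_angle_series(traj, "resid 1", "resid 2", "resid 3")
        assert s.theta[0] == pytest.approx(90.0)

    def test_coincident_points_raise(self):
        traj = point_system([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(UndefinedAngleError):
            hinge_angle_series(traj, "resid 1", "resid 2", "resid 3")

    def test_synthetic_crystallographic_dimer_is_flat(self):
        """The side-by-side dimer built with crystal geometry reads ~180 deg
        at the default catalytic-lysine / interface-valine anchors."""
        topology, frame = build_synthetic_dimer(hinge_angle=180.0, seed=0)
        traj = Trajectory(topology=topology, frames=[frame])
        s = hinge_angle_series(traj)
        assert s.theta[0] == pytest.approx(180.0, abs=1e-6)

    @pytest.mark.parametrize("angle", [140.0, 110.0])
    def test_bent_dimer_angles_reproduced(self, angle):
        topology, frame = build_synthetic_dimer(hinge_angle=angle, seed=1)
        traj = Trajectory(topology=topology, frames=[frame])
        s = hinge_angle_series(traj)
        assert s.theta[0] == pytest.approx(angle, abs=1e-6)

    def test_invariant_under_rigid_motion(self, rng):
        topology, frame = build_synthetic_dimer(hinge_angle=150.0, seed=2)
        R = Rotation.random(rng=rng).as_matrix()
        moved = frame.coordinates @ R.T + rng.normal(size=3)
        traj = Trajectory(topology=topology, frames=[
            Frame(time=0.0, coordinates=moved, box=frame.box)])
        s = hinge_angle_series(traj)
        assert s.theta[0] == pytest.approx(150.0, abs=1e-8)


class TestSubunitDistances:
    def test_static_lysine_height(self):
        traj = point_system([[5, 5, 3]])
        lipid = Topology(
            names=np.array(["PO4"]), residue_indices=np.array([2]),
            residue_names=np.array(["POPC"]), subunits=np.array(["M"]),
            masses=np.array([72.0]), species=np.array(["PC"]),
            headgroup=np.array([True]))
        top = traj.topology.concat(lipid)
        coords = np.vstack([traj.frames[0].coordinates, [[5, 5, 0]]])
        t = Trajectory(topology=top, frames=[
            Frame(time=0.0, coordinates=coords, box=[50., 50., 50.])])
        s = subunit_distance_series(t, "species protein", "species PC")
        assert s.values[0] == pytest.approx(3.0)

    def test_one_subunit_bound_dimer_plateaus_lower(self):
        dimer = build_synthetic_dimer(seed=0)
        bilayer = build_bilayer(seed=1)
        params = EncounterParams(n_frames=300, dt=0.5, tau=15.0,
                                 noise_sigma=0.05,
                                 modes=(BindingMode(rzz=1.0, weight=1.0),),
                                 seed=3)
        traj, truth = simulate_dimer_encounter(dimer, bilayer, params,
                                               unbound_offset=2.5)
        sa = subunit_distance_series(traj, "subunit A and species protein",
                                     "not species protein")
        sb = subunit_distance_series(traj, "subunit B and species protein",
                                     "not species protein")
        tail = slice(-50, None)
        assert sa.values[tail].mean() < sb.values[tail].mean() - 1.0
        assert sa.values[tail].mean() == pytest.approx(
            truth.params.bound_distance, abs=0.3)


def hbond_system(coords, box=(20.0, 20.0, 20.0)):
    n = len(coords)
    topology = Topology(
        names=np.array([f"X{i}" for i in range(n)]),
        residue_indices=np.arange(1, n + 1),
        residue_names=np.array(["ALA"] * n),
        subunits=np.array(["A"] * n),
        masses=np.full(n, 12.0),
        species=np.array(["protein"] * n),
        headgroup=np.zeros(n, dtype=bool))
    return Trajectory(topology=topology, frames=[
        Frame(time=0.0, coordinates=np.asarray(coords, float),
              box=np.asarray(box, float))])


class TestCountHbonds:
    def test_ideal_geometry_counts_one(self):
        # donor at origin, H on the D->A axis, acceptor at 0.30 nm
        traj = hbond_system([[0, 0, 0], [0.1, 0, 0], [0.3, 0, 0]])
        counts = count_hbonds(traj, [0], {0: [1]}, [2])
        assert counts[0] == 1

    def test_distance_cutoff_excludes(self):
        traj = hbond_system([[0, 0, 0], [0.1, 0, 0], [0.4, 0, 0]])
        assert count_hbonds(traj, [0], {0: [1]}, [2])[0] == 0

    def test_angle_cutoff_excludes(self):
        # hydrogen at 90 degrees off the D->A axis
        traj = hbond_system([[0, 0, 0], [0, 0.1, 0], [0.3, 0, 0]])
        assert count_hbonds(traj, [0], {0: [1]}, [2])[0] == 0

    def test_donor_without_hydrogen_raises(self):
        traj = hbond_system([[0, 0, 0], [0.3, 0, 0]])
        with pytest.raises(ValueError, match="hydrogen"):
            count_hbonds(traj, [0], {}, [1])

    def test_matches_triple_loop_oracle(self, rng):
        """Implementation equals a naive loop over (D, H, A) triples."""
        box = np.array([3.0, 3.0, 3.0])
        crit = HBondCriterion()
        for _ in range(25):
            n_d, n_a = 5, 12
            donors = list(range(n_d))
            acceptors = list(range(n_d * 2, n_d * 2 + n_a))
            coords = rng.uniform(0, 3, (n_d * 2 + n_a, 3))
            hmap = {d: [n_d + d] for d in donors}
            traj = hbond_system(coords, box=box)
            got = count_hbonds(traj, donors, hmap, acceptors, crit)[0]
            expected = 0
            for d in donors:
                for h in hmap[d]:
                    for a in acceptors:
                        da = min_image_displacement(coords[d], coords[a], box)
                        if np.linalg.norm(da) > crit.max_da_distance:
                            continue
                        dh = min_image_displacement(coords[d], coords[h], box)
                        cosang = np.dot(dh, da) / (
                            np.linalg.norm(dh) * np.linalg.norm(da))
                        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) \
                                <= crit.max_hda_angle:
                            expected += 1
            assert got == expected

    def test_monotone_in_cutoffs(self, rng):
        box = np.array([2.0, 2.0, 2.0])
        coords = rng.uniform(0, 2, (20, 3))
        donors = list(range(5))
        hmap = {d: [5 + d] for d in donors}
        acceptors = list(range(10, 20))
        traj = hbond_system(coords, box=box)
        prev = -1
        for dmax in (0.2, 0.35, 0.6, 1.0):
            c = count_hbonds(traj, donors, hmap, acceptors,
                             HBondCriterion(max_da_distance=dmax,
                                            max_hda_angle=30.0))[0]
            assert c >= prev
            prev = c
        prev = -1
        for amax in (10.0, 30.0, 90.0, 179.0):
            c = count_hbonds(traj, donors, hmap, acceptors,
                             HBondCriterion(max_da_distance=0.6,
                                            max_hda_angle=amax))[0]
            assert c >= prev
            prev = c


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        x = np.full(20, 3.0)
        np.testing.assert_allclose(moving_average(x, window=5.0), 3.0)

    def test_alternating_series_flattens(self):
        x = np.tile([0.0, 2.0], 50)
        out = moving_average(x, window=40.0)
        np.testing.assert_allclose(out[20:-20], 1.0, atol=0.06)

    def test_output_length_equals_input_length(self, rng):
        for n in (1, 2, 7, 100):
            x = rng.normal(size=n)
            assert len(moving_average(x, window=3.0)) == n


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        traj = point_system(pts, n_frames=4)
        _, fluct = rmsf(traj)
        np.testing.assert_allclose(fluct, 0.0, atol=1e-12)

    def test_two_point_alternation_gives_amplitude(self):
        """One residue alternating +-a about its mean has RMSF = a.

        The rigid-body fit absorbs ~1/n of a single residue's motion, so a
        large particle count keeps the closed form accurate.
        """
        rng = np.random.default_rng(1)
        base = rng.normal(size=(60, 3)) * 3.0
        a = 0.25
        up = base.copy()
        up[0, 0] += a
        down = base.copy()
        down[0, 0] -= a
        traj = point_system(base, coords_per_frame=[up, down] * 10,
                            n_frames=20)
        _, fluct = rmsf(traj)
        assert fluct[0] == pytest.approx(a, rel=0.05)
        np.testing.assert_allclose(fluct[1:], 0.0, atol=0.02)

    def test_rigid_body_motion_removed(self, rng):
        base = rng.normal(size=(15, 3)) * 2.0
        frames = []
        for i in range(12):
            R = Rotation.from_euler("xyz", rng.uniform(-40, 40, 3),
                                    degrees=True).as_matrix()
            frames.append(base @ R.T + rng.normal(size=3))
        traj = point_system(base, coords_per_frame=frames, n_frames=12)
        _, fluct = rmsf(traj)
        np.testing.assert_allclose(fluct, 0.0, atol=1e-8)

    def test_selection_without_backbone_raises(self):
        traj = point_system([[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                            names=["O1", "O2", "O3"], n_frames=2)
        with pytest.raises(Exception, match="backbone|Ca"):
            rmsf(traj)
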