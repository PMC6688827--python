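"""Distance series, exponential binding fits and contact analysis."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from membind import (
    BindingMode,
    DistanceSeries,
    EncounterParams,
    com_distance_series,
    contact_timeseries,
    count_proximal_lipids,
    ensemble_mean,
    fit_binding_curve,
    normalize_profile,
    residue_contact_profile,
    simulate_encounter,
)
from membind.binding import ContactProfile
from membind.core import Frame, SelectionError, Topology, Trajectory
from membind.geometry import min_image_distance


def make_system(protein_xyz, lipid_xyz, box=(10.0, 10.0, 10.0),
                lipid_species="PI4P", n_frames=1):
    """Tiny hand-built system: one-bead residues + one-bead lipids."""
    protein_xyz = np.asarray(protein_xyz, float)
    lipid_xyz = np.asarray(lipid_xyz, float)
    n_p, n_l = len(protein_xyz), len(lipid_xyz)
    topology = Topology(
        names=np.array(["BB"] * n_p + ["PO4"] * n_l),
        residue_indices=np.arange(1, n_p + n_l + 1),
        residue_names=np.array(["ALA"] * n_p + ["POP4"] * n_l),
        subunits=np.array(["A"] * n_p + ["M"] * n_l),
        masses=np.full(n_p + n_l, 72.0),
        species=np.array(["protein"] * n_p + [lipid_species] * n_l),
        headgroup=np.array([False] * n_p + [True] * n_l))
    coords = np.vstack([protein_xyz, lipid_xyz])
    frames = [Frame(time=float(i), coordinates=coords.copy(),
                    box=np.asarray(box, float)) for i in range(n_frames)]
    return Trajectory(topology=topology, frames=frames)


class TestComDistanceSeries:
    def test_constant_z_component(self):
        traj = make_system([[5, 5, 8]], [[5, 5, 0]], box=(10, 10, 50),
                           n_frames=3)
        s = com_distance_series(traj, "species protein", "species PI4P",
                                metric="z_component")
        np.testing.assert_allclose(s.values, 8.0)

    def test_euclidean_with_xy_offset(self):
        traj = make_system([[8, 9, 8]], [[5, 5, 0]],
                           box=(50.0, 50.0, 50.0))
        s = com_distance_series(traj, "species protein", "species PI4P",
                                metric="euclidean3d")
        np.testing.assert_allclose(s.values, np.sqrt(9 + 16 + 64))

    def test_matches_planted_exponential(self, bound_run, fast_params):
        traj, _ = bound_run
        s = com_distance_series(traj, "species protein",
                                "not species protein", metric="z_component")
        p = fast_params
        expected = p.bound_distance + \
            (p.start_distance - p.bound_distance) * np.exp(-s.times / p.tau)
        np.testing.assert_allclose(s.values, expected, atol=1e-9)

    def test_empty_selection_raises(self):
        traj = make_system([[5, 5, 8]], [[5, 5, 0]])
        with pytest.raises(SelectionError):
            com_distance_series(traj, "species PIP2", "species PI4P")


class TestEnsembleMean:
    def test_pointwise_mean(self):
        a = DistanceSeries(times=[0, 1, 2], values=[4, 4, 4])
        b = DistanceSeries(times=[0, 1, 2], values=[6, 6, 6])
        np.testing.assert_allclose(ensemble_mean([a, b]).values, 5.0)

    def test_single_series_is_identity(self):
        a = DistanceSeries(times=[0, 1, 2], values=[1, 2, 3])
        np.testing.assert_allclose(ensemble_mean([a]).values, a.values)

    def test_mismatched_grids_raise_without_resample(self):
        a = DistanceSeries(times=[0, 1, 2], values=[1, 2, 3])
        b = DistanceSeries(times=[0, 0.5, 1], values=[1, 2, 3])
        with pytest.raises(ValueError):
            ensemble_mean([a, b])
        out = ensemble_mean([a, b], resample=True)
        assert len(out) == 3

    def test_ensemble_tau_within_5_percent(self, protein, bilayer):
        """Mean curve over 25 seeded replicates recovers the planted tau."""
        base = EncounterParams(n_frames=800, dt=0.5, tau=50.0,
                               noise_sigma=0.3,
                               modes=(BindingMode(rzz=1.0, weight=1.0),))
        series = []
        for seed in range(25):
            traj, _ = simulate_encounter(protein, bilayer,
                                         replace(base, seed=seed))
            series.append(com_distance_series(
                traj, "species protein", "not species protein",
                metric="z_component"))
        fit = fit_binding_curve(ensemble_mean(series))
        assert fit.converged
        assert fit.tau == pytest.approx(50.0, rel=0.05)


class TestFitBindingCurve:
    def test_noiseless_parameters_recovered(self):
        t = np.arange(0, 1000, 0.5)
        d = 4.0 + (8.0 - 4.0) * np.exp(-t / 50.0)
        fit = fit_binding_curve(DistanceSeries(times=t, values=d))
        assert fit.converged
        assert fit.d0 == pytest.approx(8.0, abs=1e-6)
        assert fit.d_inf == pytest.approx(4.0, abs=1e-6)
        assert fit.tau == pytest.approx(50.0, rel=1e-6)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            fit_binding_curve(DistanceSeries(times=[0, 1, 2, 3],
                                             values=[2, 2, 2, 2]))

    def test_scale_equivariance(self, rng):
        """Scaling times by c scales the fitted tau by c."""
        t = np.arange(0, 500, 0.5)
        d = 4.0 + 4.0 * np.exp(-t / 70.0) + rng.normal(0, 0.05, t.size)
        tau1 = fit_binding_curve(DistanceSeries(times=t, values=d)).tau
        for c in (0.1, 3.0, 10.0):
            tauc = fit_binding_curve(
                DistanceSeries(times=c * t, values=d)).tau
            assert tauc == pytest.approx(c * tau1, rel=1e-6)


class TestContacts:
    def test_contact_below_cutoff_counts(self):
        traj = make_system([[5, 5, 5]], [[5, 5, 5.65]], n_frames=4)
        p = residue_contact_profile(traj, cutoff=0.7)
        assert p.raw[0] == 4

    def test_cutoff_is_strict(self):
        traj = make_system([[5, 5, 5]], [[5, 5, 5.70]], n_frames=4)
        p = residue_contact_profile(traj, cutoff=0.7)
        assert p.raw[0] == 0

    @pytest.mark.parametrize("mode", ["min_particle", "com"])
    def test_matches_naive_oracle_on_random_frames(self, rng, mode):
        """Vectorised counts equal an O(N*M) double loop, 50 random frames."""
        box = np.array([6.0, 6.0, 6.0])
        for _ in range(50):
            n_res, n_lip = 50, 20
            traj = make_system(rng.uniform(0, 6, (n_res, 3)),
                               rng.uniform(0, 6, (n_lip, 3)), box=box)
            cutoff = float(rng.uniform(0.3, 1.5))
            series = contact_timeseries(traj, cutoff=cutoff, mode=mode)
            coords = traj.frames[0].coordinates
            expected = np.zeros(n_res, dtype=int)
            for i in range(n_res):        # one bead per residue: min_particle
                for j in range(n_lip):    # and com coincide on this system
                    if min_image_distance(coords[i], coords[n_res + j],
                                          box) < cutoff:
                        expected[i] = 1
                        break
            np.testing.assert_array_equal(series.matrix[:, 0], expected)

    def test_per_lipid_count_variant(self):
        traj = make_system([[5, 5, 5]], [[5, 5, 5.4], [5, 5.3, 5], [5, 5, 9]])
        series = contact_timeseries(traj, cutoff=0.7, per_lipid_count=True)
        assert series.matrix[0, 0] == 2

    def test_profile_equals_row_sums_of_timeseries(self, bound_run):
        traj, _ = bound_run
        series = contact_timeseries(traj)
        profile = residue_contact_profile(traj)
        np.testing.assert_array_equal(profile.raw, series.matrix.sum(axis=1))

    def test_empty_target_warns_all_zero(self):
        traj = make_system([[5, 5, 5]], [[5, 5, 5.4]], lipid_species="PC")
        with pytest.warns(UserWarning):
            p = residue_contact_profile(
                traj, lipid_target_sel="species PI4P and headgroup")
        assert p.all_zero

    def test_hotspots_persistently_occupied_after_binding(self, bound_run):
        traj, truth = bound_run
        series = contact_timeseries(traj)
        hot = np.isin(series.residues, truth.params.hotspot_residues)
        post = series.matrix[:, truth.binding_frame + 60:]
        # central hotspot rows are occupied nearly every post-binding frame
        best = post[hot].mean(axis=1).max()
        assert best > 0.95
        # far from the membrane (early approach) nothing is in contact
        far = truth.distance_mean > truth.params.bound_distance + 1.5
        assert series.matrix[:, far].sum() == 0

    def test_hotspot_recovery_as_top_k(self, protein, bilayer):
        """Planted hotspots are exactly the top-k contact residues."""
        params = EncounterParams(n_frames=1000, dt=0.5, tau=30.0,
                                 noise_sigma=0.2,
                                 modes=(BindingMode(rzz=1.0, weight=1.0),),
                                 seed=11)
        traj, truth = simulate_encounter(protein, bilayer, params)
        profile = residue_contact_profile(traj)
        k = len(truth.params.hotspot_residues)
        order = np.argsort(-profile.raw, kind="stable")
        top_k = set(int(r) for r in profile.residues[order[:k]])
        assert top_k == set(truth.params.hotspot_residues)


class TestNormalizeProfile:
    def test_normalises_to_peak(self):
        p = ContactProfile(residues=np.array([1, 2, 3]),
                           raw=np.array([2, 8, 4]),
                           normalized=np.zeros(3), cutoff=0.7,
                           mode="min_particle")
        out = normalize_profile(p)
        np.testing.assert_allclose(out.normalized, [0.25, 1.0, 0.5])
        assert not out.all_zero

    def test_all_zero_flagged(self):
        p = ContactProfile(residues=np.array([1, 2]), raw=np.array([0, 0]),
                           normalized=np.zeros(2), cutoff=0.7,
                           mode="min_particle")
        out = normalize_profile(p)
        np.testing.assert_allclose(out.normalized, 0.0)
        assert out.all_zero


class TestCountProximalLipids:
    def test_counts_within_radius(self):
        traj = make_system([[5, 5, 5]],
                           [[5, 5, 6], [5, 8, 5], [9, 5, 5]],
                           box=(30.0, 30.0, 30.0))
        counts = count_proximal_lipids(traj, "species protein",
                                       "species PI4P and headgroup",
                                       radius=3.5)
        assert counts[0] == 2

    def test_zero_when_radius_too_small(self):
        traj = make_system([[5, 5, 5]], [[5, 5, 6]])
        assert count_proximal_lipids(traj, "species protein",
                                     "species PI4P", radius=0.5)[0] == 0

    def test_matches_brute_force_oracle(self, rng):
        box = np.array([8.0, 8.0, 8.0])
        for _ in range(20):
            # compact site (unwrap-safe) plus scattered single-bead lipids
            site_beads = rng.uniform(2, 6, 3) + rng.uniform(-0.3, 0.3, (3, 3))
            traj = make_system(site_beads,
                               rng.uniform(0, 8, (15, 3)), box=box)
            radius = float(rng.uniform(1.0, 5.0))
            got = count_proximal_lipids(traj, "species protein",
                                        "species PI4P", radius=radius)[0]
            coords = traj.frames[0].coordinates
            site = coords[:3].mean(axis=0)
            expected = sum(
                min_image_distance(site, coords[3 + j], box) < radius
                for j in range(15))
            assert got == expected

    def test_empty_site_raises(self):
        traj = make_system([[5, 5, 5]], [[5, 5, 6]])
        with pytest.raises(SelectionError):
            count_proximal_lipids(traj, "species PIP2", "species PI4P")
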