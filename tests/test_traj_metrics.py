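"""Subsampling, balanced frames, RMSD/RMSF, contacts, H-bonds, comparisons."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from epibind.errors import SelectionError, UndefinedRatioError, ValidationError
from epibind.structio import ReplicaEnsemble, Selection, StructureModel, Trajectory
from epibind.traj_metrics import (
    TimeSeries,
    balanced_frames,
    contact_count,
    ensemble_stats,
    fitted_rmsd_series,
    hbond_count,
    interface_series,
    percent_difference,
    plateau_value,
    rmsf_com,
    subsample,
)
from conftest import (
    brute_force_hbonds,
    brute_force_pairs,
    make_atom,
    point_model,
    two_group_model,
)


def flat_traj(topo, n_frames, spacing=1.0):
    frames = np.repeat(topo.coords[None], n_frames, axis=0)
    return Trajectory(topo, frames, np.arange(n_frames) * spacing)


class TestSubsample:
    def test_dense_trajectory_keeps_whole_nanoseconds(self):
        topo = point_model([(0, 0, 0)])
        times = np.round(np.arange(0, 5.001, 0.1), 10)
        traj = Trajectory(topo, np.zeros((times.size, 1, 3)), times)
        out = subsample(traj, 1.0)
        np.testing.assert_allclose(out.frame_times, [0, 1, 2, 3, 4, 5])

    def test_interval_finer_than_spacing_is_identity(self):
        topo = point_model([(0, 0, 0)])
        traj = flat_traj(topo, 5, spacing=2.0)
        out = subsample(traj, 1.0)
        np.testing.assert_allclose(out.frame_times, traj.frame_times)

    def test_single_frame(self):
        topo = point_model([(0, 0, 0)])
        traj = Trajectory(topo, np.zeros((1, 1, 3)), [0.0])
        assert subsample(traj, 1.0).n_frames == 1

    def test_nonpositive_interval_rejected(self):
        topo = point_model([(0, 0, 0)])
        with pytest.raises(ValidationError):
            subsample(flat_traj(topo, 3), 0.0)


class TestBalancedFrames:
    def test_truncates_to_shortest_replica(self):
        topo = point_model([(0, 0, 0)])
        ens = ReplicaEnsemble([flat_traj(topo, 11), flat_traj(topo, 9)])
        out = balanced_frames(ens, 1.0)
        assert [t.n_frames for t in out.replicas] == [9, 9]

    def test_equal_replicas_unchanged(self):
        topo = point_model([(0, 0, 0)])
        ens = ReplicaEnsemble([flat_traj(topo, 7), flat_traj(topo, 7)])
        out = balanced_frames(ens, 1.0)
        assert [t.n_frames for t in out.replicas] == [7, 7]

    def test_counts_exactly_equal_across_replicas(self):
        topo = point_model([(0, 0, 0)])
        rng = np.random.default_rng(6)
        ens = ReplicaEnsemble([flat_traj(topo, int(n))
                               for n in rng.integers(5, 30, 6)])
        counts = {t.n_frames for t in balanced_frames(ens, 1.0).replicas}
        assert len(counts) == 1


def _rmsd_fixture():
    """Antigen chain A (4 atoms) + binder chain B (3 atoms)."""
    atoms = [make_atom(1, "CA", "C", (0, 0, 0), "A", 1),
             make_atom(2, "CA", "C", (4, 0, 0), "A", 2),
             make_atom(3, "CA", "C", (0, 4, 0), "A", 3),
             make_atom(4, "CA", "C", (0, 0, 4), "A", 4),
             make_atom(5, "CA", "C", (8, 8, 0), "B", 1),
             make_atom(6, "CA", "C", (9, 8, 0), "B", 2),
             make_atom(7, "CA", "C", (8, 9, 0), "B", 3)]
    return StructureModel(atoms)


class TestFittedRmsd:
    def test_static_trajectory_is_zero(self):
        topo = _rmsd_fixture()
        traj = flat_traj(topo, 4)
        ts = fitted_rmsd_series(traj, topo.coords, Selection("chain A"),
                                Selection("chain B"))
        np.testing.assert_allclose(ts.values, 0.0, atol=1e-9)

    def test_rigid_binder_translation_gives_constant_offset(self):
        topo = _rmsd_fixture()
        frames = np.repeat(topo.coords[None], 3, axis=0)
        frames[:, 4:, 2] += 5.0  # binder shifted 5 A in z, antigen static
        traj = Trajectory(topo, frames, [0.0, 1.0, 2.0])
        ts = fitted_rmsd_series(traj, topo.coords, Selection("chain A"),
                                Selection("chain B"))
        np.testing.assert_allclose(ts.values, 5.0, atol=1e-9)

    def test_matches_per_frame_oracle(self):
        topo = _rmsd_fixture()
        rng = np.random.default_rng(13)
        frames = np.repeat(topo.coords[None], 3, axis=0)
        frames += rng.normal(0, 0.3, frames.shape)
        traj = Trajectory(topo, frames, [0.0, 1.0, 2.0])
        ts = fitted_rmsd_series(traj, topo.coords, Selection("chain A"),
                                Selection("chain B"))
        from epibind.pose_analysis import kabsch_superpose
        for f in range(3):
            tr, _ = kabsch_superpose(frames[f][:4], topo.coords[:4])
            moved = tr.apply(frames[f][4:])
            expected = np.sqrt(((moved - topo.coords[4:]) ** 2)
                               .sum(axis=1).mean())
            assert ts.values[f] == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_global_rigid_transform(self):
        topo = _rmsd_fixture()
        rng = np.random.default_rng(14)
        frames = np.repeat(topo.coords[None], 4, axis=0)
        frames += rng.normal(0, 0.4, frames.shape)
        traj = Trajectory(topo, frames, np.arange(4.0))
        base = fitted_rmsd_series(traj, topo.coords, Selection("chain A"),
                                  Selection("chain B")).values
        rot = Rotation.random(random_state=3).as_matrix()
        trans = np.array([12.0, -5.0, 30.0])
        moved = Trajectory(topo, frames @ rot.T + trans, np.arange(4.0))
        out = fitted_rmsd_series(moved, topo.coords, Selection("chain A"),
                                 Selection("chain B")).values
        np.testing.assert_allclose(out, base, atol=1e-8)


class TestEnsembleStats:
    def test_identical_series_sem_zero(self):
        ts = [TimeSeries([0.0, 1.0], [2.0, 4.0]) for _ in range(10)]
        es = ensemble_stats(ts)
        np.testing.assert_allclose(es.mean.values, [2, 4])
        np.testing.assert_allclose(es.sem.values, 0.0)

    def test_two_point_hand_value(self):
        es = ensemble_stats([TimeSeries([0.0], [1.0]),
                             TimeSeries([0.0], [3.0])])
        assert es.mean.values[0] == pytest.approx(2.0)
        assert es.sem.values[0] == pytest.approx(1.0)  # sd sqrt(2) / sqrt(2)

    def test_single_series_sem_missing(self):
        es = ensemble_stats([TimeSeries([0.0, 1.0], [1.0, 2.0])])
        assert es.sem is None

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValidationError):
            ensemble_stats([TimeSeries([0.0], [1.0]),
                            TimeSeries([5.0], [1.0])])


class TestPlateau:
    def test_constant_series(self):
        ts = [TimeSeries(np.arange(500.0), np.full(500, 7.5))
              for _ in range(3)]
        value, sem = plateau_value(ensemble_stats(ts), window=200.0)
        assert value == pytest.approx(7.5)
        assert sem == pytest.approx(0.0)

    def test_linear_ramp_final_window_mean(self):
        times = np.arange(0.0, 1001.0)
        values = times / 10.0  # 0 -> 100 over 1000 ns
        es = ensemble_stats([TimeSeries(times, values)] * 2)
        value, _ = plateau_value(es, window=200.0)
        # mean of a linear segment over [800, 1000] ns = value at 900 ns
        assert value == pytest.approx(90.0)

    def test_window_longer_than_span_clipped(self, caplog):
        es = ensemble_stats([TimeSeries(np.arange(10.0), np.arange(10.0))])
        with caplog.at_level("WARNING"):
            value, sem = plateau_value(es, window=500.0)
        assert value == pytest.approx(4.5)
        assert sem is None
        assert any("window" in r.message for r in caplog.records)


class TestRmsfCom:
    def test_static_trajectory_zero(self):
        topo = _rmsd_fixture()
        traj = flat_traj(topo, 5)
        profile = rmsf_com(traj, Selection("chain A"))
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in profile.values.values())

    def test_two_frame_displacement_hand_value(self):
        topo = _rmsd_fixture()
        frames = np.repeat(topo.coords[None], 2, axis=0)
        frames[0, 4, 0] -= 1.0   # residue B:1 at +/- 1 A about its mean
        frames[1, 4, 0] += 1.0
        traj = Trajectory(topo, frames, [0.0, 1.0])
        profile = rmsf_com(traj, Selection("chain A"))
        assert profile.values[("B", 1)] == pytest.approx(1.0, abs=1e-9)
        assert profile.values[("B", 2)] == pytest.approx(0.0, abs=1e-9)

    def test_single_frame_rejected(self):
        topo = _rmsd_fixture()
        with pytest.raises(ValidationError):
            rmsf_com(flat_traj(topo, 1), Selection("chain A"))


class TestContacts:
    def test_strict_inequality_at_cutoff(self):
        sel = Selection("chain A"), Selection("chain B")
        at_44 = two_group_model([(0, 0, 0)], [(4.4, 0, 0)])
        at_45 = two_group_model([(0, 0, 0)], [(4.5, 0, 0)])
        assert contact_count(at_44.coords, at_44, *sel) == 1
        assert contact_count(at_45.coords, at_45, *sel) == 0

    def test_hydrogens_not_counted(self):
        atoms = [make_atom(1, "C", "C", (0, 0, 0), "A", 1),
                 make_atom(2, "HB", "H", (1.0, 0, 0), "B", 1),
                 make_atom(3, "O", "O", (2.0, 0, 0), "B", 2)]
        model = StructureModel(atoms)
        assert contact_count(model.coords, model, Selection("chain A"),
                             Selection("chain B")) == 1

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        pts_a = rng.uniform(0, 15, (25, 3))
        pts_b = rng.uniform(0, 15, (25, 3))
        model = two_group_model(pts_a, pts_b)
        got = contact_count(model.coords, model, Selection("chain A"),
                            Selection("chain B"))
        assert got == len(brute_force_pairs(pts_a, pts_b, 4.5))

    def test_overlapping_groups_rejected(self):
        model = point_model([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(SelectionError):
            contact_count(model.coords, model, Selection("chain A"),
                          Selection("all"))


def hbond_triplet(da_dist, angle_deg):
    """D at origin, A on x-axis, H placed to give the requested angle."""
    from epibind.synthetic_data import _solve_hydrogen_position
    h = _solve_hydrogen_position(da_dist, angle_deg)
    atoms = [make_atom(1, "N", "N", (0, 0, 0), "D", 1),
             make_atom(2, "H", "H", tuple(h), "D", 1),
             make_atom(3, "O", "O", (da_dist, 0, 0), "B", 1)]
    return StructureModel(atoms)


class TestHbonds:
    @pytest.mark.parametrize("dist,angle,expected", [
        (3.4, 170.0, 1),
        (3.4, 140.0, 0),
        (3.6, 180.0, 0),
        (3.5, 150.0, 1),   # both bounds inclusive
    ])
    def test_criteria_bounds(self, dist, angle, expected):
        model = hbond_triplet(dist, angle)
        got = hbond_count(model.coords, model, Selection("chain D"),
                          Selection("chain B"))
        assert got == expected

    def test_donor_without_hydrogen_skipped(self):
        atoms = [make_atom(1, "N", "N", (0, 0, 0), "D", 1),
                 make_atom(2, "O", "O", (3.0, 0, 0), "B", 1)]
        model = StructureModel(atoms)
        assert hbond_count(model.coords, model, Selection("chain D"),
                           Selection("chain B")) == 0

    def test_matches_triple_enumeration_oracle(self):
        from epibind.synthetic_data import make_hbond_lattice
        rng = np.random.default_rng(17)
        dists = rng.uniform(2.8, 4.0, 6)
        angles = rng.uniform(120, 180, 6)
        model, expected = make_hbond_lattice(6, 6, list(dists), list(angles))
        donors = [i for i, a in enumerate(model.atoms)
                  if a.chain_id == "D" and a.element == "N"]
        acceptors = [i for i, a in enumerate(model.atoms)
                     if a.chain_id == "B"]
        hydrogens_of = {
            d: [i for i, a in enumerate(model.atoms)
                if a.is_hydrogen
                and np.linalg.norm(model.coords[i] - model.coords[d]) <= 1.2]
            for d in donors}
        oracle = brute_force_hbonds(model.coords, donors, hydrogens_of,
                                    acceptors)
        got = hbond_count(model.coords, model, Selection("chain D"),
                          Selection("chain B"))
        assert got == oracle == expected


class TestInterfaceSeries:
    def _static_ensemble(self, models_counts):
        """Replicas whose per-frame contact counts are fixed by geometry."""
        replicas = []
        for count in models_counts:
            # `count` A-B pairs at ~1 A, the rest far off-lattice
            pts_a = [(10.0 * i, 0, 0) for i in range(max(models_counts))]
            pts_b = [(10.0 * i + (1.0 if i < count else 55.3), 0.5, 0)
                     for i in range(max(models_counts))]
            model = two_group_model(pts_a, pts_b)
            replicas.append(flat_traj(model, 4))
        return replicas

    def test_static_ensemble_constant_series(self):
        (traj,) = self._static_ensemble([3])
        es = interface_series(ReplicaEnsemble([traj]), "contacts",
                              Selection("chain A"), Selection("chain B"))
        np.testing.assert_allclose(es.mean.values, 3.0)

    def test_two_replicas_mean(self):
        # one topology; replica 1 frames realize 10 contacts, replica 2
        # frames 20 (the same B atoms moved close in replica 2)
        base = two_group_model(
            [(10.0 * i, 0, 0) for i in range(20)],
            [(10.0 * i + (1.0 if i < 10 else 55.3), 0.5, 0)
             for i in range(20)])
        frames2 = np.repeat(base.coords[None], 4, axis=0)
        for i in range(10, 20):
            frames2[:, 20 + i, 0] = 10.0 * i + 1.0
        ens = ReplicaEnsemble([
            flat_traj(base, 4),
            Trajectory(base, frames2, np.arange(4.0))])
        es = interface_series(ens, "contacts", Selection("chain A"),
                              Selection("chain B"))
        np.testing.assert_allclose(es.mean.values, 15.0)

    def test_unbalanced_ensemble_rejected(self):
        topo = point_model([(0, 0, 0)])
        ens = ReplicaEnsemble([flat_traj(topo, 3), flat_traj(topo, 5)])
        with pytest.raises(ValidationError):
            interface_series(ens, "contacts", Selection("chain A"),
                             Selection("chain A"))


class TestPercentDifference:
    def _constant_ensemble(self, values):
        return ensemble_stats([
            TimeSeries(np.arange(3.0), np.full(3, v)) for v in values])

    def test_headline_statistic_form(self):
        a = self._constant_ensemble([18.0, 19.0])   # grand mean 18.5
        b = self._constant_ensemble([10.0, 10.0])
        assert percent_difference(a, b) == pytest.approx(85.0)

    def test_identical_ensembles_zero(self):
        a = self._constant_ensemble([4.0, 6.0])
        assert percent_difference(a, a) == pytest.approx(0.0)

    def test_zero_reference_rejected(self):
        a = self._constant_ensemble([1.0])
        b = self._constant_ensemble([0.0])
        with pytest.raises(UndefinedRatioError):
            percent_difference(a, b)
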