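"""Ion RMSF, hydration counting, unbinding detection and classification."""

import logging

import numpy as np
import pytest

from conftest import brute_nwater, brute_rmsf, full_window, make_traj
from nkaproton.metrics import (EXCLUDED_UNBINDING, STABLE, UNSTABLE,
                               ReplicaMetrics, StabilityThresholds,
                               classify_stability, detect_unbinding,
                               hydration_count, ion_rmsf, replica_metrics)
from nkaproton.trajectory import InsufficientDataError, MetricWindow


def _static_ions(F=5, n=3):
    base = np.array([[0.0, 0, 0], [9, 0, 0], [4.5, 8, 0]])[:n]
    return np.repeat(base[None], F, axis=0)


class TestRMSF:
    def test_static_ion_has_zero_rmsf(self):
        traj = make_traj(_static_ions())
        per, mean = ion_rmsf(traj, full_window(traj))
        assert np.allclose(per, 0) and mean == 0

    def test_two_frame_symmetric_case(self):
        ions = _static_ions(2)
        ions[1, 0] = [1.0, 0, 0]  # ion 0 moves 1 Å along x
        per, _ = ion_rmsf(make_traj(ions), None)
        assert per[0] == pytest.approx(0.5)
        assert per[1] == per[2] == 0

    def test_isotropic_gaussian_matches_sigma_sqrt3(self):
        rng = np.random.default_rng(42)
        sigma, F = 0.2, 2000
        ions = _static_ions(F) + rng.normal(0, sigma, (F, 3, 3))
        traj = make_traj(ions)
        _, mean = ion_rmsf(traj, full_window(traj))
        assert mean == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_insufficient_frames_rejected(self):
        traj = make_traj(_static_ions(5))
        with pytest.raises(InsufficientDataError):
            ion_rmsf(traj, MetricWindow(3.9, 4.0))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        ions = _static_ions(50) + rng.normal(0, 0.3, (50, 3, 3))
        _, before = ion_rmsf(make_traj(ions), None)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = ions @ R.T + np.array([12.0, -3.0, 4.0])
        _, after = ion_rmsf(make_traj(moved), None)
        assert after == pytest.approx(before, rel=1e-12)

    def test_linear_scaling_about_mean(self):
        rng = np.random.default_rng(1)
        ions = _static_ions(50) + rng.normal(0, 0.3, (50, 3, 3))
        traj = make_traj(ions)
        per, _ = ion_rmsf(traj, full_window(traj))
        scaled = ions.mean(axis=0) + 2.5 * (ions - ions.mean(axis=0))
        per2, _ = ion_rmsf(make_traj(scaled), full_window(traj))
        assert np.allclose(per2, 2.5 * per)


class TestHydration:
    def test_cutoff_boundary(self):
        base = np.array([[0.0, 0, 0], [50.0, 0, 0], [100.0, 0, 0]])
        ions = np.repeat(base[None], 2, axis=0)
        waters = np.tile(np.array([[[4.0, 0, 0], [6.0, 0, 0]]]), (2, 1, 1))
        traj = make_traj(ions, waters)
        counts, mean = hydration_count(traj, cutoff=5.0,
                                       window=full_window(traj))
        assert list(counts) == [1, 1] and mean == 1.0

    def test_shared_water_counts_once(self):
        ions = np.tile(np.array([[[0.0, 0, 0], [6.0, 0, 0], [3.0, 8, 0]]]),
                       (2, 1, 1))
        waters = np.tile(np.array([[[3.0, 0, 0]]]), (2, 1, 1))  # 3 Å from two ions
        traj = make_traj(ions, waters)
        counts, _ = hydration_count(traj, 5.0, full_window(traj))
        assert list(counts) == [1, 1]

    def test_poisson_occupancy_recovered(self):
        from nkaproton.synthetic import PlantedStateSpec, simulate_trajectory
        lam, F = 6.0, 2000
        spec = PlantedStateSpec(symbol="3[EEE]", sigma=0.1, lam=lam,
                                n_replicas=1, n_frames=F, seed=11)
        (traj,), _ = simulate_trajectory(spec)
        counts, mean = hydration_count(traj, 5.0, full_window(traj))
        se = np.sqrt(lam / len(counts))
        assert abs(mean - lam) < 3 * se

    def test_no_waters_warns_and_returns_zero(self, caplog):
        traj = make_traj(_static_ions())
        with caplog.at_level(logging.WARNING):
            counts, mean = hydration_count(traj, 5.0, full_window(traj))
        assert mean == 0.0 and "no water" in caplog.text

    def test_minimum_image_when_box_present(self):
        ions = _static_ions(2, n=3)
        # water at x=19.5 in a 20 Å box is 0.5 Å from the ion at x=0
        waters = np.tile(np.array([[[19.5, 0.0, 0.0]]]), (2, 1, 1))
        traj = make_traj(ions, waters, box=np.array([20.0, 20.0, 20.0]))
        counts, _ = hydration_count(traj, 5.0, full_window(traj))
        assert list(counts) == [1, 1]
        traj_nobox = make_traj(ions, waters)
        counts, _ = hydration_count(traj_nobox, 5.0, full_window(traj_nobox))
        assert list(counts) == [0, 0]


class TestBruteForceEquivalence:
    """Vectorised metrics must match naive double loops exactly."""

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        F = int(rng.integers(2, 11))
        n_water = int(rng.integers(0, 17))
        ions = rng.uniform(-10, 10, (F, 3, 3))
        waters = rng.uniform(-10, 10, (F, n_water, 3)) if n_water else None
        box = np.array([25.0, 30.0, 27.0]) if seed % 2 else None
        traj = make_traj(ions, waters, box=box)
        w = full_window(traj)
        per, mean = ion_rmsf(traj, w)
        ref_per, ref_mean = brute_rmsf(traj, w)
        assert np.allclose(per, ref_per, rtol=1e-10, atol=0)
        assert mean == pytest.approx(ref_mean, rel=1e-10)
        counts, nmean = hydration_count(traj, 5.0, w)
        ref_counts, ref_nmean = brute_nwater(traj, 5.0, w)
        assert list(counts) == ref_counts
        assert nmean == pytest.approx(ref_nmean, rel=1e-10, abs=1e-12)


class TestUnbinding:
    def test_small_fluctuation_stays_bound(self):
        rng = np.random.default_rng(3)
        ions = _static_ions(20) + rng.uniform(-0.5, 0.5, (20, 3, 3))
        assert not detect_unbinding(make_traj(ions)).any()

    def test_final_frame_displacement_flags_unbound(self):
        ions = _static_ions(20)
        ions[10:, 1] += [0, 0, 8.0]
        flags = detect_unbinding(make_traj(ions))
        assert list(flags) == [False, True, False]

    def test_excursion_returning_is_not_unbinding(self):
        ions = _static_ions(20)
        ions[5:15, 2] += [7.0, 0, 0]  # leaves, then returns by final frame
        assert not detect_unbinding(make_traj(ions)).any()


def _replica(nwater, rmsf, unbound=(False, False, False)):
    return ReplicaMetrics(per_ion_rmsf=np.full(3, rmsf), mean_rmsf=rmsf,
                          per_frame_nwater=np.array([int(nwater)]),
                          mean_nwater=nwater, unbound=np.array(unbound))


class TestClassification:
    def test_all_replicas_inside_box_is_stable(self):
        reps = [_replica(7.0, 0.40), _replica(6.5, 0.45), _replica(7.9, 0.49)]
        assert classify_stability("3[EEE]", reps).verdict == STABLE

    def test_one_violating_replica_is_unstable(self):
        reps = [_replica(7.0, 0.40), _replica(8.2, 0.30), _replica(7.0, 0.40)]
        report = classify_stability("x", reps)
        assert report.verdict == UNSTABLE
        assert any("replica 1" in f and "N_water" in f for f in report.failures)

    def test_thresholds_are_strict(self):
        assert classify_stability("x", [_replica(8.0, 0.50)]).verdict == UNSTABLE
        assert classify_stability("x", [_replica(7.99, 0.499)]).verdict == STABLE

    def test_unbinding_excludes_state(self):
        reps = [_replica(7.0, 0.4), _replica(7.0, 0.4, (False, True, False))]
        assert classify_stability("x", reps).verdict == EXCLUDED_UNBINDING

    def test_empty_replica_list_rejected(self):
        with pytest.raises(ValueError):
            classify_stability("x", [])

    def test_custom_thresholds(self):
        thr = StabilityThresholds(nwater=10.0, rmsf=1.0)
        assert classify_stability("x", [_replica(9.0, 0.8)], thr).verdict == STABLE
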