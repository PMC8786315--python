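import numpy as np
import pytest

from cryonano import (
    CountPair,
    MotionTrajectorySet,
    ResLogTable,
    SyntheticSpec,
    bfactor_from_reslog,
    concentration_from_count,
    group_trajectories,
    make_reslog,
    make_trajectories,
    rmsd_vs_exposure,
    vitreous_fraction,
)


class TestVitreousFraction:
    @pytest.mark.parametrize("kept, total, percent", [(815, 945, 86), (43, 82, 52), (91, 121, 75)])
    def test_dataset_fractions(self, kept, total, percent):
        assert vitreous_fraction(CountPair(kept, total)).percent_display == percent

    def test_zero_kept_has_positive_upper_ci(self):
        vf = vitreous_fraction(CountPair(0, 10))
        assert vf.percent_display == 0
        assert vf.ci_high_percent > 0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            CountPair(5, 0)
        with pytest.raises(ValueError):
            CountPair(11, 10)


class TestConcentration:
    def test_tomographic_count_estimate(self):
        est = concentration_from_count(1483, 9.4e6, 480.0, 3.4)
        assert est.molar_uM_display == pytest.approx(262.0)
        assert est.mass_mg_ml_display == pytest.approx(126.0)
        assert est.fold_increase_display == pytest.approx(37.0)

    def test_zero_particles(self):
        est = concentration_from_count(0, 1e6, 480.0, 3.4)
        assert est.molar_uM == 0.0
        assert est.fold_increase == 0.0

    def test_linearity(self):
        e1 = concentration_from_count(100, 1e6, 480.0, 1.0)
        e2 = concentration_from_count(200, 1e6, 480.0, 1.0)
        e_half_v = concentration_from_count(100, 5e5, 480.0, 1.0)
        assert e2.molar_uM == pytest.approx(2 * e1.molar_uM)
        assert e2.mass_mg_ml == pytest.approx(2 * e1.mass_mg_ml)
        assert e_half_v.molar_uM == pytest.approx(2 * e1.molar_uM)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            concentration_from_count(10, 0.0, 480.0, 1.0)


class TestBFactor:
    def test_noiseless_recovery_exact(self):
        table = make_reslog(SyntheticSpec(reslog_params=(178.0, 0.02, 8, 0.0)))
        fit = bfactor_from_reslog(table)
        assert fit.ok
        assert fit.bfactor_A2 == pytest.approx(178.0, abs=1e-9)

    def test_intercept_shift_leaves_b_unchanged(self):
        t1 = make_reslog(SyntheticSpec(reslog_params=(200.0, 0.02, 8, 0.0)))
        t2 = make_reslog(SyntheticSpec(reslog_params=(200.0, 0.05, 8, 0.0)))
        b1 = bfactor_from_reslog(t1).bfactor_A2
        b2 = bfactor_from_reslog(t2).bfactor_A2
        assert b1 == pytest.approx(b2, abs=1e-9)

    def test_unbiased_under_noise(self):
        # inverse-variance noise on 1/d^2; estimator mean over many seeds
        # should land on the generative B within Monte-Carlo error
        estimates = []
        for seed in range(500):
            table = make_reslog(SyntheticSpec(seed=seed, reslog_params=(178.0, 0.02, 8, 2e-3)))
            fit = bfactor_from_reslog(table)
            if fit.ok:
                estimates.append(fit.bfactor_A2)
        mean = np.mean(estimates)
        sem = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 178.0) < 4 * sem + 1.0

    def test_table_averaging(self):
        tables = [
            make_reslog(SyntheticSpec(seed=s, reslog_params=(178.0, 0.02, 8, 0.0)))
            for s in range(3)
        ]
        assert bfactor_from_reslog(tables).bfactor_A2 == pytest.approx(178.0, abs=1e-9)

    def test_two_rows_rejected(self):
        with pytest.raises(ValueError):
            bfactor_from_reslog(ResLogTable([100.0, 200.0], [5.0, 4.0]))

    def test_negative_slope_flagged(self):
        fit = bfactor_from_reslog(ResLogTable([100.0, 1000.0, 10000.0], [3.0, 4.0, 5.0]))
        assert not fit.ok
        assert np.isnan(fit.bfactor_A2)


def _linear_drift_set(rate=0.1, n_frames=40, direction=(1.0, 0.0), movie="m0"):
    d = np.asarray(direction) / np.linalg.norm(direction)
    pos = rate * np.arange(n_frames + 1)[:, None] * d[None, :]
    return {movie: pos}


class TestRmsdVsExposure:
    def test_zero_trajectories(self):
        trajs = MotionTrajectorySet({"m": np.zeros((41, 2))}, exposure_per_frame=1.0)
        _, rmsd, summary = rmsd_vs_exposure(trajs, (0, 40))
        assert summary == 0.0
        assert np.allclose(rmsd, 0.0)

    def test_linear_drift_closed_form(self):
        trajs = MotionTrajectorySet(_linear_drift_set(0.1, 40), exposure_per_frame=1.0)
        exposures, rmsd, summary = rmsd_vs_exposure(trajs, (0, 40))
        assert summary == pytest.approx(4.0)
        assert np.allclose(rmsd, 0.1 * exposures)

    def test_opposite_drifts_do_not_cancel(self):
        pos = _linear_drift_set(0.1, 40, (1, 0), "m1")
        pos.update(_linear_drift_set(0.1, 40, (-1, 0), "m2"))
        trajs = MotionTrajectorySet(pos, exposure_per_frame=1.0)
        _, _, summary = rmsd_vs_exposure(trajs, (0, 40))
        assert summary == pytest.approx(4.0)  # RMS, not a mean displacement

    def test_rotation_invariance(self):
        theta = np.radians(37.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        trajs = make_trajectories(SyntheticSpec(seed=2), n_frames=40)
        rotated = MotionTrajectorySet(
            {k: v @ rot.T for k, v in trajs.positions_A.items()},
            exposure_per_frame=1.0, labels=trajs.labels,
        )
        _, r1, s1 = rmsd_vs_exposure(trajs, (0, 40))
        _, r2, s2 = rmsd_vs_exposure(rotated, (0, 40))
        assert s1 == pytest.approx(s2)
        assert np.allclose(r1, r2)

    def test_monotone_for_monotone_drift(self):
        trajs = MotionTrajectorySet(_linear_drift_set(0.05, 60), exposure_per_frame=1.0)
        _, rmsd, _ = rmsd_vs_exposure(trajs, (0, 60))
        assert np.all(np.diff(rmsd) >= 0)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            rmsd_vs_exposure(MotionTrajectorySet({}, exposure_per_frame=1.0), (0, 40))


class TestGroupTrajectories:
    def test_single_direction_zero_dispersion(self):
        trajs = make_trajectories(
            SyntheticSpec(seed=0, motion_clusters=[(0.0, 5.0, 4)]), angle_jitter_deg=0.0
        )
        stats = group_trajectories(trajs, by="shot_position")
        assert len(stats) == 1
        assert stats[0].mean_angle_deg == pytest.approx(0.0, abs=1e-9)
        assert stats[0].circular_dispersion == pytest.approx(0.0, abs=1e-12)

    def test_three_cluster_recovery(self):
        trajs = make_trajectories(SyntheticSpec(seed=4), angle_jitter_deg=3.0)
        stats = group_trajectories(trajs, by="shot_position")
        expected = {"pos0": 0.0, "pos1": 120.0, "pos2": 240.0}
        for s in stats:
            diff = (s.mean_angle_deg - expected[s.group] + 180) % 360 - 180
            assert abs(diff) < 5.0

    def test_single_trajectory_dispersion_zero(self):
        trajs = make_trajectories(SyntheticSpec(seed=0, motion_clusters=[(45.0, 5.0, 1)]))
        stats = group_trajectories(trajs, by="shot_position")
        assert stats[0].circular_dispersion == 0.0

    def test_unknown_grouping_raises(self):
        trajs = make_trajectories(SyntheticSpec(seed=0))
        with pytest.raises(ValueError):
            group_trajectories(trajs, by="magnification")
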