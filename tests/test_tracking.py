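"""Tracker: matching statistic, kinematic constraints, deflection, summaries."""

from dataclasses import replace

import numpy as np
import pytest

from fetalkick import synthetic_cine as sc
from fetalkick import tracking as tr
from fetalkick.errors import (ConfigurationError, DegenerateMatchError,
                              TrackLostError)
from conftest import truth_as_trajectories


def blob_frame(shape=(40, 40), centers=((20, 20),), amp=1.0, sigma=1.5):
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for cx, cy in centers:
        img += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
    return img


class TestNccMatch:
    def test_exact_subpatch_scores_one_at_true_location(self):
        rng = np.random.default_rng(0)
        frame = rng.random((30, 30))
        ens = tr.TemplateEnsemble(0.8)
        ens.add(tr._extract_patch(frame, (17, 11), 2))
        pos, score = tr.ncc_match(frame, ens, (5, 25, 5, 25))
        assert pos == (17, 11)
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_flat_region_is_degenerate(self):
        frame = np.zeros((30, 30))
        frame[20:, 20:] = 1.0  # texture elsewhere, flat search region
        ens = tr.TemplateEnsemble(0.8)
        ens.add(np.ones((5, 5)))
        with pytest.raises(DegenerateMatchError):
            tr.ncc_match(frame, ens, (2, 10, 2, 10))

    def test_combined_score_is_weighted_average(self):
        """The ensemble map equals the weight-average of per-template maps."""
        rng = np.random.default_rng(1)
        frame = rng.random((30, 30))
        t1 = tr._extract_patch(frame, (10, 10), 2)
        t2 = tr._extract_patch(frame, (15, 18), 2)
        ens = tr.TemplateEnsemble(0.25)  # weights 0.2 / 0.8
        ens.add(t1)
        ens.add(t2)
        region = (8, 20, 8, 20)
        _, _, combined = tr._match_region(frame, ens, region)
        maps = []
        for t in (t1, t2):
            e = tr.TemplateEnsemble(1.0)
            e.add(t)
            maps.append(tr._match_region(frame, e, region)[2])
        w = ens.weights
        assert np.allclose(combined, w[0] * maps[0] + w[1] * maps[1],
                           atol=1e-12)
        # spot check of the weighted-average arithmetic at one pixel
        iy, ix = 3, 4
        manual = 0.75 * 0.9 + 0.25 * 0.5
        assert manual == pytest.approx(0.8)

    def test_recency_weights_favor_newest(self):
        ens = tr.TemplateEnsemble(0.5)
        for _ in range(4):
            ens.add(np.zeros((3, 3)))
        w = ens.weights
        assert w.sum() == pytest.approx(1.0)
        assert np.all(np.diff(w) > 0)  # newest (last) largest


class TestTrackSequence:
    def test_noiseless_recovery_within_one_pixel(self, cohort):
        for scen in cohort:
            s = replace(scen, noise_sd=0.0)
            truth = sc.generate_kick_kinematics(s)
            seq = sc.render_frames(truth, s)
            seeds = tr.seeds_from_truth(truth, seq)
            hip, knee, ankle = tr.track_sequence(seq, seeds)
            for traj, ref in ((hip, truth.hip), (knee, truth.knee),
                              (ankle, truth.ankle)):
                err = np.linalg.norm(traj.mm - ref, axis=1) / s.pixel_size_mm
                assert err.max() <= 1.0, f"{s.name}/{traj.name}: {err.max():.2f} px"

    def test_decoy_outside_length_annulus_rejected(self):
        # ankle blob moves; a brighter decoy sits inside the search disc but
        # violates the tibia-length constraint
        knee_c, ankle_c, decoy = (10, 20), (30, 20), (27, 23)
        f0 = blob_frame(centers=(knee_c, (5, 5), ankle_c))
        f1 = blob_frame(centers=(knee_c, (5, 5), (31, 20)))
        f1 += blob_frame(centers=(decoy,), amp=2.0)
        seq = sc.ImageSequence(frames=np.stack([f0, f1]), pixel_size_mm=1.0,
                               frame_interval_s=0.3,
                               origin_mm=np.zeros(2))
        cfg = tr.TrackingConfig(template_halfwidth=2, search_radius=4,
                                min_match_score=0.2)
        hip, knee, ankle = tr.track_sequence(seq, [(5, 5), knee_c, ankle_c],
                                             cfg)
        # decoy is ~4.2 px from the knee (tibia is 20): rejected
        assert np.linalg.norm(ankle.px[1] - np.array([31, 20])) <= 1.5
        assert np.linalg.norm(ankle.px[1] - np.array(decoy)) > 2.0

    def test_pure_noise_frame_loses_track(self):
        rng = np.random.default_rng(0)
        f0 = blob_frame(centers=((8, 8), (20, 20), (32, 32)))
        f1 = rng.random((40, 40))
        seq = sc.ImageSequence(frames=np.stack([f0, f1]), pixel_size_mm=1.0,
                               frame_interval_s=0.3, origin_mm=np.zeros(2))
        with pytest.raises(TrackLostError):
            tr.track_sequence(seq, [(8, 8), (20, 20), (32, 32)])

    def test_single_frame_returns_seeds(self, fetus_a_sequence):
        seq = sc.ImageSequence(frames=fetus_a_sequence.frames[:1],
                               pixel_size_mm=fetus_a_sequence.pixel_size_mm,
                               frame_interval_s=0.303,
                               origin_mm=fetus_a_sequence.origin_mm)
        seeds = [(30, 30), (40, 35), (50, 45)]
        hip, knee, ankle = tr.track_sequence(seq, seeds)
        assert len(hip) == 1
        assert tuple(hip.px[0]) == seeds[0]
        assert tuple(ankle.px[0]) == seeds[2]

    def test_seeds_outside_frame_rejected(self, fetus_a_sequence):
        with pytest.raises(ConfigurationError):
            tr.track_sequence(fetus_a_sequence, [(-3, 4), (10, 10), (20, 20)])

    def test_deterministic(self, fetus_a, fetus_a_truth, fetus_a_sequence):
        seeds = tr.seeds_from_truth(fetus_a_truth, fetus_a_sequence)
        a = tr.track_sequence(fetus_a_sequence, seeds)
        b = tr.track_sequence(fetus_a_sequence, seeds)
        for x, y in zip(a, b):
            assert np.array_equal(x.px, y.px)

    def test_tracked_lengths_within_constraint_band(self, fetus_a,
                                                    fetus_a_tracked):
        hip, knee, ankle = fetus_a_tracked
        fem = np.linalg.norm(knee.mm - hip.mm, axis=1)
        tib = np.linalg.norm(ankle.mm - knee.mm, axis=1)
        # never further than the allowed band from the true lengths plus
        # seed quantization slack
        assert np.all(np.abs(fem - fetus_a.femur_length_mm)
                      <= 0.10 * fetus_a.femur_length_mm + fetus_a.pixel_size_mm)
        assert np.all(np.abs(tib - fetus_a.tibia_length_mm)
                      <= 0.10 * fetus_a.tibia_length_mm + fetus_a.pixel_size_mm)


class TestSegmentLengths:
    def test_ground_truth_lengths_recovered(self, fetus_a, fetus_a_truth,
                                            fetus_a_sequence):
        hip, knee, ankle = truth_as_trajectories(fetus_a_truth,
                                                 fetus_a_sequence)
        femur, tibia = tr.segment_lengths(hip, knee, ankle)
        assert femur == pytest.approx(51.02, abs=1e-9)
        assert tibia == pytest.approx(54.58, abs=1e-9)

    def test_tracked_lengths_within_ten_percent(self, fetus_a_tracked):
        femur, tibia = tr.segment_lengths(*fetus_a_tracked)
        assert abs(femur - 51.02) <= 0.10 * 51.02
        assert abs(tibia - 54.58) <= 0.10 * 54.58

    def test_coincident_joints_give_zero_length(self, fetus_a_sequence):
        n = 4
        z = tr.JointTrajectory("j", np.full((n, 2), 10.0), 2.2,
                               np.zeros(2), np.ones(n), np.ones(n, bool))
        femur, tibia = tr.segment_lengths(z, z, z)
        assert femur == 0.0 and tibia == 0.0

    def test_mismatched_lengths_rejected(self, fetus_a_tracked):
        hip, knee, ankle = fetus_a_tracked
        short = tr.JointTrajectory("x", hip.px[:-1], hip.pixel_size_mm,
                                   hip.origin_mm, hip.score[:-1],
                                   hip.valid[:-1])
        with pytest.raises(ConfigurationError):
            tr.segment_lengths(short, knee, ankle)


class TestWallDeflection:
    def test_constructed_ramp_measures_exactly(self):
        # ankle moves 5.00 mm outward along the normal after first contact
        a, b = 80.0, 75.0
        n_hat = np.array([1.0, 0.0])
        start = np.array([a - 10.0, 0.0])
        pos = [start + s * n_hat for s in (0, 4, 8, 10, 12, 15)]
        pos = np.array(pos)  # contact from s=10 (on the surface)
        traj = tr.JointTrajectory("ankle", pos / 2.2, 2.2, np.zeros(2),
                                  np.ones(6), np.ones(6, bool))
        res = tr.wall_deflection(traj, (a, b), contact_band_mm=0.5)
        assert res.window == (3, 5)
        assert res.max_displacement_mm == pytest.approx(5.0, abs=1e-9)

    def test_static_ankle_measures_zero(self):
        pos = np.tile([70.0, 0.0], (5, 1))
        traj = tr.JointTrajectory("ankle", pos / 2.2, 2.2, np.zeros(2),
                                  np.ones(5), np.ones(5, bool))
        res = tr.wall_deflection(traj, (70.0, 65.0))
        assert res.max_displacement_mm == pytest.approx(0.0, abs=1e-9)

    def test_no_contact_returns_empty_window(self):
        pos = np.tile([10.0, 0.0], (5, 1))
        traj = tr.JointTrajectory("ankle", pos / 2.2, 2.2, np.zeros(2),
                                  np.ones(5), np.ones(5, bool))
        res = tr.wall_deflection(traj, (70.0, 65.0))
        assert res.window is None
        assert res.max_displacement_mm == 0.0

    def test_fetus_a_deflection_within_one_pixel(self, fetus_a,
                                                 fetus_a_tracked):
        _, _, ankle = fetus_a_tracked
        res = tr.wall_deflection(ankle, fetus_a.inner_semi_axes)
        assert abs(res.max_displacement_mm - 6.40) <= 2.2


class TestSummarize:
    def test_cohort_displacements(self):
        s = tr.summarize([6.40, 7.37, 7.07])
        assert round(s.mean, 2) == 6.95
        assert round(s.spread, 2) == 0.41
        assert s.spread == pytest.approx(0.4055, abs=5e-4)

    def test_cohort_reaction_forces(self):
        s = tr.summarize([0.72, 0.33, 0.51])
        assert round(s.mean, 2) == 0.52
        assert round(s.spread, 2) == 0.16

    def test_single_value_has_zero_spread(self):
        s = tr.summarize([3.3])
        assert s.mean == 3.3 and s.spread == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            tr.summarize([])
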