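"""Centroid tracking: segmentation, centroids, continuity, loess smoothing."""

import numpy as np
import pytest

import lxkin as lk
from lxkin.smoothing import loess_quadratic
from lxkin.tracking import Component
from lxkin.video import VideoSequence
from conftest import brute_force_vtr_centroid, make_scene


def frame_with_blobs(shape, blobs):
    """blobs: list of (row, col, radius, intensity) hard disks."""
    f = np.zeros(shape)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c, rad, inten in blobs:
        f[(rows - r) ** 2 + (cols - c) ** 2 <= rad**2] = inten
    return f


VTR20 = lk.VTRSpec("LX", (0, 0, 20, 20))


class TestSegmentation:
    def test_single_blob_one_component(self):
        f = frame_with_blobs((20, 20), [(10, 10, 3, 1.0)])
        assert len(lk.segment_components(f, VTR20)) == 1

    def test_two_separated_blobs_two_components(self):
        f = frame_with_blobs((20, 20), [(5, 5, 2, 1.0), (14, 14, 2, 1.0)])
        assert len(lk.segment_components(f, VTR20)) == 2

    def test_all_background_empty_set(self):
        comps = lk.segment_components(np.zeros((20, 20)), VTR20)
        assert comps == []

    def test_components_restricted_to_vtr(self):
        f = frame_with_blobs((20, 20), [(3, 3, 2, 1.0), (16, 16, 2, 1.0)])
        vtr = lk.VTRSpec("LX", (0, 0, 10, 10))
        comps = lk.segment_components(f, vtr)
        assert len(comps) == 1
        assert comps[0].rows.max() < 10


class TestCentroid:
    def test_single_pixel(self):
        comp = Component(np.array([10]), np.array([20]), np.array([0.7]))
        assert lk.intensity_weighted_centroid(comp) == (10.0, 20.0)

    def test_hand_oracle_two_pixels(self):
        # (0*1 + 4*3) / (1+3) = 3
        comp = Component(np.array([5, 5]), np.array([0, 4]), np.array([1.0, 3.0]))
        r, c = lk.intensity_weighted_centroid(comp)
        assert (r, c) == (5.0, 3.0)

    def test_symmetric_blob_geometric_center(self):
        f = frame_with_blobs((21, 21), [(10, 10, 4, 1.0)])
        comp = lk.segment_components(f, lk.VTRSpec("LX", (0, 0, 21, 21)))[0]
        assert lk.intensity_weighted_centroid(comp) == pytest.approx((10.0, 10.0))

    def test_zero_intensity_rejected(self):
        comp = Component(np.array([1]), np.array([1]), np.array([0.0]))
        with pytest.raises(ValueError):
            lk.intensity_weighted_centroid(comp)


class TestInitialization:
    def test_seed_on_only_blob(self):
        f = frame_with_blobs((20, 20), [(10, 10, 3, 1.0)])
        cent = lk.initialize_track(f, VTR20, lk.SeedPoint((9.0, 11.0)))
        assert cent == pytest.approx((10.0, 10.0))

    def test_seed_equidistant_tie_breaks_row_major(self):
        f = frame_with_blobs((21, 21), [(5, 10, 2, 1.0), (15, 10, 2, 1.0)])
        cent = lk.initialize_track(f, lk.VTRSpec("LX", (0, 0, 21, 21)),
                                   lk.SeedPoint((10.0, 10.0)))
        assert cent == pytest.approx((5.0, 10.0))  # first component in row-major order

    def test_three_components_seed_selects_larynx(self):
        # three bright structures in the VTR, as in a mid-sagittal larynx view
        f = frame_with_blobs((30, 30), [(5, 8, 2, 0.9), (14, 20, 2, 0.8), (24, 9, 3, 1.0)])
        vtr = lk.VTRSpec("LX", (0, 0, 30, 30))
        assert len(lk.segment_components(f, vtr)) == 3
        cent = lk.initialize_track(f, vtr, lk.SeedPoint((23.0, 10.0)))
        assert cent == pytest.approx((24.0, 9.0), abs=0.2)

    def test_empty_first_frame_is_failure(self):
        with pytest.raises(RuntimeError, match="initialization failed"):
            lk.initialize_track(np.zeros((20, 20)), VTR20, lk.SeedPoint((10.0, 10.0)))

    def test_seed_outside_vtr_rejected(self):
        f = frame_with_blobs((20, 20), [(10, 10, 3, 1.0)])
        with pytest.raises(ValueError, match="outside the VTR"):
            lk.initialize_track(f, lk.VTRSpec("LX", (0, 0, 10, 10)),
                                lk.SeedPoint((15.0, 15.0)))


class TestTracking:
    def test_stationary_blob_constant_track(self, acq):
        scene = lk.PhantomScene(
            larynx_blob=lk.Blob((50.0, 40.0), (4.0, 4.0)),
            larynx_gesture=lk.GestureSpec(10, 10, 0, 10, 0.0),
        )
        video, truth = lk.render_phantom_video(scene, acq, 600.0, seed=0)
        vtr = lk.VTRSpec("LX", (40, 32, 21, 16))
        track = lk.track_centroids(video, vtr, lk.SeedPoint((50.0, 40.0)))
        assert track["valid"].all()
        np.testing.assert_allclose(track["row_px"], truth["lx_row_px"], atol=0.05)

    def test_cosine_ramp_displacement_recovered(self, phantom, vtr, seed_point, acq):
        _, video, truth = phantom
        track = lk.track_centroids(video, vtr, seed_point)
        disp_px = track["row_px"].iloc[0] - track["row_px"].min()
        assert disp_px * acq.px_size_mm == pytest.approx(5.0, abs=0.5 * acq.px_size_mm)

    def test_oracle_equivalence_noiseless(self, phantom, vtr, tracked):
        # tracked centroid vs brute-force whole-VTR intensity-weighted average
        _, video, _ = phantom
        for k in range(video.n_frames):
            r, c = brute_force_vtr_centroid(video.data[k], vtr)
            assert abs(r - tracked["row_px"][k]) < 0.1
            assert abs(c - tracked["col_px"][k]) < 0.1

    def test_distractor_rejected_by_continuity(self, acq, lx_gesture, vtr, seed_point):
        # distractor enters the VTR ~10 px from the larynx path
        scene = make_scene(lx_gesture)
        scene.distractors.append(
            lk.MovingBlob(
                lk.Blob((46.0, 46.0), (2.0, 2.0), 1.0),
                lk.GestureSpec(300, 300, 400, 300, -12.0),  # sweeps down into view
            )
        )
        vtr_wide = lk.VTRSpec("LX", (40, 32, 23, 18))
        video, truth = lk.render_phantom_video(scene, acq, 1800.0, seed=2)
        track = lk.track_centroids(video, vtr_wide, seed_point)
        dev = np.abs(track.loc[track["valid"], "row_px"]
                     - truth.loc[track["valid"], "lx_row_px"])
        assert dev.max() < 1.0

    def test_dropout_flagged_and_recovered(self, acq, vtr, seed_point):
        scene = make_scene(lk.GestureSpec(100, 150, 100, 150, 2.0))
        video, _ = lk.render_phantom_video(scene, acq, 800.0, seed=0)
        video.data[20:23] = 0.0  # three lost frames
        track = lk.track_centroids(video, vtr, seed_point)
        assert not track["valid"][20:23].any()
        assert track["valid"][23:].all()
        assert np.isfinite(track.loc[track["valid"], "row_px"]).all()

    def test_track_invariant_to_intensity_rescaling(self, phantom, vtr, seed_point):
        _, video, _ = phantom
        scaled = VideoSequence(video.data * 0.37, video.acq)
        t1 = lk.track_centroids(video, vtr, seed_point)
        t2 = lk.track_centroids(scaled, vtr, seed_point)
        np.testing.assert_allclose(t1["row_px"], t2["row_px"], atol=1e-9)
        np.testing.assert_allclose(t1["col_px"], t2["col_px"], atol=1e-9)

    def test_vertical_mm_positive_up_within_vtr(self, tracked, vtr, acq):
        v = tracked.loc[tracked["valid"], "vertical_mm"]
        assert (v >= 0).all()
        assert (v <= vtr.height_mm(acq.px_size_mm)).all()
        # raising gesture: vertical position increases during the ramp
        assert v.iloc[40] > v.iloc[0]


class TestLoessQuadratic:
    times = np.arange(60) * 12.0

    def test_constant_unchanged(self):
        y = np.full(60, 1.7)
        np.testing.assert_allclose(loess_quadratic(y, self.times, 30), y, atol=1e-10)

    def test_exact_quadratic_unchanged(self):
        y = 1e-4 * self.times**2 - 0.05 * self.times + 3
        out = loess_quadratic(y, self.times, 30)
        np.testing.assert_allclose(out[5:-5], y[5:-5], atol=1e-6)

    def test_noisy_cosine_rms_below_noise(self):
        g = lk.GestureSpec(150, 250, 100, 200, 5.0)
        truth = lk.cosine_gesture_trajectory(g, self.times)
        rng = np.random.default_rng(8)
        rms = []
        for _ in range(20):
            noisy = truth + rng.normal(0, 0.5, len(truth))
            rms.append(np.sqrt(np.mean((loess_quadratic(noisy, self.times, 30) - truth) ** 2)))
        assert np.mean(rms) < 0.5

    def test_monotone_gesture_no_overshoot(self, phantom, vtr, seed_point, lx_gesture):
        _, video, _ = phantom
        track = lk.track_centroids(video, vtr, seed_point)
        sm = lk.smooth_local_quadratic(track)
        overshoot = sm["vertical_mm"].max() - sm["vertical_mm"].iloc[0]
        assert overshoot - lx_gesture.amplitude_mm < 0.02 * lx_gesture.amplitude_mm

    def test_short_track_rejected(self, tracked):
        with pytest.raises(ValueError, match="span"):
            lk.smooth_local_quadratic(tracked.iloc[:20].copy())

    def test_invalid_frames_interpolated_then_reflagged(self, tracked):
        t = tracked.copy()
        t.loc[40:42, "valid"] = False
        t.loc[40:42, ["row_px", "col_px", "vertical_mm", "x_mm", "y_mm"]] = np.nan
        sm = lk.smooth_local_quadratic(t)
        assert not sm["valid"][40:43].any()
        assert np.isfinite(sm["row_px"]).all()
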