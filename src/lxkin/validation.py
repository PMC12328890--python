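"""End-to-end validation computations on phantoms with known truth.

These routines exercise the full pipeline - rendering, tracking,
landmark detection, statistics - against independent oracles (closed
forms, brute-force averages, Monte-Carlo calibration) and return the
measured error figures.  They are used by the validation tests and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .acquisition import AcquisitionSpec
from .phantom import Blob, FillRegion, GestureSpec, MovingBlob, PhantomScene, render_phantom_video
from .landmarks import derive_measures, find_gesture_landmarks
from .roi import ROISpec, roi_intensity_series, smooth_weighted_linear
from .stats import brown_forsythe, pooled_weighted_mean
from .study import GROUP_COUNTS, default_class_params
from .tracking import SeedPoint, VTRSpec, smooth_local_quadratic, track_centroids


def acquisition_geometry() -> dict[str, float]:
    """Frame rate, per-image span and pixel size of the study protocol."""
    acq = AcquisitionSpec()
    return {
        "effective_frame_rate_fps": acq.frame_rate_fps,
        "image_span_ms": acq.image_span_ms,
        "pixel_size_mm": acq.px_size_mm,
    }


def pooled_table_totals() -> dict[str, float]:
    """Count-weighted pooled Total means from the per-speaker group cells."""
    params = default_class_params().set_index(["speaker", "class"])

    def total(cls: str, measure: str) -> float:
        speakers = sorted(GROUP_COUNTS[cls])
        means = [params.loc[(s, cls), f"{measure}_mean"] for s in speakers]
        counts = [GROUP_COUNTS[cls][s] for s in speakers]
        return pooled_weighted_mean(means, counts)

    return {
        "pooled_lx_displacement_ejective_mm": total("voiceless_ejective", "lx_displacement_mm"),
        "pooled_lx_displacement_implosive_mm": total("voiced_implosive", "lx_displacement_mm"),
        "pooled_onset_lag_ejective_ms": total("voiceless_ejective", "onset_lag_ms"),
        "pooled_onset_lag_implosive_ms": total("voiced_implosive", "onset_lag_ms"),
        "pooled_onset_lag_voiced_pulmonic_ms": total("voiced_pulmonic", "onset_lag_ms"),
        "pooled_target_lag_voiced_pulmonic_ms": total("voiced_pulmonic", "target_lag_ms"),
    }


# -- phantom geometry shared by the checks ---------------------------------

_ACQ = AcquisitionSpec()
_VTR = VTRSpec("LX", (42, 32, 21, 16))
_ORAL = {"center": (20.0, 20.0), "radius": 3.0}
_ORAL_GESTURE = GestureSpec(onset_ms=350.0, transition_ms=220.0, hold_ms=300.0,
                            release_ms=250.0, amplitude_mm=1.0)


def _scene(amplitude_mm: float, lx_onset_ms: float, with_oral: bool = True,
           distractor: bool = False) -> PhantomScene:
    base_row = 56.0 if amplitude_mm >= 0 else 50.0
    scene = PhantomScene(
        larynx_blob=Blob((base_row, 40.0), (4.0, 4.0), 1.0),
        larynx_gesture=GestureSpec(lx_onset_ms, 250.0, 250.0, 300.0, amplitude_mm),
        oral_tissue=FillRegion(_ORAL["center"], _ORAL["radius"], 1.0) if with_oral else None,
        oral_gesture=_ORAL_GESTURE if with_oral else None,
    )
    if distractor:
        scene.distractors.append(
            MovingBlob(Blob((46.0, 46.0), (2.0, 2.0), 1.0),
                       GestureSpec(300.0, 300.0, 400.0, 300.0, -12.0))
        )
    return scene


def _vtr_oracle(frame: np.ndarray, vtr: VTRSpec) -> tuple[float, float]:
    sub = frame[vtr.slices]
    rows = np.arange(vtr.rect_px[0], vtr.rect_px[0] + vtr.rect_px[2], dtype=float)
    cols = np.arange(vtr.rect_px[1], vtr.rect_px[1] + vtr.rect_px[3], dtype=float)
    w = sub.sum()
    return float(sub.sum(axis=1) @ rows / w), float(sub.sum(axis=0) @ cols / w)


def tracker_oracle_check(seed: int = 0) -> dict[str, float]:
    """Tracked centroid vs brute-force whole-VTR average, noiseless phantom."""
    scene = _scene(5.0, 400.0, with_oral=False)
    video, _ = render_phantom_video(scene, _ACQ, 1800.0, seed)
    track = track_centroids(video, _VTR, SeedPoint((56.0, 40.0)))
    dev = 0.0
    for k in range(video.n_frames):
        r, c = _vtr_oracle(video.data[k], _VTR)
        dev = max(dev, abs(r - track["row_px"][k]), abs(c - track["col_px"][k]))
    return {"tracker_oracle_max_dev_px": dev}


def distractor_check(seed: int = 0) -> dict[str, float]:
    """Max deviation from truth when a distractor sweeps through the VTR."""
    scene = _scene(5.0, 400.0, with_oral=False, distractor=True)
    video, truth = render_phantom_video(scene, _ACQ, 1800.0, seed)
    track = track_centroids(video, _VTR, SeedPoint((56.0, 40.0)))
    ok = track["valid"].to_numpy()
    dev = np.abs(track.loc[ok, "row_px"].to_numpy() - truth.loc[ok, "lx_row_px"].to_numpy())
    return {"distractor_max_dev_px": float(dev.max())}


def landmark_closed_form_check() -> dict[str, float]:
    """Detector on a sampled cosine ramp vs the analytic 20 % crossings."""
    from .phantom import cosine_gesture_trajectory

    g = GestureSpec(400.0, 250.0, 250.0, 300.0, 5.0)
    times = np.arange(150) * _ACQ.frame_period_ms
    lm = find_gesture_landmarks(cosine_gesture_trajectory(g, times), times)
    return {
        "landmark_ons_error_ms": abs(lm.ons.time_ms - g.threshold_crossing_toward(0.2)),
        "landmark_tons_error_ms": abs(lm.tons.time_ms - g.threshold_crossing_settle(0.2)),
    }


def recovery_grid(seed: int = 0) -> dict[str, float]:
    """End-to-end recovery of displacement and lags over a parameter grid.

    20 combinations: 4 signed amplitudes x 5 onset lags.  Truth for the
    lags is the difference of the closed-form 20 % crossing times of the
    prescribed trajectories; truth for displacement is the closed-form
    position change between the true ONS and MAX landmarks,
    ``A * (1 - (1 - sqrt(1 - 0.04)) / 2)``.
    """
    amplitudes = (5.0, 3.0, -2.5, -4.0)
    lags = (-50.0, 0.0, 50.0, 100.0, 150.0)
    disp_err = lag_err = target_err = 0.0
    n = 0
    for amp in amplitudes:
        for lag in lags:
            lx_onset = _ORAL_GESTURE.onset_ms + lag
            scene = _scene(amp, lx_onset)
            video, _ = render_phantom_video(scene, _ACQ, 1800.0, seed + n)
            base_row = 56.0 if amp >= 0 else 50.0
            track = track_centroids(video, _VTR, SeedPoint((base_row, 40.0)))
            track = smooth_local_quadratic(track)
            direction = "raising" if amp >= 0 else "lowering"
            lx_lm = find_gesture_landmarks(track["vertical_mm"], track["time_ms"],
                                           direction=direction)
            roi = ROISpec("LAB", _ORAL["center"], _ORAL["radius"])
            series = smooth_weighted_linear(roi_intensity_series(video, roi))
            oral_lm = find_gesture_landmarks(series["value"], series["time_ms"])
            meas = derive_measures(lx_lm, oral_lm)

            lx_g = scene.larynx_gesture
            true_disp = amp * (1.0 - (1.0 - np.sqrt(1.0 - 0.04)) / 2.0)
            true_onset_lag = lx_g.threshold_crossing_toward() - _ORAL_GESTURE.threshold_crossing_toward()
            true_target_lag = lx_g.threshold_crossing_toward() - _ORAL_GESTURE.threshold_crossing_settle()
            disp_err = max(disp_err, abs(meas.lx_displacement_mm - true_disp))
            lag_err = max(lag_err, abs(meas.onset_lag_ms - true_onset_lag))
            target_err = max(target_err, abs(meas.target_lag_ms - true_target_lag))
            n += 1
    return {
        "recovery_max_displacement_error_mm": disp_err,
        "recovery_max_onset_lag_error_ms": lag_err,
        "recovery_max_target_lag_error_ms": target_err,
        "recovery_grid_size": n,
    }


def brown_forsythe_calibration(seed: int = 0, n_sim: int = 2000, n: int = 80,
                               alpha: float = 0.05) -> dict[str, float]:
    """Type-I error of the variance test on equal-variance normal groups."""
    rng = np.random.default_rng(seed)
    rej = sum(
        brown_forsythe([rng.normal(0.0, 1.0, n), rng.normal(0.0, 1.0, n)]).p_value < alpha
        for _ in range(n_sim)
    )
    return {"brown_forsythe_type1_rate": rej / n_sim, "brown_forsythe_n_sim": n_sim}


def variance_ordering_study(seed: int = 0, n_rep: int = 200,
                            alpha: float = 0.05) -> dict[str, float]:
    """Detectability of the published onset-lag variance ordering.

    Onset lags are simulated at the published pooled SDs and counts
    (ejectives 88.7/123, implosives 96.4/83, voiced pulmonics 137.3/76);
    each replicate study tests pulmonic vs pooled non-pulmonic variance
    homogeneity with the median-based Levene test.
    """
    spec = {
        "ejective": (64.33, 88.7, 123),
        "implosive": (68.14, 96.4, 83),
        "pulmonic": (-23.06, 137.3, 76),
    }
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_rep):
        draws = {k: rng.normal(m, s, c) for k, (m, s, c) in spec.items()}
        nonpulmonic = np.concatenate([draws["ejective"], draws["implosive"]])
        res = brown_forsythe([draws["pulmonic"], nonpulmonic])
        rej += res.p_value < alpha
    return {"variance_ordering_rejection_rate": rej / n_rep,
            "variance_ordering_n_rep": n_rep}
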