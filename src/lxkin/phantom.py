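"""Synthetic rtMRI-like phantom videos with known ground truth.

The phantom emulates the two signal sources the kinematic pipeline
consumes: a bright, compact "larynx" object that translates vertically
inside a fixed vocal-tract region, and an oral-constriction "tissue"
element that fills a fixed region of interest as the constriction forms.
Gestures follow a cosine ramp-hold-release trajectory, which is smooth,
has a single velocity peak per movement phase, and admits closed-form
20 % velocity-threshold crossing times - so every landmark the detector
reports can be checked analytically.

For a ramp of amplitude ``A`` and transition duration ``T`` the position
is ``A * (1 - cos(pi*(t - t0)/T)) / 2``; the velocity peaks at the
midpoint with value ``A*pi/(2*T)`` and crosses the fraction ``q`` of the
peak at ``t0 + (T/pi)*asin(q)`` (e.g. 0.0641*T for q = 0.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec
from .video import VideoSequence


@dataclass(frozen=True)
class GestureSpec:
    """Cosine ramp-hold-release trajectory of a single gesture.

    ``amplitude_mm`` is signed: positive = raising (toward the image top).
    Times are in ms from the start of the recording.
    """

    onset_ms: float
    transition_ms: float
    hold_ms: float
    release_ms: float
    amplitude_mm: float

    def __post_init__(self) -> None:
        if self.transition_ms <= 0:
            raise ValueError("transition_ms must be positive")
        if self.release_ms <= 0:
            raise ValueError("release_ms must be positive")
        if self.hold_ms < 0:
            raise ValueError("hold_ms must be non-negative")

    # -- closed-form landmark times -------------------------------------
    def threshold_crossing_toward(self, q: float = 0.2) -> float:
        """Time where |velocity| first reaches fraction q of its peak."""
        return self.onset_ms + (self.transition_ms / math.pi) * math.asin(q)

    def threshold_crossing_settle(self, q: float = 0.2) -> float:
        """Time where |velocity| falls back below fraction q of its peak."""
        return self.onset_ms + self.transition_ms * (1.0 - math.asin(q) / math.pi)

    def peak_velocity(self) -> float:
        """Peak speed of the transition, mm/ms."""
        return abs(self.amplitude_mm) * math.pi / (2.0 * self.transition_ms)

    @property
    def end_ms(self) -> float:
        return self.onset_ms + self.transition_ms + self.hold_ms + self.release_ms


def cosine_gesture_trajectory(spec: GestureSpec, t) -> np.ndarray:
    """Evaluate the gesture position (mm, signed) at times ``t`` (ms).

    Zero before onset, cosine ramp to the target, constant hold, mirrored
    cosine release back to zero; continuous everywhere.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    A = spec.amplitude_mm
    t0 = spec.onset_ms
    T, H, R = spec.transition_ms, spec.hold_ms, spec.release_ms
    pos = np.zeros_like(t)
    ramp = (t >= t0) & (t < t0 + T)
    pos[ramp] = A * (1.0 - np.cos(np.pi * (t[ramp] - t0) / T)) / 2.0
    hold = (t >= t0 + T) & (t < t0 + T + H)
    pos[hold] = A
    rel = (t >= t0 + T + H) & (t < t0 + T + H + R)
    pos[rel] = A * (1.0 + np.cos(np.pi * (t[rel] - (t0 + T + H)) / R)) / 2.0
    return float(pos[0]) if scalar else pos


@dataclass(frozen=True)
class Blob:
    """Elliptical Gaussian intensity blob.

    ``center_px`` is (row, col) of the resting position; ``radii_px`` the
    (row, col) half-widths (the Gaussian sigma is radius/2, so the blob's
    visible footprint roughly matches an ellipse of those radii).
    """

    center_px: tuple[float, float]
    radii_px: tuple[float, float] = (3.0, 3.0)
    peak_intensity: float = 1.0

    def __post_init__(self) -> None:
        if min(self.radii_px) < 1.0:
            raise ValueError("blob radii must be >= 1 px")
        if not (0.0 < self.peak_intensity <= 1.0):
            raise ValueError("peak intensity must lie in (0, 1]")

    def render(self, shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        sr, sc = self.radii_px[0] / 2.0, self.radii_px[1] / 2.0
        d2 = ((rows - center[0]) / sr) ** 2 + ((cols - center[1]) / sc) ** 2
        return self.peak_intensity * np.exp(-0.5 * d2)


@dataclass(frozen=True)
class FillRegion:
    """Circular region whose intensity scales with constriction degree.

    Models tissue entering a fixed oral region of interest: the region's
    intensity is ``peak * g(t)/|A|`` where ``g`` is the tied gesture's
    trajectory, so the ROI mean-intensity series is proportional to the
    gesture position and carries the same landmark times.
    """

    center_px: tuple[float, float]
    radius_px: float = 3.0
    peak_intensity: float = 1.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        d2 = (rows - self.center_px[0]) ** 2 + (cols - self.center_px[1]) ** 2
        return d2 <= self.radius_px**2


@dataclass
class MovingBlob:
    """A blob translating vertically along its own gesture trajectory."""

    blob: Blob
    gesture: GestureSpec | None = None


@dataclass
class PhantomScene:
    """Scene description for one phantom video."""

    larynx_blob: Blob
    larynx_gesture: GestureSpec
    oral_tissue: FillRegion | None = None
    oral_gesture: GestureSpec | None = None
    distractors: list[MovingBlob] = field(default_factory=list)
    noise_sd: float = 0.0
    noise_model: str = "gaussian"  # or "rician"

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _blob_center_at(blob: Blob, gesture: GestureSpec | None, t_ms: np.ndarray,
                    px_size_mm: float) -> np.ndarray:
    """Per-frame (row, col) center; raising (positive mm) moves up (row -)."""
    centers = np.tile(np.asarray(blob.center_px, dtype=float), (len(t_ms), 1))
    if gesture is not None:
        centers[:, 0] -= cosine_gesture_trajectory(gesture, t_ms) / px_size_mm
    return centers


def render_phantom_video(
    scene: PhantomScene,
    acq: AcquisitionSpec,
    duration_ms: float,
    seed: int,
) -> tuple[VideoSequence, pd.DataFrame]:
    """Render the scene and return the video plus a ground-truth table.

    The ground truth records, per frame, the exact (sub-pixel) larynx
    center in px and its vertical position in mm relative to the resting
    position (positive = raised).  Identical seeds give bit-identical
    videos.  A blob whose footprint would leave the frame is an error.
    """
    n_frames = int(math.floor(duration_ms * acq.frame_rate_fps / 1000.0))
    if n_frames < 1:
        raise ValueError("duration too short for a single frame")
    if scene.larynx_gesture.end_ms > duration_ms:
        raise ValueError("duration_ms does not cover the larynx gesture")
    t_ms = np.arange(n_frames) * acq.frame_period_ms
    shape = (acq.grid_px, acq.grid_px)

    lx_centers = _blob_center_at(scene.larynx_blob, scene.larynx_gesture, t_ms, acq.px_size_mm)
    for centers, blob in [(lx_centers, scene.larynx_blob)] + [
        (_blob_center_at(d.blob, d.gesture, t_ms, acq.px_size_mm), d.blob)
        for d in scene.distractors
    ]:
        lo = centers - np.asarray(blob.radii_px)
        hi = centers + np.asarray(blob.radii_px)
        if lo.min() < 0 or (hi[:, 0].max() >= shape[0]) or (hi[:, 1].max() >= shape[1]):
            raise ValueError("blob leaves the frame during its trajectory")

    frames = np.zeros((n_frames, *shape), dtype=float)
    for k in range(n_frames):
        frames[k] += scene.larynx_blob.render(shape, tuple(lx_centers[k]))
    for d in scene.distractors:
        centers = _blob_center_at(d.blob, d.gesture, t_ms, acq.px_size_mm)
        for k in range(n_frames):
            frames[k] += d.blob.render(shape, tuple(centers[k]))
    if scene.oral_tissue is not None:
        mask = scene.oral_tissue.mask(shape)
        if scene.oral_gesture is not None:
            g = cosine_gesture_trajectory(scene.oral_gesture, t_ms)
            fill = scene.oral_tissue.peak_intensity * np.abs(g) / abs(
                scene.oral_gesture.amplitude_mm
            )
        else:
            fill = np.full(n_frames, scene.oral_tissue.peak_intensity)
        frames[:, mask] += fill[:, None]

    if scene.noise_sd > 0:
        rng = np.random.default_rng(seed)
        if scene.noise_model == "gaussian":
            frames = frames + rng.normal(0.0, scene.noise_sd, frames.shape)
        else:  # rician magnitude noise
            re = frames + rng.normal(0.0, scene.noise_sd, frames.shape)
            im = rng.normal(0.0, scene.noise_sd, frames.shape)
            frames = np.hypot(re, im)

    truth = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "time_ms": t_ms,
            "lx_row_px": lx_centers[:, 0],
            "lx_col_px": lx_centers[:, 1],
            "lx_vertical_mm": cosine_gesture_trajectory(scene.larynx_gesture, t_ms),
        }
    )
    return VideoSequence(frames, acq), truth
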