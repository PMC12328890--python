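"""Intensity-weighted centroid tracking of non-constriction gestures.

Vertical larynx motion does not form a constriction at a fixed place, so
it cannot be read from a fixed ROI.  Instead a rectangular vocal-tract
region (VTR) tall enough to contain the larynx's full excursion is fixed
once per speaker, and within it each frame is segmented into connected
components of supra-threshold pixels.  Each component is summarised by
its intensity-weighted centroid; a seed point picks the larynx component
on the first frame, and thereafter the component whose centroid is
closest to the previous centroid is followed.  The continuity rule keeps
other bright objects that enter the VTR from capturing the track.

The vertical coordinate is reported in mm above the bottom edge of the
VTR, so larynx raising is positive - matching the sign convention of the
displacement measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .smoothing import loess_quadratic
from .video import VideoSequence


@dataclass(frozen=True)
class VTRSpec:
    """Fixed rectangular vocal-tract region, in pixel units.

    ``rect_px`` is (top, left, height, width).  For the larynx the study
    convention is a height of ~40 mm and width of 10-20 mm.
    """

    label: str
    rect_px: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        top, left, height, width = self.rect_px
        if height < 1 or width < 1 or top < 0 or left < 0:
            raise ValueError("invalid VTR rectangle")

    @property
    def slices(self) -> tuple[slice, slice]:
        top, left, height, width = self.rect_px
        return slice(top, top + height), slice(left, left + width)

    @property
    def bottom_edge_row(self) -> float:
        """Row coordinate of the VTR's bottom edge (half a pixel below
        the last row of pixel centers)."""
        top, _, height, _ = self.rect_px
        return top + height - 0.5

    def height_mm(self, px_size_mm: float) -> float:
        return self.rect_px[2] * px_size_mm

    def validate_inside(self, shape: tuple[int, int]) -> None:
        top, left, height, width = self.rect_px
        if top + height > shape[0] or left + width > shape[1]:
            raise ValueError(f"VTR {self.label!r} extends outside the frame")


@dataclass(frozen=True)
class SeedPoint:
    """Initial (row, col) point on the object of interest, inside the VTR."""

    point_px: tuple[float, float]

    def validate_inside(self, vtr: VTRSpec) -> None:
        top, left, height, width = vtr.rect_px
        r, c = self.point_px
        if not (top <= r < top + height and left <= c < left + width):
            raise ValueError("seed point lies outside the VTR")


@dataclass
class Component:
    """One connected component: pixel coordinates and intensities."""

    rows: np.ndarray
    cols: np.ndarray
    intensities: np.ndarray

    @property
    def centroid(self) -> tuple[float, float]:
        return intensity_weighted_centroid(self)


def intensity_weighted_centroid(component: Component) -> tuple[float, float]:
    """Sum(intensity * coordinate) / Sum(intensity), per axis."""
    total = component.intensities.sum()
    if component.intensities.size == 0:
        raise ValueError("empty component")
    if total <= 0:
        raise ValueError("component has zero total intensity")
    r = float(np.dot(component.intensities, component.rows) / total)
    c = float(np.dot(component.intensities, component.cols) / total)
    return r, c


def segment_components(
    frame: np.ndarray,
    vtr: VTRSpec,
    threshold: str | float = "fraction",
    fraction: float = 0.2,
) -> list[Component]:
    """8-connected components of supra-threshold pixels inside the VTR.

    ``threshold`` is either a fixed absolute intensity, the string
    ``"fraction"`` (default: ``fraction`` times the robust maximum - the
    99.5th percentile - of the VTR), or ``"otsu"``.  The default
    fraction of 0.2 keeps the component's low-intensity skirt: a cut
    half-way up the object's profile discards boundary pixels whose
    large weights make the component centroid oscillate by 0.1-0.2 px
    with the object's sub-pixel position, while a 0.2 cut keeps that
    discretization bias below 0.1 px.  An empty list means
    no object in the VTR this frame; that is a signal value, not an
    error.  Components are returned in row-major order of their first
    pixel (the scikit-image labelling order), which is the documented
    tie-break order.
    """
    vtr.validate_inside(frame.shape)
    sub = frame[vtr.slices]
    if isinstance(threshold, str):
        if threshold == "fraction":
            thr = fraction * float(np.percentile(sub, 99.5))
        elif threshold == "otsu":
            from skimage.filters import threshold_otsu

            thr = float(threshold_otsu(sub)) if np.ptp(sub) > 0 else np.inf
        else:
            raise ValueError(f"unknown threshold policy {threshold!r}")
    else:
        thr = float(threshold)
    binary = sub > thr
    if not binary.any():
        return []
    labels = measure.label(binary, connectivity=2)
    top, left = vtr.rect_px[0], vtr.rect_px[1]
    comps = []
    for lab in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == lab)
        comps.append(
            Component(
                rows=rr + top,
                cols=cc + left,
                intensities=sub[rr, cc],
            )
        )
    return comps


def initialize_track(
    first_frame: np.ndarray,
    vtr: VTRSpec,
    seed: SeedPoint,
    threshold: str | float = "fraction",
) -> tuple[float, float]:
    """Centroid of the component closest to the seed on the first frame.

    Ties are broken by component (row-major) order.  An empty component
    set is an initialization failure.
    """
    seed.validate_inside(vtr)
    comps = segment_components(first_frame, vtr, threshold)
    if not comps:
        raise RuntimeError("initialization failed: no component in the first frame")
    seed_pt = np.asarray(seed.point_px, dtype=float)
    cents = np.array([c.centroid for c in comps])
    d2 = np.sum((cents - seed_pt) ** 2, axis=1)
    return tuple(cents[int(np.argmin(d2))])


def track_centroids(
    video: VideoSequence,
    vtr: VTRSpec,
    seed: SeedPoint,
    threshold: str | float = "fraction",
) -> pd.DataFrame:
    """Frame-by-frame nearest-previous-centroid tracking.

    Returns a DataFrame with columns frame, time_ms, row_px, col_px,
    x_mm, y_mm, vertical_mm (mm above the VTR bottom edge) and valid.
    Frames with no component are flagged invalid; the last valid centroid
    is carried as the continuity reference so the track can resume after
    dropouts.  Distractor components farther from the previous centroid
    than the tracked object are never selected.
    """
    px = video.acq.px_size_mm
    first = initialize_track(video.data[0], vtr, seed, threshold)
    rows = np.full(video.n_frames, np.nan)
    cols = np.full(video.n_frames, np.nan)
    valid = np.zeros(video.n_frames, dtype=bool)
    rows[0], cols[0] = first
    valid[0] = True
    ref = np.asarray(first, dtype=float)
    for k in range(1, video.n_frames):
        comps = segment_components(video.data[k], vtr, threshold)
        if not comps:
            continue  # dropout: keep ref, leave frame invalid
        cents = np.array([c.centroid for c in comps])
        d2 = np.sum((cents - ref) ** 2, axis=1)
        pick = cents[int(np.argmin(d2))]
        rows[k], cols[k] = pick
        valid[k] = True
        ref = pick
    vertical_mm = (vtr.bottom_edge_row - rows) * px
    return pd.DataFrame(
        {
            "frame": np.arange(video.n_frames),
            "time_ms": video.times_ms,
            "row_px": rows,
            "col_px": cols,
            "x_mm": cols * px,
            "y_mm": rows * px,
            "vertical_mm": vertical_mm,
            "valid": valid,
        }
    )


def smooth_local_quadratic(track: pd.DataFrame, span_points: int = 30) -> pd.DataFrame:
    """Loess-smooth a centroid track (both axes) with a fixed-point span.

    Invalid frames are linearly interpolated before smoothing and remain
    flagged invalid afterwards.  A track with fewer valid frames than the
    span is rejected.
    """
    n_valid = int(track["valid"].sum())
    if n_valid < span_points:
        raise ValueError(f"track has {n_valid} valid frames, fewer than span {span_points}")
    out = track.copy()
    t = track["time_ms"].to_numpy()
    good = track["valid"].to_numpy()
    # loess is linear in the response, so smoothing the px and the mm
    # columns independently is exactly consistent (mm are affine in px)
    for col in ("row_px", "col_px", "x_mm", "y_mm", "vertical_mm"):
        if col not in track.columns:
            continue
        y = track[col].to_numpy(dtype=float)
        y = np.interp(t, t[good], y[good])
        out[col] = loess_quadratic(y, t, span_points)
    return out
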