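"""Region-of-interest analysis of oral constriction gestures.

Oral constrictions (lip, tongue-tip and tongue-body closures) are indexed
by the mean pixel intensity of small pseudo-circular regions placed along
the vocal-tract midline: as the active articulator moves into the region,
more tissue (higher proton density) enters it and the mean intensity
rises.  The midline itself is derived from the per-pixel temporal
standard deviation of the video - pixels that see tissue move in and out
have the highest SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothing import local_linear_gaussian
from .video import VideoSequence


def compute_sd_map(video: VideoSequence) -> np.ndarray:
    """Per-pixel sample standard deviation of intensity over time."""
    if video.n_frames < 2:
        raise ValueError("SD map needs at least 2 frames")
    return np.std(video.data, axis=0, ddof=1)


def derive_midline(sd_map: np.ndarray, n_select: int) -> np.ndarray:
    """Order the ``n_select`` highest-SD pixels into a connected path.

    Selection is by SD rank (ties broken in row-major order); the path is
    chained greedily by nearest neighbour starting from the most anterior
    (left-most, then top-most) selected pixel.  Returns an (n, 2) array of
    (row, col) coordinates.  Deterministic given the map.
    """
    sd_map = np.asarray(sd_map, dtype=float)
    if not np.any(sd_map > 0):
        raise ValueError("SD map is all zero; no moving tissue to trace")
    if n_select < 1:
        raise ValueError("n_select must be positive")
    flat = sd_map.ravel()
    # stable sort on (-sd, row-major index) -> deterministic tie-break
    order = np.argsort(-flat, kind="stable")[:n_select]
    pts = np.column_stack(np.unravel_index(order, sd_map.shape)).astype(float)

    # start from the most anterior pixel (min col, then min row)
    start = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    remaining = list(range(len(pts)))
    path = [remaining.pop(start)]
    while remaining:
        cur = pts[path[-1]]
        d2 = np.sum((pts[remaining] - cur) ** 2, axis=1)
        nxt = int(np.argmin(d2))  # ties: lowest index = row-major order
        path.append(remaining.pop(nxt))
    return pts[path].astype(int)


@dataclass(frozen=True)
class ROISpec:
    """Pseudo-circular region of interest.

    ``label`` is conventionally LAB (lower lip), COR (tongue tip) or DOR
    (tongue body/velar) but any name is accepted.  Membership is a
    center-in-circle test on pixel centers.
    """

    label: str
    center_px: tuple[float, float]  # (row, col)
    radius_px: float = 3.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("ROI radius must be >= 1 px")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        d2 = (rows - self.center_px[0]) ** 2 + (cols - self.center_px[1]) ** 2
        return d2 <= self.radius_px**2

    def validate_inside(self, shape: tuple[int, int]) -> None:
        r, c = self.center_px
        if (
            r - self.radius_px < -0.5
            or c - self.radius_px < -0.5
            or r + self.radius_px > shape[0] - 0.5
            or c + self.radius_px > shape[1] - 0.5
        ):
            raise ValueError(f"ROI {self.label!r} extends outside the frame")


def roi_intensity_series(video: VideoSequence, roi: ROISpec) -> pd.DataFrame:
    """Per-frame mean intensity inside the region.

    Returns a DataFrame with columns frame, time_ms, value, label.
    """
    roi.validate_inside(video.shape)
    mask = roi.mask(video.shape)
    values = video.data[:, mask].mean(axis=1)
    return pd.DataFrame(
        {
            "frame": np.arange(video.n_frames),
            "time_ms": video.times_ms,
            "value": values,
            "label": roi.label,
        }
    )


def smooth_weighted_linear(series: pd.DataFrame, kernel_width: float = 0.9) -> pd.DataFrame:
    """Smooth an intensity series with the locally weighted linear fit.

    ``kernel_width`` is the Gaussian kernel bandwidth in frame periods.
    Output has the same length and timestamps as the input.
    """
    out = series.copy()
    out["value"] = local_linear_gaussian(
        series["value"].to_numpy(), series["time_ms"].to_numpy(), kernel_width
    )
    return out
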