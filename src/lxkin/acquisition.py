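"""Acquisition geometry of the real-time MRI protocol.

The imaging protocol acquires a mid-sagittal slice with a 13-interleaf
spiral gradient-echo sequence.  One spiral arm takes one repetition time
(TR), so a fully sampled image spans ``interleaves * tr_ms``.  Videos are
reconstructed with a sliding window of a small number of TRs, which sets
the effective frame rate: ``1000 / (sliding_window_tr * tr_ms)`` frames/s.
The in-plane pixel size follows from the field of view and the image grid.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionSpec:
    """Spatial and temporal calibration of an rtMRI video.

    Defaults reproduce the study protocol: 200 mm field of view on an
    84 x 84 grid (2.4 mm pixels), TR 6.004 ms, 13 spiral interleaves and a
    2-TR sliding-window reconstruction (83.3 frames/s effective).
    """

    fov_mm: float = 200.0
    grid_px: int = 84
    tr_ms: float = 6.004
    interleaves: int = 13
    sliding_window_tr: int = 2

    def __post_init__(self) -> None:
        for name in ("fov_mm", "grid_px", "tr_ms", "interleaves", "sliding_window_tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def frame_rate_fps(self) -> float:
        """Effective frame rate of the sliding-window reconstruction."""
        return 1000.0 / (self.sliding_window_tr * self.tr_ms)

    @property
    def frame_period_ms(self) -> float:
        return self.sliding_window_tr * self.tr_ms

    @property
    def px_size_mm(self) -> float:
        """In-plane pixel size (isotropic)."""
        return self.fov_mm / self.grid_px

    @property
    def image_span_ms(self) -> float:
        """Time span of the data contributing to one fully sampled image."""
        return self.interleaves * self.tr_ms
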