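"""In-memory video container and plain-text-friendly I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .acquisition import AcquisitionSpec


@dataclass
class VideoSequence:
    """Ordered stack of grayscale frames with spatial/temporal calibration.

    ``data`` has shape (n_frames, n_rows, n_cols); intensities are floats,
    nominally in [0, 1].  Row 0 is the top of the image, so anatomical
    raising (upward movement) corresponds to decreasing row index.
    """

    data: np.ndarray
    acq: AcquisitionSpec = field(default_factory=AcquisitionSpec)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("video data must be (n_frames, rows, cols)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times_ms(self) -> np.ndarray:
        """Timestamp of each frame (ms), frame 0 at t = 0."""
        return np.arange(self.n_frames) * self.acq.frame_period_ms

    def write_tiff(self, path: str | Path) -> None:
        """Write as a multi-page grayscale TIFF (one page per frame)."""
        tifffile.imwrite(str(path), self.data.astype(np.float32))

    @classmethod
    def read_tiff(cls, path: str | Path, acq: AcquisitionSpec | None = None) -> "VideoSequence":
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        return cls(np.asarray(data, dtype=float), acq or AcquisitionSpec())
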