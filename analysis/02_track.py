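#!/usr/bin/env python
"""Track the phantoms: larynx centroid tracks and oral ROI series.

Reads the videos written by 01_simulate.py, runs intensity-weighted
centroid tracking (loess-smoothed) and the ROI mean-intensity analysis
(locally weighted linear smoothing), writes the tracks/series as CSV,
and reports the tracking error against the rendered ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import lxkin as lk
from lxkin.validation import _ACQ, _ORAL, _VTR

OUT = Path("results/analysis")


def main() -> None:
    for vpath in sorted(OUT.glob("phantom_*.tif")):
        name = vpath.stem
        video = lk.VideoSequence.read_tiff(vpath, _ACQ)
        truth = pd.read_csv(OUT / f"{name}_truth.csv")
        base_row = float(truth["lx_row_px"].iloc[0])
        track = lk.track_centroids(video, _VTR, lk.SeedPoint((base_row, 40.0)))
        smooth = lk.smooth_local_quadratic(track)
        smooth.to_csv(OUT / f"{name}_track.csv", index=False)

        ok = track["valid"].to_numpy()
        err_px = np.abs(track.loc[ok, "row_px"].to_numpy()
                        - truth.loc[ok, "lx_row_px"].to_numpy())
        print(f"{name}: tracked {ok.sum()}/{len(track)} frames, "
              f"max |row error| {err_px.max():.3f} px "
              f"({err_px.max() * _ACQ.px_size_mm:.3f} mm)")

        roi = lk.ROISpec("LAB", _ORAL["center"], _ORAL["radius"])
        series = lk.smooth_weighted_linear(lk.roi_intensity_series(video, roi))
        series.to_csv(OUT / f"{name}_roi_LAB.csv", index=False)

    # midline derivation from the temporal-SD map of the raising phantom
    video = lk.VideoSequence.read_tiff(OUT / "phantom_raising.tif", _ACQ)
    sd_map = lk.compute_sd_map(video)
    midline = lk.derive_midline(sd_map, n_select=15)
    pd.DataFrame(midline, columns=["row_px", "col_px"]).to_csv(
        OUT / "midline.csv", index=False)
    print(f"midline: {len(midline)} highest-SD pixels chained "
          f"(anterior start at {tuple(int(v) for v in midline[0])})")


if __name__ == "__main__":
    main()
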