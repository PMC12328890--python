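"""Reproducible pipeline stages over the library, driven by a config.

A run is fully determined by the config plus a seed: ``simulate`` writes
phantom videos (multi-page TIFF) with ground-truth CSVs and a token
table; ``track`` extracts ROI intensity series and centroid tracks;
``measure`` detects landmarks and derives the kinematic measures;
``stats`` produces the grouped summary tables and variability tests.
Every stage appends to a JSON run manifest holding the config hash and
the outputs it wrote, so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionSpec
from .landmarks import MEASURES, apply_omission_rule, derive_measures, find_gesture_landmarks
from .phantom import Blob, FillRegion, GestureSpec, MovingBlob, PhantomScene, render_phantom_video
from .roi import ROISpec, roi_intensity_series, smooth_weighted_linear
from .stats import brown_forsythe, cv_equality_test, group_summary, lag_duration_correlation
from .study import StudyDesign, generate_study_tokens
from .tracking import SeedPoint, VTRSpec, smooth_local_quadratic, track_centroids
from .video import VideoSequence


@dataclass
class PipelineConfig:
    """Everything a run needs besides the seed; YAML-serializable."""

    out_dir: str = "results/run"
    duration_ms: float = 1800.0
    acquisition: dict = field(default_factory=dict)
    scenes: list[dict] = field(default_factory=list)
    vtr: dict = field(default_factory=lambda: {"label": "LX", "rect_px": [44, 32, 19, 16]})
    seed_point: list[float] = field(default_factory=lambda: [56.0, 40.0])
    rois: list[dict] = field(
        default_factory=lambda: [{"label": "LAB", "center_px": [20.0, 20.0], "radius_px": 3.0}]
    )
    kernel_width: float = 0.9
    loess_span: int = 30
    landmark_threshold: float = 0.2
    segmentation_fraction: float = 0.2
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def acq(self) -> AcquisitionSpec:
        return AcquisitionSpec(**self.acquisition)


def _default_scene(amplitude_mm: float = 5.0, onset_lag_ms: float = 50.0) -> dict:
    """A canonical one-token scene: oral closure plus a lagged LX gesture."""
    oral_onset = 350.0
    return {
        "name": f"amp{amplitude_mm:+.1f}_lag{onset_lag_ms:+.0f}",
        "larynx": {
            "center_px": [56.0, 40.0],
            "radii_px": [4.0, 4.0],
            "gesture": {
                "onset_ms": oral_onset + onset_lag_ms,
                "transition_ms": 250.0,
                "hold_ms": 250.0,
                "release_ms": 300.0,
                "amplitude_mm": amplitude_mm,
            },
        },
        "oral": {
            "center_px": [20.0, 20.0],
            "radius_px": 3.0,
            "gesture": {
                "onset_ms": oral_onset,
                "transition_ms": 220.0,
                "hold_ms": 300.0,
                "release_ms": 250.0,
                "amplitude_mm": 1.0,
            },
        },
        "noise_sd": 0.0,
    }


def scene_from_dict(d: dict) -> PhantomScene:
    lx = d["larynx"]
    scene = PhantomScene(
        larynx_blob=Blob(tuple(lx["center_px"]), tuple(lx.get("radii_px", [4.0, 4.0]))),
        larynx_gesture=GestureSpec(**lx["gesture"]),
        noise_sd=d.get("noise_sd", 0.0),
        noise_model=d.get("noise_model", "gaussian"),
    )
    if "oral" in d:
        oral = d["oral"]
        scene.oral_tissue = FillRegion(tuple(oral["center_px"]), oral.get("radius_px", 3.0))
        scene.oral_gesture = GestureSpec(**oral["gesture"])
    for dist in d.get("distractors", []):
        scene.distractors.append(
            MovingBlob(
                Blob(tuple(dist["center_px"]), tuple(dist.get("radii_px", [2.0, 2.0])),
                     dist.get("peak_intensity", 1.0)),
                GestureSpec(**dist["gesture"]) if "gesture" in dist else None,
            )
        )
    return scene


class Manifest:
    """Append-only record of a run: config hash, stages, outputs."""

    def __init__(self, out_dir: Path, config: PipelineConfig, seed: int):
        self.path = out_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "config_sha256": config.sha256(),
                "seed": seed,
                "software_version": _version(),
                "stages": {},
            }

    def record(self, stage: str, outputs: list[Path], **extra) -> None:
        hashes = {str(p): hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs}
        self.data["stages"][stage] = {"outputs": hashes, **extra}
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _version() -> str:
    from . import __version__

    return __version__


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def cmd_simulate(config: PipelineConfig, seed: int, video: bool = True) -> Path:
    """Write token tables and (optionally) phantom videos + ground truth."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = []

    tokens = generate_study_tokens(StudyDesign(), seed=seed)
    tok_path = out / "tokens.csv"
    tokens.to_csv(tok_path, index=False)
    outputs.append(tok_path)

    if video:
        scenes = config.scenes or [_default_scene()]
        acq = config.acq()
        for i, sd in enumerate(scenes):
            scene = scene_from_dict(sd)
            vid, truth = render_phantom_video(scene, acq, config.duration_ms, seed + i)
            name = sd.get("name", f"scene{i:02d}")
            vpath = out / f"{name}.tif"
            vid.write_tiff(vpath)
            tpath = out / f"{name}_truth.csv"
            truth.to_csv(tpath, index=False)
            outputs += [vpath, tpath]

    manifest = Manifest(out, config, seed)
    manifest.record("simulate", outputs, n_tokens=len(tokens))
    return out


def cmd_track(config: PipelineConfig, seed: int) -> Path:
    """ROI series and centroid tracks for every simulated scene."""
    out = Path(config.out_dir)
    acq = config.acq()
    vtr = VTRSpec(config.vtr["label"], tuple(config.vtr["rect_px"]))
    seed_pt = SeedPoint(tuple(config.seed_point))
    outputs = []
    for vpath in sorted(out.glob("*.tif")):
        vid = VideoSequence.read_tiff(vpath, acq)
        track = track_centroids(vid, vtr, seed_pt)
        track = smooth_local_quadratic(track, config.loess_span)
        tpath = out / f"{vpath.stem}_track.csv"
        track.to_csv(tpath, index=False)
        outputs.append(tpath)
        for rd in config.rois:
            roi = ROISpec(rd["label"], tuple(rd["center_px"]), rd.get("radius_px", 3.0))
            series = roi_intensity_series(vid, roi)
            series = smooth_weighted_linear(series, config.kernel_width)
            spath = out / f"{vpath.stem}_roi_{roi.label}.csv"
            series.to_csv(spath, index=False)
            outputs.append(spath)
    manifest = Manifest(out, config, seed)
    manifest.record("track", outputs)
    return out


def cmd_measure(config: PipelineConfig, seed: int) -> Path:
    """Landmarks + derived measures for every tracked scene."""
    out = Path(config.out_dir)
    rows = []
    for tpath in sorted(out.glob("*_track.csv")):
        stem = tpath.name[: -len("_track.csv")]
        track = pd.read_csv(tpath)
        amp = _scene_amplitude(config, stem)
        direction = "lowering" if amp is not None and amp < 0 else "raising"
        lx_lm = find_gesture_landmarks(
            track["vertical_mm"], track["time_ms"], config.landmark_threshold, direction
        )
        roi_paths = sorted(out.glob(f"{stem}_roi_*.csv"))
        oral_lm = None
        if roi_paths:
            series = pd.read_csv(roi_paths[0])
            oral_lm = find_gesture_landmarks(
                series["value"], series["time_ms"], config.landmark_threshold, "raising"
            )
        meas = derive_measures(lx_lm, oral_lm) if oral_lm else None
        row = {"scene": stem}
        for name, lm in [("lx", lx_lm), ("oral", oral_lm)]:
            if lm is None:
                continue
            for field_ in ("ons", "pvel", "tons", "max", "toff"):
                l = getattr(lm, field_)
                row[f"{name}_{field_}_ms"] = l.time_ms
                row[f"{name}_{field_}_found"] = l.found
        if meas is not None:
            row.update(meas.as_dict())
        rows.append(row)
    mpath = out / "measures.csv"
    pd.DataFrame(rows).to_csv(mpath, index=False)
    manifest = Manifest(out, config, seed)
    manifest.record("measure", [mpath], n_scenes=len(rows))
    return out


def _scene_amplitude(config: PipelineConfig, stem: str) -> float | None:
    for sd in config.scenes or [_default_scene()]:
        if sd.get("name", "") == stem:
            return sd["larynx"]["gesture"]["amplitude_mm"]
    return None


def cmd_stats(config: PipelineConfig, seed: int) -> Path:
    """Group summaries and variability tests on the simulated token table."""
    out = Path(config.out_dir)
    tokens = pd.read_csv(out / "tokens.csv")
    retained, omission_log = apply_omission_rule(tokens)
    outputs = []
    for meas in MEASURES:
        summ = group_summary(retained[meas], meas)
        path = out / f"summary_{meas}.csv"
        summ.to_csv(path, index=False)
        outputs.append(path)
    omission_path = out / "omission_log.csv"
    omission_log.to_csv(omission_path, index=False)
    outputs.append(omission_path)

    lag_tab = retained["onset_lag_ms"]
    tests = {}
    grp = lambda cls: lag_tab.loc[lag_tab["class"] == cls, "onset_lag_ms"].to_numpy()
    pairs = [
        ("ejective_vs_implosive", "voiceless_ejective", "voiced_implosive"),
        ("implosive_vs_voiced", "voiced_implosive", "voiced_pulmonic"),
    ]
    for name, a, b in pairs:
        bf = brown_forsythe([grp(a), grp(b)], (a, b))
        tests[f"brown_forsythe_{name}"] = {
            "F": bf.statistic, "df1": bf.df1, "df2": bf.df2, "p": bf.p_value,
        }
    dur = retained["lx_duration_ms"]
    cv = cv_equality_test(
        [dur.loc[dur["class"] == c, "lx_duration_ms"].to_numpy()
         for c in ("voiceless_ejective", "voiced_implosive")],
        ("voiceless_ejective", "voiced_implosive"),
    )
    tests["cv_equality_duration"] = {"statistic": cv.statistic, "p": cv.p_value, "cvs": list(cv.cvs)}
    corr = lag_duration_correlation(
        tokens[tokens["class"].isin(["voiced_pulmonic", "voiced_implosive"])], "onset_lag_ms"
    )
    tests["lag_duration_correlation"] = {
        c.label: {"r": c.r, "p": c.p_value, "n": c.n} for c in corr if c.defined
    }
    tpath = out / "tests.json"
    tpath.write_text(json.dumps(tests, indent=2, sort_keys=True))
    outputs.append(tpath)
    manifest = Manifest(out, config, seed)
    manifest.record("stats", outputs)
    return out
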