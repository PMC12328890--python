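"""Velocity-threshold gesture landmarks and derived timing measures.

A gesture's time course - an ROI mean-intensity series for oral
constrictions, a vertical centroid position for the larynx - is reduced
to five landmarks defined on its velocity profile:

* ONS   movement onset: last time before peak velocity at which the
        toward-target velocity crosses 20 % of the first velocity peak;
* PVEL  first peak of the toward-target velocity;
* TONS  target attainment: first fall below the 20 % threshold after
        PVEL and before the positional extremum;
* MAX   maximum displacement: the velocity minimum (|v| minimum)
        closest to the signal's extremum;
* TOFF  target offset: first rise of the away-from-target speed above
        20 % of the release movement's peak velocity, after MAX.

Landmark times are located at sub-frame resolution by linear
interpolation of the velocity between frames; a landmark that cannot be
located is reported with ``found = False`` rather than raising - the
token-omission rule downstream consumes those flags.

From the landmarks of a larynx (LX) gesture and its coordinated oral
gesture the study's dependent variables are derived: LX displacement
(position at MAX minus position at ONS, signed, mm), LX extremum
(absolute vertical position at MAX, mm), onset lag (LX_ONS - Oral_ONS,
ms), target lag (LX_ONS - Oral_TONS, ms) and LX duration
(LX_TOFF - LX_ONS, ms).  Positive lags mean the larynx movement starts
after the oral landmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASURES = (
    "lx_displacement_mm",
    "lx_extremum_mm",
    "onset_lag_ms",
    "target_lag_ms",
    "lx_duration_ms",
)


def estimate_velocity(signal, times) -> np.ndarray:
    """Signal velocity per ms: central differences, one-sided at the ends."""
    signal = np.asarray(signal, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(signal) < 3:
        raise ValueError("need at least 3 points to estimate velocity")
    if np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return np.gradient(signal, times)


@dataclass
class Landmark:
    time_ms: float = math.nan
    value: float = math.nan
    found: bool = False


@dataclass
class GestureLandmarks:
    """The five landmark timepoints of one gesture."""

    ons: Landmark = field(default_factory=Landmark)
    pvel: Landmark = field(default_factory=Landmark)
    tons: Landmark = field(default_factory=Landmark)
    max: Landmark = field(default_factory=Landmark)
    toff: Landmark = field(default_factory=Landmark)

    def all_found(self, *names: str) -> bool:
        names = names or ("ons", "pvel", "tons", "max", "toff")
        return all(getattr(self, n).found for n in names)


def _first_local_max(v: np.ndarray, floor: float) -> int | None:
    """Index of the first local maximum of v strictly above ``floor``."""
    n = len(v)
    for i in range(n):
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < n - 1 else -np.inf
        if v[i] > floor and v[i] >= left and v[i] >= right:
            return i
    return None


def _cross_up_before(v, t, thr, i_end) -> float | None:
    """Last upward crossing of ``thr`` in v[:i_end+1], interpolated."""
    for j in range(i_end - 1, -1, -1):
        if v[j] < thr <= v[j + 1]:
            return float(t[j] + (thr - v[j]) * (t[j + 1] - t[j]) / (v[j + 1] - v[j]))
    return None


def _cross_down_after(v, t, thr, i_start, i_stop) -> float | None:
    """First downward crossing of ``thr`` in v[i_start:i_stop+1]."""
    for j in range(i_start, i_stop):
        if v[j] >= thr > v[j + 1]:
            return float(t[j] + (thr - v[j]) * (t[j + 1] - t[j]) / (v[j + 1] - v[j]))
    return None


def find_gesture_landmarks(
    signal,
    times,
    threshold: float = 0.2,
    direction: str = "raising",
    noise_floor_frac: float = 0.05,
) -> GestureLandmarks:
    """Locate the five velocity-threshold landmarks on a smoothed signal.

    ``direction`` selects the gesture target: ``"raising"`` treats the
    signal maximum as the target (larynx raising, constriction
    formation), ``"lowering"`` the minimum.  ``noise_floor_frac`` sets
    the floor (as a fraction of the global |v| maximum) below which a
    velocity peak is not accepted as PVEL - a raw first local maximum is
    fragile under noise.  Failure to locate a landmark is encoded in its
    ``found`` flag.
    """
    if direction not in ("raising", "lowering"):
        raise ValueError("direction must be 'raising' or 'lowering'")
    s = np.asarray(signal, dtype=float)
    t = np.asarray(times, dtype=float)
    g = s if direction == "raising" else -s
    v = estimate_velocity(g, t)
    lm = GestureLandmarks()
    vmax_abs = np.max(np.abs(v))
    if vmax_abs == 0:
        return lm
    floor = noise_floor_frac * vmax_abs

    # PVEL: first local maximum of the toward-target velocity above floor
    ip = _first_local_max(v, floor)
    if ip is None:
        return lm
    lm.pvel = Landmark(float(t[ip]), float(s[ip]), True)
    thr = threshold * v[ip]

    # ONS: last upward crossing of the threshold before PVEL
    t_ons = _cross_up_before(v, t, thr, ip)
    if t_ons is not None:
        lm.ons = Landmark(t_ons, float(np.interp(t_ons, t, s)), True)

    # positional extremum after PVEL (first occurrence)
    i_ext = ip + int(np.argmax(g[ip:]))

    # TONS: first fall below the threshold after PVEL, before the extremum
    t_tons = _cross_down_after(v, t, thr, ip, i_ext)
    if t_tons is not None:
        lm.tons = Landmark(t_tons, float(np.interp(t_tons, t, s)), True)

    # MAX: |v| minimum closest to the extremum
    absv = np.abs(v)
    cand = [
        i
        for i in range(max(ip, 1), len(v) - 1)
        if absv[i] <= absv[i - 1] and absv[i] <= absv[i + 1]
    ]
    if cand:
        i_max = min(cand, key=lambda i: (abs(t[i] - t[i_ext]), i))
        lm.max = Landmark(float(t[i_max]), float(s[i_max]), True)

        # TOFF: release movement after MAX; away-from-target speed = -v.
        # The release reference is the peak velocity of the movement away
        # from the target: the global -v maximum after MAX (a first local
        # maximum is fragile against small tracking wiggles on the hold).
        rel = -v[i_max:]
        ir = int(np.argmax(rel)) if len(rel) else None
        if ir is not None and rel[ir] > noise_floor_frac * vmax_abs:
            thr_off = threshold * rel[ir]
            t_toff = _cross_up_before(rel, t[i_max:], thr_off, ir)
            if t_toff is not None and t_toff >= t[i_max]:
                lm.toff = Landmark(t_toff, float(np.interp(t_toff, t, s)), True)
    return lm


@dataclass
class KinematicMeasures:
    """Per-token dependent variables; unavailable measures are NaN."""

    lx_displacement_mm: float = math.nan
    lx_extremum_mm: float = math.nan
    onset_lag_ms: float = math.nan
    target_lag_ms: float = math.nan
    lx_duration_ms: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}


def derive_measures(
    lx_landmarks: GestureLandmarks,
    oral_landmarks: GestureLandmarks,
) -> KinematicMeasures:
    """Combine LX and oral landmarks into the study's dependent variables.

    Each measure is computed only when its required landmarks were found;
    otherwise it stays NaN (unavailable) and the token-omission rule will
    drop the token for that variable.
    """
    m = KinematicMeasures()
    if lx_landmarks.all_found("ons", "max"):
        m.lx_displacement_mm = lx_landmarks.max.value - lx_landmarks.ons.value
        # absolute position within the VTR (mm above its bottom edge)
        m.lx_extremum_mm = lx_landmarks.max.value
    if lx_landmarks.all_found("ons") and oral_landmarks.all_found("ons"):
        m.onset_lag_ms = lx_landmarks.ons.time_ms - oral_landmarks.ons.time_ms
    if lx_landmarks.all_found("ons") and oral_landmarks.all_found("tons"):
        m.target_lag_ms = lx_landmarks.ons.time_ms - oral_landmarks.tons.time_ms
    if lx_landmarks.all_found("ons", "toff"):
        m.lx_duration_ms = lx_landmarks.toff.time_ms - lx_landmarks.ons.time_ms
    return m


def apply_omission_rule(
    table: pd.DataFrame, measures: tuple[str, ...] = MEASURES
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Drop tokens whose gestures were not captured, per dependent variable.

    A token is omitted for a measure when the measure is NaN or the token
    carries an ``omitted`` flag (no quantifiable vertical larynx
    movement).  Returns one retained-rows table per measure plus a
    per-(speaker, consonant) omission-count table.
    """
    table = table.copy()
    omitted_flag = (
        table["omitted"].astype(bool)
        if "omitted" in table.columns
        else pd.Series(False, index=table.index)
    )
    retained: dict[str, pd.DataFrame] = {}
    logs = []
    for meas in measures:
        if meas not in table.columns:
            continue
        drop = omitted_flag | table[meas].isna()
        retained[meas] = table.loc[~drop]
        counts = (
            table.loc[drop]
            .groupby(["speaker", "consonant"], observed=True)
            .size()
            .rename("n_omitted")
            .reset_index()
        )
        counts["measure"] = meas
        logs.append(counts)
    log = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["speaker", "consonant", "n_omitted", "measure"])
    )
    return retained, log
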