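"""Token-level simulator of the Hausa non-pulmonic consonant study.

Three speakers each produced 12 target consonants (velar and labio-velar
ejective stops, an alveolar ejective fricative, bilabial and alveolar
implosives, their pulmonic counterparts, and two nasals) in two prosodic
conditions (phrase-initial, phrase-internal) with 7 repetitions:
168 tokens per speaker.

The simulator draws each token's kinematic measures from per-
(speaker x consonant-class) normal distributions whose default means and
SDs are the study's published group statistics, and flags tokens as
omitted (no quantifiable vertical larynx movement) with per-
(speaker x consonant) Bernoulli probabilities matching the study's
reported omission counts (out of 14 tokens per consonant per speaker).
Quantities the study reports only as a range - the larynx-movement
durations, 200-600 ms - or not at all (nasal-class magnitudes, lag
distributions for voiceless pulmonics and nasals, which the study
excludes from the lag analyses) use documented assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPEAKERS = ("S1", "S2", "S3")
CONDITIONS = ("phrase_initial", "phrase_internal")
REPETITIONS = 7

# consonant -> class
CONSONANTS: dict[str, str] = {
    "k'": "voiceless_ejective",
    "kw'": "voiceless_ejective",
    "s'": "voiceless_ejective",
    "k": "voiceless_pulmonic",
    "kw": "voiceless_pulmonic",
    "s": "voiceless_pulmonic",
    "6b": "voiced_implosive",  # ASCII for the bilabial implosive
    "6d": "voiced_implosive",  # ASCII for the alveolar implosive
    "b": "voiced_pulmonic",
    "d": "voiced_pulmonic",
    "m": "nasal",
    "n": "nasal",
}
CLASSES = tuple(dict.fromkeys(CONSONANTS.values()))


@dataclass(frozen=True)
class StudyDesign:
    speakers: tuple[str, ...] = SPEAKERS
    consonants: dict[str, str] = field(default_factory=lambda: dict(CONSONANTS))
    conditions: tuple[str, ...] = CONDITIONS
    repetitions: int = REPETITIONS

    @property
    def tokens_per_speaker(self) -> int:
        return len(self.consonants) * len(self.conditions) * self.repetitions


# Published group statistics: {(speaker, class): {measure: (mean, sd)}}.
# LX displacement and extremum in mm; lags and durations in ms.
_T = {
    "voiceless_ejective": {
        "S1": {"disp": (5.33, 4.5), "ext": (25.87, 4.6), "onset": (70.55, 90.2), "target": (-43.53, 67.3)},
        "S2": {"disp": (6.81, 4.2), "ext": (25.9, 4.4), "onset": (43.63, 81.5), "target": (-66.48, 71.4)},
        "S3": {"disp": (3.33, 2.1), "ext": (30.54, 2.9), "onset": (78.63, 92.5), "target": (-31.44, 82.7)},
    },
    "voiceless_pulmonic": {
        "S1": {"disp": (2.89, 3.7), "ext": (25.52, 5.8)},
        "S2": {"disp": (6.65, 3.3), "ext": (23.43, 2.3)},
        "S3": {"disp": (2.29, 1.8), "ext": (29.61, 2.9)},
    },
    "voiced_implosive": {
        "S1": {"disp": (-1.92, 3.5), "ext": (21.84, 3.8), "onset": (22.69, 95.7), "target": (-75.16, 101.6)},
        "S2": {"disp": (-4.79, 4.4), "ext": (18.12, 4.9), "onset": (102.50, 53.2), "target": (0.85, 48.6)},
        "S3": {"disp": (-1.64, 1.5), "ext": (26.94, 3.2), "onset": (77.62, 115.0), "target": (-15.01, 121.3)},
    },
    "voiced_pulmonic": {
        "S1": {"disp": (-0.62, 4.5), "ext": (20.68, 5.2), "onset": (-20.87, 160.3), "target": (-132.62, 136.8)},
        "S2": {"disp": (-3.62, 5.6), "ext": (18.24, 6.1), "onset": (-11.53, 119.0), "target": (-122.0, 114.3)},
        "S3": {"disp": (-1.91, 2.8), "ext": (26.27, 4.1), "onset": (-35.16, 136.3), "target": (-145.82, 140.0)},
    },
}

# Published retained-token counts per (class, speaker): the unbalanced
# group sizes that enter the count-weighted pooled means.
GROUP_COUNTS = {
    "voiceless_ejective": {"S1": 40, "S2": 41, "S3": 42},
    "voiceless_pulmonic": {"S1": 37, "S2": 38, "S3": 42},
    "voiced_implosive": {"S1": 27, "S2": 28, "S3": 28},
    "voiced_pulmonic": {"S1": 23, "S2": 25, "S3": 28},
}

# Assumptions for cells the study does not print (see docs/methods.md):
# voiceless pulmonics and nasals are excluded from the lag analyses, and
# only the 200-600 ms range of larynx-movement duration is reported.
_LAG_DEFAULT = {"onset": (0.0, 130.0), "target": (-120.0, 130.0)}
_NASAL_DEFAULT = {"disp": (-1.0, 2.5), "ext": (22.0, 4.0), **_LAG_DEFAULT}
_DURATION = {  # ms, within the reported 200-600 ms range
    "voiceless_ejective": (350.0, 70.0),
    "voiceless_pulmonic": (400.0, 90.0),
    "voiced_implosive": (400.0, 80.0),
    "voiced_pulmonic": (450.0, 100.0),
    "nasal": (450.0, 100.0),
}

# Omission counts out of 14 tokens per consonant per speaker, as
# reported; absent consonants had no omissions.
OMISSION_COUNTS: dict[str, dict[str, int]] = {
    "S1": {"m": 8, "n": 7, "6d": 1, "b": 3, "d": 2, "k": 3, "kw": 1, "s": 1, "kw'": 2},
    "S2": {"m": 2, "n": 2, "b": 3, "k": 1, "kw": 2, "kw'": 1},
    "S3": {},
}

_KEYMAP = {
    "disp": "lx_displacement_mm",
    "ext": "lx_extremum_mm",
    "onset": "onset_lag_ms",
    "target": "target_lag_ms",
    "dur": "lx_duration_ms",
}


def default_class_params() -> pd.DataFrame:
    """Per-(speaker, class) means and SDs for the five measures.

    One row per cell with columns ``<measure>_mean`` / ``<measure>_sd``
    and an ``omission_p`` left to per-consonant resolution.
    """
    rows = []
    for cls in CLASSES:
        for spk in SPEAKERS:
            cell = dict(_NASAL_DEFAULT) if cls == "nasal" else dict(_T[cls][spk])
            cell.setdefault("onset", _LAG_DEFAULT["onset"])
            cell.setdefault("target", _LAG_DEFAULT["target"])
            cell["dur"] = _DURATION[cls]
            row = {"speaker": spk, "class": cls}
            for short, (mean, sd) in cell.items():
                row[f"{_KEYMAP[short]}_mean"] = mean
                row[f"{_KEYMAP[short]}_sd"] = sd
            rows.append(row)
    return pd.DataFrame(rows)


def omission_probability(speaker: str, consonant: str) -> float:
    """Per-token omission probability (reported count / 14)."""
    return OMISSION_COUNTS.get(speaker, {}).get(consonant, 0) / 14.0


def generate_study_tokens(
    design: StudyDesign | None = None,
    params: pd.DataFrame | None = None,
    seed: int = 0,
    with_omissions: bool = True,
) -> pd.DataFrame:
    """Draw one token table: one row per (speaker, consonant, condition, rep).

    Measures are independent normal draws from the cell's mean/SD;
    ``omitted`` flags follow the per-consonant Bernoulli probabilities
    when ``with_omissions`` is set.  Reproducible under ``seed``.
    """
    design = design or StudyDesign()
    params = default_class_params() if params is None else params
    lookup = params.set_index(["speaker", "class"])
    rng = np.random.default_rng(seed)
    rows = []
    for spk in design.speakers:
        for cons, cls in design.consonants.items():
            try:
                cell = lookup.loc[(spk, cls)]
            except KeyError:
                raise KeyError(f"missing class parameters for ({spk!r}, {cls!r})") from None
            p_omit = omission_probability(spk, cons) if with_omissions else 0.0
            for cond in design.conditions:
                for rep in range(1, design.repetitions + 1):
                    row = {
                        "speaker": spk,
                        "consonant": cons,
                        "class": cls,
                        "condition": cond,
                        "rep": rep,
                    }
                    for meas in _KEYMAP.values():
                        mean = cell[f"{meas}_mean"]
                        sd = cell[f"{meas}_sd"]
                        row[meas] = rng.normal(mean, sd) if sd > 0 else mean
                    row["omitted"] = bool(rng.random() < p_omit)
                    rows.append(row)
    return pd.DataFrame(rows)
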