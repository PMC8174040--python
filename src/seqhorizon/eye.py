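"""Gaze-to-digit mapping and press-relative eye position profiles.

Tracker x-coordinates are converted to fractional digit positions with
``D_t = 1 + (x_t - x0) / px``, where ``x_t`` is the median gaze position in
a 25-ms window around the keypress, ``x0`` the gaze position on the first
digit at trial start, and ``px`` the tracker-units-per-digit constant of
the block.  Subtracting the pressed position gives the eye lead: 0 means
the eye is exactly on the digit being pressed, +1 a full digit ahead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: window around the keypress over which the gaze median is taken (ms)
PRESS_WINDOW_MS = 25.0

#: window-size grouping used for profiles: 1, 2, 3, and "4+" for w >= 4
W_GROUP_LABELS = ("1", "2", "3", "4+")


@dataclass(frozen=True)
class EyeCalibration:
    """Block-constant mapping from tracker units to digit positions."""

    x0: float   # gaze at the first digit, trial start (tracker units)
    px: float   # tracker units per digit spacing

    def __post_init__(self):
        if self.px <= 0:
            raise ValueError("px must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"x0": self.x0, "px": self.px}))

    @classmethod
    def from_json(cls, path: str | Path) -> "EyeCalibration":
        d = json.loads(Path(path).read_text())
        return cls(x0=float(d["x0"]), px=float(d["px"]))


def eye_digit_at_press(
    times: np.ndarray,
    gaze_x: np.ndarray,
    press_time: float,
    calib: EyeCalibration,
    window_ms: float = PRESS_WINDOW_MS,
) -> float:
    """Fractional digit the eye fixates at the time of a press.

    Median gaze over ``press_time +/- window_ms/2``; NaN samples (blinks)
    are dropped first, and an empty window yields NaN rather than an
    interpolated value.
    """
    times = np.asarray(times, float)
    gaze_x = np.asarray(gaze_x, float)
    half = window_ms / 2.0
    sel = (times >= press_time - half) & (times <= press_time + half)
    vals = gaze_x[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return 1.0 + (float(np.median(vals)) - calib.x0) / calib.px


def relative_eye_position(d_t: float, press_position: int) -> float:
    """Eye lead in digits: gaze digit minus the pressed position (1-based)."""
    if not 1 <= press_position:
        raise ValueError("press_position must be >= 1")
    return d_t - press_position


def w_group(w: int | np.ndarray) -> np.ndarray:
    """Map window size to the profile grouping 1 / 2 / 3 / 4+."""
    w = np.asarray(w)
    return np.where(w >= 4, "4+", w.astype(str))


def press_eye_table(
    record,
    times: np.ndarray,
    gaze_x: np.ndarray,
    calib: EyeCalibration,
    window_ms: float = PRESS_WINDOW_MS,
) -> pd.DataFrame:
    """Per-press gaze digits and leads for one trial record."""
    rows = []
    for pos, e in enumerate(record.events, start=1):
        d_t = eye_digit_at_press(times, gaze_x, e.press_time, calib, window_ms)
        rows.append({
            "participant": record.participant, "day": record.day,
            "block": record.block, "trial": record.trial, "w": record.w,
            "press": pos, "d_t": d_t,
            "rel_pos": relative_eye_position(d_t, pos),
        })
    return pd.DataFrame(rows)


def eye_profile(
    eye_df: pd.DataFrame,
    press_range: tuple[int, int] = (3, 10),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Press-relative eye position profiles and ANOVA cell means.

    ``eye_df`` is a long per-press table with columns participant, day, w,
    press, rel_pos.  Returns ``(profile, cells)``:

    - ``profile``: group mean (participant-then-group averaging) of the
      eye lead per (day, w-group, press);
    - ``cells``: per-participant mean lead over presses in ``press_range``
      per (day, w-group), the cells of the day x window repeated-measures
      ANOVA.  Participants lacking any eye data are simply absent.
    """
    df = eye_df.dropna(subset=["rel_pos"]).copy()
    df["w_group"] = w_group(df["w"].to_numpy())
    subj = (df.groupby(["participant", "day", "w_group", "press"], sort=True)
              ["rel_pos"].mean().reset_index())
    profile = (subj.groupby(["day", "w_group", "press"], sort=True)["rel_pos"]
                   .mean().reset_index()
                   .rename(columns={"rel_pos": "mean_rel_pos"}))
    lo, hi = press_range
    mid = subj[(subj["press"] >= lo) & (subj["press"] <= hi)]
    cells = (mid.groupby(["participant", "day", "w_group"], sort=True)
                ["rel_pos"].mean().reset_index())
    return profile, cells
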