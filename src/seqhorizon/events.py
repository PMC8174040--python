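"""Trial-level event processing: press detection, RT/MT/IPI, reward rules.

A press is registered when the force on a key crosses 1 N upward and ends
when it falls back below 1 N.  Reaction time (RT) runs from stimulus onset
to the first press onset; movement time (MT) from the first press onset to
the release of the last press; interpress intervals (IPIs) are the times
between consecutive press onsets (13 per 14-press sequence).  A trial is an
error if any produced digit differs from its target or the press count is
wrong, and error trials are excluded from all timing aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: default press/release force threshold (N)
FORCE_THRESHOLD = 1.0

#: a key must stay below threshold at least this long before a new press
#: on the same key is registered (ms); guards against sensor noise
DEBOUNCE_MS = 20.0


@dataclass(frozen=True)
class PressEvent:
    """One detected keypress: 1 N upward crossing to downward crossing."""

    key: int                    # digit 1..5
    press_time: float           # ms
    release_time: float         # ms; NaN if the trace ended mid-press

    def __post_init__(self):
        if not math.isnan(self.release_time) and self.release_time <= self.press_time:
            raise ValueError("release_time must follow press_time")


@dataclass(frozen=True)
class ForceTrace:
    """Per-key sampled force time series for one trial (5 keys)."""

    times: np.ndarray           # (n,) ms, strictly increasing
    forces: np.ndarray          # (n, n_keys) N, non-negative
    participant: int = 0
    day: int = 0
    block: int = 0
    trial: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, float)
        f = np.asarray(self.forces, float)
        if t.ndim != 1 or f.ndim != 2 or f.shape[0] != t.shape[0]:
            raise ValueError("times must be (n,), forces (n, n_keys)")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "forces", f)


@dataclass
class TrialRecord:
    """One produced sequence with its target and detected press events."""

    participant: int
    day: int
    block: int
    trial: int
    w: int
    stim_onset: float
    target: tuple[int, ...]
    events: list[PressEvent]

    @property
    def produced(self) -> tuple[int, ...]:
        return tuple(e.key for e in self.events)

    @property
    def is_error(self) -> bool:
        if len(self.events) != len(self.target):
            return True
        return any(e.key != t for e, t in zip(self.events, self.target))


def detect_presses(
    trace: ForceTrace,
    threshold: float = FORCE_THRESHOLD,
    debounce_ms: float = DEBOUNCE_MS,
) -> list[PressEvent]:
    """Detect press events as supra-threshold force excursions.

    One event per contiguous excursion per key: the press time is the first
    sample at/above ``threshold`` after being below, the release time the
    first sample back below.  Sub-``debounce_ms`` dips below threshold on
    the same key are bridged.  Events from all keys are merged and sorted
    by press time; an excursion still above threshold at the end of the
    trace yields a NaN release time.
    """
    if trace.times.size == 0:
        raise ValueError("empty force trace")
    t = trace.times
    events: list[PressEvent] = []
    for k in range(trace.forces.shape[1]):
        above = trace.forces[:, k] >= threshold
        if not above.any():
            continue
        # rising/falling sample indices of supra-threshold runs
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = list(edges[~above[edges]] + 1)
        ends = list(edges[above[edges]] + 1)      # first below-threshold sample
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(-1)                        # unterminated excursion
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and merged[-1][1] != -1 and t[s] - t[merged[-1][1]] < debounce_ms:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            release = float("nan") if e == -1 else float(t[e])
            events.append(PressEvent(key=k + 1, press_time=float(t[s]), release_time=release))
    events.sort(key=lambda e: e.press_time)
    return events


def compute_rt(trial: TrialRecord) -> float:
    """Reaction time: stimulus onset to first press onset (ms)."""
    if not trial.events:
        return float("nan")
    return trial.events[0].press_time - trial.stim_onset


def compute_mt(trial: TrialRecord) -> float:
    """Movement time: first press onset to release of the last press (ms)."""
    n = len(trial.target)
    if len(trial.events) < n:
        return float("nan")
    last_release = trial.events[n - 1].release_time
    if math.isnan(last_release):
        return float("nan")
    return last_release - trial.events[0].press_time


def compute_ipis(trial: TrialRecord) -> np.ndarray:
    """Interpress intervals: consecutive press-onset differences (ms).

    Returns ``seq_length - 1`` values; raises on trials with missing
    presses (those are error trials and are excluded upstream).
    """
    n = len(trial.target)
    if len(trial.events) < n:
        raise ValueError("trial has fewer presses than sequence length")
    onsets = np.array([e.press_time for e in trial.events[:n]])
    return np.diff(onsets)


# -- adaptive MT threshold and reward points ------------------------------


@dataclass(frozen=True)
class ThresholdState:
    """Adaptive MT threshold used for the 3-point reward criterion."""

    current_threshold: float
    best_median_mt: float = math.inf

    def __post_init__(self):
        if self.current_threshold <= 0:
            raise ValueError("threshold must be positive")


def update_threshold(
    state: ThresholdState,
    block_median_mt: float,
    block_error_rate: float,
) -> ThresholdState:
    """Advance the adaptive threshold after a block.

    The threshold drops by 5% only if the block median MT beats the best
    median recorded so far (strictly) and the block error rate is <= 15%;
    otherwise it is unchanged.
    """
    if block_median_mt < state.best_median_mt and block_error_rate <= 0.15:
        return ThresholdState(
            current_threshold=0.95 * state.current_threshold,
            best_median_mt=block_median_mt,
        )
    return state


def award_points(is_error: bool, mt: float, threshold: float) -> int:
    """Reward points for one trial: 0 (error), 1 (correct), 3 (correct and
    MT at least 5% faster than the threshold, inclusive)."""
    if is_error:
        return 0
    if mt <= 0.95 * threshold:
        return 3
    return 1


# -- tabular interface ----------------------------------------------------

PRESS_COLUMNS = [
    "participant", "day", "block", "trial", "w", "position",
    "target_digit", "produced_digit", "press_time_ms", "release_time_ms",
    "stim_onset_ms",
]


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Long press-level table (one row per press) from trial records."""
    cols: dict[str, list] = {c: [] for c in PRESS_COLUMNS}
    for r in records:
        n = len(r.events)
        cols["participant"] += [r.participant] * n
        cols["day"] += [r.day] * n
        cols["block"] += [r.block] * n
        cols["trial"] += [r.trial] * n
        cols["w"] += [r.w] * n
        cols["position"] += list(range(1, n + 1))
        cols["target_digit"] += [
            r.target[i] if i < len(r.target) else -1 for i in range(n)
        ]
        cols["produced_digit"] += [e.key for e in r.events]
        cols["press_time_ms"] += [e.press_time for e in r.events]
        cols["release_time_ms"] += [e.release_time for e in r.events]
        cols["stim_onset_ms"] += [r.stim_onset] * n
    df = pd.DataFrame(cols)
    for c in ("participant", "day", "block", "trial", "w", "position",
              "target_digit", "produced_digit"):
        df[c] = df[c].astype(np.int64)
    return df


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild trial records from a press-level table."""
    records = []
    for key, g in df.groupby(["participant", "day", "block", "trial"], sort=True):
        g = g.sort_values("position")
        records.append(TrialRecord(
            participant=int(key[0]), day=int(key[1]), block=int(key[2]),
            trial=int(key[3]), w=int(g["w"].iloc[0]),
            stim_onset=float(g["stim_onset_ms"].iloc[0]),
            target=tuple(int(x) for x in g["target_digit"]),
            events=[
                PressEvent(int(k), float(p), float(rl))
                for k, p, rl in zip(g["produced_digit"], g["press_time_ms"],
                                    g["release_time_ms"])
            ],
        ))
    return records


TRIAL_KEYS = ["participant", "day", "block", "trial"]


def trial_summary(press_df: pd.DataFrame, seq_length: int = 14) -> pd.DataFrame:
    """Per-trial RT, MT and error flag from a press-level table."""
    df = press_df.sort_values(TRIAL_KEYS + ["position"]).copy()
    df["wrong"] = (df["produced_digit"] != df["target_digit"]).astype(int)
    g = df.groupby(TRIAL_KEYS, sort=True)
    out = g.agg(
        w=("w", "first"),
        n_presses=("position", "size"),
        first_press=("press_time_ms", "first"),
        last_release=("release_time_ms", "last"),
        stim_onset=("stim_onset_ms", "first"),
        n_wrong=("wrong", "sum"),
    ).reset_index()
    out["is_error"] = (out["n_wrong"] > 0) | (out["n_presses"] != seq_length)
    out["rt_ms"] = out["first_press"] - out["stim_onset"]
    out["mt_ms"] = out["last_release"] - out["first_press"]
    return out.drop(columns=["first_press", "last_release", "stim_onset"])


def block_summary(
    summary: pd.DataFrame,
    initial_threshold: float | None = None,
    include_error_trials_in_median: bool = False,
) -> pd.DataFrame:
    """Per-block medians, error rates, adaptive thresholds and points.

    Blocks are processed in (participant, day, block) order; the adaptive
    threshold evolves independently per participant.  By default the block
    median MT excludes error trials; if ``initial_threshold`` is None the
    threshold starts at each participant's first-block median MT.
    """
    rows = []
    for pid, pdat in summary.groupby("participant", sort=True):
        state = None
        for (day, block), b in pdat.groupby(["day", "block"], sort=True):
            ok = b if include_error_trials_in_median else b[~b["is_error"]]
            med = float(ok["mt_ms"].median()) if len(ok) else float("nan")
            err = float(b["is_error"].mean())
            if state is None:
                thr = initial_threshold if initial_threshold is not None else med
                state = ThresholdState(current_threshold=thr)
            points = int(sum(
                award_points(e, mt, state.current_threshold)
                for e, mt in zip(b["is_error"], b["mt_ms"])
            ))
            rows.append({
                "participant": pid, "day": day, "block": block,
                "median_mt_ms": med, "error_rate": err,
                "threshold_ms": state.current_threshold, "points": points,
            })
            if not math.isnan(med):
                state = update_threshold(state, med, err)
    return pd.DataFrame(rows)


def ipi_frame(press_df: pd.DataFrame, seq_length: int = 14) -> pd.DataFrame:
    """Long IPI table from a press-level table, error trials excluded.

    Columns: participant, day, block, trial, w, transition (1-based),
    ipi_ms.
    """
    summ = trial_summary(press_df, seq_length=seq_length)
    good = summ[~summ["is_error"]][TRIAL_KEYS]
    df = press_df.merge(good, on=TRIAL_KEYS, how="inner")
    df = df.sort_values(TRIAL_KEYS + ["position"])
    ipi = df.groupby(TRIAL_KEYS, sort=False)["press_time_ms"].diff().shift(-1)
    out = df.loc[ipi.notna(), TRIAL_KEYS + ["w", "position"]].copy()
    out["transition"] = out.pop("position")
    out["ipi_ms"] = ipi.dropna().to_numpy()
    return out.reset_index(drop=True)
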