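"""Generative simulator of viewing-window discrete sequence production.

The "soft horizon" model: every interpress interval has an
information-limited component that decays exponentially with the number of
visible future items, ``IPI(w) = C + A * exp(-b (w - 1))``, so that the
scheduled movement time follows the same exponential law that the analysis
fits, and the generating horizon ``w* = ln(100)/b + 1`` is known exactly.
The first and last transitions receive an extra speed-up (they are reliably
faster than mid-sequence transitions in this paradigm), noise is
multiplicative lognormal, and practice effects act as compounding daily
gains on the serial-response and asymptotic components plus a linear
expansion of the horizon.

Randomness is keyed: every (participant, day, block, trial) derives its own
stream from the master seed, so extending the design never perturbs
already-generated trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .events import ForceTrace, PressEvent, TrialRecord, trials_to_frame
from .eye import EyeCalibration
from .params import LOG100, GenerativeParams

# stream tags for keyed seeding
_TAG_FACTORS = 1
_TAG_BLOCK = 2
_TAG_TRIAL = 3
_TAG_EYE = 4


def keyed_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for a hierarchical key under one master seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def sample_sequence(n_digits: int, seq_length: int, rng: np.random.Generator) -> list[int]:
    """Random target sequence built from concatenated digit shuffles.

    Independent random permutations of ``1..n_digits`` are concatenated and
    truncated to ``seq_length``, so every digit appears at least
    ``seq_length // n_digits`` times.
    """
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    if n_digits < 2:
        raise ValueError("n_digits must be >= 2")
    reps = -(-seq_length // n_digits)
    parts = [rng.permutation(n_digits) + 1 for _ in range(reps)]
    return list(np.concatenate(parts)[:seq_length].astype(int))


def scheduled_profile(
    params: GenerativeParams,
    w: int,
    day: int,
    horizon_mult: float = 1.0,
    speed_factor: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Noise-free schedule for one trial: (RT, IPIs, press durations), ms.

    ``horizon_mult`` scales the participant's ``w* - 1``; ``speed_factor``
    multiplies all scheduled times (> 1 means slower).
    """
    if w not in params.window_set:
        raise ValueError(f"w={w} not in window_set {params.window_set}")
    n_trans = params.n_transitions
    w_star = 1.0 + (params.w_star_day(day) - 1.0) * horizon_mult
    b = LOG100 / (w_star - 1.0)
    day_sr = (1.0 - params.sr_gain_per_day) ** (day - 1)
    day_on = (1.0 - params.online_gain_per_day) ** (day - 1)
    sr = params.sr_time * speed_factor * day_sr
    c_ipi = params.c_true / n_trans * speed_factor * day_on
    a_ipi = sr - c_ipi
    if a_ipi <= 0:
        raise ValueError("degenerate schedule: w=1 IPI not slower than asymptote")
    ipis = np.full(n_trans, c_ipi + a_ipi * math.exp(-b * (w - 1)))
    if w >= 2:
        ipis[0] -= params.first_last_discount
        ipis[-1] -= params.first_last_discount
    ipis = np.maximum(ipis, params.min_ipi)
    # initiation time is decision-limited, not scaled by execution speed
    rt = params.rt_base + params.rt_per_item * min(w, params.preplan_cap)
    durations = np.full(params.seq_length, params.press_duration)
    return rt, ipis, durations


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma * sigma)


def simulate_trial(
    params: GenerativeParams,
    w: int,
    sequence: list[int] | tuple[int, ...],
    day: int,
    rng: np.random.Generator,
    *,
    participant: int = 1,
    block: int = 1,
    trial: int = 1,
    horizon_mult: float = 1.0,
    speed_factor: float = 1.0,
    stim_onset: float = 0.0,
) -> TrialRecord:
    """Simulate one trial: scheduled profile + noise + press errors."""
    seq = tuple(int(d) for d in sequence)
    if len(seq) != params.seq_length:
        raise ValueError("sequence length does not match params.seq_length")
    rt, ipis, durs = scheduled_profile(params, w, day, horizon_mult, speed_factor)
    n, nt = params.seq_length, params.n_transitions
    noise = _lognormal_factors(rng, params.noise_cv, 1 + nt + n)
    rt = rt * noise[0]
    ipis = ipis * noise[1:1 + nt]
    durs = durs * noise[1 + nt:]
    # keep releases inside the interval to the next press
    durs[:-1] = np.minimum(durs[:-1], 0.8 * ipis)
    onsets = stim_onset + rt + np.concatenate(([0.0], np.cumsum(ipis)))
    wrong = rng.random(n) < params.press_error_rate
    offsets = rng.integers(1, params.n_digits, size=n)
    produced = np.where(
        wrong, (np.array(seq) - 1 + offsets) % params.n_digits + 1, seq
    )
    events = [
        PressEvent(key=int(produced[i]), press_time=float(onsets[i]),
                   release_time=float(onsets[i] + durs[i]))
        for i in range(n)
    ]
    return TrialRecord(
        participant=participant, day=day, block=block, trial=trial, w=w,
        stim_onset=stim_onset, target=seq, events=events,
    )


def participant_factors(params: GenerativeParams) -> pd.DataFrame:
    """Per-participant ability draws: horizon multiplier and time factor.

    Log horizon multiplier and log time factor are bivariate normal with
    correlation ``horizon_speed_coupling`` (negative: larger horizons go
    with faster execution, producing the across-participant horizon-MT
    correlation seen in this paradigm).
    """
    rho = params.horizon_speed_coupling
    rows = []
    for pid in range(1, params.n_participants + 1):
        z1, e, z3 = _participant_draws(params, pid)
        z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * e
        rows.append({
            "participant": pid,
            "horizon_mult": math.exp(params.participant_horizon_sd * z1),
            "speed_factor": math.exp(params.participant_speed_sd * z2),
            "eye_lead_mult": math.exp(params.eye_lead_sd * z3),
        })
    return pd.DataFrame(rows)


def _participant_draws(params: GenerativeParams, pid: int) -> np.ndarray:
    return keyed_rng(params.seed, _TAG_FACTORS, pid).standard_normal(3)


def block_window_order(params: GenerativeParams, pid: int, day: int, block: int) -> np.ndarray:
    """Window sizes of one block: balanced repeats, randomized within block."""
    rng = keyed_rng(params.seed, _TAG_BLOCK, pid, day, block)
    ws = np.array(params.window_set)
    reps, rem = divmod(params.trials_per_block, ws.size)
    order = np.concatenate([np.tile(ws, reps),
                            rng.choice(ws, size=rem, replace=False)])
    rng.shuffle(order)
    return order.astype(int)


@dataclass
class SimulatedExperiment:
    """A complete synthetic experiment with its generative ground truth."""

    params: GenerativeParams
    records: list[TrialRecord]
    truth: pd.DataFrame            # per participant x day: b_true, w_star_true

    @cached_property
    def frame(self) -> pd.DataFrame:
        """Press-level long table (cached)."""
        return trials_to_frame(self.records)

    def calibration(self) -> EyeCalibration:
        return EyeCalibration(x0=self.params.eye_x0, px=self.params.eye_px)

    def force_trace(self, record: TrialRecord) -> ForceTrace:
        return synthesize_force_trace(record, self.params)

    def eye_stream(self, record: TrialRecord) -> tuple[np.ndarray, np.ndarray]:
        rng = keyed_rng(self.params.seed, _TAG_EYE, record.participant,
                        record.day, record.block, record.trial)
        return synthesize_eye_stream(record, self.params, rng)


def simulate_experiment(params: GenerativeParams) -> SimulatedExperiment:
    """Full factorial experiment: participants x days x blocks x trials.

    Window sizes are randomized within block; every trial draws a fresh
    random sequence.  The truth table records each participant's true decay
    rate and effective horizon per day.  Fully reproducible from
    ``params.seed``; force traces and eye streams are synthesized on demand
    from the returned object.
    """
    factors = participant_factors(params)
    records: list[TrialRecord] = []
    truth_rows = []
    for row in factors.itertuples(index=False):
        pid = int(row.participant)
        for day in range(1, params.n_days + 1):
            w_star = 1.0 + (params.w_star_day(day) - 1.0) * row.horizon_mult
            truth_rows.append({
                "participant": pid, "day": day,
                "w_star_true": w_star, "b_true": LOG100 / (w_star - 1.0),
                "horizon_mult": row.horizon_mult,
                "speed_factor": row.speed_factor,
            })
            for block in range(1, params.blocks_per_day + 1):
                windows = block_window_order(params, pid, day, block)
                for t, w in enumerate(windows, start=1):
                    rng = keyed_rng(params.seed, _TAG_TRIAL, pid, day, block, t)
                    seq = sample_sequence(params.n_digits, params.seq_length, rng)
                    records.append(simulate_trial(
                        params, int(w), seq, day, rng,
                        participant=pid, block=block, trial=t,
                        horizon_mult=row.horizon_mult,
                        speed_factor=row.speed_factor,
                    ))
    return SimulatedExperiment(params=params, records=records,
                               truth=pd.DataFrame(truth_rows))


def synthesize_force_trace(
    record: TrialRecord,
    params: GenerativeParams,
    peak: float = 2.5,
    ramp_ms: float = 30.0,
    pad_ms: float = 100.0,
) -> ForceTrace:
    """Render a trial's presses as smooth force pulses on a sample grid.

    Each press is a half-sine pulse that crosses 1 N exactly at the
    scheduled press time and falls below 1 N exactly at the release time,
    with strictly sub-threshold linear ramps on both sides; pulse shape is
    irrelevant to the contract, only the threshold crossings matter.
    """
    dt = 1000.0 / params.sample_rate_hz
    t_end = max(e.release_time for e in record.events) + pad_ms
    t = np.arange(0.0, t_end, dt)
    forces = np.zeros((t.size, params.n_digits))
    for e in record.events:
        k = e.key - 1
        tp, tr = e.press_time, e.release_time
        rise = (t >= tp - ramp_ms) & (t < tp)
        forces[rise, k] = np.maximum(
            forces[rise, k], 0.999 * (t[rise] - (tp - ramp_ms)) / ramp_ms)
        hold = (t >= tp) & (t <= tr)
        pulse = 1.0 + (peak - 1.0) * np.sin(np.pi * (t[hold] - tp) / (tr - tp))
        forces[hold, k] = np.maximum(forces[hold, k], pulse)
        fall = (t > tr) & (t <= tr + ramp_ms)
        forces[fall, k] = np.maximum(
            forces[fall, k], 0.999 * (1.0 - (t[fall] - tr) / ramp_ms))
    return ForceTrace(times=t, forces=forces, participant=record.participant,
                      day=record.day, block=record.block, trial=record.trial)


def scripted_eye_digit(
    params: GenerativeParams,
    w: int,
    press_position: int,
    lead_mult: float = 1.0,
) -> float:
    """Noise-free gaze digit at the time of a given press.

    Gaze leads the current press by ``lead_mult * eye_lead_gain *
    min(w - 1, eye_lead_cap)`` digits, clipped to the stimulus line; for
    w = 1 the scripted lead is zero (nothing beyond the next item is
    visible).  ``lead_mult`` is the participant's idiosyncratic gain.
    """
    lead = lead_mult * params.eye_lead_gain * min(w - 1, params.eye_lead_cap)
    return float(np.clip(press_position + lead, 1, params.seq_length))


def synthesize_eye_stream(
    record: TrialRecord,
    params: GenerativeParams,
    rng: np.random.Generator,
    pad_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Saccade-and-fixate gaze samples for one trial.

    Gaze steps between fixations midway between consecutive press onsets,
    so the 25-ms window around each press sees a constant scripted
    position; Gaussian noise (``eye_noise_sd`` digits) is added per sample.
    Returns (times_ms, gaze_x in tracker units).
    """
    dt = 1000.0 / params.sample_rate_hz
    onsets = np.array([e.press_time for e in record.events])
    t_end = max(e.release_time for e in record.events) + pad_ms
    t = np.arange(0.0, t_end, dt)
    mids = (onsets[:-1] + onsets[1:]) / 2.0
    seg = np.searchsorted(mids, t, side="right")  # 0-based press index
    lead_mult = math.exp(
        params.eye_lead_sd * _participant_draws(params, record.participant)[2])
    digits = np.array([
        scripted_eye_digit(params, record.w, p + 1, lead_mult)
        for p in range(len(onsets))
    ])[seg]
    noisy = digits + params.eye_noise_sd * rng.standard_normal(t.size)
    gaze_x = params.eye_x0 + (noisy - 1.0) * params.eye_px
    return t, gaze_x
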