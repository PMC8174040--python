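"""Parameters of the soft-horizon generative model.

The simulator emulates a viewing-window discrete sequence production (DSP)
experiment: participants produce 14-press sequences over the digits 1-5
while only ``w`` upcoming digits are visible.  The generative model mirrors
the analysis model: the information-limited component of every interpress
interval (IPI) decays exponentially with the number of visible future items,
so the scheduled movement time follows ``MT(w) = a * exp(-b (w - 1)) + c``
and the true effective planning horizon ``w* = -ln(0.01)/b + 1`` is known
exactly for every participant and day.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

#: drop criterion defining the effective horizon (1% above the asymptote)
HORIZON_CRITERION = 0.01

#: -ln(0.01), the log-factor mapping decay rate b to horizon w* - 1
LOG100 = -math.log(HORIZON_CRITERION)


def b_from_w_star(w_star: float) -> float:
    """Decay rate of the exponential MT model for a given effective horizon."""
    if w_star <= 1:
        raise ValueError(f"w_star must exceed 1, got {w_star}")
    return LOG100 / (w_star - 1.0)


def w_star_from_b(b: float, criterion: float = HORIZON_CRITERION) -> float:
    """Effective horizon implied by decay rate ``b`` (window items)."""
    if b <= 0:
        raise ValueError(f"b must be positive, got {b}")
    return -math.log(criterion) / b + 1.0


@dataclass(frozen=True)
class GenerativeParams:
    """Study-design constants and generative parameters of the simulator.

    Defaults reproduce the study conditions: 14 participants x 5 days,
    8 sequence blocks of 27 trials per day, window sizes
    {1,2,3,4,5,6,7,8,14} randomized within block, 14-press sequences over
    digits 1-5, trial error rates in the 10-15% range, and a day-1 group
    planning horizon near 3.2 items expanding by ~0.17 items/day.

    Timing parameters are in milliseconds; the decay rate is expressed as
    the day-1 effective horizon ``w_star_true`` (items), from which
    ``b_true = ln(100) / (w_star_true - 1)``.
    """

    # design
    n_participants: int = 14
    n_days: int = 5
    blocks_per_day: int = 8
    trials_per_block: int = 27
    window_set: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 14)
    seq_length: int = 14
    n_digits: int = 5

    # planning horizon (day 1 group value, items) and its practice expansion
    w_star_true: float = 3.2
    horizon_slope_per_day: float = 0.17

    # timing of the IPI model
    c_true: float = 2800.0          # asymptotic MT component (ms)
    sr_time: float = 500.0          # single serial-response IPI at w=1 (ms)
    first_last_discount: float = 80.0   # speed-up of IPI 1 and IPI 13 (ms)
    min_ipi: float = 40.0           # floor applied after the discount (ms)
    press_duration: float = 150.0   # press-to-release time (ms)

    # reaction time model: RT = rt_base + rt_per_item * min(w, preplan_cap)
    rt_base: float = 450.0
    rt_per_item: float = 75.0
    preplan_cap: int = 4

    # practice effects (fractional gain per day, compounded)
    sr_gain_per_day: float = 0.0225
    online_gain_per_day: float = 0.118

    # between-participant heterogeneity (lognormal sd on log scale)
    participant_horizon_sd: float = 0.25
    participant_speed_sd: float = 0.15
    horizon_speed_coupling: float = -0.75

    # noise and errors
    noise_cv: float = 0.12
    press_error_rate: float = 0.0095

    # eye movement script
    eye_lead_gain: float = 0.5      # digits of lead per visible future item
    eye_lead_cap: int = 4
    eye_lead_sd: float = 0.25       # lognormal sd of per-participant lead gain
    eye_noise_sd: float = 0.3       # digits
    eye_x0: float = 100.0           # tracker units at first digit
    eye_px: float = 35.0            # tracker units per digit spacing

    # sampling of synthesized force / eye streams
    sample_rate_hz: float = 200.0

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_participants": self.n_participants,
            "n_days": self.n_days,
            "blocks_per_day": self.blocks_per_day,
            "trials_per_block": self.trials_per_block,
            "seq_length": self.seq_length,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_digits < 2:
            raise ValueError("n_digits must be >= 2")
        if not self.window_set:
            raise ValueError("window_set must be non-empty")
        if any(w < 1 or w > self.seq_length for w in self.window_set):
            raise ValueError("window_set values must lie in [1, seq_length]")
        if self.w_star_true <= 1:
            raise ValueError("w_star_true must exceed 1")
        if self.c_true <= 0 or self.sr_time <= 0:
            raise ValueError("c_true and sr_time must be positive")
        if not 0 <= self.press_error_rate < 1:
            raise ValueError("press_error_rate must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.a_true <= 0:
            raise ValueError(
                "sr_time must exceed c_true / (seq_length - 1): the w=1 IPI "
                "must be slower than the asymptotic IPI"
            )
        if not -1 < self.horizon_speed_coupling < 1:
            raise ValueError("horizon_speed_coupling must be in (-1, 1)")

    # -- derived quantities of the exponential MT model -------------------

    @property
    def n_transitions(self) -> int:
        return self.seq_length - 1

    @property
    def b_true(self) -> float:
        """Day-1 group decay rate of the MT saturation curve (1/item)."""
        return b_from_w_star(self.w_star_true)

    @property
    def a_true(self) -> float:
        """Span of the MT curve (ms): MT(1) - asymptote = n_trans*sr - c."""
        return self.n_transitions * self.sr_time - self.c_true

    def w_star_day(self, day: int) -> float:
        """Group effective horizon on practice day ``day`` (1-based)."""
        return self.w_star_true + self.horizon_slope_per_day * (day - 1)

    def replace(self, **kwargs) -> "GenerativeParams":
        return dataclasses.replace(self, **kwargs)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_set"] = list(self.window_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        d = dict(d)
        if "window_set" in d:
            d["window_set"] = tuple(d["window_set"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerativeParams":
        return cls.from_dict(json.loads(Path(path).read_text()))
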