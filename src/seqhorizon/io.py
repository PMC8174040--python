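"""Plain-text I/O: CSV tables and JSON sidecars for simulated experiments."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .events import PRESS_COLUMNS, ForceTrace
from .params import GenerativeParams


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Press-level trial table (one row per press) to CSV."""
    missing = [c for c in PRESS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PRESS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df


def write_force_trace(trace: ForceTrace, path: str | Path) -> None:
    """Force trace to long CSV: one row per (sample, key)."""
    n, k = trace.forces.shape
    pd.DataFrame({
        "participant": np.repeat(trace.participant, n * k),
        "day": np.repeat(trace.day, n * k),
        "block": np.repeat(trace.block, n * k),
        "trial": np.repeat(trace.trial, n * k),
        "time_ms": np.repeat(trace.times, k),
        "key": np.tile(np.arange(1, k + 1), n),
        "force_N": trace.forces.ravel(),
    }).to_csv(path, index=False)


def read_force_trace(path: str | Path) -> ForceTrace:
    df = pd.read_csv(path)
    wide = df.pivot(index="time_ms", columns="key", values="force_N").sort_index()
    first = df.iloc[0]
    return ForceTrace(
        times=wide.index.to_numpy(float),
        forces=wide.to_numpy(float),
        participant=int(first["participant"]), day=int(first["day"]),
        block=int(first["block"]), trial=int(first["trial"]),
    )


def write_eye_samples(df: pd.DataFrame, path: str | Path) -> None:
    """Eye samples to CSV (trial ids, time_ms, gaze_x)."""
    df.to_csv(path, index=False)


def read_eye_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sidecar(
    path: str | Path,
    params: GenerativeParams,
    truth: pd.DataFrame | None = None,
) -> None:
    """JSON sidecar with generative parameters and per-unit ground truth."""
    payload = {"params": params.to_dict()}
    if truth is not None:
        payload["truth"] = truth.to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=2))


def read_sidecar(path: str | Path) -> tuple[GenerativeParams, pd.DataFrame | None]:
    payload = json.loads(Path(path).read_text())
    params = GenerativeParams.from_dict(payload["params"])
    truth = (pd.DataFrame(payload["truth"])
             if payload.get("truth") is not None else None)
    return params, truth
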