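"""Interpress-interval decomposition into preplanned and online planning.

Which transitions can be prepared before the first press depends only on
the viewing window: with w visible items, the first ``min(w - 1, 3)``
transitions can be preplanned (the preplanning capacity saturates at three
items ahead); the rest must be planned online during execution.  For w = 1
no transition can be preplanned and improvements reflect single-response
(stimulus identification, S-R mapping, execution) gains, labeled "sr".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .eye import w_group

CATEGORY_SR = "sr"
CATEGORY_PREPLANNED = "preplanned"
CATEGORY_ONLINE = "online"

#: maximum number of transitions that can be preplanned
PREPLAN_LIMIT = 3

#: mid-sequence transitions used for online-planning contrasts
MIDDLE_TRANSITIONS = (5, 12)


def preplanned_count(w: int) -> int:
    """Number of transitions preplannable with window size ``w``."""
    return 0 if w <= 1 else min(w - 1, PREPLAN_LIMIT)


def label_ipi(w: int, transition: int, n_transitions: int = 13) -> str:
    """Planning category of one transition: sr / preplanned / online."""
    if not 1 <= transition <= n_transitions:
        raise ValueError(
            f"transition must be in 1..{n_transitions}, got {transition}")
    if w < 1:
        raise ValueError("w must be >= 1")
    if w == 1:
        return CATEGORY_SR
    if transition <= preplanned_count(w):
        return CATEGORY_PREPLANNED
    return CATEGORY_ONLINE


def label_table(ipi_df: pd.DataFrame, n_transitions: int = 13) -> pd.DataFrame:
    """Add the planning-category column to a long IPI table."""
    df = ipi_df.copy()
    w = df["w"].to_numpy()
    tr = df["transition"].to_numpy()
    if tr.min() < 1 or tr.max() > n_transitions:
        raise ValueError("transition out of range")
    cat = np.where(
        w == 1, CATEGORY_SR,
        np.where(tr <= np.minimum(w - 1, PREPLAN_LIMIT),
                 CATEGORY_PREPLANNED, CATEGORY_ONLINE))
    df["category"] = cat
    return df


def ipi_profile(ipi_df: pd.DataFrame) -> pd.DataFrame:
    """Mean IPI per (w-group, transition), w grouped as 1 / 2 / 3 / 4+.

    Aggregation is participant-then-group: participant means are computed
    first so every participant contributes equally regardless of trial
    counts.  Expects error trials to be excluded already (the long IPI
    table is built from correct trials only).
    """
    df = ipi_df.copy()
    df["w_group"] = w_group(df["w"].to_numpy())
    subj = (df.groupby(["participant", "w_group", "transition"], sort=True)
              ["ipi_ms"].mean().reset_index())
    return (subj.groupby(["w_group", "transition"], sort=True)["ipi_ms"]
                .mean().reset_index()
                .rename(columns={"ipi_ms": "mean_ipi_ms"}))


def middle_ipi_means(ipi_df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean of mid-sequence transitions (5-12) per w."""
    lo, hi = MIDDLE_TRANSITIONS
    mid = ipi_df[(ipi_df["transition"] >= lo) & (ipi_df["transition"] <= hi)]
    return (mid.groupby(["participant", "w"], sort=True)["ipi_ms"]
               .mean().reset_index())


def middle_ipi_contrasts(ipi_df: pd.DataFrame) -> pd.DataFrame:
    """Paired tests between adjacent window sizes on middle IPIs.

    Middle transitions index the speed of online planning; the contrasts
    w = 1 vs 2, 2 vs 3 and 3 vs 4 test how far ahead extra visual
    information still speeds up mid-sequence production.
    """
    from .stats import paired_t

    wide = middle_ipi_means(ipi_df).pivot(index="participant", columns="w",
                                          values="ipi_ms")
    rows = []
    for w1, w2 in ((1, 2), (2, 3), (3, 4)):
        if w1 not in wide.columns or w2 not in wide.columns:
            continue
        pair = wide[[w1, w2]].dropna()
        t, df_, p = paired_t(pair[w1], pair[w2])
        rows.append({"w_low": w1, "w_high": w2,
                     "mean_low_ms": float(pair[w1].mean()),
                     "mean_high_ms": float(pair[w2].mean()),
                     "t": t, "df": df_, "p": p})
    return pd.DataFrame(rows)


def normalized_improvement(
    df: pd.DataFrame,
    value: str,
    cells: list[str],
    subject: str = "participant",
    day_col: str = "day",
    day_early: int | None = None,
    day_late: int | None = None,
) -> pd.DataFrame:
    """Percent improvement from early to late practice, per cell.

    For each subject and cell (e.g. each w, or each category x w), the
    improvement is ``(mean_early - mean_late) / mean(mean_early,
    mean_late) * 100`` -- normalizing by the across-day average makes the
    score invariant to each participant's overall speed.  Cells missing
    either day yield NaN.
    """
    if day_early is None:
        day_early = int(df[day_col].min())
    if day_late is None:
        day_late = int(df[day_col].max())
    sel = df[df[day_col].isin([day_early, day_late])]
    means = (sel.groupby([subject, day_col] + cells, sort=True)[value]
                .mean().reset_index())
    wide = means.pivot_table(index=[subject] + cells, columns=day_col,
                             values=value, aggfunc="first")
    for d in (day_early, day_late):
        if d not in wide.columns:
            wide[d] = float("nan")
    early, late = wide[day_early], wide[day_late]
    out = wide.reset_index()[[subject] + cells].copy()
    out["improvement_pct"] = (
        (early - late) / ((early + late) / 2.0) * 100.0
    ).to_numpy()
    return out


def category_improvement(
    ipi_df: pd.DataFrame,
    exclude_last_transition: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Normalized IPI improvement per planning category and w-group.

    The per-category score separates gains in single responses (w = 1),
    preplanning (early transitions, w >= 2) and online planning (the
    rest); the final transition stays in "online" by convention, and
    ``exclude_last_transition`` drops it as a robustness check (it carries
    its own end-of-sequence speed-up).
    """
    df = label_table(ipi_df)
    if exclude_last_transition:
        df = df[df["transition"] < df["transition"].max()]
    df["w_group"] = w_group(df["w"].to_numpy())
    return normalized_improvement(df, "ipi_ms", ["category", "w_group"],
                                  **kwargs)
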