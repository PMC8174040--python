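"""Exponential MT-vs-window model and the effective planning horizon.

Mean movement time as a function of viewing window size ``w`` is modeled
as ``MT'(w) = a * exp(-b (w - 1)) + c``: at w = 1 the curve starts at
``a + c`` and saturates toward the asymptote ``c`` with decay rate ``b``.
The effective planning horizon ``w*`` is the window size at which the
predicted MT has dropped 99% of the way to the asymptote,
``w* = -ln(0.01)/b + 1``.  Fits use Levenberg-Marquardt nonlinear least
squares on per-participant mean MTs, with ``b`` optimized on the log scale
so the horizon stays defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .params import HORIZON_CRITERION

#: multi-start values for the decay rate (1/item)
B_STARTS = (0.2, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class ExponentialFit:
    """Fitted (a, b, c) of the MT saturation curve plus fit metadata."""

    a: float        # span (ms); MT'(1) = a + c
    b: float        # decay rate (1/window item)
    c: float        # asymptote (ms)
    sse: float      # sum of squared residuals (ms^2)
    converged: bool
    n_points: int

    @property
    def valid(self) -> bool:
        """True when the fit supports a horizon: converged with a, b > 0."""
        return (self.converged and np.isfinite(self.b) and self.b > 0
                and self.a > 0)

    def predict(self, w) -> np.ndarray:
        w = np.asarray(w, float)
        return self.a * np.exp(-self.b * (w - 1.0)) + self.c


@dataclass(frozen=True)
class HorizonEstimate:
    """Effective planning horizon for one participant x day (or subset)."""

    w_star: float
    criterion: float = HORIZON_CRITERION
    source: tuple = ()


def _model(w, a, log_b, c):
    return a * np.exp(-np.exp(log_b) * (w - 1.0)) + c


def fit_exponential(
    w_values,
    mt_means,
    init: tuple[float, float, float] | None = None,
) -> ExponentialFit:
    """Least-squares fit of ``a * exp(-b (w - 1)) + c`` to mean MTs.

    Initialization follows the data (span, smallest mean, b0 = 0.5) unless
    ``init`` provides (a0, b0, c0); on failure the fit is restarted over a
    small grid of decay rates.  Flat data leave ``b`` unidentifiable and
    the fit is flagged invalid.
    """
    w = np.asarray(w_values, float)
    mt = np.asarray(mt_means, float)
    keep = np.isfinite(w) & np.isfinite(mt)
    w, mt = w[keep], mt[keep]
    if np.unique(w).size < 4:
        raise ValueError("need at least 4 distinct window sizes")
    if np.any(mt <= 0):
        raise ValueError("mean MTs must be positive")
    if np.ptp(mt) == 0:
        return ExponentialFit(a=0.0, b=float("nan"), c=float(mt[0]), sse=0.0,
                              converged=False, n_points=w.size)
    order = np.argsort(w)
    w, mt = w[order], mt[order]
    if init is not None:
        a0, b0, c0 = init
        starts = [(a0, b0, c0)]
    else:
        a0 = float(mt[0] - mt[-1])
        c0 = float(mt[-1])
        starts = [(a0, 0.5, c0)]
    starts += [(abs(a0) or 1.0, b0, c0) for b0 in B_STARTS]
    best: ExponentialFit | None = None
    for a_s, b_s, c_s in starts:
        if b_s <= 0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _model, w, mt, p0=[a_s, math.log(b_s), c_s],
                    method="lm", maxfev=20000,
                    ftol=1e-13, xtol=1e-13, gtol=1e-13)
        except (RuntimeError, ValueError):
            continue
        a, b, c = float(popt[0]), float(math.exp(popt[1])), float(popt[2])
        sse = float(np.sum((_model(w, *popt) - mt) ** 2))
        fit = ExponentialFit(a=a, b=b, c=c, sse=sse, converged=True,
                             n_points=w.size)
        if best is None or sse < best.sse:
            best = fit
        if init is None and sse <= 1e-9 * np.sum(mt ** 2):
            break
    if best is None:
        return ExponentialFit(a=float("nan"), b=float("nan"), c=float("nan"),
                              sse=float("inf"), converged=False,
                              n_points=w.size)
    return best


def effective_horizon(
    fit: ExponentialFit,
    criterion: float = HORIZON_CRITERION,
    source: tuple = (),
) -> HorizonEstimate:
    """Horizon at which MT' has dropped ``1 - criterion`` of the way to c.

    ``w* = -ln(criterion)/b + 1``; for the default criterion of 0.01 the
    predicted MT at ``w*`` equals ``c + 0.01 a`` exactly.  Changing the
    criterion rescales ``w* - 1`` by a log ratio and never reorders
    participants.
    """
    if not 0 < criterion < 1:
        raise ValueError("criterion must be in (0, 1)")
    if not fit.valid:
        return HorizonEstimate(w_star=float("nan"), criterion=criterion,
                               source=source)
    return HorizonEstimate(w_star=-math.log(criterion) / fit.b + 1.0,
                           criterion=criterion, source=source)


def mean_mt_by_w(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, day, w) mean MT over correct trials."""
    ok = summary[~summary["is_error"]]
    return (ok.groupby(["participant", "day", "w"], sort=True)["mt_ms"]
              .mean().reset_index())


def fit_cohort(
    summary: pd.DataFrame,
    per_day: bool = True,
    criterion: float = HORIZON_CRITERION,
) -> pd.DataFrame:
    """Exponential fit and horizon per participant (x day).

    Pools all non-error trials of the unit (participant, or participant x
    day), averages MT per window size, and fits the exponential.  Returns
    a tidy table with a, b, c, sse, converged, valid, w_star.
    """
    ok = summary[~summary["is_error"]]
    keys = ["participant", "day"] if per_day else ["participant"]
    means = (ok.groupby(keys + ["w"], sort=True)["mt_ms"].mean().reset_index())
    rows = []
    for ids, g in means.groupby(keys, sort=True):
        ids = ids if isinstance(ids, tuple) else (ids,)
        fit = fit_exponential(g["w"], g["mt_ms"])
        est = effective_horizon(fit, criterion, source=ids)
        rows.append(dict(zip(keys, ids)) | {
            "a": fit.a, "b": fit.b, "c": fit.c, "sse": fit.sse,
            "converged": fit.converged, "valid": fit.valid,
            "w_star": est.w_star, "n_points": fit.n_points,
        })
    return pd.DataFrame(rows)


def split_half_horizon_mt(
    summary: pd.DataFrame,
    day: int,
    w_min_mt: int = 6,
) -> pd.DataFrame:
    """Split-half quantities for the horizon-MT correlation on one day.

    The planning horizon is estimated from odd-numbered blocks and the
    mean MT for large windows (w > 5 by default, i.e. ``w >= w_min_mt``)
    from even-numbered blocks, removing the statistical dependency between
    the two measures.  Participants with fewer than two odd or two even
    blocks that day yield missing values.
    """
    d = summary[(summary["day"] == day) & (~summary["is_error"])]
    rows = []
    for pid, g in d.groupby("participant", sort=True):
        odd = g[g["block"] % 2 == 1]
        even = g[g["block"] % 2 == 0]
        w_star = float("nan")
        mt_even = float("nan")
        if odd["block"].nunique() >= 2 and even["block"].nunique() >= 2:
            means = odd.groupby("w")["mt_ms"].mean()
            if means.size >= 4:
                fit = fit_exponential(means.index, means.to_numpy())
                w_star = effective_horizon(fit, source=(pid, day)).w_star
            large = even[even["w"] >= w_min_mt]
            if len(large):
                mt_even = float(large["mt_ms"].mean())
        rows.append({"participant": pid, "day": day,
                     "w_star_odd": w_star, "mt_even_large_w": mt_even})
    return pd.DataFrame(rows)


def horizon_mt_correlation(summary: pd.DataFrame, w_min_mt: int = 6) -> pd.DataFrame:
    """Per-day Pearson correlation between split-half w* and large-w MT."""
    from .stats import pearson_r

    rows = []
    for day in sorted(summary["day"].unique()):
        sh = split_half_horizon_mt(summary, day, w_min_mt).dropna()
        r, p, n = pearson_r(sh["w_star_odd"], sh["mt_even_large_w"])
        rows.append({"day": day, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def mt_vs_larger_contrasts(summary: pd.DataFrame) -> pd.DataFrame:
    """Paired test of MT(w) against the mean MT over all larger windows.

    Locates the saturation point of the MT curve: the last window size
    whose MT still differs from the average of everything beyond it.
    """
    from .stats import paired_t

    means = (summary[~summary["is_error"]]
             .groupby(["participant", "w"], sort=True)["mt_ms"].mean()
             .unstack("w"))
    ws = sorted(means.columns)
    rows = []
    for i, w in enumerate(ws[:-1]):
        larger = means[ws[i + 1:]].mean(axis=1)
        t, df, p = paired_t(means[w], larger)
        rows.append({"w": w, "mean_diff_ms": float((means[w] - larger).mean()),
                     "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def horizon_expansion(w_star_by_day: dict[int, float] | pd.Series) -> float:
    """Horizon change from the first to the last practice day (items)."""
    s = pd.Series(w_star_by_day).sort_index()
    return float(s.iloc[-1] - s.iloc[0])
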