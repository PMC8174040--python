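"""Within-subject statistics: repeated-measures ANOVA, t tests, SEM.

Inference on condition means follows the classical within-subject
decomposition: each effect is tested against its subject-by-effect
interaction, so F = MS_effect / MS_(subject x effect) with df
(a - 1), (a - 1)(n - 1).  For two levels this reduces exactly to the
paired t test (F = t^2).  No sphericity correction is applied by default
and no multiple-testing correction anywhere -- every test is reported as
computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM


@dataclass(frozen=True)
class RMAnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float


def rm_anova(
    df: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
) -> pd.DataFrame:
    """One- or two-way within-subject repeated-measures ANOVA.

    ``df`` is a long table of cell means (replicates within a cell are
    averaged).  Subjects missing any cell are listwise-dropped.  Returns a
    tidy table with one row per effect: effect, F, df_num, df_den, p.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name one or two factors")
    data = df[[subject, dv] + within].dropna()
    cells = data.groupby([subject] + within, observed=True)[dv].mean().reset_index()
    n_cells = int(np.prod([cells[f].nunique() for f in within]))
    counts = cells.groupby(subject, observed=True).size()
    complete = counts[counts == n_cells].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        import logging
        logging.getLogger(__name__).warning(
            "rm_anova: dropping %d subject(s) with incomplete cells: %s",
            len(dropped), dropped)
    cells = cells[cells[subject].isin(complete)]
    if cells[subject].nunique() < 2:
        raise ValueError("need at least 2 subjects with complete cells")
    for f in within:
        if cells[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    res = AnovaRM(cells, depvar=dv, subject=subject, within=within).fit()
    tab = res.anova_table
    out = pd.DataFrame({
        "effect": tab.index,
        "F": tab["F Value"].to_numpy(float),
        "df_num": tab["Num DF"].to_numpy(float).round().astype(int),
        "df_den": tab["Den DF"].to_numpy(float).round().astype(int),
        "p": tab["Pr > F"].to_numpy(float),
    }).reset_index(drop=True)
    # constant marginal means -> zero effect SS -> F = 0 by definition
    # (the contrast-based computation can return 0/0 artifacts there)
    scale = max(float(cells[dv].abs().mean()), 1.0)
    for i, effect in enumerate(out["effect"]):
        marg = cells.groupby(effect.split(":"), observed=True)[dv].mean()
        if marg.std(ddof=0) <= 1e-12 * scale:
            out.at[i, "F"] = 0.0
            out.at[i, "p"] = 1.0
    return out


def paired_t(x, y, two_sided: bool = True) -> tuple[float, int, float]:
    """Two-sided (or one-sided) paired-samples t test: (t, df, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    if np.all(x == y):
        # zero difference with zero variance: no effect by definition
        return 0.0, int(x.size - 1), 1.0
    alternative = "two-sided" if two_sided else "greater"
    res = sps.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def one_sample_t(x, mu: float = 0.0, two_sided: bool = True) -> tuple[float, int, float]:
    """One-sample t test of the mean against ``mu``: (t, df, p)."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    alternative = "two-sided" if two_sided else "greater"
    res = sps.ttest_1samp(x, mu, alternative=alternative)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float, int]:
    """Pearson correlation: (r, p, n); NaN with zero variance or n < 3."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), int(x.size)
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def within_subject_sem(
    df: pd.DataFrame,
    dv: str,
    condition: str | list[str],
    subject: str = "participant",
) -> pd.DataFrame:
    """Condition SEMs on subject-centered data.

    Each subject's mean across conditions is removed (and the grand mean
    added back) before computing the per-condition SEM, so the error bars
    reflect the within-subject error term rather than between-subject
    offsets.
    """
    conds = [condition] if isinstance(condition, str) else list(condition)
    cells = df.groupby([subject] + conds, observed=True)[dv].mean().reset_index()
    subj_mean = cells.groupby(subject, observed=True)[dv].transform("mean")
    grand = cells[dv].mean()
    cells["_resid"] = cells[dv] - subj_mean + grand
    out = cells.groupby(conds, observed=True).agg(
        mean=(dv, "mean"),
        sem=("_resid", lambda s: s.std(ddof=1) / math.sqrt(len(s))),
        n=(dv, "size"),
    ).reset_index()
    return out


def chance_level(n_choices: int) -> float:
    """Probability of a correct keypress under uniform guessing."""
    if n_choices < 1:
        raise ValueError("n_choices must be >= 1")
    return 1.0 / n_choices


def unexplained_gain_share(
    horizon_predicted_drop_ms: float,
    gain_large_w_ms: float,
    gain_w1_ms: float,
) -> float:
    """Share (%) of the large-w practice gain, beyond single-response
    gains, accounted for by the horizon-predicted MT drop.

    The denominator is the practice gain at the largest window minus the
    gain at w = 1 (the single-response component present at every window).
    """
    residual = gain_large_w_ms - gain_w1_ms
    if residual == 0:
        raise ValueError("no residual gain to explain")
    return horizon_predicted_drop_ms / residual * 100.0
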