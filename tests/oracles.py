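"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def grid_search_sse(w, mt, b_grid=None):
    """Best SSE of a*exp(-b(w-1))+c over a dense b grid, with (a, c)
    profiled out by ordinary linear least squares at each b."""
    w = np.asarray(w, float)
    mt = np.asarray(mt, float)
    if b_grid is None:
        b_grid = np.geomspace(1e-3, 20.0, 600)
    best = np.inf
    for b in b_grid:
        x = np.exp(-b * (w - 1.0))
        X = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(X, mt, rcond=None)
        sse = float(np.sum((X @ coef - mt) ** 2))
        best = min(best, sse)
    return best


def loop_ipi_profile(ipi_df):
    """Participant-then-group mean IPI per (w-group, transition) computed
    with explicit loops."""
    df = ipi_df.copy()
    out = {}
    groups = {"1": [1], "2": [2], "3": [3],
              "4+": sorted(set(df["w"]) - {1, 2, 3})}
    for glabel, ws in groups.items():
        sub = df[df["w"].isin(ws)]
        for tr in sorted(sub["transition"].unique()):
            cell = sub[sub["transition"] == tr]
            per_subj = []
            for pid in sorted(cell["participant"].unique()):
                per_subj.append(cell[cell["participant"] == pid]["ipi_ms"].mean())
            out[(glabel, tr)] = float(np.mean(per_subj))
    return out


def paired_t_from_differences(x, y):
    """Textbook paired t statistic from the difference scores."""
    d = np.asarray(x, float) - np.asarray(y, float)
    return d.mean() / (d.std(ddof=1) / np.sqrt(d.size))


def loop_within_subject_sem(table):
    """Within-subject SEM of a subjects x conditions array via loops."""
    table = np.asarray(table, float)
    n, k = table.shape
    grand = table.mean()
    centered = np.empty_like(table)
    for i in range(n):
        for j in range(k):
            centered[i, j] = table[i, j] - table[i].mean() + grand
    return centered.std(axis=0, ddof=1) / np.sqrt(n)


def loop_rm_anova_oneway(table):
    """Classical one-way within-subject ANOVA from a subjects x levels
    array, computed with explicit sums of squares."""
    table = np.asarray(table, float)
    n, a = table.shape
    grand = table.mean()
    ss_effect = n * np.sum((table.mean(axis=0) - grand) ** 2)
    ss_subj = a * np.sum((table.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_effect - ss_subj
    df_num = a - 1
    df_den = (a - 1) * (n - 1)
    return (ss_effect / df_num) / (ss_err / df_den), df_num, df_den
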