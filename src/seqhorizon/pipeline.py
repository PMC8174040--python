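"""End-to-end pipeline: traces/trial tables -> tidy figure-level results.

``run_pipeline`` executes trial processing, horizon fitting, IPI
decomposition, eye analysis and within-subject statistics on a simulated
(or loaded) experiment and writes every result as a tidy CSV.  The whole
pipeline is a pure function of (inputs, config, seed); rerunning with the
same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import eye as eye_mod
from . import horizon as hz
from . import ipi as ipi_mod
from . import stats as st
from .events import ipi_frame, block_summary, trial_summary
from .params import GenerativeParams
from .simulate import SimulatedExperiment, simulate_experiment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Either simulate (default) or point ``trials_csv`` at a press-level
    table with the standard schema.  All randomness flows from
    ``params.seed``.
    """

    params: GenerativeParams = field(default_factory=GenerativeParams)
    trials_csv: str | None = None
    include_eye: bool = True
    eye_press_range: tuple[int, int] = (3, 10)
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = GenerativeParams.from_dict(raw.pop("params", {}) | {})
        return cls(params=params, **raw)


def _eye_table(exp: SimulatedExperiment) -> pd.DataFrame:
    """Per-press gaze digits for every correct trial (streaming).

    Eye streams are synthesized and reduced trial by trial, so the full
    continuous gaze recordings never have to be held in memory at once.
    """
    calib = exp.calibration()
    frames = []
    for rec in exp.records:
        if rec.is_error:
            continue
        t, x = exp.eye_stream(rec)
        frames.append(eye_mod.press_eye_table(rec, t, x, calib))
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["participant", "day", "block", "trial",
                                       "w", "press", "d_t", "rel_pos"]))


def improvement_share(summary: pd.DataFrame, fits_by_day: pd.DataFrame,
                      w_min_mt: int = 6) -> dict:
    """How much of the large-w practice gain the horizon expansion predicts.

    Combines (1) the day-first-to-last MT gains at w = 1 and at the largest
    window, (2) the horizon expansion from the per-day fits, and (3) the
    across-participant regression slope of large-w MT on split-half w*
    (averaged over days) into the share of the extra-beyond-single-response
    gain attributable to planning-horizon growth.
    """
    days = sorted(summary["day"].unique())
    d0, d1 = days[0], days[-1]
    ok = summary[~summary["is_error"]]
    w_max = int(ok["w"].max())
    gm = (ok.groupby(["participant", "day", "w"])["mt_ms"].mean()
            .groupby(["day", "w"]).mean())
    gain_w1 = float(gm.loc[(d0, 1)] - gm.loc[(d1, 1)])
    gain_wmax = float(gm.loc[(d0, w_max)] - gm.loc[(d1, w_max)])
    by_day = (fits_by_day[fits_by_day["valid"]]
              .groupby("day")["w_star"].mean())
    expansion = hz.horizon_expansion(by_day)
    slopes = []
    for day in days:
        sh = hz.split_half_horizon_mt(summary, day, w_min_mt).dropna()
        if len(sh) >= 3 and sh["w_star_odd"].std() > 0:
            slopes.append(float(np.polyfit(sh["w_star_odd"],
                                           sh["mt_even_large_w"], 1)[0]))
    slope = float(np.mean(slopes)) if slopes else float("nan")
    predicted_drop = -slope * expansion
    share = (st.unexplained_gain_share(predicted_drop, gain_wmax, gain_w1)
             if gain_wmax != gain_w1 else float("nan"))
    return {
        "day_first": d0, "day_last": d1, "w_max": w_max,
        "gain_w1_ms": gain_w1, "gain_wmax_ms": gain_wmax,
        "horizon_expansion_items": expansion,
        "mt_per_item_slope_ms": slope,
        "predicted_mt_drop_ms": predicted_drop,
        "share_pct": share,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full analysis; returns a dict of tidy tables (and writes CSVs).

    Keys: trial_summary, block_summary, mt_by_window, rt_by_window, fits,
    fits_by_day, horizon_by_day, mt_improvement, ipi_profile,
    ipi_contrasts, ipi_improvement, correlation, anova, ttests,
    improvement_share, eye_profile, eye_cells (if eye enabled),
    exclusions.
    """
    params = config.params
    if config.trials_csv is not None:
        from .io import read_trials

        press = read_trials(config.trials_csv)
        exp = None
    else:
        exp = simulate_experiment(params)
        press = exp.frame

    results: dict = {}
    summary = trial_summary(press, seq_length=params.seq_length)
    results["trial_summary"] = summary
    results["block_summary"] = block_summary(summary)

    n_err = int(summary["is_error"].sum())
    exclusions = {"error_trials": n_err, "n_trials": int(len(summary)),
                  "error_rate": n_err / max(len(summary), 1)}
    ok = summary[~summary["is_error"]]

    # MT / RT curves with within-subject error bars
    subj_mt = (ok.groupby(["participant", "w"])["mt_ms"].mean().reset_index())
    results["mt_by_window"] = st.within_subject_sem(subj_mt, "mt_ms", "w")
    subj_rt = (ok.groupby(["participant", "w"])["rt_ms"].mean().reset_index())
    results["rt_by_window"] = st.within_subject_sem(subj_rt, "rt_ms", "w")

    # exponential fits and horizons
    fits = hz.fit_cohort(summary, per_day=False)
    fits_by_day = hz.fit_cohort(summary, per_day=True)
    results["fits"] = fits
    results["fits_by_day"] = fits_by_day
    exclusions["invalid_fits"] = int((~fits["valid"]).sum())
    exclusions["invalid_fits_by_day"] = int((~fits_by_day["valid"]).sum())
    if config.strict and (exclusions["invalid_fits"]
                          or exclusions["invalid_fits_by_day"]):
        raise RuntimeError("invalid exponential fits under --strict")
    valid_day = fits_by_day[fits_by_day["valid"]]
    results["horizon_by_day"] = (
        valid_day.groupby("day")["w_star"]
        .agg(["mean", "std", "count"]).reset_index()
        .rename(columns={"mean": "w_star_mean", "std": "w_star_sd",
                         "count": "n"}))

    days = sorted(summary["day"].unique())
    d0, d1 = days[0], days[-1]

    # practice improvement, normalized within each window size
    results["mt_improvement"] = ipi_mod.normalized_improvement(
        ok, "mt_ms", ["w"], day_early=d0, day_late=d1)

    # IPI decomposition
    ipis = ipi_frame(press, seq_length=params.seq_length)
    labeled = ipi_mod.label_table(ipis, n_transitions=params.n_transitions)
    results["ipi_table"] = labeled
    results["ipi_profile"] = ipi_mod.ipi_profile(ipis)
    results["ipi_contrasts"] = ipi_mod.middle_ipi_contrasts(ipis)
    results["ipi_improvement"] = ipi_mod.category_improvement(
        ipis, day_early=d0, day_late=d1)

    # split-half horizon-MT correlation per day
    results["correlation"] = hz.horizon_mt_correlation(summary)

    # ANOVAs and t tests
    anovas = []

    def add_anova(df, dv, within, label):
        try:
            tab = st.rm_anova(df, dv, within)
        except ValueError as exc:
            log.warning("skipping ANOVA %s: %s", label, exc)
            return
        tab.insert(0, "analysis", label)
        anovas.append(tab)

    add_anova(subj_mt, "mt_ms", ["w"], "mt_by_w")
    add_anova(subj_rt, "rt_ms", ["w"], "rt_by_w")
    ends = ok[ok["day"].isin([d0, d1])]
    subj_mt_day = (ends.groupby(["participant", "day", "w"])["mt_ms"]
                   .mean().reset_index())
    add_anova(subj_mt_day, "mt_ms", ["day", "w"], "mt_by_day_w")
    subj_rt_day = (ends.groupby(["participant", "day", "w"])["rt_ms"]
                   .mean().reset_index())
    add_anova(subj_rt_day, "rt_ms", ["day", "w"], "rt_by_day_w")
    placement = (labeled[labeled["w"] > 1]
                 .groupby(["participant", "transition"])["ipi_ms"]
                 .mean().reset_index())
    add_anova(placement, "ipi_ms", ["transition"], "ipi_by_placement_wgt1")

    ttests = []
    for row in hz.mt_vs_larger_contrasts(summary).itertuples(index=False):
        ttests.append({"analysis": f"mt_w{row.w}_vs_larger", "t": row.t,
                       "df": row.df, "p": row.p,
                       "estimate": row.mean_diff_ms})
    wstar_wide = (valid_day[valid_day["day"].isin([d0, d1])]
                  .pivot(index="participant", columns="day", values="w_star")
                  .dropna())
    if len(wstar_wide) >= 2 and {d0, d1} <= set(wstar_wide.columns):
        t, df_, p = st.paired_t(wstar_wide[d1], wstar_wide[d0])
        ttests.append({"analysis": "w_star_day_last_vs_first", "t": t,
                       "df": df_, "p": p,
                       "estimate": float((wstar_wide[d1] - wstar_wide[d0]).mean())})
    results["ttests"] = pd.DataFrame(ttests)

    # share of the practice gain attributable to horizon expansion
    results["improvement_share"] = pd.DataFrame(
        [improvement_share(summary, fits_by_day)])

    # eye analysis
    if config.include_eye and exp is not None:
        eye_df = _eye_table(exp)
        n_press_nan = int(eye_df["rel_pos"].isna().sum())
        exclusions["eye_presses_missing"] = n_press_nan
        profile, cells = eye_mod.eye_profile(eye_df, config.eye_press_range)
        results["eye_profile"] = profile
        results["eye_cells"] = cells
        ends_cells = cells[cells["day"].isin([d0, d1])]
        add_anova(ends_cells, "rel_pos", ["day", "w_group"], "eye_by_day_wgroup")

    results["anova"] = (pd.concat(anovas, ignore_index=True)
                        if anovas else pd.DataFrame())
    results["exclusions"] = exclusions
    log.info("exclusions: %s", exclusions)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in results.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "exclusions.json").write_text(
            json.dumps(exclusions, indent=2))
        params.to_json(outdir / "params.json")
    return results


def recovery_study(
    w_star_values=(2.5, 3.5, 4.5),
    seed: int = 0,
    params: GenerativeParams | None = None,
) -> pd.DataFrame:
    """Truth-vs-recovered horizon across generating horizons.

    For each true group horizon, simulates a full experiment (horizon held
    constant across days), fits the exponential per participant on day-
    pooled mean MTs, and compares the group-mean recovered w* with the
    group-mean generating w* (participants keep their individual
    heterogeneity, recorded in the truth table).
    """
    base = params if params is not None else GenerativeParams()
    rows = []
    for i, w_star in enumerate(w_star_values):
        p = base.replace(w_star_true=float(w_star),
                         horizon_slope_per_day=0.0, seed=seed + i)
        exp = simulate_experiment(p)
        summary = trial_summary(exp.frame, seq_length=p.seq_length)
        fits = hz.fit_cohort(summary, per_day=False)
        merged = fits.merge(
            exp.truth.groupby("participant")["w_star_true"].mean().reset_index(),
            on="participant")
        valid = merged[merged["valid"]]
        rows.append({
            "w_star_nominal": float(w_star),
            "w_star_true_mean": float(merged["w_star_true"].mean()),
            "w_star_recovered_mean": float(valid["w_star"].mean()),
            "bias": float(valid["w_star"].mean() - merged["w_star_true"].mean()),
            "n_valid": int(len(valid)),
            "n_participants": int(len(merged)),
        })
    return pd.DataFrame(rows)
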