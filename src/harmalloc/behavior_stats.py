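"""Model-free behavioral summaries of harm-allocation choices.

Two families of summaries: (i) how often subjects take the Rawlsian
(group) option and how much extra total harm they accept by doing so, with
a one-sample t-test of the group-choice rate against chance; (ii) default
effects — Rawlsian choice rates by default condition compared with a
repeated-measures ANOVA (Greenhouse-Geisser corrected) and paired t-tests,
plus the probability of actively switching away from each default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import DEFAULT_CONDITIONS

REQUIRED_COLS = ("subject", "c_one", "c_group", "n_group",
                 "default_cond", "chose_one")


def _check(cohort: pd.DataFrame) -> None:
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    missing = [c for c in REQUIRED_COLS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")


def rawlsian_choice_stats(cohort: pd.DataFrame) -> dict:
    """Per-subject and group-level Rawlsian choice summary.

    Returns per-subject proportions of group choices, the group mean/SD, a
    one-sample t-test against 0.5, and the mean extra total harm accepted
    per trial: choosing the group on a trial adds
    ``delta_total = c_group*n_group - c_one`` seconds relative to the
    utilitarian option.
    """
    _check(cohort)
    df = cohort.copy()
    df["chose_group"] = 1 - df["chose_one"]
    df["extra_harm"] = (
        (df["c_group"] * df["n_group"] - df["c_one"]) * df["chose_group"]
    )
    per_subject = (
        df.groupby("subject")
        .agg(prop_group=("chose_group", "mean"),
             mean_extra_harm=("extra_harm", "mean"),
             n_trials=("chose_group", "size"))
        .reset_index()
    )
    props = per_subject["prop_group"].to_numpy(float)
    n = len(props)
    if n > 1 and props.std(ddof=1) > 0:
        t, p = stats.ttest_1samp(props, 0.5)
        t, p = float(t), float(p)
    else:
        t, p = float("nan"), float("nan")
    return {
        "per_subject": per_subject,
        "mean_prop_group": float(props.mean()),
        "sd_prop_group": float(props.std(ddof=1)) if n > 1 else 0.0,
        "t_vs_chance": t,
        "p_vs_chance": p,
        "df": n - 1,
        "mean_extra_harm": float(per_subject["mean_extra_harm"].mean()),
        "sd_extra_harm": float(per_subject["mean_extra_harm"].std(ddof=1))
        if n > 1 else 0.0,
    }


def _condition_rates(cohort: pd.DataFrame) -> pd.DataFrame:
    rates = (
        cohort.assign(chose_group=lambda d: 1 - d["chose_one"])
        .groupby(["subject", "default_cond"])["chose_group"]
        .mean()
        .unstack("default_cond")
    )
    missing = set(DEFAULT_CONDITIONS) - set(rates.columns)
    if missing or rates.isna().any().any():
        raise ValueError(f"every subject needs all three default conditions; "
                         f"missing {missing or 'cells'}")
    return rates[list(DEFAULT_CONDITIONS)]


def _degenerate_rm_anova(rates: np.ndarray) -> dict:
    """One-way repeated-measures decomposition for inputs pingouin's
    sphericity machinery cannot handle (zero variance somewhere)."""
    n, k = rates.shape
    grand = rates.mean()
    ss_cond = n * float(((rates.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((rates.mean(axis=1) - grand) ** 2).sum())
    ss_err = float(((rates - grand) ** 2).sum()) - ss_cond - ss_subj
    ms_cond = ss_cond / (k - 1)
    ms_err = ss_err / ((k - 1) * (n - 1))
    if ms_err > 0:
        F = ms_cond / ms_err
        p = float(stats.f.sf(F, k - 1, (k - 1) * (n - 1)))
    else:
        F = 0.0 if ms_cond == 0 else float("inf")
        p = float("nan")
    return {
        "F": F,
        "df1": float(k - 1),
        "df2": float((k - 1) * (n - 1)),
        "epsilon": float("nan"),
        "p": p,
        "sphericity_corrected": False,
    }


def default_effect_tests(cohort: pd.DataFrame) -> dict:
    """Default-condition contrasts on the Rawlsian choice rate.

    Returns per-condition rates, the repeated-measures ANOVA across the
    three default conditions with Greenhouse-Geisser correction (F,
    corrected dfs, epsilon), paired t-tests between conditions, and the
    paired t-test on the probability of switching away from the default
    (one-default: switching = choosing group; group-default: switching =
    choosing one).
    """
    _check(cohort)
    import pingouin as pg

    rates = _condition_rates(cohort)
    long = (
        rates.reset_index()
        .melt(id_vars="subject", var_name="default_cond", value_name="rate")
    )
    try:
        aov = pg.rm_anova(
            data=long, dv="rate", within="default_cond", subject="subject",
            correction=True, detailed=True,
        )
    except ZeroDivisionError:
        aov = None
    if aov is not None and "eps" in aov.columns and np.isfinite(aov["eps"].iloc[0]):
        row = aov.iloc[0]
        eps = float(row["eps"])
        df1, df2 = float(aov["DF"].iloc[0]), float(aov["DF"].iloc[1])
        gg_col = next((c for c in aov.columns if "GG" in c), None)
        has_gg = gg_col is not None and np.isfinite(row[gg_col])
        anova = {
            "F": float(row["F"]),
            "df1": eps * df1 if has_gg else df1,
            "df2": eps * df2 if has_gg else df2,
            "epsilon": eps,
            "p": float(row[gg_col]) if has_gg else float(row["p_unc"]),
            "sphericity_corrected": bool(has_gg),
        }
    else:
        # degenerate input (zero between- or within-condition variance):
        # fall back to the direct decomposition without a GG correction
        anova = _degenerate_rm_anova(rates.to_numpy(float))

    def paired(a: np.ndarray, b: np.ndarray) -> dict:
        if np.std(a - b, ddof=1) == 0:
            return {"t": float("nan"), "p": float("nan"), "df": len(a) - 1}
        t, p = stats.ttest_rel(a, b)
        return {"t": float(t), "p": float(p), "df": len(a) - 1}

    # switching probability: actively overriding the default
    switch_one_default = rates["one_default"].to_numpy(float)  # chose group
    switch_group_default = 1.0 - rates["group_default"].to_numpy(float)

    return {
        "condition_rates": rates,
        "anova": anova,
        "t_group_vs_no_default": paired(
            rates["group_default"].to_numpy(float),
            rates["none"].to_numpy(float)),
        "t_group_vs_one_default": paired(
            rates["group_default"].to_numpy(float),
            rates["one_default"].to_numpy(float)),
        "t_switch_one_vs_group_default": paired(
            switch_one_default, switch_group_default),
        "mean_switch_one_default": float(switch_one_default.mean()),
        "mean_switch_group_default": float(switch_group_default.mean()),
    }
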