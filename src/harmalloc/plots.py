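"""Small plotting helpers for the standard diagnostics figures.

Aesthetics are deliberately minimal; each function returns the Axes so
callers can restyle or save as they wish.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(4, 4))
    return ax


def recovery_scatter(scatter: pd.DataFrame, parameter: str, ax=None):
    """Truth vs. posterior-mean estimate for one parameter, with the
    identity line."""
    ax = _ax(ax)
    sub = scatter[scatter["parameter"] == parameter]
    ax.scatter(sub["truth"], sub["estimate"], s=18, alpha=0.7)
    lo = min(sub["truth"].min(), sub["estimate"].min())
    hi = max(sub["truth"].max(), sub["estimate"].max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    r = np.corrcoef(sub["truth"], sub["estimate"])[0, 1]
    ax.set_xlabel(f"true {parameter}")
    ax.set_ylabel(f"recovered {parameter}")
    ax.set_title(f"{parameter}: r = {r:.2f}")
    return ax


def condition_rates(rates: pd.DataFrame, ax=None):
    """Per-condition Rawlsian choice rates: cohort mean bars with subject
    lines overlaid."""
    ax = _ax(ax)
    conds = list(rates.columns)
    x = np.arange(len(conds))
    ax.bar(x, rates.mean(axis=0), color="lightgray", zorder=1)
    for _, row in rates.iterrows():
        ax.plot(x, row.to_numpy(), "o-", alpha=0.35, lw=0.8, zorder=2)
    ax.set_xticks(x, conds)
    ax.set_ylabel("P(choose group)")
    ax.set_ylim(0, 1)
    return ax


def predicted_vs_observed(ppc: dict, ax=None):
    """Posterior-predictive per-subject choice proportions."""
    ax = _ax(ax)
    ax.scatter(ppc["observed"], ppc["predicted"], s=20)
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("observed P(group)")
    ax.set_ylabel("predicted P(group)")
    r = ppc["correlation"]
    ax.set_title(f"posterior predictive: r = {r:.2f}")
    return ax
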