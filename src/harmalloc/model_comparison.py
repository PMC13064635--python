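"""Model comparison by approximate leave-one-out cross-validation and
posterior predictive checking.

The pointwise unit is one trial: the hierarchical fit stores a per-draw,
per-trial log-likelihood matrix, from which Pareto-smoothed importance
sampling (PSIS) yields the expected log pointwise predictive density
(elpd_loo) and LOOIC = -2 * elpd_loo.  Pairwise model contrasts report the
difference in elpd with the paired standard error sd(pointwise diff)*sqrt(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import pearsonr

from .choice_model import VARIANTS, design_arrays, logits
from .hierarchical import PosteriorFit

PARETO_K_WARN = 0.7


@dataclass
class LooResult:
    """PSIS-LOO summary for one fitted model."""

    name: str
    elpd_loo: float
    loo_se: float
    pointwise: np.ndarray  # per-observation elpd contributions
    pareto_k: np.ndarray

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd_loo

    @property
    def n_obs(self) -> int:
        return len(self.pointwise)

    @property
    def high_k_fraction(self) -> float:
        return float(np.mean(self.pareto_k > PARETO_K_WARN))


def psis_loo(fit: PosteriorFit, name: str | None = None) -> LooResult:
    """Pareto-smoothed importance-sampling LOO from the stored pointwise
    log-likelihood matrix."""
    import arviz as az

    if fit.log_lik is None or fit.log_lik.size == 0:
        raise ValueError("fit carries no pointwise log-likelihood matrix")
    idata = fit.to_inference_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    return LooResult(
        name=name or fit.model.name,
        elpd_loo=float(res.elpd_loo),
        loo_se=float(res.se),
        pointwise=np.asarray(res.loo_i.values, float),
        pareto_k=np.asarray(res.pareto_k.values, float),
    )


def compare(results: list[LooResult]) -> pd.DataFrame:
    """All ordered pairwise elpd contrasts.

    Row (a, b) reports elpd_diff = elpd(a) - elpd(b) with the paired SE;
    negative values mean model ``a`` predicts worse than model ``b``.
    """
    n_obs = {r.n_obs for r in results}
    if len(n_obs) > 1:
        raise ValueError("LOO results computed on different observation sets")
    rows = []
    for a in results:
        for b in results:
            d = a.pointwise - b.pointwise
            se = float(d.std(ddof=1) * np.sqrt(len(d))) if a is not b else 0.0
            rows.append((a.name, b.name, float(d.sum()), se,
                         a.looic, b.looic))
    return pd.DataFrame(
        rows, columns=["model", "reference", "elpd_diff", "se_diff",
                       "looic_model", "looic_reference"]
    )


def posterior_predictive(
    fit: PosteriorFit,
    data: pd.DataFrame,
    thin: int = 10,
) -> dict:
    """Predicted vs. observed per-subject Rawlsian (group) choice proportions.

    For a thinned subset of posterior draws the per-trial choice
    probabilities are averaged analytically (the expectation of simulated
    Bernoulli draws), giving each subject's predicted probability of
    choosing the group; reported with the Pearson correlation against the
    observed proportions.
    """
    subjects = fit.subjects
    if len(subjects) < 2:
        raise ValueError("posterior predictive check needs >= 2 subjects")
    pred = np.zeros(len(subjects))
    obs = np.zeros(len(subjects))
    model = fit.model
    for i, s in enumerate(subjects):
        sub = data[data["subject"] == s]
        arr = design_arrays(sub)
        obs[i] = 1.0 - sub["chose_one"].mean()
        draws = {
            k: fit.subject_draws[k][:, ::thin, i].ravel() for k in model.free
        }
        n_draws = len(next(iter(draws.values())))
        acc = 0.0
        for d in range(n_draws):
            pdict = model.resolve(**{k: draws[k][d] for k in model.free})
            acc += float(np.mean(1.0 - expit(
                logits(arr, pdict, ratio_phi=model.ratio_phi))))
        pred[i] = acc / n_draws
    if np.std(obs) == 0.0 or np.std(pred) == 0.0:
        r, p = float("nan"), float("nan")
    else:
        r, p = pearsonr(pred, obs)
    return {
        "predicted": pred,
        "observed": obs,
        "correlation": float(r),
        "p_value": float(p),
        "subjects": list(subjects),
    }
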