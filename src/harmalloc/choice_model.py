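"""Utility model family for harm-allocation choices.

The winning model scores the "one" option (harm C_one to a single person)
against the "group" option (harm C_group to each of N_group people) with a
convex mixture of a utilitarian term (total harm) and a Rawlsian maximin
term (worst-off harm), shifted by an agreeability threshold phi:

    U(one)   = -(1 - alpha) * C_one           - alpha * (C_one + phi)
    U(group) = -(1 - alpha) * C_group*N_group - alpha * C_group
    dU       = U(one) - U(group)
             = (1 - alpha) * d_total - alpha * (d_single + phi)

    d_total  = C_group*N_group - C_one   (extra total harm of the group option)
    d_single = C_one - C_group           (extra worst-off harm of the one option)

alpha in [0, 1] weights maximin (alpha=1) against utilitarian (alpha=0)
considerations; phi (seconds) is the harm premium on one person the decider
treats as mutually acceptable; choices are softmax in dU with inverse
temperature tau:  P(choose one) = 1 / (1 + exp(-tau * dU)).

Constrained and alternative variants used for model comparison are defined
in :data:`VARIANTS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .task_design import TrialSpec

WINNING_MODEL = "full_constant_phi"


@dataclass(frozen=True)
class SubjectParams:
    """Free parameters of the winning model for one subject.

    alpha : maximin weight in [0, 1] (0 = utilitarian, 1 = pure maximin)
    phi   : agreeability threshold in seconds (unbounded)
    tau   : softmax inverse temperature, > 0
    kappa : optional default-stickiness bonus (extension variant only)
    """

    alpha: float
    phi: float
    tau: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0,1], got {self.alpha}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not np.isfinite(self.phi):
            raise ValueError("phi must be finite")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model family.

    ``free`` names the per-subject free parameters; ``fixed`` pins the
    remaining utility parameters.  ``ratio_phi`` switches the agreeability
    term from an additive constant to a multiple of the group member's harm.
    """

    name: str
    free: tuple[str, ...]
    fixed: Mapping[str, float] = field(default_factory=dict)
    ratio_phi: bool = False

    def resolve(self, **free_values: float) -> dict[str, float]:
        missing = set(self.free) - set(free_values)
        if missing:
            raise ValueError(f"missing free parameters {missing} for {self.name}")
        out = {"alpha": 0.0, "phi": 0.0, "tau": 1.0, "kappa": 0.0}
        out.update(self.fixed)
        out.update({k: free_values[k] for k in self.free})
        return out


VARIANTS: dict[str, ModelSpec] = {
    "full_constant_phi": ModelSpec("full_constant_phi", ("alpha", "phi", "tau")),
    "alpha_fixed_1": ModelSpec("alpha_fixed_1", ("phi", "tau"), {"alpha": 1.0}),
    "alpha_fixed_0": ModelSpec("alpha_fixed_0", ("tau",), {"alpha": 0.0, "phi": 0.0}),
    "no_phi": ModelSpec("no_phi", ("alpha", "tau"), {"phi": 0.0}),
    "ratio_phi": ModelSpec("ratio_phi", ("alpha", "phi", "tau"), ratio_phi=True),
    "default_bias_ext": ModelSpec(
        "default_bias_ext", ("alpha", "phi", "tau", "kappa")
    ),
}


@dataclass(frozen=True)
class UtilityComponents:
    delta_total: float
    delta_single: float
    delta_u: float
    u_one: float
    u_group: float


# ---------------------------------------------------------------------------
# vectorized utilities on design arrays


def design_arrays(design: pd.DataFrame) -> dict[str, np.ndarray]:
    """Extract the numeric arrays the model needs from a design/choice table.

    ``default_sign`` codes the default condition: +1 if "one" is the default,
    -1 if "group" is, 0 if there is no default.
    """
    sign = np.select(
        [design["default_cond"] == "one_default",
         design["default_cond"] == "group_default"],
        [1.0, -1.0],
        default=0.0,
    )
    return {
        "c_one": design["c_one"].to_numpy(float),
        "c_group": design["c_group"].to_numpy(float),
        "n_group": design["n_group"].to_numpy(float),
        "default_sign": sign,
    }


def delta_u_arrays(
    c_one: np.ndarray,
    c_group: np.ndarray,
    n_group: np.ndarray,
    alpha,
    phi,
    ratio_phi: bool = False,
) -> np.ndarray:
    """dU = U(one) - U(group), broadcasting over trials and parameters."""
    d_total = c_group * n_group - c_one
    if ratio_phi:
        # agreeable harm to the one is a multiple phi of each member's harm
        return (1.0 - alpha) * d_total - alpha * (c_one - phi * c_group)
    d_single = c_one - c_group
    return (1.0 - alpha) * d_total - alpha * (d_single + phi)


def logits(arrays: Mapping[str, np.ndarray], params: Mapping[str, float],
           ratio_phi: bool = False) -> np.ndarray:
    """Softmax logit of choosing "one": tau*dU (+ kappa toward the default)."""
    du = delta_u_arrays(
        arrays["c_one"], arrays["c_group"], arrays["n_group"],
        params["alpha"], params["phi"], ratio_phi=ratio_phi,
    )
    return params["tau"] * du + params.get("kappa", 0.0) * arrays["default_sign"]


def logit_grads(arrays: Mapping[str, np.ndarray], params: Mapping[str, float],
                ratio_phi: bool = False) -> dict[str, np.ndarray]:
    """Per-trial derivatives of the logit w.r.t. each natural parameter."""
    c_one, c_group, n_group = arrays["c_one"], arrays["c_group"], arrays["n_group"]
    d_total = c_group * n_group - c_one
    alpha, phi, tau = params["alpha"], params["phi"], params["tau"]
    if ratio_phi:
        du = (1.0 - alpha) * d_total - alpha * (c_one - phi * c_group)
        d_alpha = -d_total - (c_one - phi * c_group)
        d_phi = alpha * c_group
    else:
        d_single = c_one - c_group
        du = (1.0 - alpha) * d_total - alpha * (d_single + phi)
        d_alpha = -d_total - (d_single + phi)
        d_phi = -alpha * np.ones_like(du)
    return {
        "alpha": tau * d_alpha,
        "phi": tau * d_phi,
        "tau": du,
        "kappa": arrays["default_sign"],
    }


# ---------------------------------------------------------------------------
# scalar / dataset level API


def utility_components(trial: TrialSpec, params: SubjectParams) -> UtilityComponents:
    """Utility decomposition of one trial under the constant-phi model."""
    a, p = params.alpha, params.phi
    u_one = -(1 - a) * trial.c_one - a * (trial.c_one + p)
    u_group = -(1 - a) * trial.c_group * trial.n_group - a * trial.c_group
    du = (1 - a) * trial.delta_total - a * (trial.delta_single + p)
    return UtilityComponents(
        delta_total=trial.delta_total,
        delta_single=trial.delta_single,
        delta_u=du,
        u_one=u_one,
        u_group=u_group,
    )


def choice_prob(trial: TrialSpec, params: SubjectParams) -> float:
    """P(choose "one") under the softmax rule; in (0,1), 0.5 at dU = 0."""
    du = utility_components(trial, params).delta_u
    sign = {"one_default": 1.0, "group_default": -1.0}.get(trial.default_cond, 0.0)
    return float(expit(params.tau * du + params.kappa * sign))


def _require_choices(data: pd.DataFrame) -> np.ndarray:
    if "chose_one" not in data.columns:
        raise ValueError("choice table lacks a 'chose_one' column")
    y = data["chose_one"].to_numpy()
    if np.any(pd.isna(y)):
        raise ValueError("missing choices present; filter or impute first")
    return y.astype(float)


def log_likelihood(
    data: pd.DataFrame,
    params: SubjectParams,
    model: ModelSpec | str = WINNING_MODEL,
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of observed choices.

    ``data`` is one subject's trial table with a binary ``chose_one`` column
    (1 = chose the single individual).  The per-trial vector is what LOO
    consumes downstream.
    """
    if isinstance(model, str):
        model = VARIANTS[model]
    y = _require_choices(data)
    arr = design_arrays(data)
    pdict = model.resolve(**{k: getattr(params, k) for k in model.free})
    logit = logits(arr, pdict, ratio_phi=model.ratio_phi)
    # log P(y) = -log(1 + exp(-(2y-1) * logit)), computed stably
    pointwise = -np.logaddexp(0.0, -(2.0 * y - 1.0) * logit)
    return float(pointwise.sum()), pointwise


def simulate_choices(
    design: pd.DataFrame,
    params: SubjectParams,
    seed: int | np.random.Generator,
    model: ModelSpec | str = WINNING_MODEL,
) -> pd.DataFrame:
    """Simulate Bernoulli choices on a design; returns the design plus
    ``chose_one`` (int) and ``choice`` ("one"/"group") columns."""
    if isinstance(model, str):
        model = VARIANTS[model]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    arr = design_arrays(design)
    pdict = model.resolve(**{k: getattr(params, k) for k in model.free})
    p_one = expit(logits(arr, pdict, ratio_phi=model.ratio_phi))
    chose_one = (rng.random(len(p_one)) < p_one).astype(int)
    out = design.copy()
    out["chose_one"] = chose_one
    out["choice"] = np.where(chose_one == 1, "one", "group")
    return out


def mean_choice_prob(design: pd.DataFrame, params: SubjectParams,
                     model: ModelSpec | str = WINNING_MODEL) -> float:
    """Analytic long-run mean of P(choose one) over a design."""
    if isinstance(model, str):
        model = VARIANTS[model]
    arr = design_arrays(design)
    pdict = model.resolve(**{k: getattr(params, k) for k in model.free})
    return float(expit(logits(arr, pdict, ratio_phi=model.ratio_phi)).mean())
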