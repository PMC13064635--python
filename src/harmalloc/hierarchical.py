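"""Hierarchical Bayesian estimation of the harm-allocation model family.

Subject-level parameters are modelled as draws from group distributions on
an unconstrained latent scale and estimated jointly with the group
parameters (partial pooling).  By default the latent scale uses the
noncentered parameterization

    theta_s = T(mu + sigma * z_s),   z_s ~ Normal(0, 1)

with T the inverse-probit for bounded parameters (alpha in (0,1), tau in
(0, 20]) and the identity for unbounded ones (phi, in seconds).  Group
priors are weakly informative: Normal for locations, half-Normal for
scales.  Sampling is adaptive HMC (4 chains x 1,000 kept draws after 1,000
warmup by default), storing the pointwise log-likelihood of every kept
draw for LOO-based model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri
from scipy.stats import norm

from . import _hmc
from .choice_model import (
    ModelSpec,
    VARIANTS,
    WINNING_MODEL,
    design_arrays,
    logit_grads,
    logits,
)

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))

TAU_UPPER = 20.0


class ConvergenceWarning(UserWarning):
    pass


class SamplerError(RuntimeError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Group prior for one parameter.

    transform: 'probit01' (T = Phi), 'probit_scaled' (T = upper * Phi) or
    'identity'.  mu ~ Normal(mu_loc, mu_scale); sigma ~ half-Normal(sigma_scale).
    """

    transform: str
    mu_loc: float = 0.0
    mu_scale: float = 1.0
    sigma_scale: float = 0.5
    upper: float = 1.0

    def to_natural(self, a: np.ndarray) -> np.ndarray:
        if self.transform == "probit01":
            return ndtr(a)
        if self.transform == "probit_scaled":
            return self.upper * ndtr(a)
        return a

    def dnatural(self, a: np.ndarray) -> np.ndarray:
        if self.transform == "probit01":
            return np.exp(-0.5 * a * a) / _SQRT_2PI
        if self.transform == "probit_scaled":
            return self.upper * np.exp(-0.5 * a * a) / _SQRT_2PI
        return np.ones_like(a)


DEFAULT_PRIORS: dict[str, PriorSpec] = {
    "alpha": PriorSpec("probit01", 0.0, 1.0, 0.5),
    "tau": PriorSpec("probit_scaled", 0.0, 1.0, 0.5, upper=TAU_UPPER),
    "phi": PriorSpec("identity", 0.0, 20.0, 10.0),
    "kappa": PriorSpec("identity", 0.0, 1.0, 0.5),
}
#: the agreeability ratio is O(1), unlike the additive threshold in seconds
RATIO_PHI_PRIOR = PriorSpec("identity", 0.0, 2.0, 1.0)


@dataclass(frozen=True)
class FitSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    max_leapfrog: int = 256
    traj_length: float = 6.0
    parameterization: str = "noncentered"  # or "centered"
    fixed_sigma: Mapping[str, float] = field(default_factory=dict)
    rhat_threshold: float = 1.1

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "FitSettings":
        """Reduced profile: 2 chains x (500 warmup + 500 kept)."""
        return cls(chains=2, warmup=500, draws=500, seed=seed, **kw)


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one model on one cohort."""

    model: ModelSpec
    subjects: list
    subject_draws: dict[str, np.ndarray]  # name -> (chains, draws, n_subjects)
    group_draws: dict[str, np.ndarray]  # mu_*/sigma_* -> (chains, draws)
    log_lik: np.ndarray  # (chains, draws, n_obs)
    diagnostics: dict
    settings: FitSettings

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_means(self, param: str) -> np.ndarray:
        """Posterior-mean point estimate per subject."""
        return self.subject_draws[param].mean(axis=(0, 1))

    def to_inference_data(self):
        import arviz as az

        posterior = {k: v for k, v in self.group_draws.items()}
        posterior.update(
            {k: v for k, v in self.subject_draws.items()}
        )
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"choice": self.log_lik},
        )


class _HierarchicalProblem:
    """Unconstrained log posterior and gradient for one model/cohort."""

    def __init__(
        self,
        data: pd.DataFrame,
        model: ModelSpec,
        priors: Mapping[str, PriorSpec],
        parameterization: str,
        fixed_sigma: Mapping[str, float],
    ):
        self.model = model
        self.priors = {k: priors[k] for k in model.free}
        self.parameterization = parameterization
        self.fixed_sigma = dict(fixed_sigma)

        self.subjects = sorted(data["subject"].unique())
        sub_map = {s: i for i, s in enumerate(self.subjects)}
        self.n_sub = len(self.subjects)
        self.sub_idx = data["subject"].map(sub_map).to_numpy()
        self.arrays = design_arrays(data)
        y = data["chose_one"].to_numpy()
        if np.any(pd.isna(y)):
            raise ValueError("missing choices in cohort table")
        self.y = y.astype(float)
        self.n_obs = len(self.y)

        # layout: per free param: mu, [log_sigma], z[n_sub]
        self.slices: dict[str, dict[str, slice | int]] = {}
        pos = 0
        for k in model.free:
            entry: dict = {"mu": pos}
            pos += 1
            if k not in self.fixed_sigma:
                entry["log_sigma"] = pos
                pos += 1
            entry["z"] = slice(pos, pos + self.n_sub)
            pos += self.n_sub
            self.slices[k] = entry
        self.dim = pos

    # -- parameter bookkeeping -------------------------------------------
    def unpack(self, x: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        out = {}
        for k, sl in self.slices.items():
            mu = x[sl["mu"]]
            sigma = (
                self.fixed_sigma[k]
                if "log_sigma" not in sl
                # clipped so extreme warmup proposals stay finite
                else float(np.exp(np.clip(x[sl["log_sigma"]], -30.0, 30.0)))
            )
            z = x[sl["z"]]
            if self.parameterization == "noncentered":
                a = mu + sigma * z
            else:
                a = z  # centered: z-block stores the latent values directly
            out[k] = {"mu": mu, "sigma": sigma, "z": z, "a": a,
                      "natural": self.priors[k].to_natural(a)}
        return out

    def natural_subject_params(self, x: np.ndarray) -> dict[str, np.ndarray]:
        return {k: v["natural"] for k, v in self.unpack(x).items()}

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = np.zeros(self.dim)
        init_mu = {"alpha": 1.5, "tau": -2.0, "phi": 0.0, "kappa": 0.0}
        for k, sl in self.slices.items():
            mu0 = init_mu.get(k, 0.0) + 0.1 * rng.standard_normal()
            x[sl["mu"]] = mu0
            if "log_sigma" in sl:
                x[sl["log_sigma"]] = np.log(0.3) + 0.1 * rng.standard_normal()
            if self.parameterization == "noncentered":
                x[sl["z"]] = 0.1 * rng.standard_normal(self.n_sub)
            else:
                x[sl["z"]] = mu0 + 0.1 * rng.standard_normal(self.n_sub)
        return x

    # -- log posterior ----------------------------------------------------
    def pointwise_loglik(self, x: np.ndarray) -> np.ndarray:
        params = self.natural_subject_params(x)
        full = self.model.resolve(**params)
        per_trial = {
            k: (v[self.sub_idx] if isinstance(v, np.ndarray) else v)
            for k, v in full.items()
        }
        lt = logits(self.arrays, per_trial, ratio_phi=self.model.ratio_phi)
        return -np.logaddexp(0.0, -(2.0 * self.y - 1.0) * lt)

    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros(self.dim)
        state = self.unpack(x)
        full = self.model.resolve(**{k: v["natural"] for k, v in state.items()})
        per_trial = {
            k: (v[self.sub_idx] if isinstance(v, np.ndarray) else v)
            for k, v in full.items()
        }
        lt = logits(self.arrays, per_trial, ratio_phi=self.model.ratio_phi)
        lp = float(np.sum(-np.logaddexp(0.0, -(2.0 * self.y - 1.0) * lt)))
        resid = self.y - expit(lt)  # d loglik / d logit
        grads_nat = logit_grads(self.arrays, per_trial,
                                ratio_phi=self.model.ratio_phi)

        for k, sl in self.slices.items():
            st = state[k]
            prior = self.priors[k]
            g_nat = np.bincount(
                self.sub_idx, weights=resid * grads_nat[k], minlength=self.n_sub
            )
            g_a = g_nat * prior.dnatural(st["a"])
            mu, sigma, z, a = st["mu"], st["sigma"], st["z"], st["a"]

            if self.parameterization == "noncentered":
                # priors: mu ~ N(loc, scale); z ~ N(0,1)
                lp += float(-0.5 * ((mu - prior.mu_loc) / prior.mu_scale) ** 2)
                lp += float(-0.5 * np.sum(z * z))
                grad[sl["mu"]] = g_a.sum() - (mu - prior.mu_loc) / prior.mu_scale**2
                grad[sl["z"]] = g_a * sigma - z
                if "log_sigma" in sl:
                    lp += float(-0.5 * (sigma / prior.sigma_scale) ** 2
                                + np.log(sigma))
                    grad[sl["log_sigma"]] = (
                        np.sum(g_a * z) * sigma
                        - sigma**2 / prior.sigma_scale**2
                        + 1.0
                    )
            else:
                # centered: a_s ~ N(mu, sigma)
                dev = a - mu
                lp += float(-0.5 * ((mu - prior.mu_loc) / prior.mu_scale) ** 2)
                lp += float(
                    -0.5 * np.sum((dev / sigma) ** 2) - self.n_sub * np.log(sigma)
                )
                grad[sl["mu"]] = (
                    np.sum(dev) / sigma**2 - (mu - prior.mu_loc) / prior.mu_scale**2
                )
                grad[sl["z"]] = g_a - dev / sigma**2
                if "log_sigma" in sl:
                    lp += float(-0.5 * (sigma / prior.sigma_scale) ** 2
                                + np.log(sigma))
                    grad[sl["log_sigma"]] = (
                        np.sum(dev**2) / sigma**2
                        - self.n_sub
                        - sigma**2 / prior.sigma_scale**2
                        + 1.0
                    )
        return lp, grad


def _resolve_priors(model: ModelSpec,
                    priors: Mapping[str, PriorSpec] | None) -> dict[str, PriorSpec]:
    base = dict(DEFAULT_PRIORS)
    if model.ratio_phi:
        base["phi"] = RATIO_PHI_PRIOR
    if priors:
        base.update(priors)
    return base


def fit_hierarchical(
    data: pd.DataFrame,
    model: ModelSpec | str = WINNING_MODEL,
    settings: FitSettings | None = None,
    priors: Mapping[str, PriorSpec] | None = None,
) -> PosteriorFit:
    """Fit one model variant to a cohort choice table.

    ``data`` needs columns ``subject, c_one, c_group, n_group, default_cond,
    chose_one``.  Returns a :class:`PosteriorFit`; a split-R-hat above the
    configured threshold raises a :class:`ConvergenceWarning` (never silent).
    """
    if isinstance(model, str):
        model = VARIANTS[model]
    settings = settings or FitSettings()
    if data["subject"].nunique() < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")

    prob = _HierarchicalProblem(
        data, model, _resolve_priors(model, priors),
        settings.parameterization, settings.fixed_sigma,
    )
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    chain_draws, chain_stats = [], []
    for c in range(settings.chains):
        rng = np.random.default_rng(seeds[c])
        x0 = prob.initial_point(rng)
        try:
            draws, stats = _hmc.sample_chain(
                prob.logp_grad,
                x0,
                settings.warmup,
                settings.draws,
                rng,
                target_accept=settings.target_accept,
                max_leapfrog=settings.max_leapfrog,
                traj_length=settings.traj_length,
            )
        except FloatingPointError as err:  # pragma: no cover - defensive
            raise SamplerError(f"chain {c} failed: {err}") from err
        chain_draws.append(draws)
        chain_stats.append(stats)

    # assemble posterior arrays
    n_c, n_d = settings.chains, settings.draws
    subject_draws = {k: np.empty((n_c, n_d, prob.n_sub)) for k in model.free}
    group_draws: dict[str, np.ndarray] = {}
    for k in model.free:
        group_draws[f"mu_{k}"] = np.empty((n_c, n_d))
        group_draws[f"sigma_{k}"] = np.empty((n_c, n_d))
    log_lik = np.empty((n_c, n_d, prob.n_obs))
    for c in range(n_c):
        for d in range(n_d):
            x = chain_draws[c][d]
            state = prob.unpack(x)
            for k in model.free:
                subject_draws[k][c, d] = state[k]["natural"]
                group_draws[f"mu_{k}"][c, d] = float(
                    prob.priors[k].to_natural(np.asarray(state[k]["mu"]))
                )
                group_draws[f"sigma_{k}"][c, d] = state[k]["sigma"]
            log_lik[c, d] = prob.pointwise_loglik(x)

    diagnostics = _diagnose(group_draws, subject_draws, chain_stats, settings)
    fit = PosteriorFit(
        model=model,
        subjects=prob.subjects,
        subject_draws=subject_draws,
        group_draws=group_draws,
        log_lik=log_lik,
        diagnostics=diagnostics,
        settings=settings,
    )
    if diagnostics["max_rhat"] >= settings.rhat_threshold:
        warnings.warn(
            f"split-R-hat {diagnostics['max_rhat']:.3f} exceeds "
            f"{settings.rhat_threshold}; treat estimates with caution",
            ConvergenceWarning,
            stacklevel=2,
        )
    return fit


def _diagnose(group_draws, subject_draws, chain_stats, settings) -> dict:
    import arviz as az

    ds = az.from_dict(posterior=dict(group_draws))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    max_rhat = float(max(rhat[v].values.max() for v in rhat.data_vars))
    min_ess = float(min(ess[v].values.min() for v in ess.data_vars))
    return {
        "max_rhat": max_rhat,
        "min_ess_bulk": min_ess,
        "divergences": int(sum(s.divergences for s in chain_stats)),
        "accept_rate": float(np.mean([s.accept_rate for s in chain_stats])),
        "step_sizes": [s.step_size for s in chain_stats],
        "seed": settings.seed,
        "chains": settings.chains,
        "warmup": settings.warmup,
        "draws": settings.draws,
        "parameterization": settings.parameterization,
    }


def summarize(fit: PosteriorFit) -> pd.DataFrame:
    """Tidy posterior summary.

    Group rows report, per parameter, the posterior mean/SD of the
    transformed group location (``level='group'``) and of the latent group
    scale (``level='group_scale'``), plus the spread of subject point
    estimates (``level='between_subject'``) — the two candidate readings of
    a group-level SD.  Subject rows give per-subject posterior
    means/SDs.
    """
    rows = []
    for k in fit.model.free:
        mu = fit.group_draws[f"mu_{k}"]
        sg = fit.group_draws[f"sigma_{k}"]
        rows.append((k, "group", None, mu.mean(), mu.std(ddof=1)))
        rows.append((k, "group_scale", None, sg.mean(), sg.std(ddof=1)))
        means = fit.subject_means(k)
        rows.append((k, "between_subject", None, means.mean(),
                     means.std(ddof=1) if len(means) > 1 else 0.0))
        per_sub_sd = fit.subject_draws[k].std(axis=(0, 1), ddof=1)
        for s, m, sd in zip(fit.subjects, means, per_sub_sd):
            rows.append((k, "subject", s, m, sd))
    return pd.DataFrame(rows, columns=["parameter", "level", "subject",
                                       "mean", "sd"])


def prior_predictive(
    model: ModelSpec | str = WINNING_MODEL,
    n: int = 1000,
    seed: int = 0,
    priors: Mapping[str, PriorSpec] | None = None,
) -> pd.DataFrame:
    """Draw subject-level natural parameters from the prior (one level of
    subjects under group draws), mainly for prior sanity checks."""
    if isinstance(model, str):
        model = VARIANTS[model]
    pr = _resolve_priors(model, priors)
    rng = np.random.default_rng(seed)
    out = {}
    for k in model.free:
        p = pr[k]
        mu = rng.normal(p.mu_loc, p.mu_scale, n)
        sigma = np.abs(rng.normal(0.0, p.sigma_scale, n))
        a = mu + sigma * rng.standard_normal(n)
        out[k] = p.to_natural(a)
    return pd.DataFrame(out)
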