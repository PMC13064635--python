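# harmalloc

Computational modelling of **harm-allocation moral decisions**: when people
must assign painful cold-pressor time either to a single individual or to
each member of a small group, do they minimize total harm (the utilitarian
strategy) or protect the worst-off individual at the cost of more harm
overall (the Rawlsian *maximin* strategy) — and what latent quantities
govern the trade-off?

The package is written for computational cognitive scientists who want a
fully tested, self-contained re-implementation of this analysis: the task
design, the hierarchical Bayesian choice-model family, leave-one-out model
comparison, parameter-recovery validation, model-free behavioral
statistics, and the intersubject representational similarity analysis
(IS-RSA) that links between-subject similarity in model parameters to
similarity in voxelwise neural responses. Every stage runs on synthetic
data generated in-package, so the whole pipeline is testable offline.

## The model

Each trial offers harm `C_one` seconds to one person versus `C_group`
seconds to each of `N_group` people, constrained so that
`C_group <= C_one <= C_group * N_group`. The winning model scores the
options as

```
U(one)   = -(1-α) C_one        - α (C_one + φ)
U(group) = -(1-α) C_group·N_group - α C_group
ΔU       = U(one) - U(group) = (1-α) Δtotal - α (Δsingle + φ)
P(choose one) = 1 / (1 + e^(-τ·ΔU))
```

with `Δtotal = C_group·N_group - C_one` and `Δsingle = C_one - C_group`.
`α ∈ [0,1]` weights the maximin (Rawlsian) against the utilitarian
consideration, `φ` (seconds) is an *agreeability threshold* — the harm
premium on one person the decider treats as mutually acceptable — and `τ`
is the softmax inverse temperature. Constrained variants (`α` pinned to 0
or 1, `φ` removed, or `φ` as a multiplicative ratio) form the comparison
family. Subject parameters are estimated jointly under group-level
distributions (noncentered parameterization) with an in-package adaptive
HMC sampler using analytic gradients; model comparison uses PSIS-LOO on
trial-level log-likelihoods; IS-RSA regresses dyadic neural similarity
`1/(1+d)` on `φ`-similarity with `α`-similarity as covariate, in an exact
multi-membership random-intercept GLS, with BH-FDR thresholding and
minimum-size cluster extraction. Details and design rationale:
[docs/methods.md](docs/methods.md).

## Worked example

```python
import warnings
from harmalloc.synthetic_data import generate_cohort
from harmalloc.behavior_stats import rawlsian_choice_stats
from harmalloc.hierarchical import fit_hierarchical, FitSettings, summarize
from harmalloc.model_comparison import psis_loo, compare, posterior_predictive

# 12 simulated subjects on a 150-trial design
params, cohort = generate_cohort(n_subjects=12, seed=11)

st = rawlsian_choice_stats(cohort)
print(f"Rawlsian choice proportion: M = {st['mean_prop_group']:.2f} "
      f"(SD = {st['sd_prop_group']:.2f}), t({st['df']}) = {st['t_vs_chance']:.2f}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fits = {m: fit_hierarchical(cohort, model=m,
                                settings=FitSettings.fast(seed=0))
            for m in ("full_constant_phi", "alpha_fixed_0", "no_phi")}

grp = summarize(fits["full_constant_phi"]).query("level == 'group'")
loos = [psis_loo(f, name=m) for m, f in fits.items()]
rows = compare(loos).set_index(["model", "reference"])
ppc = posterior_predictive(fits["full_constant_phi"], cohort)
```

Output (printed by the session this README was written from):

```
Rawlsian choice proportion: M = 0.59 (SD = 0.14), t(11) = 2.31
Extra total harm accepted: 79.7 s per trial (SD = 30.0)
Group posterior means: alpha = 0.96 (SD 0.02), phi = -14.4 s (SD 3.0), tau = 0.102
elpd(alpha_fixed_0) - elpd(full) = -582.0 (SE 22.0)
elpd(no_phi) - elpd(full) = -32.8 (SE 8.2)
Posterior predictive check: r(predicted, observed) = 0.999
```

Reading it: the simulated cohort chooses the group (Rawlsian) option on
59% of trials — significantly above chance — accepting ~80 s of extra
total harm per trial to spare the single individual. The hierarchical fit
recovers a maximin weight near 0.96 with a negative agreeability
threshold, the full three-parameter model predicts held-out trials far
better than the utilitarian-only (`alpha_fixed_0`) or threshold-free
(`no_phi`) variants, and posterior predictions track observed per-subject
choice proportions almost perfectly.

The same pipeline is available from the shell:

```bash
harmalloc --seed 3 --outdir run --fast all   # design → simulate → fit →
                                             # compare → behavior →
                                             # recover → isrsa
```

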