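# Methods

`harmalloc` models choices in an incentivized harm-allocation dilemma:
on each trial a decision-maker assigns painful cold-pressor time either to
a single individual ("the one", `C_one` seconds) or to each member of a
small group ("the group", `C_group` seconds per member, `N_group` members).
The design guarantees `C_group <= C_one <= C_group * N_group`, so the one
option always minimizes total harm (utilitarian) while the group option
always minimizes the largest harm any single person receives (Rawlsian
maximin). This note documents the models, the estimation machinery, the
synthetic data the package tests itself on, and the numerical choices made
where the design was genuinely open.

## Task design

The harm grid is 30–180 s in 10-s steps with group sizes 3 and 4; 246
(C_one, C_group, N_group) triples satisfy the constraint. A session takes
50 unique triples, replicates each under three default conditions (no
default, one-default, group-default — the default is what inaction
implements), and randomizes presentation order and screen side, giving 150
trials. The reference experiment used a fixed, predetermined list of 50
pairs; since that list lives in external task code, `sample_design` draws
the 50 triples uniformly from the valid set under a recorded seed and can
alternatively load an explicit pair list from file. Group size is sampled
jointly with the pair by default; a strict 3/4 alternation schedule is
available via `alternate_group_sizes` because the alternation order of the
original sequence is not recoverable. Trial timing (3 s wait phase, 2.5 s
response window) is carried as metadata only; nothing about timing is
simulated, and the generator always records a response (inaction under a
default is coded as choosing the default option).

## Choice model family

The winning model scores the options

    U(one)   = -(1 - alpha) * C_one          - alpha * (C_one + phi)
    U(group) = -(1 - alpha) * C_group*N_group - alpha * C_group
    dU       = U(one) - U(group) = (1 - alpha) * d_total - alpha * (d_single + phi)

with `d_total = C_group*N_group - C_one` and `d_single = C_one - C_group`,
and passes `dU` through a softmax with inverse temperature `tau`:
`P(choose one) = 1 / (1 + exp(-tau * dU))`. Parameters, with units:

- `alpha` (unitless, [0, 1]): maximin weight. 0 = pure utilitarian
  (choice driven by total harm alone), 1 = pure maximin (choice driven by
  the worst-off comparison alone).
- `phi` (seconds): agreeability threshold — the harm premium on the single
  individual the decider treats as mutually acceptable. Under `alpha = 1`
  the one option is preferred exactly when `d_single < -phi`.
- `tau` (1/utility): softmax steepness; utilities are in seconds, so
  `tau ~ 0.1` makes a 20-s utility gap a ~2-logit preference.

Note on sign conventions: `dU` is the utility of the *one* option relative
to the group option and feeds `P(choose one)`; descriptions of the same
quantity as "the utility of the Rawlsian option" invert the perspective.
The algebra and softmax used here are mutually consistent and asserted as
an identity in the tests.

Variants used for model comparison: `alpha_fixed_1` and `alpha_fixed_0`
(the weight pinned to each extreme; under `alpha = 0` the agreeability
term vanishes, so that variant frees only `tau`), `no_phi` (threshold
pinned to 0), and `ratio_phi`, in which the agreeable harm to the one is a
*multiple* of the group member's harm: `dU = (1-alpha)*d_total -
alpha*(C_one - phi*C_group)`. The ratio form is a reconstruction — only
its verbal description is available — chosen so that `phi_ratio = 1`
reproduces the constant-threshold model at `phi_const = 0` (asserted in
tests). A `default_bias_ext` variant adds a stickiness bonus `kappa`
toward the default option on the logit scale; it is an extension beyond
the compared family, motivated by the observed default effect. Ties
(`dU = 0`) get probability exactly 0.5.

## Hierarchical estimation

Subject parameters are partial-pooled through group distributions on an
unconstrained latent scale: `theta_s = T(mu + sigma * z_s)` with
`z_s ~ N(0,1)` (noncentered; a centered option exists and is checked for
agreement on well-identified data). `T` is the inverse probit for `alpha`
(range (0,1)) and for `tau` (scaled to (0, 20]), and the identity for
`phi`. Priors are weakly informative, following the conventions of the
hBayesDM family of hierarchical choice-model packages: latent group means
`N(0,1)` (except `phi`, modelled on the raw seconds scale with mean
`N(0, 20)`), group scales half-normal (0.5 for probit-scale parameters,
10 s for `phi`, and `N(0,2)`/half-N(1) for the O(1) ratio threshold). All
priors are configurable per parameter; the exact priors of the reference
analysis are not public.

Because no Stan/PyMC-class probabilistic-programming backend is part of
this package's dependency set, sampling is done by an in-package adaptive
Hamiltonian Monte Carlo sampler with analytic gradients (the likelihood is
Bernoulli-logit in quantities linear in the parameters, so gradients are
exact and cheap). Warmup uses dual-averaging step-size adaptation
targeting 0.8 acceptance and windowed diagonal mass-matrix estimation;
trajectory lengths are jittered (about 6 mass-standardized units,
at most 128 leapfrog steps) to avoid resonance. Defaults are 4 chains
with 1,000 warmup and 1,000 kept draws each; the fast profile used in
tests is 2 x (500 + 500). Gradients are verified against finite
differences in the test suite for every variant and both
parameterizations. Convergence is summarized by split-R-hat and bulk ESS
(via arviz) over the group-level draws; R-hat >= 1.1 raises a visible
`ConvergenceWarning`, never a silent pass. Pointwise per-trial
log-likelihoods are stored for every kept draw.

## Model comparison and posterior predictive checks

PSIS-LOO (via `arviz.loo`) operates on the stored trial-level
log-likelihood matrix; the pointwise unit is one trial, which is the
natural grain of the hierarchical likelihood. `LOOIC = -2 * elpd_loo`
exactly. Pairwise contrasts report `elpd(a) - elpd(b)` with the paired
standard error `sd(pointwise difference) * sqrt(n)`; ordered pairs are
always explicit, so the sign convention is unambiguous. Posterior
predictive checks average the per-trial choice probabilities over a
thinned subset of posterior draws — the analytic expectation of simulated
Bernoulli draws, with zero simulation variance — and report each subject's
predicted vs. observed proportion of group (Rawlsian) choices and their
Pearson correlation. Observed proportion sets with zero variance yield an
explicitly undefined correlation.

## Synthetic cohorts and what they do (not) emulate

`GroupParams` fixes the study conditions for simulation and recovery:

- `alpha = expit(Normal(logit(0.95), 1.0))` — concentrated near the
  reference group estimate of 0.95, with most subjects above 0.85 and a
  tail toward more utilitarian mixtures;
- `phi ~ Normal(-10.03, 12.0)` s — centered on the reference group
  estimate; the spread was set from a Fisher-information calculation on
  the task grid (per-subject SE of `phi` is about 6 s at typical
  parameters), which implies that wide, sign-varying individual variation
  in this parameter requires a between-subject SD on the order of 10 s.
  A group-level SD of 2.85 is read here as the posterior uncertainty of
  the group mean, not the between-subject spread; `summarize` reports
  both quantities so either reading is checkable.
- `tau ~ LogNormal(log 0.1, 0.3)` — choices are value-driven but
  stochastic; at these utilities (tens to hundreds of seconds) this
  reproduces realistic choice consistency.

Simulated cohorts reproduce the qualitative behavioral signature of the
task (majority Rawlsian choice, extra total harm accepted on the order of
a minute per trial pair). They do not emulate response times, learning or
fatigue across trials, non-response, or any default-stickiness beyond
what the generating model contains — so passing tests certify the
pipeline's statistical machinery on data that satisfies the model's own
assumptions, not robustness to real-data violations of them.

Parameter recovery draws truths from these distributions, simulates one
session per subject, refits, and correlates posterior-mean estimates with
truths. On this design, recovery of `alpha` is strong (r near 0.9 at the
full 68-subject scale) and recovery of `phi` is bounded by per-subject
identifiability at roughly r 0.8 under these conditions; hierarchical
estimates beat independent per-subject maximum likelihood on both
parameters, so these figures reflect the information in 150 trials rather
than estimator quality. Recovery on truths taken from *fitted* subject
estimates (a common alternative) is systematically easier, because fitted
estimates are shrunken toward well-identified configurations; the package
deliberately uses distribution-drawn truths, which is the stricter test.
The fast profile for continuous testing is 16 subjects, 2 chains x
(500 + 500); the acceptance script runs 68 subjects, 4 chains x
(500 + 500).

## Beta maps and IS-RSA

Synthetic "beta maps" stand in for per-subject voxelwise parametric
responses to the harm assigned to the worst-off individual; they are
generated directly with the semantics the dyadic analysis assumes (no
hemodynamics, no GLM on time series; files are labelled synthetic).
Default geometry is a 20x20x20 grid with one 5x5x5 planted region whose
voxels respond as `slope * weight(voxel) * phi_subject` plus Gaussian
noise (weight tapers from 1 at the plant center to 0.5 at its edge), and
independent noise voxels elsewhere. By construction, subjects with closer
`phi` have more similar planted-region responses.

The IS-RSA stage converts any per-subject measure to pairwise similarity
`1/(1 + Euclidean distance)` (absolute difference for scalars), giving
values in (0, 1]. Per voxel, the n(n-1)/2 dyadic neural similarities are
regressed on `phi`-similarity with `alpha`-similarity as a covariate, in
a mixed model with participant random intercepts. Because each pair loads
on two subjects, the random-intercept design is multi-membership: one
shared variance component, dyad covariance `sigma_u^2 (Z Z')` with `Z`
the dyad-membership matrix. The model is estimated exactly by REML: `Z Z'`
is fixed across voxels, so a single eigendecomposition reduces each voxel
to a 1-D profile optimization over the variance ratio — this makes
whole-volume maps cheap (roughly a millisecond per voxel) while agreeing
with a general mixed-model solver (statsmodels `MixedLM` with variance
components) to numerical precision, which the tests verify. Inference on
the `phi`-similarity coefficient is a normal-approximation Wald test by
default; a subject-level permutation test (shuffle `phi`, rebuild the
similarity matrix, refit) is available for small cohorts. Behavioral
values enter the distance on their raw scale by default, matching the
similarity formula above; a z-scoring switch exists because either
convention is defensible. Voxels whose neural similarities are
constant are flagged undefined rather than failing the run.

Voxelwise p-values are Benjamini-Hochberg corrected with survivors at
q < 0.05; surviving voxels are grouped into connected components with
face (6-) connectivity — the most conservative common convention,
configurable to 18 or 26 — and clusters below 5 voxels are discarded.
On the default synthetic geometry the planted region is recovered as a
surviving cluster and null voxels show approximately nominal
false-positive rates (checked against binomial error in the tests).

## Behavioral statistics

The Rawlsian choice summary reports each subject's proportion of group
choices, the cohort mean/SD and a one-sample t-test against 0.5, and the
mean extra total harm accepted per trial (`d_total` on group-choice
trials, 0 otherwise). Default effects are tested with a one-way
repeated-measures ANOVA over the three default conditions with
Greenhouse-Geisser correction (the correction yielding fractional
corrected dfs; epsilon is reported), plus paired t-tests between conditions
and between the two switching probabilities (the probability of actively
overriding a default, defined only for the two default conditions).
Degenerate inputs (zero variance anywhere in the decomposition) fall back
to a direct sum-of-squares computation with the F reported as 0 or
infinity and no sphericity correction, rather than erroring. Non-response
trials are included as default choices (the task implements the default
on inaction); a filter flag exposes the alternative reading.

## Known limitations

- The exact 50-pair list, the reference priors, and the full roster of
  alternative models are not public; stand-ins are documented above and
  exposed as configuration.
- Recovery correlations depend materially on the assumed between-subject
  truth spread; the frozen defaults are a principled reconstruction, not
  a recorded set of simulation settings.
- The HMC sampler is a static-trajectory implementation, not NUTS; on
  strongly funnel-shaped posteriors (very small cohorts, extreme
  parameters) occasional chains can mix poorly — diagnostics surface this
  rather than hiding it, and the noncentered default mitigates it.
- IS-RSA operates on scalar per-voxel similarities, not searchlight
  pattern similarity, and no anatomical labelling or registration is
  attempted.
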