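# Methods

This note documents the models, estimators and synthetic-data generators
implemented in `strifun`, the numerical choices behind them, and what the
package's tests do and do not establish about real data.

## Task model

The task is a restless two-armed bandit with two interleaved contexts: two
slot machines (red/blue), each offering a hand and a foot response.  On
half the trials (abort trials) the trial is cancelled before the go cue;
on the other half the subject responds and receives binary feedback.  The
reward probability of each (stimulus, action) pair follows a bounded
Gaussian random walk:

    p_{t+1} = p_t + N(0, sigma_step),    p_1 ~ U(0.15, 0.85),

with walks confined to [0.15, 0.85], walk means constrained to
[0.4, 0.6], and an optional cap on the absolute pairwise correlation of
the four walks (0.38 reproduces the realized value reported for the
original schedule).  `sigma_step` defaults to an SD of 0.01; the notation
N(0, 0.01) is ambiguous between SD and variance, and an SD of 0.1 would
contradict the stated slow drift, so SD is the default and
`step_is_variance=True` selects the other reading.  At the boundaries the
per-trial increment is redrawn until the walk stays inside; this preserves
the per-step Gaussian away from the bounds.  Trial order is a uniform
random shuffle of 128 copies of each of the four (stimulus, kind) types,
rejected until no type occurs more than 3 times in a row; rejection over
uniform shuffles yields a uniform draw from the admissible arrangements.

One walk set serves a whole cohort per session, but the assignment of walk
pairs to slot machines and of walks within a pair to actions is
re-randomized per subject (`RewardWalkSet.with_assignment`).  This matches
reward availability and volatility across subjects while decorrelating the
environment realization, which matters for hierarchical fitting (below).

## Learning model family

The base learner is Q-learning over the four (stimulus, action) values,
initialized at 0.5 (the neutral point between the 0/1 outcomes and the
fixed point of the decay extension):

    delta_t = r_t - Q(s, a);   Q(s, a) <- Q(s, a) + alpha * delta_t,

with softmax action selection with inverse temperature beta.  Five
optional extensions, each toggled independently: a separate learning rate
for r = 0 feedback (`neg_alpha`); an additive utility offset toward the
hand response (`effector_bias`); a lapse parameter eps in (0, 0.5)
compressing choice probabilities into [eps, 1-eps]; geometric decay of all
unchosen values toward 0.5 with per-trial rate d (on trials without a
response all four values decay); and a perseverance bonus kappa added to
the utility of the action last taken for the same stimulus.  Bias and
perseverance enter the softmax additively rather than scaled by beta so
their magnitudes are comparable across subjects.  Missed trials are
excluded from the likelihood and contribute decay only.

The session likelihood is a sequential replay of the recorded choices; it
is implemented twice — once over the public per-trial operations, and once
as a numba-compiled kernel used by the fitting code — and the two routes
are held to 1e-10 agreement in the test suite.  The kernel uses the
numerically stable logistic (the exponential argument is kept
non-positive), floors choice probabilities at 1e-300, and the
beta = exp(x) transform clips the exponent at +-50.

## Hierarchical fitting

Parameters are fitted in an unconstrained space (logit for rates and
decay, a (0, 0.5)-scaled logit for the lapse, log for beta, identity for
signed offsets) under a diagonal Gaussian population prior.  The EM
E-step first locates each subject's MAP by L-BFGS-B (3 restarts jittered
from the prior on the first iteration, warm starts afterwards) with a
central-difference Hessian at the optimum.  The default E-step then
estimates each subject's posterior mean and variance by importance
sampling: 2000 Student-t(5) draws around the MAP, scaled by the Cholesky
factor of twice the Laplace covariance, with the draws fixed per subject
across iterations (common random numbers) so the EM map is deterministic
and its convergence criterion (max |delta mu| < 1e-3) is well defined.

The mode-based E-step (`e_step="laplace"`, the form used in the EM
literature this family of fits descends from) is retained, but parameter
recovery on simulated cohorts showed why posterior moments are the
default: at ~500 choices per subject the alpha/beta likelihood surface is
skewed, the posterior mode sits in the tail, the inverse Hessian
overstates precision, and the population estimates drift along a nearly
flat ridge of the marginal likelihood toward low learning rates with a
collapsing population variance.  The sampling E-step removes the
mode-vs-mean bias, and a weakly-informative inverse-gamma(2, 1)
hyperprior on each population variance (posterior-mode M-step update)
prevents the few-groups variance collapse; with 24 subjects its pull is
O(1/n) when the data are informative.  Model-comparison fits use the
mode-based E-step: both candidate models are fitted and scored
identically, and the iBIC ranking is not sensitive to the E-step choice,
while the runtime difference is large.

Model comparison uses a Monte-Carlo integrated BIC: for each
subject-session, parameter vectors are drawn from the fitted population
prior, the log marginal likelihood is estimated as the log mean likelihood
(log-sum-exp stabilized), and

    iBIC = -2 * sum log p(choices) + M * log(N_choices),

with M = 2 population-level parameters (mean and variance) per active
model parameter and N_choices the total recorded choices.  Both sessions
of a subject share one parameter vector; the marginal likelihood is
estimated per session and summed.

## Synthetic neuroimaging cohorts

The generator stands in for tractography and fMRI GLM outputs.  All
subjects share one voxel lattice — a connected blob grown by uniform
random accretion, emulating a striatal region of interest — which makes
"native" and "group" space coincide and removes registration from scope.
Connectivity: each cortical target has a cohort-level archetype field (a
mixture of 3 Gaussian bumps, length scale 3 voxels, column means scaled
to a lognormal multiple of 50 expected streamlines — a per-target share
of the 10k streamlines seeded per voxel in the emulated protocol); a
subject's counts are Poisson draws around the archetype scaled by
per-target mean-one lognormal jitter (SD 0.3).  Two targets default to
all-zero columns, emulating parcels absent in some subjects.  Contrast
maps are the generative converse of the regression being tested:

    y = lambda_c * z(C_z w) + lambda_g * z(g) + N(0, noise_sd),

with w the planted target weights, g a group-consistent smooth map, and
optional lattice-domain Gaussian smoothing (FWHM 4 voxels = 6 mm at
1.5 mm) applied last.  Cohort defaults (24 subjects, 500 voxels, 148
targets, 3 contrasts, lambda_c = 1, lambda_g = 0.5, noise_sd = 0.3)
mirror the emulated study's scale.  The distributional forms are
declared, not inferred from data: only nonnegativity, the count scale,
spatial smoothness and cross-subject consistency matter downstream.

What the generator does not emulate: registration and segmentation error,
distance- and curvature-dependent tractography bias, spatially
autocorrelated (rather than white-then-smoothed) GLM noise, and any
coupling between a subject's behavioral parameters and their anatomy.
Passing recovery tests therefore demonstrates the estimators are correct
and well calibrated under the declared generative family, not that the
original tissue-level effects are reproducible.

## Structure-function regression

Per subject, the design matrix is an intercept plus the column-z-scored
streamline counts (z-scoring uses the population-SD convention, divisor
n; all-zero columns stay zero and contribute nothing; rank-deficient
designs take the minimum-norm least-squares solution).  Under
leave-one-out cross-validation the training subjects' weight vectors are
averaged unweighted — every participant counts equally regardless of
voxel count — and applied to the held-out design; accuracy is the Pearson
correlation between z-scored prediction and z-scored observed map (mean
absolute error is also recorded).  A 4-fold variant averages weights over
training folds.  The group-average benchmark predicts a held-out subject
by the z-scored mean of the training subjects' z-scored maps.

Unique and shared variance are separated by semipartial correlation:
orthogonalize one prediction on the other (simple regression with
intercept), correlate the residuals with the observed map, and square;
the two-predictor regression R^2 is the total, and shared = total minus
the two unique components (asserted to 1e-10 on every call; shared may be
negative under suppression).  Group-level inference is a two-tailed
one-sample t-test of the per-subject correlations against zero (raw r by
default, Fisher-z behind a flag).

A calibration fact, established in the test suite and worth knowing when
interpreting output: under a global null (no planted link, no
group-consistent component) the t-test on the *full* cross-validated
correlations is anti-conservative by construction — held-out subjects
share training data, the pair (i, j) contributes the same noise overlap
to r_i and r_j, and the variance of the mean r is about twice what the
t-test assumes (~17% type-I at alpha = 0.05, reproduced by an idealized
shared-design simulation).  The *orthogonalized* correlations do not
inherit this coupling: regressing the connectivity prediction on the
group-average prediction removes the shared training-noise component, and
their t-test is calibrated.  Null-calibration checks in this package
therefore score the orthogonalized connectivity correlations, which is
also the quantity that carries the unique-variance claim.

## Behavioral summary statistics

Percent missed is relative to response trials; percent rewarded to
answered trials.  Reaction-time statistics are computed only when an
``rt`` column is supplied (real data; the simulator does not model RT).
The paired effect size is reconstructed from summary statistics as
d = mean / (sqrt(n) * halfwidth / t_{1-alpha/2, n-1}), which inverts a
reported confidence interval into the paired SD.

## Problem sizes used by the shipped studies

Parameter recovery: median over 3 replicate cohorts of 24 subjects x 2
sessions x 512 trials (fresh walk environments per cohort; a single
cohort sees only two environments, whose realization noise dominates the
cohort-level error).  Model recovery: 10 replicate cohorts in the test
suite and 6 in the acceptance script, iBIC with 20k samples per session.
Structure-function recovery: one planted cohort at the default scale;
null calibration: 20 full-scale link-free cohorts plus 200 reduced
cohorts (12 subjects, 120 voxels, 30 targets) for the type-I rate.

## Known limitations

* With ~500 choices per subject the population mean of the learning rates
  is weakly identified for unlucky walk realizations; single-cohort
  recovery errors of 0.1-0.15 in alpha occur even though the fitter is at
  the marginal-likelihood optimum.  Replicate-cohort medians are the
  meaningful recovery measure.
* EM convergence along near-flat ridges is slow; fits returned with
  ``converged=False`` at ``max_iter`` are typically within the ridge
  region and their subject-level estimates are stable, but the reported
  population mean can still be drifting slowly.
* The exact functional forms of perseverance, effector bias and decay are
  conventions (stated above) isolated behind ``ModelSpec``; alternative
  forms can be swapped without touching the fitting machinery.
* iBIC depends on the declared penalty sample size (total recorded
  choices); other conventions shift all models by a constant only when
  parameter counts match, so rankings between models of different size
  depend on this choice.
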