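# Methods

This note records the models, numerical choices and limitations behind the
package, in the order the pipeline runs them.

## First-level model

Each subject's response vector `y` (n scans) is modelled as

    y = X b + e,    e ~ N(0, exp(-lam) I)

with prior `b ~ N(0, sigma_W^2 I)` (default `sigma_W^2 = 1`, matching the
unit-variance prior conventionally placed on condition-specific neural
effects) and a Gaussian prior on the noise log-precision `lam`. Inference is
mean-field variational Bayes: a conjugate Gaussian update of `q(b)` given the
expected noise precision `E[e^lam]`, alternated with a Gauss–Newton update of
`q(lam)` (Gaussian, variance from the curvature), until the free energy F
changes by less than `tol` (default 1e-4 nats, max 64 sweeps). The updates
solve the exact stationary conditions of F within each factor, so F is
non-decreasing up to inner-loop tolerance. Fits are deterministic: both
factors start at their prior means.

Two properties anchor correctness. With the noise precision clamped
(`noise_prior.variance = 0`) the model is exactly linear-Gaussian, the bound
is tight, and F equals the closed-form log marginal likelihood
(`log_evidence_linear_gaussian`); the test suite verifies agreement to
~1e-13 nats. With free noise, coefficient recovery and noise-variance
recovery are verified by simulation.

**Noise hyperprior.** The default prior on `lam` is the weakly-informative
N(0, 16): an SD of 4 log-units spans noise precisions from ~3e-4 to ~3e3,
so the posterior is data-dominated at any realistic noise level (n = 155
scans contribute likelihood precision ~n/2). A tight noise hyperprior is
deliberately avoided: when it conflicts with the data scale it biases the
residual-variance estimate and thereby corrupts the group-level partition
into within- and between-subject variance.

## Bayesian model reduction

For a likelihood that is Gaussian in the parameters, the full fit determines
the likelihood exactly through its curvature `A = qP - pP` and linear term
`b = qP qE - pP pE` (precisions `P = C^{-1}`, prior `(pE, pC)`, posterior
`(qE, qC)`). Any reduced prior `(rE, rC)` over retained parameters, with a
subset fixed at the prior mean (the zero-prior-variance limit), then yields
the reduced posterior and the evidence change in closed form:

    sP = A_RR + rP
    sE = sP^{-1} (b_R - A_RS f_S + rP rE)
    dF = 1/2 [ln det rP - ln det sP - ln det pP + ln det qP]
       + 1/2 [sE' sP sE - rE' rP rE - qE' qP qE + pE' pP pE]
       + b_S' f_S - 1/2 f_S' A_SS f_S

where R/S index retained/switched-off parameters and `f_S` the fixed values.
Switched-off parameters are removed exactly in precision coordinates — no
large-precision surrogate — so `dF(full -> full) = 0` identically and
reductions compose (off {a} then {b} equals off {a,b}, verified to 1e-8).
Against the analytic evidence of refitted reduced designs the worst error
over 100 random linear-Gaussian instances is below 1e-6 nats.

## Group level: parametric empirical Bayes

Subject parameter densities are summarized by the hierarchical GLM

    theta_i = beta + eps_i,  eps_i ~ N(0, Pi_b^{-1}),  Pi_b = Q0 + e^{-gamma} Q1

with the group-mean design `X = 1_N (x) I_M` (the only between-subject effect
modelled is the group mean). Priors: `beta` inherits the first-level prior;
`gamma ~ N(0, 1/16)`, encoding the expectation that between-subject variance
is ~16 times smaller than the unit within-subject prior. Defaults
`Q1 = 16 I` (so gamma = 0 corresponds to between-subject variance 1/16) and
`Q0 = I/128` as a precision floor; both configurable. A single scalar gamma
is shared by all parameters.

Because each subject's likelihood is recovered exactly from its fit via the
BMR identity, the conditional evidence `ln p(Y | gamma)` and the conditional
posterior over beta are available in closed form — subject posterior
*covariances*, not just means, enter the computation, so noisy subjects are
automatically down-weighted. gamma is optimized by Gauss–Newton with
step-halving from gamma = 0 (tolerance 1e-4 on the step and the objective),
and then *marginalized by quadrature* on a 21-node grid spanning ±5 Laplace
SDs around the mode: the reported beta posterior is the moment-matched
mixture over the gamma grid, and the free energy is the trapezoid-integrated
marginal evidence. Conditioning on the gamma mode alone understates
hyperparameter uncertainty; with the quadrature treatment a well-specified
simulation (effects and gamma drawn from the model's own priors, noise
clamped or free) gives 89.8% coverage for nominal 90% credible intervals
(600 component checks), i.e. the implementation is calibrated.

With gamma clamped the beta posterior provably equals the posterior of the
collapsed single-level model `y_i = X beta + X eps_i + noise` (verified to
machine precision), which fixes the free-energy bookkeeping without relying
on any particular published expression.

**Empirical Bayes update.** After a common architecture is chosen, each
subject is re-evaluated (analytically, via BMR) under the group posterior
predictive prior `N(beta_hat, Pi_b^{-1} + Cov(beta_hat))`; parameters pruned
at the group level stay switched off. Re-fitting the group model to the
updated subjects under the original beta prior reproduces the same group
posterior (fixed point, verified to 1e-3).

## Model spaces and pruning

- `greedy_prune`: backward elimination; each pass removes the parameter whose
  switch-off *most increases* the group evidence, while any increase remains
  (threshold 0 by default; ties break by label order). This is deliberately
  stricter than the comparison-space rule: pruning fixes one architecture,
  so only strictly redundant parameters may go.
- `build_comparison_space`: breadth-first walk of the elimination lattice,
  retaining any model whose cumulative log evidence stays strictly above
  -3 nats relative to the full model (~20-fold odds), deduplicated, capped at
  `max_models = 64` (highest-evidence models kept). The "search with
  replacement" is realized as a subset-lattice walk — the only reading that
  yields a well-defined finite model set.
- `enumerate_submodels`: the full 2^p on/off lattice (minus the all-off
  model by default), refused above p = 16.

Scoring applies BMR per model and softmaxes the log evidences under flat
model priors. The group-level beta prior is the canonical (zero-mean)
first-level prior even after the empirical-Bayes update, so "switched off"
always means *fixed at zero* and every dataset is scored against the same
null hypotheses.

## The three measures and their reporting

Measures (a) and (b) are reported relative to the minimum (the worst
dataset, which is set to zero); measure (c) is absolute because its natural
reference is the flat model prior (0 nats) and its ceiling `ln k`. Pairwise
dataset contrasts use the two-way softmax `100 e^d / (1 + e^d)` and the
Kass–Raftery bins ([0, 1.1) inconclusive, [1.1, 3) positive, [3, 5) strong,
[5, inf) very strong; boundary values fall upward). Differences below 1.1
nats are labelled "inconclusive" — no stronger claim is conventional there.

The comparison space is built once from the *pooled* group model and reused
for every dataset, so all datasets face identical hypotheses and none is
favored by defining the space. Datasets must contribute the same subjects
under the same model structure (a repeated-measures design); unequal designs
are rejected rather than reweighted.

## Validation simulation

The generator emulates a repeated-measures SNR study: for experiment i,
subject j, noise level k,

    y_ijk = X b_ij + e_ijk,   b_ij ~ N([0.89, 0.89, 0.45], 0.18 I)

Group effects: two strong condition effects (0.89) and one half-sized
novelty effect (0.45); between-subject variance 0.18; within-subject prior
variance 1; i.i.d. Gaussian noise scaled per subject so the realized
modelled-signal-to-noise variance ratio exactly hits each dataset's target
on the grid 0.003 to 0.498 in steps of 0.005 (100 levels); 16 subjects per
experiment; 100 experiments by default. A subject's true effects are shared
across noise levels within an experiment (only the noise differs).

The design matrix is three interleaved boxcar regressors over 155 scans
(block length 3 scans, two-block gaps, conditions rotating through a 27-scan
cycle), convolved with a fixed exponential decay kernel (time constant one
block) as a crude sustained-response filter, and scaled to unit column norm;
maximum pairwise column correlation 0.33. Seeds derive from
`SeedSequence(master_seed, spawn_key=(experiment, dataset, subject))`, so
any slice regenerates independently and sweeps are byte-reproducible.

What the generator does *not* emulate: temporal autocorrelation,
physiological fluctuations, acquisition-specific noise structure, or
nonlinear observation models. Passing tests therefore demonstrate that the
measures track information content under idealized white-noise conditions,
not that they rank real acquisition protocols correctly.

**Problem sizes.** The routinely-run validation uses the scaled-down sweep
(10 experiments x 20 SNR levels x 16 subjects) and 200-replicate coverage
runs; the full 100 x 100 sweep is available behind
`SimulationConfig()` defaults / `bdc simulate` without `--reduced`.

**Observed behavior and two known shortfalls.** Certainty and parameter
information gain rise monotonically with SNR (Spearman rho ≈ 0.92–0.95
across experiment means); model information gain rises from ~0.6 nats at
SNR 0.003 to a plateau of ~1.9 nats (> 90% of ln 7), and at the lowest SNRs
the posterior mass concentrates on the full model and the model lacking the
small 0.45 effect. Two caveats, both analyzed rather than tuned away:

1. Model information gain saturates by roughly SNR 0.03 under this design
   (per-subject information scales as `n_scans * snr / ||beta||^2`), so over
   the long plateau its across-experiment means are rank-noise; its grid-wide
   Spearman rho is ~0.7–0.8, not > 0.9, although the curve is monotone from
   the noisiest dataset to the plateau.
2. At high SNR, 90% group credible intervals cover the generating means in
   ~83% of replicates, not ~90%. This is a prior-data conflict inherent to
   the study conditions: the gamma hyperprior N(0, 1/16) encodes
   between-subject variance 1/16 ≈ 0.06, while the generating variance is
   0.18; with 16 subjects the posterior between-subject variance shrinks to
   ~0.115 and intervals narrow accordingly. Under data drawn from the
   model's own priors coverage is nominal (89.8%), so this is a property of
   the conditions, not a defect of the estimator.

## Numerical policies

- All information quantities in nats; no bits option.
- Cholesky factorizations add at most `1e-8 * mean-diagonal` jitter before
  failing loudly; posteriors whose covariance condition number exceeds 1e12
  raise a degenerate-posterior error naming the offending parameters.
- Softmaxes are log-sum-exp stabilized; the pairwise (two-way) softmax is
  the canonical nats-to-probability mapping.
- Gamma optimization uses central finite differences (h = 1e-3) on the
  scalar conditional evidence; steps are clipped to ±4 log-units and halved
  until the objective does not decrease.
- Fit containers are JSON with explicit dimensions and row-major covariance
  flattening; reads validate symmetry, positive semi-definiteness and the
  format version.

## Limitations

- Single between-subject effect (the group mean); covariate designs at the
  second level are out of scope.
- One shared variance scale gamma across parameters; per-parameter random
  effects precisions are not modelled.
- First-level noise is a single i.i.d. component (pre-whitened data
  assumed); no AR modelling.
- The automated comparison space can collapse to the full model alone when
  every parameter is strongly supported — model-level comparison is then
  uninformative by construction, and the enumerated lattice (`space="full"`)
  is the appropriate choice for small parameter sets.
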