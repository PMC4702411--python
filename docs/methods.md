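# Methods

## The model

`kinclust` classifies irregularly sampled biomarker trajectories — the
motivating application is total hCG measured repeatedly during the first 21
days after curettage of a hydatidiform mole — into `G` latent groups, each
defined by a *typical trajectory* from a mechanistic model, and evaluates the
resulting hard classification as a diagnostic test for gestational
trophoblastic neoplasia (GTN).

### Mean model: two-compartment kinetics

hCG enters plasma (compartment 1) as a bolus of size `mu10`, exchanges with
tissues (compartment 2) and is eliminated from plasma; residual trophoblastic
tissue may keep producing hormone:

    d mu1/dt = -(k12 + k10) mu1 + k21 mu2 + r(t)
    d mu2/dt =   k12 mu1 - k21 mu2,            mu2(0) = 0

with `r(t) = 0`, `r(t) = A` (constant production) or `r(t) = A*t` (production
growing with tumor size).  Units: rates `k12, k21, k10` in /day, `mu10` in
IU/L, `A` in IU/L/day (constant) or IU/L/day^2 (linear).  Biology motivates
the cross-group constraints: exchange and elimination reflect normal
physiology, so `k12, k21, k10` are shared by all groups; GTN acts only
through production and initial level, so `mu10_g` and `A_g` are
group-specific, with `A = 0` pinned in the group with the lowest trajectory
level (assumed disease-free).  The non-biological competitor
`mu1(t) = c exp(a t) + c2 exp(a2 t)` carries four unconstrained coefficients
per group.

Because the system is linear with constant coefficients, its solution is a
sum of two exponentials (eigenvalues of the transfer matrix) plus a
polynomial particular term (the steady state `A/k10` for constant production;
an affine-in-`t` term for linear production).  The analytic solution is used
inside the likelihood — the M-step evaluates `mu1` thousands of times — and
the LSODA numeric path (absolute tolerance 1e-6) is retained for the
degenerate cases (repeated eigenvalues, `k21*k10 = 0` with production) and as
an independent cross-check; the test suite enforces agreement below 1e-5
relative over random parameter draws.  When checking agreement the numeric
side runs at `atol=1e-12, rtol=1e-10`: trajectories with fast elimination
decay to ~1e-7 IU/L by day 21, below what an absolute tolerance of 1e-6 can
resolve on a relative scale.

### Error model and classification likelihood

Measurements are modeled on the natural-log scale:
`Y_ij ~ N(ln mu1g(t_ij), sigma_g^2)`, independent within a subject given the
group ("shared" variance ties `sigma_g^2` across groups).  With hard
memberships `z_ig` and mixing weights `pi_g`, the fit maximizes the
classification log-likelihood

    l_c = sum_i sum_g z_ig [ log pi_g + log f_g(Y_i) ].

### The CEM algorithm

Each iteration: E-step (posterior memberships by Bayes), C-step (argmax
assignment; ties to the lowest label), M-step (maximum likelihood given the
assignment).  Iterations stop when the relative change of `l_c` is at most
1e-6 (safety cap 500 iterations).  Initialization uses the stochastic (SEM)
variant — the C-step replaced by one multinomial draw per subject — run for
100 iterations from a uniformly random partition; the parameters and
assignment of the iteration with the highest `l_c` seed the CEM pass.
After every M-step, groups are relabeled in ascending order of mean
predicted log-hCG over the fixed grid t = 0, 1, ..., 21 days; this single
statistic defines both "lowest group" (where `A = 0` binds) and "highest
group" (the disease-positive class).

### The M-step

Given assignments, `pi_g = n_g/N` and the mean parameters minimize the
residual sum of squares of `Y_ij - ln mu1g(t_ij)`.  The shared-kinetics
constraint makes the compartment M-step one joint nonlinear least-squares
problem over all subjects; the bi-exponential groups are independent
problems.  Numerical choices:

* damped least squares (Levenberg–Marquardt, tolerance 1e-6) rather than a
  raw Gauss–Newton step;
* positivity of kinetic parameters by optimizing their logarithms — no
  clipping or bound constraints; `A = 0` is structural (the lowest group has
  no production parameter);
* warm starts from the previous iteration's parameters; the first M-step of
  a chain uses method-of-moments heuristics (`mu10_g` from the mean log
  value at each subject's earliest time, rates at 0.5/day, `A_g` from the
  steady-state moment `k10 * exp(mean late log value)`);
* variance estimates are maximum likelihood (`RSS/m`, not bias-corrected);
  with per-group variances the joint compartment problem is solved by two
  iteratively reweighted passes, since groups then enter the likelihood with
  different precisions (exact ML in the shared and bi-exponential cases);
* a bi-exponential mean that turns non-positive is an infeasible point: its
  log-density is -inf in the E-step, and the M-step objective adds a smooth
  penalty growing with the violation.

### Degenerate states and restarts

A hard C-step can empty a group (typically when SEM hands over a
near-duplicate group holding one or two subjects).  The policy: the chain is
abandoned and a fresh SEM chain started, up to `n_restarts` attempts
(default 1; the simulation harness and acceptance runs use 8).  Because
`l_c` has many local optima, the fit can also be asked to collect
`best_of` successful chains and return the one with the highest `l_c`
(default 1, the classical single-chain design; the simulation harness uses
best-of-2 — inferior local optima, not outright failures, are what
occasionally inflate error rates in small noisy cohorts).  Inside SEM, an empty
stochastic draw is redrawn up to 10 times, then the partition is reshuffled.
A residual variance collapsing to zero (all residuals numerically zero)
raises an explicit error advising a noise floor.  `l_c` is asserted
non-decreasing across complete CEM iterations to 1e-9 relative; the one
mechanism that can genuinely break monotonicity — a relabeling that rebinds
the `A = 0` constraint to a different group mid-run — is transient and
flagged with a warning if it ever lowers `l_c`.

## Model choice and diagnostics

Criteria: `AIC = -2l + 2k`, `BIC = -2l + k ln N` with `l` the observed-data
mixture log-likelihood and `N` the number of subjects (the likelihood unit
is the subject, not the measurement), and `ICL = -2 l_c + k ln N` — the BIC
penalty applied to the classification likelihood, the natural convention in
a hard-assignment fit.  The free-parameter count `k` lives in one function
shared by all criteria: mean-model parameters after constraints, plus 1 or
`G` variances, plus `G-1` mixing weights.  For four groups this gives 20 for
the unconstrained bi-exponential and 14 for the compartment model with
constant production and shared variance.

The classification becomes a diagnostic test by predicting disease for the
top-level group only.  Accuracy (sensitivity, specificity, PPV, NPV,
percentage well-classified) is estimated with stratified k-fold
cross-validation (default k=4; per-stratum fold counts differ by at most 1).
Held-out subjects are scored with the trained model's posteriors — all
parameters including `pi` frozen, no refitting — and the median over folds
is reported, the even-fold median being the mean of the two middle values.
Undefined metrics (empty denominator) are reported as undefined, never as 0.

The initialization-sensitivity analysis moves 10 randomly chosen subjects
out of each converged group (a group smaller than that keeps one member),
refits from the perturbed partition without the SEM pre-step, and reports
how many subjects end up reassigned; the default of three repetitions
matches standard practice of probing a basin of attraction a few times.

## The synthetic-data generator

No registry of real post-curettage trajectories ships with the package, so
synthetic cohorts define all study conditions.  The generator emulates a
monitoring registry: per subject a latent group from `pi`, a measurement
count drawn from {2..6} with probabilities (0.25, 0.35, 0.20, 0.12, 0.08)
(median 3, range 2-6), a first visit uniform in days 0-3 and subsequent
gaps uniform in 4-9 days — compressed proportionally when the schedule
would pass day 21 — then log-scale Gaussian noise around the group's
analytic mean trajectory.  The canonical scenario, the frozen reference for
all stochastic checks, uses G=4 compartment groups with constant
production: shared `k12=0.7, k21=0.25, k10=0.6` /day;
`mu10 = (3e3, 2e4, 1e5, 2e5)` IU/L; `A = (0, 50, 400, 4000)` IU/L/day;
`pi = (0.10, 0.44, 0.38, 0.08)` mirroring registry-like group-size
proportions; `sigma = 0.45` on the log scale; n = 1000 subjects.  The top
group carries the disease label.

What the generator does *not* emulate: within-group heterogeneity (every
subject shares its group's exact mean curve), values censored at the assay
detection limit, visit schedules correlated with disease severity, and
mole-type subpopulations.  Passing tests therefore demonstrate correctness
of the estimation machinery under the model's own assumptions, not
performance on real registry data.

The simulation harness refits each simulated cohort and reports the subject
misclassification rate and per-parameter relative bias, with estimated
groups aligned to true groups by the same ascending-trajectory-level
statistic the fitter uses internally (never by Hungarian matching, so the
alignment cannot flatter the fit).  Under the canonical scenario the
classification error stays in the low single digits of percent and the
maximum absolute bias over the shared kinetics and the four initial levels
stays below 5%.  At this separation the error rate is dominated by overlap
between adjacent middle groups; pushing the residual SD up to ~0.8 raises
the error toward 7-8% but contaminates the small top group enough to bias
its `mu10` and `A` well past 5% — low error and low bias are jointly
attainable only at moderate noise, which is why the scenario is frozen at
`sigma = 0.45`.  Problem sizes used by the shipped checks — 20 replicates of
n=1000 for the canonical study, a 3x3 (sigma, n) grid at 10 replicates per
cell for the trend check — keep the full suite to a few minutes on one core
while leaving Monte-Carlo error near one percentage point.

## Known limitations

* Hard assignments only; no within-group random effects (a subject's
  deviation from its typical trajectory is absorbed into `sigma^2`).
* `l_c` has many local optima; a single SEM chain (the default) carries no
  global-optimum guarantee.  `n_restarts` is the provided mitigation.
* The `A = 0` group and the disease-positive group are defined through the
  mean-log-level ordering; exotic parameter sets where trajectory curves
  cross could make that ordering unstable between iterations.
* Values at or below the assay detection limit must be imputed upstream;
  the log transform is undefined at 0 and the package refuses such rows.
* The bi-exponential M-step is a non-convex fit with no positivity
  safeguard on the mean; for pathological groups it relies on the penalty
  and restarts rather than on constraints.
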