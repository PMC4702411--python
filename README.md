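# kinclust

Model-based classification of longitudinal biomarker trajectories with
compartment kinetics and a classification-EM (CEM) algorithm.

After curettage of a hydatidiform mole, women are monitored with repeated
hCG measurements; most show a bi-exponential decline, but incomplete
evacuation can progress to gestational trophoblastic neoplasia (GTN), whose
signature is a residual hormone production superimposed on the decline.
`kinclust` groups such trajectories — 2 to 6 irregularly timed measurements
per subject within 21 days — into `G` latent classes whose typical curves
come from a two-compartment pharmacokinetic model, and turns the
classification into an early diagnostic test.  It is aimed at
biostatisticians working with short, irregular biomarker series where the
latent heterogeneity has a mechanistic interpretation.

## The model in brief

Plasma concentration `mu1(t)` follows

    d mu1/dt = -(k12 + k10) mu1 + k21 mu2 + r(t)
    d mu2/dt =   k12 mu1 - k21 mu2,          mu2(0) = 0

with residual production `r(t) = 0`, `A`, or `A*t`.  Transfer and
elimination rates `k12, k21, k10` are shared by all groups (normal
physiology); `mu10_g` (initial level) and `A_g` (production) are
group-specific, with `A = 0` in the lowest-level group.  Log measurements
are Gaussian around `ln mu1g(t)`.  Estimation maximizes the classification
log-likelihood

    l_c = sum_i sum_g z_ig [ log pi_g + log f_g(Y_i) ]

by CEM (E-step posteriors, hard C-step, constrained nonlinear
least-squares M-step), initialized from the best of 100 stochastic-EM
iterations, stopping at a relative `l_c` change of 1e-6.  An unconstrained
bi-exponential mean (`c e^{at} + c2 e^{a2 t}` per group) is included as the
non-mechanistic competitor, and BIC/AIC/ICL plus diagnostic accuracy
(sensitivity, specificity, PPV, NPV, classification rate, stratified 4-fold
cross-validation) support model choice.  Details: `docs/methods.md`.

## Worked example

Simulate a registry-like cohort from the frozen canonical scenario (four
groups, shared kinetics, constant production in the upper groups), fit the
4-group model, and evaluate the top-group disease rule:

```python
import numpy as np
from kinclust import (FitConfig, accuracy, canonical_scenario, cem_fit,
                      classify_disease, simulate_cohort)

scenario = canonical_scenario(n_subjects=500)
cohort, truth = simulate_cohort(scenario, np.random.default_rng(7))
fit = cem_fit(cohort, scenario.spec(), FitConfig(seed=7, n_restarts=8))

print("group sizes:", fit.group_sizes)
print("true sizes :", np.bincount(truth.z, minlength=4))
print("error rate : %.1f%%" % (100 * np.mean(fit.assignment.z != truth.z)))
print("kinetics   : k12=%.3f k21=%.3f k10=%.3f"
      % (fit.structure.k12, fit.structure.k21, fit.structure.k10))
summary = accuracy(classify_disease(fit), cohort.disease_labels())
print("sens %.1f%%  spec %.1f%%  PPV %.1f%%  NPV %.1f%%"
      % (summary.sensitivity, summary.specificity, summary.ppv, summary.npv))
```

Output:

```
group sizes: [ 46 214 208  32]
true sizes : [ 46 213 207  34]
error rate : 1.0%
kinetics   : k12=0.776 k21=0.283 k10=0.653
sens 91.2%  spec 99.8%  PPV 96.9%  NPV 99.4%
```

The fitted groups are reported in ascending order of trajectory level; the
top group is the disease-positive class.  Only 1% of the 500 subjects land
in the wrong group, the recovered rates sit near the generating values
(0.7, 0.25, 0.6 /day; single-cohort estimates wobble by ~10%), and on this
cleanly generated cohort the top-group rule is an excellent test — real
registry series, with within-group heterogeneity the generator does not
emulate, behave far less cleanly (see `docs/methods.md`).

The same workflows are available from the shell:

```sh
kinclust simulate --scenario canonical --seed 7 --out-dir sim/
kinclust fit sim/cohort.csv --groups 4 --production constant --seed 7
kinclust select sim/cohort.csv --seed 7      # 13-candidate comparison table
kinclust cv sim/cohort.csv --groups 4 --folds 4 --seed 7
kinclust sensitivity sim/cohort.csv --groups 4 --seed 7
```

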