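"""SEM-initialized Classification-EM for kinetic trajectory groups.

The fit alternates three steps until the classification log-likelihood
l_c stabilizes (relative change <= 1e-6):

* E-step: posterior membership probabilities by Bayes' theorem;
* C-step: hard assignment to the maximum-posterior group (SEM variant:
  one multinomial draw per subject instead of the argmax);
* M-step: maximum likelihood for pi and the group parameters given the
  assignment.  For the compartment model the transfer/elimination rates
  are shared across groups, so the M-step is ONE joint nonlinear
  least-squares problem over all subjects; the bi-exponential competitor
  has no cross-group ties and is fitted group by group.

Positivity of the kinetic parameters is obtained by optimizing their
logarithms (no clipping, no bound constraints); the A = 0 constraint of
the lowest group is structural — that group simply has no production
parameter.  The damped (Levenberg-Marquardt) least-squares direction is
used rather than a plain Gauss-Newton step.

Initialization follows the stochastic-EM recipe: a uniform random
partition, then 100 SEM iterations, keeping the parameters and
assignment of the iteration with the highest l_c.  Groups are relabeled
after every M-step in ascending order of mean predicted log-hCG so that
"group 1 = lowest trajectory level" stays true throughout.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .kinetic_models import BiExpParams, CompartmentParams, ModelSpec, solve_compartment
from .likelihood import (
    Assignment,
    DegenerateGroupError,
    GroupStructure,
    classification_loglik,
    count_free_parameters,
    information_criteria,
    log_density_matrix,
    mixture_loglik,
    posterior_matrix,
)
from .trajectory_data import Cohort, FlatCohort

__all__ = [
    "FitConfig",
    "FitResult",
    "EmptyGroupError",
    "DegenerateVarianceError",
    "MStepError",
    "m_step",
    "e_step",
    "c_step",
    "stochastic_c_step",
    "sem_initialize",
    "cem_fit",
    "perturb_partition",
    "perturb_and_refit",
]

_A_FLOOR = 1e-2  # warm-start floor for production coefficients (log scale)


class EmptyGroupError(RuntimeError):
    """An assignment left at least one group without subjects."""


class DegenerateVarianceError(RuntimeError):
    """Residual variance collapsed to zero.

    All residuals were (numerically) zero; add a noise floor to the data
    or drop the offending duplicate trajectories.
    """


class MStepError(RuntimeError):
    """The nonlinear least-squares optimizer failed; carries the last point."""

    def __init__(self, message: str, theta=None):
        super().__init__(message)
        self.theta = theta


@dataclass(frozen=True)
class FitConfig:
    """Algorithmic settings of the SEM + CEM fit.

    Defaults follow the reference procedure: 100 SEM iterations, relative
    l_c stopping tolerance 1e-6, M-step (least squares) tolerance 1e-6,
    ODE absolute tolerance 1e-6.
    """

    sem_iterations: int = 100
    cem_rel_tol: float = 1e-6
    mstep_tol: float = 1e-6
    ode_abs_tol: float = 1e-6
    max_cem_iterations: int = 500
    seed: int = 0
    n_restarts: int = 1
    best_of: int = 1
    mstep_max_nfev: Optional[int] = None

    def __post_init__(self):
        for name in ("cem_rel_tol", "mstep_tol", "ode_abs_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sem_iterations < 0 or self.max_cem_iterations < 1:
            raise ValueError("iteration counts out of range")


@dataclass
class FitResult:
    """Converged parameters, hard assignment and bookkeeping of one fit."""

    structure: GroupStructure
    assignment: Assignment
    lc_trace: list
    criteria: dict
    loglik: float  # observed-data mixture log-likelihood
    loglik_c: float  # classification log-likelihood at the solution
    converged: bool
    n_iterations: int
    group_sizes: np.ndarray
    sem_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.to_dict(),
            "assignment": self.assignment.z.tolist(),
            "lc_trace": list(self.lc_trace),
            "criteria": {k: float(v) for k, v in self.criteria.items()},
            "loglik": self.loglik,
            "loglik_c": self.loglik_c,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "group_sizes": self.group_sizes.tolist(),
        }


# ---------------------------------------------------------------------------
# M-step


def _as_flat(cohort) -> FlatCohort:
    return cohort if isinstance(cohort, FlatCohort) else cohort.flat()


def _group_rows(flat: FlatCohort, z: np.ndarray, G: int):
    """Per-group measurement-row index arrays for a subject assignment."""
    subj_of_row = np.repeat(np.arange(flat.n_subjects), flat.n_per_subject)
    zrow = z[subj_of_row]
    return [np.where(zrow == g)[0] for g in range(G)]


def _heuristic_mu10(flat: FlatCohort, z: np.ndarray, g: int) -> float:
    first = flat.offsets[:-1][z == g]
    return float(np.exp(np.mean(flat.y[first])))


def _heuristic_A(flat, rows_g, k10: float) -> float:
    late = rows_g[flat.t[rows_g] >= 10.0]
    if len(late) == 0:
        return 1.0
    # steady-state moment: mu1 -> A/k10 under constant production
    return max(_A_FLOOR, 0.5 * k10 * float(np.exp(np.mean(flat.y[late]))))


def _compartment_theta0(flat, z, spec, warm: Optional[GroupStructure]):
    """Initial log-scale parameter vector [ln k12, ln k21, ln k10,
    ln mu10_1..G, ln A_2..G]."""
    G = spec.n_groups
    has_A = spec.production != "none"
    if warm is not None and warm.spec.mean_model == "compartment":
        k = [warm.k12, warm.k21, warm.k10]
        mu10 = np.maximum(warm.mu10, 1e-6)
        A = np.maximum(warm.A[1:], _A_FLOOR) if has_A and G > 1 else np.empty(0)
    else:
        k = [0.5, 0.5, 0.5]
        mu10 = np.array([_heuristic_mu10(flat, z, g) for g in range(G)])
        if has_A and G > 1:
            rows = _group_rows(flat, z, G)
            A = np.array([_heuristic_A(flat, rows[g], k[2]) for g in range(1, G)])
        else:
            A = np.empty(0)
    theta = np.concatenate([np.log(k), np.log(mu10), np.log(A) if len(A) else A])
    return np.clip(theta, -40.0, 40.0)


def _unpack_compartment(theta, spec) -> dict:
    G = spec.n_groups
    theta = np.clip(theta, -40.0, 40.0)
    k12, k21, k10 = np.exp(theta[:3])
    mu10 = np.exp(theta[3 : 3 + G])
    A = np.zeros(G)
    if spec.production != "none" and G > 1:
        A[1:] = np.exp(theta[3 + G :])
    return dict(k12=float(k12), k21=float(k21), k10=float(k10), mu10=mu10, A=A)


def _compartment_residuals(theta, flat, rows, spec, weights):
    p = _unpack_compartment(theta, spec)
    out = np.empty(flat.n_measurements)
    for g, rows_g in enumerate(rows):
        if len(rows_g) == 0:
            continue
        kind = spec.production if (g > 0 and spec.production != "none") else "none"
        cp = CompartmentParams(
            mu10=p["mu10"][g], k12=p["k12"], k21=p["k21"], k10=p["k10"],
            A=p["A"][g], production=kind,
        )
        mu = solve_compartment(cp, flat.t[rows_g])
        res = flat.y[rows_g] - np.log(np.maximum(mu, 1e-300))
        out[rows_g] = res if weights is None else res * weights[g]
    return out


def _biexp_theta0(flat, rows_g, warm_row):
    if warm_row is not None:
        return np.asarray(warm_row, dtype=float)
    t, y = flat.t[rows_g], flat.y[rows_g]
    # single-exponential moment fit on the log scale, split 80/20
    if len(np.unique(t)) >= 2:
        slope, intercept = np.polyfit(t, y, 1)
    else:
        slope, intercept = -0.1, float(np.mean(y))
    c = math.exp(np.clip(intercept, -40, 40))
    return np.array([0.8 * c, min(slope, 0.0) * 1.5, 0.2 * c, min(slope, 0.0) * 0.2])


def _biexp_residuals(theta, t, y):
    c, a, c2, a2 = theta
    mu = c * np.exp(np.clip(a * t, -700, 700)) + c2 * np.exp(np.clip(a2 * t, -700, 700))
    bad = ~np.isfinite(mu) | (mu <= 1e-12)
    res = y - np.log(np.where(bad, 1e-12, mu))
    # infeasible region (mu <= 0): smooth penalty growing with the violation
    return np.where(bad, (np.abs(y) + 28.0) + 1e3 * np.maximum(0.0, -mu), res)


def _run_lsq(fun, theta0, config, args=()):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            sol = least_squares(
                fun,
                theta0,
                args=args,
                method="lm",
                ftol=config.mstep_tol,
                xtol=config.mstep_tol,
                gtol=config.mstep_tol,
                max_nfev=config.mstep_max_nfev,
            )
        except Exception as exc:  # pragma: no cover - optimizer blow-up
            raise MStepError(f"least-squares failure: {exc}", theta=theta0) from exc
    if not np.all(np.isfinite(sol.x)):
        raise MStepError("least-squares returned non-finite parameters", theta=sol.x)
    return sol


def m_step(
    cohort,
    assignment,
    spec: ModelSpec,
    config: FitConfig,
    warm: Optional[GroupStructure] = None,
) -> GroupStructure:
    """Maximum-likelihood update of all parameters given hard assignments.

    pi_g = n_g/N.  Mean parameters minimize the residual sum of squares of
    (Y_ij - ln mu1g(t_ij)); the shared-kinetics compartment problem is
    solved jointly, the bi-exponential groups independently.  sigma^2 is
    the ML estimate RSS/m (not bias-corrected), per group or pooled.  With
    per-group variances the joint compartment problem is iteratively
    reweighted (two passes) since groups then enter the likelihood with
    different precisions.
    """
    flat = _as_flat(cohort)
    z = assignment.z if isinstance(assignment, Assignment) else np.asarray(assignment, int)
    G = spec.n_groups
    sizes = np.bincount(z, minlength=G)
    if np.any(sizes == 0):
        raise EmptyGroupError(f"empty group in M-step (sizes {sizes.tolist()})")
    pi = sizes / flat.n_subjects
    rows = _group_rows(flat, z, G)
    m_per_group = np.array([len(r) for r in rows])

    if spec.mean_model == "compartment":
        theta0 = _compartment_theta0(flat, z, spec, warm)
        if spec.variance == "per_group":
            if warm is not None:
                sig = np.sqrt(warm.sigma2_vector())
            else:
                sig = np.ones(G)
            theta = theta0
            for _ in range(2):  # IRLS passes for group-specific precisions
                w = 1.0 / np.maximum(sig, 1e-8)
                sol = _run_lsq(
                    _compartment_residuals, theta, config, args=(flat, rows, spec, w)
                )
                theta = sol.x
                raw = _compartment_residuals(theta, flat, rows, spec, None)
                sig = np.array(
                    [math.sqrt(np.mean(raw[r] ** 2)) if len(r) else 1.0 for r in rows]
                )
            sigma2 = sig**2
        else:
            sol = _run_lsq(
                _compartment_residuals, theta0, config, args=(flat, rows, spec, None)
            )
            theta = sol.x
            raw = _compartment_residuals(theta, flat, rows, spec, None)
            sigma2 = float(np.mean(raw**2))
        p = _unpack_compartment(theta, spec)
        structure = GroupStructure(
            spec=spec, pi=pi, sigma2=_checked_sigma2(sigma2),
            k12=p["k12"], k21=p["k21"], k10=p["k10"], mu10=p["mu10"], A=p["A"],
        )
    else:
        coefs = np.empty((G, 4))
        rss_g = np.empty(G)
        for g in range(G):
            t_g, y_g = flat.t[rows[g]], flat.y[rows[g]]
            warm_row = warm.biexp[g] if (warm is not None and warm.biexp is not None) else None
            theta0 = _biexp_theta0(flat, rows[g], warm_row)
            sol = _run_lsq(_biexp_residuals, theta0, config, args=(t_g, y_g))
            coefs[g] = sol.x
            r = _biexp_residuals(sol.x, t_g, y_g)
            rss_g[g] = float(np.sum(r * r))
        if spec.variance == "per_group":
            sigma2 = _checked_sigma2(rss_g / m_per_group)
        else:
            sigma2 = _checked_sigma2(float(rss_g.sum() / m_per_group.sum()))
        structure = GroupStructure(spec=spec, pi=pi, sigma2=sigma2, biexp=coefs)
    return structure


def _checked_sigma2(s2):
    if np.any(np.asarray(s2) < 1e-14):
        raise DegenerateVarianceError(
            "degenerate variance: residuals are numerically zero; add a "
            "noise floor to the measurements"
        )
    return s2


# ---------------------------------------------------------------------------
# E / C steps


def e_step(cohort, structure: GroupStructure) -> np.ndarray:
    """Posterior membership matrix (N, G) for every subject."""
    return posterior_matrix(_as_flat(cohort), structure)


def c_step(posteriors: np.ndarray) -> Assignment:
    """Argmax assignment; ties break toward the lowest group index."""
    return Assignment(np.argmax(posteriors, axis=1))


def stochastic_c_step(posteriors: np.ndarray, rng: np.random.Generator) -> Assignment:
    """One multinomial draw per subject with its posterior row."""
    p = np.asarray(posteriors, dtype=float)
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0  # guard against round-off shortfall
    u = rng.random(p.shape[0])
    return Assignment(np.argmax(u[:, None] < cum, axis=1))


# ---------------------------------------------------------------------------
# relabeling and the SEM / CEM drivers


def _relabel(structure: GroupStructure, z: np.ndarray):
    """Sort groups by ascending trajectory level; remap assignments."""
    order = np.argsort(structure.level_order_stat(), kind="stable")
    if np.array_equal(order, np.arange(structure.n_groups)):
        return structure, z
    new_label = np.empty_like(order)
    new_label[order] = np.arange(structure.n_groups)
    return structure.permuted(order), new_label[z]


def _random_partition(n: int, G: int, rng: np.random.Generator) -> np.ndarray:
    for _ in range(100):
        z = rng.integers(0, G, size=n)
        if len(np.unique(z)) == G:
            return z
    raise EmptyGroupError("could not draw a partition covering all groups")


def sem_initialize(cohort, spec: ModelSpec, config: FitConfig, rng):
    """Stochastic-EM warm start for the CEM algorithm.

    Starts from a uniform random partition, runs ``config.sem_iterations``
    rounds of (E-step, multinomial C-step, M-step), and returns the
    parameters and assignment of the iteration with the maximal
    classification log-likelihood.  Empty stochastic draws are redrawn up
    to 10 times, then the partition is reshuffled.
    """
    flat = _as_flat(cohort)
    structure, z, trace = _sem(flat, spec, config, rng)
    return structure, Assignment(z), trace


def _sem(flat, spec, config, rng):
    G = spec.n_groups
    z = _random_partition(flat.n_subjects, G, rng)
    structure = m_step(flat, z, spec, config)
    structure, z = _relabel(structure, z)
    lc = classification_loglik(flat, z, structure)
    best = (lc, structure.copy(), z.copy())
    trace = [lc]
    for _ in range(config.sem_iterations):
        tau = e_step(flat, structure)
        z_new = None
        for _attempt in range(10):
            cand = stochastic_c_step(tau, rng).z
            if len(np.unique(cand)) == G:
                z_new = cand
                break
        if z_new is None:
            z_new = _random_partition(flat.n_subjects, G, rng)
        structure = m_step(flat, z_new, spec, config, warm=structure)
        structure, z_new = _relabel(structure, z_new)
        lc = classification_loglik(flat, z_new, structure)
        trace.append(lc)
        if lc > best[0]:
            best = (lc, structure.copy(), z_new.copy())
        z = z_new
    _, structure, z = best
    return structure, z, trace


def cem_fit(
    cohort,
    spec: ModelSpec,
    config: FitConfig,
    initial_partition: Optional[np.ndarray] = None,
) -> FitResult:
    """SEM-initialized CEM fit of a G-group classification model.

    When ``initial_partition`` is given the SEM pre-step is skipped and
    the algorithm starts with an M-step on that partition (the mode used
    by the initialization-sensitivity analysis).  A chain whose C-step
    empties a group is abandoned and a fresh SEM chain started, up to
    ``config.n_restarts`` attempts in total; with ``config.best_of`` > 1
    the fit collects that many successful chains and returns the one with
    the highest classification log-likelihood (l_c has many local optima
    and a single chain carries no global guarantee).
    """
    flat = _as_flat(cohort)
    if flat.n_subjects < 2 * spec.n_groups:
        raise ValueError("cohort too small: need at least 2 subjects per group")
    rng = np.random.default_rng(config.seed)
    last_err = None
    best = None
    n_ok = 0
    for _chain in range(max(1, config.n_restarts, config.best_of)):
        try:
            result = _cem_once(flat, spec, config, rng, initial_partition)
        except (EmptyGroupError, MStepError) as err:
            last_err = err
            if initial_partition is not None:
                break  # a prescribed start has nothing to restart from
            continue
        n_ok += 1
        if best is None or result.loglik_c > best.loglik_c:
            best = result
        if n_ok >= max(1, config.best_of):
            break
    if best is not None:
        return best
    raise RuntimeError(
        f"CEM failed after {max(1, config.n_restarts, config.best_of)} "
        f"chain(s): {last_err}"
    ) from last_err


def _cem_once(flat, spec, config, rng, initial_partition):
    G = spec.n_groups
    sem_trace = []
    if initial_partition is None:
        structure, z, sem_trace = _sem(flat, spec, config, rng)
    else:
        z = np.asarray(initial_partition, dtype=int)
        structure = m_step(flat, z, spec, config)
        structure, z = _relabel(structure, z)
    lc = classification_loglik(flat, z, structure)
    trace = [lc]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_cem_iterations + 1):
        tau = e_step(flat, structure)
        z_new = c_step(tau).z
        if len(np.unique(z_new)) < G:
            raise EmptyGroupError("empty group in C-step")
        structure = m_step(flat, z_new, spec, config, warm=structure)
        structure, z_new = _relabel(structure, z_new)
        lc_new = classification_loglik(flat, z_new, structure)
        trace.append(lc_new)
        if lc_new + 1e-9 * abs(lc) < lc:
            warnings.warn(
                f"l_c decreased by {lc - lc_new:.3e} at CEM iteration {n_iter}",
                RuntimeWarning,
            )
        z, lc_prev, lc = z_new, lc, lc_new
        if abs(lc - lc_prev) <= config.cem_rel_tol * abs(lc_prev):
            converged = True
            break

    k = count_free_parameters(spec)
    ll = mixture_loglik(flat, structure)
    crit = information_criteria(ll, k, flat.n_subjects, loglik_c=lc)
    assignment = Assignment(z)
    return FitResult(
        structure=structure,
        assignment=assignment,
        lc_trace=trace,
        criteria=crit,
        loglik=ll,
        loglik_c=lc,
        converged=converged,
        n_iterations=n_iter,
        group_sizes=assignment.group_sizes(G),
        sem_trace=sem_trace,
    )


# ---------------------------------------------------------------------------
# initialization-sensitivity analysis


def perturb_partition(
    z: np.ndarray, n_groups: int, n_moved_per_group: int, rng: np.random.Generator
) -> np.ndarray:
    """Move ``n_moved_per_group`` random subjects out of each group.

    Each moved subject goes to a uniformly chosen other group; a group
    smaller than the request loses all but one member.
    """
    z = np.asarray(z, dtype=int)
    z0 = z.copy()
    for g in range(n_groups):  # membership judged on the original assignment
        members = np.where(z == g)[0]
        n_move = min(n_moved_per_group, max(len(members) - 1, 0))
        if n_move == 0:
            continue
        moved = rng.choice(members, size=n_move, replace=False)
        others = np.delete(np.arange(n_groups), g)
        z0[moved] = rng.choice(others, size=n_move)
    return z0


def perturb_and_refit(
    cohort,
    spec: ModelSpec,
    config: FitConfig,
    fit: FitResult,
    n_moved_per_group: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Shake the converged partition and refit without the SEM pre-step.

    ``n_moved_per_group`` randomly chosen subjects of each group are moved
    to a random other group; the perturbed partition seeds a fresh CEM
    chain.  Groups smaller than the request lose all but one subject.
    Reports how many subjects end in a different group than the original
    fit, and the l_c difference.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    z0 = perturb_partition(fit.assignment.z, spec.n_groups, n_moved_per_group, rng)
    refit = cem_fit(cohort, spec, config, initial_partition=z0)
    n_changed = int(np.sum(refit.assignment.z != fit.assignment.z))
    return {
        "n_moved_per_group": n_moved_per_group,
        "n_changed": n_changed,
        "lc_original": fit.loglik_c,
        "lc_refit": refit.loglik_c,
        "lc_difference": refit.loglik_c - fit.loglik_c,
        "refit": refit,
    }
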