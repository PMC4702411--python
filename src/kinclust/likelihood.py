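"""Group-wise Gaussian likelihood of log-trajectories and model criteria.

Each latent group g carries a typical trajectory mu1g(t); the j-th log
measurement of subject i is Y_ij ~ N(ln mu1g(t_ij), sigma_g^2),
independent given the group.  The classification log-likelihood jointly
scores the data and a hard assignment z:

    l_c(Y; alpha, pi, z) = sum_i sum_g z_ig [ log pi_g + log f_g(Y_i) ]

Cross-group constraints of the compartment model are structural here:
the transfer/elimination rates k12, k21, k10 live in single shared slots,
and the residual-production coefficient A of group 1 (the group with the
lowest trajectory level) is pinned to zero.  The unconstrained
bi-exponential competitor stores a free 4-vector per group.

Densities are only ever combined through log-sum-exp; raw densities are
never materialized.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .kinetic_models import (
    BiExpParams,
    CompartmentParams,
    InvalidMeanTrajectory,
    ModelSpec,
    biexp_predict,
    mean_log_trajectory,
    solve_compartment,
)
from .trajectory_data import Cohort, FlatCohort, Trajectory

__all__ = [
    "GroupStructure",
    "Assignment",
    "DegenerateGroupError",
    "UnexplainableTrajectoryError",
    "log_density_group",
    "log_density_matrix",
    "classification_loglik",
    "posterior_membership",
    "posterior_matrix",
    "mixture_loglik",
    "count_free_parameters",
    "information_criteria",
    "LEVEL_GRID",
]

#: fixed grid on which groups are ordered by mean predicted log-hCG
LEVEL_GRID = np.arange(0.0, 22.0)

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateGroupError(ValueError):
    """A group is empty (or has no variance) where the model needs one."""


class UnexplainableTrajectoryError(ValueError):
    """Every group assigns zero density to a trajectory."""


@dataclass(frozen=True)
class Assignment:
    """Hard group memberships: z[i] is the group index of subject i."""

    z: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z, dtype=int)
        object.__setattr__(self, "z", z)

    @property
    def n_subjects(self) -> int:
        return len(self.z)

    def indicator(self, n_groups: int) -> np.ndarray:
        out = np.zeros((len(self.z), n_groups), dtype=int)
        out[np.arange(len(self.z)), self.z] = 1
        return out

    def group_sizes(self, n_groups: int) -> np.ndarray:
        return np.bincount(self.z, minlength=n_groups)


@dataclass
class GroupStructure:
    """All parameters of a G-group classification model.

    Compartment mode: shared ``k12, k21, k10`` plus per-group ``mu10`` and
    ``A`` (with ``A[0] == 0`` by constraint).  Bi-exp mode: a free
    ``(G, 4)`` coefficient array ``biexp`` (columns c, a, c2, a2).
    ``sigma2`` is a scalar for a shared residual variance or a length-G
    vector for per-group variances.  Groups are kept sorted by ascending
    trajectory level (see :meth:`level_order_stat`).
    """

    spec: ModelSpec
    pi: np.ndarray
    sigma2: object  # float or (G,) ndarray
    k12: float = None
    k21: float = None
    k10: float = None
    mu10: np.ndarray = None
    A: np.ndarray = None
    biexp: np.ndarray = None

    def __post_init__(self):
        G = self.spec.n_groups
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (G,):
            raise ValueError(f"pi must have shape ({G},)")
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be strictly positive and sum to 1")
        if self.spec.mean_model == "compartment":
            self.mu10 = np.asarray(self.mu10, dtype=float)
            if self.A is None:
                self.A = np.zeros(G)
            self.A = np.asarray(self.A, dtype=float)
            if self.mu10.shape != (G,) or self.A.shape != (G,):
                raise ValueError("mu10 and A must be length-G vectors")
        else:
            self.biexp = np.asarray(self.biexp, dtype=float)
            if self.biexp.shape != (G, 4):
                raise ValueError("biexp must have shape (G, 4)")
        if np.ndim(self.sigma2) == 0:
            self.sigma2 = float(self.sigma2)
            if self.sigma2 <= 0:
                raise ValueError("sigma2 must be positive")
        else:
            self.sigma2 = np.asarray(self.sigma2, dtype=float)
            if self.sigma2.shape != (G,) or np.any(self.sigma2 <= 0):
                raise ValueError("per-group sigma2 must be positive, length G")

    # -- accessors -------------------------------------------------------
    @property
    def n_groups(self) -> int:
        return self.spec.n_groups

    def sigma2_vector(self) -> np.ndarray:
        if np.ndim(self.sigma2) == 0:
            return np.full(self.n_groups, self.sigma2)
        return self.sigma2

    def compartment_params(self, g: int) -> CompartmentParams:
        if self.spec.mean_model != "compartment":
            raise ValueError("not a compartment structure")
        A = 0.0 if g == 0 else float(self.A[g])
        kind = self.spec.production if (g > 0 and self.spec.production != "none") else "none"
        return CompartmentParams(
            mu10=float(self.mu10[g]), k12=self.k12, k21=self.k21, k10=self.k10,
            A=A, production=kind,
        )

    def biexp_params(self, g: int) -> BiExpParams:
        if self.spec.mean_model != "biexp":
            raise ValueError("not a bi-exponential structure")
        return BiExpParams(*self.biexp[g])

    def group_mean_log(self, g: int, times) -> np.ndarray:
        """ln mu1g(t); raises InvalidMeanTrajectory for non-positive means."""
        if self.spec.mean_model == "compartment":
            return mean_log_trajectory(self.spec, self.compartment_params(g), times)
        return mean_log_trajectory(self.spec, self.biexp_params(g), times)

    def mean_log_matrix(self, times) -> np.ndarray:
        """(G, T) matrix of group mean log-trajectories.

        Rows where the mean is non-positive carry +inf sentinels at the
        offending times (the density then evaluates to -inf there) rather
        than raising, so one sick group cannot abort a whole E-step.
        """
        t = np.asarray(times, dtype=float)
        out = np.empty((self.n_groups, len(t)))
        for g in range(self.n_groups):
            if self.spec.mean_model == "compartment":
                mu = solve_compartment(self.compartment_params(g), t)
            else:
                mu = biexp_predict(self.biexp_params(g), t)
            mu = np.asarray(mu, dtype=float)
            bad = ~np.isfinite(mu) | (mu <= 0)
            row = np.where(bad, np.inf, np.log(np.where(bad, 1.0, mu)))
            out[g] = row
        return out

    def level_order_stat(self) -> np.ndarray:
        """Mean predicted log-hCG per group over the fixed day grid 0..21.

        This single statistic defines both the "lowest group" (A = 0
        constraint) and the "highest trajectory level" group used as the
        disease-positive class.
        """
        out = np.empty(self.n_groups)
        for g in range(self.n_groups):
            if self.spec.mean_model == "compartment":
                mu = solve_compartment(self.compartment_params(g), LEVEL_GRID)
            else:
                mu = biexp_predict(self.biexp_params(g), LEVEL_GRID)
            out[g] = float(np.mean(np.log(np.clip(mu, 1e-300, None))))
        return out

    def permuted(self, order: np.ndarray) -> "GroupStructure":
        """Relabel groups by ``order`` (new label j = old label order[j])."""
        order = np.asarray(order, dtype=int)
        sigma2 = self.sigma2 if np.ndim(self.sigma2) == 0 else self.sigma2[order]
        kw = dict(spec=self.spec, pi=self.pi[order], sigma2=sigma2,
                  k12=self.k12, k21=self.k21, k10=self.k10)
        if self.spec.mean_model == "compartment":
            kw.update(mu10=self.mu10[order], A=self.A[order])
        else:
            kw.update(biexp=self.biexp[order])
        return GroupStructure(**kw)

    def copy(self) -> "GroupStructure":
        return self.permuted(np.arange(self.n_groups))

    def to_dict(self) -> dict:
        d = {"spec": self.spec.to_dict(), "pi": self.pi.tolist()}
        d["sigma2"] = (
            self.sigma2 if np.ndim(self.sigma2) == 0 else self.sigma2.tolist()
        )
        if self.spec.mean_model == "compartment":
            d.update(k12=self.k12, k21=self.k21, k10=self.k10,
                     mu10=self.mu10.tolist(), A=self.A.tolist())
        else:
            d["biexp"] = self.biexp.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroupStructure":
        d = dict(d)
        d["spec"] = ModelSpec.from_dict(d["spec"])
        return cls(**d)


# ---------------------------------------------------------------------------
# densities


def _as_flat(cohort) -> FlatCohort:
    if isinstance(cohort, FlatCohort):
        return cohort
    return cohort.flat()


def log_density_group(
    trajectory: Trajectory, g: int, structure: GroupStructure
) -> float:
    """log f_g(Y_i): diagonal multivariate-Gaussian log density of one
    subject's log measurements under group g's mean trajectory.

    Returns -inf when the group's mean trajectory is invalid (mu1 <= 0)
    at any of the subject's times.
    """
    s2 = structure.sigma2_vector()[g]
    if s2 <= 0:
        raise DegenerateGroupError("sigma2 must be positive")
    try:
        m = structure.group_mean_log(g, trajectory.times)
    except InvalidMeanTrajectory:
        return -np.inf
    r = trajectory.log_values - m
    n = trajectory.n_measurements
    return float(-0.5 * n * (_LOG_2PI + math.log(s2)) - np.sum(r * r) / (2.0 * s2))


def log_density_matrix(cohort, structure: GroupStructure) -> np.ndarray:
    """(N, G) matrix of per-subject log f_g values, fully vectorized."""
    flat = _as_flat(cohort)
    G = structure.n_groups
    s2 = structure.sigma2_vector()
    if np.any(s2 <= 0):
        raise DegenerateGroupError("sigma2 must be positive")
    M = structure.mean_log_matrix(flat.t)  # (G, n_measurements); +inf = invalid
    out = np.empty((flat.n_subjects, G))
    starts = flat.offsets[:-1]
    n_i = flat.n_per_subject
    for g in range(G):
        r = flat.y - M[g]
        r2 = np.where(np.isfinite(r), r * r, np.inf)
        rss = np.add.reduceat(r2, starts)
        out[:, g] = -0.5 * n_i * (_LOG_2PI + math.log(s2[g])) - rss / (2.0 * s2[g])
    return out


def classification_loglik(cohort, assignment, structure: GroupStructure) -> float:
    """l_c = sum_i [ log pi_{z_i} + log f_{z_i}(Y_i) ] (hard assignments)."""
    z = assignment.z if isinstance(assignment, Assignment) else np.asarray(assignment, int)
    flat = _as_flat(cohort)
    if len(z) != flat.n_subjects:
        raise ValueError("assignment length does not match cohort size")
    if np.ndim(structure.sigma2) == 1:
        sizes = np.bincount(z, minlength=structure.n_groups)
        if np.any(sizes == 0):
            raise DegenerateGroupError(
                "degenerate group: empty group under per-group variances"
            )
    logf = log_density_matrix(flat, structure)
    rows = np.arange(flat.n_subjects)
    return float(np.sum(np.log(structure.pi[z]) + logf[rows, z]))


def posterior_matrix(cohort, structure: GroupStructure) -> np.ndarray:
    """(N, G) posterior membership probabilities tau_ig (Bayes, E-step)."""
    logf = log_density_matrix(cohort, structure)
    a = logf + np.log(structure.pi)[None, :]
    norm = logsumexp(a, axis=1)
    if np.any(~np.isfinite(norm)):
        bad = np.where(~np.isfinite(norm))[0]
        raise UnexplainableTrajectoryError(
            f"trajectory unexplainable by any group (subjects {bad.tolist()})"
        )
    return np.exp(a - norm[:, None])


def posterior_membership(
    trajectory: Trajectory, structure: GroupStructure
) -> np.ndarray:
    """Posterior probabilities over groups for a single trajectory."""
    logf = np.array(
        [log_density_group(trajectory, g, structure) for g in range(structure.n_groups)]
    )
    a = logf + np.log(structure.pi)
    norm = logsumexp(a)
    if not np.isfinite(norm):
        raise UnexplainableTrajectoryError("trajectory unexplainable by any group")
    return np.exp(a - norm)


def mixture_loglik(cohort, structure: GroupStructure) -> float:
    """Observed-data log-likelihood sum_i log sum_g pi_g f_g(Y_i)."""
    logf = log_density_matrix(cohort, structure)
    return float(np.sum(logsumexp(logf + np.log(structure.pi)[None, :], axis=1)))


# ---------------------------------------------------------------------------
# parameter counting and criteria


def count_free_parameters(spec: ModelSpec) -> int:
    """Free parameters after constraints, one convention for all criteria.

    mean-model parameters (after the shared-kinetics and A=0 constraints
    for the compartment model; 4 free coefficients per group for the
    bi-exponential) + variance parameters (1 shared or G per-group) +
    (G - 1) mixing weights.
    """
    G = spec.n_groups
    n_var = 1 if spec.variance == "shared" else G
    n_pi = G - 1
    if spec.mean_model == "biexp":
        n_mean = 4 * G
    else:
        n_mean = 3 + G  # shared k12,k21,k10 + per-group mu10
        if spec.production != "none":
            n_mean += G - 1  # A free except in the lowest group
    return n_mean + n_var + n_pi


def information_criteria(loglik: float, k: int, n: int, loglik_c: float = None) -> dict:
    """AIC, BIC and ICL from a log-likelihood and a parameter count.

    AIC = -2 l + 2k;  BIC = -2 l + k ln n with n the number of subjects;
    ICL applies the BIC penalty to the classification log-likelihood l_c
    (hard assignments), the natural convention in a CEM fit.  When
    ``loglik_c`` is omitted the assignments are taken as entropy-free and
    ICL coincides with BIC.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    if loglik_c is None:
        loglik_c = loglik
    return {
        "AIC": -2.0 * loglik + 2.0 * k,
        "BIC": -2.0 * loglik + k * math.log(n),
        "ICL": -2.0 * loglik_c + k * math.log(n),
    }
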