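"""Mean-trajectory models for post-curettage hCG kinetics.

Two mean models are provided for the plasma concentration mu1(t):

* a two-compartment pharmacokinetic model.  hCG enters plasma
  (compartment 1) as a bolus of size mu10, exchanges with tissues
  (compartment 2) at rates k12 and k21 (/day), is eliminated from plasma
  at rate k10 (/day), and may be re-produced by residual trophoblastic
  tissue at rate r(t) = A (constant) or r(t) = A*t (linear in time):

      d mu1/dt = -(k12 + k10) mu1 + k21 mu2 + r(t)
      d mu2/dt =   k12 mu1 - k21 mu2,          mu2(0) = 0

* an unconstrained bi-exponential curve
  mu1(t) = c exp(a t) + c2 exp(a2 t), which reproduces the shape of the
  homogeneous compartment solution but carries no kinetic interpretation.

The linear constant-coefficient system has an analytic solution
(sum of two exponentials plus a polynomial particular term); it is
implemented here and preferred for speed, with an LSODA numeric path kept
for the degenerate cases (repeated eigenvalues, singular transfer matrix)
and as an independent cross-check.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CompartmentParams",
    "BiExpParams",
    "ModelSpec",
    "ClosedFormUnavailable",
    "RepeatedEigenvalues",
    "InvalidMeanTrajectory",
    "SolverError",
    "solve_compartment_closed_form",
    "solve_compartment_numeric",
    "solve_compartment",
    "biexp_predict",
    "mean_log_trajectory",
]

PRODUCTION_KINDS = ("none", "constant", "linear")
_PRODUCTION_ALIASES = {"linear_in_time": "linear"}

MEAN_MODELS = ("compartment", "biexp")
VARIANCE_KINDS = ("shared", "per_group")


class ClosedFormUnavailable(ValueError):
    """The analytic solution does not apply; fall back to the numeric solver."""


class RepeatedEigenvalues(ClosedFormUnavailable):
    """The homogeneous system has a (numerically) repeated eigenvalue."""


class InvalidMeanTrajectory(ValueError):
    """The mean concentration is non-positive, so its log is undefined."""


class SolverError(RuntimeError):
    """The numeric ODE solver failed to converge; carries the parameters."""

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params


def _normalize_production(kind: str) -> str:
    kind = _PRODUCTION_ALIASES.get(kind, kind)
    if kind not in PRODUCTION_KINDS:
        raise ValueError(f"unknown production kind {kind!r}")
    return kind


@dataclass(frozen=True)
class CompartmentParams:
    """Kinetic parameters of the two-compartment model for one group.

    ``A`` is in IU/L/day for constant production and IU/L/day^2 for
    production proportional to time; it is ignored when ``production`` is
    ``"none"``.  The initial tissue concentration mu2(0) is structurally 0.
    """

    mu10: float
    k12: float
    k21: float
    k10: float
    A: float = 0.0
    production: str = "none"

    def __post_init__(self):
        object.__setattr__(self, "production", _normalize_production(self.production))
        for name in ("mu10", "k12", "k21", "k10", "A"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    @property
    def effective_A(self) -> float:
        return 0.0 if self.production == "none" else self.A


@dataclass(frozen=True)
class BiExpParams:
    """Coefficients of mu1(t) = c exp(a t) + c2 exp(a2 t); unconstrained."""

    c: float
    a: float
    c2: float
    a2: float

    def __post_init__(self):
        for name in ("c", "a", "c2", "a2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of a classification model.

    mean_model : "compartment" or "biexp"
    production : residual-production hypothesis (compartment only)
    n_groups   : number of latent trajectory groups G
    variance   : "shared" (one sigma^2) or "per_group" (sigma_g^2)
    """

    mean_model: str = "compartment"
    production: str = "constant"
    n_groups: int = 2
    variance: str = "shared"

    def __post_init__(self):
        if self.mean_model not in MEAN_MODELS:
            raise ValueError(f"unknown mean model {self.mean_model!r}")
        object.__setattr__(self, "production", _normalize_production(self.production))
        if self.variance not in VARIANCE_KINDS:
            raise ValueError(f"unknown variance kind {self.variance!r}")
        if not (1 <= int(self.n_groups)):
            raise ValueError("n_groups must be a positive integer")
        object.__setattr__(self, "n_groups", int(self.n_groups))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))

    def describe(self) -> str:
        prod = {"none": "-", "constant": "A", "linear": "A*t"}[self.production]
        var = "s2" if self.variance == "shared" else "s2_g"
        if self.mean_model == "biexp":
            return f"biexp G={self.n_groups} {var}"
        return f"compartment G={self.n_groups} r={prod} {var}"


def _transfer_matrix(p: CompartmentParams) -> np.ndarray:
    return np.array(
        [[-(p.k12 + p.k10), p.k21], [p.k12, -p.k21]], dtype=float
    )


def _closed_form_pieces(p: CompartmentParams):
    """Eigen-decomposition and particular solution of the system.

    Returns (lam, V, c, part) so that the state is
    V @ (c * exp(lam t)) + part(t), with part(t) a (2,)-or-(2,T) array.
    """
    M = _transfer_matrix(p)
    s = p.k12 + p.k21 + p.k10
    disc = s * s - 4.0 * p.k21 * p.k10  # always >= 0 for non-negative rates
    if disc <= max(1e-14, 1e-10 * s * s):
        raise RepeatedEigenvalues(
            "transfer matrix has (numerically) repeated eigenvalues; "
            "use the numeric solver"
        )
    lam, V = np.linalg.eig(M)
    lam = lam.real
    V = V.real

    A = p.effective_A
    if A == 0.0:
        def part(t):
            return np.zeros((2,) + np.shape(t))

        part0 = np.zeros(2)
    else:
        det = p.k21 * p.k10
        if det <= 1e-300:
            raise ClosedFormUnavailable(
                "singular transfer matrix (k21*k10 = 0) with residual "
                "production; use the numeric solver"
            )
        b = np.array([-A, 0.0])
        if p.production == "constant":
            xp = np.linalg.solve(M, b)  # steady state: mu1 -> A/k10

            def part(t):
                return xp[:, None] * np.ones(np.shape(t)) if np.ndim(t) else xp

            part0 = xp
        else:  # linear in time: particular solution affine in t
            u = np.linalg.solve(M, b)
            w = np.linalg.solve(M, u)

            def part(t):
                t = np.asarray(t, dtype=float)
                return u[:, None] * t[None, :] + w[:, None] if t.ndim else u * t + w

            part0 = w
    x0 = np.array([p.mu10, 0.0])
    c = np.linalg.solve(V, x0 - part0)
    return lam, V, c, part


def solve_compartment_closed_form(
    params: CompartmentParams, times, return_tissue: bool = False
):
    """Analytic plasma concentration mu1 at the requested times.

    The homogeneous part is c1 exp(lam1 t) + c2 exp(lam2 t) with lam1,2 the
    eigenvalues of the transfer matrix; constant production adds the steady
    state, linear production a particular solution affine in t.

    Raises :class:`RepeatedEigenvalues` / :class:`ClosedFormUnavailable`
    where the derivation breaks down (caller should use the numeric path).
    """
    t = np.asarray(times, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    lam, V, c, part = _closed_form_pieces(params)
    E = np.exp(lam[:, None] * t[None, :])
    X = V @ (c[:, None] * E) + part(t)
    mu1 = X[0]
    if scalar:
        mu1 = mu1[0]
        X = X[:, 0]
    if return_tissue:
        return mu1, X[1] if not scalar else X[1]
    return mu1


def solve_compartment_numeric(
    params: CompartmentParams,
    times,
    abs_tol: float = 1e-6,
    rel_tol: float = 1e-9,
    return_tissue: bool = False,
):
    """LSODA solution of the compartment system at the requested times.

    The solver switches automatically between Adams and BDF multistep
    methods depending on stiffness.  ``abs_tol`` defaults to 1e-6.
    """
    t = np.asarray(times, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    uniq, inv = np.unique(t, return_inverse=True)
    x0 = [params.mu10, 0.0]
    A = params.effective_A
    kind = params.production

    def rhs(tt, x):
        r = A if kind == "constant" else (A * tt if kind == "linear" else 0.0)
        return [
            -(params.k12 + params.k10) * x[0] + params.k21 * x[1] + r,
            params.k12 * x[0] - params.k21 * x[1],
        ]

    t_end = float(uniq[-1])
    if t_end == 0.0:
        sol_y = np.array([x0] * len(uniq)).T
    else:
        t_eval = uniq if uniq[0] == 0.0 else np.concatenate(([0.0], uniq))
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            x0,
            method="LSODA",
            t_eval=t_eval,
            atol=abs_tol,
            rtol=rel_tol,
        )
        if not sol.success:
            raise SolverError(
                f"LSODA failed: {sol.message}", params=params
            )
        sol_y = sol.y if uniq[0] == 0.0 else sol.y[:, 1:]
    mu1 = sol_y[0][inv]
    mu2 = sol_y[1][inv]
    if scalar:
        mu1, mu2 = mu1[0], mu2[0]
    if return_tissue:
        return mu1, mu2
    return mu1


def solve_compartment(
    params: CompartmentParams, times, method: str = "auto", abs_tol: float = 1e-6
):
    """Plasma concentration; analytic path with numeric fallback.

    method : "auto" (closed form, numeric on degeneracy), "closed_form",
             or "numeric".
    """
    if method == "closed_form":
        return solve_compartment_closed_form(params, times)
    if method == "numeric":
        return solve_compartment_numeric(params, times, abs_tol=abs_tol)
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    try:
        return solve_compartment_closed_form(params, times)
    except ClosedFormUnavailable:
        return solve_compartment_numeric(params, times, abs_tol=abs_tol)


def biexp_predict(params: BiExpParams, times):
    """Pointwise evaluation of c exp(a t) + c2 exp(a2 t)."""
    t = np.asarray(times, dtype=float)
    # clip the exponent so runaway optimizer steps cannot overflow
    e1 = np.exp(np.clip(params.a * t, -700.0, 700.0))
    e2 = np.exp(np.clip(params.a2 * t, -700.0, 700.0))
    return params.c * e1 + params.c2 * e2


def mean_log_trajectory(spec: ModelSpec, params, times, method: str = "auto"):
    """ln mu1(t): the mean of log-hCG in the Gaussian measurement model.

    Raises :class:`InvalidMeanTrajectory` when mu1 <= 0 anywhere (possible
    only for unconstrained bi-exponential parameters); an M-step must treat
    such a point as infeasible.
    """
    if spec.mean_model == "compartment":
        if not isinstance(params, CompartmentParams):
            raise TypeError("compartment spec requires CompartmentParams")
        mu = solve_compartment(params, times, method=method)
    else:
        if not isinstance(params, BiExpParams):
            raise TypeError("biexp spec requires BiExpParams")
        mu = biexp_predict(params, times)
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(~np.isfinite(mu_arr)) or np.any(mu_arr <= 0):
        raise InvalidMeanTrajectory(
            "invalid mean trajectory: mu1(t) <= 0 at some requested time"
        )
    out = np.log(mu_arr)
    return float(out[0]) if np.ndim(mu) == 0 else out
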