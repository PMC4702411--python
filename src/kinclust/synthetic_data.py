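"""Synthetic cohorts with the structure the classifier assumes, plus the
simulation-study harness (classification error rate, parameter bias).

The generator emulates a post-curettage hCG monitoring registry: each
subject belongs to one of G latent groups drawn from mixing weights pi,
contributes 2-6 roughly weekly measurements (median 3) inside a 21-day
window, and observes the group's compartment-model mean on the natural
log scale plus Gaussian noise of standard deviation sigma.  Subjects of
the designated top group(s) carry the disease label.

The canonical scenario frozen here is the reference design for all
stochastic checks: G = 4 groups under constant residual production with
shared kinetics k12 = 0.7, k21 = 0.25, k10 = 0.6 /day, initial levels
mu10 = (3e3, 2e4, 1e5, 2e5) IU/L, production A = (0, 50, 400, 4000)
IU/L/day, weights pi = (0.10, 0.44, 0.38, 0.08) and log-scale residual
SD sigma = 0.45.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cem_engine import FitConfig, cem_fit
from .kinetic_models import CompartmentParams, ModelSpec, solve_compartment
from .likelihood import GroupStructure
from .trajectory_data import Cohort, Measurement, Trajectory

__all__ = [
    "ScenarioConfig",
    "CohortTruth",
    "SimulationReport",
    "canonical_scenario",
    "simulate_cohort",
    "run_simulation_study",
    "monotonicity_sweep",
]

#: measurement-count distribution over {2..6}: median 3, min 2, max 6
DEFAULT_COUNT_PROBS = ((2, 0.25), (3, 0.35), (4, 0.20), (5, 0.12), (6, 0.08))


@dataclass(frozen=True)
class ScenarioConfig:
    """Generating truth and sampling design of a synthetic cohort."""

    n_subjects: int = 1000
    k12: float = 0.7
    k21: float = 0.25
    k10: float = 0.6
    mu10: tuple = (3e3, 2e4, 1e5, 2e5)
    A: tuple = (0.0, 50.0, 400.0, 4000.0)
    pi: tuple = (0.10, 0.44, 0.38, 0.08)
    sigma: float = 0.45
    production: str = "constant"
    count_probs: tuple = DEFAULT_COUNT_PROBS
    first_day_max: float = 3.0
    gap_min: float = 4.0
    gap_max: float = 9.0
    horizon: float = 21.0
    diseased_groups: tuple = (3,)

    def __post_init__(self):
        G = len(self.mu10)
        if not (len(self.A) == len(self.pi) == G):
            raise ValueError("mu10, A and pi must have equal length")
        if abs(sum(self.pi) - 1.0) > 1e-9 or any(p <= 0 for p in self.pi):
            raise ValueError("pi must be strictly positive and sum to 1")
        if self.A[0] != 0.0:
            raise ValueError("the lowest group must have A = 0")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if any(g < 0 or g >= G for g in self.diseased_groups):
            raise ValueError("diseased_groups out of range")

    @property
    def n_groups(self) -> int:
        return len(self.mu10)

    def spec(self, variance: str = "shared") -> ModelSpec:
        return ModelSpec(
            mean_model="compartment",
            production=self.production,
            n_groups=self.n_groups,
            variance=variance,
        )

    def group_params(self, g: int) -> CompartmentParams:
        kind = self.production if (g > 0 and self.production != "none") else "none"
        return CompartmentParams(
            mu10=self.mu10[g], k12=self.k12, k21=self.k21, k10=self.k10,
            A=self.A[g], production=kind,
        )

    def true_structure(self, variance: str = "shared") -> GroupStructure:
        sigma2 = max(self.sigma, 1e-8) ** 2
        return GroupStructure(
            spec=self.spec(variance),
            pi=np.asarray(self.pi),
            sigma2=sigma2 if variance == "shared" else np.full(self.n_groups, sigma2),
            k12=self.k12, k21=self.k21, k10=self.k10,
            mu10=np.asarray(self.mu10), A=np.asarray(self.A),
        )

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "k12": self.k12, "k21": self.k21, "k10": self.k10,
            "mu10": list(self.mu10), "A": list(self.A), "pi": list(self.pi),
            "sigma": self.sigma, "production": self.production,
            "count_probs": [list(cp) for cp in self.count_probs],
            "first_day_max": self.first_day_max,
            "gap_min": self.gap_min, "gap_max": self.gap_max,
            "horizon": self.horizon,
            "diseased_groups": list(self.diseased_groups),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("mu10", "A", "pi", "diseased_groups"):
            if key in d:
                d[key] = tuple(d[key])
        if "count_probs" in d:
            d["count_probs"] = tuple((int(c), float(p)) for c, p in d["count_probs"])
        return cls(**d)


def canonical_scenario(**overrides) -> ScenarioConfig:
    """The frozen reference scenario (module docstring); overridable fields."""
    return replace(ScenarioConfig(), **overrides) if overrides else ScenarioConfig()


@dataclass(frozen=True)
class CohortTruth:
    """Hidden generating record: true group per subject and true structure."""

    z: np.ndarray
    structure: GroupStructure


def _sample_times(scenario: ScenarioConfig, m: int, rng) -> np.ndarray:
    """Roughly weekly schedule: first visit in [0, 3] days, gaps ~ U(4, 9),
    compressed proportionally when the last visit would pass the horizon."""
    t0 = rng.uniform(0.0, scenario.first_day_max)
    gaps = rng.uniform(scenario.gap_min, scenario.gap_max, size=m - 1)
    t = t0 + np.concatenate(([0.0], np.cumsum(gaps)))
    if t[-1] > scenario.horizon:
        span = (scenario.horizon - t0) * rng.uniform(0.96, 1.0)
        t = t0 + (t - t0) * span / (t[-1] - t0)
    return t


def simulate_cohort(scenario: ScenarioConfig, rng) -> tuple:
    """Draw one cohort; returns (public Cohort, hidden CohortTruth).

    Groups are multinomial in pi; log measurements are the group mean
    log-trajectory (analytic compartment solution) plus N(0, sigma^2)
    noise, exponentiated back to IU/L.  The truth record never travels
    with the public cohort.
    """
    G = scenario.n_groups
    n = scenario.n_subjects
    z = rng.choice(G, size=n, p=np.asarray(scenario.pi))
    counts = np.array([c for c, _ in scenario.count_probs])
    probs = np.array([p for _, p in scenario.count_probs])
    m_per = rng.choice(counts, size=n, p=probs / probs.sum())
    times = [_sample_times(scenario, m, rng) for m in m_per]

    # one analytic solve per group over its subjects' pooled times
    mean_log = [None] * n
    for g in range(G):
        subj = np.where(z == g)[0]
        if len(subj) == 0:
            continue
        pooled = np.concatenate([times[i] for i in subj])
        mu = solve_compartment(scenario.group_params(g), pooled)
        if np.any(mu <= 0):
            raise ValueError("scenario yields non-positive mean concentration")
        logs = np.log(mu)
        pos = 0
        for i in subj:
            mean_log[i] = logs[pos : pos + m_per[i]]
            pos += m_per[i]

    width = len(str(n))
    trajectories = []
    for i in range(n):
        y = mean_log[i] + scenario.sigma * rng.standard_normal(m_per[i])
        trajectories.append(
            Trajectory(
                subject_id=f"S{i:0{width}d}",
                measurements=tuple(
                    Measurement(time=float(t), value=float(np.exp(v)))
                    for t, v in zip(times[i], y)
                ),
                disease_label=int(z[i] in scenario.diseased_groups),
            )
        )
    return Cohort(tuple(trajectories)), CohortTruth(z=z, structure=scenario.true_structure())


@dataclass
class SimulationReport:
    """Aggregate of a replicate study: error rate and parameter bias.

    ``relative_bias`` maps parameter names to the mean of
    100*(estimate - truth)/truth across successful replicates, after
    aligning estimated to true groups by ascending mean log-trajectory
    (the same ordering the fitter maintains internally).
    """

    error_rates: list
    relative_bias: dict
    n_replicates: int
    n_failed: int
    records: list = field(default_factory=list)

    @property
    def mean_error_rate(self) -> float:
        return float(np.mean(self.error_rates))

    def max_abs_bias(self, params: Sequence[str]) -> float:
        return float(max(abs(self.relative_bias[p]) for p in params))

    def to_dict(self) -> dict:
        return {
            "error_rates": [float(e) for e in self.error_rates],
            "mean_error_rate": self.mean_error_rate,
            "relative_bias": {k: float(v) for k, v in self.relative_bias.items()},
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
        }


def _replicate_seed(base_seed: int, r: int) -> int:
    return int((base_seed * 100003 + 7919 * r + 1) % (2**31 - 1))


def _bias_record(structure: GroupStructure, scenario: ScenarioConfig) -> dict:
    rec = {
        "k12": 100.0 * (structure.k12 - scenario.k12) / scenario.k12,
        "k21": 100.0 * (structure.k21 - scenario.k21) / scenario.k21,
        "k10": 100.0 * (structure.k10 - scenario.k10) / scenario.k10,
    }
    for g in range(scenario.n_groups):
        rec[f"mu10_{g + 1}"] = (
            100.0 * (structure.mu10[g] - scenario.mu10[g]) / scenario.mu10[g]
        )
        if g > 0 and scenario.A[g] > 0:
            rec[f"A_{g + 1}"] = 100.0 * (structure.A[g] - scenario.A[g]) / scenario.A[g]
    return rec


def run_simulation_study(
    scenario: ScenarioConfig,
    n_replicates: int,
    fit_config: FitConfig,
    base_seed: int = 1,
) -> SimulationReport:
    """Replicate (simulate -> fit -> compare-to-truth) study.

    Estimated groups need no explicit matching step: both the generator's
    groups and the fitter's labels are ordered by ascending trajectory
    level, so label g compares to truth g directly.  Replicates whose fit
    fails are excluded and counted in ``n_failed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    spec = scenario.spec()
    error_rates, bias_rows, records = [], [], []
    n_failed = 0
    for r in range(n_replicates):
        seed = _replicate_seed(base_seed, r)
        rng = np.random.default_rng(seed)
        cohort, truth = simulate_cohort(scenario, rng)
        try:
            fit = cem_fit(cohort, spec, replace(fit_config, seed=seed))
        except Exception as exc:
            n_failed += 1
            records.append({"replicate": r, "seed": seed, "error": str(exc)})
            continue
        err = 100.0 * float(np.mean(fit.assignment.z != truth.z))
        bias = _bias_record(fit.structure, scenario)
        error_rates.append(err)
        bias_rows.append(bias)
        records.append(
            {"replicate": r, "seed": seed, "error_rate": err, "bias": bias,
             "converged": fit.converged, "lc": fit.loglik_c}
        )
    if not error_rates:
        raise RuntimeError("all replicates failed")
    mean_bias = {
        k: float(np.mean([row[k] for row in bias_rows])) for k in bias_rows[0]
    }
    return SimulationReport(
        error_rates=error_rates,
        relative_bias=mean_bias,
        n_replicates=n_replicates,
        n_failed=n_failed,
        records=records,
    )


def monotonicity_sweep(
    base_scenario: ScenarioConfig,
    sigma_grid: Sequence[float],
    n_grid: Sequence[int],
    n_replicates: int,
    fit_config: FitConfig,
    base_seed: int = 1,
) -> pd.DataFrame:
    """Mean error rate over a (sigma, n) grid.

    The expectation: error weakly increases with the residual noise and
    weakly decreases with the sample size, up to Monte-Carlo wobble.
    """
    rows = []
    for si, sigma in enumerate(sigma_grid):
        for ni, n in enumerate(n_grid):
            scenario = replace(base_scenario, sigma=float(sigma), n_subjects=int(n))
            cell_seed = base_seed + 1009 * (si * len(n_grid) + ni)
            report = run_simulation_study(
                scenario, n_replicates, fit_config, base_seed=cell_seed
            )
            rows.append(
                {
                    "sigma": float(sigma),
                    "n_subjects": int(n),
                    "mean_error_rate": report.mean_error_rate,
                    "n_failed": report.n_failed,
                }
            )
    return pd.DataFrame(rows)
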