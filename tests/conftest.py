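"""Shared fixtures: small synthetic cohorts built from known truth."""
from __future__ import annotations

import numpy as np
import pytest

from kinclust.kinetic_models import CompartmentParams, ModelSpec, solve_compartment
from kinclust.trajectory_data import Cohort, Measurement, Trajectory


def build_cohort(group_params, n_per_group, times, sigma, rng, labels_from_group=None):
    """Cohort sampled around the given group mean trajectories.

    Returns (cohort, true_group_per_subject).  ``labels_from_group`` maps a
    group index to a 0/1 disease label when labeled subjects are needed.
    """
    times = np.asarray(times, dtype=float)
    trajs, z = [], []
    i = 0
    for g, p in enumerate(group_params):
        mean_log = np.log(solve_compartment(p, times))
        for _ in range(n_per_group[g]):
            y = mean_log + sigma * rng.standard_normal(len(times))
            label = None if labels_from_group is None else labels_from_group[g]
            trajs.append(
                Trajectory(
                    subject_id=f"s{i:04d}",
                    measurements=tuple(
                        Measurement(float(t), float(np.exp(v)))
                        for t, v in zip(times, y)
                    ),
                    disease_label=label,
                )
            )
            z.append(g)
            i += 1
    return Cohort(tuple(trajs)), np.array(z)


# two groups with a 5-unit gap in initial log level: essentially separable
LOW_GROUP = CompartmentParams(mu10=100.0, k12=0.7, k21=0.25, k10=0.6)
HIGH_GROUP = CompartmentParams(mu10=100.0 * np.exp(5.0), k12=0.7, k21=0.25, k10=0.6)
TWO_GROUP_SPEC = ModelSpec("compartment", "none", 2, "shared")


@pytest.fixture(scope="session")
def separated_cohort():
    rng = np.random.default_rng(42)
    cohort, z = build_cohort(
        [LOW_GROUP, HIGH_GROUP], [30, 30], [0, 4, 9, 14, 20], 0.3, rng
    )
    return cohort, z


@pytest.fixture(scope="session")
def labeled_separated_cohort():
    rng = np.random.default_rng(43)
    cohort, z = build_cohort(
        [LOW_GROUP, HIGH_GROUP],
        [44, 20],
        [0, 4, 9, 14, 20],
        0.3,
        rng,
        labels_from_group={0: 0, 1: 1},
    )
    return cohort, z
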