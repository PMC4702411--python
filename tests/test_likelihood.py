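"""Densities, classification log-likelihood, posteriors and criteria."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from kinclust.kinetic_models import CompartmentParams, ModelSpec, solve_compartment
from kinclust.likelihood import (
    Assignment,
    GroupStructure,
    classification_loglik,
    count_free_parameters,
    information_criteria,
    log_density_group,
    log_density_matrix,
    posterior_matrix,
    posterior_membership,
)
from kinclust.trajectory_data import Cohort, Measurement, Trajectory

SPEC2 = ModelSpec("compartment", "none", 2, "shared")


def structure_2g(sigma2=1.0, pi=(0.5, 0.5), mu10=(100.0, 14841.3)):
    return GroupStructure(
        spec=SPEC2,
        pi=np.array(pi),
        sigma2=sigma2,
        k12=0.7,
        k21=0.25,
        k10=0.6,
        mu10=np.array(mu10),
        A=np.zeros(2),
    )


def on_mean_trajectory(structure, g, times, subject_id="x"):
    mu = solve_compartment(structure.compartment_params(g), np.asarray(times, float))
    return Trajectory(
        subject_id,
        tuple(Measurement(float(t), float(v)) for t, v in zip(times, mu)),
    )


class TestLogDensity:
    def test_on_mean_measurements(self):
        # each exactly-on-mean point contributes -0.5*ln(2*pi) at sigma2=1
        s = structure_2g(sigma2=1.0)
        traj = on_mean_trajectory(s, 0, [0.0, 5.0])
        got = log_density_group(traj, 0, s)
        assert got == pytest.approx(-math.log(2 * math.pi), abs=1e-10)

    def test_additivity_over_measurements(self):
        s = structure_2g(sigma2=1.0)
        t2 = on_mean_trajectory(s, 0, [0.0, 5.0])
        t4 = on_mean_trajectory(s, 0, [0.0, 5.0, 9.0, 13.0])
        assert log_density_group(t4, 0, s) == pytest.approx(
            2 * log_density_group(t2, 0, s), abs=1e-10
        )

    def test_matches_multivariate_normal_oracle(self):
        rng = np.random.default_rng(11)
        s = structure_2g(sigma2=0.37)
        times = np.array([0.0, 3.0, 8.0, 15.0])
        mean = np.log(solve_compartment(s.compartment_params(1), times))
        y = mean + rng.normal(size=4)
        traj = Trajectory(
            "o", tuple(Measurement(float(t), float(np.exp(v))) for t, v in zip(times, y))
        )
        oracle = multivariate_normal(mean=mean, cov=0.37 * np.eye(4)).logpdf(y)
        assert log_density_group(traj, 1, s) == pytest.approx(oracle, abs=1e-12)

    def test_matrix_matches_per_subject_calls(self, separated_cohort):
        cohort, _ = separated_cohort
        s = structure_2g(sigma2=0.5)
        mat = log_density_matrix(cohort.flat(), s)
        for i in (0, 17, 45):
            for g in (0, 1):
                assert mat[i, g] == pytest.approx(
                    log_density_group(cohort.trajectories[i], g, s), rel=1e-12
                )


class TestClassificationLoglik:
    def test_single_group_reduces_to_density(self):
        spec1 = ModelSpec("compartment", "none", 1, "shared")
        s = GroupStructure(
            spec=spec1, pi=np.array([1.0]), sigma2=0.5,
            k12=0.7, k21=0.25, k10=0.6, mu10=np.array([500.0]), A=np.zeros(1),
        )
        traj = on_mean_trajectory(s, 0, [0.0, 6.0])
        cohort = Cohort((traj,))
        assert classification_loglik(cohort, np.array([0]), s) == pytest.approx(
            log_density_group(traj, 0, s)
        )

    def test_additivity_over_subjects(self, separated_cohort):
        cohort, z = separated_cohort
        s = structure_2g(sigma2=0.4)
        lc = classification_loglik(cohort, z, s)
        doubled = Cohort(
            tuple(cohort.trajectories)
            + tuple(
                Trajectory(t.subject_id + "_b", t.measurements)
                for t in cohort.trajectories
            )
        )
        lc2 = classification_loglik(doubled, np.concatenate([z, z]), s)
        assert lc2 == pytest.approx(2 * lc, rel=1e-12)

    def test_hand_computed_sum(self):
        s = structure_2g(sigma2=0.8, pi=(0.3, 0.7))
        rng = np.random.default_rng(3)
        times = [0.0, 7.0, 14.0]
        trajs, z = [], [0, 1, 1]
        for i, g in enumerate(z):
            mean = np.log(solve_compartment(s.compartment_params(g), np.array(times)))
            y = mean + 0.5 * rng.normal(size=3)
            trajs.append(
                Trajectory(
                    f"h{i}",
                    tuple(Measurement(t, float(np.exp(v))) for t, v in zip(times, y)),
                )
            )
        cohort = Cohort(tuple(trajs))
        expected = sum(
            math.log(s.pi[g]) + log_density_group(trajs[i], g, s)
            for i, g in enumerate(z)
        )
        assert classification_loglik(cohort, np.array(z), s) == pytest.approx(
            expected, abs=1e-12
        )

    def test_cstep_assignment_maximizes_lc_over_all_assignments(self, separated_cohort):
        """Exhaustive check on 6 subjects: the argmax C-step assignment
        dominates every other hard assignment under the same parameters."""
        cohort, _ = separated_cohort
        small = cohort.subset(range(27, 33))  # straddles both groups
        s = structure_2g(sigma2=0.4)
        tau = posterior_matrix(small.flat(), s)
        z_star = np.argmax(tau, axis=1)
        lc_star = classification_loglik(small, z_star, s)
        for bits in itertools.product([0, 1], repeat=6):
            lc = classification_loglik(small, np.array(bits), s)
            assert lc <= lc_star + 1e-9


class TestPosteriors:
    def test_identical_groups_return_prior(self):
        s = structure_2g(sigma2=1.0, pi=(0.5, 0.5), mu10=(100.0, 100.0))
        traj = on_mean_trajectory(s, 0, [0.0, 5.0])
        np.testing.assert_allclose(posterior_membership(traj, s), [0.5, 0.5])
        s2 = structure_2g(sigma2=1.0, pi=(0.9, 0.1), mu10=(100.0, 100.0))
        np.testing.assert_allclose(posterior_membership(traj, s2), [0.9, 0.1])

    def test_matches_raw_density_bayes(self):
        s = structure_2g(sigma2=0.6, pi=(0.4, 0.6))
        rng = np.random.default_rng(8)
        times = np.array([0.0, 6.0, 12.0])
        mean = np.log(solve_compartment(s.compartment_params(0), times))
        y = mean + 0.4 * rng.normal(size=3)
        traj = Trajectory(
            "p", tuple(Measurement(float(t), float(np.exp(v))) for t, v in zip(times, y))
        )
        raw = np.array(
            [s.pi[g] * math.exp(log_density_group(traj, g, s)) for g in (0, 1)]
        )
        np.testing.assert_allclose(
            posterior_membership(traj, s), raw / raw.sum(), atol=1e-10
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        mu = np.sort(10 ** rng.uniform(2, 5, size=2))
        pi1 = rng.uniform(0.05, 0.95)
        s = structure_2g(
            sigma2=rng.uniform(0.05, 2.0), pi=(pi1, 1 - pi1), mu10=tuple(mu)
        )
        times = np.array([0.0, 5.0, 11.0])
        y = rng.uniform(2, 12, size=3)
        traj = Trajectory(
            "q", tuple(Measurement(float(t), float(np.exp(v))) for t, v in zip(times, y))
        )
        tau = posterior_membership(traj, s)
        assert abs(tau.sum() - 1.0) < 1e-12


class TestParameterCounting:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (ModelSpec("biexp", "none", 4, "shared"), 20),  # 4*4 + 1 + 3
            (ModelSpec("compartment", "constant", 4, "shared"), 14),  # 3+4+3+1+3
            (ModelSpec("compartment", "constant", 2, "per_group"), 9),  # 3+2+1+2+1
            (ModelSpec("compartment", "linear", 3, "shared"), 11),
            (ModelSpec("compartment", "none", 2, "shared"), 7),
        ],
    )
    def test_convention(self, spec, expected):
        assert count_free_parameters(spec) == expected


class TestInformationCriteria:
    def test_closed_forms(self):
        crit = information_criteria(0.0, 1, math.e**2)
        assert crit["BIC"] == pytest.approx(2.0)
        assert information_criteria(-100.0, 5, 10)["AIC"] == pytest.approx(210.0)

    def test_icl_equals_bic_under_hard_assignments(self):
        crit = information_criteria(-50.0, 3, 40, loglik_c=-50.0)
        assert crit["ICL"] == pytest.approx(crit["BIC"])

    def test_icl_penalizes_classification_likelihood(self):
        crit = information_criteria(-50.0, 3, 40, loglik_c=-60.0)
        assert crit["ICL"] == pytest.approx(crit["BIC"] + 20.0)


class TestStructuralConstraints:
    def test_shared_kinetics_single_slot(self):
        s = structure_2g()
        # one storage slot: both groups necessarily see the same rates
        assert s.compartment_params(0).k12 == s.compartment_params(1).k12 == s.k12

    def test_lowest_group_production_pinned_to_zero(self):
        spec = ModelSpec("compartment", "constant", 2, "shared")
        s = GroupStructure(
            spec=spec, pi=np.array([0.5, 0.5]), sigma2=1.0,
            k12=0.7, k21=0.25, k10=0.6,
            mu10=np.array([100.0, 1000.0]), A=np.array([5.0, 50.0]),
        )
        # group 0's production is structurally ignored even if the slot is set
        assert s.compartment_params(0).effective_A == 0.0
        assert s.compartment_params(1).effective_A == 50.0

    def test_pi_must_be_simplex(self):
        with pytest.raises(ValueError):
            structure_2g(pi=(0.5, 0.6))
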