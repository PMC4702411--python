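"""The SEM-initialized CEM algorithm: steps, convergence, determinism."""
import numpy as np
import pytest
from sklearn.metrics import rand_score

from kinclust.cem_engine import (
    perturb_partition,
    DegenerateVarianceError,
    EmptyGroupError,
    FitConfig,
    c_step,
    cem_fit,
    e_step,
    m_step,
    perturb_and_refit,
    sem_initialize,
    stochastic_c_step,
)
from kinclust.kinetic_models import CompartmentParams, ModelSpec
from kinclust.likelihood import classification_loglik, mixture_loglik
from kinclust.trajectory_data import Cohort, Measurement, Trajectory

from conftest import HIGH_GROUP, LOW_GROUP, TWO_GROUP_SPEC, build_cohort

CONFIG = FitConfig(sem_iterations=25, seed=0)


def assert_monotone_trace(trace):
    trace = np.asarray(trace)
    scale = np.maximum(np.abs(trace[:-1]), 1.0)
    assert np.all(np.diff(trace) >= -1e-9 * scale)


class TestMStep:
    def test_recovers_mono_exponential_truth(self):
        rng = np.random.default_rng(5)
        truth = CompartmentParams(mu10=1000.0, k12=0.0, k21=0.0, k10=0.2)
        cohort, _ = build_cohort([truth], [20], [0, 3, 7, 14, 21], 1e-6, rng)
        spec = ModelSpec("compartment", "none", 1, "shared")
        st = m_step(cohort, np.zeros(20, int), spec, CONFIG)
        # k12 drifts to ~0 (boundary) so only the identified parameters
        assert st.mu10[0] == pytest.approx(1000.0, rel=1e-4)
        assert st.k10 == pytest.approx(0.2, rel=1e-4)

    def test_mixing_weights_are_group_fractions(self, separated_cohort):
        cohort, z = separated_cohort
        st = m_step(cohort, z, TWO_GROUP_SPEC, CONFIG)
        np.testing.assert_allclose(st.pi, [0.5, 0.5])

    def test_registry_scale_mixing_weights(self):
        # group sizes 700/353 out of 1053 subjects -> pi = (0.6648, 0.3352)
        rng = np.random.default_rng(12)
        cohort, _ = build_cohort(
            [LOW_GROUP, HIGH_GROUP], [700, 353], [0, 7, 14], 0.3, rng
        )
        z = np.repeat([0, 1], [700, 353])
        st = m_step(cohort, z, TWO_GROUP_SPEC, CONFIG)
        np.testing.assert_allclose(st.pi, [0.6648, 0.3352], atol=5e-5)

    def test_empty_group_rejected(self, separated_cohort):
        cohort, _ = separated_cohort
        with pytest.raises(EmptyGroupError):
            m_step(cohort, np.zeros(cohort.n_subjects, int), TWO_GROUP_SPEC, CONFIG)

    def test_zero_residuals_degenerate_variance(self):
        # identical, exactly interpolable subjects leave zero residual
        trajs = tuple(
            Trajectory(f"d{i}", (Measurement(0.0, 1000.0), Measurement(7.0, 500.0)))
            for i in range(3)
        )
        spec = ModelSpec("compartment", "none", 1, "shared")
        with pytest.raises(DegenerateVarianceError, match="noise floor"):
            m_step(Cohort(trajs), np.zeros(3, int), spec, CONFIG)

    def test_biexp_groups_fitted_independently(self, separated_cohort):
        cohort, z = separated_cohort
        spec = ModelSpec("biexp", "none", 2, "shared")
        st_joint = m_step(cohort, z, spec, CONFIG)
        # refit group 0 alone: identical coefficients (no cross-group ties)
        idx0 = np.where(z == 0)[0]
        sub = cohort.subset(idx0)
        spec1 = ModelSpec("biexp", "none", 1, "shared")
        st_alone = m_step(sub, np.zeros(len(idx0), int), spec1, CONFIG)
        np.testing.assert_allclose(st_alone.biexp[0], st_joint.biexp[0], rtol=1e-6)

    def test_per_group_variance_estimates(self, separated_cohort):
        cohort, z = separated_cohort
        spec = ModelSpec("compartment", "none", 2, "per_group")
        st = m_step(cohort, z, spec, CONFIG)
        assert st.sigma2.shape == (2,)
        # generator noise sd = 0.3 in both groups
        np.testing.assert_allclose(np.sqrt(st.sigma2), 0.3, atol=0.08)


class TestESCSteps:
    def test_e_step_equivariant_and_matches_loop(self, separated_cohort):
        cohort, z = separated_cohort
        st = m_step(cohort, z, TWO_GROUP_SPEC, CONFIG)
        tau = e_step(cohort.flat(), st)
        assert tau.shape == (cohort.n_subjects, 2)
        np.testing.assert_allclose(tau.sum(axis=1), 1.0, atol=1e-12)
        perm = np.random.default_rng(1).permutation(cohort.n_subjects)
        permuted = cohort.subset(perm)
        np.testing.assert_allclose(e_step(permuted.flat(), st), tau[perm], rtol=1e-10)

    def test_c_step_argmax_and_ties(self):
        post = np.array([[0.2, 0.5, 0.3], [0.5, 0.5, 0.0], [0.1, 0.2, 0.7]])
        np.testing.assert_array_equal(c_step(post).z, [1, 0, 2])

    def test_stochastic_c_step_degenerate_row(self):
        rng = np.random.default_rng(0)
        post = np.tile([1.0, 0.0], (50, 1))
        assert np.all(stochastic_c_step(post, rng).z == 0)

    def test_stochastic_c_step_frequencies(self):
        rng = np.random.default_rng(7)
        post = np.tile([0.5, 0.5], (10_000, 1))
        freq = np.mean(stochastic_c_step(post, rng).z == 0)
        assert abs(freq - 0.5) < 3 * 0.005  # 3 SE of a fair binomial

    def test_stochastic_c_step_seeded(self):
        post = np.random.default_rng(3).dirichlet([1, 1, 1], size=200)
        z1 = stochastic_c_step(post, np.random.default_rng(55)).z
        z2 = stochastic_c_step(post, np.random.default_rng(55)).z
        np.testing.assert_array_equal(z1, z2)


class TestSemInitialize:
    def test_recovers_separated_groups(self, separated_cohort):
        cohort, z_true = separated_cohort
        st, a, _ = sem_initialize(
            cohort.flat(), TWO_GROUP_SPEC, CONFIG, np.random.default_rng(3)
        )
        assert rand_score(z_true, a.z) >= 0.95

    def test_zero_iterations_is_initial_m_step(self, separated_cohort):
        cohort, _ = separated_cohort
        cfg = FitConfig(sem_iterations=0, seed=9)
        rng = np.random.default_rng(9)
        st, a, trace = sem_initialize(cohort.flat(), TWO_GROUP_SPEC, cfg, rng)
        assert len(trace) == 1  # just the fit of the initial random partition

    def test_seeded_determinism(self, separated_cohort):
        cohort, _ = separated_cohort
        out = []
        for _ in range(2):
            st, a, _ = sem_initialize(
                cohort.flat(), TWO_GROUP_SPEC, CONFIG, np.random.default_rng(17)
            )
            out.append((st, a.z))
        np.testing.assert_array_equal(out[0][1], out[1][1])
        np.testing.assert_array_equal(out[0][0].mu10, out[1][0].mu10)


class TestCemFit:
    def test_separated_cohort_classified(self, separated_cohort):
        cohort, z_true = separated_cohort
        fit = cem_fit(cohort, TWO_GROUP_SPEC, CONFIG)
        assert fit.converged
        assert 100 * np.mean(fit.assignment.z != z_true) < 5.0
        assert_monotone_trace(fit.lc_trace)
        assert fit.group_sizes.sum() == cohort.n_subjects

    def test_single_group_reduces_to_joint_nls(self, separated_cohort):
        cohort, _ = separated_cohort
        sub = cohort.subset(range(30))  # one homogeneous group
        spec1 = ModelSpec("compartment", "none", 1, "shared")
        fit = cem_fit(sub, spec1, CONFIG)
        # with G=1 and pi=1 the classification and mixture likelihoods agree
        assert fit.loglik_c == pytest.approx(mixture_loglik(sub.flat(), fit.structure))

    def test_seeded_determinism(self, separated_cohort):
        cohort, _ = separated_cohort
        f1 = cem_fit(cohort, TWO_GROUP_SPEC, CONFIG)
        f2 = cem_fit(cohort, TWO_GROUP_SPEC, CONFIG)
        np.testing.assert_array_equal(f1.assignment.z, f2.assignment.z)
        assert f1.criteria == f2.criteria

    def test_groups_ordered_by_trajectory_level(self, separated_cohort):
        cohort, _ = separated_cohort
        fit = cem_fit(cohort, TWO_GROUP_SPEC, CONFIG)
        stat = fit.structure.level_order_stat()
        assert np.all(np.diff(stat) > 0)

    def test_cohort_too_small_rejected(self, separated_cohort):
        cohort, _ = separated_cohort
        with pytest.raises(ValueError, match="too small"):
            cem_fit(cohort.subset([0, 1, 2]), TWO_GROUP_SPEC, CONFIG)


class TestPerturbAndRefit:
    def test_deep_separation_is_stable(self, separated_cohort):
        cohort, _ = separated_cohort
        fit = cem_fit(cohort, TWO_GROUP_SPEC, CONFIG)
        rep = perturb_and_refit(
            cohort, TWO_GROUP_SPEC, CONFIG, fit, n_moved_per_group=5,
            rng=np.random.default_rng(2),
        )
        assert rep["n_changed"] == 0
        # both runs stop within the CEM tolerance of the same optimum
        assert abs(rep["lc_difference"]) < 1e-4 * abs(fit.loglik_c)

    def test_zero_moves_identical_refit(self, separated_cohort):
        cohort, _ = separated_cohort
        fit = cem_fit(cohort, TWO_GROUP_SPEC, CONFIG)
        rep = perturb_and_refit(
            cohort, TWO_GROUP_SPEC, CONFIG, fit, n_moved_per_group=0,
            rng=np.random.default_rng(2),
        )
        assert rep["n_changed"] == 0

    def test_small_group_keeps_one_member(self):
        # requesting more moves than a group holds moves all but one
        z = np.repeat([0, 1, 2], [4, 25, 25])
        z0 = perturb_partition(z, 3, 10, np.random.default_rng(4))
        kept = [np.sum((z == g) & (z0 == g)) for g in range(3)]
        assert kept[0] == 1  # 4-member group loses 3
        assert kept[1] == 15 and kept[2] == 15
        np.testing.assert_array_equal(np.sort(np.unique(z0)), [0, 1, 2])
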