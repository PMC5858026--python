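"""Hierarchical group model: diagnostics, recovery, difference and correlation."""

import numpy as np
import pytest

from hmetad.fit_hierarchical import (
    HierModelSpec,
    calc_ci,
    calc_hdi,
    dic,
    fit_group,
    fit_group_correlation,
    group_difference,
    rhat,
)
from hmetad.fit_point import fit_mle
from hmetad.sdt_core import ConfidenceCounts
from hmetad.simulate import GroupSimSpec, simulate_correlated_group, simulate_group

SMALL = dict(n_samples=1_500, n_burnin=600)


class TestRhat:
    def test_identical_constant_chains_return_one(self):
        assert rhat(np.ones((3, 100))) == 1.0

    def test_iid_chains_stay_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 10_000))
        assert 1.0 <= rhat(x) <= 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 5_000))
        x[1] += 10.0
        assert rhat(x) > 5.0

    def test_requires_multiple_chains(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestIntervals:
    def test_ci_percentile_convention(self):
        s = np.arange(1, 1001, dtype=float)
        ci = calc_ci(s)
        assert ci.lo == pytest.approx(25.975, abs=1e-9)
        assert ci.hi == pytest.approx(975.025, abs=1e-9)

    def test_symmetric_samples_ci_close_to_hdi(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=100_000)
        ci, hdi = calc_ci(s), calc_hdi(s)
        assert ci.lo == pytest.approx(hdi.lo, abs=0.05)
        assert ci.hi == pytest.approx(hdi.hi, abs=0.05)

    def test_skewed_samples_hdi_shorter_than_ci(self):
        rng = np.random.default_rng(3)
        s = rng.exponential(size=100_000)
        ci, hdi = calc_ci(s), calc_hdi(s)
        assert (hdi.hi - hdi.lo) < (ci.hi - ci.lo)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            calc_ci(np.arange(10))


class TestDIC:
    def test_constant_deviance_gives_zero_complexity(self):
        assert dic(np.full(500, 42.0), 42.0) == pytest.approx(42.0)

    def test_conjugate_normal_mean_effective_parameters(self):
        # y_i ~ N(theta, 1), flat prior: p_D = 1 exactly in expectation
        rng = np.random.default_rng(4)
        y = rng.normal(0.0, 1.0, 50)
        theta = rng.normal(y.mean(), 1.0 / np.sqrt(50), 100_000)
        deviance = ((y[None, :] - theta[:, None]) ** 2).sum(axis=1)
        d_at_mean = ((y - theta.mean()) ** 2).sum()
        p_d = np.mean(deviance) - d_at_mean
        assert p_d == pytest.approx(1.0, abs=0.1)
        assert dic(deviance, d_at_mean) == pytest.approx(d_at_mean + 2 * p_d, abs=1e-9)


@pytest.fixture(scope="module")
def example_post():
    data = simulate_group(GroupSimSpec(n_subjects=20, n_trials=400, mratio=0.8, seed=11))
    return fit_group(data, HierModelSpec(n_samples=2_500, n_burnin=600, seed=1))


class TestFitGroup:
    def test_example_conditions_recover_efficiency(self, example_post):
        assert example_post.mean_mratio == pytest.approx(0.8, abs=0.1)
        assert example_post.ci_mratio().contains(0.8)
        assert float(np.max(example_post.rhat["mu_logMratio"])) < 1.1

    def test_parameter_expansion_identities(self, example_post):
        s = example_post.samples
        logm = s["mu_logMratio"][..., None] + s["xi"][..., None] * s["delta"]
        np.testing.assert_allclose(logm, s["logMratio"], atol=1e-10)
        np.testing.assert_allclose(
            s["sigma_logMratio"], np.abs(s["xi"]) * s["sigma_delta"], atol=1e-12
        )
        assert (s["sigma_logMratio"] >= 0).all()

    def test_criteria_ordering_holds_in_every_draw(self, example_post):
        s = example_post.samples
        meta_c = np.exp(s["logMratio"]) * example_post.c
        assert (s["cS1"][..., -1] <= meta_c + 1e-12).all()
        assert (s["cS2"][..., 0] >= meta_c - 1e-12).all()
        assert (np.diff(s["cS1"], axis=-1) >= 0).all()
        assert (np.diff(s["cS2"], axis=-1) >= 0).all()

    def test_subject_posteriors_track_mle_at_large_n(self):
        data = simulate_group(
            GroupSimSpec(n_subjects=2, n_trials=20_000, d_prime_sd=0.0, mratio=0.9, seed=5)
        )
        post = fit_group(data, HierModelSpec(seed=2, **SMALL))
        mle_logs = np.log([fit_mle(c).mratio for c in data])
        post_logs = post.pooled("logMratio").mean(axis=0)
        np.testing.assert_allclose(post_logs, mle_logs, atol=0.05)

    def test_near_empty_data_returns_the_prior(self):
        # d' estimates are 0 for flat counts, so the likelihood carries no
        # information about efficiency and mu_M must reproduce its N(0,1) prior
        flat = [ConfidenceCounts(nR_S1=[1, 1, 1, 1], nR_S2=[1, 1, 1, 1]) for _ in range(3)]
        post = fit_group(flat, HierModelSpec(n_samples=4_000, n_burnin=800, seed=4))
        mu = post.pooled("mu_logMratio")
        q = np.percentile(mu, [25, 50, 75])
        assert np.abs(q[1]) < 0.15
        assert q[2] - q[0] == pytest.approx(2 * 0.6745, abs=0.2)  # N(0,1) IQR

    def test_zero_high_confidence_error_cells_fit_without_padding(self):
        data = simulate_group(
            GroupSimSpec(n_subjects=8, d_prime_mean=3.0, d_prime_sd=0.1, n_trials=60, mratio=0.8, seed=6)
        )
        assert any((c.nR_S1[c.k :] == 0).any() or (c.nR_S2[: c.k] == 0).any() for c in data)
        post = fit_group(data, HierModelSpec(n_samples=800, n_burnin=300, seed=3))
        assert np.isfinite(post.mean_mratio)
        assert len(post.subjects_used) == 8

    def test_seed_determinism(self):
        data = simulate_group(GroupSimSpec(n_subjects=6, n_trials=100, seed=7))
        spec = HierModelSpec(n_samples=500, n_burnin=200, seed=9)
        a, b = fit_group(data, spec), fit_group(data, spec)
        assert a.mean_mratio == pytest.approx(b.mean_mratio, abs=1e-12)
        assert a.dic == pytest.approx(b.dic, abs=1e-9)

    @pytest.mark.parametrize("level", [0.5, 1.0, 2.0])
    def test_recovery_across_efficiency_levels(self, level):
        covered = 0
        for rep in range(3):
            data = simulate_group(
                GroupSimSpec(n_subjects=20, n_trials=400, mratio=level, seed=1000 * rep + int(level * 10))
            )
            post = fit_group(data, HierModelSpec(seed=rep, **SMALL))
            covered += post.ci_mratio().contains(level)
        assert covered >= 2

    def test_too_few_subjects_rejected(self):
        data = simulate_group(GroupSimSpec(n_subjects=1, seed=0))
        with pytest.raises(ValueError):
            fit_group(data)


class TestGroupDifference:
    def test_identical_posteriors_give_zero_difference(self, example_post):
        diff = group_difference(example_post, example_post)
        assert np.all(diff.samples == 0.0)
        assert not diff.excludes_zero

    def test_detects_simulated_effect(self):
        a = simulate_group(GroupSimSpec(n_subjects=20, n_trials=400, mratio=1.0, seed=21))
        b = simulate_group(GroupSimSpec(n_subjects=20, n_trials=400, mratio=0.6, seed=22))
        post_a = fit_group(a, HierModelSpec(seed=1, **SMALL))
        post_b = fit_group(b, HierModelSpec(seed=2, **SMALL))
        diff = group_difference(post_a, post_b)
        assert diff.excludes_zero
        assert np.mean(diff.samples) > 0  # A more efficient than B, log units

    def test_null_calibration_over_replicates(self):
        # identically simulated groups: the 95% interval should rarely exclude 0
        contained = 0
        reps = 6
        for rep in range(reps):
            a = simulate_group(GroupSimSpec(n_subjects=20, n_trials=400, mratio=1.0, seed=3000 + rep))
            b = simulate_group(GroupSimSpec(n_subjects=20, n_trials=400, mratio=1.0, seed=4000 + rep))
            post_a = fit_group(a, HierModelSpec(seed=rep, **SMALL))
            post_b = fit_group(b, HierModelSpec(seed=100 + rep, **SMALL))
            contained += not group_difference(post_a, post_b).excludes_zero
        assert contained >= reps - 1


class TestCorrelation:
    def test_uncorrelated_tasks_center_on_zero(self):
        d1, d2, _ = simulate_correlated_group(
            n_subjects=30, rho=0.0, c2_S2=[1.0], n_trials=200, seed=31
        )
        post = fit_group_correlation(d1, d2, HierModelSpec(seed=1, **SMALL))
        rho = post.pooled("rho")
        assert calc_ci(rho).contains(0.0)
        assert abs(rho.mean()) < 0.35

    def test_duplicated_task_yields_high_correlation(self):
        d1, _, _ = simulate_correlated_group(
            n_subjects=25, rho=0.3, c2_S2=[1.0], n_trials=200, seed=32
        )
        post = fit_group_correlation(d1, d1, HierModelSpec(seed=2, **SMALL))
        assert np.mean(post.pooled("rho")) > 0.7

    def test_mismatched_subject_counts_rejected(self):
        d1, d2, _ = simulate_correlated_group(n_subjects=6, n_trials=100, seed=33)
        with pytest.raises(ValueError):
            fit_group_correlation(d1, d2[:-1])
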