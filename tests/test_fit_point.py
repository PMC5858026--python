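"""Single-subject MLE and SSE meta-d' fits."""

import numpy as np
import pytest
from scipy.optimize import minimize

from hmetad.fit_point import fit_mle, fit_sse, loglik_type2
from hmetad.sdt_core import ConfidenceCounts, MetaDParams, type2_probs
from hmetad.simulate import GroupSimSpec, SimSpec, metad_sim, simulate_group

from conftest import random_counts, random_metad_params


class TestLoglik:
    def test_all_zero_counts_give_zero(self):
        z = np.zeros(8, dtype=int)
        counts = ConfidenceCounts(nR_S1=z, nR_S2=z.copy())
        params = random_metad_params(np.random.default_rng(0), k=4)
        assert loglik_type2(params, counts) == 0.0

    def test_matches_term_by_term_summation(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            params = random_metad_params(rng)
            counts = random_counts(rng, params.k)
            table = type2_probs(params).p  # independent path through the public table
            k = params.k
            expected = 0.0
            for stim, vec in ((0, counts.nR_S1), (1, counts.nR_S2)):
                for j, n in enumerate(vec):
                    if n == 0:
                        continue
                    resp = 0 if j < k else 1
                    conf = k - j if j < k else j - k + 1
                    expected += n * np.log(table[stim, resp, conf - 1])
            assert loglik_type2(params, counts) == pytest.approx(expected, abs=1e-10)

    def test_true_parameters_maximize_over_meta_d(self):
        # counts exactly proportional to the model probabilities peak at truth
        params = MetaDParams(
            meta_d=1.5, meta_c=0.1, cS1=np.array([-1.0, -0.4]), cS2=np.array([0.6, 1.2])
        )
        cells = type2_probs(params).p
        big = 10_000
        k = params.k
        nR = np.zeros((2, 2 * k))
        for stim in (0, 1):
            nR[stim, :k] = (big * cells[stim, 0])[::-1]
            nR[stim, k:] = 2 * big * cells[stim, 1]
        counts = ConfidenceCounts(nR_S1=np.round(nR[0]).astype(int), nR_S2=np.round(nR[1]).astype(int))
        grid = np.linspace(0.5, 2.5, 81)
        lls = [
            loglik_type2(
                MetaDParams(meta_d=m, meta_c=params.meta_c, cS1=params.cS1, cS2=params.cS2), counts
            )
            for m in grid
        ]
        assert grid[int(np.argmax(lls))] == pytest.approx(1.5, abs=0.05)


def _grid_polish_oracle(counts, padding=0.25):
    """Brute-force reference: coarse grid over meta-d', criteria optimized at
    each node by a generic optimizer, then local polish of the winner."""
    from hmetad.fit_point import _fit, _unpack, loglik_matrix
    from hmetad.sdt_core import type1_stats

    t1 = type1_stats(counts, padding=padding)
    k = counts.k
    nmat = counts.as_matrix() + padding
    anchor = ("relative", t1.c_rel)

    def neg_ll(z, meta_d):
        theta = np.concatenate([[meta_d], z])
        ll = loglik_matrix(nmat, *_unpack(theta, anchor, k))
        return -ll if np.isfinite(ll) else 1e12

    best = (np.inf, None, None)
    for meta_d in np.arange(0.25, 4.01, 0.25):
        res = minimize(neg_ll, np.full(2 * (k - 1), np.log(0.5)), args=(meta_d,), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000})
        if res.fun < best[0]:
            best = (res.fun, meta_d, res.x)
    res = minimize(
        lambda th: neg_ll(th[1:], th[0]),
        np.concatenate([[best[1]], best[2]]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000},
    )
    return res.x[0]


class TestMLE:
    def test_self_recovery_on_ideal_observer(self):
        counts = metad_sim(SimSpec(d_prime=2.0, n_trials=100_000, mratio=1.0, seed=12))
        fit = fit_mle(counts)
        assert fit.converged
        assert fit.mratio == pytest.approx(1.0, abs=0.05)

    def test_tutorial_vectors_match_grid_polish_oracle(self, tutorial_counts):
        fit = fit_mle(tutorial_counts)
        oracle_meta_d = _grid_polish_oracle(tutorial_counts)
        assert fit.params.meta_d == pytest.approx(oracle_meta_d, abs=1e-3)

    def test_constraints_preserved_on_random_data(self):
        rng = np.random.default_rng(3)
        for seed in rng.integers(0, 10_000, 12):
            spec = SimSpec(
                d_prime=float(rng.uniform(0.5, 2.5)),
                c=float(rng.uniform(-0.4, 0.4)),
                n_trials=200,
                mratio=float(rng.uniform(0.4, 1.6)),
                seed=int(seed),
            )
            fit = fit_mle(metad_sim(spec))
            full = np.concatenate([fit.params.cS1, [fit.params.meta_c], fit.params.cS2])
            assert (np.diff(full) >= -1e-9).all()
            assert fit.params.meta_c == pytest.approx(
                fit.type1.c_rel * fit.params.meta_d, abs=1e-6
            )

    def test_group_mean_consistency(self):
        # many subjects with plenty of trials: mean fitted ratio near truth
        data = simulate_group(
            GroupSimSpec(n_subjects=100, n_trials=10_000, mratio=0.8, seed=14)
        )
        ratios = [fit_mle(c).mratio for c in data]
        assert np.mean(ratios) == pytest.approx(0.8, abs=0.03)

    def test_padding_misestimates_at_low_trial_counts(self):
        # 20 trials with sparse high-confidence cells: the 0.25-cell correction
        # pulls the fitted efficiency far from truth (here, downward)
        data = simulate_group(
            GroupSimSpec(
                n_subjects=30, d_prime_mean=2.0, d_prime_sd=0.0,
                c2_S2=np.array([2.0]), n_trials=20, mratio=1.0, seed=15,
            )
        )
        ratios = np.array([fit_mle(c, padding=0.25).mratio for c in data])
        ratios = ratios[np.isfinite(ratios)]
        assert np.mean(ratios) < 0.6  # truth is 1.0


class TestSSE:
    def test_agrees_with_mle_on_large_samples(self):
        counts = metad_sim(SimSpec(d_prime=2.0, n_trials=100_000, mratio=1.0, seed=16))
        assert fit_sse(counts).mratio == pytest.approx(fit_mle(counts).mratio, abs=0.02)

    def test_finite_objective_with_zero_cells(self):
        counts = metad_sim(SimSpec(d_prime=3.0, n_trials=40, mratio=0.8, seed=17))
        fit = fit_sse(counts, padding=0.25)
        assert np.isfinite(fit.logL)

    def test_sse_optimum_no_worse_than_mle_solution(self):
        from hmetad.fit_point import _cond_probs_matrix

        counts = metad_sim(SimSpec(d_prime=1.5, n_trials=80, mratio=0.9, seed=18))
        sse_fit = fit_sse(counts, padding=0.25)
        mle_fit = fit_mle(counts, padding=0.25)

        def sse_value(fit):
            k = counts.k
            nmat = counts.as_matrix() + 0.25
            totals = np.stack([nmat[:, :k].sum(axis=1), nmat[:, k:].sum(axis=1)], axis=1)
            denom = np.concatenate(
                [np.repeat(totals[:, :1], k, axis=1), np.repeat(totals[:, 1:], k, axis=1)], axis=1
            )
            obs = nmat / denom
            model = _cond_probs_matrix(
                np.float64(fit.params.meta_d), np.float64(fit.params.meta_c),
                fit.params.cS1, fit.params.cS2,
            )
            return ((obs - model) ** 2).sum()

        assert sse_value(sse_fit) <= sse_value(mle_fit) + 1e-9
        assert sse_fit.logL == pytest.approx(sse_value(sse_fit), abs=1e-8)
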