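"""DT preprocessing, bimodality analyses, FDR, and permutation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog

from beadsampling.dip import dip_statistic
from beadsampling.stats import (
    cluster_permutation_curve,
    dip_test,
    fit_logdt_mixture,
    preprocess_dts,
    spearman_fdr,
)


def dip_brute_force(x):
    """Independent dip oracle: distance to the closest unimodal cdf.

    For each candidate mode position, a linear program finds the minimal
    band half-width d admitting a monotone convex-then-concave function
    within [F_n - d, F_n + d] at the data points.
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    m = u.size
    cum_at = np.cumsum(counts) / n
    cum_below = cum_at - counts / n
    best = np.inf
    dt = np.diff(u)
    for p in range(m):
        c = np.zeros(m + 1)
        c[-1] = 1.0
        A, b = [], []
        for k in range(m):
            r = np.zeros(m + 1)
            r[k], r[-1] = 1.0, -1.0
            A.append(r)
            b.append(cum_below[k])
            r = np.zeros(m + 1)
            r[k], r[-1] = -1.0, -1.0
            A.append(r)
            b.append(-cum_at[k])
        for k in range(m - 1):
            r = np.zeros(m + 1)
            r[k], r[k + 1] = 1.0, -1.0
            A.append(r)
            b.append(0.0)
        for k in range(m - 2):
            if k + 1 <= p - 1:  # convex region: slope_k <= slope_{k+1}
                r = np.zeros(m + 1)
                r[k] += -1.0 / dt[k]
                r[k + 1] += 1.0 / dt[k] + 1.0 / dt[k + 1]
                r[k + 2] += -1.0 / dt[k + 1]
                A.append(r)
                b.append(0.0)
            if k >= p:  # concave region: slope_k >= slope_{k+1}
                r = np.zeros(m + 1)
                r[k] += 1.0 / dt[k]
                r[k + 1] += -1.0 / dt[k] - 1.0 / dt[k + 1]
                r[k + 2] += 1.0 / dt[k + 1]
                A.append(r)
                b.append(0.0)
        res = linprog(
            c, A_ub=np.array(A), b_ub=np.array(b),
            bounds=[(0.0, 1.0)] * (m + 1), method="highs",
        )
        if res.success and res.fun < best:
            best = res.fun
    return best


class TestDipStatistic:
    def test_known_small_cases(self):
        assert dip_statistic(np.array([0.0, 1.0])) == pytest.approx(0.25)
        # a perfectly spaced grid is as uniform as a sample can be
        assert dip_statistic(np.arange(8.0)) == pytest.approx(1.0 / 16)

    def test_lower_bound_half_jump(self, rng):
        for n in (5, 17, 100):
            x = rng.normal(size=n)
            assert dip_statistic(x) >= 1.0 / (2 * n) - 1e-12

    def test_two_cluster_data_has_large_dip(self):
        x = np.concatenate([np.linspace(0, 0.02, 30), np.linspace(1, 1.02, 30)])
        assert dip_statistic(x) > 0.2

    @given(
        st.lists(
            st.integers(-5000, 5000), min_size=4, max_size=24, unique=True
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_lp_oracle(self, values):
        # milli-spaced grid keeps the LP well conditioned while exercising
        # arbitrary spacing patterns
        x = np.array(values, dtype=float) / 1000.0
        assert dip_statistic(x) == pytest.approx(dip_brute_force(x), abs=1e-6)

    def test_matches_lp_oracle_on_bimodal_samples(self, rng):
        for n in (20, 40):
            x = np.concatenate(
                [rng.normal(-3, 0.5, n // 2), rng.normal(3, 0.5, n - n // 2)]
            )
            assert dip_statistic(x) == pytest.approx(
                dip_brute_force(x), abs=1e-6
            )

    def test_dip_test_calibration(self, rng):
        x = rng.normal(size=800)
        d, p = dip_test(x, n_boot=200, rng=rng)
        assert d >= 0
        assert p > 0.05  # unimodal data should not reject
        bimodal = np.concatenate(
            [rng.normal(-2, 0.4, 400), rng.normal(2, 0.4, 400)]
        )
        _, p_bi = dip_test(bimodal, n_boot=200, rng=rng)
        assert p_bi < 0.01


class TestPreprocessDTs:
    def test_equal_dts_keep_everything(self):
        pool = preprocess_dts([0.5] * 20)
        assert pool.mask.all()

    def test_extreme_point_excluded(self):
        dts = [0.5] * 20 + [0.51] * 20 + [50.0]
        pool = preprocess_dts(dts)
        assert pool.n_excluded == 1
        assert not pool.mask[-1]

    def test_exclusion_idempotent(self, rng):
        dts = np.exp(rng.normal(-0.5, 0.6, 500))
        pool = preprocess_dts(dts)
        lo, hi = pool.fences
        retained = pool.included
        assert np.all((retained >= lo) & (retained <= hi))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            preprocess_dts([0.5, -0.1])
        with pytest.raises(ValueError):
            preprocess_dts([])

    def test_per_participant_mode(self, rng):
        dts = np.exp(rng.normal(0, 0.4, 100))
        pids = ["a"] * 50 + ["b"] * 50
        pool = preprocess_dts(dts, participant=pids, per_participant=True)
        assert pool.mask.shape == (100,)


class TestLogDTMixture:
    def test_recovers_separated_components(self, rng):
        x = np.concatenate([rng.normal(-1.3, 0.3, 800), rng.normal(0.8, 0.4, 400)])
        fit = fit_logdt_mixture(x, rng=0)
        assert fit.means[0] == pytest.approx(-1.3, abs=0.1)
        assert fit.means[1] == pytest.approx(0.8, abs=0.15)
        assert fit.weights.sum() == pytest.approx(1.0)
        assert fit.prefers_two_components

    def test_single_gaussian_prefers_one_component(self, rng):
        x = rng.normal(0.0, 0.5, 1000)
        fit = fit_logdt_mixture(x, rng=0)
        assert not fit.prefers_two_components

    def test_minimum_points(self):
        with pytest.raises(ValueError):
            fit_logdt_mixture(np.ones(5))


class TestSpearmanFDR:
    def test_perfect_monotone_pair(self):
        out = spearman_fdr([(np.arange(10), np.arange(10) ** 2)])
        rho, p_raw, p_fdr = out[0]
        assert rho == pytest.approx(1.0)
        assert p_fdr == p_raw  # single comparison

    def test_bh_step_up_hand_example(self):
        """BH on p = (.01, .02, .03, .04) adjusts all four to .04."""
        rng = np.random.default_rng(0)
        import scipy.stats as sps

        adj = sps.false_discovery_control([0.01, 0.02, 0.03, 0.04], method="bh")
        assert np.allclose(adj, 0.04)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_fdr([(np.ones(5), np.arange(5))])


class TestClusterPermutation:
    def test_perfect_dependence_yields_significant_cluster(self, rng):
        n = 24
        index = np.sort(rng.normal(size=n))
        curve = cluster_permutation_curve(
            index, index.copy(), n_perm=300, rng=rng, reference="zero"
        )
        assert curve.rho_overall == pytest.approx(1.0)
        assert len(curve.clusters) == 1
        assert curve.clusters[0].p_value < 0.05

    def test_null_data_rarely_produces_clusters(self, rng):
        n = 20
        hits = 0
        reps = 60
        for _ in range(reps):
            idx = rng.normal(size=n)
            aq = rng.normal(size=n)
            curve = cluster_permutation_curve(
                idx, aq, n_perm=150, rng=rng, reference="zero"
            )
            if any(c.p_value < 0.05 for c in curve.clusters):
                hits += 1
        assert hits / reps <= 0.15  # loose bound at this replicate count

    def test_overall_reference_runs(self, rng):
        n = 30
        idx = rng.normal(size=n)
        aq = 0.5 * idx + rng.normal(size=n)
        curve = cluster_permutation_curve(
            idx, aq, n_perm=200, rng=rng, reference="overall"
        )
        assert curve.ks[0] == 10
        assert curve.ks[-1] == n
        assert np.all(np.abs(curve.rho[np.isfinite(curve.rho)]) <= 1.0)

    def test_unstable_null_refused(self, rng):
        with pytest.raises(ValueError):
            cluster_permutation_curve(
                np.arange(12), np.arange(12), n_perm=50, rng=rng
            )
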