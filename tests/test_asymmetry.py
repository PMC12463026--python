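"""Classical detectors vs independent oracles and their null behavior."""

import itertools

import numpy as np
import pytest
from scipy import stats

from funnelbias.asymmetry import (
    DegenerateDesignError,
    begg_test,
    egger_test,
    trim_and_fill,
)
from funnelbias.simulate import ScenarioConfig, Selection, generate_dataset, simulate_study_pool


def hand_ols_intercept_t(x, y):
    """Two-column OLS by explicit normal equations; returns (t, p) of intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    b0 = (sxx * sy - sx * sxy) / det
    b1 = (n * sxy - sx * sy) / det
    resid = y - b0 - b1 * x
    sigma2 = (resid**2).sum() / (n - 2)
    var_b0 = sigma2 * sxx / det
    t = b0 / np.sqrt(var_b0)
    return t, 2 * stats.t.sf(abs(t), df=n - 2)


class TestEgger:
    def test_mirrored_dataset_has_zero_intercept(self):
        # Pairs (y, s) and (-y, s) over distinct s force antisymmetry.
        y = np.array([0.8, -0.8, 1.5, -1.5, 0.3, -0.3])
        s = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        res = egger_test(y, s)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)
        assert not res.flagged

    def test_matches_hand_normal_equations(self):
        y = np.array([0.5, 0.3, 1.2, -0.2, 0.8])
        s = np.array([1.1, 1.9, 3.3, 2.4, 2.8])
        res = egger_test(y, s)
        t, p = hand_ols_intercept_t(1.0 / s, y / s)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_degenerate_equal_precisions(self):
        with pytest.raises(DegenerateDesignError):
            egger_test([0.1, 0.2, 0.3], [2.0, 2.0, 2.0])

    def test_needs_three_studies(self):
        with pytest.raises(ValueError):
            egger_test([0.1, 0.2], [1.0, 2.0])

    def test_type_one_error_near_nominal(self):
        # No suppression, tau2=0: rejection rate should sit at alpha.
        rejections = 0
        reps = 800
        for seed in range(reps):
            rng = np.random.default_rng(60_000 + seed)
            pool = simulate_study_pool(75, 0.0, 0.0, rng)
            res = egger_test([r.effect for r in pool], [r.se for r in pool])
            rejections += res.flagged
        rate = rejections / reps
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / reps)


class TestBegg:
    def test_fully_concordant_is_maximal(self):
        # Deviates strictly increasing with variance: every pair concordant.
        s = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        w = 1.0 / s**2
        # pick y so that (y - mu_fe)/sqrt(s^2 - 1/sum w) is increasing in s^2
        y = np.array([-2.0, -1.0, 0.5, 2.0, 4.0])
        res = begg_test(y, s, continuity=False)
        n = 5
        v = s**2 - 1.0 / w.sum()
        t = (y - (w * y).sum() / w.sum()) / np.sqrt(v)
        assert np.all(np.diff(t) > 0)  # confirms construction
        expected_z = (n * (n - 1) / 2) / np.sqrt(n * (n - 1) * (2 * n + 5) / 18)
        assert res.statistic == pytest.approx(expected_z, abs=1e-12)

    def test_matches_exhaustive_pair_enumeration(self, rng):
        pool = simulate_study_pool(6, 0.0, 1.0, rng)
        y = np.array([r.effect for r in pool])
        s = np.array([r.se for r in pool])
        res = begg_test(y, s)
        # brute force all 15 pairs on independently recomputed deviates
        w = 1.0 / s**2
        mu = (w * y).sum() / w.sum()
        t = (y - mu) / np.sqrt(s**2 - 1.0 / w.sum())
        p_count = q_count = 0
        for i, j in itertools.combinations(range(6), 2):
            c = np.sign(t[i] - t[j]) * np.sign(s[i] ** 2 - s[j] ** 2)
            if c > 0:
                p_count += 1
            elif c < 0:
                q_count += 1
        assert f"P={p_count} Q={q_count}" == res.detail
        sd = np.sqrt(6 * 5 * 17 / 18)
        s_stat = p_count - q_count
        expected = (s_stat - np.sign(s_stat)) / sd if s_stat else 0.0
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self, rng):
        pool = simulate_study_pool(12, 0.0, 1.0, rng)
        y = np.array([r.effect for r in pool])
        s = np.array([r.se for r in pool])
        res = begg_test(y, s)
        perm = rng.permutation(12)
        res_p = begg_test(y[perm], s[perm])
        assert res_p.statistic == pytest.approx(res.statistic, abs=1e-12)
        assert res_p.p_value == pytest.approx(res.p_value, abs=1e-12)


def independent_trim_fill_L0(y, s, max_iter=50):
    """Re-implementation of iterated L0 trimming using sorted positions.

    Written without the package's rank helpers: ranks come from argsort of
    |deviate|, the dominant side is fixed by the first centering, and the
    fixed-effect mean is recomputed on the trimmed set each round.
    """
    y = np.asarray(y, float)
    s = np.asarray(s, float)
    n = y.size
    w = 1.0 / s**2

    def fe(vals_mask):
        return (w[vals_mask] * y[vals_mask]).sum() / w[vals_mask].sum()

    d0 = y - fe(np.ones(n, bool))
    ranks0 = stats.rankdata(np.abs(d0))
    side_right = ranks0[d0 > 0].sum() >= ranks0[d0 < 0].sum()
    k0 = 0
    for _ in range(max_iter):
        signed = y if side_right else -y
        keep = np.ones(n, bool)
        keep[np.argsort(-signed, kind="stable")[:k0]] = False
        d = y - fe(keep)
        ranks = stats.rankdata(np.abs(d))
        t_sum = ranks[d > 0].sum() if side_right else ranks[d < 0].sum()
        l0 = (4.0 * t_sum - n * (n + 1)) / (2.0 * n - 1.0)
        k_new = min(max(0, int(np.floor(l0 + 0.5))), n - 2)
        if k_new == k0:
            break
        k0 = k_new
    return k0


class TestTrimAndFill:
    def test_symmetric_funnel_imputes_nothing(self):
        # every (y, s) paired with its mirror about the pooled mean
        y_half = np.array([0.3, 1.1, 2.2, 0.7])
        s_half = np.array([1.0, 1.6, 2.4, 3.0])
        y = np.concatenate([y_half, -y_half])
        s = np.concatenate([s_half, s_half])
        for est in ("L0", "R0"):
            res = trim_and_fill(y, s, estimator=est)
            assert res.k0 == 0
            assert not res.flagged

    def test_one_sided_toy_matches_independent_iteration(self):
        # 10-study toy: symmetric core plus 3 extra right-side extremes,
        # mimicking a funnel whose left tail was suppressed.
        y = np.array([0.0, 0.2, -0.2, 0.5, -0.5, 0.1, -0.1, 2.5, 3.0, 3.6])
        s = np.array([1.0, 1.2, 1.2, 1.5, 1.5, 2.0, 2.0, 2.5, 2.8, 3.0])
        res = trim_and_fill(y, s, estimator="L0")
        assert res.k0 == independent_trim_fill_L0(y, s)
        assert res.k0 > 0
        assert res.flagged

    @pytest.mark.parametrize("est", ["L0", "R0"])
    def test_k0_bounded_by_n(self, rng, est):
        for _ in range(10):
            pool = simulate_study_pool(12, 0.0, 1.0, rng)
            res = trim_and_fill(
                [r.effect for r in pool], [r.se for r in pool], estimator=est
            )
            assert 0 <= res.k0 <= 12

    def test_r0_exact_test_pvalue(self):
        # run-length null: p = 2^-(k0+1); k0 = 0 must never flag.
        y = np.array([0.1, -0.2, 0.15, -0.05, 0.3, -0.25])
        s = np.ones(6) * 2.0
        res = trim_and_fill(y, s, estimator="R0")
        assert res.p_value == pytest.approx(2.0 ** -(res.k0 + 1))

    def test_permutation_invariance(self, rng):
        pool = simulate_study_pool(15, 0.0, 1.0, rng)
        y = np.array([r.effect for r in pool])
        s = np.array([r.se for r in pool])
        perm = rng.permutation(15)
        for est in ("L0", "R0"):
            a = trim_and_fill(y, s, estimator=est)
            b = trim_and_fill(y[perm], s[perm], estimator=est)
            assert a.k0 == b.k0
            assert a.flagged == b.flagged


class TestFrozenCrossCheck:
    """Frozen values verified against the R package metafor (version 4.8-0).

    The dataset is regenerated deterministically from the simulator; the
    expected numbers were confirmed equal to regtest(model="lm",
    predictor="sei"), ranktest(), and trimfill(estimator=...) output.
    """

    @pytest.fixture()
    def dataset(self):
        config = ScenarioConfig(
            n_published=30, severity=1 / 5, tau2=0.0,
            selection=Selection.EFFECT_SIZE, seed=7,
        )
        ds = generate_dataset(config, 3)
        return ds.effects(), ds.ses()

    def test_egger_matches_metafor(self, dataset):
        y, s = dataset
        res = egger_test(y, s)
        assert res.statistic == pytest.approx(1.793306, abs=1e-6)
        assert res.p_value == pytest.approx(0.08373308, abs=1e-7)

    def test_begg_matches_metafor(self, dataset):
        y, s = dataset
        res = begg_test(y, s)
        # Kendall tau = (P - Q) / (n(n-1)/2) as reported by ranktest()
        assert res.detail == "P=258 Q=177"
        assert (258 - 177) / (30 * 29 / 2) == pytest.approx(0.1862069, abs=1e-7)

    def test_trimfill_matches_metafor(self, dataset):
        y, s = dataset
        assert trim_and_fill(y, s, estimator="L0").k0 == 5
        r0 = trim_and_fill(y, s, estimator="R0")
        assert r0.k0 == 13
        assert r0.p_value == pytest.approx(6.103516e-05, rel=1e-5)

    def test_reml_matches_metafor(self, dataset):
        from funnelbias.reml import reml_fit

        y, s = dataset
        fit = reml_fit(y, s)
        assert fit.mu_hat == pytest.approx(0.2315457, abs=1e-6)
        assert fit.se_mu == pytest.approx(0.354787, abs=1e-6)
        assert fit.tau2_hat == pytest.approx(0.0, abs=1e-8)


class TestPowerBehavior:
    def test_power_monotone_in_severity(self):
        # Scenario 1 at n=30, tau2=0: Egger rejections should not decrease
        # as suppression severity grows (within Monte-Carlo tolerance).
        reps = 300
        rates = []
        for sev in (1 / 10, 1 / 5, 1 / 3):
            config = ScenarioConfig(
                n_published=30, severity=sev, tau2=0.0,
                selection=Selection.P_VALUE, seed=99,
            )
            flags = 0
            for rep in range(reps):
                ds = generate_dataset(config, rep)
                flags += egger_test(ds.effects(), ds.ses()).flagged
            rates.append(flags / reps)
        mc = 3 * np.sqrt(0.25 / reps)
        assert rates[1] >= rates[0] - mc
        assert rates[2] >= rates[1] - mc
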