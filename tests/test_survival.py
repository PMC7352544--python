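import itertools

import numpy as np
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank
from lifelines.statistics import multivariate_logrank_test

from hoxpress.survival import km_estimate, logrank_test, pair_km, tiered_km


class TestKMEstimate:
    def test_no_events_flat_curve(self):
        km = km_estimate(np.arange(1, 11), np.zeros(10, dtype=int))
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_single_death_among_four(self):
        km = km_estimate([5, 6, 7, 8], [1, 0, 0, 0])
        assert km.survival_at(4.9) == 1.0
        assert km.survival_at(5.0) == pytest.approx(0.75)

    def test_mixed_fixture_matches_hand_product_limit(self):
        # times [1d, 2c, 3d, 4d, 4c, 5d]:
        # S = 5/6, then *3/4 = 0.625, *2/3 = 0.41667, *0/1 = 0
        km = km_estimate([1, 2, 3, 4, 4, 5], [1, 0, 1, 1, 0, 1])
        np.testing.assert_allclose(km.event_times, [1, 3, 4, 5])
        np.testing.assert_allclose(km.at_risk, [6, 4, 3, 1])
        np.testing.assert_allclose(km.survival, [5 / 6, 0.625, 5 / 12, 0.0])

    def test_reproduces_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=50).round(3)
        km = km_estimate(t, np.ones(50, dtype=int))
        for q in [1.0, 5.0, 20.0]:
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        if e.sum() == 0:
            e[0] = 1
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in km.event_times:
            assert km.survival_at(q) == pytest.approx(
                float(kmf.survival_function_at_times(q).iloc[0])
            )

    def test_degenerate_input_warns(self, caplog):
        with caplog.at_level("WARNING", logger="hoxpress"):
            km_estimate([0, 0, 0], [0, 0, 0])
        assert "degenerate" in caplog.text


class TestLogrank:
    def test_group_vs_copy_of_itself(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 1, 0]
        chi2, p = logrank_test([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_identical_groups(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [1, 1, 0, 1, 1]
        _, p = logrank_test([(t, e)] * 3)
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_relabeling_oracle(self):
        """Asymptotic two-group p agrees with the exact permutation p from
        all C(8,4) = 70 relabelings, within 0.02."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 12.0, 14.0, 16.0])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        chi2_obs, p_asym = logrank_test(
            [(times[:4], events[:4]), (times[4:], events[4:])]
        )
        perm_stats = []
        for combo in itertools.combinations(range(8), 4):
            rest = [i for i in range(8) if i not in combo]
            chi2, _ = logrank_test(
                [(times[list(combo)], events[list(combo)]), (times[rest], events[rest])]
            )
            perm_stats.append(chi2)
        p_perm = np.mean([c >= chi2_obs - 1e-12 for c in perm_stats])
        assert p_perm == pytest.approx(4 / 70)
        assert abs(p_asym - p_perm) < 0.02

    @pytest.mark.parametrize("seed", range(5))
    def test_two_group_matches_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        t1, t2 = rng.exponential(10, 30), rng.exponential(14, 25)
        e1, e2 = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
        e1[0] = e2[0] = 1
        chi2, p = logrank_test([(t1, e1), (t2, e2)])
        ref = lifelines_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_three_group_matches_lifelines(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        g = np.repeat([0, 1, 2], 20)
        chi2, p = logrank_test([(t[g == i], e[g == i]) for i in range(3)])
        ref = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariant_to_within_group_order(self):
        rng = np.random.default_rng(8)
        t1, e1 = rng.exponential(5, 20), rng.integers(0, 2, 20)
        t2, e2 = rng.exponential(9, 20), rng.integers(0, 2, 20)
        e1[0] = e2[0] = 1
        perm = rng.permutation(20)
        assert logrank_test([(t1, e1), (t2, e2)]) == pytest.approx(
            logrank_test([(t1[perm], e1[perm]), (t2, e2)])
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1.0], [1]), ([], [])])


def _null_survival(rng, n):
    t_event = rng.exponential(1000.0, n)
    t_cens = rng.exponential(4000.0, n)
    return np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int)


class TestTieredKM:
    def test_strong_planted_hazard_detected_at_first_tier(self, planted_cohort):
        tum = planted_cohort.cohort.tumor.data
        surv = planted_cohort.survival
        res = tiered_km(
            tum.loc["HOXA13"].to_numpy(),
            surv["time"].to_numpy(),
            surv["event"].to_numpy(),
            gene="HOXA13",
        )
        assert res.tier == "median2" and res.significant

    def test_null_gene_reaches_no_tier_in_most_seeds(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            t, e = _null_survival(rng, 200)
            x = rng.standard_normal(200)
            hits += tiered_km(x, t, e, n_tests=39).significant
        assert hits <= 6  # >= 90% of seeds end at tier none

    def test_extreme_quartile_effect_escalates_past_median(self):
        # Hazard rises with |x|: both extremes risky, so a median split sees
        # two identically mixed groups and only the finer tiers can detect.
        found = []
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            n = 300
            x = rng.standard_normal(n)
            rate = np.where(np.abs(x) > 0.8, 6e-3, 5e-4)
            t = rng.exponential(1.0 / rate)
            e = np.ones(n, dtype=int)
            res = tiered_km(x, t, e, n_tests=39)
            found.append(res.tier)
        assert all(t in ("tertile3", "quartile_extremes") for t in found)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            tiered_km([1, 2, 3], [1, 2, 3], [1, 1, 1])

    def test_median_split_fwer_controlled(self):
        """Under the null the median-split tier alone keeps Bonferroni
        family-wise error across 39 genes at <= 5% (binomial slack)."""
        fam_err = 0
        n_seeds = 150
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t, e = _null_survival(rng, 120)
            x = rng.standard_normal((39, 120))
            any_hit = False
            for g in range(39):
                high = x[g] > np.median(x[g])
                _, p = logrank_test([(t[high], e[high]), (t[~high], e[~high])])
                if min(1.0, 39 * p) < 0.05:
                    any_hit = True
                    break
            fam_err += any_hit
        # Binomial(150, 0.05) upper 99.5% bound ~ 14
        assert fam_err <= 14

    def test_full_escalation_stays_below_union_bound(self):
        """Sequential tier escalation without cross-tier correction inflates
        the family-wise error; it must still respect the 3-alpha union bound."""
        fam_err = 0
        n_seeds = 120
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            t, e = _null_survival(rng, 120)
            any_hit = any(
                tiered_km(rng.standard_normal(120), t, e, n_tests=39).significant
                for _ in range(39)
            )
            fam_err += any_hit
        assert fam_err / n_seeds < 3 * 0.05 + 0.08  # union bound + binomial slack


class TestPairKM:
    def test_duplicated_gene_degenerates_to_single_gene(self):
        rng = np.random.default_rng(4)
        n = 100
        x = rng.standard_normal(n)
        t, e = _null_survival(rng, n)
        res = pair_km(x, x.copy(), t, e)
        assert res.n1 == n // 2
        assert res.p_pair == pytest.approx(res.p_single_a, abs=1e-12)
        assert res.p_pair == pytest.approx(res.p_single_b, abs=1e-12)

    def test_independent_genes_quarter_intersection(self):
        rng = np.random.default_rng(5)
        n = 1000
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        t, e = _null_survival(rng, n)
        res = pair_km(a, b, t, e)
        assert res.n1 / n == pytest.approx(0.25, abs=0.04)
        assert res.n2 / n == pytest.approx(0.25, abs=0.04)

    def test_degenerate_empty_intersection(self):
        # perfectly anti-correlated genes: nobody is high (or low) on both
        x = np.arange(10, dtype=float)
        t = np.arange(1, 11, dtype=float)
        e = np.ones(10, dtype=int)
        res = pair_km(x, -x, t, e)
        assert res.n1 == 0 and res.n2 == 0
        assert not res.selected

    def test_additive_joint_hazard_selects_pair(self):
        selected = 0
        for seed in range(25):
            rng = np.random.default_rng(200 + seed)
            n = 300
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            rate = 1e-3 * np.exp(0.5 * a + 0.5 * b)
            t = rng.exponential(1.0 / rate)
            e = np.ones(n, dtype=int)
            res = pair_km(a, b, t, e)
            selected += res.selected
        assert selected >= 15  # joint signal beats each marginal in most seeds

    def test_null_pair_pvalues_uniform(self):
        """With no survival effect, pair log-rank p-values are uniform:
        empirical rate at nominal 0.05 within the binomial 95% interval."""
        from scipy import stats as sps

        hits = 0
        n_seeds = 400
        for seed in range(n_seeds):
            rng = np.random.default_rng(40_000 + seed)
            n = 60
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            t, e = _null_survival(rng, n)
            res = pair_km(a, b, t, e, n_tests=1)
            hits += res.p_pair < 0.05
        lo, hi = sps.binom.interval(0.95, n_seeds, 0.05)
        assert lo <= hits <= hi
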