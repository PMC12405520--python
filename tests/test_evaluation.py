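"""Survival metrics against exhaustive oracles and reference libraries."""

import numpy as np
import pandas as pd
import pytest

from pansurv.core import IntegrityError, ValidationError
from pansurv.evaluation import (
    aggregate_cv,
    bootstrap_ci_and_ztest,
    censoring_survival,
    harrell_cindex,
    km_curve,
    logrank_test,
    mannwhitney_compare,
    median_risk_split,
    time_dependent_auc,
)


def brute_force_cindex(risks, times, events):
    conc = comp = 0.0
    for i in range(len(risks)):
        for j in range(len(risks)):
            if events[i] == 1 and times[i] < times[j]:
                comp += 1
                if risks[i] > risks[j]:
                    conc += 1
                elif risks[i] == risks[j]:
                    conc += 0.5
    return conc / comp if comp else None


def random_dataset(seed, n_max=40):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, n_max + 1)
    return (rng.standard_normal(n), rng.exponential(10, n) + 0.1,
            rng.integers(0, 2, n))


class TestCindex:
    def test_perfect_concordance(self):
        assert harrell_cindex([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert harrell_cindex([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_worked_example(self):
        assert harrell_cindex([1.0, 0.5, 0.2], [2, 1, 3], [1, 1, 0]) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_pair_oracle(self, seed):
        r, t, e = random_dataset(seed)
        ours = harrell_cindex(r, t, e)
        ref = brute_force_cindex(r, t, e)
        if ref is None:
            assert ours is None
        else:
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored

        r, t, e = random_dataset(123)
        ref = concordance_index_censored(e.astype(bool), t, r)[0]
        assert harrell_cindex(r, t, e) == pytest.approx(ref, abs=1e-10)

    def test_negation_symmetry(self):
        r, t, e = random_dataset(7)
        c1 = harrell_cindex(r, t, e)
        c2 = harrell_cindex(-r, t, e)
        assert c1 + c2 == pytest.approx(1.0)

    def test_no_comparable_pairs_flagged(self):
        with pytest.warns(UserWarning):
            assert harrell_cindex([1, 2], [1, 2], [0, 0]) is None

    def test_monotone_rescale_invariance(self):
        r, t, e = random_dataset(9)
        assert harrell_cindex(np.exp(r), t, e) == harrell_cindex(r, t, e)


class TestKaplanMeier:
    def test_no_events_flat(self):
        km = km_curve([1, 2, 3], [0, 0, 0])
        assert km.n_events == 0 and len(km.times) == 0
        assert km.at(2.5) == 1.0

    def test_hand_product_limit_n4(self):
        km = km_curve([1, 2, 3, 4], [1, 0, 0, 0])
        assert km.at(1) == pytest.approx(0.75)

    def test_hand_product_limit_n2(self):
        km = km_curve([1, 2], [1, 1])
        assert km.survival == pytest.approx([0.5, 0.0])

    def test_matches_lifelines_to_1e8(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = rng.exponential(10, 60) + 0.1
        e = rng.integers(0, 2, 60)
        km = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(km.times, km.survival):
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]), abs=1e-8
            )

    def test_monotone_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 40) + 0.1
        e = rng.integers(0, 2, 40)
        km = km_curve(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.ci_lower >= 0) & (km.ci_upper <= 1))
        assert np.all(km.ci_lower <= km.survival + 1e-12)
        assert np.all(km.survival <= km.ci_upper + 1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        t = np.array([3.0, 1.0, 2.0, 4.0, 5.0])
        km = km_curve(t, np.ones(5, dtype=int))
        for ti in km.times:
            assert km.at(ti) == pytest.approx((t > ti).mean())


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a", "a", "a", "b", "b", "b"]
        chi2, p = logrank_test(g, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_hypergeometric_example(self):
        # A: events at 1,2; B: censored at 3,4
        g = ["A", "A", "B", "B"]
        t = [1, 2, 3, 4]
        e = [1, 1, 0, 0]
        chi2, p = logrank_test(g, t, e)
        # t=1: O-E = 1 - 2/4 = 0.5, V = 1*(1/2)(1/2)(3/3) = 0.25
        # t=2: O-E = 1 - 1/3 = 2/3, V = 1*(1/3)(2/3)(2/2) = 2/9
        # chi2 = (0.5+2/3)^2 / (0.25+2/9) = 2.8824; p = 0.0896
        assert chi2 == pytest.approx((0.5 + 2 / 3) ** 2 / (0.25 + 2 / 9), abs=1e-10)
        assert chi2 == pytest.approx(2.88, abs=0.01)
        assert p == pytest.approx(0.090, abs=0.001)

    def test_group_relabel_symmetry(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 30) + 0.1
        e = rng.integers(0, 2, 30)
        g = np.where(rng.random(30) < 0.5, "A", "B")
        assert logrank_test(g, t, e) == pytest.approx(
            logrank_test(np.where(g == "A", "B", "A"), t, e)
        )

    def test_matches_lifelines_to_1e8(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(6)
        t = rng.exponential(10, 50) + 0.1
        e = rng.integers(0, 2, 50)
        g = rng.random(50) < 0.4
        chi2, p = logrank_test(np.where(g, "A", "B"), t, e)
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)


class TestTimeDependentAUC:
    def test_perfect_model_auc_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 200) + 0.1
        auc, _ = time_dependent_auc(-t, t, np.ones(200, dtype=int))
        assert auc == pytest.approx(1.0)

    def test_random_risks_near_half(self):
        rng = np.random.default_rng(1)
        n = 2000
        t = rng.exponential(10, n) + 0.1
        e = rng.integers(0, 2, n)
        r = rng.standard_normal(n)     # independent of survival
        auc, _ = time_dependent_auc(r, t, e)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_single_time_no_censoring_equals_pair_counting(self):
        rng = np.random.default_rng(2)
        n = 50
        t = rng.exponential(10, n) + 0.1
        e = np.ones(n, dtype=int)
        r = rng.standard_normal(n)
        auc, per_time = time_dependent_auc(r, t, e, n_times=1)
        t0 = per_time["time"].iloc[0]
        cases, controls = t <= t0, t > t0
        num = den = 0.0
        for i in np.flatnonzero(cases):
            for j in np.flatnonzero(controls):
                den += 1
                num += 1.0 if r[i] > r[j] else (0.5 if r[i] == r[j] else 0.0)
        assert auc == pytest.approx(num / den, abs=1e-12)

    def test_matches_scikit_survival_ipcw_estimator(self):
        from sksurv.metrics import cumulative_dynamic_auc

        rng = np.random.default_rng(3)
        n = 120
        t = rng.exponential(10, n) + 0.1
        e = rng.integers(0, 2, n)
        e[t > np.percentile(t, 85)] = 0          # keep G(t) well-defined on the grid
        r = -0.5 * t + rng.standard_normal(n)
        _, per_time = time_dependent_auc(r, t, e)
        y = np.array(list(zip(e.astype(bool), t)), dtype=[("e", bool), ("t", float)])
        ref_auc, _ = cumulative_dynamic_auc(y, y, r, per_time["time"].values)
        assert np.allclose(per_time["auc"].values, ref_auc, atol=1e-8)


class TestMedianSplit:
    def test_even_split(self):
        labels = median_risk_split([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_odd_split_ge_median_rule(self):
        labels = median_risk_split([1, 2, 3])
        assert list(labels) == ["low", "high", "high"]

    def test_degenerate_flagged(self):
        with pytest.warns(UserWarning):
            median_risk_split([2, 2, 2])


class TestBootstrap:
    def test_identical_models_p_one(self):
        rng = np.random.default_rng(0)
        r = rng.standard_normal(30)
        t = rng.exponential(10, 30) + 0.1
        e = np.ones(30, dtype=int)
        out = bootstrap_ci_and_ztest(r, r, t, e, n_boot=50, seed=1)
        assert out["p"] == 1.0 and out["ci_a"] == out["ci_b"]

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        ra, rb = rng.standard_normal(20), rng.standard_normal(20)
        t = rng.exponential(10, 20) + 0.1
        e = rng.integers(0, 2, 20)
        e[:4] = 1
        o1 = bootstrap_ci_and_ztest(ra, rb, t, e, n_boot=50, seed=9)
        o2 = bootstrap_ci_and_ztest(ra, rb, t, e, n_boot=50, seed=9)
        assert o1 == o2

    def test_matches_independent_resampling_loop(self):
        rng = np.random.default_rng(2)
        n, n_boot, seed = 5, 50, 3
        ra, rb = rng.standard_normal(n), rng.standard_normal(n)
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.ones(n, dtype=int)
        out = bootstrap_ci_and_ztest(ra, rb, t, e, n_boot=n_boot, seed=seed)
        # independent re-implementation with the same seeded stream
        rng2 = np.random.default_rng(seed)
        cas = []
        for _ in range(n_boot):
            while True:
                idx = rng2.integers(0, n, size=n)
                ca = brute_force_cindex(ra[idx], t[idx], e[idx])
                if ca is not None:
                    break
            cas.append(ca)
        assert out["ci_a"][0] == pytest.approx(np.percentile(cas, 2.5), abs=1e-12)
        assert out["ci_a"][1] == pytest.approx(np.percentile(cas, 97.5), abs=1e-12)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        u, p = mannwhitney_compare([0.7] * 5, [0.7] * 5)
        assert p == 1.0

    def test_complete_separation_exact_p(self):
        u, p = mannwhitney_compare([0.9] * 5, [0.1] * 5)
        # hmm: ties within groups; use distinct values for the exact path
        u, p = mannwhitney_compare([0.9, 0.91, 0.92, 0.93, 0.94],
                                   [0.1, 0.11, 0.12, 0.13, 0.14])
        assert u == 25.0
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_swap_symmetry(self):
        a = [0.9, 0.91, 0.92, 0.93, 0.94]
        b = [0.1, 0.11, 0.12, 0.13, 0.14]
        ua, pa = mannwhitney_compare(a, b)
        ub, pb = mannwhitney_compare(b, a)
        assert pa == pytest.approx(pb) and ub == pytest.approx(25 - ua)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mannwhitney_compare([], [0.5])


class TestAggregateCV:
    def _oof(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.exponential(10, n) + 0.1
        return pd.DataFrame(
            dict(
                patient_id=[f"p{i}" for i in range(n)],
                risk=-t + 0.01 * rng.standard_normal(n),
                time=t,
                event=np.ones(n, dtype=int),
                cancer=np.where(np.arange(n) % 2 == 0, "A", "B"),
            )
        )

    def test_perfect_ordering_c_one(self):
        oof = self._oof()
        oof["risk"] = -oof["time"]
        report = aggregate_cv(oof)
        assert report.c_index == 1.0

    def test_per_cancer_partition(self):
        report = aggregate_cv(self._oof())
        assert sum(s.n_patients for s in report.per_cancer.values()) == report.n_patients

    def test_duplicate_predictions_rejected(self):
        oof = self._oof()
        oof.loc[1, "patient_id"] = "p0"
        with pytest.raises(IntegrityError):
            aggregate_cv(oof)

    def test_pooled_equals_brute_force_over_union(self):
        oof = self._oof(seed=5)
        report = aggregate_cv(oof)
        assert report.c_index == pytest.approx(
            brute_force_cindex(oof["risk"].values, oof["time"].values,
                               oof["event"].values)
        )

    def test_ipcw_weights_from_censoring_km(self):
        # censoring survival estimator mirrors km on flipped indicators
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 0]
        G = censoring_survival(t, e)
        ref = km_curve(t, [0, 1, 0, 1])
        assert np.array_equal(G.times, ref.times)
        assert np.allclose(G.survival, ref.survival)
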