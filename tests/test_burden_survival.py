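"""Dichotomization, Kaplan–Meier, log-rank, cutoff scan, rank tests, FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from fusionburden.burden_survival import (compare_groups, dichotomize_quantile,
                                          fdr_adjust, km_estimate, logrank,
                                          logrank_two, quantile_threshold,
                                          scan_cutoffs, survival_at,
                                          default_subgroups, ClinicalRecord,
                                          clinical_to_frame)
from fusionburden.synthetic_cohort import CohortConfig, simulate_burden_survival
from helpers import brute_bh, brute_km, brute_logrank_two, cloglog_ci


def random_survival(rng, n, censor_frac=0.3, scale=50.0):
    times = np.round(rng.exponential(scale, size=n), 2)
    events = rng.random(n) > censor_frac
    return times, events


class TestDichotomize:
    def test_sixty_percent_rule_on_one_to_ten(self):
        values = {f"s{i}": i for i in range(1, 11)}
        groups, thr = dichotomize_quantile(values, 0.6)
        assert thr == 6
        assert {s for s, g in groups.items() if g == "high"} == {"s7", "s8", "s9", "s10"}

    def test_threshold_definition(self, rng):
        vals = rng.integers(0, 30, size=47).astype(float)
        for q in (0.1, 0.25, 0.6, 0.9):
            thr = quantile_threshold(vals, q)
            assert (vals <= thr).sum() >= q * len(vals)
            smaller = vals[vals < thr]
            if smaller.size:
                assert (vals <= smaller.max()).sum() < q * len(vals)

    def test_group_sizes_match_counting_oracle(self, rng):
        values = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=80))}
        groups, thr = dichotomize_quantile(values, 0.6)
        n_high = sum(1 for v in values.values() if v > thr)
        assert sum(1 for g in groups.values() if g == "high") == n_high

    def test_all_identical_warns_and_goes_low(self):
        with pytest.warns(UserWarning):
            groups, _ = dichotomize_quantile({"a": 2.0, "b": 2.0, "c": 2.0}, 0.6)
        assert set(groups.values()) == {"low"}


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self, rng):
        curve = km_estimate([10, 20, 70, 80], [True] * 4)
        assert survival_at(curve, 60)["rate"] == pytest.approx(0.5)
        # property over random inputs
        for _ in range(20):
            times = rng.integers(1, 50, size=30).astype(float)
            curve = km_estimate(times, [True] * 30)
            for t in rng.choice(times, 5):
                assert survival_at(curve, t)["rate"] == pytest.approx(
                    np.mean(times > t))

    def test_all_censored_survival_is_one(self):
        curve = km_estimate([5, 10, 15], [False] * 3)
        assert curve.event_times.size == 0
        out = survival_at(curve, 60)
        assert out == {"rate": 1.0, "ci_low": 1.0, "ci_high": 1.0}

    def test_matches_product_limit_oracle(self, rng):
        times, events = random_survival(rng, 60)
        curve = km_estimate(times, events)
        uniq, surv = brute_km(times, events)
        assert list(curve.event_times) == uniq
        assert curve.survival == pytest.approx(surv)

    def test_matches_lifelines(self, rng):
        times, events = random_survival(rng, 120)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert kmf.predict(t) == pytest.approx(s)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([-1.0], [True])


class TestSurvivalAt:
    def test_before_first_event_degenerate(self):
        curve = km_estimate([10.0], [True])
        assert survival_at(curve, 5) == {"rate": 1.0, "ci_low": 1.0, "ci_high": 1.0}

    def test_zero_variance_point_interval(self):
        curve = km_estimate([10, 20], [True, True])
        curve.greenwood_var[:] = 0.0
        out = survival_at(curve, 15)
        assert out["ci_low"] == out["rate"] == out["ci_high"]

    def test_cloglog_interval_matches_closed_form(self, rng):
        times, events = random_survival(rng, 100)
        curve = km_estimate(times, events)
        t = float(np.median(times))
        out = survival_at(curve, t)
        idx = np.searchsorted(curve.event_times, t, side="right") - 1
        lo, hi = cloglog_ci(curve.survival[idx], curve.greenwood_var[idx])
        assert out["ci_low"] == pytest.approx(lo)
        assert out["ci_high"] == pytest.approx(hi)
        assert 0 <= out["ci_low"] <= out["rate"] <= out["ci_high"] <= 1


class TestLogRank:
    def test_label_swap_symmetry(self, rng):
        ta, ea = random_survival(rng, 40)
        tb, eb = random_survival(rng, 35)
        r1 = logrank_two(ta, ea, tb, eb)
        r2 = logrank_two(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_identical_groups_statistic_zero(self):
        t = [3.0, 5.0, 8.0]
        e = [True, False, True]
        r = logrank_two(t, e, t, e)
        assert r.statistic == pytest.approx(0.0, abs=1e-12) and r.p == pytest.approx(1.0)

    def test_two_versus_two_worked_example(self):
        """Group A events at {1,2}, group B at {3,4}: chi-square 49/17."""
        r = logrank_two([1, 2], [True, True], [3, 4], [True, True])
        assert r.statistic == pytest.approx(49 / 17)
        assert r.df == 1
        assert r.statistic == pytest.approx(
            brute_logrank_two([1, 2], [True, True], [3, 4], [True, True]))

    def test_no_events_at_all(self):
        r = logrank_two([1, 2], [False, False], [3], [False])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_censored_subject_before_first_event_no_effect(self, rng):
        """A subject censored strictly before the first event time never
        enters a risk set, so the statistic is unchanged."""
        ta, ea = random_survival(rng, 30)
        tb, eb = random_survival(rng, 30)
        base = logrank_two(ta, ea, tb, eb)
        first_event = np.concatenate([ta[ea], tb[eb]]).min()
        extended = logrank_two(np.append(ta, first_event / 2),
                               np.append(ea, False), tb, eb)
        assert extended.statistic == pytest.approx(base.statistic)

    def test_matches_hand_oracle_on_random_data(self, rng):
        for _ in range(10):
            ta, ea = random_survival(rng, 25)
            tb, eb = random_survival(rng, 20)
            assert logrank_two(ta, ea, tb, eb).statistic == pytest.approx(
                brute_logrank_two(ta, ea, tb, eb))

    def test_three_group_matches_lifelines(self, rng):
        groups = [random_survival(rng, n) for n in (30, 25, 40)]
        r = logrank([(t, e) for t, e in groups])
        df = pd.DataFrame({
            "t": np.concatenate([t for t, _ in groups]),
            "e": np.concatenate([e for _, e in groups]),
            "g": np.repeat([0, 1, 2], [30, 25, 40]),
        })
        ref = multivariate_logrank_test(df["t"], df["g"], df["e"])
        assert r.statistic == pytest.approx(ref.test_statistic)
        assert r.p == pytest.approx(ref.p_value)
        assert r.df == 2


class TestCompareGroups:
    def test_extreme_separation_exact_enumeration(self):
        """{1,2,3} vs {4,5,6}: the most extreme rank-sum; exact two-sided
        p = 2 / C(6,3) = 0.1."""
        values = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6}
        labels = {k: ("g1" if k in "abc" else "g2") for k in values}
        _, p = compare_groups(values, labels, test="wilcoxon")
        assert p == pytest.approx(2 / 20)

    def test_label_swap_invariance(self, rng):
        values = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=40))}
        labels = {s: ("x" if i < 22 else "y") for i, s in enumerate(values)}
        flipped = {s: ("y" if l == "x" else "x") for s, l in labels.items()}
        assert compare_groups(values, labels)[1] == \
            pytest.approx(compare_groups(values, flipped)[1])

    def test_kruskal_type_one_error_calibrated(self, rng):
        """Three-group null: rejection rate ~ 5% over 2000 replicates."""
        rejections = 0
        reps = 2000
        for _ in range(reps):
            values = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=45))}
            labels = {f"s{i}": f"g{i % 3}" for i in range(45)}
            _, p = compare_groups(values, labels, test="kruskal")
            rejections += p < 0.05
        assert 0.03 < rejections / reps < 0.075

    def test_group_count_validation(self):
        values = {"a": 1.0, "b": 2.0, "c": 3.0}
        with pytest.raises(ValueError):
            compare_groups(values, {"a": "x", "b": "y", "c": "z"}, test="wilcoxon")
        with pytest.raises(ValueError):
            compare_groups(values, {"a": "x", "b": "x", "c": "x"}, test="kruskal")


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037]) == pytest.approx([0.037])

    def test_stepup_arithmetic(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_definitional_oracle(self, rng):
        for _ in range(20):
            p = rng.random(size=int(rng.integers(1, 40)))
            assert fdr_adjust(p) == pytest.approx(brute_bh(p), abs=1e-12)

    def test_monotone_bounded(self, rng):
        p = rng.random(size=30)
        adj = fdr_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestCutoffScan:
    def test_single_subgroup_single_quantile(self, rng):
        burden, clinical, _ = simulate_burden_survival(
            CohortConfig(n_samples=80), seed=3)
        res = scan_cutoffs(burden, clinical, subgroups={"all": list(burden)},
                           grid=[0.5])
        assert res.selected_quantile == 0.5
        assert set(res.table["subgroup"]) == {"all"}

    def test_scan_is_deterministic(self, rng):
        burden, clinical, _ = simulate_burden_survival(
            CohortConfig(n_samples=120), seed=5)
        r1 = scan_cutoffs(burden, clinical)
        r2 = scan_cutoffs(burden, clinical)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.selected_quantile == r2.selected_quantile

    def test_untestable_cells_excluded_from_coverage(self):
        clinical = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "subtype": ["TNBC"] * 6,
            "efs_months": [5.0, 10, 15, 20, 25, 30],
            "efs_event": [True] * 6,
        })
        burden = {f"s{i}": 1 for i in range(6)}  # all tied -> empty high arm
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scan_cutoffs(burden, clinical, subgroups={"all": list(burden)})
        assert not res.table["testable"].any()
        assert all(v == 0 for v in res.coverage.values())

    def test_high_burden_arm_has_worse_five_year_efs(self):
        """Planted hazard ratio 3: the high arm's 5-year EFS point estimate
        falls below the low arm's in essentially every replicate."""
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            burden, clinical, truth = simulate_burden_survival(seed=seed)
            groups = truth["groups"]
            rates = {}
            for arm in ("high", "low"):
                sub = clinical[clinical["sample_id"].map(groups) == arm]
                curve = km_estimate(sub["efs_months"], sub["efs_event"])
                rates[arm] = survival_at(curve, 60.0)["rate"]
            wins += rates["high"] < rates["low"]
        assert wins >= n_seeds - 1


class TestClinicalRecords:
    def test_record_validation(self):
        with pytest.raises(ValueError):
            ClinicalRecord("s1", "TNBC", -1.0, True)
        with pytest.raises(ValueError):
            ClinicalRecord("s1", "IDK", 10.0, True)

    def test_frame_roundtrip_and_default_subgroups(self):
        records = [ClinicalRecord(f"s{i}", "TNBC", 10.0 + i, i % 2 == 0)
                   for i in range(20)]
        frame = clinical_to_frame(records)
        groups = default_subgroups(frame, min_size=15)
        assert set(groups) == {"all", "subtype:TNBC"}
        assert len(groups["all"]) == 20
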