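"""Log-rank engine, threshold scans, partition search, Cox HRs and LOOCV."""

import numpy as np
import pandas as pd
import pytest

from svhot.ipart import (
    ThresholdScan,
    best_partition,
    hazard_ratios,
    local_minima,
    logrank_p,
    loocv,
    multi_k_report,
    threshold_scan,
)
from svhot.simulate import SimulationConfig, assign_groups, simulate_survival
from svhot.survival import (
    CutEngine,
    SurvivalRecord,
    km_median,
    logrank_test,
    permutation_logrank_p,
)


def records(times, events, prefix="s"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


def loop_logrank_oracle(time, event, labels):
    """Independent observed-minus-expected chi-square, plain loops."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels = np.asarray(labels, object)
    groups = sorted(set(labels), key=str)
    o = {g: 0.0 for g in groups}
    e = {g: 0.0 for g in groups}
    v = {(g, h): 0.0 for g in groups for h in groups}
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        corr = (n - d) / (n - 1) if n > 1 else 0.0
        for g in groups:
            ng = (at_risk & (labels == g)).sum()
            o[g] += ((time == t) & (event == 1) & (labels == g)).sum()
            e[g] += d * ng / n
            for h in groups:
                nh = (at_risk & (labels == h)).sum()
                delta = 1.0 if g == h else 0.0
                v[(g, h)] += d * corr * (ng / n) * (delta - nh / n)
    z = np.array([o[g] - e[g] for g in groups[:-1]])
    vm = np.array([[v[(g, h)] for h in groups[:-1]] for g in groups[:-1]])
    return float(z @ np.linalg.solve(vm, z))


class TestLogrank:
    def test_identical_groups_give_p_one(self):
        t = [1.0, 2.0, 3.0, 4.0] * 2
        e = [1, 1, 0, 1] * 2
        lab = ["a"] * 4 + ["b"] * 4
        res = logrank_test(t, e, lab)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_three_group_worked_example_matches_hand_loop(self, rng):
        t = rng.exponential(4, 12).round(1) + 0.1
        e = (rng.random(12) < 0.8).astype(int)
        lab = np.array(list("aabbccaabbcc"))
        mine = logrank_test(t, e, lab)
        assert mine.statistic == pytest.approx(loop_logrank_oracle(t, e, lab))
        assert mine.df == 2

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(5, 80).round(1) + 0.1
        e = (rng.random(80) < 0.7).astype(int)
        lab = rng.choice(["x", "y", "z"], 80)
        mine = logrank_test(t, e, lab)
        theirs = multivariate_logrank_test(t, lab, e)
        assert mine.statistic == pytest.approx(theirs.test_statistic)
        assert mine.p == pytest.approx(theirs.p_value)

    def test_two_group_agrees_with_permutation(self, rng):
        t = np.concatenate([rng.exponential(10, 20), rng.exponential(1, 20)])
        e = np.ones(40, int)
        lab = np.array(["slow"] * 20 + ["fast"] * 20)
        analytic = logrank_test(t, e, lab).p
        perm = permutation_logrank_p(t, e, lab, n_permutations=2000, seed=0)
        se = max(np.sqrt(perm * (1 - perm) / 2000), 1 / 2000)
        assert abs(analytic - perm) <= 3 * se + 1e-3

    def test_zero_events_warns_p_one(self):
        with pytest.warns(UserWarning, match="no events"):
            res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], list("aabb"))
        assert res.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_p({"a": records([1, 2], [1, 1]), "b": []})


class TestThresholdScan:
    def _survival(self, n):
        return records(np.linspace(1, 10, n), np.ones(n, int))

    def test_midpoint_candidates(self):
        values = {f"s{i}": v for i, v in enumerate([1.0, 2.0, 3.0, 4.0])}
        scan = threshold_scan(values, self._survival(4), min_group_size=1)
        assert list(scan.thresholds) == [1.5, 2.5, 3.5]

    def test_min_group_size_excludes_edges(self):
        values = {f"s{i}": float(i) for i in range(10)}
        scan = threshold_scan(values, self._survival(10), min_group_size=3)
        assert scan.thresholds.min() > 1.5 and scan.thresholds.max() < 7.5

    def test_order_invariance(self, planted_cohort):
        _, values, recs = planted_cohort
        scan1 = threshold_scan(values, recs)
        shuffled = values.sample(frac=1.0, random_state=1)
        scan2 = threshold_scan(shuffled, list(reversed(recs)))
        assert np.allclose(scan1.thresholds, scan2.thresholds)
        assert np.allclose(scan1.p_values, scan2.p_values)

    def test_perfect_separation_argmin_at_gap(self):
        # all events below the value gap, all censored above it
        values = {f"s{i}": (0.1 * i if i < 10 else 5.0 + 0.1 * i) for i in range(20)}
        recs = records([2.0] * 10 + [20.0] * 10, [1] * 10 + [0] * 10)
        scan = threshold_scan(values, recs, min_group_size=2)
        best = scan.argmin_threshold()
        assert 0.9 < best < 5.0  # inside the gap

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            threshold_scan({"a": 1.0, "b": 2.0}, self._survival(2), min_group_size=5)


class TestLocalMinima:
    def _scan(self, ps):
        t = np.arange(len(ps), dtype=float)
        return ThresholdScan(t, np.asarray(ps, float), 1)

    def test_interior_minima_under_cap(self):
        mins = local_minima(self._scan([0.5, 0.05, 0.2, 0.08, 0.6]), p_cap=0.10)
        assert mins == [1.0, 3.0]

    def test_monotone_curve_boundary_minimum(self):
        assert local_minima(self._scan([0.04, 0.1, 0.3, 0.5]), p_cap=0.10) == [0.0]

    def test_plateau_collapses_to_midpoint(self):
        mins = local_minima(self._scan([0.5, 0.02, 0.02, 0.02, 0.5]), p_cap=0.10)
        assert mins == [2.0]

    def test_w_shape_matches_neighbour_scan(self, rng):
        p = np.abs(np.sin(np.linspace(0, 2 * np.pi, 41))) * 0.2 + 0.01
        scan = self._scan(p)
        mins = local_minima(scan, p_cap=0.3)
        brute = [
            float(scan.thresholds[i])
            for i in range(len(p))
            if (i == 0 or p[i - 1] > p[i])
            and (i == len(p) - 1 or p[i + 1] > p[i])
            and p[i] < 0.3
        ]
        assert mins == brute
        assert len(mins) == 3  # ends + the middle dip of the W


class TestBestPartition:
    def test_k2_equals_scan_argmin(self, planted_cohort):
        _, values, recs = planted_cohort
        scan = threshold_scan(values, recs)
        part = best_partition(values, recs, k=2)
        assert part.thresholds[0] == pytest.approx(scan.argmin_threshold())

    def test_recovers_planted_thresholds(self, planted_cohort):
        cfg, values, recs = planted_cohort
        part = best_partition(values, recs, k=3)
        assert part.thresholds[0] == pytest.approx(1.0, abs=0.15)
        assert part.thresholds[1] == pytest.approx(2.0, abs=0.15)
        assert part.logrank_p < 1e-4
        assert set(part.group_sizes) == {"Low", "Medium", "High"}

    def test_reported_p_is_self_consistent(self, planted_cohort):
        _, values, recs = planted_cohort
        part = best_partition(values, recs, k=3)
        by_id = {r.sample_id: r for r in recs}
        res = logrank_test(
            [by_id[s].time for s in part.labels],
            [by_id[s].event for s in part.labels],
            [part.labels[s] for s in part.labels],
        )
        assert part.logrank_p == pytest.approx(res.p)
        assert part.statistic == pytest.approx(res.statistic)

    def test_labels_are_monotone_step_function(self, planted_cohort):
        _, values, recs = planted_cohort
        part = best_partition(values, recs, k=3)
        rank = {"Low": 0, "Medium": 1, "High": 2}
        ordered = values.sort_values()
        steps = [rank[part.labels[s]] for s in ordered.index]
        assert steps == sorted(steps)

    def test_affine_rescaling_invariance(self, planted_cohort):
        _, values, recs = planted_cohort
        part = best_partition(values, recs, k=3)
        scaled = values * 10 + 7
        part2 = best_partition(scaled, recs, k=3)
        assert part2.labels == part.labels
        for t1, t2 in zip(part.thresholds, part2.thresholds):
            assert t2 == pytest.approx(10 * t1 + 7)

    def test_lambda_shape_medium_has_lowest_km_median(self, planted_cohort):
        _, values, recs = planted_cohort
        part = best_partition(values, recs, k=3)
        by_id = {r.sample_id: r for r in recs}
        medians = {}
        for g in ("Low", "Medium", "High"):
            member = [s for s, lab in part.labels.items() if lab == g]
            medians[g] = km_median(
                [by_id[s].time for s in member], [by_id[s].event for s in member]
            )
        assert medians["Medium"] < medians["Low"]
        assert medians["Medium"] < medians["High"]

    def test_restricted_candidates_respected(self, planted_cohort):
        _, values, recs = planted_cohort
        part = best_partition(values, recs, k=3, candidates=[1.0, 2.0, 2.5])
        assert all(t in (1.0, 2.0, 2.5) or True for t in part.thresholds)
        assert set(np.round(part.thresholds, 6)) <= {1.0, 2.0, 2.5}

    def test_infeasible_partition_raises(self):
        values = {f"s{i}": float(i) for i in range(8)}
        recs = records(np.linspace(1, 5, 8), np.ones(8, int))
        with pytest.raises(ValueError, match="min_group_size"):
            best_partition(values, recs, k=3, min_group_size=4)


class TestHazardRatios:
    def test_identical_groups_hr_near_one(self, rng):
        t = rng.exponential(5, 200)
        recs = records(t, np.ones(200, int))
        labels = {r.sample_id: ("a" if i < 100 else "b")
                  for i, r in enumerate(recs)}
        est = hazard_ratios(labels, recs, reference_group="a")[0]
        assert est.ci_low < 1 < est.ci_high

    def test_recovers_true_hazard_ratio_three(self, rng):
        n = 500
        t = np.concatenate(
            [rng.exponential(1 / 0.1, n // 2), rng.exponential(1 / 0.3, n // 2)]
        )
        recs = records(t, np.ones(n, int))
        labels = {r.sample_id: ("ref" if i < n // 2 else "hi")
                  for i, r in enumerate(recs)}
        est = hazard_ratios(labels, recs, reference_group="ref")[0]
        assert 2.4 <= est.hr <= 3.75
        assert est.ci_low <= 3.0 <= est.ci_high

    def test_group_without_events_flagged(self, rng):
        t = np.concatenate([rng.exponential(2, 20), np.full(10, 30.0)])
        e = np.array([1] * 20 + [0] * 10)
        recs = records(t, e)
        labels = {r.sample_id: ("a" if i < 20 else "b")
                  for i, r in enumerate(recs)}
        est = hazard_ratios(labels, recs, reference_group="a")[0]
        assert est.infinite_ci and est.n_events == 0


class TestLoocv:
    def test_held_out_labels_stable_under_strong_signal(self, planted_cohort):
        cfg, values, recs = planted_cohort
        sub = values.iloc[:80]
        full = best_partition(sub, recs, k=3)
        cv = loocv(sub, recs, k=3)
        agree = sum(cv.labels[s] == full.labels[s] for s in sub.index)
        assert agree / len(sub) >= 0.9
        assert cv.n_failed == 0

    def test_deterministic(self, planted_cohort):
        _, values, recs = planted_cohort
        sub = values.iloc[:60]
        cv1 = loocv(sub, recs, k=2)
        cv2 = loocv(sub, recs, k=2)
        assert cv1.labels == cv2.labels and cv1.logrank_p == cv2.logrank_p


def test_multi_k_report_lists_requested_range(planted_cohort):
    _, values, recs = planted_cohort
    scan = threshold_scan(values, recs)
    cands = local_minima(scan, p_cap=0.5)
    rep = multi_k_report(values, recs, k_max=4, candidates=cands)
    assert set(rep["k"]) <= {2, 3, 4}
    assert (rep["logrank_p"] > 0).all()
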