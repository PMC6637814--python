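"""Method-comparison statistics: counts, descriptives, lagged correlation,
Venn overlap, confusion-matrix performance."""

import numpy as np
import pandas as pd
import pytest

import pulseqc as pq
from conftest import make_panel


def _result(panel, keys, method="m"):
    flags = pd.DataFrame(False, index=panel.values.index, columns=panel.hormones)
    for (p, t, h) in keys:
        flags.loc[(p, t), h] = True
    return pq.OutlierResult(method, {}, flags)


@pytest.fixture
def full_panel():
    rng = np.random.default_rng(0)
    return make_panel(
        {"P1": {h: 5 + rng.standard_normal(144) * 0.1 for h in pq.config.HORMONES}}
    )


class TestCountOutliers:
    def test_worked_percentages(self, full_panel):
        res = _result(full_panel, [("P1", 10, "glucose"), ("P1", 10, "insulin")])
        comp = pq.count_outliers(full_panel, res)
        assert comp.pct_timepoints_mean == pytest.approx(100 / 144)
        assert comp.pct_datapoints_mean == pytest.approx(200 / 720)

    def test_empty_and_full(self, full_panel):
        empty = _result(full_panel, [])
        comp = pq.count_outliers(full_panel, empty)
        assert comp.pct_timepoints_mean == 0 and comp.pct_datapoints_mean == 0
        allflags = pq.OutlierResult("m", {}, full_panel.notna())
        comp = pq.count_outliers(full_panel, allflags)
        assert comp.pct_timepoints_mean == 100 and comp.pct_datapoints_mean == 100

    def test_datapoint_pct_bounded_by_timepoint_pct(self, sim_panel_truth):
        panel, _ = sim_panel_truth
        res = pq.detect_stepwise(panel)
        comp = pq.count_outliers(panel, res)
        assert comp.pct_datapoints_mean <= comp.pct_timepoints_mean + 1e-12


class TestDescriptives:
    def test_unflagged_stats(self):
        panel = make_panel({"P1": {"glucose": [1.0, 2.0, 3.0]}})
        out = pq.descriptives(panel)
        row = out.loc["glucose"]
        assert row["mean_mean"] == 2 and row["median_mean"] == 2
        assert row["min_mean"] == 1 and row["max_mean"] == 3

    def test_weighted_mean(self):
        panel = make_panel({"P1": {"glucose": [1.0, 2.0, 3.0]}})
        probs = pd.DataFrame(
            {"glucose": [0.0, 0.0, 1.0]}, index=panel.values.index
        )
        res = pq.OutlierResult("em", {}, probs > 0.9, probabilities=probs,
                               threshold=0.9)
        out = pq.descriptives(panel, res, weighted=True)
        assert out.loc["glucose", "mean_mean"] == pytest.approx(1.5)

    def test_flagging_minimum_raises_min(self):
        panel = make_panel({"P1": {"glucose": [1.0, 2.0, 3.0, 4.0]}})
        res = _result(panel, [("P1", 0, "glucose")])
        out = pq.descriptives(panel, res)
        assert out.loc["glucose", "min_mean"] == 2.0
        assert out.loc["glucose", "mean_mean"] == pytest.approx(3.0)

    def test_removing_nothing_changes_nothing(self, full_panel):
        base = pq.descriptives(full_panel)
        same = pq.descriptives(full_panel, _result(full_panel, []))
        pd.testing.assert_frame_equal(base, same)


class TestCrossCorrelation:
    def _series(self, values):
        return pd.Series(np.asarray(values, dtype=float),
                         index=np.arange(len(values)))

    def test_identity_peaks_at_lag_zero(self):
        rng = np.random.default_rng(1)
        x = self._series(rng.standard_normal(100))
        r = pq.cross_correlation(x, x, max_lag_minutes=60)
        assert r.lag0 == pytest.approx(1.0)
        assert r.max_correlation == pytest.approx(1.0)
        assert r.lag_at_max == 0

    def test_forward_shift_gives_negative_lag(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(120)
        x = self._series(base[:-2])
        y = self._series(base[2:])  # y(t) = x(t+2): y leads x
        r = pq.cross_correlation(x, y, max_lag_minutes=60)
        assert r.lag_at_max == -20.0
        assert r.max_correlation == pytest.approx(1.0)

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(3)
        x = self._series(rng.standard_normal(80))
        y = self._series(rng.standard_normal(80) + 0.5 * x.to_numpy())
        rxy = pq.cross_correlation(x, y, max_lag_minutes=40)
        ryx = pq.cross_correlation(y, x, max_lag_minutes=40)
        np.testing.assert_allclose(rxy.correlations, ryx.correlations[::-1],
                                   atol=1e-12)

    def test_unit_weights_match_unweighted(self):
        rng = np.random.default_rng(4)
        x = self._series(rng.standard_normal(90))
        y = self._series(rng.standard_normal(90))
        w = pd.Series(1.0, index=x.index)
        r0 = pq.cross_correlation(x, y, max_lag_minutes=30)
        r1 = pq.cross_correlation(x, y, max_lag_minutes=30, weights_x=w,
                                  weights_y=w)
        np.testing.assert_allclose(r0.correlations, r1.correlations)

    def test_insufficient_overlap_is_missing(self):
        x = self._series([1.0, 2.0, 3.0] * 4)
        r = pq.cross_correlation(x, x, max_lag_minutes=30, min_overlap=10)
        # at lag ±30 min only 9 pairs overlap
        assert np.isnan(r.correlations[0]) and np.isnan(r.correlations[-1])


class TestOverlap:
    def test_basic_regions(self, full_panel):
        a = _result(full_panel, [("P1", 0, "glucose"), ("P1", 1, "glucose")], "A")
        b = _result(full_panel, [("P1", 1, "glucose"), ("P1", 2, "glucose")], "B")
        regions = pq.overlap_counts({"A": a, "B": b})
        assert regions == {"A": 1, "B": 1, "A&B": 1}

    def test_identical_results_all_shared(self, full_panel):
        keys = [("P1", 5, "TSH"), ("P1", 9, "GH")]
        regions = pq.overlap_counts(
            {"A": _result(full_panel, keys), "B": _result(full_panel, keys)}
        )
        assert regions == {"A": 0, "B": 0, "A&B": 2}

    def test_disjoint_results(self, full_panel):
        a = _result(full_panel, [("P1", 0, "glucose")])
        b = _result(full_panel, [("P1", 1, "glucose")])
        regions = pq.overlap_counts({"A": a, "B": b})
        assert regions["A&B"] == 0

    def test_three_way_regions_sum_to_union(self, sim_panel_truth):
        panel, _ = sim_panel_truth
        results = {
            "tukey": pq.detect_tukey(panel),
            "stepwise": pq.detect_stepwise(panel),
            "em": pq.detect_em(panel, seed=0),
        }
        regions = pq.overlap_counts(results, level="datapoint")
        union = set()
        for res in results.values():
            union |= res.flagged_keys()
        assert sum(regions.values()) == len(union)
        # marginal totals recoverable from the regions
        for name, res in results.items():
            total = sum(v for k, v in regions.items() if name in k.split("&"))
            assert total == len(res.flagged_keys())


class TestDetectionPerformance:
    def test_confusion_arithmetic(self, full_panel):
        truth_keys = [("P1", t, "glucose") for t in range(5)]
        found = truth_keys[:4] + [("P1", 50, "TSH"), ("P1", 60, "GH")]
        mask = pd.DataFrame(False, index=full_panel.values.index,
                            columns=full_panel.hormones)
        etype = pd.DataFrame(None, index=full_panel.values.index,
                             columns=full_panel.hormones, dtype=object)
        for (p, t, h) in truth_keys:
            mask.loc[(p, t), h] = True
            etype.loc[(p, t), h] = "spike"
        truth = pq.SimulationTruth(error_mask=mask, error_type=etype)
        res = _result(full_panel, found)
        perf = pq.detection_performance(res, truth, full_panel)
        assert perf.loc["overall", "sensitivity"] == pytest.approx(0.8)
        assert perf.loc["overall", "precision"] == pytest.approx(4 / 6)

    def test_perfect_and_empty_detectors(self, sim_panel_truth):
        panel, truth = sim_panel_truth
        perfect = pq.OutlierResult("m", {}, truth.error_mask & panel.notna())
        perf = pq.detection_performance(perfect, truth, panel)
        assert perf.loc["overall", "sensitivity"] == 1.0
        assert perf.loc["overall", "specificity"] == 1.0
        empty = _result(panel, [])
        perf = pq.detection_performance(empty, truth, panel)
        assert perf.loc["overall", "sensitivity"] == 0.0
        assert perf.loc["overall", "specificity"] == 1.0
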