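import datetime as dt

import numpy as np
import pytest

from gmolesta import (
    DAMAS_MODEL,
    KIM_MODEL,
    TABLE1_PARAMS,
    DeviationRecord,
    accumulate_cdd,
    cdd_to_julian_day,
    deviation_anova,
    deviation_summary,
    observed_50pct,
    peak_cdd,
    predict_peak_days,
    segment_peaks,
)
from gmolesta.errors import InvalidInputError
from gmolesta.experiments import validation_loop


class TestSegmentPeaks:
    def test_four_clean_peaks(self):
        seg = segment_peaks([1, 3, 1, 2, 5, 2, 1, 4, 2, 1, 6, 3])
        assert len(seg.segments) == 4
        assert not seg.shortfall
        maxima = [s.start + int(np.argmax(s.counts)) for s in seg.segments]
        assert maxima == [1, 4, 10 - 3, 10]  # observations 2, 5, 8, 11 (1-based)

    def test_totals_partition_the_series(self):
        counts = [0, 1, 3, 1, 2, 5, 2, 1, 4, 2, 1, 6, 3, 0]
        seg = segment_peaks(counts)
        assert sum(s.total for s in seg.segments) == sum(counts)

    def test_single_hump_flags_shortfall(self):
        seg = segment_peaks([0, 0, 2, 4, 1, 0, 0])
        assert len(seg.segments) == 1
        assert seg.shortfall
        assert seg.segments[0].counts == (2, 4, 1)

    def test_strictly_increasing_is_one_open_segment(self):
        seg = segment_peaks([1, 2, 3, 4, 5])
        assert len(seg.segments) == 1
        assert seg.shortfall

    def test_more_than_four_candidates_merged_preserving_total(self):
        counts = [5, 1, 6, 1, 7, 1, 8, 1, 2, 1]  # five decrease endings
        seg = segment_peaks(counts)
        assert seg.n_candidates > 4
        assert len(seg.segments) == 4
        assert sum(s.total for s in seg.segments) == sum(counts)

    def test_all_zero_series_raises(self):
        with pytest.raises(InvalidInputError):
            segment_peaks([0, 0, 0])

    def test_ties_continue_the_phase(self):
        # plateau at the top is one peak, not two
        seg = segment_peaks([1, 3, 3, 1, 2, 5, 1, 1, 4, 1, 2, 6, 1])
        assert len(seg.segments) == 4


class TestObserved50pct:
    def test_symmetric_two_reads_cross_halfway(self):
        seg = segment_peaks([2, 2]).segments[0]
        res = observed_50pct(seg, [100.0, 115.0])
        assert res.value == pytest.approx(107.5)

    def test_bracketing_interpolation(self):
        seg = segment_peaks([1, 3]).segments[0]
        res = observed_50pct(seg, [100.0, 115.0])
        # 100 + 15 * (0.5 - 0.25) / (1.0 - 0.25)
        assert res.value == pytest.approx(105.0)

    def test_single_observation_is_edge_flagged(self):
        seg = segment_peaks([4, 1]).segments[0]  # first read already past half
        res = observed_50pct(seg, [100.0, 115.0])
        assert res.edge
        assert res.value == 100.0

    def test_result_lies_within_segment_span(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            counts = list(rng.integers(1, 20, size=6))
            seg = segment_peaks(counts).segments[0]
            axis = np.arange(seg.start, seg.stop + 1) * 15.0 + 60.0
            val = observed_50pct(seg, axis).value
            assert axis[0] <= val <= axis[-1]


class TestPredictPeakDays:
    def test_first_peak_day_by_construction(self, quiet_year_temps, quiet_year_cdd):
        days = predict_peak_days(TABLE1_PARAMS, quiet_year_temps)
        assert days[0] == cdd_to_julian_day(quiet_year_cdd, 172.23)

    def test_days_nondecreasing_across_peaks(self, quiet_year_temps):
        for model in (TABLE1_PARAMS, KIM_MODEL, DAMAS_MODEL):
            days = predict_peak_days(model, quiet_year_temps)
            got = [d for d in days if d is not None]
            assert got == sorted(got)

    def test_matches_direct_scan_oracle(self, quiet_year_temps):
        for model in (KIM_MODEL, DAMAS_MODEL):
            cdd = accumulate_cdd(quiet_year_temps, model.thresholds)
            for day, target in zip(predict_peak_days(model, quiet_year_temps), model.peak_cdds):
                scan = next(
                    (i + 1 for i, c in enumerate(cdd.cumulative) if c >= target), None
                )
                assert day == scan


TABLE2_OBSERVED = (139.0, 169.0, 204.0, 242.0)
TABLE2_PREDICTED = {
    "this study": (119, 169, 205, 236),
    "Kim et al.": (104, 168, 206, 242),
    "Damas et al.": (99, 124, 165, 217),
}


def _table2_records():
    return [
        DeviationRecord(site_id="KR", year=2024, model=name,
                        predicted=pred, observed=TABLE2_OBSERVED)
        for name, pred in TABLE2_PREDICTED.items()
    ]


class TestDeviationSummary:
    def test_published_mean_deviations(self):
        summary = deviation_summary(_table2_records())
        assert summary.loc["this study", "mean_abs_dev"] == pytest.approx(6.75)
        assert summary.loc["Kim et al.", "mean_abs_dev"] == pytest.approx(9.50)
        assert summary.loc["Damas et al.", "mean_abs_dev"] == pytest.approx(37.25)

    def test_published_improvement_margins(self):
        summary = deviation_summary(_table2_records())
        ours = summary.loc["this study", "mean_abs_dev"]
        assert round(summary.loc["Kim et al.", "mean_abs_dev"] - ours, 1) == 2.8
        assert round(summary.loc["Damas et al.", "mean_abs_dev"] - ours, 1) == 30.5

    def test_identical_prediction_gives_zero(self):
        rec = DeviationRecord(site_id="X", year=2024, model="m",
                              predicted=(100, 150, 200, 250),
                              observed=(100.0, 150.0, 200.0, 250.0))
        summary = deviation_summary([rec])
        assert summary.loc["m", "mean_abs_dev"] == 0.0


class TestDeviationAnova:
    def test_identical_groups_share_one_letter(self):
        res = deviation_anova({"a": [3.0] * 5, "b": [3.0] * 5, "c": [3.0] * 5})
        assert res.f_statistic == 0.0
        assert len(set(res.letters.values())) == 1

    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(2)
        res = deviation_anova(
            {"small": 1.0 + rng.normal(0, 0.1, 5), "large": 100.0 + rng.normal(0, 0.1, 5)}
        )
        assert res.letters["small"] != res.letters["large"]
        assert res.p_value < 1e-6

    def test_f_matches_two_pass_oracle(self):
        rng = np.random.default_rng(4)
        groups = {f"g{i}": rng.normal(i, 1.0, 8) for i in range(3)}
        res = deviation_anova(groups)
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_oracle = (ssb / 2) / (ssw / (len(allv) - 3))
        assert res.f_statistic == pytest.approx(f_oracle, abs=1e-9)

    def test_degenerate_groups_raise(self):
        with pytest.raises(InvalidInputError):
            deviation_anova({"only": [1.0, 2.0]})


class TestValidationLoop:
    def test_observed_half_occurrence_converges_to_generating_medians(self):
        """Dense large-N data: each peak's observed 50% CDD lands within one
        observation interval of the generating component median."""
        res = validation_loop(seed=3)
        assert not res["segmentation"].shortfall
        for err, width in zip(res["abs_error_cdd"], res["interval_width_cdd"]):
            assert err <= width
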