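"""Flowering curves, 50%-crossing estimation, and error arithmetic."""

import datetime as dt

import numpy as np
import pytest

import headingdate as hd
from headingdate.core import ValidationError
from headingdate.detector import DetectionSet


def make_detections(daily_counts, start=dt.date(2013, 8, 1),
                    times=(dt.time(9, 0),)):
    """DetectionSets with the given count on consecutive days (each day's
    count split equally over ``times`` is not attempted: every image of a
    day carries the full per-image count given)."""
    dets = []
    for i, counts in enumerate(daily_counts):
        if not isinstance(counts, (list, tuple)):
            counts = [counts] * len(times)
        for t, c in zip(times, counts):
            ts = dt.datetime.combine(start + dt.timedelta(days=i), t)
            dets.append(DetectionSet(
                f"img_{i}_{t.hour}", ts, None,
                [hd.Box(0, 0, 1, 1)] * c, [1.0] * c))
    return dets


class TestFloweringCurve:
    def test_running_sum(self):
        curve = hd.build_flowering_curve(make_detections([1, 3, 4, 2]))
        assert curve.counts == [1, 3, 4, 2]
        assert curve.cumulative == [1, 4, 8, 10]
        assert curve.total == 10

    def test_all_zero_counts(self):
        curve = hd.build_flowering_curve(make_detections([0, 0, 0]))
        assert curve.total == 0
        assert curve.cumulative == [0, 0, 0]

    def test_daily_totals_group_multiple_images(self):
        dets = make_detections([[1, 2], [3, 0]],
                               times=(dt.time(9, 0), dt.time(15, 0)))
        curve = hd.build_flowering_curve(dets)
        assert sorted(curve.daily_totals.values()) == [3, 3]

    def test_duplicate_timestamps_rejected(self):
        d = make_detections([1])[0]
        clone = DetectionSet("other", d.timestamp, None, [], [])
        with pytest.raises(ValidationError, match="duplicate"):
            hd.build_flowering_curve([d, clone])

    def test_cumulative_nondecreasing_and_ends_at_total(self):
        rng = np.random.default_rng(4)
        curve = hd.build_flowering_curve(
            make_detections(list(rng.integers(0, 9, size=14))))
        assert all(b >= a for a, b in zip(curve.cumulative,
                                          curve.cumulative[1:]))
        assert curve.cumulative[-1] == curve.total
        assert sum(curve.daily_totals.values()) == curve.total


class TestHeadingEstimate:
    def test_crossing_day(self):
        curve = hd.build_flowering_curve(make_detections([1, 3, 4, 2]))
        est = hd.estimate_heading_date(curve, dt.date(2013, 8, 1))
        assert est.estimated_date == dt.date(2013, 8, 3)  # cumulative 8 >= 5
        assert est.estimated_day == 2

    def test_single_day_flowering(self):
        curve = hd.build_flowering_curve(make_detections([0, 12, 0]))
        assert (hd.estimate_heading_date(curve).estimated_date
                == dt.date(2013, 8, 2))

    def test_tie_uses_first_crossing(self):
        curve = hd.build_flowering_curve(make_detections([1, 2, 2, 1]))
        # cumulative 1,3,5,6; half-total 3 -> day 2 by the >= rule
        assert (hd.estimate_heading_date(curve).estimated_date
                == dt.date(2013, 8, 2))

    def test_no_flowering_is_error(self):
        curve = hd.build_flowering_curve(make_detections([0, 0]))
        with pytest.raises(ValidationError, match="no flowering"):
            hd.estimate_heading_date(curve)

    def test_time_shift_equivariance(self):
        base = hd.build_flowering_curve(make_detections([2, 5, 1]))
        shifted = hd.build_flowering_curve(
            make_detections([2, 5, 1], start=dt.date(2013, 8, 11)))
        assert (hd.estimate_heading_date(shifted).estimated_date
                - hd.estimate_heading_date(base).estimated_date).days == 10

    def test_count_scale_invariance(self):
        a = hd.build_flowering_curve(make_detections([2, 5, 1]))
        b = hd.build_flowering_curve(make_detections([6, 15, 3]))
        assert (hd.estimate_heading_date(a).estimated_date
                == hd.estimate_heading_date(b).estimated_date)


class TestErrorArithmetic:
    @pytest.mark.parametrize("observed,estimated,expected", [
        (dt.date(2013, 8, 24), dt.date(2013, 8, 26), +2),
        (dt.date(2014, 8, 6), dt.date(2014, 8, 6), 0),
        (dt.date(2014, 8, 6), dt.date(2014, 8, 5), -1),
    ])
    def test_signed_day_convention(self, observed, estimated, expected):
        assert hd.estimation_error(estimated, observed) == expected

    def test_mean_absolute_error(self):
        assert hd.mean_absolute_error([+2, +1, +1, 0, 0]) == pytest.approx(0.8)
        assert hd.mean_absolute_error([0, 0, 0]) == 0.0
        assert hd.mean_absolute_error([-1, +1]) == 1.0
        with pytest.raises(ValidationError):
            hd.mean_absolute_error([])


def test_end_to_end_oracle_recovers_true_day(small_series):
    """Oracle detection + 50% rule reproduce the generator's analytic
    heading day on the tiny series."""
    window = hd.WindowConfig(80, 80, 80, classifier_input_size=32)
    dets = hd.detect_series(small_series, hd.LuminanceOracle(), window)
    curve = hd.build_flowering_curve(dets)
    est = hd.estimate_heading_date(curve, small_series.transplanting_date)
    params = hd.PhenologyParams(emergence_schedule={80: 2, 81: 3},
                                images_per_day=1, rng_seed=7)
    assert est.estimated_day == hd.true_heading_date(params) == 81


def test_field_observation_fixture_consistency():
    """The shipped field-book reference dates reproduce their own printed
    signed errors."""
    for name, obs in hd.FIELD_OBSERVATIONS.items():
        err = hd.estimation_error(obs.reported_estimated_50_date,
                                  obs.observed_50_date)
        assert err == obs.reported_error_days, name
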