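"""Flowering curves and 50%-flowering (heading) date estimation.

The heading date of a paddy-rice crop is operationalised as the date when
half of the panicles have exserted.  Detected flowering-region counts are a
proxy proportional to the panicle count, so the estimator accumulates the
per-image region counts over the season in timestamp order and reports the
calendar day of the first image at which the running total reaches 50% of
the season total (>= rule, no interpolation: whole-day estimates).

The curve is built from raw per-image counts rather than per-day sums, so
the 50% crossing is located against the time each image was captured;
per-day totals are kept alongside for plotting and correlation checks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ValidationError
from .detector import DetectionSet, count_regions


@dataclass
class FloweringCurve:
    """Per-image counts, per-day totals and the cumulative count curve."""

    timestamps: list[dt.datetime]
    counts: list[int]
    cumulative: list[int]
    daily_totals: dict[dt.date, int]
    total: int

    def day_totals_by_index(self, transplanting_date: dt.date) -> dict[int, int]:
        return {(day - transplanting_date).days: c
                for day, c in self.daily_totals.items()}


@dataclass
class HeadingEstimate:
    """Estimated 50%-flowering date with optional field-observation error."""

    estimated_date: dt.date
    estimated_timestamp: dt.datetime
    estimated_day: int | None = None
    observed_date: dt.date | None = None
    error_days: int | None = None

    def against_observed(self, observed: dt.date) -> "HeadingEstimate":
        return HeadingEstimate(
            estimated_date=self.estimated_date,
            estimated_timestamp=self.estimated_timestamp,
            estimated_day=self.estimated_day,
            observed_date=observed,
            error_days=estimation_error(self.estimated_date, observed))


def build_flowering_curve(detections: Sequence[DetectionSet]) -> FloweringCurve:
    """Aggregate per-image detection counts into a flowering curve.

    Images are ordered by timestamp; duplicate timestamps are an error
    (they would make the cumulative curve ambiguous).
    """
    dets = sorted(detections, key=lambda d: d.timestamp)
    for a, b in zip(dets, dets[1:]):
        if a.timestamp == b.timestamp:
            raise ValidationError(
                f"duplicate timestamp {a.timestamp} "
                f"({a.image_id!r} and {b.image_id!r})")
    timestamps = [d.timestamp for d in dets]
    counts = [count_regions(d) for d in dets]
    cumulative = list(np.cumsum(counts, dtype=int)) if counts else []
    daily: dict[dt.date, int] = {}
    for ts, c in zip(timestamps, counts):
        daily[ts.date()] = daily.get(ts.date(), 0) + c
    return FloweringCurve(timestamps=timestamps, counts=counts,
                          cumulative=cumulative, daily_totals=daily,
                          total=int(sum(counts)))


def estimate_heading_date(curve: FloweringCurve,
                          transplanting_date: dt.date | None = None
                          ) -> HeadingEstimate:
    """First image timestamp whose cumulative count reaches half the season
    total; its calendar day is the estimated heading date."""
    if curve.total <= 0:
        raise ValidationError("no flowering detected: cannot estimate the "
                              "50%-flowering date")
    for ts, cum in zip(curve.timestamps, curve.cumulative):
        if 2 * cum >= curve.total:
            day = ((ts.date() - transplanting_date).days
                   if transplanting_date is not None else None)
            return HeadingEstimate(estimated_date=ts.date(),
                                   estimated_timestamp=ts,
                                   estimated_day=day)
    raise AssertionError("unreachable: cumulative curve ends at total")


def estimation_error(estimated: dt.date, observed: dt.date) -> int:
    """Signed whole-day error: (estimated) − (field observed)."""
    return (estimated - observed).days


def mean_absolute_error(errors: Sequence[int | float]) -> float:
    """Mean of absolute signed-day errors."""
    if len(errors) == 0:
        raise ValidationError("no errors to average")
    return float(np.mean(np.abs(np.asarray(errors, dtype=float))))


@dataclass(frozen=True)
class FieldObservation:
    """Field-book reference dates for one real acquisition sequence.

    ``paper_day_labels`` keeps the printed day numbering of the source
    field study verbatim; note it differs from elapsed-day counting
    (transplanting = day 0) by +1 for the 2013 rows and +2 for the 2014
    rows, so the package reports calendar dates and its own elapsed days
    and never mixes the two conventions.
    """

    transplanting_date: dt.date
    first_panicle_date: dt.date
    observed_50_date: dt.date
    reported_estimated_50_date: dt.date
    reported_error_days: int
    paper_day_labels: tuple[int, int, int] = ()  # 1st panicle, observed, estimated


#: Reference field observations of the five real sequences (inputs to the
#: error computation, not recomputed by the package).
FIELD_OBSERVATIONS: dict[str, FieldObservation] = {
    "Kinmaze": FieldObservation(
        dt.date(2013, 5, 31), dt.date(2013, 8, 21),
        dt.date(2013, 8, 24), dt.date(2013, 8, 26), +2, (83, 86, 88)),
    "Kamenoo": FieldObservation(
        dt.date(2013, 5, 31), dt.date(2013, 8, 20),
        dt.date(2013, 8, 23), dt.date(2013, 8, 24), +1, (82, 85, 86)),
    "Koshihikari-1": FieldObservation(
        dt.date(2014, 5, 29), dt.date(2014, 8, 2),
        dt.date(2014, 8, 5), dt.date(2014, 8, 6), +1, (67, 70, 71)),
    "Koshihikari-2": FieldObservation(
        dt.date(2014, 5, 29), dt.date(2014, 8, 3),
        dt.date(2014, 8, 6), dt.date(2014, 8, 6), 0, (68, 71, 71)),
    "Koshihikari-3": FieldObservation(
        dt.date(2014, 5, 29), dt.date(2014, 8, 4),
        dt.date(2014, 8, 7), dt.date(2014, 8, 7), 0, (69, 72, 72)),
}


def plot_flowering_curve(curve: FloweringCurve, path,
                         estimate: HeadingEstimate | None = None,
                         title: str = "") -> None:
    """Write a flowering-stage plot (per-day counts + cumulative curve)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    days = sorted(curve.daily_totals)
    ax.bar(days, [curve.daily_totals[d] for d in days],
           color="tab:green", alpha=0.6, label="regions per day")
    ax2 = ax.twinx()
    ax2.plot(curve.timestamps, curve.cumulative, color="tab:blue",
             label="cumulative")
    ax2.axhline(curve.total / 2, color="grey", ls="--", lw=0.8)
    if estimate is not None:
        ax2.axvline(estimate.estimated_timestamp, color="tab:red", ls=":",
                    label=f"50% flowering: {estimate.estimated_date}")
    ax.set_xlabel("date")
    ax.set_ylabel("detected flowering regions / day")
    ax2.set_ylabel("cumulative detected regions")
    if title:
        ax.set_title(title)
    fig.autofmt_xdate()
    handles, labels = ax2.get_legend_handles_labels()
    ax2.legend(handles, labels, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
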