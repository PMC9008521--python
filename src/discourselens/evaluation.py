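"""Recovery checks of planted structure from a pipeline run.

Given a :class:`~discourselens.pipeline.PipelineResult` produced from a
synthetic stream and its ground truth, this module measures how well
the pipeline recovers the planted phenomena: the orders-of-magnitude
rank improvement of the anchor phrase, event-day rank spikes with the
planted happiness-shift signs, and the month in which retweets of the
anchor first sustainedly outnumber organic uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def median_rank_by_year(rank_series: pd.Series) -> pd.Series:
    """Median daily rank per calendar year, ignoring missing days."""
    return rank_series.groupby(rank_series.index.year).median()


def rank_improvement(rank_series: pd.Series) -> dict:
    """First-year vs last-year median rank and the improvement factor
    (>1 means the last year ranks better, i.e. numerically smaller)."""
    medians = median_rank_by_year(rank_series).dropna()
    if len(medians) < 2:
        raise ValueError("need at least two years with observed ranks")
    first_year, last_year = int(medians.index[0]), int(medians.index[-1])
    first, last = float(medians.iloc[0]), float(medians.iloc[-1])
    return {
        "first_year": first_year,
        "last_year": last_year,
        "first_year_median_rank": first,
        "last_year_median_rank": last,
        "improvement_factor": first / last,
    }


def event_checks(
    result, *, baseline_days: int = 14, spike_factor: float = 2.0
) -> pd.DataFrame:
    """Per planted event: did the anchor's rank spike, and did the
    ambient-happiness shift have the planted sign?

    A spike means the event-day rank is at least ``spike_factor`` times
    better (smaller) than the median rank over the ``baseline_days``
    days before the event.  Sign correctness: awareness events must
    shift happiness up, tragedies down.
    """
    rows = []
    series = result.rank_series
    for rec in result.shifts:
        ev_date = pd.Timestamp(rec["date"])
        day_rank = series.get(ev_date, np.nan)
        window = series.loc[
            ev_date - pd.Timedelta(days=baseline_days) : ev_date - pd.Timedelta(days=1)
        ].dropna()
        baseline = float(window.median()) if len(window) else np.nan
        spiked = bool(
            np.isfinite(day_rank)
            and np.isfinite(baseline)
            and day_rank * spike_factor <= baseline
        )
        delta = rec["delta"]
        if rec["status"] != "ok" or not np.isfinite(delta):
            sign_ok = False
        elif rec["kind"] == "awareness":
            sign_ok = delta > 0
        else:
            sign_ok = delta < 0
        rows.append(
            {
                "date": rec["date"],
                "kind": rec["kind"],
                "rank_on_day": float(day_rank) if np.isfinite(day_rank) else np.nan,
                "baseline_rank": baseline,
                "rank_spike": spiked,
                "delta_h": delta,
                "sign_correct": bool(sign_ok),
            }
        )
    return pd.DataFrame(rows)


def crossing_error_months(result, truth) -> dict:
    """Detected vs planted retweet-balance crossing month."""
    planted = truth.planted_crossing_month
    detected = result.crossing
    detected_str = str(detected) if detected is not None else None
    if planted is None or detected is None:
        err = None
    else:
        p = pd.Period(planted, freq="M")
        d = pd.Period(detected_str, freq="M")
        err = int((d - p).n)
    return {
        "planted_month": planted,
        "detected_month": detected_str,
        "error_months": err,
    }


def qualitative_report(result, truth) -> dict:
    """Bundle the planted-structure recovery checks into one record."""
    growth = rank_improvement(result.rank_series)
    events = event_checks(result)
    crossing = crossing_error_months(result, truth)
    n_events = len(events)
    return {
        "growth": growth,
        "events": events,
        "event_sign_accuracy": (
            float(events["sign_correct"].mean()) if n_events else None
        ),
        "event_spike_accuracy": (
            float(events["rank_spike"].mean()) if n_events else None
        ),
        "crossing": crossing,
    }
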