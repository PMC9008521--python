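"""Contagiogram statistics: organic/retweet balance, relative
amplification against the background corpus, and smoothed rank panels.

For a target n-gram, each month m gets the organic and retweet shares
f_OT(m) + f_RT(m) = 1 of its occurrences; months with f_RT > 1/2 are
*amplified* (retweets outnumber originals).  The heatmap statistic is
the relative amplification

    R = [c_RT,tau / c_OT,tau] / [C_RT / C_OT],

the target's retweet/organic odds divided by the background corpus
odds over all n-grams of the same order in the same (weekday, month)
cell.  R > 1 means the target is retweeted more than a typical n-gram;
cells are aggregated as ratios of summed counts, never means of daily
ratios, and cells with zero organic counts are reported undefined
rather than clamped.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .ngrams import NgramLedger
from .sentiment import rolling_smooth


def _target_daily_counts(
    ledgers: Mapping[dt.date, NgramLedger], target: str
) -> pd.DataFrame:
    rows = []
    for date in sorted(ledgers):
        _, ot, rt = ledgers[date].entry(target)
        rows.append((date, ot, rt))
    if not rows:
        raise ValueError("no daily ledgers supplied")
    df = pd.DataFrame(rows, columns=["date", "ot", "rt"])
    df["date"] = pd.to_datetime(df["date"])
    return df.set_index("date")


def monthly_balance(
    ledgers: Mapping[dt.date, NgramLedger], target: str
) -> pd.DataFrame:
    """Per-month organic/retweet fractions of the target n-gram.

    Columns ``f_ot, f_rt, amplified``; months with zero occurrences are
    missing (NaN fractions, amplified=False).
    """
    daily = _target_daily_counts(ledgers, target)
    monthly = daily.resample("MS").sum()
    total = monthly["ot"] + monthly["rt"]
    with np.errstate(invalid="ignore"):
        f_rt = monthly["rt"] / total
    f_rt[total == 0] = np.nan
    out = pd.DataFrame(
        {
            "month": monthly.index.to_period("M"),
            "f_ot": 1.0 - f_rt,
            "f_rt": f_rt,
            "amplified": (f_rt > 0.5).fillna(False),
        }
    ).set_index("month")
    return out


def amplification_heatmap(
    ledgers: Mapping[dt.date, NgramLedger],
    target: str,
    background: pd.DataFrame,
) -> pd.DataFrame:
    """Relative amplification R on a (weekday, month) grid.

    ``background`` is a date-indexed frame with columns ``ot, rt``
    giving total organic/retweet token counts for the same n-gram order;
    it must cover every date the target ledgers cover.  Returns columns
    ``weekday, month, R, defined, c_ot, c_rt, bg_ot, bg_rt``.
    """
    daily = _target_daily_counts(ledgers, target)
    bg = background.copy()
    bg.index = pd.to_datetime(bg.index)
    missing = daily.index.difference(bg.index)
    if len(missing):
        days = ", ".join(str(d.date()) for d in missing[:10])
        raise ValueError(f"background missing {len(missing)} dates: {days}")

    joined = daily.join(bg.rename(columns={"ot": "bg_ot", "rt": "bg_rt"}))
    joined["weekday"] = joined.index.dayofweek
    joined["month"] = joined.index.to_period("M")
    g = joined.groupby(["weekday", "month"], observed=True)[
        ["ot", "rt", "bg_ot", "bg_rt"]
    ].sum()
    defined = (g["ot"] > 0) & (g["bg_ot"] > 0) & (g["bg_rt"] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (g["rt"] / g["ot"]) / (g["bg_rt"] / g["bg_ot"])
    out = g.reset_index().rename(
        columns={"ot": "c_ot", "rt": "c_rt"}
    )
    out["R"] = np.where(defined.to_numpy(), R.to_numpy(), np.nan)
    out["defined"] = defined.to_numpy()
    return out[["weekday", "month", "R", "defined", "c_ot", "c_rt", "bg_ot", "bg_rt"]]


@dataclass
class RankPanel:
    """Daily rank series with month-scale smoothing and weekly envelope."""

    daily: pd.Series
    smoothed: pd.Series
    weekly_band: pd.DataFrame  # index ISO (year, week), columns min/max


def smoothed_rank_panel(
    rank_series: pd.Series, window_days: int = 30
) -> RankPanel:
    """Month-scale smoothing of a daily rank series.

    Smoothing is a trailing mean of log10(rank) transformed back —
    ranks live on a log axis — skipping missing days; the weekly band is
    the per-ISO-week min and max of the raw ranks.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    s = rank_series.astype(float)
    s.index = pd.to_datetime(s.index)
    log_s = np.log10(s)
    smoothed = 10.0 ** rolling_smooth(log_s, window_days)
    iso = s.index.isocalendar()
    band = (
        pd.DataFrame({"rank": s.to_numpy(), "year": iso["year"].to_numpy(), "week": iso["week"].to_numpy()})
        .groupby(["year", "week"])["rank"]
        .agg(["min", "max"])
    )
    return RankPanel(daily=s, smoothed=smoothed, weekly_band=band)


def detect_crossing(
    balance: pd.DataFrame, min_run: int = 3
) -> pd.Period | None:
    """Earliest month beginning a run of >= ``min_run`` consecutive
    amplified months (f_RT > 1/2), or None.

    Months with no occurrences break a run.
    """
    if len(balance) < min_run:
        return None
    months = balance.index
    amplified = balance["amplified"].to_numpy(dtype=bool)
    run = 0
    for i, flag in enumerate(amplified):
        run = run + 1 if flag else 0
        if run == min_run:
            return months[i - min_run + 1]
    return None
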