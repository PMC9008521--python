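"""Contagiogram statistics: OT/RT balance, relative amplification
against the background, rank smoothing and crossing detection."""

import datetime as dt
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from discourselens.amplification import (
    amplification_heatmap,
    detect_crossing,
    monthly_balance,
    smoothed_rank_panel,
)
from discourselens.ngrams import NgramLedger, count_stream
from discourselens.schedules import LogisticSchedule
from discourselens.synth import StreamConfig, generate_stream
from discourselens.tables import daily_ledger_map

from .oracles import naive_log_rolling_mean


def target_ledger(date, ot, rt, gram="t", n=2):
    return NgramLedger(
        date, n, Counter({gram: ot} if ot else {}), Counter({gram: rt} if rt else {})
    )


def month_of_daily(year, month, ot_per_day, rt_per_day):
    days = pd.date_range(dt.date(year, month, 1), periods=28, freq="D")
    return {d.date(): target_ledger(d.date(), ot_per_day, rt_per_day) for d in days}


class TestMonthlyBalance:
    def test_fractions_and_amplified_flag(self):
        ledgers = month_of_daily(2021, 1, ot_per_day=0, rt_per_day=0)
        ledgers.update(
            {
                dt.date(2021, 1, 5): target_ledger(dt.date(2021, 1, 5), 10, 30),
            }
        )
        out = monthly_balance(ledgers, "t")
        row = out.loc[pd.Period("2021-01")]
        assert row["f_rt"] == pytest.approx(0.75)
        assert row["f_ot"] == pytest.approx(0.25)
        assert bool(row["amplified"])

    def test_equal_counts_not_amplified(self):
        ledgers = {dt.date(2021, 2, 1): target_ledger(dt.date(2021, 2, 1), 5, 5)}
        out = monthly_balance(ledgers, "t")
        assert out.iloc[0]["f_rt"] == pytest.approx(0.5)
        assert not bool(out.iloc[0]["amplified"])

    def test_empty_month_missing(self):
        ledgers = {
            dt.date(2021, 1, 3): target_ledger(dt.date(2021, 1, 3), 2, 1),
            dt.date(2021, 3, 3): target_ledger(dt.date(2021, 3, 3), 1, 2),
        }
        out = monthly_balance(ledgers, "t")
        assert np.isnan(out.loc[pd.Period("2021-02"), "f_rt"])
        assert not bool(out.loc[pd.Period("2021-02"), "amplified"])

    def test_matches_brute_force_recount(self, rng, small_vocab):
        from .oracles import random_stream

        stream = random_stream(rng, 400, small_vocab, span_days=90)
        daily = daily_ledger_map(count_stream(stream, orders=(2,)), 2)
        out = monthly_balance(daily, "mental health")
        for month, row in out.iterrows():
            ot = rt = 0
            for tw in stream:
                if pd.Period(tw.date, freq="M") != month:
                    continue
                from discourselens.ngrams import extract_ngrams, tokenize

                hits = extract_ngrams(tokenize(tw.text), 2).count("mental health")
                if tw.is_retweet:
                    rt += hits
                else:
                    ot += hits
            if ot + rt == 0:
                assert np.isnan(row["f_rt"])
            else:
                assert row["f_rt"] == pytest.approx(rt / (ot + rt))

    def test_f_ot_plus_f_rt_is_one(self, rng):
        days = pd.date_range("2021-01-01", periods=120, freq="D")
        ledgers = {
            d.date(): target_ledger(
                d.date(), int(rng.integers(0, 9)), int(rng.integers(0, 9))
            )
            for d in days
        }
        out = monthly_balance(ledgers, "t").dropna()
        assert np.allclose(out["f_ot"] + out["f_rt"], 1.0, atol=1e-12)


class TestHeatmap:
    def background(self, dates, ot, rt):
        return pd.DataFrame({"date": dates, "ot": ot, "rt": rt}).set_index("date")

    def test_three_to_one_odds_vs_flat_background(self):
        days = [dt.date(2021, 3, 1) + dt.timedelta(days=k) for k in range(28)]
        ledgers = {d: target_ledger(d, 1, 3) for d in days}
        bg = self.background(days, [100] * 28, [100] * 28)
        out = amplification_heatmap(ledgers, "t", bg)
        assert np.allclose(out["R"], 3.0)

    def test_self_comparison_is_neutral(self, rng):
        days = [dt.date(2021, 3, 1) + dt.timedelta(days=k) for k in range(56)]
        ot = rng.integers(50, 150, len(days))
        rt = rng.integers(50, 150, len(days))
        ledgers = {
            d: target_ledger(d, int(o), int(r)) for d, o, r in zip(days, ot, rt)
        }
        bg = self.background(days, ot, rt)
        out = amplification_heatmap(ledgers, "t", bg)
        assert out["defined"].all()
        assert np.allclose(out["R"], 1.0, atol=1e-12)

    def test_zero_organic_cell_is_undefined_not_infinite(self):
        days = [dt.date(2021, 3, 1) + dt.timedelta(days=k) for k in range(7)]
        ledgers = {d: target_ledger(d, 0, 5) for d in days}
        bg = self.background(days, [10] * 7, [10] * 7)
        out = amplification_heatmap(ledgers, "t", bg)
        assert (~out["defined"]).all()
        assert out["R"].isna().all()

    def test_misaligned_dates_error_lists_missing(self):
        days = [dt.date(2021, 3, 1), dt.date(2021, 3, 2)]
        ledgers = {d: target_ledger(d, 1, 1) for d in days}
        bg = self.background(days[:1], [10], [10])
        with pytest.raises(ValueError, match="2021-03-02"):
            amplification_heatmap(ledgers, "t", bg)

    def test_recovers_planted_retweet_boost(self):
        cfg = StreamConfig(
            start_date=dt.date(2020, 1, 1),
            end_date=dt.date(2020, 5, 1),
            messages_per_day=3000,
            vocab_size=1000,
            anchor_prevalence=0.02,
            retweet_prob=0.3,
            anchor_retweet_boost=2.0,
            rng_seed=17,
        )
        tweets, _ = generate_stream(cfg)
        ledgers2 = daily_ledger_map(count_stream(tweets, orders=(2,)), 2)
        bg_rows = []
        for date, lg in sorted(ledgers2.items()):
            bg_rows.append(
                (date, sum(lg.organic.values()), sum(lg.retweet.values()))
            )
        bg = pd.DataFrame(bg_rows, columns=["date", "ot", "rt"]).set_index("date")
        out = amplification_heatmap(ledgers2, "mental health", bg)
        # background includes the boosted anchor messages themselves, which
        # pulls the measured ratio slightly below the planted odds factor
        assert out["R"].median() == pytest.approx(2.0, rel=0.10)


class TestRankPanel:
    def test_constant_series(self):
        idx = pd.date_range("2021-01-01", periods=30, freq="D")
        panel = smoothed_rank_panel(pd.Series(100.0, index=idx), 30)
        assert np.allclose(panel.smoothed.dropna(), 100.0)
        assert (panel.weekly_band["min"] == 100.0).all()
        assert (panel.weekly_band["max"] == 100.0).all()

    def test_alternating_series_weekly_band(self):
        idx = pd.date_range("2021-01-04", periods=14, freq="D")  # Mon start
        vals = [10.0, 1000.0] * 7
        panel = smoothed_rank_panel(pd.Series(vals, index=idx), 7)
        assert (panel.weekly_band["min"] == 10.0).all()
        assert (panel.weekly_band["max"] == 1000.0).all()

    def test_matches_log_rolling_oracle(self, rng):
        idx = pd.date_range("2021-01-01", periods=60, freq="D")
        vals = rng.integers(1, 5000, len(idx)).astype(float)
        vals[rng.integers(0, len(idx), 10)] = np.nan
        series = pd.Series(vals, index=idx)
        panel = smoothed_rank_panel(series, 30)
        import math

        oracle = naive_log_rolling_mean(
            [math.log10(v) if v == v else float("nan") for v in vals], 30
        )
        got = panel.smoothed.reindex(idx).to_numpy()
        expected = np.array([10.0**v if v == v else np.nan for v in oracle])
        assert np.allclose(got, expected, equal_nan=True)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            smoothed_rank_panel(pd.Series(dtype=float), 0)


class TestCrossing:
    def balance_from_frt(self, frt):
        months = pd.period_range("2015-01", periods=len(frt), freq="M")
        return pd.DataFrame(
            {
                "f_ot": [1 - v for v in frt],
                "f_rt": frt,
                "amplified": [v > 0.5 for v in frt],
            },
            index=months,
        )

    def test_never_amplified_gives_none(self):
        assert detect_crossing(self.balance_from_frt([0.3] * 24)) is None

    def test_step_series_detects_month_13(self):
        balance = self.balance_from_frt([0.4] * 12 + [0.6] * 12)
        assert detect_crossing(balance) == pd.Period("2016-01")

    def test_single_month_blip_ignored(self):
        balance = self.balance_from_frt([0.4, 0.6, 0.4] * 8)
        assert detect_crossing(balance) is None

    def test_recovers_planted_crossing_in_90pct_of_seeded_runs(self):
        hits = 0
        runs = 20
        for seed in range(runs):
            cfg = StreamConfig(
                start_date=dt.date(2016, 1, 1),
                end_date=dt.date(2018, 1, 1),
                messages_per_day=60,
                vocab_size=500,
                anchor_prevalence=0.3,
                retweet_prob=LogisticSchedule(
                    0.2, 0.8, dt.date(2017, 1, 1), 15.0
                ),
                rng_seed=seed,
            )
            tweets, truth = generate_stream(cfg)
            daily = daily_ledger_map(count_stream(tweets, orders=(2,)), 2)
            balance = monthly_balance(daily, "mental health")
            detected = detect_crossing(balance)
            planted = pd.Period(truth.planted_crossing_month, freq="M")
            if detected is not None and abs((detected - planted).n) <= 1:
                hits += 1
        assert hits / runs >= 0.9
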