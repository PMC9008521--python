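"""Counting engine: tokenization conventions, ledgers vs brute-force
recounts, tied ranks, anchored subsets and aggregates."""

import datetime as dt
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discourselens.ngrams import (
    NgramLedger,
    RankedDistribution,
    anchor_subset,
    count_stream,
    extract_ngrams,
    merge_ledgers,
    rank_distribution,
    rank_of_count,
    rank_timeseries,
    summarize_corpus,
    tokenize,
    yearly_aggregate,
)
from discourselens.stream import Tweet

from .oracles import naive_anchor_subset, naive_count, naive_ranks, random_stream

D = dt.date(2021, 5, 1)


def tw(text, date=D, rt=False, i=[0]):
    i[0] += 1
    return Tweet(id=f"t{i[0]}", date=date, text=text, lang="en", is_retweet=rt)


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Mental health matters", ["mental", "health", "matters"]),
            ("", []),
            ("#BellLetsTalk!", ["#bellletstalk"]),
            ("@User: hi!!", ["@user", "hi"]),
            ("it's  (really)   fine...", ["it's", "really", "fine"]),
            ("# @ ...", []),
        ],
    )
    def test_conventions(self, text, expected):
        assert tokenize(text) == expected

    def test_case_folding_can_be_disabled(self):
        assert tokenize("Mental Health", lowercase=False) == ["Mental", "Health"]


class TestExtractNgrams:
    @pytest.mark.parametrize(
        "tokens,n,expected",
        [
            (["a", "b", "c"], 2, ["a b", "b c"]),
            (["a", "b", "c"], 3, ["a b c"]),
            (["a"], 2, []),
            (["a", "a", "a"], 2, ["a a", "a a"]),
        ],
    )
    def test_windows(self, tokens, n, expected):
        assert extract_ngrams(tokens, n) == expected

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            extract_ngrams(["a"], 4)


class TestCountStream:
    def test_two_organic_messages(self):
        ledgers = count_stream([tw("a b"), tw("a b")], orders=(1,))
        ledger = ledgers[(D, 1)]
        assert ledger.entry("a") == (2, 2, 0)
        assert ledger.entry("b") == (2, 2, 0)

    def test_organic_plus_retweet(self):
        ledgers = count_stream([tw("a"), tw("a", rt=True)], orders=(1,))
        assert ledgers[(D, 1)].entry("a") == (2, 1, 1)

    def test_total_is_organic_plus_retweet_everywhere(self, rng, small_vocab):
        stream = random_stream(rng, 200, small_vocab)
        for ledger in count_stream(stream).values():
            for g in ledger.types():
                total, org, rt = ledger.entry(g)
                assert total == org + rt

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 60))
    def test_matches_naive_recount(self, seed, n):
        rng = np.random.default_rng(seed)
        vocab = [f"w{i}" for i in range(15)]
        stream = random_stream(rng, n, vocab, span_days=5)
        ledgers = count_stream(stream)
        oracle = naive_count(stream)
        assert set(ledgers) == set(oracle)
        for key, ledger in ledgers.items():
            assert {g: list(ledger.entry(g)) for g in ledger.types()} == {
                g: v for g, v in oracle[key].items()
            }

    def test_token_conservation(self, rng, small_vocab):
        stream = random_stream(rng, 150, small_vocab, span_days=3)
        ledgers = count_stream(stream)
        for n in (1, 2, 3):
            emitted = Counter()
            for msg in stream:
                emitted[msg.date] += len(extract_ngrams(tokenize(msg.text), n))
            for date, total in emitted.items():
                if total == 0:
                    continue
                ledger = ledgers[(date, n)]
                assert sum(ledger.total_counts().values()) == total


class TestRanking:
    def test_fractional_tie_convention(self):
        dist = RankedDistribution.from_counts({"a": 5, "b": 3, "c": 3, "d": 1})
        ranks = dist.df["rank"]
        assert ranks["a"] == 1 and ranks["b"] == 2.5 and ranks["c"] == 2.5
        assert ranks["d"] == 4

    def test_single_entry(self):
        dist = RankedDistribution.from_counts({"only": 7})
        assert dist.df.loc["only", "rank"] == 1.0
        assert dist.df.loc["only", "frequency"] == 1.0

    def test_random_counts_match_sort_based_oracle(self, rng):
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(1, 30, 200))}
        dist = RankedDistribution.from_counts(counts)
        oracle = naive_ranks(counts)
        for g, r in oracle.items():
            assert dist.df.loc[g, "rank"] == pytest.approx(r)

    def test_rank_sum_and_frequency_invariants(self, rng):
        for _ in range(20):
            counts = {
                f"g{i}": int(c) for i, c in enumerate(rng.integers(1, 10, 50))
            }
            dist = RankedDistribution.from_counts(counts)
            n = len(dist)
            assert dist.df["rank"].sum() == pytest.approx(n * (n + 1) / 2, abs=1e-9)
            assert dist.df["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_rank_of_count_shortcut_agrees(self, rng):
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(1, 12, 80))}
        dist = RankedDistribution.from_counts(counts)
        for g in list(counts)[:20]:
            assert rank_of_count(counts, g) == pytest.approx(dist.df.loc[g, "rank"])
        assert rank_of_count(counts, "absent") is None

    def test_empty_ledger_errors(self):
        with pytest.raises(ValueError):
            rank_distribution(NgramLedger(D, 1))

    def test_which_selects_partition(self):
        ledger = NgramLedger(D, 1, Counter({"a": 3}), Counter({"a": 1, "b": 4}))
        assert rank_distribution(ledger, "organic").df.loc["a", "count"] == 3
        assert rank_distribution(ledger, "retweet").df.loc["b", "rank"] == 1.0


class TestAnchorSubset:
    def test_contiguous_inclusion(self):
        kept = anchor_subset([tw("my mental health matters")], "mental health")
        assert len(kept) == 1

    def test_non_contiguous_exclusion(self):
        kept = anchor_subset([tw("mental illness and health")], "mental health")
        assert kept == []

    def test_punctuation_variant_matches(self):
        kept = anchor_subset([tw("Mental Health!")], "mental health")
        assert len(kept) == 1

    def test_empty_anchor_errors(self):
        with pytest.raises(ValueError):
            anchor_subset([tw("x")], "  ")

    def test_matches_naive_scan(self, rng, small_vocab):
        stream = random_stream(rng, 100, small_vocab)
        kept = anchor_subset(stream, "mental health")
        assert [t.id for t in kept] == [
            t.id for t in naive_anchor_subset(stream, "mental health")
        ]

    def test_subset_plus_complement_ledgers_equal_full(self, rng, small_vocab):
        stream = random_stream(rng, 120, small_vocab)
        kept = anchor_subset(stream, "mental health")
        kept_ids = {t.id for t in kept}
        rest = [t for t in stream if t.id not in kept_ids]
        assert len(kept) + len(rest) == len(stream)
        full = count_stream(stream)
        parts = count_stream(kept), count_stream(rest)
        for key, ledger in full.items():
            for g in ledger.types():
                summed = tuple(
                    sum(p[key].entry(g)[i] if key in p else 0 for p in parts)
                    for i in range(3)
                )
                assert summed == ledger.entry(g)


class TestTimeSeriesAndAggregates:
    def make_daily(self):
        stream = [
            tw("a a b", date=dt.date(2020, 12, 30)),
            tw("a b", date=dt.date(2020, 12, 31)),
            tw("b b b", date=dt.date(2021, 1, 1)),
        ]
        return count_stream(stream, orders=(1,))

    def test_absent_target_is_missing_with_undefined_median(self):
        daily = {
            date: rank_distribution(lg)
            for (date, n), lg in self.make_daily().items()
        }
        series, median = rank_timeseries(daily, "zzz")
        assert series.isna().all()
        assert median is None

    def test_constant_counts_give_constant_series(self):
        daily = {
            d: RankedDistribution.from_counts({"a": 5, "b": 2})
            for d in [dt.date(2021, 1, i) for i in (1, 2, 3)]
        }
        series, median = rank_timeseries(daily, "a")
        assert (series == 1.0).all()
        assert median == 1.0

    def test_yearly_aggregate_pools_counts_within_year(self):
        years = yearly_aggregate(
            {date: lg for (date, n), lg in self.make_daily().items()}
        )
        assert set(years) == {2020, 2021}
        assert years[2020].df.loc["a", "count"] == 3
        assert years[2021].df.loc["b", "count"] == 3

    def test_yearly_aggregate_matches_brute_force(self, rng, small_vocab):
        stream = random_stream(rng, 200, small_vocab, span_days=400)
        daily = {
            date: lg
            for (date, n), lg in count_stream(stream, orders=(1,)).items()
        }
        years = yearly_aggregate(daily)
        oracle = {}
        for msg in stream:
            for tok in tokenize(msg.text):
                oracle.setdefault(msg.date.year, Counter())[tok] += 1
        for year, dist in years.items():
            assert Counter(
                {g: int(c) for g, c in dist.df["count"].items()}
            ) == oracle[year]

    def test_merge_rejects_mixed_orders(self):
        with pytest.raises(ValueError):
            merge_ledgers([NgramLedger(D, 1), NgramLedger(D, 2)])


class TestSummaries:
    def test_counts_by_hand(self):
        ledgers = count_stream([tw("a b"), tw("a", rt=True)], orders=(1,))
        s = summarize_corpus(ledgers, D, "toy")
        assert (s.unique_1grams, s.total_1grams, s.total_1grams_no_retweets) == (
            2, 3, 2,
        )

    def test_missing_date_errors(self):
        with pytest.raises(KeyError):
            summarize_corpus({}, D)

    def test_matches_brute_force(self, rng, small_vocab):
        stream = random_stream(rng, 300, small_vocab, span_days=10)
        ledgers = count_stream(stream, orders=(1,))
        for date in {t.date for t in stream}:
            toks = [
                (tok, t.is_retweet)
                for t in stream
                if t.date == date
                for tok in tokenize(t.text)
            ]
            if not toks:
                continue
            s = summarize_corpus(ledgers, date)
            assert s.unique_1grams == len({w for w, _ in toks})
            assert s.total_1grams == len(toks)
            assert s.total_1grams_no_retweets == sum(1 for _, rt in toks if not rt)
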