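"""Tokenization, dated n-gram count ledgers and tied-rank distributions.

The counting model follows the day-resolved n-gram bookkeeping used for
large social-media streams: for every UTC calendar day and every order
n in {1, 2, 3}, the number of times each unique n-gram appeared is
recorded, split into *organic* occurrences (originally authored
messages) and *retweet* occurrences (shared copies).  Distributions are
ranked by descending count with fractional (average) ranks for ties, so
rank sums are exactly N(N+1)/2 and rank-based statistics are
well-defined under heavy tying.

Tokenization convention: split on unicode whitespace, case-fold to
lowercase (configurable), strip leading/trailing punctuation but keep a
leading ``#`` or ``@`` so hashtags and handles survive as single types.
"""

from __future__ import annotations

import datetime as dt
import logging
import string
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stream import Tweet

logger = logging.getLogger(__name__)

ORDERS = (1, 2, 3)

# ASCII punctuation plus common typographic marks seen in social text.
_PUNCT = string.punctuation + "“”‘’…«»—–"


def tokenize(text: str, *, lowercase: bool = True) -> list[str]:
    """Split ``text`` into tokens.

    Total function: any unicode string maps to a (possibly empty) token
    list.  A leading ``#`` or ``@`` is preserved; other leading and all
    trailing punctuation is stripped; tokens that are empty after
    stripping are dropped.
    """
    if lowercase:
        text = text.lower()
    out: list[str] = []
    append = out.append
    for raw in text.split():
        c0 = raw[0]
        if c0 == "#" or c0 == "@":
            core = raw[1:].strip(_PUNCT)
            if core:
                append(c0 + core)
        else:
            tok = raw.strip(_PUNCT)
            if tok:
                append(tok)
    return out


def extract_ngrams(tokens: Sequence[str], n: int) -> list[str]:
    """All contiguous length-``n`` windows of ``tokens``, duplicates kept.

    n-grams are space-joined strings, e.g. ``"a b"``.
    """
    if n not in ORDERS:
        raise ValueError(f"n must be one of {ORDERS}, got {n}")
    if n == 1:
        return list(tokens)
    if len(tokens) < n:
        return []
    if n == 2:
        return [a + " " + b for a, b in zip(tokens, tokens[1:])]
    return [a + " " + b + " " + c for a, b, c in zip(tokens, tokens[1:], tokens[2:])]


@dataclass
class NgramLedger:
    """Per-day, per-order n-gram counts split into organic and retweet.

    ``count_total = count_organic + count_retweet`` holds by
    construction; totals are derived, never stored separately.
    """

    date: dt.date | None
    n: int
    organic: Counter = field(default_factory=Counter)
    retweet: Counter = field(default_factory=Counter)

    def total_counts(self) -> Counter:
        total = Counter(self.organic)
        total.update(self.retweet)
        return total

    def counts(self, which: str = "total") -> Counter:
        if which == "total":
            return self.total_counts()
        if which == "organic":
            return self.organic
        if which == "retweet":
            return self.retweet
        raise ValueError(f"which must be total/organic/retweet, got {which!r}")

    def entry(self, ngram: str) -> tuple[int, int, int]:
        o = self.organic.get(ngram, 0)
        r = self.retweet.get(ngram, 0)
        return o + r, o, r

    def types(self) -> set[str]:
        return set(self.organic) | set(self.retweet)

    def __len__(self) -> int:
        return len(self.types())

    def add_tokens(self, ngram_list: Iterable[str], is_retweet: bool) -> None:
        (self.retweet if is_retweet else self.organic).update(ngram_list)


LedgerSet = dict[tuple[dt.date, int], NgramLedger]
"""Mapping (day, order) -> ledger."""


def count_stream(
    stream: Iterable[Tweet],
    orders: Sequence[int] = ORDERS,
    *,
    lowercase: bool = True,
) -> LedgerSet:
    """Count n-grams per UTC calendar day over a message stream.

    Organic and retweet counts accumulate separately from the
    ``is_retweet`` flag.  Messages without a date are skipped with a
    logged warning.
    """
    for n in orders:
        if n not in ORDERS:
            raise ValueError(f"unsupported order {n}")
    ledgers: LedgerSet = {}
    for msg in stream:
        if msg.date is None:
            logger.warning("message %s has no date; skipped", msg.id)
            continue
        tokens = tokenize(msg.text, lowercase=lowercase)
        for n in orders:
            grams = extract_ngrams(tokens, n)
            if not grams:
                continue
            key = (msg.date, n)
            ledger = ledgers.get(key)
            if ledger is None:
                ledger = ledgers[key] = NgramLedger(msg.date, n)
            ledger.add_tokens(grams, msg.is_retweet)
    return ledgers


def merge_ledgers(
    parts: Iterable[NgramLedger], *, date: dt.date | None = None
) -> NgramLedger:
    """Entrywise sum of ledgers (all of one order)."""
    parts = list(parts)
    if not parts:
        raise ValueError("cannot merge an empty collection of ledgers")
    n = parts[0].n
    merged = NgramLedger(date, n)
    for p in parts:
        if p.n != n:
            raise ValueError("cannot merge ledgers of different orders")
        merged.organic.update(p.organic)
        merged.retweet.update(p.retweet)
    return merged


@dataclass
class RankedDistribution:
    """A dated/labelled map n-gram -> (count, frequency, tied rank).

    ``df`` is indexed by n-gram with columns ``count``, ``frequency``,
    ``rank``; ranks are fractional (average) over count ties, so the
    rank sum over N types is exactly N(N+1)/2.
    """

    label: str
    n: int
    df: pd.DataFrame

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], *, label: str = "", n: int = 1
    ) -> "RankedDistribution":
        if not counts:
            raise ValueError("cannot rank an empty distribution")
        items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        grams = [g for g, _ in items]
        c = np.asarray([v for _, v in items], dtype=float)
        ranks = rankdata(-c, method="average")
        df = pd.DataFrame(
            {"count": c, "frequency": c / c.sum(), "rank": ranks},
            index=pd.Index(grams, name="ngram"),
        )
        return cls(label=label, n=n, df=df)

    def rank_of(self, ngram: str) -> float | None:
        try:
            return float(self.df.at[ngram, "rank"])
        except KeyError:
            return None

    def __len__(self) -> int:
        return len(self.df)


def rank_distribution(
    ledger: NgramLedger, which: str = "total", *, label: str | None = None
) -> RankedDistribution:
    """Tied-rank distribution of a ledger's counts.

    ``which`` selects the total, organic-only or retweet-only counts.
    """
    counts = {g: c for g, c in ledger.counts(which).items() if c > 0}
    if not counts:
        raise ValueError("ledger has no entries with positive count")
    if label is None:
        label = ledger.date.isoformat() if ledger.date else ""
    return RankedDistribution.from_counts(counts, label=label, n=ledger.n)


def rank_of_count(counts: Mapping[str, int], target: str) -> float | None:
    """Tied rank of ``target`` in a raw count mapping, without building
    the full distribution (streaming-friendly)."""
    c_t = counts.get(target)
    if not c_t:
        return None
    above = 0
    tied = 0
    for c in counts.values():
        if c > c_t:
            above += 1
        elif c == c_t:
            tied += 1
    return above + (tied + 1) / 2.0


def contains_contiguous(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> bool:
    m = len(phrase_tokens)
    if m == 0 or len(tokens) < m:
        return False
    first = phrase_tokens[0]
    phrase = list(phrase_tokens)
    for i in range(len(tokens) - m + 1):
        if tokens[i] == first and list(tokens[i : i + m]) == phrase:
            return True
    return False


def anchor_subset(
    stream: Iterable[Tweet], anchor_phrase: str, *, lowercase: bool = True
) -> list[Tweet]:
    """Messages whose token sequence contains the anchor phrase as
    contiguous tokens, matched under the same case-folding as
    :func:`tokenize`."""
    phrase_tokens = tokenize(anchor_phrase, lowercase=lowercase)
    if not phrase_tokens:
        raise ValueError("anchor phrase is empty after tokenization")
    return [
        msg
        for msg in stream
        if contains_contiguous(tokenize(msg.text, lowercase=lowercase), phrase_tokens)
    ]


def rank_timeseries(
    daily: Mapping[dt.date, RankedDistribution], target: str
) -> tuple[pd.Series, float | None]:
    """Daily rank series of ``target`` plus the series median.

    Days where the target is absent are missing values (NaN), never a
    sentinel rank; the median ignores missing days and is None when the
    target never appears.
    """
    dates = sorted(daily)
    values = [daily[d].rank_of(target) for d in dates]
    series = pd.Series(
        [np.nan if v is None else v for v in values],
        index=pd.DatetimeIndex(dates, name="date"),
        name=target,
        dtype=float,
    )
    median = None if series.dropna().empty else float(series.median())
    return series, median


def yearly_aggregate(
    ledgers: Mapping[dt.date, NgramLedger], which: str = "total"
) -> dict[int, RankedDistribution]:
    """Sum daily counts per calendar year, then rank each year."""
    by_year: dict[int, list[NgramLedger]] = {}
    for date, ledger in ledgers.items():
        by_year.setdefault(date.year, []).append(ledger)
    out = {}
    for year, parts in sorted(by_year.items()):
        merged = merge_ledgers(parts)
        out[year] = rank_distribution(merged, which, label=str(year))
    return out


@dataclass(frozen=True)
class CorpusSummary:
    """Daily size statistics in the style of a corpus summary table."""

    date: dt.date
    label: str
    unique_1grams: int
    total_1grams: int
    total_1grams_no_retweets: int


def summarize_corpus(
    ledgers: LedgerSet, date: dt.date, label: str = ""
) -> CorpusSummary:
    """Unique / total / organic-only 1-gram counts for one day."""
    ledger = ledgers.get((date, 1))
    if ledger is None:
        raise KeyError(f"no 1-gram ledger for {date}")
    total = sum(ledger.organic.values()) + sum(ledger.retweet.values())
    return CorpusSummary(
        date=date,
        label=label,
        unique_1grams=len(ledger),
        total_1grams=total,
        total_1grams_no_retweets=sum(ledger.organic.values()),
    )
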