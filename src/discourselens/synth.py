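"""Synthetic message-stream generator with planted statistical structure.

The generator emulates the statistical skeleton of a decade-scale 10%
social-media sample at desk scale, so every downstream stage (counting,
ranking, sentiment, divergence, amplification) is testable without any
proprietary download.  Planted structure:

* a Zipf-distributed background vocabulary of pseudo-words;
* an anchor topic (default phrase ``"mental health"``) whose daily
  prevalence pi(t) follows a configurable schedule, by default growing
  two orders of magnitude (1e-4 -> 1e-2) across the window;
* annual awareness events and irregular tragedy events that boost the
  prevalence multiplicatively with exponential (half-life) decay and
  switch the topic vocabulary into a high- or low-happiness regime;
* a retweet probability rho(t) that rises through 0.5 mid-series, with
  a configurable odds multiplier for anchor-topic messages (social
  amplification of the topic).

Every anchor-topic message contains the anchor phrase as contiguous
tokens; background messages draw only from the background vocabulary,
which excludes the anchor tokens, so they can never contain the phrase.
Identical configs and seeds reproduce identical streams byte-for-byte.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .schedules import (
    ConstantSchedule,
    LogisticSchedule,
    LogLinearSchedule,
    schedule_from_dict,
)
from .sentiment import load_lexicon
from .stream import Tweet

REGIMES = ("baseline", "awareness", "tragedy")

_CONSONANTS = "bcdfghjklmnpqrstvwz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]  # 95


def pseudo_word(i: int) -> str:
    """Deterministic pronounceable pseudo-word for vocabulary index i."""
    base = len(_SYLLABLES)
    parts = []
    i += base  # force >= 2 syllables and injectivity
    while i:
        parts.append(_SYLLABLES[i % base])
        i //= base
    return "".join(reversed(parts))


@dataclass(frozen=True)
class Event:
    """A planted discourse event.

    ``boost`` multiplies the anchor prevalence on the event day and
    decays with the given half-life on following days; ``kind`` selects
    the sentiment regime of the topic vocabulary while the event
    dominates.
    """

    date: dt.date
    kind: str  # "awareness" | "tragedy"
    boost: float
    half_life_days: float

    def __post_init__(self):
        if self.kind not in ("awareness", "tragedy"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.boost < 1.0:
            raise ValueError("event boost must be >= 1")
        if self.half_life_days <= 0:
            raise ValueError("half-life must be positive")

    def to_dict(self) -> dict:
        return {
            "date": self.date.isoformat(),
            "kind": self.kind,
            "boost": self.boost,
            "half_life_days": self.half_life_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        return cls(
            date=dt.date.fromisoformat(str(d["date"])),
            kind=d["kind"],
            boost=float(d["boost"]),
            half_life_days=float(d["half_life_days"]),
        )


@dataclass
class StreamConfig:
    """Full parameterization of one simulated stream.

    ``end_date`` is exclusive.  Schedules map dates to probabilities;
    ``anchor_retweet_boost`` multiplies the retweet *odds* of anchor
    messages relative to the background rate, so the contagiogram's
    relative-amplification statistic recovers it directly.
    """

    start_date: dt.date
    end_date: dt.date
    messages_per_day: int
    vocab_size: int = 20_000
    zipf_exponent: float = 1.0
    anchor_phrase: str = "mental health"
    anchor_prevalence: object = field(default_factory=lambda: ConstantSchedule(0.01))
    events: list[Event] = field(default_factory=list)
    retweet_prob: object = field(default_factory=lambda: ConstantSchedule(0.3))
    anchor_retweet_boost: float = 1.0
    topic_sentiment: dict = field(
        default_factory=lambda: {"baseline": 5.5, "awareness": 7.0, "tragedy": 2.8}
    )
    topic_kernel_width: float = 0.7
    topic_token_prob: float = 0.7
    min_tokens: int = 5
    max_tokens: int = 25
    lexicon_path: str | None = None
    rng_seed: int = 0

    def __post_init__(self):
        self.anchor_prevalence = schedule_from_dict(self.anchor_prevalence)
        self.retweet_prob = schedule_from_dict(self.retweet_prob)
        self.events = [
            e if isinstance(e, Event) else Event.from_dict(e) for e in self.events
        ]
        self.validate()

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days

    @property
    def anchor_tokens(self) -> tuple[str, ...]:
        return tuple(self.anchor_phrase.lower().split())

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=k) for k in range(self.n_days)]

    def validate(self) -> None:
        if self.n_days <= 0:
            raise ValueError("configuration error: empty simulation window")
        if self.messages_per_day <= 0:
            raise ValueError("configuration error: messages_per_day must be positive")
        if self.vocab_size <= 0:
            raise ValueError("vocab_size must be positive")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.anchor_retweet_boost <= 0:
            raise ValueError("anchor_retweet_boost must be positive")
        if not self.anchor_tokens:
            raise ValueError("anchor phrase must contain at least one token")
        if self.min_tokens <= len(self.anchor_tokens):
            raise ValueError("min_tokens must exceed the anchor phrase length")
        if self.max_tokens < self.min_tokens:
            raise ValueError("max_tokens must be >= min_tokens")
        if not (0.0 <= self.topic_token_prob <= 1.0):
            raise ValueError("topic_token_prob must be in [0,1]")
        for ev in self.events:
            if not (self.start_date <= ev.date < self.end_date):
                raise ValueError(f"event {ev.date} outside the simulation window")
        # spot-check schedule ranges across the window
        for d in (self.start_date, self.end_date - dt.timedelta(days=1)):
            for name, sched in (
                ("anchor_prevalence", self.anchor_prevalence),
                ("retweet_prob", self.retweet_prob),
            ):
                v = sched(d)
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name}({d}) = {v} outside [0,1]")

    def to_dict(self) -> dict:
        return {
            "start_date": self.start_date.isoformat(),
            "end_date": self.end_date.isoformat(),
            "messages_per_day": self.messages_per_day,
            "vocab_size": self.vocab_size,
            "zipf_exponent": self.zipf_exponent,
            "anchor_phrase": self.anchor_phrase,
            "anchor_prevalence": self.anchor_prevalence.to_dict(),
            "events": [e.to_dict() for e in self.events],
            "retweet_prob": self.retweet_prob.to_dict(),
            "anchor_retweet_boost": self.anchor_retweet_boost,
            "topic_sentiment": dict(self.topic_sentiment),
            "topic_kernel_width": self.topic_kernel_width,
            "topic_token_prob": self.topic_token_prob,
            "min_tokens": self.min_tokens,
            "max_tokens": self.max_tokens,
            "lexicon_path": self.lexicon_path,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StreamConfig":
        d = dict(d)
        d["start_date"] = dt.date.fromisoformat(str(d["start_date"]))
        d["end_date"] = dt.date.fromisoformat(str(d["end_date"]))
        return cls(**d)


def _last_wednesday_of_january(year: int) -> dt.date:
    d = dt.date(year, 1, 31)
    while d.weekday() != 2:
        d -= dt.timedelta(days=1)
    return d


def default_events(start_year: int = 2015, end_year: int = 2019) -> list[Event]:
    """The default planted event calendar: an annual late-January and an
    annual October-10 awareness day, plus three irregular tragedies."""
    events: list[Event] = []
    for year in range(start_year, end_year + 1):
        events.append(
            Event(_last_wednesday_of_january(year), "awareness", 25.0, 1.5)
        )
        events.append(Event(dt.date(year, 10, 10), "awareness", 10.0, 1.5))
    for date in (dt.date(2015, 6, 17), dt.date(2017, 4, 18), dt.date(2018, 6, 8)):
        events.append(Event(date, "tragedy", 15.0, 2.5))
    return sorted(events, key=lambda e: e.date)


def default_config(seed: int = 0, *, messages_per_day: int = 1000) -> StreamConfig:
    """The reference study conditions: 3650 days (2010-01-01 onward),
    anchor prevalence growing 1e-4 -> 1e-2, awareness/tragedy events
    from 2015, and a retweet probability tipping through 0.5 around the
    start of 2017 with a 2x odds boost for anchor messages."""
    start = dt.date(2010, 1, 1)
    end = start + dt.timedelta(days=3650)
    return StreamConfig(
        start_date=start,
        end_date=end,
        messages_per_day=messages_per_day,
        anchor_prevalence=LogLinearSchedule(start, end, 1e-4, 1e-2),
        events=default_events(),
        retweet_prob=LogisticSchedule(0.15, 0.75, dt.date(2017, 1, 1), 30.0),
        anchor_retweet_boost=2.0,
        rng_seed=seed,
    )


def event_multiplier(config: StreamConfig, date: dt.date) -> tuple[float, str]:
    """Combined multiplicative event boost and the day's sentiment regime.

    The regime is the kind of the dominant active event when its decayed
    contribution still at least doubles the prevalence; baseline
    otherwise.
    """
    m = 1.0
    best_contrib, best_kind = 0.0, "baseline"
    for ev in config.events:
        age = (date - ev.date).days
        if age < 0:
            continue
        contrib = (ev.boost - 1.0) * 2.0 ** (-age / ev.half_life_days)
        m += contrib
        if contrib > best_contrib:
            best_contrib, best_kind = contrib, ev.kind
    regime = best_kind if best_contrib >= 1.0 else "baseline"
    return m, regime


def anchor_retweet_prob(rho: float, boost: float) -> float:
    """Retweet probability for anchor messages: background odds times boost."""
    return boost * rho / (1.0 - rho + boost * rho)


class _SimContext:
    """Precomputed sampling tables shared across days."""

    def __init__(self, config: StreamConfig):
        anchor = set(config.anchor_tokens)
        vocab: list[str] = []
        i = 0
        while len(vocab) < config.vocab_size:
            w = pseudo_word(i)
            i += 1
            if w not in anchor:
                vocab.append(w)
        self.vocab = np.array(vocab, dtype=object)
        p = np.arange(1, config.vocab_size + 1, dtype=float) ** (
            -config.zipf_exponent
        )
        self.zipf_cum = np.cumsum(p / p.sum())

        lexicon = load_lexicon(config.lexicon_path)
        self.lexicon = lexicon
        words = sorted(lexicon.scores)
        self.topic_words = np.array(words, dtype=object)
        h = np.asarray([lexicon.scores[w] for w in words])
        self.topic_cum: dict[str, np.ndarray] = {}
        self.topic_mean: dict[str, float] = {}
        for regime in REGIMES:
            mu = float(config.topic_sentiment[regime])
            w = np.exp(-((h - mu) ** 2) / (2.0 * config.topic_kernel_width**2))
            w /= w.sum()
            self.topic_cum[regime] = np.cumsum(w)
            self.topic_mean[regime] = float((w * h).sum())


@dataclass
class GroundTruth:
    """Planted-structure record accompanying a simulated stream.

    One row per simulated day plus the event calendar, the realized
    per-regime topic-vocabulary happiness means, and the scheduled month
    in which the anchor's retweet share first exceeds one half.
    """

    anchor_phrase: str
    daily: list[dict]
    events: list[dict]
    regime_sentiment_means: dict[str, float]
    planted_crossing_month: str | None

    def daily_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.daily)
        df["date"] = pd.to_datetime(df["date"])
        return df.set_index("date")


def planted_crossing_month(config: StreamConfig) -> str | None:
    """First calendar month whose mean scheduled anchor retweet
    probability exceeds 0.5, as 'YYYY-MM'."""
    by_month: dict[str, list[float]] = {}
    for d in config.dates():
        rho_a = anchor_retweet_prob(
            config.retweet_prob(d), config.anchor_retweet_boost
        )
        by_month.setdefault(f"{d.year:04d}-{d.month:02d}", []).append(rho_a)
    for month, vals in sorted(by_month.items()):
        if sum(vals) / len(vals) > 0.5:
            return month
    return None


def _generate_day(
    config: StreamConfig, ctx: _SimContext, day_index: int, date: dt.date
) -> tuple[list[Tweet], dict]:
    seed = abs(int(config.rng_seed)) % (2**31)
    rng = np.random.default_rng([seed, day_index])
    n = config.messages_per_day

    pi = config.anchor_prevalence(date)
    mult, regime = event_multiplier(config, date)
    pi_eff = min(1.0, pi * mult)
    rho = config.retweet_prob(date)
    rho_anchor = anchor_retweet_prob(rho, config.anchor_retweet_boost)

    is_anchor = rng.random(n) < pi_eff
    lengths = rng.integers(config.min_tokens, config.max_tokens + 1, size=n)
    rt_u = rng.random(n)
    is_rt = np.where(is_anchor, rt_u < rho_anchor, rt_u < rho)

    anchor_tokens = list(config.anchor_tokens)
    n_a = len(anchor_tokens)
    a_idx = np.flatnonzero(is_anchor)
    a_lengths = lengths[a_idx]
    k_other = a_lengths - n_a
    slots = rng.integers(0, k_other + 1) if len(a_idx) else np.empty(0, dtype=int)
    k_total = int(k_other.sum())
    topic_mask = rng.random(k_total) < config.topic_token_prob
    n_topic = int(topic_mask.sum())
    topic_words = ctx.topic_words[
        np.searchsorted(ctx.topic_cum[regime], rng.random(n_topic))
    ]
    n_bg = int(lengths[~is_anchor].sum()) + (k_total - n_topic)
    bg_words = ctx.vocab[np.searchsorted(ctx.zipf_cum, rng.random(n_bg))]

    texts: list[str] = [""] * n
    bg_ptr = tp_ptr = mask_ptr = 0
    ai = 0
    for i in range(n):
        L = int(lengths[i])
        if is_anchor[i]:
            k = L - n_a
            toks = []
            for j in range(k):
                if topic_mask[mask_ptr]:
                    toks.append(topic_words[tp_ptr])
                    tp_ptr += 1
                else:
                    toks.append(bg_words[bg_ptr])
                    bg_ptr += 1
                mask_ptr += 1
            pos = int(slots[ai])
            ai += 1
            toks[pos:pos] = anchor_tokens
            texts[i] = " ".join(toks)
        else:
            texts[i] = " ".join(bg_words[bg_ptr : bg_ptr + L])
            bg_ptr += L

    tweets = [
        Tweet(
            id=f"d{day_index:05d}m{i:06d}",
            date=date,
            text=texts[i],
            lang="en",
            is_retweet=bool(is_rt[i]),
        )
        for i in range(n)
    ]

    n_anchor = int(is_anchor.sum())
    anchor_rt = is_rt[is_anchor]
    truth_row = {
        "date": date.isoformat(),
        "n_messages": n,
        "n_anchor": n_anchor,
        "pi_scheduled": pi,
        "pi_effective": pi_eff,
        "regime": regime,
        "realized_anchor_fraction": n_anchor / n,
        "rho_scheduled": rho,
        "rho_anchor_scheduled": rho_anchor,
        "realized_retweet_fraction": float(is_rt.mean()),
        "realized_anchor_retweet_fraction": (
            float(anchor_rt.mean()) if n_anchor else None
        ),
    }
    return tweets, truth_row


def simulate_days(
    config: StreamConfig,
) -> Iterator[tuple[dt.date, list[Tweet], dict]]:
    """Yield (date, messages, ground-truth row) one simulated day at a
    time; memory stays bounded for decade-scale runs."""
    ctx = _SimContext(config)
    for day_index, date in enumerate(config.dates()):
        tweets, row = _generate_day(config, ctx, day_index, date)
        yield date, tweets, row


def build_ground_truth(config: StreamConfig, daily_rows: list[dict]) -> GroundTruth:
    ctx = _SimContext(config)
    return GroundTruth(
        anchor_phrase=config.anchor_phrase,
        daily=daily_rows,
        events=[e.to_dict() for e in config.events],
        regime_sentiment_means=dict(ctx.topic_mean),
        planted_crossing_month=planted_crossing_month(config),
    )


def generate_stream(config: StreamConfig) -> tuple[list[Tweet], GroundTruth]:
    """Materialize the whole stream plus its ground truth.

    For decade-scale configs prefer :func:`simulate_days`, which streams
    day batches instead of holding every message in memory.
    """
    tweets: list[Tweet] = []
    rows: list[dict] = []
    for _, day_tweets, row in simulate_days(config):
        tweets.extend(day_tweets)
        rows.append(row)
    return tweets, build_ground_truth(config, rows)


def write_ground_truth(gt: GroundTruth, path) -> None:
    doc = {
        "anchor_phrase": gt.anchor_phrase,
        "events": gt.events,
        "regime_sentiment_means": gt.regime_sentiment_means,
        "planted_crossing_month": gt.planted_crossing_month,
        "daily": gt.daily,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return GroundTruth(
        anchor_phrase=doc["anchor_phrase"],
        daily=doc["daily"],
        events=doc["events"],
        regime_sentiment_means=doc["regime_sentiment_means"],
        planted_crossing_month=doc["planted_crossing_month"],
    )
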