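"""Ambient happiness scoring and happiness word-shift decomposition.

Scoring follows the hedonometer tradition: each lexicon word ``w``
carries a crowd-style happiness score ``h(w)`` on a 1–9 scale, and the
*ambient happiness* of a corpus is the count-weighted mean of ``h`` over
the lexicon-matched tokens co-occurring with the anchor phrase,

    h_avg = sum_w h(w) c(w) / sum_w c(w).

An optional *lens* excludes near-neutral words (lo < h(w) < hi) from
scoring; it is off by default.

A word shift decomposes the difference between a comparison corpus and
a reference corpus into per-word contributions

    delta_h(w) = (h(w) - h_ref) * (p_comp(w) - p_ref(w)),

where p are normalized frequencies over lexicon-matched tokens.  The
contributions sum exactly to h_comp - h_ref, so the table is a lossless
account of the shift.  Each word falls into one of four classes from
the sign of (h(w) - h_ref) and the direction of its usage change.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .ngrams import NgramLedger

BUNDLED_LEXICON = "synthetic_happiness_lexicon.tsv"


@dataclass
class SentimentLexicon:
    """word -> happiness score in [1, 9], with an optional neutral-band lens."""

    scores: dict[str, float]
    lens: tuple[float, float] | None = None

    def __post_init__(self):
        for w, h in self.scores.items():
            if not (1.0 <= h <= 9.0):
                raise ValueError(f"score for {w!r} outside [1,9]: {h}")
        if self.lens is not None:
            lo, hi = self.lens
            if not (1.0 <= lo < hi <= 9.0):
                raise ValueError(f"invalid lens interval {self.lens}")

    def passes(self, word: str) -> bool:
        """True when the word is scored and survives the lens."""
        h = self.scores.get(word)
        if h is None:
            return False
        if self.lens is not None:
            lo, hi = self.lens
            if lo < h < hi:
                return False
        return True

    def with_lens(self, lens: tuple[float, float] | None) -> "SentimentLexicon":
        return SentimentLexicon(self.scores, lens)

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, word: str) -> bool:
        return word in self.scores


def load_lexicon(path=None, *, lens: tuple[float, float] | None = None) -> SentimentLexicon:
    """Read a TSV lexicon (``word<TAB>score``); default is the bundled
    synthetic demonstration lexicon.

    The bundled file is a hand-assigned stand-in constructed for this
    package in the style of crowdsourced happiness dictionaries; it is
    not a published instrument.
    """
    if path is None:
        ref = resources.files("discourselens.data").joinpath(BUNDLED_LEXICON)
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    scores: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.lower().startswith("word\t"):
            continue
        word, value = line.split("\t")
        scores[word] = float(value)
    return SentimentLexicon(scores, lens)


def _matched_items(
    counts: Mapping[str, int], lexicon: SentimentLexicon
) -> tuple[list[str], np.ndarray, np.ndarray]:
    words = [w for w, c in counts.items() if c > 0 and lexicon.passes(w)]
    c = np.asarray([counts[w] for w in words], dtype=float)
    h = np.asarray([lexicon.scores[w] for w in words], dtype=float)
    return words, c, h


def ambient_happiness(
    ledger_or_counts, lexicon: SentimentLexicon
) -> tuple[float | None, int]:
    """Count-weighted mean happiness of a day's 1-gram counts.

    Returns ``(h_avg, matched_token_count)``; ``h_avg`` is None when no
    token matches the lexicon (after the lens).
    """
    counts = (
        ledger_or_counts.total_counts()
        if isinstance(ledger_or_counts, NgramLedger)
        else ledger_or_counts
    )
    _, c, h = _matched_items(counts, lexicon)
    matched = int(c.sum())
    if matched == 0:
        return None, 0
    return float((h * c).sum() / c.sum()), matched


def rolling_smooth(series: pd.Series, window_days: int = 7) -> pd.Series:
    """Trailing mean over a date-indexed series, skipping missing days.

    Windows with fewer than half of their in-range days available are
    reported missing (during the warm-up at the series head the window
    is the part that overlaps the series, so a dense series smooths from
    day one).  ``window_days=1`` is the identity.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if series.empty:
        return series.copy()
    idx = pd.date_range(series.index.min(), series.index.max(), freq="D")
    full = series.reindex(idx)
    roll = full.rolling(window=window_days, min_periods=1)
    smoothed = roll.mean()
    available = roll.count()
    in_range = np.minimum(np.arange(len(idx)) + 1, window_days)
    required = np.ceil(in_range / 2.0)
    smoothed[available.to_numpy() < required] = np.nan
    smoothed.index.name = series.index.name
    return smoothed


_CLASSES = {
    (1, 1): "+↑",
    (1, -1): "+↓",
    (-1, 1): "−↑",
    (-1, -1): "−↓",
}


@dataclass
class ShiftTable:
    """Per-word decomposition of an ambient-happiness difference.

    ``df`` columns: ``word, h, p_ref, p_comp, contribution, class,
    rank_in_comp`` (usage rank of the word among comparison-corpus
    matched words) and ``happiness_rank_comp`` (rank of h(w) among the
    same set, happiest first); sorted by |contribution| descending,
    alphabetical tie-break.  The first ``top_k`` rows are flagged for
    display; the full table is retained.
    """

    ref_label: str
    comp_label: str
    h_ref: float
    h_comp: float
    df: pd.DataFrame
    top_k: int

    @property
    def delta(self) -> float:
        return self.h_comp - self.h_ref

    def head(self) -> pd.DataFrame:
        return self.df[self.df["top"]]


def word_shift(
    ref: NgramLedger | Mapping[str, int],
    comp: NgramLedger | Mapping[str, int],
    lexicon: SentimentLexicon,
    top_k: int = 20,
    *,
    ref_label: str = "reference",
    comp_label: str = "comparison",
) -> ShiftTable:
    """Decompose h_comp - h_ref into per-word contributions.

    Frequencies are normalized over lexicon-matched, lens-passing
    tokens within each corpus; a word present in only one corpus gets
    p = 0 in the other (no smoothing).  Raises if either corpus matches
    no lexicon words.
    """
    ref_counts = ref.total_counts() if isinstance(ref, NgramLedger) else ref
    comp_counts = comp.total_counts() if isinstance(comp, NgramLedger) else comp

    h_ref, n_ref = ambient_happiness(ref_counts, lexicon)
    h_comp, n_comp = ambient_happiness(comp_counts, lexicon)
    if h_ref is None:
        raise ValueError("reference corpus matches no lexicon words")
    if h_comp is None:
        raise ValueError("comparison corpus matches no lexicon words")

    words = sorted(
        w
        for w in set(ref_counts) | set(comp_counts)
        if lexicon.passes(w) and (ref_counts.get(w, 0) > 0 or comp_counts.get(w, 0) > 0)
    )
    h = np.asarray([lexicon.scores[w] for w in words])
    c_ref = np.asarray([ref_counts.get(w, 0) for w in words], dtype=float)
    c_comp = np.asarray([comp_counts.get(w, 0) for w in words], dtype=float)
    p_ref = c_ref / c_ref.sum()
    p_comp = c_comp / c_comp.sum()
    contribution = (h - h_ref) * (p_comp - p_ref)

    dp = p_comp - p_ref
    classes = [
        _CLASSES[(int(np.sign(hw - h_ref)), int(np.sign(d)))]
        if (hw != h_ref and d != 0.0)
        else "·"
        for hw, d in zip(h, dp)
    ]

    df = pd.DataFrame(
        {
            "word": words,
            "h": h,
            "p_ref": p_ref,
            "p_comp": p_comp,
            "contribution": contribution,
            "class": classes,
        }
    )
    # usage rank and happiness rank among comparison-present words
    present = df["p_comp"] > 0
    usage_rank = df.loc[present, "p_comp"].rank(ascending=False, method="average")
    happy_rank = df.loc[present, "h"].rank(ascending=False, method="average")
    df["rank_in_comp"] = usage_rank.reindex(df.index)
    df["happiness_rank_comp"] = happy_rank.reindex(df.index)

    df = df.sort_values(
        by=["contribution", "word"],
        key=lambda s: -s.abs() if s.name == "contribution" else s,
    ).reset_index(drop=True)
    df["top"] = df.index < top_k

    return ShiftTable(
        ref_label=ref_label,
        comp_label=comp_label,
        h_ref=float(h_ref),
        h_comp=float(h_comp),
        df=df,
        top_k=top_k,
    )


def build_reference(
    daily_ledgers: Mapping, event_date, mode: str = "pooled_week"
) -> NgramLedger:
    """Reference corpus for a word shift around ``event_date``.

    ``pooled_week`` (default) sums the 7 days strictly before the event;
    ``same_day_prior_week`` uses the single day event_date - 7 days.
    """
    import datetime as dt

    from .ngrams import merge_ledgers

    if isinstance(event_date, str):
        event_date = dt.date.fromisoformat(event_date)
    if mode == "pooled_week":
        days = [event_date - dt.timedelta(days=k) for k in range(1, 8)]
        parts = [daily_ledgers[d] for d in days if d in daily_ledgers]
        if not parts:
            raise ValueError(f"no reference days available before {event_date}")
        return merge_ledgers(parts)
    if mode == "same_day_prior_week":
        day = event_date - dt.timedelta(days=7)
        if day not in daily_ledgers:
            raise ValueError(f"reference day {day} not available")
        return daily_ledgers[day]
    raise ValueError(f"unknown reference mode {mode!r}")
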