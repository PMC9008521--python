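"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — explicit nested loops, direct
formula evaluation — and shares no code path with the implementation it
checks (tokenization conventions excepted, since those are the contract
under test elsewhere).
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict

from discourselens.ngrams import tokenize


def naive_count(tweets, orders=(1, 2, 3), lowercase=True):
    """Nested-loop recount: {(date, n): {ngram: [total, organic, retweet]}}."""
    out = {}
    for tw in tweets:
        toks = tokenize(tw.text, lowercase=lowercase)
        for n in orders:
            grams = []
            for i in range(len(toks) - n + 1):
                grams.append(" ".join(toks[i : i + n]))
            if not grams:
                continue
            table = out.setdefault((tw.date, n), defaultdict(lambda: [0, 0, 0]))
            for g in grams:
                table[g][0] += 1
                if tw.is_retweet:
                    table[g][2] += 1
                else:
                    table[g][1] += 1
    return out


def naive_ranks(counts):
    """Fractional tie ranks by explicit position averaging."""
    ordered = sorted(counts.items(), key=lambda kv: -kv[1])
    ranks = {}
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j][1] == ordered[i][1]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of positions i+1 .. j
        for k in range(i, j):
            ranks[ordered[k][0]] = avg
        i = j
    return ranks


def naive_anchor_subset(tweets, phrase, lowercase=True):
    """Contiguous-subsequence scan, position by position."""
    ptoks = tokenize(phrase, lowercase=lowercase)
    kept = []
    for tw in tweets:
        toks = tokenize(tw.text, lowercase=lowercase)
        hit = False
        for i in range(len(toks) - len(ptoks) + 1):
            if toks[i : i + len(ptoks)] == ptoks:
                hit = True
                break
        if hit:
            kept.append(tw)
    return kept


def naive_rtd(counts1, counts2, alpha):
    """Direct term-by-term rank-turbulence divergence evaluation."""
    r1 = naive_ranks(counts1)
    r2 = naive_ranks(counts2)
    only1 = [t for t in r1 if t not in r2]
    only2 = [t for t in r2 if t not in r1]
    imp2 = len(r2) + (len(only1) + 1) / 2.0
    imp1 = len(r1) + (len(only2) + 1) / 2.0

    pref = (alpha + 1.0) / alpha
    expo = 1.0 / (alpha + 1.0)

    def term(a, b):
        return pref * abs(a ** -alpha - b ** -alpha) ** expo

    total_un = 0.0
    for t in set(r1) | set(r2):
        a = r1.get(t, imp1)
        b = r2.get(t, imp2)
        total_un += term(a, b)

    disj2 = len(r2) + (len(r1) + 1) / 2.0
    disj1 = len(r1) + (len(r2) + 1) / 2.0
    norm = 0.0
    for t in r1:
        norm += term(r1[t], disj2)
    for t in r2:
        norm += term(disj1, r2[t])
    return total_un / norm


def naive_log_rolling_mean(values, window):
    """Trailing windowed mean with NaN skipping, element by element;
    windows with fewer than half of their in-range positions available
    are missing."""
    import math

    out = []
    for i in range(len(values)):
        lo = max(0, i - window + 1)
        chunk = [v for v in values[lo : i + 1] if v == v]  # drop NaN
        required = math.ceil(min(window, i + 1) / 2.0)
        if len(chunk) < required:
            out.append(float("nan"))
        else:
            out.append(sum(chunk) / len(chunk))
    return out


def naive_bin(pairs, cell_size):
    """Direct floor-division binning of completed rank pairs."""
    import math

    cells = defaultdict(int)
    for _, row in pairs.iterrows():
        if row["exclusivity"] == "both":
            key = (
                math.floor(math.log10(row["r1"]) / cell_size),
                math.floor(math.log10(row["r2"]) / cell_size),
                "main",
            )
        elif row["exclusivity"] == "only_1":
            key = (math.floor(math.log10(row["r1"]) / cell_size), -1, "only_1")
        else:
            key = (-1, math.floor(math.log10(row["r2"]) / cell_size), "only_2")
        cells[key] += 1
    return dict(cells)


def random_stream(rng, n_messages, vocab, anchor="mental health", p_anchor=0.2,
                  start=dt.date(2020, 11, 20), span_days=90, p_retweet=0.35):
    """Random toy stream for oracle comparisons (independent of the
    package's generator)."""
    from discourselens.stream import Tweet

    tweets = []
    anchor_toks = anchor.split()
    for i in range(n_messages):
        k = int(rng.integers(1, 12))
        toks = [vocab[int(j)] for j in rng.integers(0, len(vocab), k)]
        if rng.random() < p_anchor:
            pos = int(rng.integers(0, len(toks) + 1))
            toks[pos:pos] = anchor_toks
        tweets.append(
            Tweet(
                id=f"m{i}",
                date=start + dt.timedelta(days=int(rng.integers(0, span_days))),
                text=" ".join(toks),
                lang="en",
                is_retweet=bool(rng.random() < p_retweet),
            )
        )
    return tweets
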