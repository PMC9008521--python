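"""On-disk table formats: ledgers, ranked distributions, shift tables.

Everything is TSV, UTF-8, loss-lessly round-trippable; plots and
downstream tooling consume these exports, never in-memory state.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter

import pandas as pd

from .divergence import DivergenceResult, RankRankHistogram
from .ngrams import LedgerSet, NgramLedger, RankedDistribution
from .sentiment import ShiftTable

_FLOAT = "%.10g"


def write_ledgers(ledgers: LedgerSet, path) -> int:
    """Write a (date, order) -> ledger set as
    ``date n ngram count_total count_organic count_retweet`` rows,
    sorted for byte-stable output.  Returns the row count."""
    rows = []
    for (date, n), ledger in sorted(ledgers.items()):
        for gram in sorted(ledger.types()):
            total, org, rt = ledger.entry(gram)
            rows.append((date.isoformat(), n, gram, total, org, rt))
    df = pd.DataFrame(
        rows,
        columns=["date", "n", "ngram", "count_total", "count_organic", "count_retweet"],
    )
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def read_ledgers(path) -> LedgerSet:
    df = pd.read_csv(path, sep="\t", dtype={"ngram": str})
    ledgers: LedgerSet = {}
    for row in df.itertuples(index=False):
        date = dt.date.fromisoformat(row.date)
        key = (date, int(row.n))
        ledger = ledgers.get(key)
        if ledger is None:
            ledger = ledgers[key] = NgramLedger(date, int(row.n))
        if row.count_organic:
            ledger.organic[row.ngram] = int(row.count_organic)
        if row.count_retweet:
            ledger.retweet[row.ngram] = int(row.count_retweet)
    return ledgers


def write_ranked(dist: RankedDistribution, path) -> int:
    df = dist.df.reset_index()[["ngram", "count", "frequency", "rank"]]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT)
    return len(df)


def read_ranked(path, *, label: str = "", n: int = 1) -> RankedDistribution:
    df = pd.read_csv(path, sep="\t", dtype={"ngram": str})
    counts = Counter({r.ngram: int(r.count) for r in df.itertuples(index=False)})
    return RankedDistribution.from_counts(counts, label=label, n=n)


def write_shift_table(shift: ShiftTable, path) -> int:
    df = shift.df[
        [
            "word",
            "h",
            "p_ref",
            "p_comp",
            "contribution",
            "class",
            "rank_in_comp",
            "happiness_rank_comp",
            "top",
        ]
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"# ref={shift.ref_label}\th_ref={shift.h_ref:.10g}\t"
            f"comp={shift.comp_label}\th_comp={shift.h_comp:.10g}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT)
    return len(df)


def write_divergence(result: DivergenceResult, path) -> int:
    df = result.table.reset_index()[["type", "r1", "r2", "contribution", "exclusivity"]]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"# alpha={result.alpha:.10g}\tD={result.total:.10g}\t"
            f"normalization={result.normalization:.10g}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT)
    return len(df)


def write_histogram(hist: RankRankHistogram, path) -> int:
    hist.cells.to_csv(path, sep="\t", index=False, float_format=_FLOAT)
    return len(hist.cells)


def write_frame(df: pd.DataFrame, path, *, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT)
    return len(df)


def daily_ledger_map(ledgers: LedgerSet, n: int) -> dict[dt.date, NgramLedger]:
    """Restrict a LedgerSet to one order as a date-keyed mapping."""
    return {date: lg for (date, order), lg in ledgers.items() if order == n}
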