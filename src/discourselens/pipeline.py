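"""End-to-end pipeline: stream -> ledgers -> rank/sentiment/divergence/
contagiogram tables.

The driver consumes the stream one day at a time so decade-scale runs
stay in bounded memory: full-corpus counters exist only for the day in
flight and are reduced to scalars (anchor rank, token totals, unique
counts) before the next day loads.  The anchored sub-corpus — the
messages containing the anchor phrase — is small by construction and
its daily 1-gram ledgers are retained for sentiment analysis; yearly
accumulators hold the anchored corpus and a thinned background sample
for the divergence comparison.

All randomness flows from the single seed in the config; two runs with
identical config and seed produce byte-identical exports, including the
manifest (which therefore carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amplification import (
    amplification_heatmap,
    detect_crossing,
    monthly_balance,
    smoothed_rank_panel,
)
from .divergence import (
    filter_anchor_phrases,
    impute_absent_ranks,
    rank_rank_histogram,
    rank_turbulence_divergence,
)
from .ngrams import (
    NgramLedger,
    RankedDistribution,
    rank_of_count,
    tokenize,
)
from .sentiment import ambient_happiness, build_reference, load_lexicon, rolling_smooth, word_shift
from .stream import Tweet, read_stream
from .synth import GroundTruth, StreamConfig, build_ground_truth, simulate_days, write_ground_truth
from . import tables

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Exactly one of ``synthetic`` (a :class:`StreamConfig`) or
    ``stream_path`` (a JSONL file) supplies the messages.  ``events``
    lists (date, kind) pairs for word-shift analysis; when omitted it
    defaults to the synthetic config's planted events.
    """

    out_dir: str | Path
    synthetic: StreamConfig | None = None
    stream_path: str | None = None
    anchor_phrase: str = "mental health"
    lexicon_path: str | None = None
    lens: tuple[float, float] | None = None
    events: list[dict] | None = None
    reference_mode: str = "pooled_week"
    alpha: float = 1.0 / 3.0
    ambient_window: int = 7
    rank_window: int = 30
    crossing_min_run: int = 3
    background_sample_rate: float = 0.01
    divergence_year: int | None = None
    histogram_cell_size: float = 0.25
    lowercase: bool = True
    seed: int = 0
    plots: bool = False

    def __post_init__(self):
        if (self.synthetic is None) == (self.stream_path is None):
            raise ValueError("exactly one of synthetic / stream_path must be set")
        if isinstance(self.synthetic, dict):
            self.synthetic = StreamConfig.from_dict(self.synthetic)
        if self.events is not None:
            self.events = [
                {
                    "date": dt.date.fromisoformat(str(e["date"])).isoformat(),
                    "kind": e["kind"],
                }
                for e in self.events
            ]
        if self.lens is not None:
            self.lens = (float(self.lens[0]), float(self.lens[1]))
        if not (0.0 < self.background_sample_rate <= 1.0):
            raise ValueError("background_sample_rate must be in (0, 1]")

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
        }
        d["out_dir"] = str(self.out_dir)
        d["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        d["lens"] = list(self.lens) if self.lens else None
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def effective_events(self) -> list[dict]:
        if self.events is not None:
            return self.events
        if self.synthetic is not None:
            return [
                {"date": e.date.isoformat(), "kind": e.kind}
                for e in self.synthetic.events
            ]
        return []


@dataclass
class PipelineResult:
    """In-memory view of one run's main products (tables are on disk)."""

    out_dir: Path
    manifest: dict
    rank_series: pd.Series
    rank_median: float | None
    ambient: pd.DataFrame
    anchored_daily_1grams: dict[dt.date, NgramLedger]
    shifts: list[dict]
    divergence: dict[int, object]
    balance: pd.DataFrame | None
    heatmap: pd.DataFrame | None
    crossing: object
    summaries: pd.DataFrame
    truth: GroundTruth | None


class _Accumulator:
    """Per-run streaming state; one day of full-corpus counters at a time."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.anchor_tokens = tuple(
            tokenize(config.anchor_phrase, lowercase=config.lowercase)
        )
        if not self.anchor_tokens:
            raise ValueError("anchor phrase empty after tokenization")
        self.anchor_bigram = " ".join(self.anchor_tokens)
        self.sample_every = max(1, round(1.0 / config.background_sample_rate))
        self.msg_index = 0

        self.summary_rows: list[tuple] = []
        self.rank_rows: list[tuple[dt.date, float | None]] = []
        self.bg_bigram_rows: list[tuple[dt.date, int, int]] = []
        self.anchored_1g: dict[dt.date, NgramLedger] = {}
        self.target_2g: dict[dt.date, NgramLedger] = {}
        self.year_anchor: dict[tuple[int, int], Counter] = {}
        self.year_sample: dict[tuple[int, int], Counter] = {}

    def _year_counter(self, store, year: int, n: int) -> Counter:
        key = (year, n)
        c = store.get(key)
        if c is None:
            c = store[key] = Counter()
        return c

    def process_day(self, date: dt.date, tweets: Iterable[Tweet]) -> None:
        lowercase = self.config.lowercase
        anchor = self.anchor_bigram
        n_anchor_toks = len(self.anchor_tokens)
        day_tokens: list[str] = []
        day_bigrams: list[str] = []
        org_tokens = 0
        total_tokens = 0
        big_ot = 0
        big_rt = 0
        anchored: list[tuple[list[str], list[str], bool]] = []
        sample_msgs: list[list[str]] = []
        sample_every = self.sample_every

        for tw in tweets:
            toks = tokenize(tw.text, lowercase=lowercase)
            idx = self.msg_index
            self.msg_index += 1
            if not toks:
                continue
            nt = len(toks)
            total_tokens += nt
            day_tokens.extend(toks)
            grams2 = (
                [a + " " + b for a, b in zip(toks, toks[1:])] if nt > 1 else []
            )
            day_bigrams.extend(grams2)
            if tw.is_retweet:
                big_rt += len(grams2)
            else:
                big_ot += len(grams2)
                org_tokens += nt
            if n_anchor_toks == 2:
                hit = anchor in grams2
            elif n_anchor_toks == 1:
                hit = self.anchor_tokens[0] in toks
            else:
                hit = f" {anchor} " in f" {' '.join(toks)} "
            if hit:
                anchored.append((toks, grams2, tw.is_retweet))
            if idx % sample_every == 0:
                sample_msgs.append(toks)

        c1 = Counter(day_tokens)
        big = Counter(day_bigrams)

        self.summary_rows.append(
            (date, len(c1), total_tokens, org_tokens)
        )
        self.rank_rows.append((date, rank_of_count(big, anchor)))
        self.bg_bigram_rows.append((date, big_ot, big_rt))

        if anchored:
            ledger1 = NgramLedger(date, 1)
            target = NgramLedger(date, 2)
            y1 = self._year_counter(self.year_anchor, date.year, 1)
            y3 = self._year_counter(self.year_anchor, date.year, 3)
            for toks, grams2, is_rt in anchored:
                ledger1.add_tokens(toks, is_rt)
                hits = grams2.count(anchor)
                (target.retweet if is_rt else target.organic)[anchor] = (
                    target.retweet if is_rt else target.organic
                ).get(anchor, 0) + hits
                y1.update(toks)
                if len(toks) >= 3:
                    y3.update(
                        a + " " + b + " " + c
                        for a, b, c in zip(toks, toks[1:], toks[2:])
                    )
            self.anchored_1g[date] = ledger1
            self.target_2g[date] = target
        if sample_msgs:
            y1 = self._year_counter(self.year_sample, date.year, 1)
            y3 = self._year_counter(self.year_sample, date.year, 3)
            for toks in sample_msgs:
                y1.update(toks)
                if len(toks) >= 3:
                    y3.update(
                        a + " " + b + " " + c
                        for a, b, c in zip(toks, toks[1:], toks[2:])
                    )


def _day_batches(config: PipelineConfig):
    """Yield (date, tweets, truth_row|None) in date order."""
    if config.synthetic is not None:
        stream_cfg = dataclasses.replace(config.synthetic, rng_seed=config.seed)
        yield from simulate_days(stream_cfg)
    else:
        by_date: dict[dt.date, list[Tweet]] = {}
        for tw in read_stream(config.stream_path):
            by_date.setdefault(tw.date, []).append(tw)
        for date in sorted(by_date):
            yield date, by_date[date], None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and export tables plus a manifest; deterministic
    given config + seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "shifts").mkdir(exist_ok=True)
    (out / "contagiogram").mkdir(exist_ok=True)
    (out / "ledgers").mkdir(exist_ok=True)

    lexicon = load_lexicon(config.lexicon_path, lens=config.lens)
    acc = _Accumulator(config)
    truth_rows: list[dict] = []
    n_days = 0
    for date, tweets, truth_row in _day_batches(config):
        acc.process_day(date, tweets)
        if truth_row is not None:
            truth_rows.append(truth_row)
        n_days += 1
        if n_days % 365 == 0:
            logger.info("processed %d days (%s)", n_days, date)
    if n_days == 0:
        raise ValueError("stream contained no messages")

    table_counts: dict[str, int] = {}

    # --- corpus summaries -------------------------------------------------
    summaries = pd.DataFrame(
        acc.summary_rows,
        columns=["date", "unique_1grams", "total_1grams", "total_1grams_no_retweets"],
    )
    summaries.insert(1, "corpus", "general")
    anch_rows = []
    for date in sorted(acc.anchored_1g):
        lg = acc.anchored_1g[date]
        org = sum(lg.organic.values())
        rt = sum(lg.retweet.values())
        anch_rows.append((date, "anchored", len(lg), org + rt, org))
    summaries = pd.concat(
        [summaries, pd.DataFrame(anch_rows, columns=summaries.columns)],
        ignore_index=True,
    ).sort_values(["date", "corpus"]).reset_index(drop=True)
    table_counts["summary.tsv"] = tables.write_frame(summaries, out / "summary.tsv")

    # --- anchor rank series ----------------------------------------------
    dates = [d for d, _ in acc.rank_rows]
    rank_series = pd.Series(
        [np.nan if r is None else r for _, r in acc.rank_rows],
        index=pd.DatetimeIndex(dates, name="date"),
        name="rank",
        dtype=float,
    )
    rank_median = None if rank_series.dropna().empty else float(rank_series.median())
    panel = smoothed_rank_panel(rank_series, config.rank_window)
    rank_df = pd.DataFrame(
        {"date": rank_series.index.date, "rank": rank_series.to_numpy(),
         "smoothed": panel.smoothed.reindex(rank_series.index).to_numpy()}
    )
    table_counts["rank_series.tsv"] = tables.write_frame(rank_df, out / "rank_series.tsv")

    # --- ambient happiness ------------------------------------------------
    amb_rows = []
    for date in sorted(acc.anchored_1g):
        h, matched = ambient_happiness(acc.anchored_1g[date], lexicon)
        amb_rows.append((date, h, matched))
    ambient = pd.DataFrame(amb_rows, columns=["date", "h_avg", "matched"])
    if len(ambient):
        s = pd.Series(
            ambient["h_avg"].to_numpy(dtype=float),
            index=pd.DatetimeIndex(ambient["date"]),
        )
        smoothed = rolling_smooth(s, config.ambient_window)
        ambient["smoothed"] = smoothed.reindex(pd.DatetimeIndex(ambient["date"])).to_numpy()
    else:
        ambient["smoothed"] = []
    table_counts["ambient.tsv"] = tables.write_frame(ambient, out / "ambient.tsv")

    # --- word shifts per event --------------------------------------------
    shifts: list[dict] = []
    for ev in config.effective_events():
        ev_date = dt.date.fromisoformat(ev["date"])
        record = {"date": ev["date"], "kind": ev["kind"], "status": "ok",
                  "h_ref": np.nan, "h_comp": np.nan, "delta": np.nan}
        try:
            comp = acc.anchored_1g[ev_date]
        except KeyError:
            record["status"] = "no_event_day_corpus"
            shifts.append(record)
            logger.warning("word_shift: no anchored corpus on %s", ev_date)
            continue
        try:
            ref = build_reference(acc.anchored_1g, ev_date, config.reference_mode)
            shift = word_shift(
                ref, comp, lexicon,
                ref_label=f"week_before_{ev['date']}", comp_label=ev["date"],
            )
        except ValueError as exc:
            record["status"] = f"failed: {exc}"
            shifts.append(record)
            logger.warning("word_shift %s: %s", ev_date, exc)
            continue
        record.update(h_ref=shift.h_ref, h_comp=shift.h_comp, delta=shift.delta)
        shifts.append(record)
        name = f"shifts/shift_{ev['date']}_{ev['kind']}.tsv"
        table_counts[name] = tables.write_shift_table(shift, out / name)
    shift_summary = pd.DataFrame(
        shifts, columns=["date", "kind", "status", "h_ref", "h_comp", "delta"]
    )
    table_counts["shift_summary.tsv"] = tables.write_frame(
        shift_summary, out / "shift_summary.tsv"
    )

    # --- rank-turbulence divergence ---------------------------------------
    divergence: dict[int, object] = {}
    years_available = sorted(
        {y for (y, n) in acc.year_anchor} & {y for (y, n) in acc.year_sample}
    )
    div_year = config.divergence_year
    if div_year is None and years_available:
        div_year = years_available[-1]
    if div_year is not None and (div_year, 1) in acc.year_anchor and (div_year, 1) in acc.year_sample:
        for order in (1, 3):
            ca = acc.year_anchor.get((div_year, order))
            cs = acc.year_sample.get((div_year, order))
            if not ca or not cs:
                continue
            sys1 = RankedDistribution.from_counts(
                ca, label=f"anchored_{div_year}", n=order
            )
            if order == 3 and len(acc.anchor_tokens) == 2:
                sys1 = filter_anchor_phrases(sys1, acc.anchor_bigram)
            sys2 = RankedDistribution.from_counts(
                cs, label=f"sample_{div_year}", n=order
            )
            result = rank_turbulence_divergence(sys1, sys2, config.alpha)
            divergence[order] = result
            name = f"divergence_{order}gram.tsv"
            table_counts[name] = tables.write_divergence(result, out / name)
            hist = rank_rank_histogram(
                impute_absent_ranks(sys1, sys2), config.histogram_cell_size
            )
            hname = f"divergence_{order}gram_histogram.tsv"
            table_counts[hname] = tables.write_histogram(hist, out / hname)

    # --- contagiogram ------------------------------------------------------
    balance = heatmap = None
    crossing = None
    if acc.target_2g:
        balance = monthly_balance(acc.target_2g, acc.anchor_bigram)
        bg = pd.DataFrame(
            acc.bg_bigram_rows, columns=["date", "ot", "rt"]
        ).set_index("date")
        heatmap = amplification_heatmap(acc.target_2g, acc.anchor_bigram, bg)
        crossing = detect_crossing(balance, config.crossing_min_run)
        table_counts["contagiogram/balance.tsv"] = tables.write_frame(
            balance.reset_index(), out / "contagiogram" / "balance.tsv"
        )
        table_counts["contagiogram/heatmap.tsv"] = tables.write_frame(
            heatmap, out / "contagiogram" / "heatmap.tsv"
        )
        rp = pd.DataFrame(
            {
                "date": rank_series.index.date,
                "rank": rank_series.to_numpy(),
                "smoothed": panel.smoothed.reindex(rank_series.index).to_numpy(),
            }
        )
        iso = rank_series.index.isocalendar()
        band = panel.weekly_band
        keys = list(zip(iso["year"].to_numpy(), iso["week"].to_numpy()))
        rp["week_min"] = [band.at[k, "min"] if k in band.index else np.nan for k in keys]
        rp["week_max"] = [band.at[k, "max"] if k in band.index else np.nan for k in keys]
        table_counts["contagiogram/rankpanel.tsv"] = tables.write_frame(
            rp, out / "contagiogram" / "rankpanel.tsv"
        )

    # --- anchored ledgers + ground truth ----------------------------------
    ledger_set = {(d, 1): lg for d, lg in acc.anchored_1g.items()}
    table_counts["ledgers/anchored_1grams.tsv"] = tables.write_ledgers(
        ledger_set, out / "ledgers" / "anchored_1grams.tsv"
    )

    truth = None
    if config.synthetic is not None:
        stream_cfg = dataclasses.replace(config.synthetic, rng_seed=config.seed)
        truth = build_ground_truth(stream_cfg, truth_rows)
        write_ground_truth(truth, out / "ground_truth.json")

    manifest = {
        "package": "discourse-lens",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_days": n_days,
        "n_messages": acc.msg_index,
        "tables": dict(sorted(table_counts.items())),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, ensure_ascii=False)
        fh.write("\n")

    if config.plots:
        from . import plotting

        plotting.render_all(out)

    return PipelineResult(
        out_dir=out,
        manifest=manifest,
        rank_series=rank_series,
        rank_median=rank_median,
        ambient=ambient,
        anchored_daily_1grams=acc.anchored_1g,
        shifts=shifts,
        divergence=divergence,
        balance=balance,
        heatmap=heatmap,
        crossing=crossing,
        summaries=summaries,
        truth=truth,
    )
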