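"""Count n-grams per day, rank them with fractional ties, and follow the
anchor phrase's rank through a planted growth schedule.

Rank 1 is the most-used n-gram of the day; a falling rank series means
the phrase is gaining attention.
"""

import datetime as dt

from discourselens import (
    StreamConfig,
    count_stream,
    generate_stream,
    rank_distribution,
    rank_timeseries,
    summarize_corpus,
    yearly_aggregate,
)
from discourselens.schedules import LogLinearSchedule

start, end = dt.date(2018, 1, 1), dt.date(2020, 1, 1)
config = StreamConfig(
    start_date=start,
    end_date=end,
    messages_per_day=150,
    vocab_size=2000,
    anchor_prevalence=LogLinearSchedule(start, end, 0.002, 0.2),  # 100x growth
    retweet_prob=0.3,
    rng_seed=7,
)
tweets, _ = generate_stream(config)

ledgers = count_stream(tweets, orders=(1, 2))
daily_2g = {
    date: rank_distribution(lg) for (date, n), lg in ledgers.items() if n == 2
}
series, median = rank_timeseries(daily_2g, "mental health")
by_year = series.groupby(series.index.year).median()
print("median rank of 'mental health' by year (lower = more popular):")
for year, rank in by_year.items():
    print(f"  {year}: {rank:8.1f}")
print(f"overall median     : {median:.1f}")
print(f"improvement factor : {by_year.iloc[0] / by_year.iloc[-1]:.1f}x")

years = yearly_aggregate({d: lg for (d, n), lg in ledgers.items() if n == 2})
print(f"yearly-aggregate rank in {list(years)[-1]}: "
      f"{years[list(years)[-1]].rank_of('mental health'):.1f}")

summary = summarize_corpus(ledgers, start, "general")
print(f"day-one summary    : {summary.unique_1grams} unique / "
      f"{summary.total_1grams} total 1-grams "
      f"({summary.total_1grams_no_retweets} excluding retweets)")
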