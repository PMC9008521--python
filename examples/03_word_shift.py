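"""Score ambient happiness around an anchor phrase and decompose an
event-day drop into per-word contributions.

Ambient happiness is the lexicon-weighted mean score (1-9 scale) of the
words co-occurring with the anchor; the word shift explains a change
between a day and its pooled prior-week reference, word by word, with
contributions summing exactly to the difference.
"""

import datetime as dt

from discourselens import (
    Event,
    StreamConfig,
    ambient_happiness,
    build_reference,
    count_stream,
    generate_stream,
    load_lexicon,
    word_shift,
)
from discourselens.ngrams import anchor_subset

event_day = dt.date(2019, 2, 20)
config = StreamConfig(
    start_date=dt.date(2019, 2, 1),
    end_date=dt.date(2019, 3, 1),
    messages_per_day=400,
    vocab_size=2000,
    anchor_prevalence=0.08,
    events=[Event(event_day, "tragedy", 8.0, 2.0)],
    retweet_prob=0.3,
    rng_seed=11,
)
tweets, _ = generate_stream(config)
lexicon = load_lexicon()  # bundled synthetic demonstration lexicon

anchored = anchor_subset(tweets, "mental health")
daily = {
    date: lg
    for (date, n), lg in count_stream(anchored, orders=(1,)).items()
}

h_event, n_event = ambient_happiness(daily[event_day], lexicon)
print(f"ambient happiness on {event_day}: {h_event:.3f} ({n_event} scored tokens)")

reference = build_reference(daily, event_day, "pooled_week")
shift = word_shift(reference, daily[event_day], lexicon, top_k=8)
print(f"reference week h   : {shift.h_ref:.3f}")
print(f"shift              : {shift.delta:+.3f} (negative = sadder language)")
print("top contributions (class: word valence vs usage direction):")
for row in shift.head().itertuples(index=False):
    cls = row[list(shift.df.columns).index("class")]
    print(f"  {row.word:<12} h={row.h:.2f}  {row.contribution:+.4f}  {cls}")
check = shift.df["contribution"].sum() - shift.delta
print(f"conservation residual: {check:.2e} (contributions sum to the shift)")
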