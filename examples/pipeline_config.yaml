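# Example end-to-end pipeline configuration for `discourse-lens run`.
# A small synthetic stream (90 days); swap `synthetic:` for
# `stream_path: my_stream.jsonl` to analyze real data.
out_dir: scratch/example_run
seed: 21
anchor_phrase: mental health
alpha: 0.3333333333333333
ambient_window: 7
rank_window: 30
synthetic:
  start_date: 2019-01-01
  end_date: 2019-04-01
  messages_per_day: 150
  vocab_size: 1000
  zipf_exponent: 1.0
  anchor_phrase: mental health
  anchor_prevalence: {kind: log_linear, start_date: 2019-01-01, end_date: 2019-04-01,
                      start_value: 0.02, end_value: 0.1}
  events:
    - {date: 2019-02-14, kind: awareness, boost: 10, half_life_days: 1.5}
    - {date: 2019-03-10, kind: tragedy, boost: 10, half_life_days: 2.5}
  retweet_prob: {kind: logistic, low: 0.25, high: 0.7, midpoint: 2019-02-15, scale_days: 10}
  anchor_retweet_boost: 2.0
  rng_seed: 21
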