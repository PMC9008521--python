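# Methods

This note documents the models implemented by `discourse-lens`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions chosen where the methods
literature leaves room.

## Counting model

Messages are tokenized by splitting on unicode whitespace, case-folding
to lowercase (configurable off), and stripping leading/trailing
punctuation while preserving a leading `#` or `@`, so hashtags and
handles survive as single types. No stemming, emoji segmentation or
language-specific handling is attempted. For every UTC calendar day
and every order n ∈ {1,2,3}, the ledger records each n-gram's total,
organic and retweet counts (total = organic + retweet by construction).
Day boundaries are UTC calendar days; messages carry day-precision
timestamps.

Ranking uses descending counts with fractional (average) ranks for
ties. This makes rank sums exactly N(N+1)/2 — a testable invariant —
and keeps the divergence module consistent with its imputation rule. A
target absent on a day is recorded as missing, never as a sentinel
rank; medians and smoothers skip missing days.

The anchored sub-corpus contains exactly the messages whose token
sequence includes the anchor phrase contiguously, matched after the
same tokenization, so punctuation variants ("mental health!") match.

## Ambient happiness and word shifts

Ambient happiness is the count-weighted mean lexicon score over the
anchored corpus's lexicon-matched 1-grams. Choices:

* **Weighting** is by token occurrences, not by distinct messages (a
  per-message average would weight short messages up); this is the
  straightforward reading of "averaging the scores of each word".
* **Lens** (excluding words with lo < h < hi, conventionally (4,6)) is
  off by default and available by flag.
* The anchor's own constituent words are included in scoring by
  default (flag to exclude): they are genuine corpus content, and
  excluding them changes levels but not event-day contrasts.
* **Smoothing** is a trailing mean over a 7-day window. Windows with
  fewer than half of their in-range days observed are reported missing;
  at the series head the window is the overlapping part, so a dense
  series smooths from day one.

Word shifts use frequencies normalized over lexicon-matched tokens
within each corpus; a word absent from one corpus has p = 0 there (the
contribution formula is well-defined at zero, so no smoothing is
applied). The conservation law Σ δh_w = h_comp − h_ref is exact and is
asserted to 1e-9 in the acceptance suite. Ties at the top-k display
boundary break alphabetically for deterministic output. The reference
for an event day defaults to the pooled 7 days strictly before the
event; a same-day-prior-week single-day mode is also provided since
"the prior week" is ambiguous between the two. The export carries both
the usage rank and the happiness rank of each word within the
comparison corpus, so either vertical ordering of a shift graph can be
rendered.

## Rank-turbulence divergence

For the union of types, with fractional tied ranks r₁, r₂ and a type
absent from system 2 imputed rank N₂ + (N_x1 + 1)/2 (N₂ observed types
in system 2, N_x1 types exclusive to system 1; symmetrically for
system 1), each type contributes

    (α+1)/α · | r₁^(−α) − r₂^(−α) |^(1/(α+1)) / 𝒩,

where 𝒩 is the same sum under the all-disjoint hypothetical (observed
ranks kept, every type imputed as fully exclusive). α defaults to 1/3,
the instrument convention; the α → 0 and α → ∞ limits need special-case
formulas and are excluded (α restricted to finite positives). Near the
ends of that range the statistic increasingly weights rare (small α
... large rank) or common types, and small-count systems become
tie-dominated.

**The normalization is not a strict upper bound.** D = 0 on identical
tied rankings and D = 1 on disjoint supports hold exactly, and D ≤ 1
holds comfortably on well-populated systems. But on very small systems
the observed-overlap sum can exceed the all-disjoint normalization by a
few percent — e.g. when observed tied ranks coincide exactly with the
disjoint imputed rank, their normalization terms vanish (a pinned
2-vs-8-type instance in the unit suite reaches D ≈ 1.030 at α = 2);
random instances with ≤ 25 heavily tied types exceed 1 at roughly a
0.5% rate. The implementation reports the computed value unclamped;
treat D as effectively-but-not-formally bounded by 1 for corpus-scale
systems (the unit and acceptance suites document this property rather
than hide it).

For 3-gram comparisons of an anchored corpus, every 3-gram beginning or
ending with the anchor 2-gram can be removed (survivors re-ranked),
since those phrases are present by construction and swamp the table.
The rank–rank histogram bins shared types on a (log₁₀ r₁, log₁₀ r₂)
grid (cell size 0.25 default) with exclusive types in one-dimensional
bands; the 45°-rotated rendering used in allotaxonographs is a display
transform, not part of the data contract.

## Contagiograms

Monthly organic/retweet fractions f_OT + f_RT = 1 come from summed
daily counts; a month is *amplified* when f_RT > 1/2 strictly. The
heatmap statistic R is a ratio of summed counts per (weekday × month)
cell — ratio of sums, not mean of daily ratios, which is unstable when
single days have zero counts. Cells with zero organic counts (target
or background) are reported missing with their count annotations, never
clamped or infinite. Rank-series smoothing is a trailing 30-day mean
of log₁₀ rank transformed back (ranks live on a log axis), with the
same half-window availability rule as ambient smoothing, plus a
per-ISO-week min–max envelope. The balance crossing detector returns
the first month beginning ≥ 3 consecutive amplified months
(configurable); the run requirement suppresses single-month noise at
the cost of up to two months' detection latency on slow transitions.

## Synthetic stream generator

The generator emulates the statistical skeleton of a large 10%-sample
message stream at desk scale. Reference study conditions
(`default_config`): 3650 days from 2010-01-01, 1000 messages/day,
20,000-word Zipf background vocabulary (exponent 1.0), message lengths
uniform on 5–25 tokens, anchor prevalence log-linear 10⁻⁴ → 10⁻²
(two orders of magnitude across the window), and a retweet probability
following a logistic 0.15 → 0.75 centred on 2017-01-01 with a 30-day
scale, with anchor messages' retweet *odds* boosted 2×. The sharp
logistic scale is a deliberate study condition: it concentrates the
target's balance transition enough that month-resolution crossing
detection is statistically meaningful at ~10²–10³ anchored messages
per month.

Planted events multiply the prevalence (capped at probability 1) with
exponential half-life decay, and switch the anchor-topic vocabulary
into a sentiment regime: topic words are drawn from the lexicon with
weights ∝ exp(−(h−μ)²/2σ²), μ = 5.5 baseline / 7.0 awareness / 2.8
tragedy, σ = 0.7. The default calendar plants two annual awareness
days (late January, boost 25×, half-life 1.5 d; October 10, boost 10×)
from 2015–2019 plus three irregular tragedies (2015-06-17, 2017-04-18,
2018-06-08; boost 15×, half-life 2.5 d). Events start in 2015 rather
than earlier because below ~10⁻³ prevalence the pooled prior-week
reference corpus has non-trivial probability of containing no messages
at all, which makes the word-shift precondition fail for reasons
unrelated to the sentiment planting; at the 2015+ prevalences every
event's reference corpus is populated with overwhelming probability.

Retweets are generated as fresh messages flagged `is_retweet`, not
copies of earlier messages — every downstream statistic uses only the
flag and the text. Anchor messages contain the anchor phrase as
contiguous tokens with the remaining tokens drawn from topic (p = 0.7)
or background vocabulary; background messages draw only from the
background vocabulary, which excludes the anchor tokens, so they can
never contain the phrase. Each day derives its RNG from
(seed, day-index), making streams reproducible byte-for-byte and
generation streamable day by day in bounded memory.

**What it does not emulate:** user accounts, follower graphs and
cascade structure; hashtag co-evolution; bursty intra-day dynamics;
realistic word burstiness (tokens are i.i.d. within a regime, so rank
fluctuations are narrower than in real streams); multilinguality; and
real lexicon coverage (background pseudo-words are deliberately
out-of-lexicon, so ambient scores are driven by topic words and the
anchor tokens). Passing recovery tests therefore demonstrates that the
measurement machinery is correct and well-calibrated on known
structure — not that real discourse obeys the planted schedules.

The bundled lexicon (`data/synthetic_happiness_lexicon.tsv`, ~220 words
spanning [1,9]) is a hand-assigned stand-in constructed for this
package in the style of crowdsourced happiness dictionaries; analyses
of real text should load a published instrument via `load_lexicon`.

## Pipeline and problem sizes

The pipeline consumes the stream one day at a time: full-corpus
counters exist only for the day in flight and are reduced to scalars
(anchor rank, token totals, unique counts) before the next day loads;
only the small anchored corpus's daily ledgers and yearly accumulators
(anchored + a 1% systematic background sample, used for the divergence
comparison) persist. The reference 3.65M-message run completes in
about a minute on one CPU in well under 1 GB. All randomness flows
from the single config seed; identical configs produce byte-identical
exports, and the run manifest (config, config hash, row counts)
deliberately contains no timestamps so manifests are reproducible too.

An event whose word shift cannot be computed (no anchored messages on
the day, or no lexicon-matched tokens) is recorded as a failed row in
`shift_summary.tsv` rather than aborting the run: an empty corpus is a
measurement outcome. Malformed stream lines are skipped with logged
warnings and abort the read if they exceed 1% of lines (configurable).

The test suite exercises every counting path against naive nested-loop
oracles on random streams (up to 1000 messages), the divergence against
a direct term-by-term evaluation script (to 1e-12), the smoothers
against windowed-mean oracles, and the full pipeline against the
generator's ground truth at the reference scale. Scaled-down variants
of the planted-structure checks (e.g. 2-year streams for crossing
recovery across 20 seeds) keep the default test run to a few minutes.

## Known limitations

* Dictionary sentiment scoring has no negation, sarcasm or context
  handling; independently positive words inside tragic narratives
  still score positive.
* The organic/retweet dichotomy treats quote-style reshares and exact
  reshares identically (a single flag).
* Divergence comparisons assume both corpora were tokenized and tied
  identically; mixing rank lists from other tools with different tie
  conventions will silently change D.
* The D ≤ 1 bound caveat above applies to small systems; contribution
  tables and orderings are unaffected.
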