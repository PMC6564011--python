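# Methods

## The detection model and its assumptions

The detector treats a game as *a* categorical draws and asks, for each
n-gram of length 2–4, whether it occurs among the non-overlapping tiles
more often than an independence null predicts. The null is deliberately
weak: actions are drawn iid from the player's own marginal type
proportions, so an n-gram's null probability is the product of its
components' marginals and the tile count of that n-gram is
Binomial(n_tiles, p). Real action streams are not iid even without chunks
(game phase, task context), so confirmed chunks should be read as
"sequences over-represented relative to base rates", with held-out
confirmation guarding against selection bias rather than against all
serial dependence.

Two deliberate asymmetries:

- **Counting for inference is tiled; marking is sliding.** The binomial
  model needs (approximately) independent trials, which non-overlapping
  tiles provide and sliding windows do not. Once a chunk is confirmed,
  however, every sliding occurrence in the whole stream is marked, since
  the latency analysis concerns all chunk use, not just tile-aligned use.
  One consequence worth knowing: the proportion of marked actions exceeds
  the rate at which chunks are deliberately emitted, because chance
  occurrences of a confirmed n-gram (common bigrams especially) are marked
  too.
- **Marginals are computed from all *a* actions**, before the repeat-tile
  drop, because they define the player's overall action mix; the drop rule
  exists to remove artifactual tiles from the *trials*, not to redefine
  the mix.

Tie-breaks and edge rules are fixed for determinism: nomination ties break
by higher training count then lexicographic n-gram order; the extra tile
of an odd split goes to the training half; α = 0.05 is a strict
inequality; a length is skipped when fewer than 4 retained tiles remain.
Per-(game, length) RNG substreams derive from a master seed plus a CRC-32
hash of the game id, so cohort results do not depend on processing order.

## Latency and savings

Latency is the time since the same player's previous action; the first
action of a game has no latency and is excluded from every mean (a zero
would bias them). Baselines for savings are per game and per type, using
only non-chunked actions with defined latency: chunked actions of a type
with no eligible baseline are excluded and counted rather than scored
against a pooled baseline, avoiding cross-type and cross-player
contamination. "Inter-action latency" means non-first *chunked* actions
(the within-chunk positions); the alternative reading — all non-chunked
actions — is a different comparison and is available trivially from the
annotation table. Positive savings mean the chunked action was faster than
its baseline.

The redundant right-click analysis needs no chunk detector: maximal runs
of ≥ 2 consecutive RightClicks flanked by ScreenShifts qualify, each run's
first latency (the approach) is excluded, and a stream boundary counts as
a flanking punctuation (a run cut off by the end of the log is still a
run).

## Diversity

G counts distinct sliding subsequences of lengths 2, 3, 4 in the 400
actions around the 10-minute mark (200 each side; an action exactly at the
mark is "after"; games that cannot fill both halves are excluded, not
padded). Sliding windows are an interpretation — tiled counting would make
G depend on tile phase — and the three windows straddling the join are
included since the sample is analysed as one sequence. The permutation
baseline uses 100 uniform shuffles of the sample's multiset (preserving
the type mix, destroying order); `randomness = G − mean(S)` is reported
instead of a permutation percentile because for structured players G falls
far below every permuted S, making percentiles uninformative.

## Inference

ANOVAs are additive (League + Species, no interaction) with marginal
(Type-II-style) tests — well defined in an additive model — and a
sequential option since legacy software defaults differ. Partial
η² = SS_effect / (SS_effect + SS_residual). A factor constant in the data
is dropped with a warning, which also makes the one-factor case collapse
exactly to textbook one-way ANOVA. A constant response returns F = 0
exactly rather than 0/0 noise. Zero-variance t-test inputs return a
flagged degenerate result, never infinities. Family-wise correction for
planned comparisons is Holm by default (Bonferroni available), with pooled
variance per classic planned-comparison practice and Welch as an option.
Degrees of freedom always come from the data supplied. All tests are
invariant to row order.

## What the generator emulates — and what it does not

Each simulated player draws, per emission: a repertoire chunk (default
rates 0.08 + 0.04 for two bigrams, 0.02 trigram, 0.01 four-gram), an
artifactual repeat burst of RightClick/Train/HotkeySelect (rate 0.05,
geometric run length, mean ≈ 3.9, within-run latency × 0.30), or a single
iid action. Chunk first actions are slowed × 1.28 and subsequent actions
sped × 0.78 — chosen so first-action losses and inter-action gains roughly
cancel, i.e. net per-game savings near zero, the regime the latency
analysis must be able to measure without bias. Latency noise is lognormal
(σ = 0.5 log-units; latencies are positive and right-skewed, and the
implied coefficient of variation ≈ 0.53 matches the observed ratio of
latency SDs to means in this kind of telemetry). The skill schedule
interpolates geometrically between mean action latencies of 1019 ms
(skill 1) and 234 ms (skill 8) — the two printed anchors — and the base
draw scale is solved so that the *observed* mixture mean (chunks, bursts,
noise included) lands on the schedule. Species is a small multiplicative
nuisance factor (±3%).

The generator's analytic expected saving per chunk action,
base × e^{σ²/2} × (1 − multiplier), is exact only when repeat bursts are
disabled: bursts deflate the empirical same-type baselines of the burst
types. Savings-recovery checks therefore simulate with
`repeat_run_rate = 0`.

Deliberately **not** modelled: game state, strategy, opponent interaction,
win/loss; nonstationarity over a game (early-game build orders vs
late-game battles); cross-game player identity; chunk interleaving
(emissions complete before the next draw); and any structure in screen
positions (the fixation module is exercised on synthetic random walks).
Passing recovery tests therefore shows the *estimators* are correct under
the stated generative regime, not that real streams satisfy that regime.

## Fixation aggregation

Raw screen samples are reduced by dispersion-threshold identification
(I-DT): maximal windows with (max x − min x) + (max y − min y) ≤ threshold
and span ≥ minimum duration become fixations; one ScreenShift event is
emitted at each onset. The defaults (2.0 map units, 250 ms) are
**uncalibrated placeholders** — no published parameterisation exists for
this telemetry — and must be tuned to the coordinate system at hand.
Timestamps are integer ms canonically; a `frame_rate` option converts
frame-stamped logs. On exact timestamp ties, key actions precede screen
shifts (fixed convention for deterministic n-grams).

## Problem sizes and numerical checks

The test suite verifies: binomial tails against an exact-rational
direct-summation oracle to 1e-10 for n ≤ 500; per-candidate false
confirmation ≤ α within 3 Monte-Carlo SE on 1000 iid games of a = 2000;
≥ 95% recovery over 200 simulations of a bigram planted at 30% tile
occupancy (a = 1000, null probability ≤ 0.05); savings unbiasedness within
3 SE of the analytic expectation over 40 games with the exact
first + inter decomposition; the unique-sequence count against an O(n²)
pairwise-distinctness oracle up to 1000 actions, exact zero randomness on
constant streams, iid calibration within 3 permutation SDs, and strict
monotone decline of randomness over a five-point chunk-usage sweep; and
the additive ANOVA against the closed-form one-way F to 1e-9. The
acceptance script simulates 96 players (12 per skill level, 16-minute
games) plus 400 null and 200 planted games; these sizes give stable
Monte-Carlo estimates while keeping a full run in tens of seconds on one
CPU.

## Known limitations

- The binomial null ignores serial dependence other than chunking; its
  type-I control is exact only against iid streams (verified), and
  conservative marginally (discrete counts).
- Candidates must appear in the training half; rare true chunks can be
  missed (a sequence used once per game is invisible to prevalence-based
  detection by construction).
- Marking by sliding occurrence inflates the chunked-action proportion
  above the deliberate-use rate (chance occurrences of confirmed n-grams
  are marked).
- The diversity statistic G is computed on the 400-action sample, matching
  its permutation baseline; computing it on whole games would conflate
  diversity with game length.
- I-DT parameters are placeholders (above).
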