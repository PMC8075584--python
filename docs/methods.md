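# Methods

This note documents the models, conventions and design choices behind
`fedkit`: what the simulator generates and why, how each analysis is
defined in corner cases, and what the test suite does and does not
establish about real recordings.

## Event-log data model and dialect

A recording is a `SessionLog`: an ordered list of `Event`s plus session
metadata. Three event kinds exist — `LeftPoke`, `RightPoke`, `Pellet` —
each carrying cumulative counters *as of that event* and, for pellet
events only, the retrieval time (seconds from dispense to removal).

The on-disk dialect is UTF-8 CSV with the mandatory header

```
timestamp,device_id,session_type,event,active_poke,left_count,right_count,pellet_count,retrieval_time,operant
```

Timestamps are timezone-naive ISO-8601 at 1 s resolution; a log is a
single contiguous recording. Retrieval times are written with Python's
shortest round-tripping float representation so that
`write → read → write` is byte-identical. Conventions worth stating:

- **Blocked pokes are logged, flagged.** Pokes made while a pellet sits
  in the well, outside a time-restricted feeding window, or during an
  ongoing stimulation train are recorded with `operant=False` rather than
  dropped. Devices register these pokes physically even when the task
  ignores them; keeping them flagged preserves information and lets every
  analysis choose (`include_nonoperant`, default on, since poke totals
  conventionally include all pokes).
- **Timestamp ties** keep stable file order; nothing is reordered.
- **Slices are not renumbered**: cumulative counters in a sliced log
  still refer to the parent recording, keeping slices traceable.
- Session-level metadata that has no per-row column — light cycle, pellet
  mass, recording start/end — lives in a YAML sidecar
  (`<log>.meta.yaml`). The recording window matters because per-day rates
  need a denominator that an event list alone cannot provide (an empty
  24-h recording is 0 pellets/day, not undefined).
- Validation is total: malformed rows produce diagnostics with line
  numbers, never silent coercion; invariant violations (decreasing
  timestamps, inconsistent counters) name the offending rows.

## The task state machines

All six modes share one event-driven simulation clock: internal times are
continuous, quantized to 1 s only when logging (matching the device's log
resolution without aliasing the underlying point processes).

- **FreeFeeding** — a pellet is always available; each removal logs a
  pellet event and the next pellet is immediately available. Retrieval
  time is the elapsed time since the pellet became available.
- **TimeRestricted** — free feeding gated by a daily clock window
  `[start, end)` with midnight wrap-around; outside the window nothing is
  dispensed and pokes are non-operant.
- **FR1 / ProgressiveRatio / ClosedEconomyPR** — an active-port poke
  counts toward the current requirement when the well is empty; reaching
  the requirement dispenses a pellet, which is removed after a random
  retrieval delay. While the pellet is in the well both ports are
  inactive. The PR requirement after `k` earned pellets is `k + 1`
  (linear schedule) or `round(5·e^{0.2(k+1)} − 5)` clamped to ≥ 1
  (exponential schedule); the linear +1 progression is the default and
  the schedule is a first-class parameter, since published closed-economy
  variants differ in their exact escalation.
- **Closed-economy reset** — if no poke on either port occurs for
  `reset_timeout` (default 1800 s, boundary inclusive), the requirement
  resets to 1 and a new bout begins. The rule is evaluated on the
  *quantized* poke timestamps, deliberately: this makes the device state
  exactly reconstructible from the written log, which the breakpoint
  replay (below) exploits and the tests verify trace-for-trace. A pause
  that ends while a pellet still occupies the well does not reset (the
  bout cannot advance anyway until the pellet is taken).
- **SelfStim** — each active poke triggers a pulse train (default 1 s of
  20 Hz pulses; onsets at `k/f` for `k/f <` duration) and the session
  ends at `max_trains` trains (default 75) or the nominal duration,
  whichever comes first. Active pokes during an ongoing train do not
  retrigger and are logged non-operant. Pulse trains are not event rows;
  they are recoverable as the operant active pokes and exportable as a
  two-column voltage waveform CSV for alignment with external recordings.

Magazine training is simply FreeFeeding run before FR1; sequencing modes
is the caller's job.

## The virtual mouse

`MouseModel` is a generative stand-in for an animal, with every parameter
explicit and seedable; `(task, mouse, start, duration, light, seed)`
determines the log byte-for-byte.

| component | model | defaults |
|---|---|---|
| nose-poking | piecewise-homogeneous Poisson, dark/light rates | 60 / 20 pokes·h⁻¹ (3:1 nocturnal bias) |
| port choice | active port w.p. `acc(t) = a − (a − s)e^{−t/τ}`, `t` = exposure | s = 0.5, a = 0.85, τ = 4 h |
| retrieval delay | log-normal; median decays with exposure on the same form | 30 s → 3 s, τ = 4 h, σ = 0.8 |
| feeding bouts | meal onsets with exponential between-meal gaps per phase; meal size 1 + Poisson(mean − 1); within-meal exponential gaps | 45 min dark / 120 min light; 6 pellets; 15 s |

Rationale for the defaults: a 3:1 dark/light activity ratio, ~2.5–3 g
daily intake in ~15–17 meals of ~7 × 20 mg pellets, chance-level initial
port accuracy rising toward ~85–90 % within a night, and retrieval times
dropping from tens of seconds to a few seconds over the same exposure are
the magnitudes home-cage studies report for C57BL/6 mice. A
`poke_interval_s` override replaces the Poisson process with exactly
periodic pokes for hand-checkable fixtures.

What the generator does *not* emulate: satiety feedback from earned
pellets (poke rate does not fall as pellets accumulate), pellet hoarding,
the ~3 h post-dark-onset peak in poking, inter-individual variability
beyond the seed, and any interaction between feeding bouts and operant
poking. Consequently, passing tests show the *analyses* are correct and
the state machines faithful; they do not validate the mouse model against
real behavior beyond these qualitative patterns.

## Analysis definitions and numerical choices

- **Meal segmentation**: single-linkage chaining with inclusive gap
  threshold (`gap ≤ 60 s` joins; "within one minute" is read as a
  pairwise relation between consecutive pellets, not a fixed window from
  the meal start). Clusters under `min_pellets` (default 5) are *strays*,
  kept in every denominator. A meal's phase is the phase of its first
  pellet; meals are never split at light transitions, and within
  `meal_summary` each pellet inherits its cluster's phase so percentages
  stay in [0, 100]. The minimum-size criterion is applied identically in
  both phases.
- **IPI histogram**: 25 logarithmically spaced bins over 1 s–10 h by
  default (configurable); out-of-range intervals are clipped into the
  edge bins so counts always sum to the interval count; each interval is
  attributed to the phase of its leading pellet.
- **Chronograms**: events are counted into half-open time-of-day bins
  keyed by wall-clock hour (`clock`) or hours after lights-on (`phase`),
  using only complete 24-h spans counted from the recording start (a
  partial trailing day would otherwise bias bins sampled one extra time).
  Per log: counts / complete days; group: mean ± SEM across logs (SEM 0
  for a single log). `pokes_per_pellet` bins use per-bin poke sum /
  pellet sum and are missing (NaN, never 0) where no pellets fell.
  The day × bin count matrix behind heatmaps is exposed directly
  (`daily_bin_matrix`); group averaging is per-subject means then group
  mean, so each animal weighs equally regardless of days recorded.
- **Day/night totals**: per-phase counts over complete days divided by
  the number of days; dark + light equals the overall per-day mean.
- **Learning curves**: default 4-h session bins (configurable); windows
  without pokes (or pellets) report missing values, and retrieval-time
  bins report both mean and median since the delay distribution is
  heavy-tailed.
- **Breakpoint replay**: a pellet's completed ratio equals the number of
  operant active pokes since the previous pellet event (pokes during
  well occupancy are flagged and never count). For closed-economy logs, a
  gap ≥ `reset_timeout` between consecutive pokes that ends on an operant
  poke closes the bout. Because the simulator applies the same rule on
  the same quantized timestamps, replay reproduces the generator's
  internal ratio trace exactly — the strongest available check that both
  sides implement the same machine. A bout's breakpoint is its highest
  *completed* ratio (an attempted-but-unfinished requirement does not
  count); the session breakpoint is the max over bouts, 0 with no pellet.

## Test and acceptance-study sizes

The suite favors property tests against independent oracles: meal
segmentation is compared with an O(n²) connected-components oracle on a
thousand random pellet-time sets (n ≤ 200) including exact-60 s gaps;
closed-economy replay is checked against the simulator trace on 100
seeded day-long sessions; parameter recovery uses 7 mice × 4 days;
learning-curve monotonicity averages 50 seeded 16-h sessions. These sizes
give comfortable Monte-Carlo margins (e.g. the 3:1 day/night recovery has
a standard error around 0.04 at this size) while the whole suite runs in
seconds. `scripts/acceptance.py` uses the same study designs and prints
group-level summaries; all of its randomness derives from `--seed`.

## Known limitations

- Only the canonical CSV dialect is parsed; historical firmware variants
  are out of scope.
- Retrieval in free-feeding modes equals time-since-availability, which
  conflates "pellet waiting" with "mouse approaching"; in operant modes
  it is a genuine dispense-to-removal latency.
- The closed-economy demand analysis is descriptive (pokes per pellet,
  breakpoints); no economic demand curve is fitted.
- Group inferential statistics (ANOVA, mixed models, normality tests) are
  left to general-purpose statistics packages; `fedkit` produces the tidy
  per-subject tables they consume.
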