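# Methods

## The model

`orwait` models the flow of non-elective surgical patients through a
suite of operating rooms (ORs).  A patient "arrives" at the minute the
decision to operate is made.  Arrivals in each of five urgency classes —
EMERGENT (must reach an OR within 2 h), URGENT1 (0–4–6 h), URGENT2
(8–12 h), URGENT3 (24 h) and ADDON (add-on elective, can wait days) —
form independent homogeneous Poisson processes with per-class rates
λ_c in patients/minute.  Surgical duration is log-normal per class,
parameterised by the mean and SD of log-minutes (`meanlog`, `sdlog`);
the log-normal captures the right skew characteristic of procedure
times.  A case blocks a room for one contiguous occupancy block of

    duration + setup_cleanup (default 60 min) + duration_delta

minutes; the split of set-up before versus clean-up after surgery is not
modelled, and a patient's wait ends the minute a room is allocated.

Capacity follows a two-shift schedule: `day_or_count` rooms during
0600–2200 and `night_or_count` during 2200–0600.  In restricted
scenarios only a subset of classes (always including EMERGENT) may
*start* a case at night; running cases always continue across shift
changes, and the staffed-room cap applies to starts, never to cases
already underway.

### Queue discipline

Conceptually the engine steps through every minute: release rooms whose
occupancy ends, draw Poisson arrival counts per class, then while a
staffed room is free start the highest-priority eligible waiting
patient, FIFO within a class (non-preemptive: an emergency never bumps a
running case).  The implementation pre-draws arrivals and durations and
advances event-to-event (arrival minutes, releases, shift boundaries),
which is exactly equivalent because the queue state can change only at
those minutes; a five-year run takes well under a second.

### Numerical choices

- **Duration rounding.**  Continuous log-normal draws are rounded to the
  nearest whole minute, floored at 1.  Nearest rounding keeps the mean
  occupancy — and hence the long-run utilization — equal to the
  continuous expectation, which is what the published utilization values
  pin down; ceiling would bias utilization up by ~0.15 points.
- **Same-minute ordering.**  Within a minute: releases, then arrivals,
  then assignments.  Among same-class same-minute arrivals the draw
  order is preserved (stable queue).
- **Shift boundaries.**  Eligibility and caps are evaluated at the start
  minute only; a night-ineligible patient waiting at 05:59 starts at
  06:00.  The simulation clock starts at midnight; the day window is the
  half-open interval [360, 1320) minutes-of-day.
- **Burn-in.**  Patients arriving during the first two months (87,600
  min) of the default five-year horizon warm the system and occupy
  rooms but are excluded from all wait statistics.
- **Seeding.**  One root seed per run; replicate i uses
  `base_seed + i`.  Identical scenario + seed is bit-identical.  The
  duration sampler is injectable, which the tests use to swap in
  exponential service for the closed-form oracle.
- **Unstable scenarios** (offered load ≥ capacity, e.g. 1–2 rooms at the
  default caseload) complete normally; patients still waiting at the
  horizon are reported as pending, never dropped.

## Statistics

Per run and class we report the mean, SD, median, 95th percentile and
maximum of post-burn-in waits, plus utilization = busy room-minutes /
staffed room-minutes.  The 95th percentile is nearest-rank
(the ⌈0.95·n⌉-th order statistic), so it is always an observed value;
printed wait tables are whole minutes and no interpolation rule is
implied by them.  Replicate runs are aggregated as mean ± SD across
runs.  Bootstrap uncertainties of the median and 95th percentile use
100 resamples with replacement of the full wait sample.

Annual waiting hours normalise total post-burn-in wait minutes to a
525,600-minute year.  Scenario differences (e.g. the value of a third
night room) are computed with common random numbers — the same base
seed for both scenarios — a standard variance-reduction choice for
paired comparisons.  The marginal-cost helper prorates the annual cost
of a 24/7-staffed room by the added staffed hours per day and divides by
the waiting-hours saved.

## The analytic comparator

The closed-form model treats the suite as an M/M/s queue with
non-preemptive priorities (Cobham).  With pooled mean service S and
total rate λ, offered load a = λS and ρ = a/s, the Erlang-C delay
probability P_W (computed via the stable Erlang-B recurrence, no
factorials) gives Wq = P_W/(s/S − λ), split across classes by

    B_0 = 1,  B_k = 1 − S·Σ_{i≤k} λ_i / s,
    Wq_k = (1 − ρ)·Wq / (B_{k−1}·B_k).

The rate-weighted average of Wq_k telescopes back to Wq exactly, which
the tests assert to machine precision.  Because the solver is limited to
four priority classes, the URGENT3 and ADDON rates are pooled.  S can be
pooled from the raw mean duration (244.76 min including set-up at the
default table) or from the back-transformed rate-weighted mean of
log-durations (≈210 min), which discounts the right tail and tracks the
simulation more closely.

## Synthetic case logs

`generate_fixture_log` emulates one observation window of an
institution's administrative data: Poisson arrivals and log-normal
durations per class at the default parameter table (≈4,800 records per
simulated year), timestamps at minute resolution.  It reproduces the
statistical structure the estimator relies on (counts and log-duration
moments) but none of the features real case logs carry — calendar and
time-of-day effects, surgeon/service mix, data-entry errors — so a
passing round-trip shows the estimator is consistent, not that real
logs are this clean.  Parameter estimation divides class counts by the
window length and takes the mean and sample (n−1) SD of log-durations;
recovery is tested at one simulated year within three standard errors.

## Problem sizes used in the test suite

Acceptance-style checks run the published study design: five-year
horizons, two-month burn-in, six replicates for the three-room scenario
and four elsewhere.  Unit and property tests use one-year or shorter
horizons, which are ample for the invariants they check (discipline,
conservation, monotonicity, oracle agreement).

## Known limitations

- Homogeneous arrivals: no weekday/weekend or seasonal structure.
- No preemption, no holding-area or transport modelling, no per-surgeon
  stratification.
- The published restricted-night variant this package mirrors left its
  morning backlog-clearing order unstated; this engine clears strictly
  by priority (FIFO within class), which reproduces the uniform-capacity
  tables exactly and the restricted-night tables to within a few
  percent of total waiting, with the residual concentrated in how the
  wait is distributed between the URGENT2 and URGENT3/ADDON classes.
- The analytic comparator assumes exponential service; it is a sanity
  check on means, not a substitute for the simulation's percentiles.
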