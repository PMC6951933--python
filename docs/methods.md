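# Methods

## Scope and structure

`herdsim` implements a stochastic Monte-Carlo model of an individual dairy
cow's life events from birth to culling, advanced daily, together with a
linear-programming least-cost ration formulator. Herd-level behaviour
emerges from simulating each animal separately; there are no herd-level
transition matrices. Soil, crop, feed-storage, manure, water and economic
components of a whole-farm system are deliberately out of scope, as are
mechanistic (rumen-model) milk prediction, genetic merit, heat stress and
pen grouping; the module boundaries leave hooks for them.

## The life-cycle model

**Notation.** `N(μ, s)` is a normal distribution with mean μ and standard
deviation `s` (not variance). Continuous draws that represent day counts
are rounded to the nearest whole day with a floor of 1.

**Growth.** `W(a) = min(W0 + ADG·a, Wmax)` with defaults `W0 = 40.8` kg,
`ADG = 0.9` kg/d, `Wmax = 680` kg (non-normative cap; growth is otherwise
unbounded). Weight is deterministic given age.

**Sex and entry.** Calf sex is Bernoulli in the semen type's female
probability (sexed: 0.90; conventional: 0.49, non-normative). Males are
sold on their birth day and never enter the herd.

**Puberty.** The first-ovulation delay clock starts at 400 d. The delay is
lognormal with *arithmetic* mean 19 d and SD 11 d; the underlying normal
parameters are moment-matched, `σ² = ln(1 + (s/m)²)`,
`μ = ln m − σ²/2`. The lognormal could alternatively be read with (19, 11)
on the log scale, but that yields absurd delays (e μ ≈ 1.8 × 10⁸ d); the
arithmetic-moment reading is the only biologically plausible one and is
pinned by a closed-form oracle test.

**Cycling and breeding.** Cycle lengths are `N(21, 4)`, resampled until
positive. Heat can be detected only on the single ovulation day of each
cycle, with probability 0.60; an undetected ovulation starts a fresh
full-length cycle the next day. A detected heat triggers insemination.
Conception at service `s` (1-based, counted since the last calving)
succeeds with `max(floor, 0.339 − 0.026(s − 1))` — an *absolute*
percentage-point decrement per service, floor 0 by default.

**Pregnancy.** Conception day is gestation day 0. Scheduled diagnoses fall
on gestation days 32, 91 and 200. The daily loss hazard is 0.0096 on the
half-open window (32, 91] and 0.0017 on (91, 200], zero elsewhere: losses
before day 32 are considered absorbed in the conception rate, and none
occur after the last diagnosis. A loss is *latent* until the next
scheduled diagnosis — the cow is managed as pregnant (exempt from
reproductive culling, not re-bred) until the diagnosis reveals she is
open, at which point she restarts cycling with a fresh cycle. Gestation
length is `N(278, 6)`, resampled until it exceeds the last diagnosis day.
At term the cow calves: parity increments, services reset, lactation
starts at DIM 0, a newborn calf is generated, and cycling resumes (first
postpartum ovulation one full cycle after calving; no explicit voluntary
waiting period, which the protocol leaves unspecified).

**Lactation.** Daily milk is Wood's `y(t) = a·t^b·e^(−ct)` or MilkBot
`M(t) = a·(1 − e^((c−t)/b)/2)·e^(−dt)` at `t = DIM ≥ 1`, with parameters
keyed by (breed, parity class 1 / 2 / 3+). The shipped Wood coefficients
are non-normative placeholders of realistic magnitude (peak ~28–35 kg/d
around DIM 75–90 for mature Holsteins); both functional forms are pinned
by independent closed-form oracle tests. Pregnant cows dry off when
remaining gestation reaches the dry-period length (60 d, non-normative).

**Culling.** Two mechanisms compose, earliest trigger first:

1. *Rule-based reproductive failure*: an open heifer on the day her age
   reaches 650 d; an open cow on the first day DIM exceeds 300 (DIM 301).
   A latent-loss cow counts as pregnant until revealed.
2. *Stochastic lifetime fates*: at creation each female is screened for
   the six reasons in a fixed, configurable order (the dict order of
   `culling_reason_probs`); the first reason whose `U(0,1)` draw falls
   below its probability is assigned, making marginal probabilities exact
   for the first reason and approximately nested thereafter. The cull age
   is the generalized inverse (smallest support age with cumulative
   probability ≥ u) of an empirical step CDF. A scheduled age already in
   the past (mid-life entries) fires immediately.

CULLED and EXIT are emitted together on the cull day; an exited animal
receives no further events.

**Update order.** Within a day, animals are processed in ascending id;
each passes through age/weight → reproduction → calving/calf generation →
lactation/dry-off → culling. The order is a reproducibility convention —
the underlying biology does not constrain it.

**Random numbers.** Every animal owns a `PCG64` generator seeded with
`SeedSequence([root_seed, replicate, animal_id])`. Consequences: logs are
bit-reproducible given (seed, config, days); replicates are independent;
and adding animals to a run never changes existing animals' trajectories.

## Ration formulation

The LP is `min Σ c_f x_f` over daily dry-matter amounts subject to
`Σ comp_{f,n} x_f ≥ min_n` (and `≤ max_n` where bounded) per nutrient, a
DMI window on `Σ x_f`, per-feed inclusion bounds, and per-feed
availability rows. Availability is encoded as a constraint row rather
than a variable bound so that `min_inclusion > available` surfaces as an
infeasible LP rather than a solver error. Requirements are assembled as
`req_n = maint_n · BW + milk_n · yield` from a user-supplied coefficient
table; no normative feeding-system coefficients ship with the package, as
those belong to external requirement systems. Degenerate optima are left
to the solver; tests assert the optimal cost (unique) rather than the
diet vector, and validate it against brute-force vertex enumeration on
problems with ≤ 3 feeds.

## Synthetic defaults and what tests show

The default configuration is the worked Holstein example; fields the
example does not pin down ship as labelled non-normative placeholders:
culling-reason probabilities (0.02–0.07 each, ~0.25 lifetime total),
a 9-step culling-age CDF over 2–10 years, Wood parameters by parity, the
60-d dry period, the 680-kg weight cap, and the 180-d calf/heifer stage
boundary used only in census summaries. The synthetic culling CDF and toy
feed-library generators produce deterministic fixtures from (spec, seed);
the feed library is feasible by construction (one complete feed).

Because these placeholders are not estimates of any real herd, passing
tests demonstrate *internal correctness* — parameter recovery, exact
thresholds, conservation, determinism — not calibration to field data.
Real-herd predictions additionally require empirical lactation
parameters, culling CDFs and reason probabilities, seasonal effects and
management covariates, none of which the simulator claims.

## Numerical and testing choices

- Day counts from continuous draws: nearest integer, minimum 1. The
  truncated-normal cycle sampler resamples rather than clips, so the mean
  is preserved to well under the test tolerances at the default CV.
- Statistical tests use fixed seeds and 2-standard-error tolerances, each
  quantity on its own `SeedSequence` substream so the checks are
  independent. Monte-Carlo sizes (20k–100k trials per quantity, herd runs
  of 40–80 animal-decades) were chosen so every check resolves its target
  to well under 1% while the whole suite runs in seconds.
- The pregnancy-loss recovery uses a vectorized simulator that shares the
  scalar hazard function with the daily engine; losses per
  pregnant-animal-day at risk (the loss day counting as at risk) is the
  censored-geometric maximum-likelihood estimator of the daily rate.
- The LP oracle enumerates all hyperplane intersections (constraints plus
  bounds, with a large finite box for unbounded directions) and takes the
  feasible minimum; it shares no code with the solver path.

## Known limitations

- Heat detection is a single daily Bernoulli per cycle; multi-day
  standing estrus and detection-technology effects are not modelled.
- No re-breeding during an unrevealed pregnancy loss, and no voluntary
  waiting period after calving beyond the natural cycle delay.
- The heifer reproductive cull fires for any open heifer at ≥ 650 d,
  including the rare heifer who conceived earlier and lost; the
  alternative (exempting ever-pregnant heifers forever) would let such
  animals cycle indefinitely.
- One culling-age CDF is shared across the six reasons; per-reason CDFs
  would need a config extension.
- Milk composition, energy balance, intake-driven production and economic
  accounting are out of scope.
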