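"""Estrus-detection / AI reproductive state machine.

Puberty: the first-ovulation clock starts at ``puberty_base_age`` (400 d);
the delay to first ovulation is lognormal with arithmetic mean 19 d and SD
11 d, moment-matched onto the underlying normal.  Cycling females ovulate
every ``cycle_length`` days (N(21, 4), truncated positive); heat is
detected on the single ovulation day of each cycle with probability 0.60.
A detected heat triggers insemination; conception succeeds with
0.339 - 0.026 * (service - 1), clipped at the floor.  Pregnancy is checked
on gestation days 32, 91 and 200; between checks a latent loss occurs with
daily hazard 0.0096 then 0.0017 and is revealed only at the next scheduled
diagnosis, when the cow resumes cycling.  Gestation length is N(278, 6),
resampled above the last diagnosis day.  Open heifers are flagged for
culling at 650 d of age, open cows past 300 days in milk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .domain import (
    EV_CALVING,
    EV_DIAGNOSIS_OPEN,
    EV_DIAGNOSIS_PREGNANT,
    EV_INSEMINATION,
    EV_PREGNANCY_LOSS,
    REPRODUCTIVE_FAILURE,
    AnimalState,
    EventRecord,
    ReproState,
    SimulationConfig,
)


@dataclass
class ReproOutcome:
    """Result of one reproductive update: the (mutated) state plus emitted events."""

    state: AnimalState
    events: list[EventRecord] = field(default_factory=list)


def _round_day(x: float) -> int:
    """Round a continuous day count to the nearest whole day, at least 1."""
    return max(1, round(x))


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match (arithmetic mean, arithmetic sd) to (mu, sigma) of ln X.

    mu = ln(m^2 / sqrt(m^2 + s^2)),  sigma^2 = ln(1 + s^2 / m^2).
    """
    if mean <= 0:
        raise ValueError(f"lognormal mean must be > 0, got {mean}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_first_ovulation_age(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    """Age (d) at first ovulation: puberty base age plus a lognormal delay."""
    m, s = cfg.first_ovulation_delay_mean, cfg.first_ovulation_delay_sd
    if s == 0:
        delay = m
    else:
        mu, sigma = lognormal_params(m, s)
        delay = rng.lognormal(mu, sigma)
    return cfg.puberty_base_age + _round_day(delay)


def sample_cycle_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    """Estrus cycle length in whole days, normal truncated to positive values."""
    if cfg.cycle_length_sd == 0:
        return _round_day(cfg.cycle_length_mean)
    while True:
        x = rng.normal(cfg.cycle_length_mean, cfg.cycle_length_sd)
        if x > 0:
            return _round_day(x)


def heat_detected(cfg: SimulationConfig, rng: np.random.Generator) -> bool:
    """Whether estrus is detected on an ovulation day."""
    return rng.random() < cfg.heat_detection_prob


def conception_probability(service_number: int, cfg: SimulationConfig) -> float:
    """Conception probability at the given service (1-based), linearly decreasing."""
    if service_number < 1:
        raise ValueError(f"service_number must be >= 1, got {service_number}")
    p = cfg.conception_first_service - (service_number - 1) * cfg.conception_decrement_per_service
    return max(cfg.conception_floor, p)


def sample_gestation_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    """Gestation length in whole days, resampled until past the last diagnosis."""
    limit = max(cfg.diagnosis_days) if cfg.diagnosis_days else 0
    if cfg.gestation_sd == 0:
        g = _round_day(cfg.gestation_mean)
        if g <= limit:
            raise ValueError("degenerate gestation length does not exceed the last diagnosis day")
        return g
    while True:
        g = _round_day(rng.normal(cfg.gestation_mean, cfg.gestation_sd))
        if g > limit:
            return g


def start_new_cycle(state: AnimalState, cfg: SimulationConfig, rng: np.random.Generator) -> None:
    """Put the female at day 0 of a fresh full-length estrus cycle."""
    state.repro_state = ReproState.CYCLING
    state.day_in_cycle = 0
    state.cycle_length = sample_cycle_length(cfg, rng)


def attempt_insemination(
    state: AnimalState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sim_day: int = 0,
) -> ReproOutcome:
    """Inseminate a cycling female whose heat was detected today.

    Increments the service count; with probability
    ``conception_probability(services)`` the female becomes pregnant with a
    freshly drawn gestation length, otherwise she re-enters a new estrus
    cycle starting tomorrow.
    """
    if state.repro_state is ReproState.PREGNANT:
        raise ValueError(f"animal {state.animal_id} is already pregnant")
    state.services += 1
    events = [
        EventRecord(sim_day, state.animal_id, EV_INSEMINATION, {"service": state.services})
    ]
    if rng.random() < conception_probability(state.services, cfg):
        state.repro_state = ReproState.PREGNANT
        state.days_pregnant = 0
        state.latent_loss = False
        state.ever_conceived = True
        state.gestation_length_drawn = sample_gestation_length(cfg, rng)
    else:
        start_new_cycle(state, cfg, rng)
    return ReproOutcome(state, events)


def pregnancy_loss_hazard(days_pregnant: int, cfg: SimulationConfig) -> float:
    """Daily pregnancy-loss probability at the given gestation day.

    Nonzero only on the half-open windows between consecutive diagnosis
    days: (32, 91] at 0.0096/d and (91, 200] at 0.0017/d with defaults.
    Losses before the first diagnosis are absorbed into the conception
    rate; none occur after the last diagnosis.
    """
    for lo, hi, rate in zip(cfg.diagnosis_days, cfg.diagnosis_days[1:], cfg.daily_loss_rates):
        if lo < days_pregnant <= hi:
            return rate
    return 0.0


def daily_pregnancy_update(
    state: AnimalState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sim_day: int = 0,
) -> ReproOutcome:
    """Advance a pregnant female one day.

    Applies the latent-loss hazard, reveals any loss at the next scheduled
    diagnosis (DIAGNOSIS_OPEN, then a fresh cycle), confirms otherwise
    (DIAGNOSIS_PREGNANT), and calves when gestation completes: parity and
    lactation counters update, services reset, and cycling resumes.
    """
    if state.repro_state is not ReproState.PREGNANT:
        raise ValueError(f"animal {state.animal_id} is not pregnant")
    state.days_pregnant += 1
    d = state.days_pregnant
    events: list[EventRecord] = []

    if not state.latent_loss:
        h = pregnancy_loss_hazard(d, cfg)
        if h > 0 and rng.random() < h:
            state.latent_loss = True
            events.append(
                EventRecord(sim_day, state.animal_id, EV_PREGNANCY_LOSS, {"days_pregnant": d})
            )

    if d in cfg.diagnosis_days:
        idx = cfg.diagnosis_days.index(d)
        if state.latent_loss:
            events.append(
                EventRecord(
                    sim_day, state.animal_id, EV_DIAGNOSIS_OPEN, {"diagnosis": idx, "day": d}
                )
            )
            state.latent_loss = False
            state.days_pregnant = 0
            state.gestation_length_drawn = 0
            start_new_cycle(state, cfg, rng)
        else:
            events.append(
                EventRecord(
                    sim_day, state.animal_id, EV_DIAGNOSIS_PREGNANT, {"diagnosis": idx, "day": d}
                )
            )
    elif d == state.gestation_length_drawn and not state.latent_loss:
        state.parity += 1
        state.services = 0
        state.days_pregnant = 0
        state.gestation_length_drawn = 0
        state.dim = 0
        state.lactating = True
        state.dried_off = False
        state.calved_today = True
        events.append(
            EventRecord(sim_day, state.animal_id, EV_CALVING, {"parity": state.parity})
        )
        start_new_cycle(state, cfg, rng)
    return ReproOutcome(state, events)


def check_reproductive_cull(state: AnimalState, cfg: SimulationConfig) -> str | None:
    """Reproductive-failure cull signal, or None.

    Fires for an open heifer on the day her age reaches ``heifer_cull_age``
    (650 d) and for an open cow on the first day her days in milk exceed
    ``cow_cull_dim`` (i.e. DIM 301 with the default 300).  A female with an
    unrevealed pregnancy loss is managed as pregnant and is exempt until
    the loss is diagnosed.
    """
    if state.exit is not None or state.repro_state is ReproState.PREGNANT:
        return None
    if state.parity == 0 and state.age >= cfg.heifer_cull_age:
        return REPRODUCTIVE_FAILURE
    if state.parity >= 1 and state.dim > cfg.cow_cull_dim:
        return REPRODUCTIVE_FAILURE
    return None


def estimate_pregnancy_loss_rates(
    cfg: SimulationConfig,
    n_pregnancies: int,
    rng: np.random.Generator,
    batch: int = 20_000,
) -> dict[str, list[float]]:
    """Monte-Carlo recovery of the per-window daily loss rates.

    Simulates ``n_pregnancies`` pregnancies through the at-risk gestation
    days using exactly :func:`pregnancy_loss_hazard`, then estimates each
    window's daily rate as losses per pregnant-animal-day at risk (an
    animal's loss day counts as at risk).

    Returns a dict with per-window ``losses``, ``at_risk_days`` and
    ``rates`` lists, ordered as ``cfg.daily_loss_rates``.
    """
    if n_pregnancies < 1:
        raise ValueError("n_pregnancies must be >= 1")
    first, last = cfg.diagnosis_days[0], cfg.diagnosis_days[-1]
    days = np.arange(first + 1, last + 1)
    hazard = np.array([pregnancy_loss_hazard(int(d), cfg) for d in days])

    windows = list(zip(cfg.diagnosis_days, cfg.diagnosis_days[1:]))
    losses = np.zeros(len(windows), dtype=np.int64)
    at_risk = np.zeros(len(windows), dtype=np.int64)

    done = 0
    while done < n_pregnancies:
        n = min(batch, n_pregnancies - done)
        u = rng.random((n, days.size))
        hit = u < hazard  # (n, n_days)
        any_hit = hit.any(axis=1)
        first_idx = np.where(any_hit, hit.argmax(axis=1), days.size)
        loss_day = np.where(any_hit, days[np.minimum(first_idx, days.size - 1)], np.iinfo(np.int64).max)
        for w, (lo, hi) in enumerate(windows):
            entered = loss_day > lo  # survived all days <= lo
            lost_here = entered & (loss_day <= hi)
            losses[w] += int(lost_here.sum())
            risk = np.where(lost_here, loss_day - lo, hi - lo)
            at_risk[w] += int(risk[entered].sum())
        done += n

    rates = [l / r if r else 0.0 for l, r in zip(losses, at_risk)]
    return {
        "losses": losses.tolist(),
        "at_risk_days": at_risk.tolist(),
        "rates": rates,
    }
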