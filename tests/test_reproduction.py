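"""Reproductive state machine: samplers, conception, pregnancy and culling flags."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdsim import (
    AnimalState,
    ReproState,
    Sex,
    attempt_insemination,
    check_reproductive_cull,
    conception_probability,
    daily_pregnancy_update,
    estimate_pregnancy_loss_rates,
    heat_detected,
    pregnancy_loss_hazard,
    sample_cycle_length,
    sample_first_ovulation_age,
    sample_gestation_length,
)
from herdsim.reproduction import lognormal_params


def _female(**kw) -> AnimalState:
    base = dict(animal_id=1, sex=Sex.FEMALE, breed="Holstein")
    base.update(kw)
    return AnimalState(**base)


# --------------------------------------------------------------------------
# Samplers
# --------------------------------------------------------------------------

def test_first_ovulation_degenerate_delay_is_419(cfg, rng):
    assert sample_first_ovulation_age(cfg.copy(first_ovulation_delay_sd=0.0), rng) == 419


def test_first_ovulation_moment_matched_mean(cfg, rng):
    # closed-form oracle: arithmetic mean of the delay is 19 d, so ages average 419
    draws = np.array([sample_first_ovulation_age(cfg, rng) for _ in range(100_000)])
    se = 11.0 / math.sqrt(draws.size)
    assert abs(draws.mean() - 419.0) < max(2 * se, 0.2 + 2 * se)
    assert draws.min() >= 401


def test_lognormal_moment_matching_closed_form():
    mu, sigma = lognormal_params(19.0, 11.0)
    assert mu == pytest.approx(math.log(19.0**2 / math.sqrt(19.0**2 + 11.0**2)))
    assert sigma**2 == pytest.approx(math.log(1 + 11.0**2 / 19.0**2))
    # reconstructed arithmetic moments
    assert math.exp(mu + sigma**2 / 2) == pytest.approx(19.0)
    var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
    assert math.sqrt(var) == pytest.approx(11.0)


def test_cycle_length_degenerate_and_mean(cfg, rng):
    assert sample_cycle_length(cfg.copy(cycle_length_sd=0.0), rng) == 21
    draws = np.array([sample_cycle_length(cfg, rng) for _ in range(100_000)])
    se = 4.0 / math.sqrt(draws.size)
    assert abs(draws.mean() - 21.0) < max(2 * se, 0.05)
    assert draws.min() >= 1


def test_cycle_length_truncation_keeps_draws_positive(cfg, rng):
    wild = cfg.copy(cycle_length_mean=2.0, cycle_length_sd=10.0)
    assert min(sample_cycle_length(wild, rng) for _ in range(2_000)) >= 1


def test_gestation_degenerate_mean_and_floor(cfg, rng):
    assert sample_gestation_length(cfg.copy(gestation_sd=0.0), rng) == 278
    draws = np.array([sample_gestation_length(cfg, rng) for _ in range(100_000)])
    se = 6.0 / math.sqrt(draws.size)
    assert abs(draws.mean() - 278.0) < max(2 * se, 0.1)
    assert draws.min() > 200  # resampled past the last diagnosis day


def test_heat_detection_extremes_and_frequency(cfg, rng):
    assert all(heat_detected(cfg.copy(heat_detection_prob=1.0), rng) for _ in range(100))
    assert not any(heat_detected(cfg.copy(heat_detection_prob=0.0), rng) for _ in range(100))
    n = 100_000
    freq = sum(heat_detected(cfg, rng) for _ in range(n)) / n
    assert abs(freq - 0.60) < 2 * math.sqrt(0.6 * 0.4 / n)


# --------------------------------------------------------------------------
# Conception
# --------------------------------------------------------------------------

@pytest.mark.parametrize("service, expected", [(1, 0.339), (2, 0.313), (3, 0.287), (100, 0.0)])
def test_conception_probability_decrement(cfg, service, expected):
    assert conception_probability(service, cfg) == pytest.approx(expected)


def test_conception_probability_rejects_bad_service(cfg):
    with pytest.raises(ValueError):
        conception_probability(0, cfg)


@given(service=st.integers(min_value=1, max_value=500))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_conception_probability_nonincreasing_and_bounded(service):
    from herdsim import default_config

    cfg = default_config()
    p = conception_probability(service, cfg)
    assert cfg.conception_floor <= p <= cfg.conception_first_service
    assert p >= conception_probability(service + 1, cfg)


def test_insemination_forced_outcomes(cfg, rng):
    sure = cfg.copy(conception_first_service=1.0, conception_decrement_per_service=0.0)
    s = _female(repro_state=ReproState.CYCLING)
    attempt_insemination(s, sure, rng)
    assert s.repro_state is ReproState.PREGNANT and s.days_pregnant == 0
    assert s.gestation_length_drawn > max(cfg.diagnosis_days)

    never = cfg.copy(conception_first_service=0.0)
    s = _female(repro_state=ReproState.CYCLING)
    attempt_insemination(s, never, rng)
    assert s.repro_state is ReproState.CYCLING and s.services == 1


def test_insemination_rejects_pregnant_animal(cfg, rng):
    s = _female(repro_state=ReproState.PREGNANT)
    with pytest.raises(ValueError):
        attempt_insemination(s, cfg, rng)


def test_first_service_conception_frequency(cfg, rng):
    n = 50_000
    conceived = 0
    for _ in range(n):
        s = _female(repro_state=ReproState.CYCLING)
        attempt_insemination(s, cfg, rng)
        conceived += s.repro_state is ReproState.PREGNANT
    se = math.sqrt(0.339 * 0.661 / n)
    assert abs(conceived / n - 0.339) < max(2 * se, 0.006)


# --------------------------------------------------------------------------
# Pregnancy: hazard windows, diagnosis, loss recovery
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "day, rate",
    [(1, 0.0), (32, 0.0), (33, 0.0096), (91, 0.0096), (92, 0.0017), (200, 0.0017), (201, 0.0), (278, 0.0)],
)
def test_loss_hazard_half_open_windows(cfg, day, rate):
    assert pregnancy_loss_hazard(day, cfg) == rate


def _pregnant(cfg, gestation=278):
    return _female(
        repro_state=ReproState.PREGNANT,
        days_pregnant=0,
        gestation_length_drawn=gestation,
        ever_conceived=True,
    )


def test_first_diagnosis_is_32_days_after_insemination(cfg, rng):
    safe = cfg.copy(daily_loss_rates=(0.0, 0.0))
    s = _pregnant(safe)
    diagnosis_days = []
    for _ in range(278):
        out = daily_pregnancy_update(s, safe, rng)
        diagnosis_days += [e.payload["day"] for e in out.events if "DIAGNOSIS" in e.event]
    assert diagnosis_days == [32, 91, 200]
    assert s.parity == 1 and s.lactating and s.dim == 0  # calved on schedule


def test_zero_loss_rates_always_calve(cfg, rng):
    safe = cfg.copy(daily_loss_rates=(0.0, 0.0))
    for _ in range(20):
        s = _pregnant(safe, gestation=270)
        for _ in range(270):
            daily_pregnancy_update(s, safe, rng)
        assert s.parity == 1


def test_loss_revealed_only_at_next_diagnosis(cfg, rng):
    certain = cfg.copy(daily_loss_rates=(1.0, 0.0))
    s = _pregnant(certain)
    events = []
    for _ in range(91):
        events += daily_pregnancy_update(s, certain, rng).events
    codes = [e.event for e in events]
    assert codes.count("PREGNANCY_LOSS") == 1
    loss_day = next(e.payload["days_pregnant"] for e in events if e.event == "PREGNANCY_LOSS")
    assert loss_day == 33  # first at-risk day with certain hazard
    # remained managed as pregnant until day 91 reveal
    assert codes[-1] == "DIAGNOSIS_OPEN"
    assert s.repro_state is ReproState.CYCLING and s.day_in_cycle == 0


def test_window_survival_matches_geometric_oracle(cfg, rng):
    # closed form: P(no loss on days 33..91) = (1 - 0.0096)^59
    expected = (1 - 0.0096) ** 59
    n = 20_000
    survived = 0
    for _ in range(n):
        s = _pregnant(cfg)
        for _ in range(91):
            daily_pregnancy_update(s, cfg, rng)
        survived += s.repro_state is ReproState.PREGNANT and not s.latent_loss
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(survived / n - expected) < 2.5 * se


def test_loss_rate_recovery_both_windows(cfg, rng):
    est = estimate_pregnancy_loss_rates(cfg, 100_000, rng)
    for rate_hat, rate_true, at_risk in zip(est["rates"], cfg.daily_loss_rates, est["at_risk_days"]):
        se = math.sqrt(rate_true * (1 - rate_true) / at_risk)
        assert abs(rate_hat - rate_true) < 2 * se


# --------------------------------------------------------------------------
# Reproductive-failure culling
# --------------------------------------------------------------------------

def test_open_heifer_culled_at_650(cfg):
    assert check_reproductive_cull(_female(age=649), cfg) is None
    assert check_reproductive_cull(_female(age=650), cfg) == "reproductive_failure"


def test_cow_culled_past_300_dim(cfg):
    cow = _female(parity=1, lactating=True, repro_state=ReproState.CYCLING)
    cow.dim = 300
    assert check_reproductive_cull(cow, cfg) is None
    cow.dim = 301
    assert check_reproductive_cull(cow, cfg) == "reproductive_failure"


def test_pregnancy_exempts_from_reproductive_cull(cfg):
    cow = _female(parity=1, dim=400, repro_state=ReproState.PREGNANT)
    assert check_reproductive_cull(cow, cfg) is None
    heifer = _female(age=700, repro_state=ReproState.PREGNANT)
    assert check_reproductive_cull(heifer, cfg) is None
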