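"""Body-weight growth and daily milk yield from lactation curves.

Growth is linear at the breed's average daily gain from birth weight,
plateauing at the mature weight cap.  Milk yield follows either Wood's
gamma-type curve y(t) = a * t**b * exp(-c*t) or the MilkBot model
M(t) = a * (1 - exp((c - t)/b)/2) * exp(-d*t), evaluated at the cow's
days in milk with (breed, parity-class) specific parameters.  Pregnant
cows are dried off ``dry_period_length`` days before expected calving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .domain import (
    EV_DRY_OFF,
    AnimalState,
    ConfigError,
    CurveForm,
    EventRecord,
    LactationCurveParams,
    ReproState,
    SimulationConfig,
)


@dataclass(frozen=True)
class DailyProduction:
    milk_yield: float  # kg/d, 0 when not lactating
    body_weight: float  # kg


def body_weight(age: int, cfg: SimulationConfig) -> float:
    """Body weight (kg) at the given age: birth weight + ADG * age, capped."""
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    w = cfg.birth_weight + cfg.average_daily_gain * age
    if cfg.mature_weight_cap is not None:
        w = min(w, cfg.mature_weight_cap)
    return w


def wood_yield(t_dim: int, params: LactationCurveParams) -> float:
    """Wood's curve a * t**b * exp(-c*t) at days in milk t >= 1."""
    if params.form is not CurveForm.WOOD:
        raise ValueError("params.form must be WOOD")
    if t_dim < 1:
        raise ValueError(f"t_dim must be >= 1, got {t_dim}")
    return max(0.0, params.a * t_dim**params.b * math.exp(-params.c * t_dim))


def milkbot_yield(t_dim: int, params: LactationCurveParams) -> float:
    """MilkBot curve a * (1 - exp((c - t)/b)/2) * exp(-d*t) at t >= 1, clipped at 0."""
    if params.form is not CurveForm.MILKBOT:
        raise ValueError("params.form must be MILKBOT")
    if params.b <= 0:
        raise ValueError(f"MilkBot ramp b must be > 0, got {params.b}")
    if t_dim < 1:
        raise ValueError(f"t_dim must be >= 1, got {t_dim}")
    y = params.a * (1.0 - math.exp((params.c - t_dim) / params.b) / 2.0) * math.exp(-params.d * t_dim)
    return max(0.0, y)


def parity_class(parity: int) -> str:
    """Map a calving count to the lactation parameter class: '1', '2' or '3+'."""
    if parity < 1:
        raise ValueError(f"parity must be >= 1 for a lactating cow, got {parity}")
    return str(parity) if parity <= 2 else "3+"


def curve_params(cfg: SimulationConfig, breed: str, parity: int) -> LactationCurveParams:
    key = (breed, parity_class(parity))
    try:
        return cfg.lactation[key]
    except KeyError:
        raise ConfigError(f"no lactation parameters configured for {key}") from None


def lactation_yield(t_dim: int, params: LactationCurveParams) -> float:
    if params.form is CurveForm.WOOD:
        return wood_yield(t_dim, params)
    return milkbot_yield(t_dim, params)


def daily_production(
    state: AnimalState, cfg: SimulationConfig, sim_day: int = 0
) -> tuple[DailyProduction, list[EventRecord]]:
    """Milk yield and body weight for the current day; emits DRY_OFF when due.

    A pregnant cow is dried off the day her remaining gestation reaches
    ``dry_period_length``; from that day on she yields no milk until the
    next calving.
    """
    events: list[EventRecord] = []
    if (
        state.lactating
        and not state.dried_off
        and state.repro_state is ReproState.PREGNANT
        and state.gestation_length_drawn - state.days_pregnant <= cfg.dry_period_length
    ):
        state.lactating = False
        state.dried_off = True
        events.append(EventRecord(sim_day, state.animal_id, EV_DRY_OFF, {"dim": state.dim}))

    if state.lactating and state.dim >= 1:
        milk = lactation_yield(state.dim, curve_params(cfg, state.breed, state.parity))
    else:
        milk = 0.0
    return DailyProduction(milk_yield=milk, body_weight=state.weight), events
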