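"""Stochastic lifetime culling and inverse-CDF culling-age sampling.

At creation each female is screened once for the six stochastic culling
reasons (lameness, injury, mastitis, other diseases, udder problems,
unknown): reasons are evaluated in a fixed, configurable order and the
first whose probability exceeds a fresh U(0,1) draw is assigned; the age
at which that cull occurs is then sampled by generalized inverse of the
empirical culling-age CDF.  Day to day, the earliest trigger wins between
the scheduled stochastic fate and rule-based reproductive-failure culling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domain import (
    EV_CULLED,
    EV_EXIT,
    AnimalState,
    ConfigError,
    CullingAgeCdf,
    EventRecord,
    SimulationConfig,
)
from .reproduction import check_reproductive_cull


@dataclass(frozen=True)
class CullFate:
    """A lifetime culling assignment: reason plus the scheduled age (d).

    ``scheduled_age`` is None for rule-triggered reproductive failure,
    which has no pre-drawn age.
    """

    reason: str
    scheduled_age: int | None


def sample_cull_age(cdf: CullingAgeCdf, rng: np.random.Generator) -> int:
    """Inverse-transform draw from the empirical culling-age CDF.

    Returns the smallest support age whose cumulative probability is >= a
    fresh U(0,1) draw.
    """
    bad = cdf.violations()
    if bad:
        raise ConfigError("; ".join(bad))
    u = rng.random()
    idx = int(np.searchsorted(np.asarray(cdf.cum), u, side="left"))
    idx = min(idx, len(cdf.ages) - 1)
    return cdf.ages[idx]


def assign_cull_fate(cfg: SimulationConfig, rng: np.random.Generator) -> CullFate | None:
    """Screen a newborn female for each stochastic culling reason once.

    Reasons are evaluated in the order of ``cfg.culling_reason_probs``;
    the first reason whose U(0,1) draw falls below its lifetime
    probability wins and a culling age is sampled for it.  Returns None
    when no reason is assigned.
    """
    for reason, p in cfg.culling_reason_probs.items():
        if rng.random() < p:
            return CullFate(reason=reason, scheduled_age=sample_cull_age(cfg.culling_age_cdf, rng))
    return None


def apply_culling(
    state: AnimalState, cfg: SimulationConfig, sim_day: int = 0
) -> list[EventRecord] | None:
    """Fire the earliest applicable cull today, if any.

    Checks the scheduled stochastic fate first (it fires on the first day
    age reaches the scheduled age, immediately for animals entering older
    than it), then the reproductive-failure rule.  Emits a CULLED + EXIT
    pair on the same day and marks the animal exited.
    """
    if state.exit is not None:
        return None
    reason: str | None = None
    if (
        state.cull_fate is not None
        and state.cull_fate.scheduled_age is not None
        and state.age >= state.cull_fate.scheduled_age
    ):
        reason = state.cull_fate.reason
    if reason is None:
        reason = check_reproductive_cull(state, cfg)
    if reason is None:
        return None
    state.exit = (sim_day, reason)
    return [
        EventRecord(sim_day, state.animal_id, EV_CULLED, {"reason": reason, "age": state.age}),
        EventRecord(sim_day, state.animal_id, EV_EXIT, {"reason": reason, "age": state.age}),
    ]
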