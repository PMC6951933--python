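"""Daily-time-step Monte-Carlo herd driver.

Each simulated day every live animal is advanced through a fixed pipeline
— (1) age and weight, (2) reproduction, (3) calving and calf generation,
(4) lactation and dry-off, (5) culling — in ascending animal-id order.
Every discrete life event is appended to an audit log, and a per-day herd
summary (stage counts, lactating count, milk, entries and exits) is
accumulated.

Reproducibility: every animal owns a private PCG64 stream seeded from
(root seed, replicate, animal id), so adding animals never perturbs the
trajectories of existing ones, and replicate substreams are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .culling import apply_culling, assign_cull_fate
from .domain import (
    CALF_MAX_AGE,
    EV_BIRTH,
    EV_CALVING,
    EV_EXIT,
    EV_FIRST_OVULATION,
    EV_HEAT_DETECTED,
    EV_MALE_SOLD,
    EV_OVULATION,
    AnimalState,
    ConfigError,
    EventRecord,
    LifeStage,
    ReproState,
    Sex,
    SimulationConfig,
    validate_config,
)
from .lactation import body_weight, daily_production
from .reproduction import (
    attempt_insemination,
    daily_pregnancy_update,
    heat_detected,
    sample_cycle_length,
    sample_first_ovulation_age,
    start_new_cycle,
)

EVENT_COLUMNS = ["replicate", "sim_day", "animal_id", "event", "payload"]

SUMMARY_COLUMNS = [
    "replicate",
    "sim_day",
    "n_calves",
    "n_heifers",
    "n_cows",
    "n_lactating",
    "milk_kg",
    "births",
    "entries",
    "exits",
    "herd_size",
]


@dataclass(frozen=True)
class InitialHerdSpec:
    """How the herd is populated at day 0.

    ``n_newborn_females``: newborn female calves present at day 0.
    ``n_fresh_calvers``: first-parity cows that calved on day 0 (entering
    mid-life, e.g. purchased springers); their age is ``fresh_calver_age``.
    ``calf_arrivals``: extra calves generated on later days (day -> count),
    sexed by the configured semen type; a neutral replacement-entry
    mechanism.
    """

    n_newborn_females: int = 0
    n_fresh_calvers: int = 0
    fresh_calver_age: int = 700
    calf_arrivals: dict[int, int] = field(default_factory=dict)

    def violations(self) -> list[str]:
        out = []
        if self.n_newborn_females < 0 or self.n_fresh_calvers < 0:
            out.append("initial herd counts must be >= 0")
        if self.fresh_calver_age <= 0:
            out.append("fresh_calver_age must be > 0")
        for day, n in self.calf_arrivals.items():
            if day < 1 or n < 0:
                out.append(f"calf_arrivals[{day}]: day must be >= 1 and count >= 0")
        return out


@dataclass(frozen=True)
class ReplicateResult:
    replicate: int
    seed: int
    events: pd.DataFrame
    summary: pd.DataFrame


def generate_calf(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sim_day: int,
    animal_id: int = 0,
    force_sex: Sex | None = None,
) -> tuple[AnimalState, list[EventRecord]]:
    """Create a newborn calf and its birth events.

    Sex is drawn from the configured semen type's female probability
    (unless forced).  Male calves are sold: they receive MALE_SOLD + EXIT
    on their birth day and never enter the herd.  Female calves are
    initialized prepubertal at birth weight, with their first-ovulation
    age and stochastic cull fate drawn immediately.
    """
    try:
        p_female = cfg.female_prob_by_semen[cfg.semen_type]
    except KeyError:
        raise ConfigError(f"unknown semen type '{cfg.semen_type}'") from None
    if force_sex is not None:
        sex = force_sex
    else:
        sex = Sex.FEMALE if rng.random() < p_female else Sex.MALE
    state = AnimalState(
        animal_id=animal_id,
        sex=sex,
        breed=cfg.breed_name,
        age=0,
        weight=cfg.birth_weight,
        life_stage=LifeStage.CALF,
        repro_state=ReproState.PREPUBERTAL,
    )
    events = [
        EventRecord(
            sim_day, animal_id, EV_BIRTH, {"sex": sex.value, "weight": cfg.birth_weight}
        )
    ]
    if sex is Sex.MALE:
        state.exit = (sim_day, "male_sold")
        events.append(EventRecord(sim_day, animal_id, EV_MALE_SOLD, {}))
        events.append(EventRecord(sim_day, animal_id, EV_EXIT, {"reason": "male_sold", "age": 0}))
    else:
        state.first_ovulation_age = sample_first_ovulation_age(cfg, rng)
        state.cull_fate = assign_cull_fate(cfg, rng)
    return state, events


class HerdSimulation:
    """Stateful one-replicate simulation; step with :meth:`step_day`."""

    def __init__(
        self,
        cfg: SimulationConfig,
        initial_herd: InitialHerdSpec | None = None,
        seed: int | None = None,
        replicate: int = 0,
    ):
        bad = validate_config(cfg)
        if bad:
            raise ConfigError("; ".join(bad))
        self.cfg = cfg
        self.replicate = replicate
        self.root_seed = cfg.seed if seed is None else seed
        self.initial_herd = initial_herd or InitialHerdSpec()
        bad = self.initial_herd.violations()
        if bad:
            raise ConfigError("; ".join(bad))

        self.sim_day = 0
        self.herd: dict[int, AnimalState] = {}
        self.events: list[EventRecord] = []
        self.summary_rows: list[dict] = []
        self._streams: dict[int, np.random.Generator] = {}
        self._next_id = 1
        self._populate_day0()

    # -- internals ---------------------------------------------------------

    def _new_animal_rng(self, animal_id: int) -> np.random.Generator:
        ss = np.random.SeedSequence([int(self.root_seed), int(self.replicate), int(animal_id)])
        rng = np.random.Generator(np.random.PCG64(ss))
        self._streams[animal_id] = rng
        return rng

    def _spawn_calf(self, sim_day: int, force_sex: Sex | None = None) -> AnimalState:
        aid = self._next_id
        self._next_id += 1
        rng = self._new_animal_rng(aid)
        state, events = generate_calf(self.cfg, rng, sim_day, animal_id=aid, force_sex=force_sex)
        self.events.extend(events)
        if state.alive:
            self.herd[aid] = state
        else:
            del self._streams[aid]
        return state

    def _populate_day0(self) -> None:
        for _ in range(self.initial_herd.n_newborn_females):
            self._spawn_calf(0, force_sex=Sex.FEMALE)
        for _ in range(self.initial_herd.n_fresh_calvers):
            self._spawn_fresh_calver(0)
        self._record_summary(0, milk=0.0, events_today=self.events)

    def _spawn_fresh_calver(self, sim_day: int) -> AnimalState:
        cfg = self.cfg
        aid = self._next_id
        self._next_id += 1
        rng = self._new_animal_rng(aid)
        state = AnimalState(
            animal_id=aid,
            sex=Sex.FEMALE,
            breed=cfg.breed_name,
            age=self.initial_herd.fresh_calver_age,
            weight=body_weight(self.initial_herd.fresh_calver_age, cfg),
            life_stage=LifeStage.COW,
            parity=1,
            dim=0,
            lactating=True,
            ever_conceived=True,
        )
        state.first_ovulation_age = state.age
        start_new_cycle(state, cfg, rng)
        state.cull_fate = assign_cull_fate(cfg, rng)
        self.events.append(
            EventRecord(sim_day, aid, EV_CALVING, {"parity": 1, "entry": "fresh_calver"})
        )
        self.herd[aid] = state
        return state

    def _ovulation_day(self, state: AnimalState, rng: np.random.Generator, sim_day: int) -> None:
        """Heat check and possible AI on an ovulation day."""
        if heat_detected(self.cfg, rng):
            self.events.append(EventRecord(sim_day, state.animal_id, EV_HEAT_DETECTED, {}))
            out = attempt_insemination(state, self.cfg, rng, sim_day=sim_day)
            self.events.extend(out.events)
        else:
            start_new_cycle(state, self.cfg, rng)

    def _record_summary(self, sim_day: int, milk: float, events_today: list[EventRecord]) -> None:
        stages = {LifeStage.CALF: 0, LifeStage.HEIFER: 0, LifeStage.COW: 0}
        lactating = 0
        for a in self.herd.values():
            stages[a.life_stage] += 1
            lactating += a.lactating
        births = sum(1 for e in events_today if e.event == EV_BIRTH)
        exits = sum(1 for e in events_today if e.event == EV_EXIT)
        self.summary_rows.append(
            {
                "replicate": self.replicate,
                "sim_day": sim_day,
                "n_calves": stages[LifeStage.CALF],
                "n_heifers": stages[LifeStage.HEIFER],
                "n_cows": stages[LifeStage.COW],
                "n_lactating": lactating,
                "milk_kg": milk,
                "births": births,
                "entries": births,
                "exits": exits,
                "herd_size": len(self.herd),
            }
        )

    # -- public API --------------------------------------------------------

    def step_day(self) -> list[EventRecord]:
        """Advance the whole herd one day; returns the events emitted today."""
        cfg = self.cfg
        self.sim_day += 1
        day = self.sim_day
        n_before = len(self.events)

        for n in range(self.initial_herd.calf_arrivals.get(day, 0)):
            self._spawn_calf(day)

        milk_total = 0.0
        newborn_queue: list[Sex | None] = []
        for aid in sorted(self.herd):
            a = self.herd[aid]
            if not a.alive:
                continue
            rng = self._streams[aid]

            # 1. age & growth
            a.age += 1
            a.weight = body_weight(a.age, cfg)
            a.calved_today = False
            if a.parity >= 1:
                a.life_stage = LifeStage.COW
            elif a.age > CALF_MAX_AGE:
                a.life_stage = LifeStage.HEIFER

            # 2. reproduction
            if a.repro_state is ReproState.PREPUBERTAL and a.age >= cfg.puberty_base_age:
                a.repro_state = ReproState.AWAITING_FIRST_OVULATION
            if (
                a.repro_state is ReproState.AWAITING_FIRST_OVULATION
                and a.first_ovulation_age is not None
                and a.age >= a.first_ovulation_age
            ):
                self.events.append(EventRecord(day, aid, EV_FIRST_OVULATION, {"age": a.age}))
                a.repro_state = ReproState.CYCLING
                a.day_in_cycle = 0
                a.cycle_length = sample_cycle_length(cfg, rng)
                self._ovulation_day(a, rng, day)
            elif a.repro_state is ReproState.CYCLING:
                a.day_in_cycle += 1
                if a.day_in_cycle >= a.cycle_length:
                    self.events.append(EventRecord(day, aid, EV_OVULATION, {}))
                    self._ovulation_day(a, rng, day)
            elif a.repro_state is ReproState.PREGNANT:
                out = daily_pregnancy_update(a, cfg, rng, sim_day=day)
                self.events.extend(out.events)
                # 3. calving -> generate the newborn calf after the loop
                if a.calved_today:
                    newborn_queue.append(None)

            # 4. lactation & dry-off
            if a.lactating and not a.calved_today:
                a.dim += 1
            prod, ev = daily_production(a, cfg, sim_day=day)
            self.events.extend(ev)
            milk_total += prod.milk_yield

            # 5. culling
            cull_events = apply_culling(a, cfg, sim_day=day)
            if cull_events:
                self.events.extend(cull_events)

        for force in newborn_queue:
            self._spawn_calf(day, force_sex=force)

        self.herd = {aid: a for aid, a in self.herd.items() if a.alive}
        events_today = self.events[n_before:]
        self._record_summary(day, milk=milk_total, events_today=events_today)
        return events_today

    def run(self, n_days: int) -> None:
        if n_days < 1:
            raise ValueError("n_days must be >= 1")
        for _ in range(n_days):
            self.step_day()

    def events_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events, self.replicate)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.summary_rows, columns=SUMMARY_COLUMNS)


def events_to_frame(events: list[EventRecord], replicate: int = 0) -> pd.DataFrame:
    rows = [
        {
            "replicate": replicate,
            "sim_day": e.sim_day,
            "animal_id": e.animal_id,
            "event": e.event,
            "payload": e.payload,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def step_day(
    herd: "HerdSimulation",
) -> list[EventRecord]:
    """Functional alias: advance a :class:`HerdSimulation` by one day."""
    return herd.step_day()


def run_simulation(
    cfg: SimulationConfig,
    n_days: int,
    initial_herd_spec: InitialHerdSpec | None = None,
    replicates: int = 1,
    seed: int | None = None,
) -> list[ReplicateResult]:
    """Run ``replicates`` independent replicates of ``n_days`` days each.

    Replicate ``r`` uses the substream family (seed, r, animal_id); logs
    for one replicate are unaffected by how long any other replicate runs.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    root = cfg.seed if seed is None else seed
    results = []
    for r in range(replicates):
        sim = HerdSimulation(cfg, initial_herd=initial_herd_spec, seed=root, replicate=r)
        sim.run(n_days)
        results.append(
            ReplicateResult(
                replicate=r,
                seed=root,
                events=sim.events_frame(),
                summary=sim.summary_frame(),
            )
        )
    return results


def summarize(events: pd.DataFrame, initial_size: int = 0) -> pd.DataFrame:
    """Recompute the daily entry/exit ledger from an event log alone.

    Returns one row per sim day with births, entries, exits (total and by
    reason) and the herd size implied by the conservation identity
    ``size(t) = size(t-1) + entries(t) - exits(t)``; idempotent.
    """
    required = {"sim_day", "animal_id", "event"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event log missing columns: {sorted(missing)}")
    if events.empty:
        return pd.DataFrame(
            columns=["sim_day", "births", "entries", "exits", "herd_size"]
        ).astype({"sim_day": int, "births": int, "entries": int, "exits": int, "herd_size": int})
    days = pd.RangeIndex(int(events["sim_day"].min()), int(events["sim_day"].max()) + 1)
    out = pd.DataFrame(index=days)
    out.index.name = "sim_day"
    by = events.groupby(["sim_day", "event"]).size().unstack(fill_value=0)
    out["births"] = by.get(EV_BIRTH, pd.Series(0, index=by.index)).reindex(days, fill_value=0)
    out["entries"] = out["births"]
    out["exits"] = by.get(EV_EXIT, pd.Series(0, index=by.index)).reindex(days, fill_value=0)
    exits = events[events["event"] == EV_EXIT]
    if "payload" in events.columns and not exits.empty:
        reasons = exits["payload"].map(
            lambda p: p.get("reason", "unknown") if isinstance(p, dict) else "unknown"
        )
        for reason, grp in exits.groupby(reasons):
            col = f"exits_{reason}"
            out[col] = grp.groupby("sim_day").size().reindex(days, fill_value=0)
    out["herd_size"] = initial_size + (out["entries"] - out["exits"]).cumsum()
    return out.reset_index()
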