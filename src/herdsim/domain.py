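"""Shared domain types, enumerations and configuration defaults.

The simulator models an individual dairy animal's life course on a daily
time step: birth, linear growth at the breed's average daily gain, puberty
and estrus cycling, estrus-detection / AI breeding, scheduled pregnancy
diagnosis with latent pregnancy loss, calving and lactation, and exit by
stochastic lifetime culling or reproductive-failure culling.

All stochastic parameters live in :class:`SimulationConfig`.  The defaults
returned by :func:`default_config` reproduce a Holstein herd bred with
sexed semen under an estrus-detection/AI protocol; parameters the
literature example does not pin down (culling-reason probabilities, the
culling-age CDF, lactation-curve coefficients, dry-period length, mature
weight cap) are shipped as clearly labelled NON-NORMATIVE defaults and are
freely overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import TYPE_CHECKING, Any

if TYPE_CHECKING:  # pragma: no cover
    from .culling import CullFate


class ConfigError(ValueError):
    """A configuration value or table violates its schema."""


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class LifeStage(str, Enum):
    CALF = "calf"
    HEIFER = "heifer"
    COW = "cow"


class ReproState(str, Enum):
    """Reproductive state of a female.

    ``BRED_UNCONFIRMED`` and ``DO_NOT_BREED`` are declared for protocol
    extensions (e.g. revealing conception only at diagnosis, or flagging
    cows off the breeding list); the default estrus-detection/AI protocol
    resolves conception at insemination and culls immediately, so neither
    state is entered.
    """

    PREPUBERTAL = "prepubertal"
    AWAITING_FIRST_OVULATION = "awaiting_first_ovulation"
    CYCLING = "cycling"
    BRED_UNCONFIRMED = "bred_unconfirmed"
    PREGNANT = "pregnant"
    DO_NOT_BREED = "do_not_breed"


class CurveForm(str, Enum):
    WOOD = "WOOD"
    MILKBOT = "MILKBOT"


#: The six stochastic lifetime culling reasons, in their fixed evaluation order.
CULL_REASONS: tuple[str, ...] = (
    "lameness",
    "injury",
    "mastitis",
    "other_diseases",
    "udder_problems",
    "unknown",
)

#: Reason label for rule-triggered reproductive-failure culling.
REPRODUCTIVE_FAILURE = "reproductive_failure"

#: Parity classes used to key lactation-curve parameters.
PARITY_CLASSES: tuple[str, ...] = ("1", "2", "3+")

#: Age (d) below which a female is counted as a calf in herd summaries.
#: NON-NORMATIVE: a weaning-to-rearing boundary; has no effect on dynamics.
CALF_MAX_AGE = 180

# --------------------------------------------------------------------------
# Event codes
# --------------------------------------------------------------------------

EV_BIRTH = "BIRTH"
EV_MALE_SOLD = "MALE_SOLD"
EV_FIRST_OVULATION = "FIRST_OVULATION"
EV_OVULATION = "OVULATION"
EV_HEAT_DETECTED = "HEAT_DETECTED"
EV_INSEMINATION = "INSEMINATION"
EV_DIAGNOSIS_PREGNANT = "DIAGNOSIS_PREGNANT"
EV_DIAGNOSIS_OPEN = "DIAGNOSIS_OPEN"
EV_PREGNANCY_LOSS = "PREGNANCY_LOSS"
EV_CALVING = "CALVING"
EV_DRY_OFF = "DRY_OFF"
EV_CULLED = "CULLED"
EV_EXIT = "EXIT"

EVENT_CODES: tuple[str, ...] = (
    EV_BIRTH,
    EV_MALE_SOLD,
    EV_FIRST_OVULATION,
    EV_OVULATION,
    EV_HEAT_DETECTED,
    EV_INSEMINATION,
    EV_DIAGNOSIS_PREGNANT,
    EV_DIAGNOSIS_OPEN,
    EV_PREGNANCY_LOSS,
    EV_CALVING,
    EV_DRY_OFF,
    EV_CULLED,
    EV_EXIT,
)


@dataclass(frozen=True)
class EventRecord:
    """Append-only audit row for one discrete life event."""

    sim_day: int
    animal_id: int
    event: str
    payload: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class LactationCurveParams:
    """Parameters of a Wood or MilkBot lactation curve.

    Wood:    y(t) = a * t**b * exp(-c*t)      (a: scale kg/d, b: rise, c: decay 1/d)
    MilkBot: M(t) = a * (1 - exp((c-t)/b)/2) * exp(-d*t)
             (a: scale kg/d, b: ramp d, c: offset d, d: decay 1/d)
    """

    form: CurveForm
    a: float
    b: float
    c: float
    d: float = 0.0


@dataclass(frozen=True)
class CullingAgeCdf:
    """Empirical cumulative distribution of age at culling (step CDF).

    ``ages`` are strictly increasing whole days; ``cum`` is nondecreasing,
    within [0, 1], and ends at exactly 1.
    """

    ages: tuple[int, ...]
    cum: tuple[float, ...]

    def violations(self) -> list[str]:
        out: list[str] = []
        if len(self.ages) != len(self.cum) or len(self.ages) == 0:
            out.append("culling_age_cdf: ages and cum must be same nonzero length")
            return out
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            out.append("culling_age_cdf: ages must be strictly increasing")
        if any(b < a for a, b in zip(self.cum, self.cum[1:])):
            out.append("culling_age_cdf: cumulative probabilities must be nondecreasing")
        if self.cum[0] < 0:
            out.append("culling_age_cdf: cumulative probabilities must start >= 0")
        if abs(self.cum[-1] - 1.0) > 1e-12:
            out.append("culling_age_cdf: terminal cumulative probability must be 1")
        return out


@dataclass
class AnimalState:
    """Full per-animal record advanced by the daily engine."""

    animal_id: int
    sex: Sex
    breed: str
    age: int = 0
    weight: float = 0.0
    life_stage: LifeStage = LifeStage.CALF
    repro_state: ReproState = ReproState.PREPUBERTAL
    day_in_cycle: int = 0
    cycle_length: int = 0
    services: int = 0
    days_pregnant: int = 0
    gestation_length_drawn: int = 0
    parity: int = 0
    dim: int = 0
    lactating: bool = False
    first_ovulation_age: int | None = None
    latent_loss: bool = False
    ever_conceived: bool = False
    calved_today: bool = False
    dried_off: bool = False
    cull_fate: "CullFate | None" = None
    exit: tuple[int, str] | None = None

    @property
    def alive(self) -> bool:
        return self.exit is None


@dataclass
class SimulationConfig:
    """Every stochastic parameter of the simulated life cycle.

    ``N(mu, s)`` parameters are normal with mean ``mu`` and STANDARD
    DEVIATION ``s`` (not variance).  The first-ovulation delay is lognormal
    with ARITHMETIC mean ``first_ovulation_delay_mean`` and arithmetic SD
    ``first_ovulation_delay_sd``, moment-matched to the underlying normal.
    The conception rate drops by ``conception_decrement_per_service``
    ABSOLUTE probability points per additional service, clipped below at
    ``conception_floor``.
    """

    breed_name: str = "Holstein"
    semen_type: str = "sexed"
    birth_weight: float = 40.8
    average_daily_gain: float = 0.9
    # NON-NORMATIVE: plausible Holstein mature weight; growth plateaus here.
    mature_weight_cap: float | None = 680.0
    female_prob_by_semen: dict[str, float] = field(
        default_factory=lambda: {"sexed": 0.90, "conventional": 0.49}
    )
    puberty_base_age: int = 400
    first_ovulation_delay_mean: float = 19.0
    first_ovulation_delay_sd: float = 11.0
    cycle_length_mean: float = 21.0
    cycle_length_sd: float = 4.0
    heat_detection_prob: float = 0.60
    conception_first_service: float = 0.339
    conception_decrement_per_service: float = 0.026
    conception_floor: float = 0.0
    diagnosis_days: tuple[int, ...] = (32, 91, 200)
    daily_loss_rates: tuple[float, ...] = (0.0096, 0.0017)
    gestation_mean: float = 278.0
    gestation_sd: float = 6.0
    heifer_cull_age: int = 650
    cow_cull_dim: int = 300
    # NON-NORMATIVE lifetime probabilities for the six stochastic reasons.
    culling_reason_probs: dict[str, float] = field(
        default_factory=lambda: {
            "lameness": 0.04,
            "injury": 0.02,
            "mastitis": 0.07,
            "other_diseases": 0.05,
            "udder_problems": 0.03,
            "unknown": 0.04,
        }
    )
    # NON-NORMATIVE step CDF of age at culling (support ~2-10 yr).
    culling_age_cdf: CullingAgeCdf = field(
        default_factory=lambda: CullingAgeCdf(
            ages=(730, 1095, 1460, 1825, 2190, 2555, 2920, 3285, 3650),
            cum=(0.05, 0.15, 0.33, 0.52, 0.68, 0.80, 0.89, 0.95, 1.0),
        )
    )
    # NON-NORMATIVE Wood coefficients by (breed, parity class).
    lactation: dict[tuple[str, str], LactationCurveParams] = field(
        default_factory=lambda: {
            ("Holstein", "1"): LactationCurveParams(CurveForm.WOOD, 16.5, 0.22, 0.0024),
            ("Holstein", "2"): LactationCurveParams(CurveForm.WOOD, 21.0, 0.24, 0.0030),
            ("Holstein", "3+"): LactationCurveParams(CurveForm.WOOD, 23.0, 0.25, 0.0033),
        }
    )
    dry_period_length: int = 60  # NON-NORMATIVE
    seed: int = 12345

    def copy(self, **changes: Any) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def default_config() -> SimulationConfig:
    """Return the default configuration (Holstein, sexed semen, estrus-detection/AI).

    Normative values: birth weight 40.8 kg; ADG 0.9 kg/d; 90% female with
    sexed semen; puberty base age 400 d; first-ovulation delay lognormal
    with mean 19 d and SD 11 d; cycle length N(21, 4); heat detection 0.60;
    first-service conception 0.339 with 0.026 decrement per service;
    pregnancy diagnoses on days 32, 91 and 200 with daily loss 0.0096 and
    0.0017 between them; gestation N(278, 6); heifer cull at 650 d; open-cow
    cull past 300 DIM.  Remaining fields are documented non-normative
    defaults.
    """
    return SimulationConfig()


def _prob_fields(cfg: SimulationConfig) -> list[tuple[str, float]]:
    out = [
        ("heat_detection_prob", cfg.heat_detection_prob),
        ("conception_first_service", cfg.conception_first_service),
        ("conception_decrement_per_service", cfg.conception_decrement_per_service),
        ("conception_floor", cfg.conception_floor),
    ]
    out += [(f"female_prob_by_semen[{k}]", v) for k, v in cfg.female_prob_by_semen.items()]
    out += [(f"culling_reason_probs[{k}]", v) for k, v in cfg.culling_reason_probs.items()]
    out += [(f"daily_loss_rates[{i}]", v) for i, v in enumerate(cfg.daily_loss_rates)]
    return out


def validate_config(cfg: SimulationConfig) -> list[str]:
    """Check every invariant; return one message per violation (empty if valid)."""
    v: list[str] = []
    for name, p in _prob_fields(cfg):
        if not (0.0 <= p <= 1.0):
            v.append(f"{name}: probability {p} outside [0, 1]")
    for name, x in [
        ("birth_weight", cfg.birth_weight),
        ("average_daily_gain", cfg.average_daily_gain),
        ("puberty_base_age", cfg.puberty_base_age),
        ("first_ovulation_delay_mean", cfg.first_ovulation_delay_mean),
        ("cycle_length_mean", cfg.cycle_length_mean),
        ("gestation_mean", cfg.gestation_mean),
        ("heifer_cull_age", cfg.heifer_cull_age),
        ("cow_cull_dim", cfg.cow_cull_dim),
        ("dry_period_length", cfg.dry_period_length),
    ]:
        if not x > 0:
            v.append(f"{name}: must be > 0, got {x}")
    for name, x in [
        ("first_ovulation_delay_sd", cfg.first_ovulation_delay_sd),
        ("cycle_length_sd", cfg.cycle_length_sd),
        ("gestation_sd", cfg.gestation_sd),
    ]:
        if x < 0:
            v.append(f"{name}: must be >= 0, got {x}")
    if cfg.mature_weight_cap is not None and cfg.mature_weight_cap <= 0:
        v.append(f"mature_weight_cap: must be > 0 or None, got {cfg.mature_weight_cap}")
    if cfg.semen_type not in cfg.female_prob_by_semen:
        v.append(f"semen_type: '{cfg.semen_type}' not in female_prob_by_semen")
    if any(b <= a for a, b in zip(cfg.diagnosis_days, cfg.diagnosis_days[1:])):
        v.append(f"diagnosis_days: must be strictly increasing, got {list(cfg.diagnosis_days)}")
    if len(cfg.daily_loss_rates) != max(len(cfg.diagnosis_days) - 1, 0):
        v.append(
            "daily_loss_rates: need exactly len(diagnosis_days) - 1 rates "
            f"({len(cfg.diagnosis_days) - 1}), got {len(cfg.daily_loss_rates)}"
        )
    if cfg.diagnosis_days and cfg.gestation_sd == 0 and cfg.gestation_mean <= max(cfg.diagnosis_days):
        v.append("gestation_mean: degenerate gestation must exceed the last diagnosis day")
    v.extend(cfg.culling_age_cdf.violations())
    for key, params in cfg.lactation.items():
        label = f"lactation[{key}]"
        if params.a <= 0:
            v.append(f"{label}: scale a must be > 0")
        if params.form is CurveForm.WOOD and (params.b < 0 or params.c < 0):
            v.append(f"{label}: Wood shape parameters must be >= 0")
        if params.form is CurveForm.MILKBOT and (params.b <= 0 or params.d < 0):
            v.append(f"{label}: MilkBot requires ramp b > 0 and decay d >= 0")
    return v
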