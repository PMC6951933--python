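"""Config and table readers/writers.

The configuration file is YAML (nested mapping, strict schema: unknown
keys are rejected by name).  All tables are CSV with a header row, comma
delimiter, '.' decimal separator and UTF-8 encoding.  Dates are
simulation-day integers throughout.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .domain import (
    ConfigError,
    CullingAgeCdf,
    CurveForm,
    LactationCurveParams,
    SimulationConfig,
    validate_config,
)
from .engine import EVENT_COLUMNS
from .ration import Feed

_FEED_FIXED_COLS = ["name", "cost", "min_inclusion", "max_inclusion", "available"]

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


# --------------------------------------------------------------------------
# Simulation config (YAML)
# --------------------------------------------------------------------------

def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["diagnosis_days"] = list(cfg.diagnosis_days)
    d["daily_loss_rates"] = list(cfg.daily_loss_rates)
    d["culling_age_cdf"] = {
        "age_days": list(cfg.culling_age_cdf.ages),
        "cumulative_probability": list(cfg.culling_age_cdf.cum),
    }
    d["lactation"] = [
        {
            "breed": breed,
            "parity_class": pc,
            "form": p.form.value,
            "a": p.a,
            "b": p.b,
            "c": p.c,
            "d": p.d,
        }
        for (breed, pc), p in cfg.lactation.items()
    ]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    unknown = set(d) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(d)
    if "diagnosis_days" in kwargs:
        kwargs["diagnosis_days"] = tuple(int(x) for x in kwargs["diagnosis_days"])
    if "daily_loss_rates" in kwargs:
        kwargs["daily_loss_rates"] = tuple(float(x) for x in kwargs["daily_loss_rates"])
    if "culling_age_cdf" in kwargs:
        raw = kwargs["culling_age_cdf"]
        try:
            kwargs["culling_age_cdf"] = CullingAgeCdf(
                ages=tuple(int(a) for a in raw["age_days"]),
                cum=tuple(float(p) for p in raw["cumulative_probability"]),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"culling_age_cdf: malformed table ({exc})") from None
    if "lactation" in kwargs:
        table: dict[tuple[str, str], LactationCurveParams] = {}
        for row in kwargs["lactation"]:
            try:
                table[(row["breed"], str(row["parity_class"]))] = LactationCurveParams(
                    form=CurveForm(row["form"]),
                    a=float(row["a"]),
                    b=float(row["b"]),
                    c=float(row["c"]),
                    d=float(row.get("d", 0.0)),
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"lactation: malformed row {row!r} ({exc})") from None
        kwargs["lactation"] = table
    cfg = SimulationConfig(**kwargs)
    violations = validate_config(cfg)
    if violations:
        raise ConfigError("; ".join(violations))
    return cfg


def write_config(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(
        # sort_keys=False: mapping order is meaningful (culling-reason
        # evaluation order follows the configured dict order).
        yaml.safe_dump(config_to_dict(cfg), sort_keys=False, default_flow_style=False),
        encoding="utf-8",
    )


def read_config(path: str | Path) -> SimulationConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse config{line}: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(raw)


def default_config_path() -> Path:
    """Path of the default configuration shipped with the package."""
    return Path(__file__).parent / "data" / "default_config.yaml"


# --------------------------------------------------------------------------
# Culling-age CDF (CSV: age_days, cumulative_probability)
# --------------------------------------------------------------------------

def write_culling_cdf(cdf: CullingAgeCdf, path: str | Path) -> None:
    pd.DataFrame(
        {"age_days": cdf.ages, "cumulative_probability": cdf.cum}
    ).to_csv(path, index=False)


def read_culling_cdf(path: str | Path) -> CullingAgeCdf:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"age_days", "cumulative_probability"}
    if set(df.columns) != needed:
        raise ConfigError(f"culling CDF CSV must have columns {sorted(needed)}")
    cdf = CullingAgeCdf(
        ages=tuple(int(a) for a in df["age_days"]),
        cum=tuple(float(p) for p in df["cumulative_probability"]),
    )
    bad = cdf.violations()
    if bad:
        raise ConfigError("; ".join(bad))
    return cdf


# --------------------------------------------------------------------------
# Lactation parameter table (CSV: breed, parity_class, form, a, b, c, d)
# --------------------------------------------------------------------------

def write_lactation_table(
    table: dict[tuple[str, str], LactationCurveParams], path: str | Path
) -> None:
    rows = [
        {"breed": b, "parity_class": pc, "form": p.form.value, "a": p.a, "b": p.b, "c": p.c, "d": p.d}
        for (b, pc), p in table.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lactation_table(path: str | Path) -> dict[tuple[str, str], LactationCurveParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"breed", "parity_class", "form", "a", "b", "c"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"lactation table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], LactationCurveParams] = {}
    for row in df.itertuples(index=False):
        d = float(getattr(row, "d", 0.0) or 0.0)
        out[(row.breed, str(row.parity_class))] = LactationCurveParams(
            form=CurveForm(row.form), a=float(row.a), b=float(row.b), c=float(row.c), d=d
        )
    return out


# --------------------------------------------------------------------------
# Feed library and requirement tables (CSV)
# --------------------------------------------------------------------------

def write_feed_library(feeds: list[Feed], path: str | Path) -> None:
    nutrients = sorted({n for f in feeds for n in f.composition})
    rows = []
    for f in feeds:
        row: dict = {
            "name": f.name,
            "cost": f.cost,
            "min_inclusion": f.min_inclusion,
            "max_inclusion": f.max_inclusion,
            "available": f.available,
        }
        row.update({n: f.composition.get(n, 0.0) for n in nutrients})
        rows.append(row)
    pd.DataFrame(rows, columns=_FEED_FIXED_COLS + nutrients).to_csv(path, index=False)


def read_feed_library(path: str | Path) -> list[Feed]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"name", "cost"} - set(df.columns)
    if missing:
        raise ConfigError(f"feed library missing columns: {sorted(missing)}")
    nutrients = [c for c in df.columns if c not in _FEED_FIXED_COLS]
    feeds = []
    for row in df.itertuples(index=False):
        def _opt(value: object) -> float | None:
            return None if value is None or pd.isna(value) else float(value)

        feeds.append(
            Feed(
                name=str(row.name),
                cost=float(row.cost),
                composition={n: float(getattr(row, n)) for n in nutrients},
                min_inclusion=_opt(getattr(row, "min_inclusion", 0.0)) or 0.0,
                max_inclusion=_opt(getattr(row, "max_inclusion", None)),
                available=_opt(getattr(row, "available", None)),
            )
        )
    return feeds


def write_requirement_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_requirement_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"nutrient", "maintenance_per_kg_bw", "per_kg_milk"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"requirement table missing columns: {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# Event log and summary (CSV)
# --------------------------------------------------------------------------

def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    """Event log CSV with columns replicate, sim_day, animal_id, event, payload(JSON)."""
    out = events.copy()
    out["payload"] = out["payload"].map(lambda p: json.dumps(p, sort_keys=True))
    out.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"event log missing columns: {sorted(missing)}")
    try:
        df["payload"] = df["payload"].map(json.loads)
    except (TypeError, json.JSONDecodeError) as exc:
        raise ConfigError(f"event log payload is not valid JSON: {exc}") from None
    return df


def write_summary_csv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)


def read_summary_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
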