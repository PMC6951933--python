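"""Least-cost ration formulation by linear programming.

Choose daily dry-matter amounts x_f of each available feed to minimize
total cost sum_f cost_f * x_f subject to nutrient constraints
sum_f comp[f, n] * x_f >= min_n (and <= max_n where bounded), a total
dry-matter-intake window, and per-feed inclusion/availability bounds.
Nutrient requirements are table-driven: a maintenance term linear in body
weight plus a term linear in milk yield per nutrient, supplied by the
user's feeding system — no normative requirement coefficients ship with
the package.

The LP is solved with the HiGHS solver via :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .domain import ConfigError


@dataclass(frozen=True)
class Feed:
    """One feed: cost and nutrient composition per kg dry matter."""

    name: str
    cost: float  # currency per kg DM
    composition: dict[str, float]  # nutrient -> amount per kg DM
    min_inclusion: float = 0.0  # kg DM/d
    max_inclusion: float | None = None  # kg DM/d
    available: float | None = None  # kg DM/d

    def violations(self) -> list[str]:
        out = []
        if self.cost < 0:
            out.append(f"feed {self.name}: cost must be >= 0")
        if any(v < 0 for v in self.composition.values()):
            out.append(f"feed {self.name}: composition values must be >= 0")
        if self.min_inclusion < 0:
            out.append(f"feed {self.name}: min_inclusion must be >= 0")
        if self.max_inclusion is not None and self.min_inclusion > self.max_inclusion:
            out.append(f"feed {self.name}: min_inclusion exceeds max_inclusion")
        if self.available is not None and self.available < 0:
            out.append(f"feed {self.name}: available must be >= 0")
        return out


@dataclass(frozen=True)
class RequirementSet:
    """Daily nutrient requirements plus the dry-matter-intake window."""

    nutrient_min: dict[str, float]
    nutrient_max: dict[str, float] = field(default_factory=dict)
    dmi_min: float = 0.0
    dmi_max: float | None = None

    def violations(self) -> list[str]:
        out = []
        for n, lo in self.nutrient_min.items():
            hi = self.nutrient_max.get(n)
            if hi is not None and hi < lo:
                out.append(f"requirement {n}: max {hi} below min {lo}")
        if self.dmi_max is not None and self.dmi_max < self.dmi_min:
            out.append("dmi_max below dmi_min")
        return out


@dataclass(frozen=True)
class RationProblem:
    """Assembled LP: minimize c @ x subject to A_ub @ x <= b_ub, bounds."""

    feeds: tuple[Feed, ...]
    requirements: RequirementSet
    c: np.ndarray
    a_ub: np.ndarray
    b_ub: np.ndarray
    bounds: tuple[tuple[float, float | None], ...]
    constraint_labels: tuple[str, ...]


@dataclass(frozen=True)
class RationSolution:
    status: str  # optimal | infeasible | unbounded | error
    amounts: dict[str, float]  # feed -> kg DM/d
    total_cost: float
    achieved: dict[str, float]  # nutrient -> delivered amount/d


def build_ration_problem(feeds: list[Feed], requirements: RequirementSet) -> RationProblem:
    """Encode the least-cost diet LP from feeds and a requirement set."""
    if not feeds:
        raise ValueError("at least one feed is required")
    if not requirements.nutrient_min and not requirements.nutrient_max:
        raise ValueError("at least one nutrient requirement is required")
    bad = [m for f in feeds for m in f.violations()] + requirements.violations()
    if bad:
        raise ConfigError("; ".join(bad))

    nutrients = sorted(set(requirements.nutrient_min) | set(requirements.nutrient_max))
    for n in nutrients:
        if all(f.composition.get(n, 0.0) == 0.0 for f in feeds):
            raise ConfigError(f"nutrient '{n}' required but absent from every feed")

    n_feeds = len(feeds)
    comp = np.array([[f.composition.get(n, 0.0) for f in feeds] for n in nutrients])
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    labels: list[str] = []
    for i, n in enumerate(nutrients):
        lo = requirements.nutrient_min.get(n)
        if lo is not None:
            rows.append(-comp[i])
            rhs.append(-lo)
            labels.append(f"{n}>=min")
        hi = requirements.nutrient_max.get(n)
        if hi is not None:
            rows.append(comp[i])
            rhs.append(hi)
            labels.append(f"{n}<=max")
    ones = np.ones(n_feeds)
    if requirements.dmi_min > 0:
        rows.append(-ones)
        rhs.append(-requirements.dmi_min)
        labels.append("dmi>=min")
    if requirements.dmi_max is not None:
        rows.append(ones)
        rhs.append(requirements.dmi_max)
        labels.append("dmi<=max")
    # Availability is a constraint row (not a variable bound) so that a
    # contradiction with min_inclusion surfaces as an infeasible LP.
    for j, f in enumerate(feeds):
        if f.available is not None:
            row = np.zeros(n_feeds)
            row[j] = 1.0
            rows.append(row)
            rhs.append(f.available)
            labels.append(f"{f.name}<=available")

    bounds = tuple((f.min_inclusion, f.max_inclusion) for f in feeds)
    return RationProblem(
        feeds=tuple(feeds),
        requirements=requirements,
        c=np.array([f.cost for f in feeds], dtype=float),
        a_ub=np.array(rows, dtype=float),
        b_ub=np.array(rhs, dtype=float),
        bounds=bounds,
        constraint_labels=tuple(labels),
    )


_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_ration(problem: RationProblem) -> RationSolution:
    """Solve the assembled LP; the optimal cost is unique even when the diet is not."""
    res = linprog(
        problem.c,
        A_ub=problem.a_ub,
        b_ub=problem.b_ub,
        bounds=list(problem.bounds),
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return RationSolution(status=status, amounts={}, total_cost=math.nan, achieved={})
    x = np.asarray(res.x)
    amounts = {f.name: float(xi) for f, xi in zip(problem.feeds, x)}
    nutrients = sorted(
        set(problem.requirements.nutrient_min) | set(problem.requirements.nutrient_max)
    )
    achieved = {
        n: float(sum(f.composition.get(n, 0.0) * xi for f, xi in zip(problem.feeds, x)))
        for n in nutrients
    }
    return RationSolution(
        status="optimal", amounts=amounts, total_cost=float(res.fun), achieved=achieved
    )


def formulate_ration(feeds: list[Feed], requirements: RequirementSet) -> RationSolution:
    """Convenience wrapper: build then solve."""
    return solve_ration(build_ration_problem(feeds, requirements))


def requirements_from_production(
    milk_yield: float,
    body_weight: float,
    requirement_table: pd.DataFrame | None,
    dmi_min: float = 0.0,
    dmi_max: float | None = None,
) -> RequirementSet:
    """Assemble daily requirements for a given production level.

    ``requirement_table`` columns: ``nutrient``, ``maintenance_per_kg_bw``,
    ``per_kg_milk`` and optionally ``max_daily``; the minimum for each
    nutrient is ``maintenance_per_kg_bw * body_weight + per_kg_milk *
    milk_yield``.  The coefficients come from the user's feeding system.
    """
    if requirement_table is None:
        raise ConfigError("a requirement table is required")
    if milk_yield < 0 or body_weight < 0:
        raise ValueError("milk_yield and body_weight must be >= 0")
    needed = {"nutrient", "maintenance_per_kg_bw", "per_kg_milk"}
    missing = needed - set(requirement_table.columns)
    if missing:
        raise ConfigError(f"requirement table missing columns: {sorted(missing)}")
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    for row in requirement_table.itertuples(index=False):
        mins[row.nutrient] = (
            float(row.maintenance_per_kg_bw) * body_weight + float(row.per_kg_milk) * milk_yield
        )
        mx = getattr(row, "max_daily", None)
        if mx is not None and not (isinstance(mx, float) and math.isnan(mx)):
            maxs[row.nutrient] = float(mx)
    return RequirementSet(nutrient_min=mins, nutrient_max=maxs, dmi_min=dmi_min, dmi_max=dmi_max)
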