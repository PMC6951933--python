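"""Deterministic synthetic fixture generators.

Everything a test or demo needs can be generated from a
:class:`FixtureSpec` and a seed: the default configuration, a synthetic
step CDF of culling age, and a toy feed library with a matching
requirement table that is feasible by construction.  Fixtures are pure
functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import CullingAgeCdf, SimulationConfig, default_config
from .ration import Feed


@dataclass(frozen=True)
class FixtureSpec:
    """Which fixture to generate and its shape parameters."""

    kind: str = "culling_cdf"  # culling_cdf | feed_library | config
    n_steps: int = 5  # culling CDF step count
    n_feeds: int = 3  # 2-5
    n_nutrients: int = 3  # 2-4
    seed: int = 0

    def violations(self) -> list[str]:
        out = []
        if self.kind not in ("culling_cdf", "feed_library", "config"):
            out.append(f"unknown fixture kind '{self.kind}'")
        if self.n_steps < 1:
            out.append("n_steps must be >= 1")
        if not 2 <= self.n_feeds <= 5:
            out.append("n_feeds must be in [2, 5]")
        if not 2 <= self.n_nutrients <= 4:
            out.append("n_nutrients must be in [2, 4]")
        return out


def _check(spec: FixtureSpec) -> None:
    bad = spec.violations()
    if bad:
        raise ValueError("; ".join(bad))


def make_default_config(spec: FixtureSpec | None = None) -> SimulationConfig:
    return default_config()


def make_synthetic_culling_cdf(spec: FixtureSpec) -> CullingAgeCdf:
    """A synthetic nondecreasing step CDF with support inside [400, 4000] d.

    The terminal cumulative probability is exactly 1; step masses are a
    Dirichlet-like draw so no step is degenerate unless n_steps == 1.
    """
    _check(spec)
    rng = np.random.default_rng(spec.seed)
    lo, hi = 400, 4000
    if spec.n_steps == 1:
        age = int(rng.integers(lo, hi + 1))
        return CullingAgeCdf(ages=(age,), cum=(1.0,))
    ages = np.sort(rng.choice(np.arange(lo, hi + 1), size=spec.n_steps, replace=False))
    masses = rng.dirichlet(np.full(spec.n_steps, 2.0))
    cum = np.cumsum(masses)
    cum[-1] = 1.0
    return CullingAgeCdf(ages=tuple(int(a) for a in ages), cum=tuple(float(c) for c in cum))


def make_toy_feed_library(spec: FixtureSpec) -> tuple[list[Feed], pd.DataFrame]:
    """A small feed library plus requirement coefficient table.

    Feasible by construction: the first feed is "complete" (rich in every
    nutrient, unlimited availability), so any requirement assembled from
    the returned table for moderate production levels can be met.

    Returns (feeds, requirement_table) where the table has columns
    nutrient, maintenance_per_kg_bw, per_kg_milk.
    """
    _check(spec)
    rng = np.random.default_rng(spec.seed)
    nutrients = [f"nutrient_{i}" for i in range(spec.n_nutrients)]

    feeds = [
        Feed(
            name="complete_feed",
            cost=float(rng.uniform(0.25, 0.45)),
            composition={n: float(rng.uniform(0.6, 1.0)) for n in nutrients},
        )
    ]
    for i in range(1, spec.n_feeds):
        comp = {n: float(rng.uniform(0.0, 0.7)) for n in nutrients}
        feeds.append(
            Feed(
                name=f"feed_{i}",
                cost=float(rng.uniform(0.05, 0.35)),
                composition=comp,
                max_inclusion=float(rng.uniform(5.0, 15.0)),
            )
        )

    table = pd.DataFrame(
        {
            "nutrient": nutrients,
            "maintenance_per_kg_bw": rng.uniform(0.002, 0.01, size=spec.n_nutrients).round(5),
            "per_kg_milk": rng.uniform(0.05, 0.25, size=spec.n_nutrients).round(4),
        }
    )
    return feeds, table
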