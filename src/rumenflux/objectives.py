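"""Community-level objective suite and flux-range robustness statistics.

The community is simulated under five fitness criteria — maximize total
growth, maximize short-chain fatty-acid (SCFA) release, maximize feed
utilization, minimize methane + CO2 release, and maximize small-sugar
release — and per-reaction flux ranges are compared across the five runs.
Robustness is quantified as the population standard deviation of each
reaction's minimum and maximum flux over the runs (the five objectives
are the whole population of conditions studied, hence the 1/n formula;
the sample variant is switchable). All runs share one diet so that
differences are attributable to the objective alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .community import CommunityModel, CommunitySolution, biomass_objective, community_fva, solve_optcom
from .lp_core import FVAResult

__all__ = [
    "ObjectiveSpec",
    "ObjectiveSets",
    "RobustnessReport",
    "default_objective_suite",
    "run_objective_suite",
    "robustness_stats",
    "density_summary",
]

OBJECTIVE_NAMES = (
    "growth",
    "scfa_production",
    "feed_utilization",
    "methane_co2_release",
    "sugar_production",
)


@dataclass
class ObjectiveSpec:
    name: str
    sense: str  # max | min
    weights: dict[str, float]  # community variable -> weight

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"objective {self.name!r} has an empty reaction set")
        if self.name == "methane_co2_release" and self.sense != "min":
            raise ValueError("methane/CO2 release is a minimization objective")


@dataclass
class ObjectiveSets:
    """Membership config for the metabolite-based objectives (never
    enumerated universally; supplied per community, with defaults emitted
    by the synthetic generator)."""

    scfa: list[str] = field(default_factory=list)
    feed: list[str] = field(default_factory=list)
    gas: list[str] = field(default_factory=list)
    sugar: list[str] = field(default_factory=list)


def default_objective_suite(cm: CommunityModel, sets: ObjectiveSets) -> list[ObjectiveSpec]:
    """The five standard community objectives for one community.

    Release objectives weight the pool export variables ``u[i]``; feed
    utilization weights the community uptakes ``e[i]``; growth sums the
    member biomass fluxes.
    """
    def pool_u(mets: list[str]) -> dict[str, float]:
        return {f"u[{i}]": 1.0 for i in mets if i in cm.shared}

    def pool_e(mets: list[str]) -> dict[str, float]:
        return {f"e[{i}]": 1.0 for i in mets if i in cm.shared}

    return [
        ObjectiveSpec("growth", "max", biomass_objective(cm)),
        ObjectiveSpec("scfa_production", "max", pool_u(sets.scfa)),
        ObjectiveSpec("feed_utilization", "max", pool_e(sets.feed)),
        ObjectiveSpec("methane_co2_release", "min", pool_u(sets.gas)),
        ObjectiveSpec("sugar_production", "max", pool_u(sets.sugar)),
    ]


@dataclass
class SuiteRun:
    spec: ObjectiveSpec
    solution: Optional[CommunitySolution]
    fva: Optional[FVAResult]
    error: Optional[str] = None


def run_objective_suite(
    cm: CommunityModel,
    specs: list[ObjectiveSpec],
    method: str = "kkt",
    reactions: Optional[list[str]] = None,
) -> list[SuiteRun]:
    """Solve the community under each objective, then scan flux ranges
    with that objective fixed at its optimum. A failing spec is recorded
    and the suite continues."""
    runs: list[SuiteRun] = []
    for spec in specs:
        try:
            solution = solve_optcom(cm, spec.weights, sense=spec.sense, method=method)
            if not solution.ok:
                runs.append(SuiteRun(spec, solution, None, error=solution.status))
                continue
            result = community_fva(
                cm,
                spec.weights,
                solution.objective_value,
                reactions=reactions,
                sense=spec.sense,
                method=method,
            )
            runs.append(SuiteRun(spec, solution, result))
        except Exception as exc:  # per-spec failure, suite continues
            runs.append(SuiteRun(spec, None, None, error=str(exc)))
    return runs


# ---------------------------------------------------------------------------
# Robustness statistics
# ---------------------------------------------------------------------------

@dataclass
class RobustnessReport:
    table: pd.DataFrame  # index: reaction; columns: sd_min, sd_max, member
    fraction_nonzero: dict[str, float]  # per member
    mean_sd: float  # pooled mean over sd_min and sd_max
    sd_range: tuple[float, float]
    population: bool = True


def _member_of(rid: str) -> str:
    return rid.split(":", 1)[0] if ":" in rid else ""


def robustness_stats(
    results: list[FVAResult],
    population: bool = True,
    zero_tol: float = 1e-9,
) -> RobustnessReport:
    """Per-reaction SD of min and max flux across objective runs.

    Requires >= 2 results over an identical reaction set. ``population``
    selects the 1/n formula (default); the fractions, mean, and range in
    the report are recomputable from the emitted per-reaction table.
    """
    if len(results) < 2:
        raise ValueError("robustness statistics need at least two FVA results")
    rid_sets = [set(r.ranges) for r in results]
    common = set.intersection(*rid_sets)
    if any(s != rid_sets[0] for s in rid_sets):
        raise ValueError(
            "mismatched reaction sets across results: "
            f"union-minus-intersection = {sorted(set.union(*rid_sets) - common)}"
        )
    ddof = 0 if population else 1
    rows = []
    for rid in sorted(common):
        mins = np.array([r.ranges[rid][0] for r in results])
        maxs = np.array([r.ranges[rid][1] for r in results])
        rows.append(
            {
                "reaction": rid,
                "sd_min": float(np.std(mins, ddof=ddof)),
                "sd_max": float(np.std(maxs, ddof=ddof)),
                "member": _member_of(rid),
            }
        )
    table = pd.DataFrame(rows).set_index("reaction")
    fraction: dict[str, float] = {}
    for member, sub in table.groupby("member"):
        nonzero = ((sub["sd_min"] > zero_tol) | (sub["sd_max"] > zero_tol)).mean()
        fraction[str(member)] = float(nonzero)
    pooled = np.concatenate([table["sd_min"].to_numpy(), table["sd_max"].to_numpy()])
    return RobustnessReport(
        table=table,
        fraction_nonzero=fraction,
        mean_sd=float(pooled.mean()),
        sd_range=(float(pooled.min()), float(pooled.max())),
        population=population,
    )


def density_summary(
    sds: list[float],
    bandwidth: Optional[float] = None,
    grid_points: int = 256,
) -> pd.DataFrame:
    """Gaussian-kernel density of a set of SD values on a fixed grid.

    The bandwidth defaults to Silverman's rule,
    ``0.9 * min(sd, IQR/1.34) * n^(-1/5)``, with a small floor so that a
    degenerate (constant) input yields a narrow point mass instead of a
    singular estimate. The returned density integrates to ~1 over the
    grid (trapezoid rule, within 1e-3).
    """
    if len(sds) == 0:
        raise ValueError("density_summary needs at least one value")
    x = np.asarray(sds, dtype=float)
    n = x.size
    if bandwidth is None:
        spread = float(np.std(x))
        q75, q25 = np.percentile(x, [75, 25])
        iqr = (q75 - q25) / 1.34
        candidates = [v for v in (spread, iqr) if v > 0]
        bandwidth = 0.9 * min(candidates) * n ** (-0.2) if candidates else 0.0
        if bandwidth <= 0:
            bandwidth = max(1e-3, 0.01 * max(1.0, abs(float(x.mean()))))
    lo = float(x.min()) - 4 * bandwidth
    hi = float(x.max()) + 4 * bandwidth
    grid = np.linspace(lo, hi, grid_points)
    z = (grid[:, None] - x[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (n * bandwidth * math.sqrt(2 * math.pi))
    return pd.DataFrame({"grid": grid, "density": density, "bandwidth": bandwidth})
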