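"""Flux balance analysis (FBA) and flux variability analysis (FVA).

FBA maximizes (or minimizes) one reaction flux — typically biomass —
subject to steady-state mass balance ``S v = 0`` and flux bounds
``LB <= v <= UB``. FVA then maximizes and minimizes every reaction flux
over the same polytope, optionally with the objective flux pinned at (a
fraction of) its optimum, and reports per-reaction [min, max] ranges.

Degenerate alternate optima are expected: FBA returns an arbitrary optimal
vertex, so downstream logic in this package depends only on objective
values and FVA ranges, never on a particular FBA flux vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import _milp
from .constants import REPORT_TOL
from .model_io import MetabolicModel

__all__ = ["FBAResult", "FVAConfig", "FVAResult", "fba", "fva", "build_program"]


@dataclass
class FBAResult:
    objective_value: Optional[float]
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded | failed
    objective_reaction: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAConfig:
    """FVA options.

    ``objective_fix=(reaction_id, threshold, fraction)`` pins the objective
    reaction before scanning: at equality when ``fraction == 1`` (the
    default), or at ``>= fraction * threshold`` otherwise. ``threshold=None``
    means "compute the FBA optimum first and use that".
    """

    objective_fix: Optional[tuple[str, Optional[float], float]] = None
    tolerance: float = REPORT_TOL

    def __post_init__(self) -> None:
        if self.objective_fix is not None:
            _, _, fraction = self.objective_fix
            if not 0.0 <= fraction <= 1.0:
                raise ValueError(f"objective fraction must be in [0, 1], got {fraction}")


@dataclass
class FVAResult:
    ranges: dict[str, tuple[float, float]]
    config: FVAConfig = field(default_factory=FVAConfig)
    failures: dict[str, str] = field(default_factory=dict)

    def min(self, rid: str) -> float:
        return self.ranges[rid][0]

    def max(self, rid: str) -> float:
        return self.ranges[rid][1]


def build_program(model: MetabolicModel) -> _milp.Program:
    """Mass-balance LP skeleton: one variable per reaction, one equality
    row per metabolite."""
    prog = _milp.Program()
    for rxn in model.reactions:
        prog.add_var(rxn.id, rxn.lb, rxn.ub)
    by_met: dict[str, dict[str, float]] = {m.id: {} for m in model.metabolites}
    for rxn in model.reactions:
        for mid, coeff in rxn.stoichiometry.items():
            by_met[mid][rxn.id] = by_met[mid].get(rxn.id, 0.0) + coeff
    for mid, coeffs in by_met.items():
        prog.add_eq(coeffs, 0.0)
    return prog


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
) -> FBAResult:
    """Solve the FBA LP for one objective reaction.

    Infeasibility and unboundedness are reported through ``status``; fluxes
    are returned only for optimal solves.
    """
    rid = objective or model.biomass_reaction_id
    if not model.has_reaction(rid):
        raise KeyError(f"objective reaction {rid!r} not in model {model.id!r}")
    prog = build_program(model)
    prog.set_objective({rid: 1.0})
    sol = prog.solve(sense=sense)
    return FBAResult(
        objective_value=sol.objective if sol.ok else None,
        fluxes=sol.values if sol.ok else {},
        status=sol.status,
        objective_reaction=rid,
    )


def fva(
    model: MetabolicModel,
    reactions: Optional[Sequence[str] | Iterable[str]] = None,
    config: Optional[FVAConfig] = None,
) -> FVAResult:
    """Per-reaction [min, max] flux ranges.

    A per-reaction LP failure is recorded in ``failures`` and the scan
    continues; it never aborts the whole run.
    """
    config = config or FVAConfig()
    rids = list(reactions) if reactions is not None else model.reaction_ids
    prog = build_program(model)

    if config.objective_fix is not None:
        obj_rid, threshold, fraction = config.objective_fix
        if threshold is None:
            opt = fba(model, objective=obj_rid).objective_value
            if opt is None:
                raise RuntimeError(
                    f"cannot fix objective {obj_rid!r}: FBA not optimal"
                )
            threshold = opt
        lb, ub = prog.get_bounds(obj_rid)
        if fraction == 1.0:
            prog.set_bounds(obj_rid, threshold - config.tolerance, threshold + config.tolerance)
        else:
            prog.set_bounds(obj_rid, max(lb, fraction * threshold), ub)

    ranges: dict[str, tuple[float, float]] = {}
    failures: dict[str, str] = {}
    for rid in rids:
        endpoints = []
        for sense in ("min", "max"):
            prog.set_objective({rid: 1.0})
            sol = prog.solve(sense=sense)
            if not sol.ok:
                failures[rid] = sol.status
                break
            endpoints.append(sol.objective)
        if len(endpoints) == 2:
            lo, hi = endpoints
            if abs(lo) < config.tolerance:
                lo = 0.0
            if abs(hi) < config.tolerance:
                hi = 0.0
            if lo > hi:  # solver round-off on a point range
                lo = hi = 0.5 * (lo + hi)
            ranges[rid] = (lo, hi)
    return FVAResult(ranges=ranges, config=config, failures=failures)
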