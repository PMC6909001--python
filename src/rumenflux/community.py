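"""Bilevel community model with a shared metabolite pool (OptCom form).

Each member keeps its own FBA problem (maximize own biomass subject to
mass balance and bounds) as an *inner* problem; the *outer* problem
chooses a community objective plus per-member uptake/export allocations
``r_uptake[i,k]`` and ``r_export[i,k]`` for every shared metabolite
``i``. The pool itself obeys, for every shared metabolite,

    e[i] + sum_k r_export[i,k]  =  u[i] + sum_k r_uptake[i,k]

where ``e[i]`` is community-level uptake from the environment (capped by
the diet) and ``u[i]`` community-level release. Inside each member the
allocations appear as equality constraints on dedicated uptake/export
pseudo-fluxes, so they enter the inner problems only through primal
right-hand sides.

The bilevel program is solved by replacing every inner LP with its KKT
conditions — stationarity, primal/dual feasibility, and complementary
slackness linearized with big-M binaries — yielding a single MILP. A
"joint" single-level LP (no inner optimality) is provided as a fast
cross-check; on cooperative toy communities the two coincide. Every
returned solution is re-checked post hoc by re-solving each inner LP with
the allocations fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import _milp
from .constants import BIG_M, BOUND, REPORT_TOL
from .lp_core import FVAConfig, FVAResult
from .model_io import MetabolicModel, Metabolite, Reaction

__all__ = [
    "CommunityModel",
    "CommunitySolution",
    "build_community",
    "solve_optcom",
    "community_fva",
    "biomass_objective",
]


def _ns(member_id: str, ident: str) -> str:
    return f"{member_id}:{ident}"


@dataclass
class CommunityModel:
    members: dict[str, MetabolicModel]  # namespaced working copies
    shared: list[str]  # base metabolite ids (pool compartment)
    diet: dict[str, float]  # base id -> max community uptake e[i]
    participation: dict[str, list[str]] = field(default_factory=dict)
    originals: dict[str, MetabolicModel] = field(default_factory=dict)

    @property
    def member_ids(self) -> list[str]:
        return list(self.members)

    def biomass_var(self, member_id: str) -> str:
        return self.members[member_id].biomass_reaction_id

    def uptake_var(self, member_id: str, met: str) -> str:
        return _ns(member_id, f"UPT_{met}")

    def export_var(self, member_id: str, met: str) -> str:
        return _ns(member_id, f"EXP_{met}")

    def reaction_vars(self) -> list[str]:
        return [rid for m in self.members.values() for rid in m.reaction_ids]


def build_community(
    members: list[MetabolicModel],
    shared: list[str],
    diet: dict[str, float],
) -> CommunityModel:
    """Assemble a community from standalone member models.

    Member metabolites and reactions are namespaced with the member id.
    For every shared metabolite present in a member's extracellular
    compartment, that member's exchange reaction is replaced by a pair of
    non-negative uptake/export pseudo-fluxes tied to the outer
    allocations; exchanges for non-shared metabolites become
    secretion-only (the pool is the sole nutrient source).
    """
    if not members:
        raise ValueError("community needs at least one member")
    participation: dict[str, list[str]] = {i: [] for i in shared}
    working: dict[str, MetabolicModel] = {}
    for member in members:
        member.validate()
        k = member.id
        nm = MetabolicModel(id=k, biomass_reaction_id=_ns(k, member.biomass_reaction_id))
        for met in member.metabolites:
            nm.metabolites.append(
                Metabolite(
                    id=_ns(k, met.id),
                    name=met.name,
                    formula=met.formula,
                    charge=met.charge,
                    compartment=met.compartment,
                )
            )
        shared_e = {f"{i}[e]": i for i in shared}
        for rxn in member.reactions:
            if rxn.is_exchange:
                (mid,) = rxn.stoichiometry
                if mid in shared_e:
                    continue  # replaced by UPT/EXP below
                new = rxn.copy()
                new.id = _ns(k, rxn.id)
                new.stoichiometry = {_ns(k, m): c for m, c in rxn.stoichiometry.items()}
                new.lb = max(new.lb, 0.0)  # secretion only
                nm.reactions.append(new)
                continue
            new = rxn.copy()
            new.id = _ns(k, rxn.id)
            new.stoichiometry = {_ns(k, m): c for m, c in rxn.stoichiometry.items()}
            nm.reactions.append(new)
        for eid, i in shared_e.items():
            if member.has_metabolite(eid):
                participation[i].append(k)
                nm.reactions.append(
                    Reaction(id=_ns(k, f"UPT_{i}"), stoichiometry={_ns(k, eid): 1.0},
                             lb=0.0, ub=BOUND)
                )
                nm.reactions.append(
                    Reaction(id=_ns(k, f"EXP_{i}"), stoichiometry={_ns(k, eid): -1.0},
                             lb=0.0, ub=BOUND)
                )
        nm.validate()
        working[k] = nm
    absent = [i for i in shared if not participation[i]]
    if absent:
        raise ValueError(f"shared metabolites absent from every member: {absent}")
    return CommunityModel(
        members=working,
        shared=list(shared),
        diet=dict(diet),
        participation=participation,
        originals={m.id: m for m in members},
    )


# ---------------------------------------------------------------------------
# Program assembly
# ---------------------------------------------------------------------------

def _member_rows(cm: CommunityModel, k: str):
    """Inner constraint rows of member k.

    Yields (row_name, coeffs_on_member_vars, outer_coeffs) where the full
    joint constraint is  coeffs . v + outer_coeffs . (r, e, u) = 0.
    """
    nm = cm.members[k]
    by_met: dict[str, dict[str, float]] = {m.id: {} for m in nm.metabolites}
    for rxn in nm.reactions:
        for mid, coeff in rxn.stoichiometry.items():
            by_met[mid][rxn.id] = by_met[mid].get(rxn.id, 0.0) + coeff
    for mid, coeffs in by_met.items():
        yield f"bal[{mid}]", coeffs, {}
    for i in cm.shared:
        if k in cm.participation[i]:
            yield (
                f"link_upt[{i},{k}]",
                {cm.uptake_var(k, i): 1.0},
                {f"r_upt[{i},{k}]": -1.0},
            )
            yield (
                f"link_exp[{i},{k}]",
                {cm.export_var(k, i): 1.0},
                {f"r_exp[{i},{k}]": -1.0},
            )


def _build_joint(cm: CommunityModel) -> _milp.Program:
    prog = _milp.Program()
    for k, nm in cm.members.items():
        for rxn in nm.reactions:
            prog.add_var(rxn.id, rxn.lb, rxn.ub)
    for i in cm.shared:
        prog.add_var(f"e[{i}]", 0.0, cm.diet.get(i, 0.0))
        prog.add_var(f"u[{i}]", 0.0, BOUND)
        for k in cm.participation[i]:
            prog.add_var(f"r_upt[{i},{k}]", 0.0, BOUND)
            prog.add_var(f"r_exp[{i},{k}]", 0.0, BOUND)
    for k in cm.member_ids:
        for _, coeffs, outer in _member_rows(cm, k):
            prog.add_eq({**coeffs, **outer}, 0.0)
    for i in cm.shared:
        coeffs = {f"e[{i}]": 1.0, f"u[{i}]": -1.0}
        for k in cm.participation[i]:
            coeffs[f"r_exp[{i},{k}]"] = 1.0
            coeffs[f"r_upt[{i},{k}]"] = -1.0
        prog.add_eq(coeffs, 0.0)
    return prog


def _add_kkt(prog: _milp.Program, cm: CommunityModel) -> None:
    """Append each member's KKT system (inner objective: own biomass)."""
    for k, nm in cm.members.items():
        rows = list(_member_rows(cm, k))
        # dual variables for inner equality rows
        for name, _, _ in rows:
            prog.add_var(f"lam[{k}|{name}]", -BIG_M, BIG_M)
        # bound duals + complementarity binaries per member variable
        stationarity: dict[str, dict[str, float]] = {rxn.id: {} for rxn in nm.reactions}
        for name, coeffs, _ in rows:
            for rid, a in coeffs.items():
                stationarity[rid][f"lam[{k}|{name}]"] = stationarity[rid].get(
                    f"lam[{k}|{name}]", 0.0
                ) - a
        for rxn in nm.reactions:
            rid = rxn.id
            mu_l = f"mu_l[{rid}]"
            mu_u = f"mu_u[{rid}]"
            prog.add_var(mu_l, 0.0, BIG_M)
            prog.add_var(mu_u, 0.0, BIG_M)
            c = 1.0 if rid == nm.biomass_reaction_id else 0.0
            # c - A^T lam + mu_l - mu_u = 0
            prog.add_eq({**stationarity[rid], mu_l: 1.0, mu_u: -1.0}, -c)
            span = rxn.ub - rxn.lb
            zl = f"z_l[{rid}]"
            zu = f"z_u[{rid}]"
            prog.add_binary(zl)
            prog.add_binary(zu)
            prog.add_le({mu_l: 1.0, zl: -BIG_M}, 0.0)
            prog.add_le({mu_u: 1.0, zu: -BIG_M}, 0.0)
            # v - lb <= span*(1 - z_l);  ub - v <= span*(1 - z_u)
            prog.add_le({rid: 1.0, zl: span}, rxn.ub)
            prog.add_le({rid: -1.0, zu: span}, -rxn.lb)


# ---------------------------------------------------------------------------
# Solutions
# ---------------------------------------------------------------------------

@dataclass
class CommunitySolution:
    status: str
    objective_value: Optional[float]
    member_biomass: dict[str, float] = field(default_factory=dict)
    fluxes: dict[str, float] = field(default_factory=dict)
    allocations: dict[str, float] = field(default_factory=dict)  # r/e/u values
    pool_residual: dict[str, float] = field(default_factory=dict)
    inner_optimality: dict[str, tuple[float, float, bool]] = field(default_factory=dict)
    method: str = "kkt"

    @property
    def ok(self) -> bool:
        return self.status == _milp.OPTIMAL

    @property
    def inner_ok(self) -> bool:
        return all(flag for _, _, flag in self.inner_optimality.values())

    @property
    def community_biomass(self) -> float:
        return sum(self.member_biomass.values())


def biomass_objective(cm: CommunityModel, weights: Optional[dict[str, float]] = None
                      ) -> dict[str, float]:
    """Outer objective: (optionally weighted) sum of member biomass
    fluxes. Uniform weights reproduce the aggregate "community biomass
    flux"; abundance weights are the config-selectable variant."""
    weights = weights or {k: 1.0 for k in cm.member_ids}
    return {cm.biomass_var(k): w for k, w in weights.items()}


def _check_inner(cm: CommunityModel, values: dict[str, float],
                 tolerance: float = 1e-5) -> dict[str, tuple[float, float, bool]]:
    """Re-solve each inner LP with allocations fixed; returns
    (achieved biomass, re-solved optimum, agree?) per member."""
    out: dict[str, tuple[float, float, bool]] = {}
    for k, nm in cm.members.items():
        prog = _milp.Program()
        for rxn in nm.reactions:
            lb, ub = rxn.lb, rxn.ub
            prog.add_var(rxn.id, lb, ub)
        by_met: dict[str, dict[str, float]] = {m.id: {} for m in nm.metabolites}
        for rxn in nm.reactions:
            for mid, coeff in rxn.stoichiometry.items():
                by_met[mid][rxn.id] = by_met[mid].get(rxn.id, 0.0) + coeff
        for mid, coeffs in by_met.items():
            prog.add_eq(coeffs, 0.0)
        for i in cm.shared:
            if k in cm.participation[i]:
                r_u = values.get(f"r_upt[{i},{k}]", 0.0)
                r_e = values.get(f"r_exp[{i},{k}]", 0.0)
                prog.set_bounds(cm.uptake_var(k, i), r_u - tolerance, r_u + tolerance)
                prog.set_bounds(cm.export_var(k, i), r_e - tolerance, r_e + tolerance)
        prog.set_objective({nm.biomass_reaction_id: 1.0})
        sol = prog.solve(sense="max")
        achieved = values.get(nm.biomass_reaction_id, 0.0)
        resolved = sol.objective if sol.ok else float("nan")
        ok = sol.ok and abs(achieved - resolved) <= max(1e-4, 1e-4 * abs(resolved))
        out[k] = (achieved, resolved, ok)
    return out


def _pool_residuals(cm: CommunityModel, values: dict[str, float]) -> dict[str, float]:
    res = {}
    for i in cm.shared:
        total = values.get(f"e[{i}]", 0.0) - values.get(f"u[{i}]", 0.0)
        for k in cm.participation[i]:
            total += values.get(f"r_exp[{i},{k}]", 0.0) - values.get(f"r_upt[{i},{k}]", 0.0)
        res[i] = total
    return res


def solve_optcom(
    cm: CommunityModel,
    objective: dict[str, float],
    sense: str = "max",
    method: str = "kkt",
) -> CommunitySolution:
    """Solve the bilevel community problem.

    ``objective`` maps community variable names — member reaction fluxes,
    ``e[i]``, ``u[i]`` — to weights (see :func:`biomass_objective`).
    ``method="kkt"`` enforces inner optimality through the MILP
    reformulation; ``method="joint"`` drops it (single LP).
    """
    prog = _build_joint(cm)
    if method == "kkt":
        _add_kkt(prog, cm)
    elif method != "joint":
        raise ValueError(f"unknown method {method!r}")
    prog.set_objective(objective)
    sol = prog.solve(sense=sense)
    if not sol.ok:
        return CommunitySolution(status=sol.status, objective_value=None, method=method)
    values = sol.values
    member_biomass = {
        k: values[cm.biomass_var(k)] for k in cm.member_ids
    }
    alloc = {
        name: v
        for name, v in values.items()
        if name.startswith(("r_upt[", "r_exp[", "e[", "u["))
    }
    solution = CommunitySolution(
        status=sol.status,
        objective_value=sol.objective,
        member_biomass=member_biomass,
        fluxes={rid: values[rid] for rid in cm.reaction_vars()},
        allocations=alloc,
        pool_residual=_pool_residuals(cm, values),
        method=method,
    )
    solution.inner_optimality = _check_inner(cm, values)
    return solution


def community_fva(
    cm: CommunityModel,
    objective: dict[str, float],
    objective_value: float,
    reactions: Optional[list[str]] = None,
    sense: str = "max",
    method: str = "kkt",
    tolerance: float = REPORT_TOL,
) -> FVAResult:
    """Min/max of community variables with the outer objective fixed at
    its optimum (and, under ``method="kkt"``, inner optimality still
    enforced). ``reactions`` may name member fluxes or pool variables;
    default is every member reaction flux.
    """
    prog = _build_joint(cm)
    if method == "kkt":
        _add_kkt(prog, cm)
    tol = max(tolerance, 1e-6 * max(1.0, abs(objective_value)))
    prog.add_constr(objective, objective_value - tol, objective_value + tol)
    rids = reactions if reactions is not None else cm.reaction_vars()
    ranges: dict[str, tuple[float, float]] = {}
    failures: dict[str, str] = {}
    for rid in rids:
        if rid.startswith("net["):
            # net member exchange EXP - UPT: immune to the pool-level
            # futile circulation the raw allocations admit
            i, k = rid[4:-1].split(",")
            expr = {f"r_exp[{i},{k}]": 1.0, f"r_upt[{i},{k}]": -1.0}
        else:
            expr = {rid: 1.0}
        endpoints = []
        for s in ("min", "max"):
            prog.set_objective(expr)
            sol = prog.solve(sense=s)
            if not sol.ok:
                failures[rid] = sol.status
                break
            endpoints.append(sol.objective)
        if len(endpoints) == 2:
            lo, hi = endpoints
            if abs(lo) < tolerance:
                lo = 0.0
            if abs(hi) < tolerance:
                hi = 0.0
            if lo > hi:
                lo = hi = 0.5 * (lo + hi)
            ranges[rid] = (lo, hi)
    cfg = FVAConfig(objective_fix=None, tolerance=tolerance)
    return FVAResult(ranges=ranges, config=cfg, failures=failures)
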