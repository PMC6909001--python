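"""GapFind / GapFill: problem-metabolite detection and minimal network
completion as mixed-integer linear programs.

A *problem metabolite* is one that no feasible flux distribution can
produce (or consume) at a rate of at least epsilon. GapFind couples a
production indicator binary to every potentially producing (metabolite,
reaction) pair and maximizes the number of metabolites produced in a
single flux distribution; metabolites left at zero are the gaps. As in
the original method, the mass balance is relaxed one-sidedly to
``S v >= 0`` so that downstream accumulation never masks an upstream
production route (a terminal dead-end metabolite is a no-consumption
problem, not a no-production one). The consumption run mirrors this: each
metabolite may be drawn from an external supply, and a metabolite is
consumable when some reaction can drain it at >= epsilon given that
supply. GapFill then searches a designated reaction database for the
smallest set of additions that makes one target producible (same relaxed
balance), with alternate optima enumerated by integer cuts.

Epsilon and big-M follow the original GapFind/GapFill convention
(epsilon = 0.001, M = 1000); per-pair M values are scaled by the
stoichiometric coefficient so large coefficients cannot truncate the flux
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from . import _milp
from .constants import BIG_M, BOUND, EPS_PRODUCTION
from .model_io import DbEntry, MetabolicModel, Reaction, ReactionDatabase

__all__ = [
    "GapReport",
    "GapFillCandidate",
    "gapfind",
    "gapfill",
    "member_as_db",
    "apply_candidate",
]


@dataclass
class GapReport:
    no_production: list[str] = field(default_factory=list)
    no_consumption: list[str] = field(default_factory=list)
    root_no_production: list[str] = field(default_factory=list)
    downstream_no_production: list[str] = field(default_factory=list)

    @property
    def problem_metabolites(self) -> list[str]:
        return sorted(set(self.no_production) | set(self.no_consumption))


@dataclass
class GapFillCandidate:
    target: str
    added_reaction_ids: list[str]
    reactions: list[Reaction]
    source: str  # member id or "universal"
    cardinality: int
    solution_index: int  # 1 = optimal, >1 = integer-cut alternates
    taxa: dict[str, list[str]] = field(default_factory=dict)


def _producing_pairs(model: MetabolicModel, mirror: bool) -> dict[str, list[tuple[str, float]]]:
    """For each metabolite, the (reaction, signed coefficient) pairs that
    can produce it. ``mirror=True`` swaps production and consumption."""
    sign = -1.0 if mirror else 1.0
    pairs: dict[str, list[tuple[str, float]]] = {m.id: [] for m in model.metabolites}
    for rxn in model.reactions:
        for mid, coeff in rxn.stoichiometry.items():
            s = sign * coeff
            if s > 0 or (s < 0 and rxn.reversible):
                pairs[mid].append((rxn.id, s))
    return pairs


def _gapfind_side(
    model: MetabolicModel, mirror: bool, eps: float, metabolites: Optional[list[str]]
) -> list[str]:
    prog = _milp.Program()
    for rxn in model.reactions:
        prog.add_var(rxn.id, rxn.lb, rxn.ub)
    by_met: dict[str, dict[str, float]] = {m.id: {} for m in model.metabolites}
    for rxn in model.reactions:
        for mid, coeff in rxn.stoichiometry.items():
            by_met[mid][rxn.id] = by_met[mid].get(rxn.id, 0.0) + coeff
    for mid, coeffs in by_met.items():
        row = dict(coeffs)
        if mirror:
            # consumption run: external supply may feed each metabolite
            supply = f"s[{mid}]"
            prog.add_var(supply, 0.0, BIG_M)
            row[supply] = 1.0
        # one-sided balance: accumulation allowed, drains need sources
        prog.add_ge(row, 0.0)

    targets = metabolites if metabolites is not None else [m.id for m in model.metabolites]
    pairs = _producing_pairs(model, mirror)
    objective: dict[str, float] = {}
    for mid in targets:
        xname = f"x[{mid}]"
        prog.add_binary(xname)
        objective[xname] = 1.0
        wnames = []
        for rid, s in pairs[mid]:
            wname = f"w[{mid}|{rid}]"
            prog.add_binary(wname)
            wnames.append(wname)
            big = max(BIG_M, abs(s) * max(abs(model.reaction(rid).lb),
                                          abs(model.reaction(rid).ub), BOUND))
            # s*v >= eps*w - big*(1-w)
            prog.add_ge({rid: s, wname: -(eps + big)}, -big)
        if wnames:
            prog.add_le({xname: 1.0, **{w: -1.0 for w in wnames}}, 0.0)
        else:
            prog.add_le({xname: 1.0}, 0.0)
    prog.set_objective(objective)
    sol = prog.solve(sense="max")
    if not sol.ok:
        raise RuntimeError(f"GapFind MILP not optimal: status {sol.status}")
    return sorted(mid for mid in targets if sol[f"x[{mid}]"] < 0.5)


def _reachability_split(model: MetabolicModel, gaps: list[str]) -> tuple[list[str], list[str]]:
    """Root gaps vs gaps reachable (through the metabolite graph) from
    another gap — a reporting aid for prioritizing fixes."""
    g = nx.DiGraph()
    for rxn in model.reactions:
        consumed = [m for m, c in rxn.stoichiometry.items() if c < 0]
        produced = [m for m, c in rxn.stoichiometry.items() if c > 0]
        for a in consumed:
            for b in produced:
                g.add_edge(a, b)
                if rxn.reversible:
                    g.add_edge(b, a)
    gapset = set(gaps)
    downstream = set()
    for gap in gaps:
        if gap not in g:
            continue
        for other in gapset - {gap}:
            if other in g and nx.has_path(g, gap, other):
                downstream.add(other)
    roots = sorted(gapset - downstream)
    return roots, sorted(downstream)


def gapfind(
    model: MetabolicModel,
    eps: float = EPS_PRODUCTION,
    metabolites: Optional[list[str]] = None,
    open_exchanges: bool = True,
    both_directions: bool = True,
) -> GapReport:
    """Identify no-production and no-consumption metabolites.

    By default exchanges are opened to the artificial bounds so that a gap
    reflects missing network structure, not a closed medium; pass
    ``open_exchanges=False`` to analyze the model under its current (e.g.
    diet-limited) bounds. The no-consumption side is the same MILP run on
    the mirrored stoichiometric matrix.
    """
    model.validate()
    if open_exchanges:
        from .curation import open_all_exchanges

        model = open_all_exchanges(model)
    no_production = _gapfind_side(model, mirror=False, eps=eps, metabolites=metabolites)
    no_consumption = (
        _gapfind_side(model, mirror=True, eps=eps, metabolites=metabolites)
        if both_directions
        else []
    )
    roots, downstream = _reachability_split(model, no_production)
    return GapReport(
        no_production=no_production,
        no_consumption=no_consumption,
        root_no_production=roots,
        downstream_no_production=downstream,
    )


def _entry_is_redundant(model: MetabolicModel, entry: DbEntry) -> bool:
    from .model_io import is_redundant_reaction

    return is_redundant_reaction(model, entry.reaction)


def gapfill(
    model: MetabolicModel,
    target: str,
    db: ReactionDatabase,
    max_alternates: int = 5,
    eps: float = EPS_PRODUCTION,
    cardinality_slack: int = 0,
    relax_reversibility: bool = False,
    open_exchanges: bool = True,
) -> list[GapFillCandidate]:
    """Minimal reaction additions from ``db`` that make ``target``
    producible at >= eps.

    Returns the optimum plus integer-cut alternates (up to
    ``max_alternates`` total, stopping once cardinality exceeds the
    optimum by more than ``cardinality_slack``). An empty list means no
    fill exists in this database — a normal outcome, not an error.
    ``relax_reversibility`` additionally offers the reverse of each
    irreversible model reaction as a candidate (off by default; transport
    solutions are emphasized instead).
    """
    if open_exchanges:
        from .curation import open_all_exchanges

        model = open_all_exchanges(model)
    work = model.copy()
    candidates: list[tuple[str, Reaction, list[str]]] = []  # (var, reaction, taxa)
    for entry in db.entries:
        if _entry_is_redundant(work, entry):
            continue
        rxn = entry.reaction.copy()
        candidates.append((rxn.id, rxn, list(entry.taxa)))
    if relax_reversibility:
        for rxn in model.reactions:
            if not rxn.reversible and not rxn.is_exchange and not rxn.is_biomass:
                rev = Reaction(
                    id=f"REV_{rxn.id}",
                    stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
                    lb=0.0,
                    ub=BOUND,
                )
                candidates.append((rev.id, rev, []))
    if not candidates:
        return []

    # Union network: model + candidates (+ any new metabolites) + target sink.
    for _, rxn, _ in candidates:
        work.add_reaction(rxn, create_missing_metabolites=True)
    if not work.has_metabolite(target):
        return []
    sink = Reaction(id="__gapfill_sink__", stoichiometry={target: -1.0}, lb=eps, ub=BOUND)
    work.add_reaction(sink)

    prog = _milp.Program()
    for rxn in work.reactions:
        prog.add_var(rxn.id, rxn.lb, rxn.ub)
    by_met: dict[str, dict[str, float]] = {m.id: {} for m in work.metabolites}
    for rxn in work.reactions:
        for mid, coeff in rxn.stoichiometry.items():
            by_met[mid][rxn.id] = by_met[mid].get(rxn.id, 0.0) + coeff
    for mid, coeffs in by_met.items():
        # same one-sided balance as GapFind: accumulation never blocks a fill
        prog.add_ge(coeffs, 0.0)

    # Lexicographic tie-break: a tiny, id-ordered perturbation far below
    # the unit cardinality cost.
    ordered = sorted(c[0] for c in candidates)
    delta = {rid: 1e-6 * (k + 1) / len(ordered) for k, rid in enumerate(ordered)}
    objective: dict[str, float] = {}
    for rid, rxn, _ in candidates:
        yname = f"y[{rid}]"
        prog.add_binary(yname)
        prog.add_le({rid: 1.0, yname: -rxn.ub}, 0.0)
        prog.add_ge({rid: 1.0, yname: -rxn.lb}, 0.0)
        objective[yname] = 1.0 + delta[rid]
    prog.set_objective(objective)

    taxa_by_id = {rid: taxa for rid, _, taxa in candidates}
    rxn_by_id = {rid: rxn for rid, rxn, _ in candidates}
    out: list[GapFillCandidate] = []
    best: Optional[int] = None
    for index in range(1, max_alternates + 1):
        sol = prog.solve(sense="min")
        if not sol.ok:
            break
        chosen = sorted(rid for rid, _, _ in candidates if sol[f"y[{rid}]"] > 0.5)
        card = len(chosen)
        if best is None:
            best = card
        if card > best + cardinality_slack:
            break
        out.append(
            GapFillCandidate(
                target=target,
                added_reaction_ids=chosen,
                reactions=[rxn_by_id[rid].copy() for rid in chosen],
                source=db.source,
                cardinality=card,
                solution_index=index,
                taxa={rid: taxa_by_id[rid] for rid in chosen},
            )
        )
        # integer cut: exclude this exact solution
        prog.add_le({f"y[{rid}]": 1.0 for rid in chosen}, card - 1)
    return out


def member_as_db(member: MetabolicModel) -> ReactionDatabase:
    """Export a member's internal and transport reactions as a gap-fill
    source database (exchange and biomass reactions excluded), tagged
    with the member id."""
    entries = [
        DbEntry(reaction=r.copy(), taxa=[member.id])
        for r in member.reactions
        if not r.is_exchange and not r.is_biomass
    ]
    return ReactionDatabase(entries=entries, source=member.id)


def apply_candidate(model: MetabolicModel, candidate: GapFillCandidate) -> MetabolicModel:
    """Copy of ``model`` with a candidate's reactions added (duplicates by
    stoichiometry signature are skipped)."""
    from .model_io import is_redundant_reaction

    out = model.copy()
    for rxn in candidate.reactions:
        if is_redundant_reaction(out, rxn):
            continue
        out.add_reaction(rxn.copy(), create_missing_metabolites=True)
    return out
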