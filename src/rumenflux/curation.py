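"""Model curation diagnostics.

Mirrors the manual curation steps applied to draft reconstructions:

* elemental/charge balance checks (exact arithmetic over rationals);
* single-step proton-fix suggestions for reactions imbalanced only in H
  and charge;
* detection of "unbounded" reactions — fluxes that hit the artificial
  bound with every nutrient uptake closed, the operational signature of a
  thermodynamically infeasible cycle (TIC);
* grouping of unbounded reactions by the exact rational null basis of the
  internal stoichiometric matrix;
* blocked-reaction detection (FVA range exactly zero under open
  exchanges) and duplicate/cofactor-variant reaction detection.

Repair is deliberately a report plus a user choice, not an automatic
deletion: which member of a loop group to remove or make irreversible is
a judgment call (cofactor specificity, lumped reactions), so the package
only offers :func:`constrain_loop_representative` as a helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import sympy

from .constants import BOUND, UNBOUNDED_FRACTION
from .lp_core import FVAConfig, fva
from .model_io import MetabolicModel, Reaction

__all__ = [
    "BalanceReport",
    "LoopReport",
    "DuplicateRecord",
    "check_balance",
    "suggest_proton_fix",
    "find_unbounded",
    "group_loops",
    "find_blocked",
    "find_duplicates",
    "constrain_loop_representative",
    "open_all_exchanges",
    "close_all_exchanges",
]


# ---------------------------------------------------------------------------
# Balance
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    element_net: dict[str, dict[str, Fraction]]  # reaction -> element -> net
    charge_net: dict[str, Optional[Fraction]]
    imbalanced: list[str] = field(default_factory=list)
    unbalanceable: list[str] = field(default_factory=list)  # unknown formulas
    skipped: list[str] = field(default_factory=list)  # exchange/biomass

    def is_balanced(self, rid: str) -> bool:
        nets = self.element_net.get(rid, {})
        charge = self.charge_net.get(rid)
        return all(v == 0 for v in nets.values()) and (charge is None or charge == 0)


def _frac(x: float) -> Fraction:
    return Fraction(x).limit_denominator(10**6)


def check_balance(model: MetabolicModel) -> BalanceReport:
    """Exact element and charge bookkeeping for every reaction.

    Exchange and biomass reactions are inherently imbalanced (they move
    mass across the system boundary / into biomass) and are listed under
    ``skipped``. Reactions touching a metabolite with an unknown formula
    are ``unbalanceable`` rather than imbalanced.
    """
    mets = {m.id: m for m in model.metabolites}
    report = BalanceReport(element_net={}, charge_net={})
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.is_biomass:
            report.skipped.append(rxn.id)
            continue
        nets: dict[str, Fraction] = {}
        charge: Optional[Fraction] = Fraction(0)
        unknown = False
        for mid, coeff in rxn.stoichiometry.items():
            met = mets[mid]
            elements = met.elements
            if elements is None:
                unknown = True
                break
            c = _frac(coeff)
            for element, count in elements.items():
                nets[element] = nets.get(element, Fraction(0)) + c * count
            if met.charge is None:
                charge = None
            elif charge is not None:
                charge += c * met.charge
        if unknown:
            report.unbalanceable.append(rxn.id)
            continue
        nets = {e: v for e, v in nets.items() if v != 0}
        report.element_net[rxn.id] = nets
        report.charge_net[rxn.id] = charge
        if nets or (charge is not None and charge != 0):
            report.imbalanced.append(rxn.id)
    return report


def suggest_proton_fix(model: MetabolicModel, reaction_id: str) -> Optional[int]:
    """Signed proton count that balances a reaction imbalanced only in H
    and charge by the same integer.

    The returned value is the number of protons to add to the *reactant*
    side (negative = add to the product side). Returns ``None`` when the
    imbalance is not proton-shaped.
    """
    report = check_balance(model)
    if reaction_id not in report.element_net:
        return None
    nets = dict(report.element_net[reaction_id])
    charge = report.charge_net[reaction_id]
    h = nets.pop("H", Fraction(0))
    if nets:  # imbalanced in something other than hydrogen
        return None
    if h == 0:
        return None
    if charge is not None and charge != h:
        return None
    if h.denominator != 1:
        return None
    return int(h)


# ---------------------------------------------------------------------------
# Exchange toggling helpers
# ---------------------------------------------------------------------------

def close_all_exchanges(model: MetabolicModel) -> MetabolicModel:
    """Copy with every exchange flux pinned to zero (no nutrient uptake,
    no secretion)."""
    out = model.copy()
    for rxn in out.reactions:
        if rxn.is_exchange:
            rxn.lb = 0.0
            rxn.ub = 0.0
    return out


def open_all_exchanges(model: MetabolicModel, bound: float = BOUND) -> MetabolicModel:
    """Copy with every exchange opened to the default bounds."""
    out = model.copy()
    for rxn in out.reactions:
        if rxn.is_exchange:
            rxn.lb = -bound
            rxn.ub = bound
    return out


# ---------------------------------------------------------------------------
# Unbounded reactions & loop groups
# ---------------------------------------------------------------------------

@dataclass
class LoopReport:
    unbounded: list[str] = field(default_factory=list)
    groups: list[dict[str, Fraction]] = field(default_factory=list)
    blocked: list[str] = field(default_factory=list)

    @property
    def group_supports(self) -> list[set[str]]:
        return [set(g) for g in self.groups]


def find_unbounded(
    model: MetabolicModel,
    whitelist: Optional[set[str]] = None,
    threshold: float = UNBOUNDED_FRACTION * BOUND,
) -> LoopReport:
    """Internal reactions that hit the artificial bound with all
    exchanges closed.

    With no nutrient uptake, any non-zero steady-state flux must circulate
    in a stoichiometric cycle with zero net conversion — a TIC. FVA under
    closed exchanges therefore drives exactly the TIC members to the
    artificial bound. ``whitelist`` names reactions to ignore (e.g.
    nucleotide-degradation loops deemed harmless).
    """
    closed = close_all_exchanges(model)
    internal = [r.id for r in closed.reactions if not r.is_exchange]
    result = fva(closed, reactions=internal)
    unbounded = [
        rid
        for rid, (lo, hi) in result.ranges.items()
        if (abs(lo) >= threshold or abs(hi) >= threshold)
        and rid not in (whitelist or set())
    ]
    return LoopReport(unbounded=sorted(unbounded))


def group_loops(model: MetabolicModel, unbounded_ids: list[str]) -> LoopReport:
    """Group unbounded reactions by the exact null basis of the internal
    stoichiometric matrix.

    The null space is computed over the rationals on the integer-scaled
    matrix, so supports are exact (no spurious near-zero entries). Each
    basis vector whose support meets the unbounded set yields one group;
    the group's coefficients are the null-space weights of the cycle.
    """
    internal = [r for r in model.reactions if not r.is_exchange]
    rids = [r.id for r in internal]
    met_ids = {m.id: i for i, m in enumerate(model.metabolites)}
    S = sympy.zeros(len(met_ids), len(internal))
    for j, rxn in enumerate(internal):
        for mid, coeff in rxn.stoichiometry.items():
            S[met_ids[mid], j] += sympy.Rational(Fraction(coeff).limit_denominator(10**6))
    unbounded = set(unbounded_ids)
    groups: list[dict[str, Fraction]] = []
    for vec in S.nullspace():
        # scale to integers for readability
        denominators = [sympy.Rational(v).q for v in vec if v != 0]
        scale = sympy.ilcm(*denominators) if denominators else 1
        support = {
            rids[j]: Fraction(int(sympy.Rational(vec[j] * scale).p),
                              int(sympy.Rational(vec[j] * scale).q))
            for j in range(len(rids))
            if vec[j] != 0
        }
        if support and set(support) & unbounded:
            groups.append(support)
    return LoopReport(unbounded=sorted(unbounded), groups=groups)


def constrain_loop_representative(
    model: MetabolicModel, group: dict[str, Fraction] | set[str]
) -> MetabolicModel:
    """Copy with one representative of a loop group turned off
    (first id lexicographically).

    A directed cycle can circulate even when every member is
    irreversible, so breaking the loop requires disabling a member, not
    merely restricting its direction — the "selectively turn reactions
    on/off" repair. Which member to disable is ultimately a curation
    judgment; this helper just picks deterministically.
    """
    ids = sorted(group)
    out = model.copy()
    rep = out.reaction(ids[0])
    rep.lb = 0.0
    rep.ub = 0.0
    return out


# ---------------------------------------------------------------------------
# Blocked reactions
# ---------------------------------------------------------------------------

def find_blocked(model: MetabolicModel, tolerance: float = 1e-6) -> list[str]:
    """Reactions whose FVA range is (0, 0) with all exchanges open."""
    opened = open_all_exchanges(model)
    result = fva(opened, config=FVAConfig(tolerance=tolerance))
    return sorted(
        rid for rid, (lo, hi) in result.ranges.items() if lo == 0.0 and hi == 0.0
    )


# ---------------------------------------------------------------------------
# Duplicates
# ---------------------------------------------------------------------------

@dataclass
class DuplicateRecord:
    pair: tuple[str, str]
    orientation: str  # "same" | "reversed"
    cofactor_variant: bool = False


def _apply_cofactor_map(rxn: Reaction, mapping: dict[str, str]) -> dict[str, float]:
    from .model_io import base_id, compartment_of

    out: dict[str, float] = {}
    for mid, coeff in rxn.stoichiometry.items():
        base = base_id(mid)
        comp = compartment_of(mid)
        if base in mapping:
            mid = f"{mapping[base]}[{comp}]" if comp else mapping[base]
        out[mid] = out.get(mid, 0.0) + coeff
    return out


def _signature(stoich: dict[str, float]) -> tuple:
    items = tuple(sorted(stoich.items()))
    flipped = tuple(sorted((k, -v) for k, v in stoich.items()))
    return min(items, flipped)


def find_duplicates(
    model: MetabolicModel,
    cofactor_pairs: Optional[list[tuple[str, str]]] = None,
) -> list[DuplicateRecord]:
    """Pairs of reactions with identical (or sign-flipped identical)
    stoichiometry; with a cofactor-pair config (e.g. NAD<->NADP,
    NADH<->NADPH), pairs differing only by that swap are flagged as
    cofactor variants.
    """
    records: list[DuplicateRecord] = []
    mapping: dict[str, str] = {}
    for a, b in cofactor_pairs or []:
        mapping[a] = b
        mapping[b] = a
    seen: dict[tuple, Reaction] = {}
    for rxn in model.reactions:
        sig = _signature(rxn.stoichiometry)
        if sig in seen:
            other = seen[sig]
            orientation = (
                "same"
                if tuple(sorted(rxn.stoichiometry.items()))
                == tuple(sorted(other.stoichiometry.items()))
                else "reversed"
            )
            records.append(DuplicateRecord(pair=(other.id, rxn.id), orientation=orientation))
        else:
            seen[sig] = rxn
    if mapping:
        by_sig = {}
        for rxn in model.reactions:
            by_sig.setdefault(_signature(rxn.stoichiometry), []).append(rxn)
        mapped: dict[tuple, Reaction] = {}
        for rxn in model.reactions:
            mapped_sig = _signature(_apply_cofactor_map(rxn, mapping))
            if mapped_sig == _signature(rxn.stoichiometry):
                continue  # does not involve the cofactors
            partners = by_sig.get(mapped_sig, [])
            for other in partners:
                if other.id < rxn.id:  # report each unordered pair once
                    records.append(
                        DuplicateRecord(
                            pair=(other.id, rxn.id),
                            orientation="same",
                            cofactor_variant=True,
                        )
                    )
    return records
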