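"""Independent oracles used by the test suite.

These deliberately avoid the package's LP/MILP code paths: the FBA oracle
enumerates basic solutions of the flux polytope by brute force, and the
gap-fill oracle enumerates reaction subsets and checks each with a direct
HiGHS feasibility LP built from raw arrays.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from rumenflux.model_io import MetabolicModel, Metabolite, Reaction


def random_lp_model(rng: np.random.Generator, max_reactions: int = 6) -> MetabolicModel:
    """Random small network with integer stoichiometry and integer bounds
    that always contains v = 0 (so the FBA LP is feasible)."""
    n_mets = int(rng.integers(2, 5))
    n_rxns = int(rng.integers(3, max_reactions + 1))
    model = MetabolicModel(id="rand", biomass_reaction_id="")
    for i in range(n_mets):
        model.metabolites.append(Metabolite(id=f"m{i}[c]", compartment="c"))
    for j in range(n_rxns):
        stoich = {}
        for i in range(n_mets):
            coeff = int(rng.integers(-2, 3))
            if coeff:
                stoich[f"m{i}[c]"] = float(coeff)
        if not stoich:
            stoich[f"m{int(rng.integers(0, n_mets))}[c]"] = 1.0
        lb = float(rng.integers(-10, 1))
        ub = float(rng.integers(0, 11))
        model.reactions.append(Reaction(id=f"r{j}", stoichiometry=stoich, lb=lb, ub=ub))
    model.biomass_reaction_id = model.reactions[-1].id
    return model


def vertex_enumeration_optimum(model: MetabolicModel, objective: str, sense: str = "max"):
    """Exhaustive optimum of max/min v_obj over {S v = 0, lb <= v <= ub}.

    Every vertex of the polytope has some subset of variables pinned at a
    bound with the remainder determined by the equalities; enumerating all
    subsets and bound assignments therefore covers every vertex (plus
    interior candidates, which can only be suboptimal or equal).
    """
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds()
    n = len(model.reactions)
    obj_index = model.reaction_ids.index(objective)
    best = None
    for r in range(n + 1):
        for fixed in itertools.combinations(range(n), r):
            free = [j for j in range(n) if j not in fixed]
            for assignment in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
                v = np.zeros(n)
                for j, val in zip(fixed, assignment):
                    v[j] = val
                if free:
                    rhs = -S[:, list(fixed)] @ np.array(assignment) if fixed else np.zeros(
                        S.shape[0]
                    )
                    sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                    v[free] = sol
                if np.max(np.abs(S @ v)) > 1e-7:
                    continue
                if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                    continue
                value = v[obj_index]
                if best is None:
                    best = value
                elif sense == "max":
                    best = max(best, value)
                else:
                    best = min(best, value)
    return best


def _feasible_with_subset(model: MetabolicModel, subset, target: str, eps: float) -> bool:
    """Direct LP feasibility: model + chosen db reactions + target sink,
    one-sided balance S v >= 0 (the gap-fill producibility notion)."""
    work = model.copy()
    for entry in subset:
        rxn = entry.reaction
        sig = rxn.signature()
        if any(r.signature() == sig for r in work.reactions) or work.has_reaction(rxn.id):
            continue
        work.add_reaction(rxn.copy(), create_missing_metabolites=True)
    if not work.has_metabolite(target):
        return False
    work.add_reaction(
        Reaction(id="__sink__", stoichiometry={target: -1.0}, lb=eps, ub=1000.0)
    )
    S = work.stoichiometric_matrix().toarray()
    lb, ub = work.bounds()
    res = linprog(
        np.zeros(len(work.reactions)),
        A_ub=-S,
        b_ub=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res.status == 0


def brute_force_min_fill(model: MetabolicModel, target: str, db, eps: float = 1e-3,
                         max_size: int = 3):
    """Smallest db subset (cardinality, or None) making target producible,
    by exhaustive enumeration up to ``max_size``."""
    from rumenflux.curation import open_all_exchanges

    opened = open_all_exchanges(model)
    entries = list(db.entries)
    for size in range(0, max_size + 1):
        for subset in itertools.combinations(entries, size):
            if _feasible_with_subset(opened, subset, target, eps):
                return size
    return None
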