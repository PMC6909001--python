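"""Synthetic toy communities with planted, machine-readable ground truth.

Every pipeline stage is testable without external data: the generator
emits K-member communities sharing an extracellular pool, with planted

* no-production / no-consumption problem metabolites (on branches whose
  removal does not zero biomass, so gap tests stay decoupled from growth
  tests),
* donor-exporter / receiver-transporter cross-feeding pairs (the
  receiver lacks the transporter; the universal database contains it,
  and the transporter knowledgebase carries the receiver's evidence),
* closed stoichiometric cycles (thermodynamically infeasible loops),
* capacity bottlenecks with viral-AMG reaction sets that bypass them,

together with the diet, taxonomy, universal database, knowledgebase,
objective-set membership, and an exact truth table.

:func:`make_toy3` is the deterministic named fixture used throughout the
documentation and tests. Its three members mirror the functional guilds
of the rumen: a polysaccharide degrader (X, ferments glucose to acetate
and hydrogen), a secondary consumer (Y, grows on glucose or — once the
planted acetate transporter is restored — on acetate), and a
hydrogenotrophic methanogen (Z, consumes hydrogen and CO2 from the pool
and releases methane).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .amg import AMGSet, apply_amg
from .constants import BOUND
from .interactions import TaxonomyConfig, TransporterKB
from .model_io import (
    DbEntry,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionDatabase,
    write_model,
    write_reaction_db,
)
from .objectives import ObjectiveSets

__all__ = [
    "SyntheticSpec",
    "TruthTable",
    "Bundle",
    "generate_community",
    "make_toy3",
    "load_bundle",
]


@dataclass
class SyntheticSpec:
    seed: int = 1
    n_members: int = 3
    pathway_len: int = 3
    n_gaps: int = 3  # pure gaps, in addition to one per cross-feed
    n_cross_feeds: int = 1
    n_cycles: int = 1
    n_deadends: int = 1
    n_amg: int = 1
    uptake: float = 10.0
    bounds_scale: float = 1.0

    def validate(self) -> None:
        if self.n_members < 1 or self.pathway_len < 2:
            raise ValueError("need >= 1 member and pathway length >= 2")
        if self.n_cross_feeds > self.n_members * (self.n_members - 1):
            raise ValueError(
                f"{self.n_cross_feeds} cross-feeds exceed what "
                f"{self.n_members} members support"
            )
        for name in ("n_gaps", "n_cycles", "n_deadends", "n_amg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_amg > self.n_members:
            raise ValueError("at most one AMG set per member")


@dataclass
class TruthTable:
    no_production: list[tuple[str, str]] = field(default_factory=list)  # (member, met)
    no_consumption: list[tuple[str, str]] = field(default_factory=list)
    cross_feeds: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (member, sorted reaction-id tuple)
    cycles: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    blocked: dict[str, list[str]] = field(default_factory=dict)
    amg_bottleneck: dict[str, str] = field(default_factory=dict)
    amg_expected_widened: dict[str, list[str]] = field(default_factory=dict)

    def gaps_of(self, member_id: str) -> list[str]:
        return sorted(m for k, m in self.no_production if k == member_id)

    def to_dict(self) -> dict:
        return {
            "no_production": sorted(self.no_production),
            "no_consumption": sorted(self.no_consumption),
            "cross_feeds": sorted(self.cross_feeds),
            "cycles": sorted((k, list(c)) for k, c in self.cycles),
            "blocked": {k: sorted(v) for k, v in sorted(self.blocked.items())},
            "amg_bottleneck": dict(sorted(self.amg_bottleneck.items())),
            "amg_expected_widened": {
                k: sorted(v) for k, v in sorted(self.amg_expected_widened.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTable":
        return cls(
            no_production=[tuple(x) for x in d.get("no_production", [])],
            no_consumption=[tuple(x) for x in d.get("no_consumption", [])],
            cross_feeds=[tuple(x) for x in d.get("cross_feeds", [])],
            cycles=[(k, tuple(c)) for k, c in d.get("cycles", [])],
            blocked={k: list(v) for k, v in d.get("blocked", {}).items()},
            amg_bottleneck=dict(d.get("amg_bottleneck", {})),
            amg_expected_widened={
                k: list(v) for k, v in d.get("amg_expected_widened", {}).items()
            },
        )


@dataclass
class Bundle:
    members: list[MetabolicModel]
    truth: TruthTable
    shared: list[str]
    diet: dict[str, float]
    kb: TransporterKB
    tax: TaxonomyConfig
    universal_db: ReactionDatabase
    amg_sets: dict[str, AMGSet]
    objective_sets: ObjectiveSets
    spec: Optional[SyntheticSpec] = None

    def member(self, member_id: str) -> MetabolicModel:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def filled_members(self) -> list[MetabolicModel]:
        """Members with the planted cross-feed transporters restored in
        their receivers — the post-gap-fill models used for community
        simulation."""
        out = {m.id: m.copy() for m in self.members}
        for _, receiver, _, transporter_id in self.truth.cross_feeds:
            entry = self.universal_db.get(transporter_id)
            model = out[receiver]
            if not model.has_reaction(transporter_id):
                model.add_reaction(entry.reaction.copy(), create_missing_metabolites=True)
        return [out[m.id] for m in self.members]

    def amg_members(self) -> list[MetabolicModel]:
        """Filled members additionally augmented with their AMG sets."""
        out = []
        for m in self.filled_members():
            if m.id in self.amg_sets:
                out.append(apply_amg(m, self.amg_sets[m.id]).model)
            else:
                out.append(m)
        return out

    # ---- emission ------------------------------------------------------
    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        (directory / "models").mkdir(parents=True, exist_ok=True)
        (directory / "amg").mkdir(exist_ok=True)
        for m in self.members:
            write_model(m, directory / "models" / f"{m.id}.json")
        write_reaction_db(self.universal_db, directory / "universal_db.tsv")
        self.kb.write_tsv(directory / "transporter_kb.tsv")
        (directory / "taxonomy.yaml").write_text(
            yaml.safe_dump(
                {"ranked": self.tax.ranked, "threshold": self.tax.threshold},
                sort_keys=True,
            )
        )
        (directory / "diet.yaml").write_text(
            yaml.safe_dump({"shared": self.shared, "diet": self.diet}, sort_keys=True)
        )
        (directory / "objective_sets.yaml").write_text(
            yaml.safe_dump(
                {
                    "scfa": self.objective_sets.scfa,
                    "feed": self.objective_sets.feed,
                    "gas": self.objective_sets.gas,
                    "sugar": self.objective_sets.sugar,
                },
                sort_keys=True,
            )
        )
        for k, amg in self.amg_sets.items():
            payload = {
                "member_id": amg.member_id,
                "provenance": amg.provenance,
                "reactions": [r.to_dict() for r in amg.reactions],
            }
            (directory / "amg" / f"{k}.json").write_text(
                json.dumps(payload, indent=1, sort_keys=True) + "\n"
            )
        (directory / "truth.json").write_text(
            json.dumps(self.truth.to_dict(), indent=1, sort_keys=True) + "\n"
        )
        return directory


def load_bundle(directory: str | Path) -> Bundle:
    """Load a bundle previously written by :meth:`Bundle.write`."""
    from .model_io import read_model, read_reaction_db

    directory = Path(directory)
    members = [
        read_model(p) for p in sorted((directory / "models").glob("*.json"))
    ]
    diet_doc = yaml.safe_load((directory / "diet.yaml").read_text())
    tax_doc = yaml.safe_load((directory / "taxonomy.yaml").read_text())
    obj_doc = yaml.safe_load((directory / "objective_sets.yaml").read_text())
    amg_sets: dict[str, AMGSet] = {}
    for p in sorted((directory / "amg").glob("*.json")):
        payload = json.loads(p.read_text())
        amg_sets[payload["member_id"]] = AMGSet(
            member_id=payload["member_id"],
            reactions=[Reaction.from_dict(r) for r in payload["reactions"]],
            provenance=payload.get("provenance", []),
        )
    truth_path = directory / "truth.json"
    truth = (
        TruthTable.from_dict(json.loads(truth_path.read_text()))
        if truth_path.exists()
        else TruthTable()
    )
    return Bundle(
        members=members,
        truth=truth,
        shared=list(diet_doc["shared"]),
        diet={k: float(v) for k, v in diet_doc["diet"].items()},
        kb=TransporterKB.read_tsv(directory / "transporter_kb.tsv"),
        tax=TaxonomyConfig(ranked=tax_doc["ranked"], threshold=int(tax_doc["threshold"])),
        universal_db=read_reaction_db(directory / "universal_db.tsv"),
        amg_sets=amg_sets,
        objective_sets=ObjectiveSets(
            scfa=list(obj_doc.get("scfa", [])),
            feed=list(obj_doc.get("feed", [])),
            gas=list(obj_doc.get("gas", [])),
            sugar=list(obj_doc.get("sugar", [])),
        ),
    )


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _exchange(rid: str, met: str, lb: float, ub: float = BOUND) -> Reaction:
    return Reaction(id=rid, stoichiometry={met: -1.0}, lb=lb, ub=ub, is_exchange=True)


def _rxn(rid: str, stoich: dict[str, float], lb: float = 0.0, ub: float = BOUND,
         **flags) -> Reaction:
    return Reaction(id=rid, stoichiometry=stoich, lb=lb, ub=ub, **flags)


# ---------------------------------------------------------------------------
# The TOY3 fixture
# ---------------------------------------------------------------------------

def make_toy3() -> Bundle:
    """Deterministic three-member fixture with one planted cross-feed
    (acetate, X -> Y), four production gaps, one infeasible cycle, one
    two-reaction dead-end branch, and one AMG bottleneck bypass.

    Standalone optima (hand-solvable): X grows at 20/hr on 10 glc/hr
    (glc -> 2 triose -> biomass); Y at 5/hr (its glc -> precursor step is
    capacity-capped at 5); Z grows on hydrogen + CO2.
    """
    X = MetabolicModel(id="X", biomass_reaction_id="BIO_X")
    for mid, formula, charge, comp in [
        ("glc[e]", "C6H12O6", 0, "e"), ("glc[c]", "C6H12O6", 0, "c"),
        ("triose[c]", "C3H6O3", 0, "c"), ("triose[e]", "C3H6O3", 0, "e"),
        ("ac[c]", None, None, "c"), ("ac[e]", None, None, "e"),
        ("h2[c]", "H2", 0, "c"), ("h2[e]", "H2", 0, "e"),
        ("dead1[c]", None, None, "c"), ("dead2[c]", None, None, "c"),
        ("c1[c]", None, None, "c"), ("c2[c]", None, None, "c"),
        ("c3[c]", None, None, "c"),
    ]:
        X.metabolites.append(Metabolite(id=mid, formula=formula, charge=charge,
                                        compartment=comp))
    X.reactions = [
        _exchange("EX_glc_X", "glc[e]", -10.0),
        _rxn("T_glc_X", {"glc[e]": -1.0, "glc[c]": 1.0}, is_transport=True),
        _rxn("GLYC_X", {"glc[c]": -1.0, "triose[c]": 2.0}),
        _rxn("BIO_X", {"triose[c]": -1.0}, is_biomass=True),
        _rxn("FERM_X", {"triose[c]": -1.0, "ac[c]": 1.0, "h2[c]": 1.0}),
        _rxn("T_ac_X", {"ac[c]": -1.0, "ac[e]": 1.0}, is_transport=True),
        _exchange("EX_ac_X", "ac[e]", -BOUND),
        _rxn("T_h2_X", {"h2[c]": -1.0, "h2[e]": 1.0}, is_transport=True),
        _exchange("EX_h2_X", "h2[e]", -BOUND),
        _rxn("T_triose_X", {"triose[c]": -1.0, "triose[e]": 1.0}, is_transport=True),
        _exchange("EX_triose_X", "triose[e]", -BOUND),
        _rxn("RD1_X", {"triose[c]": -1.0, "dead1[c]": 1.0}),
        _rxn("RD2_X", {"dead1[c]": -1.0, "dead2[c]": 1.0}),
        _rxn("CYC1_X", {"c1[c]": -1.0, "c2[c]": 1.0}, lb=-BOUND),
        _rxn("CYC2_X", {"c2[c]": -1.0, "c3[c]": 1.0}, lb=-BOUND),
        _rxn("CYC3_X", {"c3[c]": -1.0, "c1[c]": 1.0}, lb=-BOUND),
    ]

    Y = MetabolicModel(id="Y", biomass_reaction_id="BIO_Y")
    for mid, comp in [("glc[e]", "e"), ("glc[c]", "c"), ("sub[c]", "c"),
                      ("ac[c]", "c"), ("ac[e]", "e"), ("gapB[c]", "c")]:
        formula = "C6H12O6" if mid.startswith("glc") else None
        Y.metabolites.append(Metabolite(id=mid, formula=formula,
                                        charge=0 if formula else None, compartment=comp))
    Y.reactions = [
        _exchange("EX_glc_Y", "glc[e]", -10.0),
        _rxn("T_glc_Y", {"glc[e]": -1.0, "glc[c]": 1.0}, is_transport=True),
        _rxn("G2S_Y", {"glc[c]": -1.0, "sub[c]": 1.0}, ub=5.0),  # planted bottleneck
        _rxn("BIO_Y", {"sub[c]": -1.0}, is_biomass=True),
        _rxn("ACK_Y", {"ac[c]": -1.0, "sub[c]": 1.0}),
        _exchange("EX_ac_Y", "ac[e]", -BOUND),
        _rxn("RGB_Y", {"gapB[c]": -1.0, "sub[c]": 1.0}),
    ]

    Z = MetabolicModel(id="Z", biomass_reaction_id="BIO_Z")
    for mid, comp in [("h2[e]", "e"), ("h2[c]", "c"), ("co2[e]", "e"), ("co2[c]", "c"),
                      ("ch4[c]", "c"), ("ch4[e]", "e"), ("gapC[c]", "c"),
                      ("gapD[c]", "c")]:
        Z.metabolites.append(Metabolite(id=mid, compartment=comp))
    Z.reactions = [
        _exchange("EX_h2_Z", "h2[e]", -BOUND),
        _rxn("T_h2_Z", {"h2[e]": -1.0, "h2[c]": 1.0}, is_transport=True),
        _exchange("EX_co2_Z", "co2[e]", -5.0),
        _rxn("T_co2_Z", {"co2[e]": -1.0, "co2[c]": 1.0}, is_transport=True),
        _rxn("MTG_Z", {"h2[c]": -4.0, "co2[c]": -1.0, "ch4[c]": 1.0}),
        _rxn("T_ch4_Z", {"ch4[c]": -1.0, "ch4[e]": 1.0}, is_transport=True),
        _exchange("EX_ch4_Z", "ch4[e]", -BOUND),
        _rxn("BIO_Z", {"h2[c]": -4.0, "co2[c]": -1.0}, is_biomass=True),
        _rxn("RGC_Z", {"gapC[c]": -1.0, "co2[c]": 1.0}),
        _rxn("RGD_Z", {"gapD[c]": -1.0, "co2[c]": 1.0}),
    ]
    for m in (X, Y, Z):
        m.validate()

    universal = ReactionDatabase(
        entries=[
            DbEntry(_rxn("uT_ac", {"ac[e]": -1.0, "ac[c]": 1.0}, lb=-BOUND,
                         is_transport=True), taxa=["RumenCocci"]),
            DbEntry(_rxn("uFIX_gapB", {"glc[c]": -1.0, "gapB[c]": 1.0}),
                    taxa=["RumenCocci"]),
            DbEntry(_rxn("uFIX_gapC", {"co2[c]": -2.0, "gapC[c]": 1.0}),
                    taxa=["RumenCocci"]),
            DbEntry(_rxn("uFIX_gapD", {"co2[c]": -2.0, "gapD[c]": 1.0}),
                    taxa=["RumenCocci"]),
            DbEntry(_rxn("uT_xen1", {"xen1[e]": -1.0, "xen1[c]": 1.0}, lb=-BOUND,
                         is_transport=True), taxa=["SoilGeneralist"]),
            DbEntry(_rxn("uDECOY", {"xen2[c]": -1.0, "xen3[c]": 1.0}),
                    taxa=["SoilGeneralist"]),
            # reverse of Y's acetate-assimilation step: an alternate
            # cardinality-1 "fill" for ac[c] that closes an infeasible
            # 2-cycle with ACK_Y and must be rejected by the TIC gate
            DbEntry(_rxn("uREV_ACK", {"sub[c]": -1.0, "ac[c]": 1.0}),
                    taxa=["RumenCocci"]),
        ],
        source="universal",
    )

    kb = TransporterKB(
        rows=[
            ("Y", "ac", "experimental", "planted:acetate permease"),
            ("Z", "h2", "experimental", "planted:hydrogenase uptake"),
        ]
    )
    tax = TaxonomyConfig(
        ranked={
            "X": ["X", "Y", "Z", "RumenCocci", "SoilGeneralist"],
            "Y": ["Y", "X", "Z", "RumenCocci", "SoilGeneralist"],
            "Z": ["Z", "X", "Y", "RumenCocci", "SoilGeneralist"],
        },
        threshold=3,
    )

    # The Y-phage AMG both bypasses the G2S capacity cap and gives Y its
    # own route to cytosolic acetate (making the planted exchange
    # dispensable, as in the post-AMG re-run).
    amg_y = AMGSet(
        member_id="Y",
        reactions=[
            _rxn("AMG_ACS_Y", {"glc[c]": -1.0, "ac[c]": 1.0, "vx[c]": 1.0}),
            _rxn("AMG_Tvx_Y", {"vx[c]": -1.0, "vx[e]": 1.0}, is_transport=True),
            _exchange("AMG_EX_vx_Y", "vx[e]", 0.0),
        ],
        provenance=[{"phage": "phiY-1", "evalue": 1e-40}],
    )

    truth = TruthTable(
        no_production=[("Y", "ac[c]"), ("Y", "gapB[c]"), ("Z", "gapC[c]"),
                       ("Z", "gapD[c]")],
        no_consumption=[("X", "dead2[c]")],
        cross_feeds=[("X", "Y", "ac", "uT_ac")],
        cycles=[("X", ("CYC1_X", "CYC2_X", "CYC3_X"))],
        blocked={
            "X": ["RD1_X", "RD2_X"],
            "Y": ["ACK_Y", "EX_ac_Y", "RGB_Y"],
            "Z": ["RGC_Z", "RGD_Z"],
        },
        amg_bottleneck={"Y": "G2S_Y"},
        amg_expected_widened={"Y": ["ACK_Y", "BIO_Y"]},
    )

    return Bundle(
        members=[X, Y, Z],
        truth=truth,
        shared=["glc", "ac", "h2", "co2", "ch4"],
        diet={"glc": 10.0, "co2": 5.0},
        kb=kb,
        tax=tax,
        universal_db=universal,
        amg_sets={"Y": amg_y},
        objective_sets=ObjectiveSets(
            scfa=["ac"], feed=["glc"], gas=["ch4", "co2"], sugar=["glc"]
        ),
    )


# ---------------------------------------------------------------------------
# Randomized generator
# ---------------------------------------------------------------------------

def generate_community(spec: SyntheticSpec) -> Bundle:
    """Generate a community per ``spec`` with exact planted truth.

    Members are linear fermenters: a dedicated substrate enters through
    a transporter, flows through a conversion chain into biomass, and a
    branch point exports a member-specific byproduct. Planted features
    are attached to non-essential branches only, so every member grows
    standalone regardless of the planting. Same seed + spec => identical
    output (all randomness comes from one seeded generator and ids are
    deterministic).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K = spec.n_members
    scale = spec.bounds_scale
    bound = BOUND * scale
    member_ids = [f"M{j + 1}" for j in range(K)]
    truth = TruthTable()
    members: list[MetabolicModel] = []
    universal_entries: list[DbEntry] = []
    kb_rows: list[tuple[str, str, str, str]] = []
    amg_sets: dict[str, AMGSet] = {}

    substrates = [f"sub{j + 1}" for j in range(K)]
    byproducts = [f"by{j + 1}" for j in range(K)]

    for j, k in enumerate(member_ids):
        m = MetabolicModel(id=k, biomass_reaction_id=f"BIO_{k}")
        s, b = substrates[j], byproducts[j]
        chain = [f"{s}[c]"] + [f"p{t}_{k}[c]" for t in range(1, spec.pathway_len)]
        for mid, comp in [(f"{s}[e]", "e"), (f"{b}[c]", "c"), (f"{b}[e]", "e")] + [
            (c, "c") for c in chain
        ]:
            m.metabolites.append(Metabolite(id=mid, compartment=comp))
        m.reactions.append(_exchange(f"EX_{s}_{k}", f"{s}[e]", -spec.uptake * scale,
                                     bound))
        m.reactions.append(
            _rxn(f"T_{s}_{k}", {f"{s}[e]": -1.0, chain[0]: 1.0}, ub=bound,
                 is_transport=True)
        )
        for t in range(len(chain) - 1):
            m.reactions.append(
                _rxn(f"C{t + 1}_{k}", {chain[t]: -1.0, chain[t + 1]: 1.0}, ub=bound)
            )
        m.reactions.append(_rxn(f"BIO_{k}", {chain[-1]: -1.0}, ub=bound,
                                is_biomass=True))
        mid_met = chain[min(1, len(chain) - 1)]
        m.reactions.append(_rxn(f"FERMB_{k}", {mid_met: -1.0, f"{b}[c]": 1.0}, ub=bound))
        m.reactions.append(
            _rxn(f"T_{b}_{k}", {f"{b}[c]": -1.0, f"{b}[e]": 1.0}, ub=bound,
                 is_transport=True)
        )
        m.reactions.append(_exchange(f"EX_{b}_{k}", f"{b}[e]", -bound, bound))
        truth.blocked[k] = []
        members.append(m)

    by_id = {m.id: m for m in members}

    # --- cycles ---------------------------------------------------------
    for c in range(spec.n_cycles):
        k = member_ids[int(rng.integers(0, K))]
        m = by_id[k]
        mets = [f"cyc{c}_{t}_{k}[c]" for t in range(3)]
        for mid in mets:
            m.metabolites.append(Metabolite(id=mid, compartment="c"))
        rids = []
        for t in range(3):
            rid = f"CYC{c}_{t}_{k}"
            m.reactions.append(
                _rxn(rid, {mets[t]: -1.0, mets[(t + 1) % 3]: 1.0}, lb=-bound, ub=bound)
            )
            rids.append(rid)
        truth.cycles.append((k, tuple(sorted(rids))))

    # --- dead-end branches (two reactions, terminal accumulation) ------
    for d in range(spec.n_deadends):
        k = member_ids[int(rng.integers(0, K))]
        m = by_id[k]
        src = f"{substrates[member_ids.index(k)]}[c]"
        d1, d2 = f"de{d}a_{k}[c]", f"de{d}b_{k}[c]"
        m.metabolites.append(Metabolite(id=d1, compartment="c"))
        m.metabolites.append(Metabolite(id=d2, compartment="c"))
        r1, r2 = f"RDE{d}a_{k}", f"RDE{d}b_{k}"
        m.reactions.append(_rxn(r1, {src: -1.0, d1: 1.0}, ub=bound))
        m.reactions.append(_rxn(r2, {d1: -1.0, d2: 1.0}, ub=bound))
        truth.blocked[k] += [r1, r2]
        truth.no_consumption.append((k, d2))

    # --- pure gaps ------------------------------------------------------
    for g in range(spec.n_gaps):
        k = member_ids[int(rng.integers(0, K))]
        m = by_id[k]
        j = member_ids.index(k)
        gap = f"gap{g}_{k}[c]"
        m.metabolites.append(Metabolite(id=gap, compartment="c"))
        rid = f"RGAP{g}_{k}"
        m.reactions.append(_rxn(rid, {gap: -1.0, f"{byproducts[j]}[c]": 1.0}, ub=bound))
        truth.no_production.append((k, gap))
        truth.blocked[k].append(rid)
        universal_entries.append(
            DbEntry(_rxn(f"uFIX_gap{g}_{k}", {f"{substrates[j]}[c]": -1.0, gap: 1.0},
                         ub=bound), taxa=["UnivClose"])
        )

    # --- cross-feeds ----------------------------------------------------
    pairs: list[tuple[str, str]] = [
        (a, b) for a in member_ids for b in member_ids if a != b
    ]
    order = rng.permutation(len(pairs))
    chosen = [pairs[i] for i in order[: spec.n_cross_feeds]]
    for donor, receiver in chosen:
        dj = member_ids.index(donor)
        met = byproducts[dj]
        r = by_id[receiver]
        rj = member_ids.index(receiver)
        if not r.has_metabolite(f"{met}[e]"):
            r.metabolites.append(Metabolite(id=f"{met}[e]", compartment="e"))
            r.reactions.append(_exchange(f"EX_{met}_{receiver}", f"{met}[e]", -bound,
                                         bound))
        r.metabolites.append(Metabolite(id=f"{met}[c]", compartment="c"))
        rid = f"XUSE_{met}_{receiver}"
        r.reactions.append(
            _rxn(rid, {f"{met}[c]": -1.0, f"{byproducts[rj]}[c]": 1.0}, ub=bound)
        )
        transporter_id = f"uT_{met}"
        if transporter_id not in [e.reaction.id for e in universal_entries]:
            universal_entries.append(
                DbEntry(
                    _rxn(transporter_id, {f"{met}[e]": -1.0, f"{met}[c]": 1.0},
                         lb=-bound, ub=bound, is_transport=True),
                    taxa=["UnivClose"],
                )
            )
        kb_rows.append((receiver, met, "experimental", "planted"))
        truth.cross_feeds.append((donor, receiver, met, transporter_id))
        truth.no_production.append((receiver, f"{met}[c]"))
        truth.blocked[receiver] += [rid, f"EX_{met}_{receiver}"]

    # --- AMG bottleneck bypasses ---------------------------------------
    amg_hosts = [member_ids[i] for i in rng.permutation(K)[: spec.n_amg]]
    for k in amg_hosts:
        m = by_id[k]
        cap_rid = f"C1_{k}"
        m.reaction(cap_rid).ub = spec.uptake * scale / 2.0
        j = member_ids.index(k)
        chain0 = f"{substrates[j]}[c]"
        chain1 = (
            f"p1_{k}[c]" if m.has_metabolite(f"p1_{k}[c]") else chain0
        )
        amg_sets[k] = AMGSet(
            member_id=k,
            reactions=[
                _rxn(f"AMG_BYP_{k}", {chain0: -1.0, chain1: 1.0, f"vx_{k}[c]": 1.0},
                     ub=bound),
                _rxn(f"AMG_Tvx_{k}", {f"vx_{k}[c]": -1.0, f"vx_{k}[e]": 1.0}, ub=bound,
                     is_transport=True),
                _exchange(f"AMG_EX_vx_{k}", f"vx_{k}[e]", 0.0, bound),
            ],
            provenance=[{"phage": f"phi{k}", "evalue": 1e-40}],
        )
        truth.amg_bottleneck[k] = cap_rid
        truth.amg_expected_widened[k] = [f"BIO_{k}"]

    for m in members:
        m.validate()

    # decoy universal entries (taxonomically distant)
    universal_entries.append(
        DbEntry(_rxn("uDECOY_far", {"zzz1[c]": -1.0, "zzz2[c]": 1.0}, ub=bound),
                taxa=["UnivFar"]),
    )

    tax = TaxonomyConfig(
        ranked={
            k: [k] + [o for o in member_ids if o != k] + ["UnivClose", "UnivFar"]
            for k in member_ids
        },
        threshold=K,  # member taxa and UnivClose pass, UnivFar fails
    )
    return Bundle(
        members=members,
        truth=truth,
        shared=sorted(set(substrates) | set(byproducts)),
        diet={s: spec.uptake * scale for s in substrates},
        kb=TransporterKB(rows=sorted(kb_rows)),
        tax=tax,
        universal_db=ReactionDatabase(entries=universal_entries, source="universal"),
        amg_sets=amg_sets,
        objective_sets=ObjectiveSets(
            scfa=sorted(byproducts),
            feed=sorted(substrates),
            gas=[byproducts[-1]],
            sugar=[substrates[0]],
        ),
        spec=spec,
    )
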