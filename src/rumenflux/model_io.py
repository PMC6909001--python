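"""Member metabolic models, reaction databases, and their on-disk dialects.

A :class:`MetabolicModel` is the stoichiometry-level description of one
community member: metabolites (with elemental formula and charge where
known), reactions (signed stoichiometry, flux bounds in mmol/gDCW/hr),
and a designated biomass reaction whose flux is the growth rate in 1/hr.

Two dialects are supported:

* a native JSON dialect (read/write, lossless) documented in the README;
* SBML Level 2 (read-only) for models exported from reconstruction
  pipelines; custom annotations do not round-trip through SBML, so it is
  never written.

Sign conventions (COBRA style, used everywhere in the package):

* stoichiometric coefficients: negative = consumed, positive = produced;
* an exchange reaction ``EX_x: x ->`` carries positive flux when the
  metabolite is secreted and negative flux when it is taken up;
* a reaction is reversible exactly when its lower bound is negative.

Compartments: ``c`` cytosol, ``e`` the member's own extracellular space,
``u`` the community's shared metabolite pool. Metabolite ids carry the
compartment as a ``[c]``-style suffix.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy import sparse

from .constants import BOUND

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "DbEntry",
    "ReactionDatabase",
    "ModelValidationError",
    "parse_formula",
    "parse_equation",
    "format_equation",
    "read_model",
    "write_model",
    "read_reaction_db",
    "write_reaction_db",
    "compartment_of",
    "base_id",
]

COMPARTMENTS = ("c", "e", "u")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_ID_SUFFIX = re.compile(r"^(?P<base>.+)\[(?P<comp>[a-z])\]$")


class ModelValidationError(ValueError):
    """A structural invariant of a model or database is violated."""


def parse_formula(formula: Optional[str]) -> Optional[dict[str, int]]:
    """Parse a Hill-style elemental formula into element counts.

    Returns ``None`` when the formula is missing or does not parse, in
    which case the metabolite is treated as having an unknown formula.
    """
    if not formula:
        return None
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            return None
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        return None
    return counts


def compartment_of(metabolite_id: str) -> Optional[str]:
    """Compartment letter from a ``met[c]``-style id, or None."""
    m = _ID_SUFFIX.match(metabolite_id)
    return m.group("comp") if m else None


def base_id(metabolite_id: str) -> str:
    """Strip the compartment suffix (and any ``member:`` namespace prefix)."""
    mid = metabolite_id.split(":", 1)[-1]
    m = _ID_SUFFIX.match(mid)
    return m.group("base") if m else mid


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    compartment: str = "c"

    @property
    def elements(self) -> Optional[dict[str, int]]:
        return parse_formula(self.formula)

    def to_dict(self) -> dict:
        d: dict = {"id": self.id, "compartment": self.compartment}
        if self.name:
            d["name"] = self.name
        if self.formula is not None:
            d["formula"] = self.formula
        if self.charge is not None:
            d["charge"] = self.charge
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Metabolite":
        return cls(
            id=d["id"],
            name=d.get("name", ""),
            formula=d.get("formula"),
            charge=d.get("charge"),
            compartment=d.get("compartment", compartment_of(d["id"]) or "c"),
        )


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = BOUND
    name: str = ""
    genes: list[str] = field(default_factory=list)
    subsystem: str = ""
    is_exchange: bool = False
    is_transport: bool = False
    is_biomass: bool = False

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def signature(self) -> tuple:
        """Canonical stoichiometry signature used for duplicate detection.

        Two reactions have equal signatures iff their stoichiometries are
        identical up to overall sign (a reverse-written copy matches).
        """
        items = tuple(sorted(self.stoichiometry.items()))
        flipped = tuple(sorted((k, -v) for k, v in self.stoichiometry.items()))
        return min(items, flipped)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lb=self.lb,
            ub=self.ub,
            name=self.name,
            genes=list(self.genes),
            subsystem=self.subsystem,
            is_exchange=self.is_exchange,
            is_transport=self.is_transport,
            is_biomass=self.is_biomass,
        )

    def to_dict(self) -> dict:
        d: dict = {
            "id": self.id,
            "stoichiometry": {k: self.stoichiometry[k] for k in sorted(self.stoichiometry)},
            "lb": self.lb,
            "ub": self.ub,
            "reversible": self.reversible,
        }
        if self.name:
            d["name"] = self.name
        if self.genes:
            d["genes"] = self.genes
        if self.subsystem:
            d["subsystem"] = self.subsystem
        for flag in ("is_exchange", "is_transport", "is_biomass"):
            if getattr(self, flag):
                d[flag] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Reaction":
        rxn = cls(
            id=d["id"],
            stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
            lb=float(d.get("lb", 0.0)),
            ub=float(d.get("ub", BOUND)),
            name=d.get("name", ""),
            genes=list(d.get("genes", [])),
            subsystem=d.get("subsystem", ""),
            is_exchange=bool(d.get("is_exchange", False)),
            is_transport=bool(d.get("is_transport", False)),
            is_biomass=bool(d.get("is_biomass", False)),
        )
        if "reversible" in d and bool(d["reversible"]) != rxn.reversible:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: serialized reversible={d['reversible']} "
                f"contradicts bounds [{rxn.lb}, {rxn.ub}]"
            )
        return rxn


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_reaction_id: str = ""

    # ---- indices -------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def has_metabolite(self, mid: str) -> bool:
        return any(m.id == mid for m in self.metabolites)

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reaction(self.biomass_reaction_id)

    # ---- stoichiometric matrix ----------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """Assemble S (metabolites x reactions) exactly from stoichiometry."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coeff in rxn.stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(coeff)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions])
        ub = np.array([r.ub for r in self.reactions])
        return lb, ub

    # ---- editing -------------------------------------------------------
    def copy(self, new_id: Optional[str] = None) -> "MetabolicModel":
        return MetabolicModel(
            id=new_id or self.id,
            metabolites=[Metabolite(**vars(m)) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
        )

    def add_metabolite(self, met: Metabolite) -> None:
        if self.has_metabolite(met.id):
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction, create_missing_metabolites: bool = False) -> None:
        if self.has_reaction(rxn.id):
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if not self.has_metabolite(mid):
                if not create_missing_metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {mid!r}"
                    )
                comp = compartment_of(mid) or "c"
                self.metabolites.append(Metabolite(id=mid, compartment=comp))
        self.reactions.append(rxn)

    def remove_reaction(self, rid: str) -> None:
        self.reactions = [r for r in self.reactions if r.id != rid]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # ---- validation ----------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` listing every violation."""
        errors: list[str] = []
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            dups = sorted({m for m in mids if mids.count(m) > 1})
            errors.append(f"duplicate metabolite ids: {dups}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dups = sorted({r for r in rids if rids.count(r) > 1})
            errors.append(f"duplicate reaction ids: {dups}")
        if not self.reactions:
            errors.append("model has no reactions")
        known = set(mids)
        for met in self.metabolites:
            if met.compartment not in COMPARTMENTS:
                errors.append(f"metabolite {met.id!r}: bad compartment {met.compartment!r}")
        for rxn in self.reactions:
            if not rxn.stoichiometry:
                errors.append(f"reaction {rxn.id!r}: empty stoichiometry")
            missing = sorted(set(rxn.stoichiometry) - known)
            if missing:
                errors.append(f"reaction {rxn.id!r}: undeclared metabolites {missing}")
            if rxn.lb > rxn.ub:
                errors.append(f"reaction {rxn.id!r}: lb {rxn.lb} > ub {rxn.ub}")
            if rxn.is_exchange:
                if len(rxn.stoichiometry) != 1:
                    errors.append(
                        f"exchange reaction {rxn.id!r} touches "
                        f"{len(rxn.stoichiometry)} metabolites (expected 1)"
                    )
                else:
                    (mid,) = rxn.stoichiometry
                    comp = compartment_of(mid)
                    if mid in known and comp not in ("e", "u"):
                        errors.append(
                            f"exchange reaction {rxn.id!r}: metabolite {mid!r} "
                            f"not in compartment e or u"
                        )
        if self.biomass_reaction_id and self.biomass_reaction_id not in set(rids):
            errors.append(f"biomass reaction {self.biomass_reaction_id!r} not found")
        if errors:
            raise ModelValidationError(
                f"model {self.id!r} invalid:\n  " + "\n  ".join(errors)
            )

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "biomass_reaction_id": self.biomass_reaction_id,
            "metabolites": [m.to_dict() for m in sorted(self.metabolites, key=lambda m: m.id)],
            "reactions": [r.to_dict() for r in sorted(self.reactions, key=lambda r: r.id)],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        model = cls(
            id=d["id"],
            metabolites=[Metabolite.from_dict(x) for x in d.get("metabolites", [])],
            reactions=[Reaction.from_dict(x) for x in d.get("reactions", [])],
            biomass_reaction_id=d.get("biomass_reaction_id", ""),
        )
        model.validate()
        return model


# ---------------------------------------------------------------------------
# Reaction database (ModelSEED-style universal table, or a member's network)
# ---------------------------------------------------------------------------

@dataclass
class DbEntry:
    reaction: Reaction
    taxa: list[str] = field(default_factory=list)


@dataclass
class ReactionDatabase:
    entries: list[DbEntry] = field(default_factory=list)
    source: str = "universal"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def ids(self) -> list[str]:
        return [e.reaction.id for e in self.entries]

    def get(self, rid: str) -> DbEntry:
        for e in self.entries:
            if e.reaction.id == rid:
                return e
        raise KeyError(rid)

    def validate(self) -> None:
        ids = self.ids()
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate database entry ids: {dups}")


# ---------------------------------------------------------------------------
# Equation strings ("2 A[c] + B[e] <=> C[c]")
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "-->", "=>", "->")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into (stoichiometry, reversible)."""
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelValidationError(f"no reaction arrow in equation {equation!r}")
    reversible = arrow in ("<=>", "<->")
    left, right = equation.split(arrow, 1)

    def side(text: str, sign: float) -> dict[str, float]:
        out: dict[str, float] = {}
        text = text.strip()
        if not text:
            return out
        for term in text.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split(None, 1)
            if len(parts) == 2 and re.fullmatch(r"\d+(\.\d+)?", parts[0]):
                coeff, mid = float(parts[0]), parts[1].strip()
            else:
                coeff, mid = 1.0, term
            out[mid] = out.get(mid, 0.0) + sign * coeff
        return out

    stoich = side(left, -1.0)
    for mid, c in side(right, +1.0).items():
        stoich[mid] = stoich.get(mid, 0.0) + c
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ModelValidationError(f"equation {equation!r} cancels to nothing")
    return stoich, reversible


def _coeff_str(c: float) -> str:
    return "" if c == 1.0 else (f"{int(c)} " if float(c).is_integer() else f"{c} ")


def format_equation(rxn: Reaction) -> str:
    lhs = [f"{_coeff_str(-c)}{m}" for m, c in sorted(rxn.stoichiometry.items()) if c < 0]
    rhs = [f"{_coeff_str(c)}{m}" for m, c in sorted(rxn.stoichiometry.items()) if c > 0]
    arrow = "<=>" if rxn.reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_model(model: MetabolicModel, path: str | Path, dialect: str = "native") -> Path:
    """Serialize a model to the native JSON dialect (the only writable one)."""
    if dialect != "native":
        raise ValueError(f"write_model supports only the native dialect, got {dialect!r}")
    model.validate()
    path = Path(path)
    path.write_text(json.dumps(model.to_dict(), indent=1, sort_keys=True) + "\n")
    return path


def read_model(path: str | Path, dialect: str = "native") -> MetabolicModel:
    """Read and validate a member model from disk.

    ``dialect="native"`` reads the JSON dialect; ``dialect="sbml2"`` reads
    an SBML Level 2 document (COBRA-style, with LOWER_BOUND/UPPER_BOUND
    kinetic-law parameters when present).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path}: not valid JSON ({exc})") from exc
        return MetabolicModel.from_dict(payload)
    if dialect == "sbml2":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(path.read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path}: document contains no model")

    model = MetabolicModel(id=sbml_model.getId() or path.stem)
    declared: set[str] = set()
    met_comp: dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        comp = sp.getCompartment() or "c"
        comp = comp[-1] if comp and comp[-1] in COMPARTMENTS else "c"
        charge = sp.getCharge() if sp.isSetCharge() else None
        model.metabolites.append(
            Metabolite(id=sp.getId(), name=sp.getName() or "", charge=charge, compartment=comp)
        )
        declared.add(sp.getId())
        met_comp[sp.getId()] = comp
    boundary = {
        sbml_model.getSpecies(i).getId()
        for i in range(sbml_model.getNumSpecies())
        if sbml_model.getSpecies(i).getBoundaryCondition()
    }

    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for ref, sign in [(rx.getReactant(j), -1.0) for j in range(rx.getNumReactants())] + [
            (rx.getProduct(j), +1.0) for j in range(rx.getNumProducts())
        ]:
            sid = ref.getSpecies()
            if sid in boundary:
                continue
            if sid not in declared:
                raise ModelValidationError(
                    f"{path}: reaction {rx.getId()!r} cites undeclared species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) + sign * ref.getStoichiometry()
        lb, ub = (-BOUND if rx.getReversible() else 0.0), BOUND
        kl = rx.getKineticLaw()
        if kl is not None:
            for pname, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                par = kl.getParameter(pname)
                if par is not None:
                    if setter == "lb":
                        lb = par.getValue()
                    else:
                        ub = par.getValue()
        rid = rx.getId()
        # single-metabolite reactions are exchanges only when they cross
        # the boundary (extracellular species or an EX_ prefix); a
        # cytosolic sink/demand is not one
        is_exchange = rid.startswith("EX_") or (
            len(stoich) == 1 and met_comp.get(next(iter(stoich))) in ("e", "u")
        )
        model.reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lb=lb,
                ub=ub,
                name=rx.getName() or "",
                is_exchange=is_exchange,
                is_biomass="biomass" in rid.lower(),
            )
        )
        if "biomass" in rid.lower() and not model.biomass_reaction_id:
            model.biomass_reaction_id = rid
    model.validate()
    return model


_DB_COLUMNS = ["id", "equation", "reversibility", "taxa"]


def write_reaction_db(db: ReactionDatabase, path: str | Path) -> Path:
    path = Path(path)
    lines = ["\t".join(_DB_COLUMNS)]
    for entry in db.entries:
        rxn = entry.reaction
        lines.append(
            "\t".join(
                [
                    rxn.id,
                    format_equation(rxn),
                    "reversible" if rxn.reversible else "irreversible",
                    ";".join(entry.taxa),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_reaction_db(path: str | Path, source: str = "universal") -> ReactionDatabase:
    """Read a tabular (TSV) reaction database.

    Columns: id, equation, reversibility, taxa (semicolon-separated).
    Row-level parse problems are collected and raised together.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ModelValidationError(f"{path}: empty database file")
    header = [h.strip() for h in lines[0].split("\t")]
    if header[: len(_DB_COLUMNS)] != _DB_COLUMNS:
        raise ModelValidationError(f"{path}: expected columns {_DB_COLUMNS}, got {header}")
    entries: list[DbEntry] = []
    problems: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < 3:
            problems.append(f"line {lineno}: expected >=3 tab-separated columns")
            continue
        rid = cells[0].strip()
        try:
            stoich, reversible = parse_equation(cells[1].strip())
        except ModelValidationError as exc:
            problems.append(f"line {lineno}: {exc}")
            continue
        rev_flag = cells[2].strip().lower()
        if rev_flag in ("reversible", "true", "1"):
            reversible = True
        elif rev_flag in ("irreversible", "false", "0"):
            reversible = False
        taxa = [t for t in (cells[3].split(";") if len(cells) > 3 else []) if t.strip()]
        compartments = {compartment_of(m) for m in stoich}
        is_transport = len(compartments - {None}) > 1
        entries.append(
            DbEntry(
                reaction=Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    lb=-BOUND if reversible else 0.0,
                    ub=BOUND,
                    is_transport=is_transport,
                ),
                taxa=[t.strip() for t in taxa],
            )
        )
    if problems:
        raise ModelValidationError(f"{path}: malformed rows:\n  " + "\n  ".join(problems))
    db = ReactionDatabase(entries=entries, source=source)
    db.validate()
    return db


def is_redundant_reaction(model: MetabolicModel, rxn: Reaction) -> bool:
    """True when adding ``rxn`` cannot enlarge the model's flux space.

    An exact stoichiometric copy is redundant; a reverse-written copy is
    redundant only against a reversible original (against an irreversible
    one it contributes the missing direction).
    """
    if model.has_reaction(rxn.id):
        return True
    items = tuple(sorted(rxn.stoichiometry.items()))
    flipped = tuple(sorted((k, -v) for k, v in rxn.stoichiometry.items()))
    for other in model.reactions:
        other_items = tuple(sorted(other.stoichiometry.items()))
        if items == other_items:
            if rxn.reversible and not other.reversible:
                continue  # adds the reverse direction
            return True
        if flipped == other_items and other.reversible:
            # reverse-written copy of a reversible reaction: same span
            return True
    return False


def integerized(values: Iterable[float], max_denominator: int = 10**6) -> list[Fraction]:
    """Rational approximations with a common integer scaling (exact for the
    decimal coefficients that occur in curated models)."""
    fracs = [Fraction(v).limit_denominator(max_denominator) for v in values]
    return fracs
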