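"""Discovery and classification of inter-species metabolite exchanges.

Every gap-fill suggestion for a member's problem metabolite is routed
through a fixed sequence of checks, cheapest first:

1. *transport plausibility* — a suggested transport reaction is only
   acceptable when the receiving organism has transporter evidence for
   that metabolite (experimental or a clear ortholog) in the
   knowledgebase;
2. *taxonomic likelihood* — the suggestion must occur in an organism
   taxonomically close to the receiver (rank at or below a configured
   threshold in the receiver's relatedness list);
3. *thermodynamic consistency* — tentatively adding the reactions must
   not create a new infeasible cycle (no new unbounded reactions under
   closed exchanges).

A surviving transport suggestion whose substrate some *other* member can
export (standalone FVA max export > epsilon) is recorded as a de novo
inter-species interaction (donor -> receiver); any other surviving
suggestion is an accepted network fix; failures are rejected with the
gate that fired. Classification is a pure function of its inputs, so a
rerun yields identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .constants import EPS_PRODUCTION
from .curation import find_unbounded, open_all_exchanges
from .gapfill import GapFillCandidate, gapfill, gapfind, member_as_db
from .lp_core import fva
from .model_io import MetabolicModel, Reaction, ReactionDatabase, base_id, compartment_of

__all__ = [
    "TransporterKB",
    "TaxonomyConfig",
    "InteractionRecord",
    "InteractionDiff",
    "classify_candidate",
    "discover_interactions",
    "diff_interactions",
]

EVIDENCE_RANK = {"none": 0, "ortholog": 1, "experimental": 2}


@dataclass
class TransporterKB:
    """Rows of (organism, metabolite, evidence level, citation)."""

    rows: list[tuple[str, str, str, str]] = field(default_factory=list)

    def lookup(self, member_id: str, metabolite: str) -> str:
        """Best evidence level for (member, metabolite); 'none' if absent."""
        best = "none"
        for org, met, level, _ in self.rows:
            if org == member_id and met == metabolite:
                if EVIDENCE_RANK.get(level, 0) > EVIDENCE_RANK[best]:
                    best = level
        return best

    @classmethod
    def read_tsv(cls, path) -> "TransporterKB":
        rows = []
        lines = open(path).read().splitlines()
        for line in lines[1:]:  # header: organism  metabolite  evidence  citation
            if not line.strip():
                continue
            cells = (line.split("\t") + ["", "", "", ""])[:4]
            rows.append((cells[0], cells[1], cells[2] or "none", cells[3]))
        return cls(rows=rows)

    def write_tsv(self, path) -> None:
        lines = ["organism\tmetabolite\tevidence\tcitation"]
        lines += ["\t".join(r) for r in self.rows]
        open(path, "w").write("\n".join(lines) + "\n")


@dataclass
class TaxonomyConfig:
    """Per-member ranked relatedness lists (closest first) and the rank
    threshold (0-based, inclusive) at which a source taxon still counts
    as 'closely related'."""

    ranked: dict[str, list[str]]
    threshold: int = 1

    def __post_init__(self) -> None:
        for member, taxa in self.ranked.items():
            if self.threshold >= len(taxa):
                raise ValueError(
                    f"threshold {self.threshold} exceeds relatedness list depth "
                    f"for {member!r}"
                )

    def rank(self, member_id: str, taxa: list[str]) -> Optional[int]:
        order = self.ranked.get(member_id, [])
        ranks = [order.index(t) for t in taxa if t in order]
        return min(ranks) if ranks else None

    def passes(self, member_id: str, taxa: list[str]) -> bool:
        r = self.rank(member_id, taxa)
        return r is not None and r <= self.threshold


@dataclass
class InteractionRecord:
    metabolite: str  # base id, without compartment suffix
    donor: Optional[str]
    receiver: str
    transport_reaction: Optional[str]
    status: str  # de_novo_interaction | accepted_fill | rejected
    evidence: list[str] = field(default_factory=list)
    phase: str = "pre_AMG"
    ambiguous_donor: bool = False
    candidate: Optional[GapFillCandidate] = None

    @property
    def key(self) -> tuple:
        return (self.metabolite, self.donor, self.receiver)


def _transport_reactions(candidate: GapFillCandidate) -> list[Reaction]:
    out = []
    for rxn in candidate.reactions:
        comps = {compartment_of(m) for m in rxn.stoichiometry} - {None}
        if rxn.is_transport or len(comps) > 1:
            out.append(rxn)
    return out


def _max_export(model: MetabolicModel, met: str, cache: dict) -> float:
    """Standalone FVA maximum of the member's exchange flux for ``met``
    (positive = secretion); 0 if the member has no such exchange."""
    key = (model.id, met)
    if key not in cache:
        ex = [
            r.id
            for r in model.reactions
            if r.is_exchange and base_id(next(iter(r.stoichiometry))) == met
        ]
        if not ex:
            cache[key] = 0.0
        else:
            opened = open_all_exchanges(model)
            result = fva(opened, reactions=ex)
            cache[key] = max((result.max(rid) for rid in ex if rid in result.ranges),
                             default=0.0)
    return cache[key]


def classify_candidate(
    candidate: GapFillCandidate,
    receiver: MetabolicModel,
    others: list[MetabolicModel],
    kb: TransporterKB,
    tax: TaxonomyConfig,
    eps: float = EPS_PRODUCTION,
    phase: str = "pre_AMG",
    _caches: Optional[dict] = None,
) -> list[InteractionRecord]:
    """Run the gate sequence on one gap-fill candidate.

    Returns one record per classification outcome; a transport candidate
    with several qualifying donors yields one record per donor, flagged
    as ambiguous.
    """
    caches = _caches if _caches is not None else {}
    export_cache = caches.setdefault("export", {})
    baseline_cache = caches.setdefault("baseline_unbounded", {})

    met = base_id(candidate.target)
    evidence: list[str] = []
    transports = _transport_reactions(candidate)

    # Gate 1: transport plausibility (only for transport suggestions)
    if transports:
        level = kb.lookup(receiver.id, met)
        if EVIDENCE_RANK[level] < EVIDENCE_RANK["ortholog"]:
            return [
                InteractionRecord(
                    metabolite=met,
                    donor=None,
                    receiver=receiver.id,
                    transport_reaction=transports[0].id,
                    status="rejected",
                    evidence=[f"transport evidence insufficient ({level})"],
                    phase=phase,
                    candidate=candidate,
                )
            ]
        evidence.append(f"transporter evidence: {level}")

    # Gate 2: taxonomic likelihood
    taxa = sorted({t for ts in candidate.taxa.values() for t in ts})
    if not tax.passes(receiver.id, taxa):
        return [
            InteractionRecord(
                metabolite=met,
                donor=None,
                receiver=receiver.id,
                transport_reaction=transports[0].id if transports else None,
                status="rejected",
                evidence=evidence + [f"taxonomic likelihood failed (taxa {taxa})"],
                phase=phase,
                candidate=candidate,
            )
        ]
    evidence.append(f"taxonomy rank <= {tax.threshold} (taxa {taxa})")

    # Gate 3: no new thermodynamically infeasible cycle
    if receiver.id not in baseline_cache:
        baseline_cache[receiver.id] = set(find_unbounded(receiver).unbounded)
    from .model_io import is_redundant_reaction

    augmented = receiver.copy()
    for rxn in candidate.reactions:
        if is_redundant_reaction(augmented, rxn):
            continue
        augmented.add_reaction(rxn.copy(), create_missing_metabolites=True)
    new_unbounded = set(find_unbounded(augmented).unbounded) - baseline_cache[receiver.id]
    if new_unbounded:
        return [
            InteractionRecord(
                metabolite=met,
                donor=None,
                receiver=receiver.id,
                transport_reaction=transports[0].id if transports else None,
                status="rejected",
                evidence=evidence
                + [f"creates thermodynamically infeasible cycle ({sorted(new_unbounded)})"],
                phase=phase,
                candidate=candidate,
            )
        ]
    evidence.append("no new infeasible cycle")

    # De novo decision: transport suggestion + some other member exports it
    if transports:
        donors = [
            other.id for other in others if _max_export(other, met, export_cache) > eps
        ]
        if donors:
            ambiguous = len(donors) > 1
            return [
                InteractionRecord(
                    metabolite=met,
                    donor=d,
                    receiver=receiver.id,
                    transport_reaction=transports[0].id,
                    status="de_novo_interaction",
                    evidence=evidence + [f"donor {d} max export > {eps}"],
                    phase=phase,
                    ambiguous_donor=ambiguous,
                    candidate=candidate,
                )
                for d in donors
            ]
    return [
        InteractionRecord(
            metabolite=met,
            donor=None,
            receiver=receiver.id,
            transport_reaction=transports[0].id if transports else None,
            status="accepted_fill",
            evidence=evidence,
            phase=phase,
            candidate=candidate,
        )
    ]


def discover_interactions(
    members: list[MetabolicModel],
    kb: TransporterKB,
    tax: TaxonomyConfig,
    db_universal: ReactionDatabase,
    max_alternates: int = 3,
    eps: float = EPS_PRODUCTION,
    phase: str = "pre_AMG",
) -> list[InteractionRecord]:
    """Full discovery sweep over a community.

    Problem metabolites are structural (identified with exchanges open, so
    a gap reflects missing network capability, not the medium). For every
    member x problem metabolite, gap filling is attempted against each
    other member's network and against the universal database; every
    candidate is classified and duplicate (metabolite, donor, receiver)
    records are collapsed, preferring the strongest status.
    """
    caches: dict = {}
    records: list[InteractionRecord] = []
    member_dbs = {m.id: member_as_db(m) for m in members}
    for member in members:
        report = gapfind(member, eps=eps, both_directions=False)
        others = [m for m in members if m.id != member.id]
        dbs = [member_dbs[o.id] for o in others] + [db_universal]
        for target in report.no_production:
            for db in dbs:
                for candidate in gapfill(
                    member, target, db, max_alternates=max_alternates, eps=eps,
                ):
                    records.extend(
                        classify_candidate(
                            candidate, member, others, kb, tax,
                            eps=eps, phase=phase, _caches=caches,
                        )
                    )
    return _collapse(records)


_STATUS_ORDER = {"de_novo_interaction": 2, "accepted_fill": 1, "rejected": 0}


def _collapse(records: list[InteractionRecord]) -> list[InteractionRecord]:
    best: dict[tuple, InteractionRecord] = {}
    for rec in records:
        key = (rec.metabolite, rec.donor, rec.receiver, rec.status)
        if key not in best:
            best[key] = rec
    # If the same (met, donor, receiver) appears with several statuses,
    # keep only the strongest.
    by_pair: dict[tuple, InteractionRecord] = {}
    for rec in best.values():
        k = rec.key
        if k not in by_pair or _STATUS_ORDER[rec.status] > _STATUS_ORDER[by_pair[k].status]:
            by_pair[k] = rec
    return sorted(
        by_pair.values(),
        key=lambda r: (-_STATUS_ORDER[r.status], r.metabolite, str(r.donor), r.receiver),
    )


@dataclass
class InteractionDiff:
    retained: list[tuple]
    lost: list[tuple]
    gained: list[tuple]


def diff_interactions(
    pre: list[InteractionRecord], post: list[InteractionRecord]
) -> InteractionDiff:
    """Compare de novo interaction sets before/after a model change
    (e.g. AMG augmentation), keyed by (metabolite, donor, receiver)."""
    pre_keys = {r.key for r in pre if r.status == "de_novo_interaction"}
    post_keys = {r.key for r in post if r.status == "de_novo_interaction"}
    return InteractionDiff(
        retained=sorted(pre_keys & post_keys),
        lost=sorted(pre_keys - post_keys),
        gained=sorted(post_keys - pre_keys),
    )
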