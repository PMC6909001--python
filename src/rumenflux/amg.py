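"""Viral auxiliary metabolic genes (AMGs): model augmentation and
flux-space shift analysis.

Phage-encoded metabolic functions are consumed as reaction lists per host
member (the alignment search that produces them — with its e-value < 1e-34
filter — happens upstream and is recorded only as provenance metadata).
Adding reactions can only enlarge the feasible flux polytope, so under
identical bounds and objective context every FVA range is weakly wider
after augmentation; the flux-shift report quantifies which ranges widened
and which shifts are significant (standard deviation of the minimum or
maximum flux > 1 across the community-objective simulations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .constants import REPORT_TOL
from .lp_core import FVAResult
from .model_io import MetabolicModel, Reaction

__all__ = ["AMGSet", "AmgApplication", "FluxShiftReport", "apply_amg", "flux_shift"]

EVALUE_CONTRACT = 1e-34


@dataclass
class AMGSet:
    member_id: str
    reactions: list[Reaction]
    provenance: list[dict] = field(default_factory=list)  # {"phage":..., "evalue":...}

    def __post_init__(self) -> None:
        for note in self.provenance:
            ev = note.get("evalue")
            if ev is not None and not ev < EVALUE_CONTRACT:
                raise ValueError(
                    f"AMG provenance e-value {ev} violates the input contract "
                    f"(< {EVALUE_CONTRACT})"
                )


@dataclass
class AmgApplication:
    model: MetabolicModel
    added: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)  # duplicates, logged not added


def apply_amg(model: MetabolicModel, amg: AMGSet) -> AmgApplication:
    """Copy of the host model augmented with the AMG reactions.

    Reactions duplicating an existing stoichiometry (exactly or
    sign-flipped) are skipped and logged. Metabolites referenced only by
    AMG reactions are created with unknown formula when their id carries
    a parseable compartment suffix.
    """
    if amg.member_id != model.id:
        raise ValueError(
            f"AMG set targets member {amg.member_id!r}, model is {model.id!r}"
        )
    from .model_io import is_redundant_reaction

    out = model.copy()
    added, skipped = [], []
    for rxn in amg.reactions:
        if is_redundant_reaction(out, rxn):
            skipped.append(rxn.id)
            continue
        out.add_reaction(rxn.copy(), create_missing_metabolites=True)
        added.append(rxn.id)
    out.validate()
    return AmgApplication(model=out, added=added, skipped=skipped)


@dataclass
class FluxShiftReport:
    #: reaction -> (pre_min, pre_max, post_min, post_max) at the primary
    #: (first) objective context
    ranges: dict[str, tuple[float, float, float, float]]
    widened: list[str]
    #: reaction -> (sd of min, sd of max) across contexts (post models)
    sd: dict[str, tuple[float, float]]
    significant: list[str]  # sd of min or max > sd_threshold
    #: reactions whose range changed by more than the absolute-delta rule
    changed_abs: list[str]
    n_contexts: int
    sd_threshold: float = 1.0

    @property
    def summary(self) -> dict[str, int]:
        return {
            "n_reactions": len(self.ranges),
            "n_widened": len(self.widened),
            "n_significant": len(self.significant),
            "n_changed_abs": len(self.changed_abs),
        }


def _population_sd(values: list[float]) -> float:
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / n)


def flux_shift(
    model_pre: MetabolicModel,
    model_post: MetabolicModel,
    contexts: list[tuple[FVAResult, FVAResult]],
    sd_threshold: float = 1.0,
    abs_threshold: float = 1e-3,
    tolerance: float = REPORT_TOL,
) -> FluxShiftReport:
    """Quantify flux-space shifts between a host model and its
    AMG-augmented version.

    ``contexts`` pairs pre/post FVA results computed under the same
    objective conditions (the five community objectives, or a single
    growth context). A reaction is *widened* when its post range contains
    its pre range with at least one strictly wider endpoint; it is
    *significant* when the SD of its minimum or maximum flux across the
    post-augmentation simulations exceeds ``sd_threshold`` (the
    absolute-delta rule serves single-context runs). Reactions present
    only post-augmentation (the additions themselves) are excluded.
    """
    if not contexts:
        raise ValueError("at least one objective context is required")
    common = set(model_pre.reaction_ids) & set(model_post.reaction_ids)
    extra_mismatch = set(model_pre.reaction_ids) - set(model_post.reaction_ids)
    if extra_mismatch:
        raise ValueError(
            f"reactions missing from the augmented model: {sorted(extra_mismatch)}"
        )
    pre0, post0 = contexts[0]
    ranges: dict[str, tuple[float, float, float, float]] = {}
    widened: list[str] = []
    changed_abs: list[str] = []
    sd: dict[str, tuple[float, float]] = {}
    significant: list[str] = []
    for rid in sorted(common):
        if rid not in pre0.ranges or rid not in post0.ranges:
            continue
        pre_lo, pre_hi = pre0.ranges[rid]
        post_lo, post_hi = post0.ranges[rid]
        ranges[rid] = (pre_lo, pre_hi, post_lo, post_hi)
        contains = post_lo <= pre_lo + tolerance and post_hi >= pre_hi - tolerance
        strict = (pre_lo - post_lo > tolerance) or (post_hi - pre_hi > tolerance)
        if contains and strict:
            widened.append(rid)
        if abs(post_lo - pre_lo) > abs_threshold or abs(post_hi - pre_hi) > abs_threshold:
            changed_abs.append(rid)
        mins = [post.ranges[rid][0] for _, post in contexts if rid in post.ranges]
        maxs = [post.ranges[rid][1] for _, post in contexts if rid in post.ranges]
        if len(mins) >= 2:
            sd_min, sd_max = _population_sd(mins), _population_sd(maxs)
            sd[rid] = (sd_min, sd_max)
            if sd_min > sd_threshold or sd_max > sd_threshold:
                significant.append(rid)
    return FluxShiftReport(
        ranges=ranges,
        widened=widened,
        sd=sd,
        significant=significant,
        changed_abs=changed_abs,
        n_contexts=len(contexts),
        sd_threshold=sd_threshold,
    )
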