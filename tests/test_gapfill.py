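"""GapFind/GapFill MILPs against planted truth and a brute-force
subset-enumeration oracle."""

import numpy as np
import pytest

from _oracles import brute_force_min_fill
from rumenflux.gapfill import apply_candidate, gapfill, gapfind, member_as_db
from rumenflux.model_io import (
    DbEntry,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionDatabase,
)
from rumenflux.synthetic import SyntheticSpec, generate_community


class TestGapFind:
    def test_metabolite_without_producer_is_flagged(self, toy3):
        report = gapfind(toy3.member("Y"))
        assert "ac[c]" in report.no_production

    def test_connected_chain_has_no_gaps(self, chain_model):
        report = gapfind(chain_model)
        assert report.no_production == []
        assert report.no_consumption == []

    def test_toy3_planted_gaps_exactly(self, toy3):
        found = []
        for member in toy3.members:
            report = gapfind(member)
            found += [(member.id, met) for met in report.no_production]
        assert sorted(found) == sorted(toy3.truth.no_production)
        assert len(found) == 4

    def test_terminal_dead_end_is_consumption_gap_only(self, toy3):
        report = gapfind(toy3.member("X"))
        assert report.no_production == []
        assert report.no_consumption == ["dead2[c]"]

    def test_root_vs_downstream_classification(self):
        # g1 (no producer) feeds g2, whose only route is through g1
        m = MetabolicModel(id="roots", biomass_reaction_id="")
        m.metabolites = [Metabolite(id=x) for x in ["g1[c]", "g2[c]", "w[c]", "s[c]"]]
        m.reactions = [
            Reaction(id="r12", stoichiometry={"g1[c]": -1.0, "g2[c]": 1.0}),
            Reaction(id="r2w", stoichiometry={"g2[c]": -1.0, "w[c]": 1.0}),
            Reaction(id="rw", stoichiometry={"w[c]": -1.0, "s[c]": 1.0}),
            Reaction(id="rs", stoichiometry={"s[c]": -1.0}),
        ]
        report = gapfind(m)
        assert "g1[c]" in report.root_no_production
        assert "g2[c]" in report.downstream_no_production


class TestGapFill:
    def test_transporter_fill_found_at_cardinality_one(self, toy3):
        # two single-reaction fills exist for cytosolic acetate: the
        # planted transporter and a loop-forming decoy (weeded out later
        # by the interaction classifier, not by GapFill itself)
        fills = gapfill(toy3.member("Y"), "ac[c]", toy3.universal_db)
        assert fills and all(f.cardinality == 1 for f in fills)
        assert fills[0].added_reaction_ids == ["uREV_ACK"]  # lexicographic tie-break
        assert ["uT_ac"] in [f.added_reaction_ids for f in fills]
        assert fills[0].source == "universal"

    def test_irrelevant_database_returns_empty(self, toy3):
        db = member_as_db(toy3.member("Y"))
        assert gapfill(toy3.member("Z"), "gapC[c]", db) == []

    def test_two_reaction_minimal_fill(self):
        m = MetabolicModel(id="two", biomass_reaction_id="")
        m.metabolites = [Metabolite(id=x) for x in ["s[c]", "g[c]", "w[c]"]]
        m.reactions = [
            Reaction(id="src", stoichiometry={"s[c]": 1.0}),
            Reaction(id="use", stoichiometry={"g[c]": -1.0, "w[c]": 1.0}),
        ]
        db = ReactionDatabase(
            entries=[
                DbEntry(Reaction(id="stepA", stoichiometry={"s[c]": -1.0, "i[c]": 1.0})),
                DbEntry(Reaction(id="stepB", stoichiometry={"i[c]": -1.0, "g[c]": 1.0})),
                DbEntry(Reaction(id="noise", stoichiometry={"z1[c]": -1.0, "z2[c]": 1.0})),
            ]
        )
        fills = gapfill(m, "g[c]", db)
        assert fills[0].cardinality == 2
        assert fills[0].added_reaction_ids == ["stepA", "stepB"]

    def test_cardinality_matches_brute_force_on_planted_instances(self):
        """MILP optimum equals exhaustive subset search on small dbs."""
        checked = 0
        for seed in range(1, 6):
            bundle = generate_community(SyntheticSpec(seed=seed))
            for member_id, target in bundle.truth.no_production:
                member = bundle.member(member_id)
                oracle = brute_force_min_fill(member, target, bundle.universal_db)
                fills = gapfill(member, target, bundle.universal_db)
                milp = fills[0].cardinality if fills else None
                assert milp == oracle, (seed, member_id, target)
                checked += 1
        assert checked >= 15

    def test_alternate_solutions_enumerated_by_integer_cuts(self):
        m = MetabolicModel(id="alt", biomass_reaction_id="")
        m.metabolites = [Metabolite(id=x) for x in ["s[c]", "g[c]", "w[c]"]]
        m.reactions = [
            Reaction(id="src", stoichiometry={"s[c]": 1.0}),
            Reaction(id="use", stoichiometry={"g[c]": -1.0, "w[c]": 1.0}),
        ]
        db = ReactionDatabase(
            entries=[
                DbEntry(Reaction(id="fillA", stoichiometry={"s[c]": -1.0, "g[c]": 1.0})),
                DbEntry(Reaction(id="fillB", stoichiometry={"s[c]": -2.0, "g[c]": 1.0})),
            ]
        )
        fills = gapfill(m, "g[c]", db, max_alternates=5)
        assert [f.solution_index for f in fills] == [1, 2]
        assert all(f.cardinality == 1 for f in fills)
        # deterministic lexicographic tie-break
        assert fills[0].added_reaction_ids == ["fillA"]

    def test_applying_candidate_removes_target_from_report(self, toy3):
        for member_id in ("Y", "Z"):
            member = toy3.member(member_id)
            for target in gapfind(member, both_directions=False).no_production:
                fills = gapfill(member, target, toy3.universal_db)
                if not fills:
                    continue
                patched = apply_candidate(member, fills[0])
                assert target not in gapfind(patched, both_directions=False).no_production


class TestMemberAsDb:
    def test_exchange_and_biomass_excluded(self, toy3):
        X = toy3.member("X")
        db = member_as_db(X)
        n_excluded = sum(1 for r in X.reactions if r.is_exchange or r.is_biomass)
        assert len(db) == len(X.reactions) - n_excluded
        assert all(not e.reaction.is_exchange for e in db.entries)
        assert db.source == "X"

    def test_transport_flag_retained(self, toy3):
        db = member_as_db(toy3.member("X"))
        assert db.get("T_ac_X").reaction.is_transport

    def test_re_adding_own_reactions_is_identity(self, toy3):
        from rumenflux.gapfill import GapFillCandidate

        X = toy3.member("X")
        db = member_as_db(X)
        candidate = GapFillCandidate(
            target="ac[c]",
            added_reaction_ids=db.ids(),
            reactions=[e.reaction for e in db.entries],
            source="X",
            cardinality=len(db),
            solution_index=1,
        )
        patched = apply_candidate(X, candidate)
        assert patched.to_dict() == X.to_dict()


class TestPlantedRecovery:
    def test_sensitivity_and_specificity_on_random_communities(self):
        for seed in range(1, 11):
            bundle = generate_community(SyntheticSpec(seed=seed))
            for member in bundle.members:
                report = gapfind(member)
                expected = bundle.truth.gaps_of(member.id)
                assert report.no_production == expected, (seed, member.id)
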