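"""Native/SBML model I/O, validation, and the reaction-database table."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from rumenflux.model_io import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    format_equation,
    parse_equation,
    parse_formula,
    read_model,
    read_reaction_db,
    write_model,
    write_reaction_db,
)
from rumenflux.synthetic import SyntheticSpec, generate_community, make_toy3


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("H2", {"H": 2}),
            ("CH3COOH", {"C": 2, "H": 4, "O": 2}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_hill_formulas(self, formula, expected):
        assert parse_formula(formula) == expected

    @pytest.mark.parametrize("bad", [None, "", "c6h12", "C6H12O6)", "6CH"])
    def test_unknown_formulas_flagged(self, bad):
        assert parse_formula(bad) is None


class TestNativeDialect:
    def test_small_model_matrix_shape(self, tmp_path):
        doc = {
            "id": "tiny",
            "biomass_reaction_id": "r2",
            "metabolites": [
                {"id": "a[c]", "compartment": "c"},
                {"id": "b[c]", "compartment": "c"},
                {"id": "c[c]", "compartment": "c"},
            ],
            "reactions": [
                {"id": "r1", "stoichiometry": {"a[c]": -1, "b[c]": 1}, "lb": 0, "ub": 10},
                {"id": "r2", "stoichiometry": {"b[c]": -1, "c[c]": 1}, "lb": 0, "ub": 10},
            ],
        }
        path = tmp_path / "tiny.json"
        path.write_text(json.dumps(doc))
        model = read_model(path)
        assert model.stoichiometric_matrix().shape == (3, 2)

    def test_matrix_entries_exactly_match_stoichiometry(self, toy3):
        X = toy3.member("X")
        S = X.stoichiometric_matrix().toarray()
        met_index = {m.id: i for i, m in enumerate(X.metabolites)}
        for j, rxn in enumerate(X.reactions):
            for i, mid in enumerate(X.metabolite_ids):
                assert S[i, j] == rxn.stoichiometry.get(mid, 0.0)

    def test_undeclared_metabolite_raises_with_id(self, tmp_path):
        doc = {
            "id": "bad",
            "metabolites": [{"id": "a[c]", "compartment": "c"}],
            "reactions": [{"id": "r1", "stoichiometry": {"ghost[c]": -1.0}, "ub": 1}],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError, match="ghost"):
            read_model(path)

    def test_empty_reaction_list_rejected(self, tmp_path):
        model = MetabolicModel(id="empty", metabolites=[Metabolite(id="a[c]")])
        with pytest.raises(ModelValidationError, match="no reactions"):
            write_model(model, tmp_path / "x.json")

    def test_reversibility_serialized_consistently(self, tmp_path):
        model = MetabolicModel(
            id="rev",
            metabolites=[Metabolite(id="a[c]"), Metabolite(id="b[c]")],
            reactions=[
                Reaction(id="r", stoichiometry={"a[c]": -1.0, "b[c]": 1.0},
                         lb=-1000.0, ub=1000.0)
            ],
        )
        path = write_model(model, tmp_path / "rev.json")
        payload = json.loads(path.read_text())
        assert payload["reactions"][0]["reversible"] is True
        # a contradictory flag must be rejected on read
        payload["reactions"][0]["reversible"] = False
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelValidationError, match="reversible"):
            read_model(path)

    def test_toy3_round_trip_is_identity(self, tmp_path, toy3):
        for member in toy3.members:
            path = write_model(member, tmp_path / f"{member.id}.json")
            again = read_model(path)
            assert again.to_dict() == member.to_dict()

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_round_trip_identity_on_random_models(self, tmp_path_factory, seed):
        bundle = generate_community(SyntheticSpec(seed=seed))
        tmp = tmp_path_factory.mktemp("roundtrip")
        for member in bundle.members:
            path = write_model(member, tmp / f"{member.id}.json")
            assert read_model(path).to_dict() == member.to_dict()


class TestSBML:
    def _write_sbml(self, path, include_ghost=False):
        import libsbml

        doc = libsbml.SBMLDocument(2, 4)
        model = doc.createModel("sbml_toy")
        comp = model.createCompartment()
        comp.setId("c")
        for sid in ["a_c", "b_c"]:
            sp = model.createSpecies()
            sp.setId(sid)
            sp.setCompartment("c")
            sp.setInitialAmount(0.0)
        rxn = model.createReaction()
        rxn.setId("r1")
        rxn.setReversible(False)
        reac = rxn.createReactant()
        reac.setSpecies("a_c")
        reac.setStoichiometry(1.0)
        prod = rxn.createProduct()
        prod.setSpecies("ghost_c" if include_ghost else "b_c")
        prod.setStoichiometry(1.0)
        bio = model.createReaction()
        bio.setId("biomass")
        bio.setReversible(False)
        br = bio.createReactant()
        br.setSpecies("b_c")
        br.setStoichiometry(1.0)
        path.write_text(libsbml.writeSBMLToString(doc))

    def test_reads_level2_document(self, tmp_path):
        path = tmp_path / "toy.xml"
        self._write_sbml(path)
        model = read_model(path, dialect="sbml2")
        assert set(model.reaction_ids) == {"r1", "biomass"}
        assert model.biomass_reaction_id == "biomass"
        assert model.reaction("r1").stoichiometry == {"a_c": -1.0, "b_c": 1.0}

    def test_undeclared_species_named_in_error(self, tmp_path):
        path = tmp_path / "bad.xml"
        self._write_sbml(path, include_ghost=True)
        with pytest.raises(ModelValidationError, match="ghost_c"):
            read_model(path, dialect="sbml2")


class TestEquationStrings:
    @pytest.mark.parametrize(
        "equation,stoich,reversible",
        [
            ("ac[e] <=> ac[c]", {"ac[e]": -1.0, "ac[c]": 1.0}, True),
            ("2 h2[c] + co2[c] -> ch4[c]", {"h2[c]": -2.0, "co2[c]": -1.0,
                                            "ch4[c]": 1.0}, False),
            ("glc[c] -> 2 triose[c]", {"glc[c]": -1.0, "triose[c]": 2.0}, False),
        ],
    )
    def test_parse(self, equation, stoich, reversible):
        got_stoich, got_rev = parse_equation(equation)
        assert got_stoich == stoich and got_rev == reversible

    def test_format_parse_round_trip(self, toy3):
        for entry in toy3.universal_db.entries:
            rxn = entry.reaction
            stoich, reversible = parse_equation(format_equation(rxn))
            assert stoich == rxn.stoichiometry
            assert reversible == rxn.reversible

    def test_no_arrow_rejected(self):
        with pytest.raises(ModelValidationError, match="arrow"):
            parse_equation("a[c] + b[c]")


class TestReactionDatabase:
    def test_transport_row_parsed(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text(
            "id\tequation\treversibility\ttaxa\n"
            "rxnT1\tac[e] <=> ac[c]\treversible\tPrevotella\n"
        )
        db = read_reaction_db(path)
        entry = db.get("rxnT1")
        assert entry.reaction.is_transport
        assert entry.reaction.reversible
        assert entry.taxa == ["Prevotella"]

    def test_round_trip_preserves_entries(self, tmp_path, toy3):
        path = write_reaction_db(toy3.universal_db, tmp_path / "u.tsv")
        again = read_reaction_db(path)
        assert again.ids() == toy3.universal_db.ids()
        for entry in toy3.universal_db.entries:
            back = again.get(entry.reaction.id)
            assert back.reaction.stoichiometry == entry.reaction.stoichiometry
            assert back.taxa == entry.taxa

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "id\tequation\treversibility\ttaxa\n"
            "r1\ta[c] -> b[c]\tirreversible\t\n"
            "r1\tb[c] -> a[c]\tirreversible\t\n"
        )
        with pytest.raises(ModelValidationError, match="r1"):
            read_reaction_db(path)

    def test_malformed_equation_reported_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "id\tequation\treversibility\ttaxa\n"
            "r1\tnot an equation\tirreversible\t\n"
        )
        with pytest.raises(ModelValidationError, match="line 2"):
            read_reaction_db(path)


class TestStructuralValidation:
    def test_exchange_must_touch_single_extracellular_metabolite(self):
        model = make_toy3().member("X")
        bad = Reaction(id="EX_bad", stoichiometry={"glc[c]": -1.0}, is_exchange=True)
        model.reactions.append(bad)
        with pytest.raises(ModelValidationError, match="EX_bad"):
            model.validate()

    def test_bound_ordering_enforced(self):
        model = make_toy3().member("X")
        model.reaction("GLYC_X").lb = 5.0
        model.reaction("GLYC_X").ub = 1.0
        with pytest.raises(ModelValidationError, match="GLYC_X"):
            model.validate()
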