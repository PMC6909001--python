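"""Balance checks, infeasible-cycle detection, null-basis grouping,
blocked reactions, and duplicate detection."""

from fractions import Fraction

import pytest

from rumenflux.curation import (
    check_balance,
    constrain_loop_representative,
    find_blocked,
    find_duplicates,
    find_unbounded,
    group_loops,
    suggest_proton_fix,
)
from rumenflux.model_io import MetabolicModel, Metabolite, Reaction


def _model(mets, rxns, model_id="bal"):
    m = MetabolicModel(id=model_id)
    m.metabolites = [Metabolite(id=i, formula=f, charge=c) for i, f, c in mets]
    m.reactions = rxns
    m.biomass_reaction_id = ""
    return m


class TestBalance:
    def test_glycolytic_split_is_balanced(self):
        m = _model(
            [("glc[c]", "C6H12O6", 0), ("triose[c]", "C3H6O3", 0)],
            [Reaction(id="r", stoichiometry={"glc[c]": -1.0, "triose[c]": 2.0})],
        )
        report = check_balance(m)
        assert report.is_balanced("r")
        assert report.imbalanced == []

    def test_missing_co2_shows_carbon_oxygen_deficit(self):
        # C6H12O6 -> 2 C2H6O drops 2 CO2
        m = _model(
            [("glc[c]", "C6H12O6", 0), ("etoh[c]", "C2H6O", 0)],
            [Reaction(id="r", stoichiometry={"glc[c]": -1.0, "etoh[c]": 2.0})],
        )
        report = check_balance(m)
        assert report.element_net["r"] == {"C": Fraction(-2), "O": Fraction(-4)}
        assert "r" in report.imbalanced

    def test_unknown_formula_is_unbalanceable_not_imbalanced(self):
        m = _model(
            [("glc[c]", "C6H12O6", 0), ("mystery[c]", None, None)],
            [Reaction(id="r", stoichiometry={"glc[c]": -1.0, "mystery[c]": 1.0})],
        )
        report = check_balance(m)
        assert report.unbalanceable == ["r"]
        assert report.imbalanced == []

    def test_exchange_and_biomass_skipped(self, toy3):
        report = check_balance(toy3.member("X"))
        assert "EX_glc_X" in report.skipped and "BIO_X" in report.skipped
        assert report.imbalanced == []

    def test_element_nets_sum_to_zero_over_balanced_set(self):
        m = _model(
            [("glc[c]", "C6H12O6", 0), ("triose[c]", "C3H6O3", 0),
             ("lac[c]", "C3H6O3", 0)],
            [
                Reaction(id="r1", stoichiometry={"glc[c]": -1.0, "triose[c]": 2.0}),
                Reaction(id="r2", stoichiometry={"triose[c]": -1.0, "lac[c]": 1.0}),
            ],
        )
        report = check_balance(m)
        total = {}
        for nets in report.element_net.values():
            for element, v in nets.items():
                total[element] = total.get(element, Fraction(0)) + v
        assert all(v == 0 for v in total.values())


class TestProtonFix:
    def _proton_model(self, product_formula, product_charge):
        return _model(
            [("a[c]", "CH4", 0), ("b[c]", product_formula, product_charge)],
            [Reaction(id="r", stoichiometry={"a[c]": -1.0, "b[c]": 1.0})],
        )

    def test_single_proton_imbalance_fixable(self):
        # products short one H and one positive charge
        m = self._proton_model("CH3", -1)
        assert suggest_proton_fix(m, "r") == -1

    def test_two_proton_imbalance_fixable(self):
        m = self._proton_model("CH2", -2)
        assert suggest_proton_fix(m, "r") == -2

    def test_carbon_imbalance_not_proton_fixable(self):
        m = self._proton_model("C2H4", 0)
        assert suggest_proton_fix(m, "r") is None

    def test_hydrogen_charge_mismatch_not_fixable(self):
        # off by one H but not by one charge
        m = self._proton_model("CH3", 0)
        assert suggest_proton_fix(m, "r") is None


class TestUnboundedAndLoops:
    def test_planted_cycle_detected_exactly(self, toy3):
        report = find_unbounded(toy3.member("X"))
        assert report.unbounded == ["CYC1_X", "CYC2_X", "CYC3_X"]

    def test_linear_member_has_no_unbounded_reactions(self, toy3):
        assert find_unbounded(toy3.member("Y")).unbounded == []

    def test_whitelist_suppresses_reporting(self, toy3):
        report = find_unbounded(toy3.member("X"), whitelist={"CYC1_X"})
        assert "CYC1_X" not in report.unbounded

    def test_cycle_groups_as_unit_nullspace_vector(self, toy3):
        X = toy3.member("X")
        report = group_loops(X, find_unbounded(X).unbounded)
        assert len(report.groups) == 1
        group = report.groups[0]
        assert set(group) == {"CYC1_X", "CYC2_X", "CYC3_X"}
        assert set(group.values()) == {Fraction(1)}

    def test_two_disjoint_cycles_give_disjoint_groups(self):
        mets = [(f"{x}[c]", None, None) for x in
                ["a1", "a2", "a3", "b1", "b2", "b3"]]
        rxns = []
        for prefix in ("a", "b"):
            for t in range(3):
                rxns.append(
                    Reaction(
                        id=f"{prefix}{t}",
                        stoichiometry={f"{prefix}{t % 3 + 1}[c]": -1.0,
                                       f"{prefix}{(t + 1) % 3 + 1}[c]": 1.0},
                        lb=-1000.0,
                    )
                )
        m = _model(mets, rxns, model_id="twocyc")
        report = group_loops(m, find_unbounded(m).unbounded)
        supports = [set(g) for g in report.groups]
        assert len(supports) == 2
        assert supports[0] & supports[1] == set()

    def test_duplicated_reversible_pair_groups_with_opposed_signs(self):
        m = _model(
            [("a[c]", None, None), ("b[c]", None, None)],
            [
                Reaction(id="f1", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}, lb=-1000.0),
                Reaction(id="f2", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}, lb=-1000.0),
            ],
        )
        report = group_loops(m, find_unbounded(m).unbounded)
        assert len(report.groups) == 1
        coeffs = sorted(report.groups[0].values())
        assert coeffs == [Fraction(-1), Fraction(1)]

    def test_constraining_representative_clears_planted_loops(self, toy3):
        X = toy3.member("X")
        before = find_unbounded(X)
        grouped = group_loops(X, before.unbounded)
        fixed = X
        for group in grouped.groups:
            fixed = constrain_loop_representative(fixed, group)
        after = find_unbounded(fixed)
        assert len(after.unbounded) < len(before.unbounded)
        assert after.unbounded == []


class TestBlocked:
    def test_never_produced_substrate_blocks_consumer(self, toy3):
        # ACK consumes cytosolic acetate, which Y cannot make or import
        assert "ACK_Y" in find_blocked(toy3.member("Y"))

    def test_biomass_not_blocked_in_connected_member(self, toy3):
        for member in toy3.members:
            assert member.biomass_reaction_id not in find_blocked(member)

    def test_planted_dead_end_branch_exactly(self, toy3):
        assert find_blocked(toy3.member("X")) == toy3.truth.blocked["X"]

    def test_blocked_matches_truth_table_all_members(self, toy3):
        for member in toy3.members:
            assert find_blocked(member) == sorted(toy3.truth.blocked[member.id])


class TestDuplicates:
    def _dup_model(self):
        return _model(
            [("a[c]", None, None), ("b[c]", None, None),
             ("nadh[c]", None, None), ("nad[c]", None, None),
             ("nadph[c]", None, None), ("nadp[c]", None, None)],
            [
                Reaction(id="r1", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}),
                Reaction(id="r2", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}),
                Reaction(id="r3", stoichiometry={"a[c]": 1.0, "b[c]": -1.0}),
                Reaction(id="d1", stoichiometry={"a[c]": -1.0, "nadh[c]": -1.0,
                                                 "b[c]": 1.0, "nad[c]": 1.0}),
                Reaction(id="d2", stoichiometry={"a[c]": -1.0, "nadph[c]": -1.0,
                                                 "b[c]": 1.0, "nadp[c]": 1.0}),
            ],
            model_id="dups",
        )

    def test_exact_and_reversed_duplicates_reported(self):
        records = find_duplicates(self._dup_model())
        pairs = {r.pair: r.orientation for r in records}
        assert pairs[("r1", "r2")] == "same"
        assert ("r1", "r3") in pairs and pairs[("r1", "r3")] == "reversed"

    def test_cofactor_variant_flagged_with_config(self):
        records = find_duplicates(
            self._dup_model(),
            cofactor_pairs=[("nadh", "nadph"), ("nad", "nadp")],
        )
        variants = [r for r in records if r.cofactor_variant]
        assert len(variants) == 1
        assert variants[0].pair == ("d1", "d2")

    def test_no_cofactor_flag_without_config(self):
        records = find_duplicates(self._dup_model())
        assert all(not r.cofactor_variant for r in records)
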