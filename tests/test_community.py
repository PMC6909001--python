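"""Bilevel community model: construction, KKT solve, pool conservation,
and collapse equivalences."""

import pytest

from rumenflux.community import (
    biomass_objective,
    build_community,
    community_fva,
    solve_optcom,
)
from rumenflux.lp_core import fba, fva

TOL = 1e-6


@pytest.fixture(scope="module")
def toy3_cm(toy3_filled_module):
    return toy3_filled_module


@pytest.fixture(scope="module")
def toy3_filled_module():
    from rumenflux.synthetic import make_toy3

    bundle = make_toy3()
    members = bundle.filled_members()
    return bundle, members, build_community(members, bundle.shared, bundle.diet)


class TestBuild:
    def test_two_members_sharing_one_metabolite(self, toy3_filled):
        X, Y = toy3_filled[0], toy3_filled[1]
        cm = build_community([X, Y], ["ac"], {})
        assert cm.participation["ac"] == ["X", "Y"]
        for k in ("X", "Y"):
            assert cm.members[k].has_reaction(cm.uptake_var(k, "ac"))
            assert cm.members[k].has_reaction(cm.export_var(k, "ac"))

    def test_toy3_has_five_pool_metabolites(self, toy3_filled_module):
        _, _, cm = toy3_filled_module
        assert len(cm.shared) == 5
        assert all(cm.participation[i] for i in cm.shared)

    def test_shared_metabolite_missing_everywhere_rejected(self, toy3_filled):
        with pytest.raises(ValueError, match="xylose"):
            build_community(toy3_filled, ["xylose"], {})

    def test_non_shared_exchanges_become_secretion_only(self, toy3_filled_module):
        _, _, cm = toy3_filled_module
        # X's private triose exchange must not allow uptake in community
        assert cm.members["X"].reaction("X:EX_triose_X").lb == 0.0

    def test_diet_caps_apply_at_community_level(self, toy3_filled):
        X = toy3_filled[0]
        cm = build_community([X], ["glc", "ac", "h2"], {"glc": 5.0})
        sol = solve_optcom(cm, biomass_objective(cm), method="joint")
        # 5 glc/hr at yield 2 -> biomass 10 regardless of X's own bounds
        assert sol.objective_value == pytest.approx(10.0, abs=1e-4)


class TestSolveOptcom:
    def test_single_member_bilevel_collapses_to_fba(self, toy3_filled):
        X = toy3_filled[0]
        cm = build_community([X], ["glc", "ac", "h2"], {"glc": 10.0})
        sol = solve_optcom(cm, biomass_objective(cm), method="kkt")
        assert sol.objective_value == pytest.approx(
            fba(X).objective_value, abs=1e-4
        )
        assert sol.inner_ok

    def test_two_member_chain_matches_hand_lp(self, toy3_filled):
        # glc is worth 2 biomass/unit to X and at most 1 to Y, so the
        # optimum routes all 10 glc to X: total 20.
        cm = build_community(toy3_filled[:2], ["glc", "ac", "h2"], {"glc": 10.0})
        sol = solve_optcom(cm, biomass_objective(cm), method="kkt")
        assert sol.objective_value == pytest.approx(20.0, abs=1e-4)
        assert sol.inner_ok

    def test_toy3_community_optimum(self, toy3_filled_module):
        # hand LP: ferment everything; X 0, Y 20 (acetate), Z 5 (hydrogen)
        _, _, cm = toy3_filled_module
        sol = solve_optcom(cm, biomass_objective(cm), method="kkt")
        assert sol.objective_value == pytest.approx(25.0, abs=1e-3)
        assert sol.member_biomass["Y"] == pytest.approx(20.0, abs=1e-3)
        assert sol.member_biomass["Z"] == pytest.approx(5.0, abs=1e-3)
        assert sol.inner_ok

    def test_zero_diet_zero_objective(self, toy3_filled_module):
        bundle, members, _ = toy3_filled_module
        cm = build_community(members, bundle.shared, {})
        sol = solve_optcom(cm, biomass_objective(cm), method="kkt")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_kkt_matches_collapsed_joint_lp(self, toy3_filled_module):
        _, _, cm = toy3_filled_module
        joint = solve_optcom(cm, biomass_objective(cm), method="joint")
        kkt = solve_optcom(cm, biomass_objective(cm), method="kkt")
        assert kkt.objective_value == pytest.approx(joint.objective_value, abs=1e-3)

    def test_pool_balance_in_every_solution(self, toy3_filled_module):
        _, _, cm = toy3_filled_module
        for method in ("joint", "kkt"):
            sol = solve_optcom(cm, biomass_objective(cm), method=method)
            for met, residual in sol.pool_residual.items():
                assert abs(residual) < TOL, (method, met)

    def test_relaxing_diet_never_decreases_objective(self, toy3_filled_module):
        bundle, members, _ = toy3_filled_module
        base = solve_optcom(
            build_community(members, bundle.shared, bundle.diet),
            biomass_objective(
                build_community(members, bundle.shared, bundle.diet)
            ),
            method="kkt",
        )
        relaxed_diet = dict(bundle.diet, glc=bundle.diet["glc"] * 2)
        cm2 = build_community(members, bundle.shared, relaxed_diet)
        relaxed = solve_optcom(cm2, biomass_objective(cm2), method="kkt")
        assert relaxed.objective_value >= base.objective_value - 1e-6

    def test_inner_optimality_verified_post_hoc(self, toy3_filled_module):
        _, _, cm = toy3_filled_module
        sol = solve_optcom(cm, biomass_objective(cm), method="kkt")
        for member, (achieved, resolved, ok) in sol.inner_optimality.items():
            assert ok, (member, achieved, resolved)

    def test_abundance_weighted_objective_variant(self, toy3_filled_module):
        _, _, cm = toy3_filled_module
        weighted = biomass_objective(cm, {"X": 1.0, "Y": 0.0, "Z": 0.0})
        sol = solve_optcom(cm, weighted, method="kkt")
        # only X's growth counts: all glucose to X
        assert sol.objective_value == pytest.approx(20.0, abs=1e-3)


@pytest.fixture(scope="module")
def growth_fixed(toy3_filled_module):
    _, _, cm = toy3_filled_module
    obj = biomass_objective(cm)
    sol = solve_optcom(cm, obj, method="kkt")
    return cm, obj, sol


class TestCommunityFVA:

    def test_objective_component_pinned(self, growth_fixed):
        cm, obj, sol = growth_fixed
        result = community_fva(cm, obj, sol.objective_value, reactions=["Z:BIO_Z"])
        lo, hi = result.ranges["Z:BIO_Z"]
        assert lo == pytest.approx(5.0, abs=1e-3)
        assert hi == pytest.approx(5.0, abs=1e-3)

    def test_net_acetate_transfer_matches_hand_interval(self, growth_fixed):
        cm, obj, sol = growth_fixed
        result = community_fva(cm, obj, sol.objective_value,
                               reactions=["net[ac,Y]", "net[ac,X]"])
        lo, hi = result.ranges["net[ac,Y]"]
        # Y must take up all 20 acetate net to grow at 20
        assert lo == pytest.approx(-20.0, abs=1e-3)
        assert hi == pytest.approx(-20.0, abs=1e-3)
        xlo, xhi = result.ranges["net[ac,X]"]
        assert xlo == pytest.approx(20.0, abs=1e-3)

    def test_decoupled_reaction_keeps_standalone_range(self, growth_fixed, toy3_filled):
        cm, obj, sol = growth_fixed
        result = community_fva(cm, obj, sol.objective_value, reactions=["X:CYC1_X"])
        standalone = fva(toy3_filled[0], reactions=["CYC1_X"])
        assert result.ranges["X:CYC1_X"] == pytest.approx(
            standalone.ranges["CYC1_X"], abs=1e-3
        )
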