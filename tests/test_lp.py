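import copy

import pytest

from emforce.errors import InfeasibleError
from emforce.lp import LinearConstraintSet, fba, flux_range, theoretical_max, worst_case_product
from emforce.network import MetabolicNetwork, Reaction, apply_condition
from emforce.synth import toy_branch, toy_branch_condition


@pytest.fixture(scope="module")
def toy_applied():
    network, part, ref = toy_branch()
    return apply_condition(network, toy_branch_condition()), part, ref


class TestFBA:
    def test_full_carbon_routing_to_product(self, toy_applied):
        net, _, _ = toy_applied
        res = fba(net, "EX_P", "max")
        assert res.objective == pytest.approx(100.0)

    def test_waste_floor_caps_product(self, toy_applied):
        net, _, _ = toy_applied
        extra = LinearConstraintSet(rows=[({"EX_W": 1.0}, ">=", 10.0)])
        assert fba(net, "EX_P", "max", extra).objective == pytest.approx(90.0)

    def test_inconsistent_floors_are_infeasible(self, toy_applied):
        net, _, _ = toy_applied
        extra = LinearConstraintSet(
            rows=[({"EX_P": 1.0}, ">=", 95.0), ({"EX_W": 1.0}, ">=", 10.0)]
        )
        assert fba(net, "EX_P", "max", extra).status == "infeasible"

    def test_unbounded_detection(self):
        from emforce.network import Metabolite

        net = MetabolicNetwork(
            [Metabolite("X", is_external=True)],
            [Reaction("FREE", {"X": 1}, lb=0, ub=float("inf"))],
        )
        # X is external -> no balance row; flux unbounded above
        assert fba(net, "FREE", "max").status == "unbounded"

    def test_duality_on_every_reported_optimum(self, toy_applied):
        net, _, _ = toy_applied
        for rid in net.reaction_ids:
            for sense in ("max", "min"):
                res = fba(net, rid, sense)
                if res.optimal:
                    assert res.dual_objective == pytest.approx(res.objective, abs=1e-6)


class TestFluxRange:
    def test_reference_space_branch_range(self, toy_applied):
        net, _, _ = toy_applied
        fr = flux_range(net, "R2")
        assert (fr.vmin, fr.vmax) == (pytest.approx(0.0), pytest.approx(100.0))

    def test_overproduction_space_narrows_range(self, toy_applied):
        net, _, _ = toy_applied
        extra = LinearConstraintSet(rows=[({"EX_P": 1.0}, ">=", 90.0)])
        fr = flux_range(net, "R2", extra)
        assert (fr.vmin, fr.vmax) == (pytest.approx(90.0), pytest.approx(100.0))

    def test_fixed_uptake_is_a_point(self, toy_applied):
        net, _, _ = toy_applied
        fr = flux_range(net, "UPT")
        assert (fr.vmin, fr.vmax) == (pytest.approx(-100.0), pytest.approx(-100.0))


class TestTheoreticalMax:
    def test_product_and_biomass_maxima_and_floors(self):
        network, _, _ = toy_branch()
        cond = toy_branch_condition()
        pmax = theoretical_max(network, cond, "product")
        bmax = theoretical_max(network, cond, "biomass")
        assert pmax == pytest.approx(100.0)
        assert bmax == pytest.approx(100.0)
        assert cond.min_product_fraction * pmax == pytest.approx(90.0)
        assert cond.min_biomass_fraction * bmax == pytest.approx(10.0)

    def test_scaling_all_bounds_scales_optima(self):
        network, _, _ = toy_branch()
        cond = toy_branch_condition()
        lam = 3.0
        scaled = copy.deepcopy(cond)
        scaled = type(cond)(
            name=cond.name,
            uptake_bounds={k: (lam * a, lam * b) for k, (a, b) in cond.uptake_bounds.items()},
            product_id=cond.product_id,
            biomass_id=cond.biomass_id,
        )
        assert theoretical_max(network, scaled, "product") == pytest.approx(
            lam * theoretical_max(network, cond, "product")
        )


class TestWorstCase:
    def test_stoichiometry_forces_product_when_kinetics_fixed(self):
        network, part, _ = toy_branch()
        cond = toy_branch_condition()
        res = worst_case_product(
            network, part, {"R1": 100.0, "R2": 90.0, "R3": 10.0}, None, cond
        )
        assert res.objective == pytest.approx(90.0, abs=1e-6)

    def test_reference_kinetics_give_reference_product(self):
        network, part, _ = toy_branch()
        cond = toy_branch_condition()
        res = worst_case_product(
            network, part, {"R1": 100.0, "R2": 20.0, "R3": 80.0}, None, cond
        )
        assert res.objective == pytest.approx(20.0, abs=1e-6)

    def test_binding_lower_bound_intervention(self):
        network, part, _ = toy_branch()
        cond = toy_branch_condition()
        extra = LinearConstraintSet(bounds={"EX_P": (90.0, 1000.0)})
        res = worst_case_product(
            network, part, {"R1": 100.0, "R2": 90.0, "R3": 10.0}, extra, cond
        )
        assert res.objective == pytest.approx(90.0, abs=1e-6)

    def test_inconsistent_kinetic_fluxes_are_infeasible(self):
        network, part, _ = toy_branch()
        cond = toy_branch_condition()
        res = worst_case_product(
            network, part, {"R1": 50.0, "R2": 90.0, "R3": 10.0}, None, cond
        )
        assert res.status == "infeasible"
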