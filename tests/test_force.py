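import pytest

from emforce.errors import ValidationError
from emforce.force import (
    ForceConfig,
    escalate,
    etot_bounds,
    force_step1,
    force_step2,
    run_design,
)
from emforce.lp import worst_case_product
from emforce.must import MustSets


@pytest.fixture(scope="module")
def small_must():
    return MustSets(must_u=frozenset({"RU"}), must_l=frozenset({"RL"}))


class TestEtotBounds:
    @pytest.mark.parametrize(
        "rid,y,expected",
        [
            ("RU", 1, (1.0, 10.0)),  # up-regulation opens [1, z]
            ("RL", 1, (0.0, 1.0)),  # down-regulation opens [0, 1]
            ("RU", 0, (1.0, 1.0)),  # unselected stays at reference
            ("RL", 0, (1.0, 1.0)),
        ],
    )
    def test_piecewise_cases(self, small_must, rid, y, expected):
        assert etot_bounds(rid, y, 10.0, small_must) == expected

    def test_z_scales_the_up_bound(self, small_must):
        assert etot_bounds("RU", 1, 4.0, small_must) == (1.0, 4.0)

    def test_selection_outside_must_sets_is_undefined(self, small_must):
        with pytest.raises(ValidationError, match="neither MUST set"):
            etot_bounds("OTHER", 1, 10.0, small_must)

    def test_invalid_y_and_z_rejected(self, small_must):
        with pytest.raises(ValidationError):
            etot_bounds("RU", 2, 10.0, small_must)
        with pytest.raises(ValidationError):
            etot_bounds("RU", 1, 1.0, small_must)


class TestStep1:
    def test_zero_budget_returns_reference_product(
        self, toy_model, toy_truth, toy_must, toy_condition
    ):
        res = force_step1(toy_model, toy_truth, toy_must, toy_condition, kappa=0)
        assert res.interventions == []
        assert res.achieved_flux == pytest.approx(20.0, abs=1e-6)

    def test_single_intervention_improves_product(
        self, toy_model, toy_truth, toy_must, toy_condition
    ):
        res = force_step1(toy_model, toy_truth, toy_must, toy_condition, kappa=1)
        assert len(res.interventions) == 1
        assert res.achieved_flux > 20.0
        assert res.biomass_flux >= 10.0 - 1e-6
        # concentration constraint: every dynamic metabolite within fivefold
        for c in res.concentrations.values():
            assert 1 / 5 - 1e-9 <= c <= 5 + 1e-9

    def test_interventions_respect_their_bounds(
        self, toy_model, toy_truth, toy_must, toy_condition
    ):
        res = force_step1(toy_model, toy_truth, toy_must, toy_condition, kappa=2)
        for iv in res.interventions:
            lb, ub = iv.bounds
            assert lb - 1e-9 <= iv.e_tot <= ub + 1e-9
            if iv.direction == "up":
                assert iv.reaction_id in toy_must.must_u
            else:
                assert iv.reaction_id in toy_must.must_l


class TestStep2:
    def test_zero_remaining_budget_matches_bare_worst_case(
        self, toy_model, toy_truth, toy_must, toy_condition
    ):
        step1 = force_step1(toy_model, toy_truth, toy_must, toy_condition, kappa=1)
        interventions, worst = force_step2(
            toy_model, step1, toy_must, toy_condition, budget=0
        )
        assert interventions == []
        bare = worst_case_product(
            toy_model.network,
            toy_model.partition,
            step1.kinetic_fluxes,
            None,
            toy_condition,
        )
        assert worst == pytest.approx(bare.objective, abs=1e-6)

    def test_worst_case_never_exceeds_achieved(
        self, toy_model, toy_truth, toy_must, toy_condition
    ):
        for kappa in (1, 2):
            d = run_design(
                toy_model, toy_truth, toy_must, toy_condition, ForceConfig(), kappa
            )
            assert d.worst_case_flux <= d.achieved_flux + 1e-6
            assert d.yield_mol_per_mol == pytest.approx(d.achieved_flux / 100.0)


class TestEscalate:
    def test_achieved_flux_non_decreasing_and_halts(
        self, toy_model, toy_truth, toy_must, toy_condition
    ):
        cfg = ForceConfig(kappa=3, stop_rel_improvement=0.01)
        schedule = escalate(toy_model, toy_truth, toy_must, toy_condition, cfg)
        assert schedule, "escalation should propose at least one design"
        values = [d.achieved_flux for d in schedule]
        assert all(b >= a - 1e-6 for a, b in zip(values, values[1:]))
        if len(values) > 1:
            last_improvement = (values[-1] - values[-2]) / max(abs(values[-1]), 1e-9)
            assert last_improvement < cfg.stop_rel_improvement

    def test_loose_stop_threshold_stops_after_first_design(
        self, toy_model, toy_truth, toy_must, toy_condition
    ):
        cfg = ForceConfig(kappa=3, stop_rel_improvement=1.0)
        schedule = escalate(toy_model, toy_truth, toy_must, toy_condition, cfg)
        assert len(schedule) == 1

    def test_product_already_at_theoretical_max_yields_empty_schedule(
        self, toy_model, toy_truth, toy_must
    ):
        from emforce.synth import toy_branch_condition

        # with no biomass floor the waste route is free to shut; call the
        # waste export the "product": reference already attains its max
        cond = toy_branch_condition(min_product_fraction=0.0, min_biomass_fraction=0.0)
        cond = type(cond)(
            name=cond.name,
            uptake_bounds=cond.uptake_bounds,
            product_id="R1",
            min_product_fraction=0.0,
            biomass_id="EX_W",
            min_biomass_fraction=0.0,
        )
        # R1 carries the full uptake already; nothing to improve
        schedule = escalate(toy_model, toy_truth, toy_must, cond, ForceConfig(kappa=2))
        assert schedule == []
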