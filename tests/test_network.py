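import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emforce.errors import BalanceError, NetworkFormatError, ValidationError
from emforce.network import (
    Condition,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    RegulatoryRule,
    apply_condition,
    load_reference_state,
    partition,
    read_network,
    write_network,
)
from emforce.synth import ToySpec, make_toy_network, toy_branch


class TestTsvIO:
    def test_toy_fixture_round_trips_content_identically(self, tmp_path):
        network, _, _ = toy_branch()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_network(network, p1)
        write_network(read_network(p1), p2)
        assert p1.read_text() == p2.read_text()
        again = read_network(p2)
        assert len(again.metabolites) == 7
        assert len(again.reactions) == 6

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(seed=st.integers(0, 1000))
    def test_random_toys_round_trip(self, tmp_path_factory, seed):
        network, _, _ = make_toy_network(ToySpec(n_chain=3, branches=((1, "waste"),), seed=seed))
        d = tmp_path_factory.mktemp("rt")
        write_network(network, d / "a.tsv")
        write_network(read_network(d / "a.tsv"), d / "b.tsv")
        assert (d / "a.tsv").read_text() == (d / "b.tsv").read_text()

    def test_undeclared_metabolite_is_named_in_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("M\tA\t\tinternal\nR\tR1\t0\t10\t-1 A + 1 ZZZ\n")
        with pytest.raises(ValidationError, match="ZZZ"):
            read_network(p)

    def test_malformed_line_reports_location(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("M\tA\tinternal\n")
        with pytest.raises(NetworkFormatError, match="bad.tsv:1"):
            read_network(p)

    def test_empty_reaction_list_rejected(self):
        with pytest.raises(ValidationError, match="empty reaction"):
            MetabolicNetwork([Metabolite("A")], [])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            MetabolicNetwork(
                [Metabolite("A"), Metabolite("A")],
                [Reaction("R1", {"A": 1})],
            )


class TestPartition:
    def test_complement_of_kinetic_ids(self, toy):
        network, _, _ = toy
        part = partition(network, {"R1", "R2", "R3"})
        assert part.stoic_ids == frozenset({"UPT", "EX_P", "EX_W"})

    def test_empty_kinetic_set_is_pure_fba_mode(self, toy):
        network, _, _ = toy
        part = partition(network, set())
        assert part.stoic_ids == frozenset(network.reaction_ids)

    def test_unknown_id_listed_in_error(self, toy):
        network, _, _ = toy
        with pytest.raises(ValidationError, match="R9"):
            partition(network, {"R1", "R9"})

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(mask=st.lists(st.booleans(), min_size=6, max_size=6))
    def test_union_and_disjointness_hold_for_any_subset(self, toy, mask):
        network, _, _ = toy
        chosen = {rid for rid, keep in zip(network.reaction_ids, mask) if keep}
        part = partition(network, chosen)
        assert part.kinetic_ids | part.stoic_ids == set(network.reaction_ids)
        assert not part.kinetic_ids & part.stoic_ids


class TestCondition:
    def test_aerobic_uptake_bounds_are_applied(self, toy):
        network, _, _ = toy
        cond = Condition(
            name="aerobic",
            uptake_bounds={"UPT": (-100.0, -100.0)},
            product_id="EX_P",
            biomass_id="EX_W",
        )
        out = apply_condition(network, cond)
        assert (out.reaction("UPT").lb, out.reaction("UPT").ub) == (-100.0, -100.0)

    def test_repression_rule_silences_target(self, toy):
        network, _, _ = toy
        rule = RegulatoryRule(
            regulator="ArcA",
            mode="repression",
            target_reaction_ids=frozenset({"R3"}),
            condition="anaerobic",
        )
        cond = Condition(
            name="anaerobic",
            uptake_bounds={"UPT": (0.0, 0.0)},
            rules=(rule,),
            product_id="EX_P",
            biomass_id="EX_W",
        )
        out = apply_condition(network, cond)
        assert (out.reaction("R3").lb, out.reaction("R3").ub) == (0.0, 0.0)
        # a rule tied to a different condition stays dormant
        cond2 = Condition(
            name="aerobic", rules=(rule,), product_id="EX_P", biomass_id="EX_W"
        )
        out2 = apply_condition(network, cond2)
        assert out2.reaction("R3").ub > 0

    def test_identity_when_no_rules_or_bounds(self, toy):
        network, _, _ = toy
        cond = Condition(name="noop", product_id="EX_P", biomass_id="EX_W")
        out = apply_condition(network, cond)
        for r in network.reactions:
            assert (out.reaction(r.id).lb, out.reaction(r.id).ub) == (r.lb, r.ub)

    def test_idempotent(self, toy, toy_condition):
        network, _, _ = toy
        once = apply_condition(network, toy_condition)
        twice = apply_condition(once, toy_condition)
        for r in once.reactions:
            assert (twice.reaction(r.id).lb, twice.reaction(r.id).ub) == (r.lb, r.ub)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="min_product_fraction"):
            Condition(name="x", product_id="P", biomass_id="B", min_product_fraction=1.5)


class TestReferenceState:
    def _write(self, tmp_path, rows):
        p = tmp_path / "ref.tsv"
        p.write_text("\n".join(f"{k}\t{v}" for k, v in rows) + "\n")
        return p

    def test_balanced_toy_reference_loads(self, toy, tmp_path):
        network, _, _ = toy
        p = self._write(
            tmp_path,
            [("UPT", -100), ("R1", 100), ("R2", 20), ("R3", 80), ("EX_P", 20), ("EX_W", 80)],
        )
        ref = load_reference_state(p, network)
        assert ref.basis_uptake == 100
        assert ref.uptake_id == "UPT"
        assert all(c == 1.0 for c in ref.concentrations.values())

    def test_imbalance_reports_worst_metabolite(self, toy, tmp_path):
        network, _, _ = toy
        p = self._write(
            tmp_path,
            [("UPT", -100), ("R1", 100), ("R2", 30), ("R3", 80), ("EX_P", 20), ("EX_W", 80)],
        )
        with pytest.raises(BalanceError, match="M"):
            load_reference_state(p, network)

    def test_all_zero_fluxes_flagged_degenerate(self, toy, tmp_path):
        network, _, _ = toy
        p = self._write(tmp_path, [(rid, 0) for rid in network.reaction_ids])
        ref = load_reference_state(p, network)
        assert ref.degenerate
        assert ref.basis_uptake == 0
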