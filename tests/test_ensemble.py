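import numpy as np
import pytest

from emforce.ensemble import EnsembleModel, GAConfig, MutantFluxDataset, StrainRecord
from emforce.errors import ValidationError
from emforce.synth import simulate_mutants


@pytest.fixture(scope="module")
def noiseless(toy_model, toy_truth):
    return simulate_mutants(
        toy_model,
        toy_truth,
        [("WT", {}), ("dR2", {"R2": 0.0}), ("dR3", {"R3": 0.0})],
        noise_sd=0.0,
        seed=1,
    )


class TestSampling:
    def test_same_seed_gives_identical_parameterization(self, toy_model):
        a = toy_model.sample_parameterization(7)
        b = toy_model.sample_parameterization(7)
        for rid in a.reaction_ids:
            np.testing.assert_array_equal(a[rid].reversibilities, b[rid].reversibilities)
            np.testing.assert_array_equal(a[rid].kf, b[rid].kf)

    def test_different_seeds_differ_but_both_anchor(self, toy_model):
        a = toy_model.sample_parameterization(1)
        b = toy_model.sample_parameterization(2)
        assert not np.array_equal(a["R2"].kf, b["R2"].kf)
        for p in (a, b):
            st = toy_model.solve_steady_state(p)
            assert st.converged
            for rid, v in toy_model.reference.fluxes.items():
                assert st.fluxes[rid] == pytest.approx(v, abs=1e-6)


class TestSteadyState:
    def test_unperturbed_returns_reference(self, toy_model, toy_truth):
        st = toy_model.solve_steady_state(toy_truth)
        assert st.converged
        for rid, v in toy_model.reference.fluxes.items():
            assert st.fluxes[rid] == pytest.approx(v, abs=1e-6)
        for m, c in st.concentrations.items():
            assert c == pytest.approx(1.0, abs=1e-9)

    def test_knockout_reroutes_all_carbon(self, toy_model, toy_truth):
        st = toy_model.solve_steady_state(toy_truth, {"R3": 0.0})
        assert st.converged
        assert st.fluxes["R3"] == 0.0
        assert st.fluxes["R2"] == pytest.approx(100.0, abs=1e-6)
        assert st.fluxes["R1"] == pytest.approx(100.0, abs=1e-6)

    def test_upregulation_steals_flux_from_sibling_branch(self, toy_model, toy_truth):
        st = toy_model.solve_steady_state(toy_truth, {"R2": 10.0})
        assert st.converged
        assert st.fluxes["R2"] > 20.0
        assert st.fluxes["R3"] < 80.0

    def test_enzyme_conservation_at_perturbed_steady_state(self, toy_model, toy_truth):
        st = toy_model.solve_steady_state(toy_truth, {"R2": 2.0})
        for rid, target in (("R1", 1.0), ("R2", 2.0), ("R3", 1.0)):
            assert sum(st.fractions[rid].values()) == pytest.approx(target, abs=1e-9)

    def test_negative_fold_rejected(self, toy_model, toy_truth):
        with pytest.raises(ValidationError):
            toy_model.solve_steady_state(toy_truth, {"R2": -1.0})


class TestFitness:
    def test_truth_scores_near_zero_on_its_own_data(self, toy_model, toy_truth, noiseless):
        assert toy_model.fitness(toy_truth, noiseless) < 1e-6

    def test_unit_deviation_contributes_one(self, toy_model, toy_truth):
        st = toy_model.solve_steady_state(toy_truth)
        meas = {"R2": st.fluxes["R2"] + 1.0}
        ds = MutantFluxDataset(
            strains=[StrainRecord("WT", {}, meas, sd={"R2": 1.0})], uptake_id="UPT"
        )
        assert toy_model.fitness(toy_truth, ds) == pytest.approx(1.0, abs=1e-9)

    def test_random_parameterization_scores_positive(self, toy_model, noiseless):
        other = toy_model.sample_parameterization(123)
        assert toy_model.fitness(other, noiseless) > 0.0

    def test_unknown_measured_reaction_rejected(self, toy_model, toy_truth):
        ds = MutantFluxDataset(strains=[StrainRecord("WT", {}, {"NOPE": 1.0})])
        with pytest.raises(ValidationError, match="NOPE"):
            toy_model.fitness(toy_truth, ds)

    def test_rescaling_measurements_and_basis_preserves_scores(
        self, toy_model, toy_truth, noiseless
    ):
        others = [toy_model.sample_parameterization(s) for s in (11, 12)]
        lam = 2.5
        scaled = MutantFluxDataset(
            strains=[
                StrainRecord(
                    s.name,
                    s.perturbations,
                    {k: lam * v for k, v in s.measurements.items()},
                )
                for s in noiseless.strains
            ],
            uptake_id=noiseless.uptake_id,
            basis_uptake=lam * noiseless.basis_uptake,
        )
        for p in others:
            f0 = toy_model.fitness(p, noiseless)
            f1 = toy_model.fitness(p, scaled)
            assert f1 == pytest.approx(f0, rel=1e-9)


class TestGA:
    def test_truth_in_ensemble_is_recovered_by_elitism(self, toy_model, toy_truth, noiseless):
        ensemble = [toy_truth] + [toy_model.sample_parameterization(s) for s in (5, 6, 7)]
        cfg = GAConfig(population_size=4, generations=1, seed=0, fitness_tol=1e-6)
        res = toy_model.ga_fit(ensemble, noiseless, cfg)
        assert res.best_fitness < 1e-6

    def test_fixed_seed_reproduces_trajectory(self, toy_model, noiseless):
        ensemble = [toy_model.sample_parameterization(s) for s in range(30, 40)]
        cfg = GAConfig(population_size=10, generations=3, seed=42, mutation_prob=0.2)
        r1 = toy_model.ga_fit([p.copy() for p in ensemble], noiseless, cfg)
        r2 = toy_model.ga_fit([p.copy() for p in ensemble], noiseless, cfg)
        assert r1.history == r2.history

    def test_best_fitness_is_monotone_under_elitism(self, toy_model, noiseless):
        ensemble = [toy_model.sample_parameterization(s) for s in range(50, 60)]
        cfg = GAConfig(population_size=10, generations=4, seed=3, mutation_prob=0.2)
        res = toy_model.ga_fit(ensemble, noiseless, cfg)
        assert all(b >= a for a, b in zip(res.history[1:], res.history))

    def test_empty_ensemble_rejected(self, toy_model, noiseless):
        with pytest.raises(ValidationError, match="nonempty"):
            toy_model.ga_fit([], noiseless, GAConfig(population_size=2, generations=1))
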