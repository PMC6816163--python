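"""Objective functions and the model-fitting drivers."""

import math

import numpy as np
import pytest

import moietykit as mk
from moietykit import simulate as sim
from moietykit.modeling import EnergyFunction


def two_entry_profiles(obs, calc):
    g = mk.Moiety("g", {"13C": 1}, ["13C_0", "13C_1"])
    mol = mk.Molecule("mol", [g], {"13C": 1})
    contents = ((0,), (1,))
    observed = mk.IsotopologueProfile("mol", ("13C",), contents, np.array(obs))
    calculated = mk.IsotopologueProfile("mol", ("13C",), contents, np.array(calc))
    return observed, calculated


class TestLoss:
    @pytest.mark.parametrize(
        "kind", ["absolute_difference", "square_difference", "log_difference"]
    )
    def test_identical_profiles_give_zero(self, kind):
        o, c = two_entry_profiles([0.2, 0.8], [0.2, 0.8])
        assert mk.loss(o, c, mk.ObjectiveSpec(kind=kind)) == 0.0

    def test_absolute_difference(self):
        o, c = two_entry_profiles([0.2, 0.8], [0.1, 0.9])
        assert mk.loss(o, c, mk.ObjectiveSpec("absolute_difference")) == pytest.approx(0.2)

    def test_square_difference(self):
        o, c = two_entry_profiles([0.2, 0.8], [0.1, 0.9])
        assert mk.loss(o, c, mk.ObjectiveSpec("square_difference")) == pytest.approx(0.02)

    def test_log_difference_natural_log(self):
        o, c = two_entry_profiles([0.2, 0.8], [0.1, 0.9])
        expected = abs(math.log(2)) + abs(math.log(8 / 9))
        got = mk.loss(o, c, mk.ObjectiveSpec("log_difference", epsilon=0.01))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.8109, abs=1e-4)

    def test_log_difference_epsilon_censors_zeros(self):
        o, c = two_entry_profiles([0.0, 1.0], [1e-8, 1.0])
        spec = mk.ObjectiveSpec("log_difference", epsilon=1e-6)
        # both entries floored at epsilon -> equal -> zero loss
        assert mk.loss(o, c, spec) == 0.0

    def test_grid_mismatch_raises(self):
        o, _ = two_entry_profiles([0.2, 0.8], [0.1, 0.9])
        other = mk.IsotopologueProfile("mol", ("13C",), ((0,),), np.array([1.0]))
        with pytest.raises(mk.GridMismatchError):
            mk.loss(o, other, mk.ObjectiveSpec())

    def test_symmetry(self):
        o, c = two_entry_profiles([0.3, 0.7], [0.25, 0.75])
        for kind in ("absolute_difference", "square_difference", "log_difference"):
            spec = mk.ObjectiveSpec(kind)
            assert mk.loss(o, c, spec) == pytest.approx(mk.loss(c, o, spec))


class TestEnergyFunction:
    def test_infeasible_expansion_gets_penalty(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        ds = sim.profile_to_dataset(base, "d")
        energy = EnergyFunction(model, ds, mk.ObjectiveSpec())
        params = np.ones(model.free_parameter_count)  # uracil sums far over 1
        assert energy(params) == mk.PENALTY_ENERGY

    def test_energy_at_truth_is_zero_for_noiseless_data(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        ds = sim.profile_to_dataset(base, "d")
        energy = EnergyFunction(model, ds, mk.ObjectiveSpec())
        assert energy(model.extract_free_parameters(truth)) == pytest.approx(0.0, abs=1e-12)


class TestLocalRefine:
    @pytest.fixture
    def noiseless(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        return model, truth, sim.profile_to_dataset(base, "d")

    def test_start_at_optimum_is_not_worsened(self, noiseless):
        model, truth, ds = noiseless
        start = model.extract_free_parameters(truth)
        params, energy = mk.local_refine(model, ds, start, objective=mk.ObjectiveSpec("square_difference"))
        assert energy <= 1e-12

    @pytest.mark.parametrize("method", ["L-BFGS-B", "TNC", "SLSQP"])
    def test_converges_from_nearby_start(self, noiseless, method):
        model, truth, ds = noiseless
        start = np.clip(model.extract_free_parameters(truth) + 0.05, 0, 1)
        params, energy = mk.local_refine(
            model, ds, start, method=method,
            objective=mk.ObjectiveSpec("square_difference"),
        )
        assert energy < 1e-6

    def test_infeasible_start_returns_start_with_penalty(self, noiseless):
        model, _, ds = noiseless
        start = np.ones(model.free_parameter_count)
        params, energy = mk.local_refine(model, ds, start)
        assert energy == mk.PENALTY_ENERGY
        np.testing.assert_array_equal(params, start)


class TestOptimize:
    def test_single_repetition_zero_steps_echoes_initial_guess(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        ds = sim.profile_to_dataset(base, "d")
        settings = mk.OptimizationSettings(
            saga=mk.SagaSettings(step_number=0), repetitions=1, seed=9
        )
        result = mk.optimize(model, [ds], settings)
        rep = result.blocks["d"][0]
        energy = EnergyFunction(model, ds, settings.objective)
        assert rep.energy == pytest.approx(energy(rep.params))

    def test_reported_energy_matches_reported_params(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        ds = sim.profile_to_dataset(base, "d")
        settings = mk.OptimizationSettings(
            saga=mk.SagaSettings(step_number=300), repetitions=3, seed=1, polish=True
        )
        result = mk.optimize(model, [ds], settings)
        energy = EnergyFunction(model, ds, settings.objective)
        for rep in result.blocks["d"]:
            assert rep.energy == pytest.approx(energy(rep.params), abs=1e-12)

    def test_split_mode_gives_one_block_per_dataset(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        d1 = sim.profile_to_dataset(base, "t1")
        d2 = sim.profile_to_dataset(base, "t2")
        settings = mk.OptimizationSettings(
            saga=mk.SagaSettings(step_number=100), repetitions=2, seed=0
        )
        result = mk.optimize(model, [d1, d2], settings)
        assert set(result.blocks) == {"t1", "t2"}
        assert all(len(reps) == 2 for reps in result.blocks.values())
        # identical datasets, identical per-dataset seeding structure:
        # blocks differ only through their seed component
        assert result.blocks["t1"][0].params.shape == (model.free_parameter_count,)

    def test_combined_mode_concatenates_blocks(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        d1 = sim.profile_to_dataset(base, "t1")
        d2 = sim.profile_to_dataset(base, "t2")
        settings = mk.OptimizationSettings(
            saga=mk.SagaSettings(step_number=100), repetitions=1,
            dataset_mode="combined", seed=0,
        )
        result = mk.optimize(model, [d1, d2], settings)
        assert set(result.blocks) == {"combined"}
        assert result.blocks["combined"][0].params.shape == (
            2 * model.free_parameter_count,
        )

    def test_combined_shared_uses_single_block(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        d1 = sim.profile_to_dataset(base, "t1")
        d2 = sim.profile_to_dataset(base, "t2")
        settings = mk.OptimizationSettings(
            saga=mk.SagaSettings(step_number=100), repetitions=1,
            dataset_mode="combined", combined_shared=True, seed=0,
        )
        result = mk.optimize(model, [d1, d2], settings)
        assert result.blocks["combined"][0].params.shape == (model.free_parameter_count,)

    def test_scipy_method_repetitions_are_random_restarts(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        ds = sim.profile_to_dataset(base, "d")
        settings = mk.OptimizationSettings(
            method="L-BFGS-B", repetitions=5, seed=2,
            objective=mk.ObjectiveSpec("square_difference"),
        )
        result = mk.optimize(model, [ds], settings)
        energies = [r.energy for r in result.blocks["d"]]
        # feasible restarts: none stuck at the infeasibility penalty, and
        # the best local run gets close to the noiseless optimum
        assert all(e < mk.PENALTY_ENERGY for e in energies)
        assert min(energies) < 1e-4

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            mk.OptimizationSettings(method="NELDER-MEAD")

    def test_empty_datasets_rejected(self, expert_single):
        model, _ = expert_single
        with pytest.raises(ValueError):
            mk.optimize(model, [], mk.OptimizationSettings())
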