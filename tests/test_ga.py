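import itertools

import numpy as np
import pytest

import fermopt
from fermopt.design import FactorSpec
from fermopt.ffnn import NetworkParams, NetworkTopology, SurrogateModel, forward
from fermopt.ga import GAConfig, decode_chromosome, evaluate_fitness, evolve
from fermopt.scaling import ScalerParams, transform


class TestDecode:
    def test_all_zero_bits_hit_low_bounds(self, factors):
        natural = decode_chromosome(np.zeros(36, dtype=int), factors)
        assert np.allclose(natural, [32, 6, 150, 0, 1.5, 0.5])

    def test_all_one_bits_hit_high_bounds(self, factors):
        natural = decode_chromosome(np.ones(36, dtype=int), factors)
        assert np.allclose(natural, [40, 8, 190, 2, 3.5, 1.5])

    def test_msb_first_linear_map(self, factors):
        bits = np.zeros(36, dtype=int)
        bits[:6] = [0, 1, 0, 1, 0, 1]  # temperature field = 21
        natural = decode_chromosome(bits, factors)
        assert natural[0] == pytest.approx(32 + 8 * 21 / 63)

    def test_decoded_values_always_in_bounds(self, factors):
        rng = np.random.default_rng(0)
        pop = rng.integers(0, 2, (200, 36))
        natural = decode_chromosome(pop, factors)
        lows = np.array([f.low for f in factors])
        highs = np.array([f.high for f in factors])
        assert np.all(natural >= lows) and np.all(natural <= highs)

    def test_wrong_length_rejected(self, factors):
        with pytest.raises(Exception):
            decode_chromosome(np.zeros(35, dtype=int), factors)


class TestFitness:
    def test_fitness_is_the_forward_pass(self, toy_model, factors):
        """The explicit weight/bias objective equals the network forward pass."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            bits = rng.integers(0, 2, 36)
            fit = evaluate_fitness(toy_model, bits, factors)
            natural = decode_chromosome(bits, factors)
            x_scaled = transform(toy_model.x_scaler, natural[None, :])[0]
            scaled_out = forward(toy_model.params, x_scaled)
            direct = toy_model.y_scaler.mins[0] + (scaled_out + 1) * (
                toy_model.y_scaler.maxs[0] - toy_model.y_scaler.mins[0]
            ) / 2
            assert fit == pytest.approx(direct, abs=1e-12)
            assert fit == pytest.approx(toy_model.predict_natural(natural), abs=1e-12)

    def test_zero_weight_network_has_constant_fitness(self, factors):
        params = NetworkParams(np.zeros((3, 6)), np.zeros(3), np.zeros(3), 0.2)
        model = SurrogateModel(
            NetworkTopology(6, 3),
            params,
            ScalerParams(np.array([f.low for f in factors]), np.array([f.high for f in factors])),
            ScalerParams(np.array([-1.0]), np.array([1.0])),  # identity output map
        )
        rng = np.random.default_rng(2)
        fits = [evaluate_fitness(model, rng.integers(0, 2, 36), factors) for _ in range(10)]
        assert np.allclose(fits, 0.2, atol=1e-12)

    def test_one_factor_toy_net_matches_hand_evaluation(self):
        # 1-4-... actually 1-1-1: y = 2*tansig(0.5*x) + 0.1 on scaled x
        factor = (FactorSpec("x", "", 0.0, 10.0),)
        params = NetworkParams(np.array([[0.5]]), np.zeros(1), np.array([2.0]), 0.1)
        model = SurrogateModel(
            NetworkTopology(1, 1),
            params,
            ScalerParams(np.array([0.0]), np.array([10.0])),
            ScalerParams(np.array([-1.0]), np.array([1.0])),
        )
        bits = np.array([1, 0, 0, 0, 0, 0])  # field value 32 -> x = 10*32/63
        x_nat = 10 * 32 / 63
        x_scaled = 2 * x_nat / 10 - 1
        expected = 2 * np.tanh(0.5 * x_scaled) + 0.1
        assert evaluate_fitness(model, bits, factor, bits_per_factor=6) == pytest.approx(
            expected, abs=1e-12
        )


class TestEvolve:
    @staticmethod
    def _two_factor_model():
        """2-input surrogate whose fitness landscape we can enumerate exactly."""
        rng = np.random.default_rng(3)
        params = NetworkParams(
            rng.normal(size=(4, 2)), rng.normal(size=4) * 0.2, rng.normal(size=4), 0.3
        )
        factors = (FactorSpec("a", "", 0.0, 1.0), FactorSpec("b", "", -1.0, 1.0))
        model = SurrogateModel(
            NetworkTopology(2, 4),
            params,
            ScalerParams(np.array([0.0, -1.0]), np.array([1.0, 1.0])),
            ScalerParams(np.array([0.0]), np.array([10.0])),
        )
        return model, factors

    def test_beats_exhaustive_enumeration_on_12_bit_problem(self):
        model, factors = self._two_factor_model()
        all_chroms = np.array(list(itertools.product((0, 1), repeat=12)))
        exhaustive = np.asarray(
            model.predict_natural(decode_chromosome(all_chroms, factors))
        )
        best_possible = exhaustive.max()
        cfg = GAConfig(chromosome_length=12, population_size=36, max_generations=200, seed=4)
        result = evolve(model, factors, cfg)
        assert result.best_predicted_activity >= 0.999 * best_possible

    def test_best_trace_monotone_with_elitism(self):
        model, factors = self._two_factor_model()
        cfg = GAConfig(chromosome_length=12, max_generations=100, elitism=1, seed=5)
        result = evolve(model, factors, cfg)
        assert np.all(np.diff(result.best_trace) >= 0)

    def test_fully_deterministic_given_seed(self):
        model, factors = self._two_factor_model()
        cfg = GAConfig(chromosome_length=12, max_generations=50, seed=6)
        a = evolve(model, factors, cfg)
        b = evolve(model, factors, cfg)
        assert np.array_equal(a.best_chromosome, b.best_chromosome)
        assert a.best_predicted_activity == b.best_predicted_activity
        assert np.array_equal(a.best_trace, b.best_trace)
        assert [f for _, f in a.top_conditions] == [f for _, f in b.top_conditions]

    def test_no_variation_operators_freeze_population(self):
        model, factors = self._two_factor_model()
        cfg = GAConfig(
            chromosome_length=12, population_size=10, crossover_prob=0.0,
            mutation_prob=0.0, elitism=10, max_generations=30, seed=7,
        )
        result = evolve(model, factors, cfg)
        assert np.all(result.best_trace == result.best_trace[0])
        # selection reorders individuals, so the mean is only reproducible up
        # to floating-point summation order
        assert np.allclose(result.mean_trace, result.mean_trace[0], rtol=1e-12)

    def test_best_conditions_inside_factor_box(self, toy_model, factors):
        result = evolve(toy_model, factors, GAConfig(max_generations=50, seed=8))
        lows = np.array([f.low for f in factors])
        highs = np.array([f.high for f in factors])
        assert np.all(result.best_conditions_natural >= lows)
        assert np.all(result.best_conditions_natural <= highs)
        for cond, _ in result.top_conditions:
            assert np.all(cond >= lows) and np.all(cond <= highs)

    def test_shortlist_is_distinct_and_sorted(self, toy_model, factors):
        result = evolve(toy_model, factors, GAConfig(max_generations=100, top_k=4, seed=9))
        fits = [f for _, f in result.top_conditions]
        assert fits == sorted(fits, reverse=True)
        conds = {tuple(np.round(c, 9)) for c, _ in result.top_conditions}
        assert len(conds) == len(result.top_conditions)
        assert fits[0] == pytest.approx(result.best_predicted_activity, abs=1e-12)

    def test_concave_separable_objective_recovers_per_factor_optimum(self, factors):
        """Mock fitness -Σ(x_i - c_i)^2: the GA must land within one lattice
        step of the per-factor exhaustive optimum."""

        target = np.array([36.5, 7.1, 171.0, 1.2, 2.4, 0.9])

        class MockModel:
            def predict_natural(self, X):
                X = np.atleast_2d(np.asarray(X, dtype=float))
                scale = np.array([f.high - f.low for f in factors])
                return -np.sum(((X - target) / scale) ** 2, axis=1)

        cfg = GAConfig(max_generations=300, seed=10)
        result = evolve(MockModel(), factors, cfg)
        for i, f in enumerate(factors):
            lattice = f.low + (f.high - f.low) * np.arange(64) / 63
            best_lattice = lattice[np.argmin(np.abs(lattice - target[i]))]
            step = (f.high - f.low) / 63
            assert abs(result.best_conditions_natural[i] - best_lattice) <= step + 1e-9

    def test_invalid_chromosome_length_rejected(self, toy_model, factors):
        with pytest.raises(ValueError):
            evolve(toy_model, factors, GAConfig(chromosome_length=35))
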