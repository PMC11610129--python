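import math

import numpy as np
import pytest

from dmsfit.transformations import (
    DEFAULT_REGISTRY,
    SplicingCompetition,
    SumOfSigmoids,
    ThreeStateFractionBound,
    TransformationError,
    TransformationRegistry,
    TwoStateFractionFolded,
    register_custom_transformations,
    splicing_competition,
    sum_of_sigmoids,
    three_state_fraction_bound,
    two_state_fraction_folded,
)

GRID = np.linspace(-20, 20, 81)


class TestTwoState:
    def test_closed_form_values(self):
        assert two_state_fraction_folded(0.0) == pytest.approx(0.5)
        assert two_state_fraction_folded(math.log(3)) == pytest.approx(0.25)
        assert two_state_fraction_folded(1e4) == pytest.approx(0.0)
        assert two_state_fraction_folded(-1e4) == pytest.approx(1.0)

    def test_matches_boltzmann_summation(self):
        # two states with energies {0, dG}: occupied fraction from the
        # partition function directly
        for dg in GRID:
            weights = np.exp(-np.array([0.0, dg]))
            assert two_state_fraction_folded(dg) == pytest.approx(
                weights[1] / weights.sum(), abs=1e-12
            )

    def test_monotone_decreasing_and_bounded(self):
        vals = two_state_fraction_folded(GRID)
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals > 0) & (vals < 1))


class TestThreeState:
    def test_equal_energies_give_third(self):
        assert three_state_fraction_bound(0.0, 0.0) == pytest.approx(1 / 3)

    def test_unfolded_state_vanishes(self):
        assert three_state_fraction_bound(-50.0, 0.0) == pytest.approx(0.5)

    def test_matches_boltzmann_summation(self):
        # direct summation over states {0, f, f+b}
        for f in np.linspace(-20, 20, 21):
            for b in np.linspace(-20, 20, 21):
                w = np.exp(-np.array([0.0, f, f + b]) + min(0.0, f, f + b))
                expected = w[2] / w.sum()
                assert three_state_fraction_bound(f, b) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_monotone_in_each_argument(self):
        f = np.linspace(-10, 10, 41)
        vals_b = three_state_fraction_bound(1.0, f)
        assert np.all(np.diff(vals_b) < 0)  # decreasing in dG_b at fixed dG_f
        vals = three_state_fraction_bound(f, -1.0)
        assert np.all((vals > 0) & (vals < 1))

    def test_gradient_matches_finite_differences(self):
        t = ThreeStateFractionBound()
        phi = np.array([[0.3, -0.7], [2.0, 1.0], [-4.0, 3.0]])
        dp = np.array([1.0, -2.0, 0.5])
        dphi, _ = t.backward(phi, {}, dp)
        eps = 1e-6
        for j in range(2):
            hi, lo = phi.copy(), phi.copy()
            hi[:, j] += eps
            lo[:, j] -= eps
            fd = dp * (t.forward(hi, {}) - t.forward(lo, {})) / (2 * eps)
            assert np.allclose(dphi[:, j], fd, atol=1e-7)


class TestSumOfSigmoids:
    def test_zero_parameters_hand_evaluation(self):
        # one hidden neuron, all weights and biases zero: the hidden layer
        # emits sigmoid(0)=0.5, the output pre-activation is 0*0.5+0=0, so
        # the (sigmoidal) output is 0.5
        params = {
            "W0": np.zeros((1, 1)),
            "b0": np.zeros(1),
            "W1": np.zeros((1, 1)),
            "b1": np.zeros(1),
        }
        out = sum_of_sigmoids([[1.7]], params, architecture=(1,))
        assert out[0] == pytest.approx(0.5)

    def test_output_linear_returns_bias(self):
        params = {
            "W0": np.ones((1, 3)),
            "b0": np.zeros(3),
            "W1": np.zeros((3, 1)),
            "b1": np.array([0.37]),
        }
        out = sum_of_sigmoids([[2.0]], params, architecture=(3,), output_linear=True)
        assert out[0] == pytest.approx(0.37)

    def test_nonnegative_weights_give_monotone_surface(self):
        rng = np.random.default_rng(3)
        t = SumOfSigmoids((20,))
        params = t.init_params(1, rng)
        for key in ("W0", "W1"):
            params[key] = np.abs(params[key])
        phi = np.linspace(-5, 5, 101)[:, None]
        out = t.forward(phi, params)
        assert np.all(np.diff(out) >= 0)

    def test_two_hidden_layers(self):
        rng = np.random.default_rng(0)
        t = SumOfSigmoids((20, 20))
        params = t.init_params(2, rng)
        assert set(params) == {"W0", "b0", "W1", "b1", "W2", "b2"}
        assert params["W0"].shape == (2, 20)
        out = t.forward(np.zeros((5, 2)), params)
        assert out.shape == (5,)

    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        t = SumOfSigmoids((4,))
        params = t.init_params(2, rng)
        phi = rng.normal(size=(6, 2))
        dp = rng.normal(size=6)
        dphi, dparams = t.backward(phi, params, dp)

        def loss():
            return float(np.dot(dp, t.forward(phi, params)))

        eps = 1e-6
        for key, arr in params.items():
            flat = arr.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                hi = loss()
                flat[i] = orig - eps
                lo = loss()
                flat[i] = orig
                assert dparams[key].ravel()[i] == pytest.approx(
                    (hi - lo) / (2 * eps), abs=1e-6
                )

    def test_empty_architecture_rejected(self):
        with pytest.raises(TransformationError):
            SumOfSigmoids(())


class TestSplicingCompetition:
    def test_closed_form_values(self):
        assert splicing_competition(1e4, k7=1.0) == pytest.approx(0.0)
        assert splicing_competition(0.0, k7=1.0) == pytest.approx(math.log(0.5))
        assert splicing_competition(math.log(2), k7=2.0) == pytest.approx(math.log(0.5))

    def test_increasing_bounded_above_by_zero(self):
        vals = splicing_competition(GRID, k7=1.5)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals < 0)

    def test_nonpositive_k7_rejected(self):
        with pytest.raises(TransformationError):
            splicing_competition(0.0, k7=0.0)

    def test_intercept_k7_gauge(self):
        # shifting the trait by c and multiplying k7 by e^c leaves the
        # molecular phenotype unchanged
        t = SplicingCompetition()
        phi = np.linspace(-3, 3, 11)[:, None]
        c = 0.8
        base = t.forward(phi, {"log_k7": np.array([0.2])})
        shifted = t.forward(phi + c, {"log_k7": np.array([0.2 + c])})
        assert np.allclose(base, shifted, atol=1e-12)


class TestFractionBounds:
    @pytest.mark.parametrize(
        "name, n_traits", [("TwoStateFractionFolded", 1), ("ThreeStateFractionBound", 2)]
    )
    def test_outputs_in_unit_interval(self, name, n_traits):
        t = DEFAULT_REGISTRY.create(name, n_traits)
        rng = np.random.default_rng(5)
        phi = rng.uniform(-30, 30, size=(200, n_traits))
        out = t.forward(phi, {})
        assert np.all((out >= 0) & (out <= 1))


PLUGIN_SOURCE = """
import numpy as np

def _evaluate(phi, params):
    k7 = np.exp(params["log_k7"][0])
    return -np.logaddexp(0.0, np.log(k7) - phi[:, 0])

TRANSFORMATIONS = [
    {
        "name": "MySplicing",
        "n_traits": 1,
        "parameters": {"log_k7": [0.0]},
        "evaluate": _evaluate,
    },
    {
        "name": "Identity2",
        "n_traits": 1,
        "parameters": {},
        "evaluate": lambda phi, params: phi[:, 0],
    },
]
"""


class TestPlugins:
    def test_plugin_matches_builtin(self, tmp_path):
        path = tmp_path / "plugin.py"
        path.write_text(PLUGIN_SOURCE)
        registry = TransformationRegistry()
        names = register_custom_transformations(str(path), registry)
        assert "MySplicing" in names
        custom = registry.create("MySplicing", 1)
        builtin = SplicingCompetition()
        phi = np.linspace(-4, 4, 17)[:, None]
        params = {"log_k7": np.array([0.3])}
        assert np.allclose(
            custom.forward(phi, params), builtin.forward(phi, params), atol=1e-12
        )

    def test_identity_plugin(self, tmp_path):
        path = tmp_path / "plugin.py"
        path.write_text(PLUGIN_SOURCE)
        registry = TransformationRegistry()
        register_custom_transformations(str(path), registry)
        t = registry.create("Identity2", 1)
        phi = np.array([[1.5], [-2.0]])
        assert np.allclose(t.forward(phi, {}), [1.5, -2.0])

    def test_wrong_arity_rejected_at_creation(self, tmp_path):
        path = tmp_path / "plugin.py"
        path.write_text(PLUGIN_SOURCE)
        registry = TransformationRegistry()
        register_custom_transformations(str(path), registry)
        with pytest.raises(TransformationError):
            registry.create("MySplicing", 2)

    def test_malformed_plugin_describes_contract(self, tmp_path):
        path = tmp_path / "bad.py"
        path.write_text("TRANSFORMATIONS = [{'name': 'X'}]\n")
        with pytest.raises(TransformationError, match="evaluate"):
            register_custom_transformations(str(path), TransformationRegistry())

    def test_finite_difference_gradients_for_plugins(self, tmp_path):
        # plug-ins without analytic gradients still train: the default
        # backward is a finite-difference fallback
        path = tmp_path / "plugin.py"
        path.write_text(PLUGIN_SOURCE)
        registry = TransformationRegistry()
        register_custom_transformations(str(path), registry)
        t = registry.create("MySplicing", 1)
        analytic = SplicingCompetition()
        phi = np.array([[0.5], [-1.0], [2.0]])
        params = {"log_k7": np.array([0.1])}
        dp = np.array([1.0, 0.5, -1.0])
        dphi_fd, dparams_fd = t.backward(phi, params, dp)
        dphi, dparams = analytic.backward(phi, params, dp)
        assert np.allclose(dphi_fd, dphi, atol=1e-6)
        assert np.allclose(dparams_fd["log_k7"], dparams["log_k7"], atol=1e-6)
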