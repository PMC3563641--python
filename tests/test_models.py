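"""Model registry: transcription oracles, conservation laws, lookup contract."""

import numpy as np
import pytest

import modeldiscrim as md
from modeldiscrim.models import (
    BENCHMARK_PARAMS,
    HYSTERETIC_ENZYME_PARAMS,
    params_to_array,
    validate_params,
)

# ---------------------------------------------------------------------------
# Independent second transcriptions, used only as oracles.  Each reaction is
# written as (stoichiometry vector, rate function) and summed — a deliberately
# different structure from the registry implementations.
# ---------------------------------------------------------------------------


def simple_enzyme_oracle(x, p):
    S, E, ES, P = x
    reactions = [
        # S + E -> ES
        (np.array([-1, -1, 1, 0]), p["k1"] * S * E),
        # ES -> S + E
        (np.array([1, 1, -1, 0]), p["km1"] * ES),
        # ES -> E + P
        (np.array([0, 1, -1, 1]), p["k2"] * ES),
    ]
    return sum(stoich * rate for stoich, rate in reactions)


def hysteretic_enzyme_oracle(x, p):
    S, Ei, EiS, Ea, EaS, P = x
    # species order: S, Ei, EiS, Ea, EaS, P; three S consumed per complex
    reactions = [
        (np.array([-3, -1, 1, 0, 0, 0]), p["k1"] * Ei * S),   # Ei + 3S -> EiS
        (np.array([3, 1, -1, 0, 0, 0]), p["k2"] * EiS),       # EiS -> Ei + 3S
        (np.array([0, 1, -1, 0, 0, 1]), p["k3"] * EiS),       # EiS -> Ei + P
        (np.array([0, -1, 0, 1, 0, 0]), p["k4"] * Ei),        # Ei -> Ea
        (np.array([0, 1, 0, -1, 0, 0]), p["k5"] * Ea),        # Ea -> Ei
        (np.array([0, 0, 0, 1, -1, 1]), p["k6"] * EaS),       # EaS -> Ea + P
        (np.array([0, 0, -1, 0, 1, 0]), p["k7"] * EiS),       # EiS -> EaS
        (np.array([0, 0, 1, 0, -1, 0]), p["k8"] * EaS),       # EaS -> EiS
        (np.array([3, 0, 0, 1, -1, 0]), p["k9"] * EaS),       # EaS -> Ea + 3S
        (np.array([-3, 0, 0, -1, 1, 0]), p["k10"] * Ea * S),  # Ea + 3S -> EaS
    ]
    return sum(stoich * rate for stoich, rate in reactions)


def benchmark_oracle(x, p, q, c_in, variant):
    B, S, M1, M2, E = x
    D = q / p["V"]
    r1 = p["k1"] * S / (p["Ks"] + S)
    r2 = p["k2"] * E * M1 * (1.0 if variant == "B" else 1.0 / (1.0 + p["K1"] * M2))
    r3 = p["k3"] if variant == "A" else p["k3"] * M1 / (1.0 + p["K2"] * M2)
    r5 = p["Y"] * r1
    return np.array(
        [
            (r5 - D) * B,
            D * (c_in - S) - r1 * B,
            r1 - r2 - r5 * M1,
            r2 - r5 * M2,
            r3 - p["kd"] * E - r5 * E,
        ]
    )


# ---------------------------------------------------------------------------


class TestSimpleEnzyme:
    def test_zero_state_has_no_flux(self):
        m = md.get_model("simple_enzyme")
        assert np.all(m(np.zeros(4), {"k1": 3, "km1": 2, "k2": 1}) == 0)

    def test_hand_evaluated_mass_action(self):
        m = md.get_model("simple_enzyme")
        out = m([1, 1, 0, 0], {"k1": 2, "km1": 0.5, "k2": 1})
        np.testing.assert_allclose(out, [-2, -2, 2, 0])

    def test_enzyme_conservation_derivative(self, rng):
        m = md.get_model("simple_enzyme")
        for _ in range(20):
            x = rng.uniform(0, 3, 4)
            p = dict(zip(m.parameters, rng.uniform(0, 5, 3)))
            dx = m(x, p)
            assert abs(dx[1] + dx[2]) < 1e-12

    def test_matches_independent_transcription(self, rng):
        m = md.get_model("simple_enzyme")
        for _ in range(50):
            x = rng.uniform(0, 5, 4)
            p = dict(zip(m.parameters, rng.uniform(0, 10, 3)))
            np.testing.assert_allclose(m(x, p), simple_enzyme_oracle(x, p), rtol=1e-12)


class TestHystereticEnzyme:
    def test_zero_state(self):
        m = md.get_model("hysteretic_enzyme")
        assert np.all(m(np.zeros(6), HYSTERETIC_ENZYME_PARAMS) == 0)

    def test_matches_independent_transcription(self, rng):
        m = md.get_model("hysteretic_enzyme")
        for _ in range(50):
            x = rng.uniform(0, 3, 6)
            p = dict(zip(m.parameters, rng.uniform(0, 8, 10)))
            np.testing.assert_allclose(
                m(x, p), hysteretic_enzyme_oracle(x, p), rtol=1e-12, atol=1e-14
            )

    def test_substrate_mass_balance_derivative(self, rng):
        """d/dt of (free S + 3 per complex + 3 per product) vanishes."""
        m = md.get_model("hysteretic_enzyme")
        coeffs = np.array([1.0, 0.0, 3.0, 0.0, 3.0, 3.0])
        for _ in range(30):
            x = rng.uniform(0, 4, 6)
            p = dict(zip(m.parameters, rng.uniform(0, 8, 10)))
            assert abs(coeffs @ m(x, p)) < 1e-10

    def test_total_enzyme_conservation_with_table_constants(self, rng):
        m = md.get_model("hysteretic_enzyme")
        coeffs = np.array([0.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        for _ in range(30):
            x = rng.uniform(0, 2, 6)
            assert abs(coeffs @ m(x, HYSTERETIC_ENZYME_PARAMS)) < 1e-12


class TestBenchmark:
    @pytest.mark.parametrize("variant,name", [
        ("correct", "benchmark"), ("A", "benchmark_A"), ("B", "benchmark_B"),
    ])
    def test_matches_independent_transcription(self, variant, name, rng):
        m = md.get_model(name)
        for _ in range(30):
            x = rng.uniform(0, 2, 5) * np.array([10.0, 5.0, 1e-3, 1e-3, 1e-2])
            q, c_in = rng.uniform(0.01, 0.5), rng.uniform(0, 10)
            got = m(x, BENCHMARK_PARAMS, {"q_in": q, "q_out": q, "c_in": c_in})
            want = benchmark_oracle(x, BENCHMARK_PARAMS, q, c_in, variant)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)

    def test_zero_state_zero_feed_has_no_flux(self):
        m = md.get_model("benchmark")
        out = m(np.zeros(5), BENCHMARK_PARAMS, {"q_in": 0.3, "q_out": 0.3, "c_in": 0.0})
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_closed_reactor_keeps_substrate_constant_without_consumers(self):
        # q = 0 and zero biomass: tank substrate has zero derivative
        m = md.get_model("benchmark")
        x = np.array([0.0, 3.0, 0.0, 0.0, 0.0])
        out = m(x, BENCHMARK_PARAMS, {"q_in": 0.0, "q_out": 0.0, "c_in": 5.0})
        assert out[1] == 0.0

    def test_variant_A_neutralized_at_constructed_state(self):
        """With synthesis constant set to the correct law's value at a state,
        variant A's rhs equals the correct model's there."""
        mc, ma = md.get_model("benchmark"), md.get_model("benchmark_A")
        x = np.array([2.0, 1.0, 5e-4, 2e-4, 1e-3])
        p = dict(BENCHMARK_PARAMS)
        inputs = {"q_in": 0.1, "q_out": 0.1, "c_in": 5.0}
        pa = dict(p)
        pa["k3"] = p["k3"] * x[2] / (1.0 + p["K2"] * x[3])
        np.testing.assert_allclose(ma(x, pa, inputs), mc(x, p, inputs), rtol=1e-12)

    def test_variant_B_equals_correct_when_inhibitor_absent(self, rng):
        mc, mb = md.get_model("benchmark"), md.get_model("benchmark_B")
        inputs = {"q_in": 0.2, "q_out": 0.2, "c_in": 4.0}
        for _ in range(10):
            x = rng.uniform(0, 2, 5)
            x[3] = 0.0  # no M2, no inhibition
            np.testing.assert_allclose(
                mb(x, BENCHMARK_PARAMS, inputs), mc(x, BENCHMARK_PARAMS, inputs), rtol=1e-12
            )


class TestRegistry:
    def test_simple_enzyme_shape(self):
        m = md.get_model("simple_enzyme")
        assert m.n_species == 4 and m.n_parameters == 3

    def test_hysteretic_enzyme_shape(self):
        m = md.get_model("hysteretic_enzyme")
        assert m.n_species == 6 and m.n_parameters == 10

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError, match="nope"):
            md.get_model("nope")

    def test_wrong_state_length_raises(self):
        with pytest.raises(ValueError, match="shape"):
            md.get_model("simple_enzyme")([1, 2, 3], {"k1": 1, "km1": 1, "k2": 1})

    def test_all_registered_models_conserve_at_random_states(self, rng):
        for name in md.available_models():
            m = md.get_model(name)
            for desc, coeffs in m.conservation:
                c = np.asarray(coeffs)
                for _ in range(100):
                    x = rng.uniform(0, 5, m.n_species)
                    p = dict(zip(m.parameters, rng.uniform(0, 3, m.n_parameters)))
                    dx = m(x, p, {k: rng.uniform(0, 1) for k in m.inputs})
                    scale = max(np.abs(c * dx).max(), 1.0)
                    assert abs(c @ dx) / scale < 1e-10, f"{name}: {desc}"

    def test_rhs_is_deterministic_and_pure(self, rng):
        m = md.get_model("hysteretic_enzyme")
        x = rng.uniform(0, 2, 6)
        x_copy = x.copy()
        a = m(x, HYSTERETIC_ENZYME_PARAMS)
        b = m(x, HYSTERETIC_ENZYME_PARAMS)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(x, x_copy)

    def test_validate_params_rejects_negative_rates(self):
        m = md.get_model("simple_enzyme")
        with pytest.raises(ValueError, match="negative"):
            validate_params(m, {"k1": 1.0, "km1": -0.1, "k2": 1.0})

    def test_params_to_array_orders_by_label(self):
        m = md.get_model("simple_enzyme")
        arr = params_to_array(m, {"k2": 3.0, "k1": 1.0, "km1": 2.0})
        np.testing.assert_array_equal(arr, [1.0, 2.0, 3.0])

    def test_plugin_loading(self, tmp_path):
        plugin = tmp_path / "plugin.py"
        plugin.write_text(
            "import numpy as np\n"
            "from modeldiscrim import KineticModel\n"
            "MODELS = [KineticModel(name='plug', species=('X',), parameters=('a',),\n"
            "          rhs=lambda x,p,u,t: np.array([p[0]]), observed=('X',))]\n"
        )
        names = md.load_plugin_models(str(plugin))
        assert names == ["plug"]
        assert md.get_model("plug")([0.0], {"a": 2.0})[0] == 2.0
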