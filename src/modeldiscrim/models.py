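"""Registry of kinetic ODE models used for model discrimination.

A :class:`KineticModel` bundles an explicit right-hand-side function with the
bookkeeping the rest of the package needs: ordered species and parameter
labels, the measurable subset of species, external-input slots and the linear
conservation relations the dynamics must respect.  Three model families ship
with the package:

* ``simple_enzyme`` — the textbook single-conformation mechanism
  S + E <-> ES -> E + P (mass action, three rate constants).
* ``hysteretic_enzyme`` — the slow-transition model of a monomeric hysteretic
  enzyme: the enzyme exists in an inactive (Ei) and an active (Ea)
  conformation whose interconversion is slow, both conformations bind three
  substrate molecules per complex, and the active conformation binds and
  turns over substrate much faster.  The slow accumulation of active enzyme
  produces the characteristic lag phase and sigmoidal progress curves.
* ``benchmark`` (variants ``correct``/``A``/``B``) — a five-state chemostat
  network of a fictitious organism (biomass, tank substrate, two metabolites
  and an inducible enzyme) driven by the external inputs ``q_in``/``q_out``
  (flow rates) and ``c_in`` (feed substrate concentration).

Parameters are addressed by label, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import importlib.util
import numpy as np

__all__ = [
    "KineticModel",
    "get_model",
    "register_model",
    "available_models",
    "load_plugin_models",
    "params_to_array",
    "validate_params",
    "SIMPLE_ENZYME_PARAMS",
    "HYSTERETIC_ENZYME_PARAMS",
    "BENCHMARK_PARAMS",
]

RhsFunction = Callable[[np.ndarray, np.ndarray, Mapping[str, float], float], np.ndarray]


@dataclass(frozen=True)
class KineticModel:
    """A named ODE system with labelled species, parameters and inputs.

    ``rhs(state, params, inputs, t)`` returns the derivative vector; ``params``
    is an array ordered like :attr:`parameters` and ``inputs`` maps input
    labels to current values.  ``conservation`` lists ``(description, coeffs)``
    pairs whose dot product with the state is constant along trajectories.
    """

    name: str
    species: tuple[str, ...]
    parameters: tuple[str, ...]
    rhs: RhsFunction
    observed: tuple[str, ...]
    inputs: tuple[str, ...] = ()
    conservation: tuple[tuple[str, tuple[float, ...]], ...] = ()

    def __post_init__(self) -> None:
        if not set(self.observed) <= set(self.species):
            raise ValueError(
                f"observed species {set(self.observed) - set(self.species)} "
                f"not part of model {self.name!r}"
            )
        for desc, coeffs in self.conservation:
            if len(coeffs) != len(self.species):
                raise ValueError(f"conservation {desc!r} has wrong length")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    def species_index(self, label: str) -> int:
        try:
            return self.species.index(label)
        except ValueError:
            raise KeyError(f"unknown species {label!r} in model {self.name!r}") from None

    def observed_indices(self) -> np.ndarray:
        return np.array([self.species.index(s) for s in self.observed], dtype=int)

    def __call__(
        self,
        state: Sequence[float],
        params: Mapping[str, float] | Sequence[float],
        inputs: Mapping[str, float] | None = None,
        t: float = 0.0,
    ) -> np.ndarray:
        """Evaluate the right-hand side with dimension checks."""
        x = np.asarray(state, dtype=float)
        if x.shape != (self.n_species,):
            raise ValueError(
                f"state has shape {x.shape}, model {self.name!r} expects "
                f"({self.n_species},)"
            )
        p = params_to_array(self, params)
        dx = np.asarray(self.rhs(x, p, inputs or {}, t), dtype=float)
        if dx.shape != (self.n_species,):
            raise ValueError(f"rhs of {self.name!r} returned shape {dx.shape}")
        return dx


def params_to_array(
    model: KineticModel, params: Mapping[str, float] | Sequence[float]
) -> np.ndarray:
    """Order a parameter mapping (or pass through an array) as the model expects."""
    if isinstance(params, Mapping):
        missing = set(model.parameters) - set(params)
        if missing:
            raise KeyError(f"missing parameters for {model.name!r}: {sorted(missing)}")
        return np.array([float(params[k]) for k in model.parameters])
    arr = np.asarray(params, dtype=float)
    if arr.shape != (model.n_parameters,):
        raise ValueError(
            f"parameter vector has shape {arr.shape}, model {model.name!r} "
            f"expects ({model.n_parameters},)"
        )
    return arr


def validate_params(model: KineticModel, params: Mapping[str, float]) -> None:
    """Raise if a parameter set is non-finite or negative (rate constants)."""
    arr = params_to_array(model, params)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite parameter values for model {model.name!r}")
    if np.any(arr < 0):
        bad = [model.parameters[i] for i in np.where(arr < 0)[0]]
        raise ValueError(f"negative rate constants for {model.name!r}: {bad}")


# ---------------------------------------------------------------------------
# Simple enzyme: S + E <-> ES -> E + P
# ---------------------------------------------------------------------------

#: Reference rate constants for the simple mechanism (estimated against data
#: generated by the hysteretic model; the dissociation constant collapses to
#: its lower bound there).
SIMPLE_ENZYME_PARAMS: dict[str, float] = {"k1": 6.4086, "km1": 0.0, "k2": 2.0749}


def _rhs_simple_enzyme(x, p, inputs, t):
    S, E, ES, P = x
    k1, km1, k2 = p
    bind = k1 * S * E
    unbind = km1 * ES
    cat = k2 * ES
    return np.array([-bind + unbind, -bind + unbind + cat, bind - unbind - cat, cat])


# ---------------------------------------------------------------------------
# Hysteretic enzyme (slow transition model)
#
# Two conformations: Ei (inactive, sluggish) and Ea (active, efficient).
# Both bind three substrate molecules per catalytic complex; product release
# regenerates the free conformation.  Conformational transitions — free
# (k4/k5) and substrate-bound (k7/k8) — are slow, which delays the build-up
# of the fast active cycle and produces the sigmoidal progress curves.
#
#   Ei + 3S -> EiS   k1      EiS -> Ei + 3S  k2      EiS -> Ei + P   k3
#   Ei -> Ea         k4      Ea -> Ei        k5
#   EaS -> Ea + P    k6      EiS -> EaS      k7      EaS -> EiS      k8
#   EaS -> Ea + 3S   k9      Ea + 3S -> EaS  k10
# ---------------------------------------------------------------------------

#: The generating ("correct") rate constants of the hysteretic model.
HYSTERETIC_ENZYME_PARAMS: dict[str, float] = {
    "k1": 0.05,
    "k2": 0.001,
    "k3": 0.06,
    "k4": 0.001,
    "k5": 0.001,
    "k6": 6.0,
    "k7": 0.001,
    "k8": 0.001,
    "k9": 0.01,
    "k10": 4.0,
}


def _rhs_hysteretic_enzyme(x, p, inputs, t):
    S, Ei, EiS, Ea, EaS, P = x
    k1, k2, k3, k4, k5, k6, k7, k8, k9, k10 = p
    bind_i = k1 * Ei * S
    unbind_i = k2 * EiS
    cat_i = k3 * EiS
    act = k4 * Ei
    deact = k5 * Ea
    cat_a = k6 * EaS
    c_act = k7 * EiS
    c_deact = k8 * EaS
    unbind_a = k9 * EaS
    bind_a = k10 * Ea * S
    return np.array(
        [
            -3.0 * (bind_i - unbind_i) - 3.0 * (bind_a - unbind_a),
            -bind_i + unbind_i + cat_i - act + deact,
            bind_i - unbind_i - cat_i - c_act + c_deact,
            act - deact - bind_a + unbind_a + cat_a,
            bind_a - unbind_a - cat_a + c_act - c_deact,
            cat_i + cat_a,
        ]
    )


# ---------------------------------------------------------------------------
# Benchmark chemostat network (fictitious organism)
#
# States: biomass B, tank substrate S, intracellular metabolites M1 and M2
# (per unit biomass) and the inducible enzyme E.  The reactor has equal in-
# and outflow q (constant volume V); the feed carries substrate at c_in.
#
#   r1 = k1 * S / (Ks + S)            specific substrate uptake (MM)
#   r2 = k2 * E * M1 / (1 + K1*M2)    enzymatic conversion M1 -> M2; the
#                                     trailing fraction is a formal law for
#                                     non-competitive inhibition by M2
#   r3 = k3 * M1 / (1 + K2*M2)        enzyme synthesis, induced by M1 and
#                                     repressed by M2
#   r4 = kd * E                       enzyme degradation
#   r5 = Y * r1                       specific growth rate
#
# Variant A replaces r3 by the constant k3 (synthesis no longer regulated);
# variant B drops the inhibition fraction from r2.  Intracellular species are
# diluted by growth; B and S are washed out/in by the flow.
# ---------------------------------------------------------------------------

#: Correct-model constants (the k1/Ks and the two inhibition constants follow
#: the published benchmark values); Y, kd and the reactor volume are fixed
#: auxiliary constants of the reconstruction.
BENCHMARK_PARAMS: dict[str, float] = {
    "k1": 342.3e-6,
    "Ks": 0.4437,
    "k2": 12.2,
    "k3": 10.0,
    "K1": 2.4e4,
    "K2": 3.0e6,
    "Y": 2000.0,
    "kd": 0.008,
    "V": 1.0,
}

_BENCHMARK_PARAM_ORDER = ("k1", "Ks", "k2", "k3", "K1", "K2", "Y", "kd", "V")


def _benchmark_rates(x, p, variant):
    B, S, M1, M2, E = x
    k1, Ks, k2, k3, K1, K2, Y, kd, V = p
    if Ks < 0 or K1 < 0 or K2 < 0:
        raise ValueError("negative Michaelis/inhibition constants")
    r1 = k1 * S / (Ks + S) if (Ks + S) > 0 else 0.0
    inhibition = 1.0 / (1.0 + K1 * M2)
    if variant == "B":
        r2 = k2 * E * M1
    else:
        r2 = k2 * E * M1 * inhibition
    if variant == "A":
        r3 = k3
    else:
        r3 = k3 * M1 / (1.0 + K2 * M2)
    r4 = kd * E
    r5 = Y * r1
    return r1, r2, r3, r4, r5


def _make_rhs_benchmark(variant: str):
    if variant not in ("correct", "A", "B"):
        raise ValueError(f"unknown benchmark variant {variant!r}")

    def rhs(x, p, inputs, t):
        B, S, M1, M2, E = x
        V = p[-1]
        q = float(inputs.get("q_in", 0.0))
        c_in = float(inputs.get("c_in", 0.0))
        D = q / V
        r1, r2, r3, r4, r5 = _benchmark_rates(x, p, variant)
        return np.array(
            [
                (r5 - D) * B,
                D * (c_in - S) - r1 * B,
                r1 - r2 - r5 * M1,
                r2 - r5 * M2,
                r3 - r4 - r5 * E,
            ]
        )

    return rhs


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, KineticModel] = {}


def register_model(model: KineticModel, overwrite: bool = False) -> None:
    if model.name in _REGISTRY and not overwrite:
        raise ValueError(f"model {model.name!r} already registered")
    _REGISTRY[model.name] = model


def get_model(name: str) -> KineticModel:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_models() -> list[str]:
    return sorted(_REGISTRY)


def load_plugin_models(path: str) -> list[str]:
    """Load user models from a python file defining ``MODELS`` (KineticModel list)."""
    spec = importlib.util.spec_from_file_location("modeldiscrim_plugin", path)
    if spec is None or spec.loader is None:
        raise ImportError(f"cannot load plugin file {path!r}")
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    models = getattr(module, "MODELS", None)
    if not models:
        raise ValueError(f"plugin {path!r} defines no MODELS list")
    for m in models:
        register_model(m, overwrite=True)
    return [m.name for m in models]


register_model(
    KineticModel(
        name="simple_enzyme",
        species=("S", "E", "ES", "P"),
        parameters=("k1", "km1", "k2"),
        rhs=_rhs_simple_enzyme,
        observed=("S", "P"),
        conservation=(
            ("total enzyme E + ES", (0.0, 1.0, 1.0, 0.0)),
            ("total substrate S + ES + P", (1.0, 0.0, 1.0, 1.0)),
        ),
    )
)

register_model(
    KineticModel(
        name="hysteretic_enzyme",
        species=("S", "Ei", "EiS", "Ea", "EaS", "P"),
        parameters=tuple(f"k{i}" for i in range(1, 11)),
        rhs=_rhs_hysteretic_enzyme,
        observed=("S", "P"),
        conservation=(
            ("total enzyme Ei + EiS + Ea + EaS", (0.0, 1.0, 1.0, 1.0, 1.0, 0.0)),
            ("total substrate S + 3 EiS + 3 EaS + 3 P", (1.0, 0.0, 3.0, 0.0, 3.0, 3.0)),
        ),
    )
)

for _variant in ("correct", "A", "B"):
    register_model(
        KineticModel(
            name="benchmark" if _variant == "correct" else f"benchmark_{_variant}",
            species=("B", "S", "M1", "M2", "E"),
            parameters=_BENCHMARK_PARAM_ORDER,
            rhs=_make_rhs_benchmark(_variant),
            observed=("B", "S", "M1", "M2", "E"),
            inputs=("q_in", "q_out", "c_in"),
        )
    )
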