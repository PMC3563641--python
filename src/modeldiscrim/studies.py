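"""Canonical study setups shipped with the package.

These functions wire together the models, designs and noise settings of the
two discrimination studies the package reproduces — the hysteretic-vs-simple
enzyme example and the chemostat benchmark — plus a closed-form saddle toy
used to validate the max-min machinery against an analytic solution.
"""

from __future__ import annotations

import numpy as np

from .design import DesignSpace, ExperimentalDesign, equispaced_design
from .estimate import FitResult, ParameterBox, least_squares_fit
from .models import HYSTERETIC_ENZYME_PARAMS, get_model
from .simulate import SolverSettings, simulate
from .stats import Dataset, NoiseModel, generate_data

__all__ = [
    "hysteretic_recovery_design",
    "hysteretic_recovery_datasets",
    "hysteretic_recovery_fit",
    "benchmark_initial_design",
    "benchmark_design_space",
    "enzyme_design_space",
    "saddle_problem",
]


# ---------------------------------------------------------------------------
# Enzyme example: parameter-recovery experiment
# ---------------------------------------------------------------------------

#: Initial concentrations of the sigmoid-producing recovery experiment.
RECOVERY_X0 = {"S": 2.0, "Ei": 0.1}
#: 26 measurement points, 10 time units apart.
RECOVERY_N_T = 26
RECOVERY_DT = 10.0
#: Noise level: σ per species = this fraction of that species' signal range.
RECOVERY_NOISE_FRACTION = 0.01


def hysteretic_recovery_design() -> ExperimentalDesign:
    """26 equally spaced measurements at 10-time-unit spacing, no perturbations."""
    return equispaced_design(RECOVERY_N_T, RECOVERY_N_T * RECOVERY_DT, RECOVERY_X0)


def hysteretic_recovery_datasets(
    n_datasets: int = 5,
    seed: int = 0,
    noise_fraction: float = RECOVERY_NOISE_FRACTION,
    settings: SolverSettings | None = None,
) -> tuple[list[Dataset], dict[str, float]]:
    """Replicated noisy data from the hysteretic model's generating constants.

    Additive Gaussian noise with a per-species σ equal to ``noise_fraction``
    of that species' signal range over the noiseless trajectory.  Returns the
    datasets and the σ per species actually used.
    """
    model = get_model("hysteretic_enzyme")
    design = hysteretic_recovery_design()
    traj = simulate(model, HYSTERETIC_ENZYME_PARAMS, design, settings)
    spans = traj.values.max(axis=1) - traj.values.min(axis=1)
    sigmas = {s: float(noise_fraction * span) for s, span in zip(traj.species, spans)}

    rng = np.random.default_rng(seed)
    datasets = []
    for r in range(n_datasets):
        values = traj.values + np.array(
            [rng.normal(0.0, sigmas[s], traj.times.size) for s in traj.species]
        )
        clipped = int(np.sum(values < 0))
        datasets.append(
            Dataset(
                times=traj.times.copy(),
                species=traj.species,
                values=np.clip(values, 0.0, None),
                noise=NoiseModel(kind="additive", sigma=max(sigmas.values())),
                replicate_id=r,
                seed=seed,
                design=design,
                meta={"model": model.name, "clipped": clipped, "sigmas": sigmas},
            )
        )
    return datasets, sigmas


def hysteretic_recovery_fit(
    n_datasets: int = 5,
    seed: int = 0,
    init_perturbation: float = 0.2,
    settings: SolverSettings | None = None,
) -> FitResult:
    """Fit all ten rate constants to the replicated recovery data.

    The fit starts from the generating constants, each perturbed by a seeded
    uniform draw within ±20% (a fixed sign pattern would systematically bias
    the estimates of weakly identified constants toward their start values),
    runs in log-parameter space (the constants span four orders of magnitude)
    and weights residuals per species by 1/σ.
    """
    model = get_model("hysteretic_enzyme")
    datasets, sigmas = hysteretic_recovery_datasets(n_datasets, seed, settings=settings)
    init_rng = np.random.default_rng(seed + 100003)
    factors = 1.0 + init_perturbation * init_rng.uniform(-1.0, 1.0, model.n_parameters)
    init = {
        k: HYSTERETIC_ENZYME_PARAMS[k] * f for k, f in zip(model.parameters, factors)
    }
    box = ParameterBox(
        {k: 1e-8 for k in model.parameters}, {k: 100.0 for k in model.parameters}
    )
    weights = {s: 1.0 / sigmas[s] for s in sigmas}
    return least_squares_fit(
        model,
        datasets,
        init=init,
        box=box,
        weights=weights,
        log_scale=True,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# Enzyme example: discrimination design space
# ---------------------------------------------------------------------------


def enzyme_design_space(n_t: int = 30, horizon: float = 250.0) -> DesignSpace:
    """Design space of the enzyme discrimination study.

    Initial substrate in [0.1, 5] and enzyme in [0.01, 0.5]; substrate and/or
    enzyme impulses allowed at ten equally spaced measurement points.
    """
    pert_indices = tuple(range(n_t // 10, n_t + 1, max(n_t // 10, 1)))
    return DesignSpace(
        x0_bounds={"S": (0.1, 5.0), "Ei": (0.01, 0.5)},
        n_t=n_t,
        horizon=horizon,
        optimize_intervals=True,
        perturbation_bounds={"S": (0.0, 1.0), "Ei": (0.0, 0.1)},
        allowed_perturbation_indices=pert_indices,
    )


# ---------------------------------------------------------------------------
# Benchmark study
# ---------------------------------------------------------------------------

#: Initial/intermediate input levels of the benchmark's standard experiment.
BENCHMARK_INPUTS = {"q0": 0.1, "q1": 0.2, "c_in0": 5.0, "c_in1": 2.0}
#: Initial state of the chemostat.
BENCHMARK_X0 = {"B": 0.05, "S": 5.0, "M1": 0.0, "M2": 0.0, "E": 0.0}


def benchmark_initial_design() -> ExperimentalDesign:
    """The benchmark's standard experiment on our design grid.

    Thirty measurement points over 60 hours (one every 2 hours; t = 0 is not
    measured).  The flow rates are raised at the 10th time point (20 h) and
    the feed substrate concentration is reduced at the 15th (30 h).
    """
    q0, q1 = BENCHMARK_INPUTS["q0"], BENCHMARK_INPUTS["q1"]
    c0, c1 = BENCHMARK_INPUTS["c_in0"], BENCHMARK_INPUTS["c_in1"]
    return equispaced_design(
        n_t=30,
        horizon=60.0,
        x0=BENCHMARK_X0,
        perturbations={10: {"q_in": q1, "q_out": q1}, 15: {"c_in": c1}},
        input_values={"q_in": q0, "q_out": q0, "c_in": c0},
    )


def benchmark_design_space() -> DesignSpace:
    """Bounds for the benchmark design variables (flows, feed, time points)."""
    return DesignSpace(
        x0_bounds={},
        n_t=30,
        horizon=60.0,
        optimize_intervals=True,
        perturbation_bounds={"q_in": (0.02, 0.5), "q_out": (0.02, 0.5), "c_in": (0.5, 10.0)},
        allowed_perturbation_indices=(10, 15),
        input_bounds={"q_in": (0.02, 0.5), "q_out": (0.02, 0.5), "c_in": (0.5, 10.0)},
    )


# ---------------------------------------------------------------------------
# Analytic saddle toy
# ---------------------------------------------------------------------------


def saddle_problem():
    """The closed-form max-min toy J(ξ, θ) = (ξ − θ)² + ξ on [0,1]×[0,1].

    The inner minimum over θ is attained at θ = ξ, giving J = ξ; the outer
    maximum sits at ξ* = 1 with J* = 1 — verifiable by a dense 2-D grid.
    The design carries ξ as the sole designed initial value of a phantom
    species ``xi``; the rival-model parameter θ lives in the first box.
    Returns (objective_fn, space, boxes, nominal, init_design).
    """

    def J(design: ExperimentalDesign, pA, pB) -> float:
        xi = float(design.x0["xi"])
        theta = float(pA["theta"])
        return (xi - theta) ** 2 + xi

    space = DesignSpace(
        x0_bounds={"xi": (0.0, 1.0)},
        n_t=2,
        horizon=1.0,
        optimize_intervals=False,
    )
    boxes = (ParameterBox({"theta": 0.0}, {"theta": 1.0}), None)
    nominal = ({"theta": 0.5}, {})
    init = ExperimentalDesign(x0={"xi": 0.25}, intervals=np.array([0.5, 0.5]))
    return J, space, boxes, nominal, init
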