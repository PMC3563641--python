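"""The Kullback-Leibler model-discrimination criterion.

Two rival models predict responses η₁, η₂ at the design's measurement times.
Assuming Gaussian measurement noise, the KL divergence between the predicted
response distributions at one species/time point is

    kl = 1/2 [ ln(σ₂²/σ₁²) + σ₁²/σ₂² + (η₁ − η₂)²/σ₂² − 1 ]

which for equal (homoscedastic) variances reduces to (η₁ − η₂)²/(2σ²) — a
scaled sum of squared differences.  The criterion J sums these terms over
species and time points, each time point weighted by smooth step functions
that (a) suppress measurements closer together than a minimum interval Δt_min
and (b) suppress measuring at a time point that also carries a perturbation.
The hard 0/1 steps are replaced by parametrized hyperbolic tangents so the
criterion stays differentiable for gradient-based optimizers.

Note the directed criterion is non-symmetric when the two variance models
differ; :func:`symmetric_objective` sums both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .design import ExperimentalDesign
from .simulate import TrajectorySet

__all__ = [
    "StepFunctionConfig",
    "VarianceModel",
    "smooth_step",
    "measurement_weight",
    "discrimination_objective",
    "symmetric_objective",
    "ObjectiveConfig",
]


@dataclass(frozen=True)
class StepFunctionConfig:
    """A tanh-smoothed Heaviside step: ½(1 + tanh(steepness·(x − center)/width))."""

    width: float
    center: float
    steepness: float = 10.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("step width must be positive")
        if self.steepness <= 0:
            raise ValueError("step steepness must be positive")


def smooth_step(x, cfg: StepFunctionConfig):
    """Rising smooth step in [0, 1]; 1/2 at the center, → Heaviside as steepness → ∞."""
    return 0.5 * (1.0 + np.tanh(cfg.steepness * (np.asarray(x, float) - cfg.center) / cfg.width))


@dataclass(frozen=True)
class VarianceModel:
    """Measurement-variance description for the KL terms.

    ``homoscedastic``: one scalar σ for everything.  ``per_model``: two
    variance functions σ₁²(t), σ₂²(t) evaluated at the measurement times.
    """

    kind: str = "homoscedastic"
    sigma: float = 1.0
    var1: Callable[[np.ndarray], np.ndarray] | None = None
    var2: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.kind not in ("homoscedastic", "per_model"):
            raise ValueError(f"unknown variance model kind {self.kind!r}")
        if self.kind == "homoscedastic" and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kind == "per_model" and (self.var1 is None or self.var2 is None):
            raise ValueError("per_model variance needs var1 and var2 functions")

    def variances(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "homoscedastic":
            v = np.full(times.shape, self.sigma**2)
            return v, v.copy()
        v1 = np.asarray(self.var1(times), dtype=float) + np.zeros(times.shape)
        v2 = np.asarray(self.var2(times), dtype=float) + np.zeros(times.shape)
        if np.any(v1 <= 0) or np.any(v2 <= 0):
            raise ValueError("variance functions must be strictly positive")
        return v1, v2


#: Default minimum-interval step: disables intervals below ~1 time unit.
DEFAULT_DT_STEP = StepFunctionConfig(width=2.0, center=1.0, steepness=10.0)
#: Default perturbation step (applied falling): suppresses measuring under a
#: perturbation of magnitude above ~0.05.
DEFAULT_PERT_STEP = StepFunctionConfig(width=0.1, center=0.05, steepness=10.0)


def measurement_weight(
    dt_interval: float,
    pert_magnitude: float,
    cfg_dt: StepFunctionConfig = DEFAULT_DT_STEP,
    cfg_p: StepFunctionConfig = DEFAULT_PERT_STEP,
) -> float:
    """Weight of one measurement point in [0, 1].

    Product of a rising step in the preceding interval Δt (intervals below the
    minimum measurement spacing contribute nothing) and a falling step in the
    scheduled perturbation magnitude (points that are simultaneously perturbed
    contribute nothing).
    """
    if dt_interval < 0:
        raise ValueError("dt_interval must be nonnegative")
    rise = smooth_step(dt_interval, cfg_dt)
    fall = 1.0 - smooth_step(abs(pert_magnitude), cfg_p)
    return float(rise * fall)


@dataclass(frozen=True)
class ObjectiveConfig:
    """Everything the criterion needs besides the two trajectories."""

    variance: VarianceModel = VarianceModel()
    dt_step: StepFunctionConfig = DEFAULT_DT_STEP
    pert_step: StepFunctionConfig = DEFAULT_PERT_STEP
    symmetric: bool = False


def _point_weights(design: ExperimentalDesign, cfg: ObjectiveConfig) -> np.ndarray:
    return np.array(
        [
            measurement_weight(
                design.intervals[i - 1],
                design.perturbation_magnitude(i),
                cfg.dt_step,
                cfg.pert_step,
            )
            for i in range(1, design.n_t + 1)
        ]
    )


def _check_aligned(traj1: TrajectorySet, traj2: TrajectorySet):
    if traj1.values.shape != traj2.values.shape or not np.allclose(
        traj1.times, traj2.times
    ):
        raise ValueError("trajectories must share times and observed species")
    if set(traj1.species) != set(traj2.species):
        raise ValueError("trajectories must observe the same species")


def discrimination_objective(
    traj1: TrajectorySet,
    traj2: TrajectorySet,
    design: ExperimentalDesign,
    cfg: ObjectiveConfig = ObjectiveConfig(),
    return_details: bool = False,
):
    """Directed KL-based distance J(model 1 → model 2) ≥ 0.

    With ``return_details`` the per-point weights and per-species/time KL
    contributions are returned alongside J.
    """
    _check_aligned(traj1, traj2)
    order = [traj2.species.index(s) for s in traj1.species]
    eta1 = traj1.values
    eta2 = traj2.values[order]
    times = traj1.times
    v1, v2 = cfg.variance.variances(times)
    diff2 = (eta1 - eta2) ** 2
    if cfg.variance.kind == "homoscedastic":
        kl = diff2 / (2.0 * v2[None, :])
    else:
        kl = 0.5 * (np.log(v2 / v1)[None, :] + (v1 / v2)[None, :] - 1.0 + diff2 / v2[None, :])
    w = _point_weights(design, cfg)
    value = float(np.sum(w[None, :] * kl))
    if return_details:
        return value, {"weights": w, "kl_terms": kl, "times": times}
    return value


def symmetric_objective(
    traj1: TrajectorySet,
    traj2: TrajectorySet,
    design: ExperimentalDesign,
    cfg: ObjectiveConfig = ObjectiveConfig(),
) -> float:
    """J_sym = J(1→2) + J(2→1); invariant under swapping the models."""
    forward = discrimination_objective(traj1, traj2, design, cfg)
    if cfg.variance.kind == "homoscedastic":
        return 2.0 * forward
    swapped = ObjectiveConfig(
        variance=VarianceModel(kind="per_model", var1=cfg.variance.var2, var2=cfg.variance.var1),
        dt_step=cfg.dt_step,
        pert_step=cfg.pert_step,
    )
    return forward + discrimination_objective(traj2, traj1, design, swapped)
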