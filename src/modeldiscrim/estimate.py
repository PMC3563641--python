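"""Parameter estimation: least-squares fits and worst-case parameter search.

Two distinct estimation problems arise in discrimination work.  Fitting a
model to measured data is a box-constrained nonlinear least-squares problem
over its rate constants.  Finding *worst-case* parameters for a fixed design
means minimizing the discrimination criterion over the feasible parameter
boxes of the rival models — the parameter pair that makes the two model
responses most similar, which is what a robust design must guard against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .design import ExperimentalDesign
from .models import KineticModel, params_to_array
from .objective import ObjectiveConfig, discrimination_objective, symmetric_objective
from .simulate import IntegrationError, SolverSettings, simulate

__all__ = [
    "ParameterBox",
    "FitResult",
    "WorstCaseResult",
    "least_squares_fit",
    "worst_case_params",
    "make_pair_objective",
]


@dataclass(frozen=True)
class ParameterBox:
    """Elementwise bounds on a subset of a model's parameters."""

    lower: Mapping[str, float]
    upper: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "lower", dict(self.lower))
        object.__setattr__(self, "upper", dict(self.upper))
        if set(self.lower) != set(self.upper):
            raise ValueError("lower and upper must cover the same parameters")
        for k in self.lower:
            if self.lower[k] > self.upper[k]:
                raise ValueError(f"box for {k!r} is reversed")

    @property
    def labels(self) -> list[str]:
        return sorted(self.lower)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([self.lower[k] for k in self.labels]),
            np.array([self.upper[k] for k in self.labels]),
        )

    def contains(self, params: Mapping[str, float], tol: float = 1e-9) -> bool:
        return all(
            self.lower[k] - tol <= float(params[k]) <= self.upper[k] + tol
            for k in self.labels
        )

    def clip(self, params: Mapping[str, float]) -> dict[str, float]:
        out = dict(params)
        for k in self.labels:
            out[k] = float(np.clip(out[k], self.lower[k], self.upper[k]))
        return out

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        lo, hi = self.arrays()
        draw = rng.uniform(lo, hi)
        return dict(zip(self.labels, map(float, draw)))

    def is_degenerate(self, tol: float = 0.0) -> bool:
        lo, hi = self.arrays()
        return bool(np.all(hi - lo <= tol))


@dataclass
class FitResult:
    params: dict[str, float]
    ssr: float
    n_points: int
    converged: bool
    per_dataset_residuals: list[np.ndarray]
    message: str = ""


@dataclass
class WorstCaseResult:
    params1: dict[str, float]
    params2: dict[str, float]
    objective: float
    starts: int
    all_start_values: list[float]
    seed: int = 0


# ---------------------------------------------------------------------------
# Least-squares fitting
# ---------------------------------------------------------------------------


def _dataset_design(model: KineticModel, ds) -> ExperimentalDesign:
    design = getattr(ds, "design", None)
    if design is None:
        raise ValueError(
            "each dataset must carry the experimental design it was measured under"
        )
    return design


def least_squares_fit(
    model: KineticModel,
    datasets: Sequence,
    init: Mapping[str, float],
    box: ParameterBox | None = None,
    fixed: set[str] | frozenset[str] = frozenset(),
    weights: Mapping[str, float] | None = None,
    log_scale: bool = False,
    settings: SolverSettings | None = None,
) -> FitResult:
    """Fit free parameters to all datasets simultaneously (pooled residuals).

    Residuals are data − model, optionally scaled per species by ``weights``
    (e.g. 1/σ_s).  Parameters named in ``fixed`` stay at their ``init``
    values; the rest are constrained to ``box`` (default: [0, ∞)).
    ``log_scale`` optimizes log-parameters, which helps when rate constants
    span orders of magnitude.
    """
    settings = settings or SolverSettings()
    init = {k: float(v) for k, v in init.items()}
    free = [k for k in model.parameters if k not in fixed]
    if not free:
        raise ValueError("no free parameters to fit")
    if box is None:
        box = ParameterBox({k: 0.0 for k in free}, {k: np.inf for k in free})
    if set(box.labels) != set(free):
        box = ParameterBox(
            {k: box.lower.get(k, 0.0) for k in free},
            {k: box.upper.get(k, np.inf) for k in free},
        )
    lo, hi = box.arrays()
    order = box.labels
    x0 = np.array([init[k] for k in order])
    x0 = np.clip(x0, lo, hi)

    designs = [_dataset_design(model, ds) for ds in datasets]
    obs_rows = [
        [model.observed.index(s) for s in ds.species] for ds in datasets
    ]
    w_arrays = []
    for ds in datasets:
        if weights is None:
            w_arrays.append(np.ones((len(ds.species), 1)))
        else:
            w_arrays.append(np.array([[weights.get(s, 1.0)] for s in ds.species]))

    n_points = int(sum(np.asarray(ds.values).size for ds in datasets))

    def model_values(x):
        p = dict(init)
        p.update(zip(order, x))
        out = []
        for ds, design, rows in zip(datasets, designs, obs_rows):
            traj = simulate(model, p, design, settings)
            out.append(traj.values[rows])
        return out

    def residuals_list(x):
        return [
            (np.asarray(ds.values) - m) for ds, m in zip(datasets, model_values(x))
        ]

    if log_scale:
        floor = 1e-10

        def resid_vec(u):
            try:
                res = residuals_list(np.exp(u))
            except IntegrationError:
                return np.full(n_points, 1e6)
            return np.concatenate(
                [(r * w).ravel() for r, w in zip(res, w_arrays)]
            )

        result = least_squares(
            resid_vec,
            np.log(np.maximum(x0, floor)),
            bounds=(np.log(np.maximum(lo, floor)), np.log(np.minimum(hi, 1e10))),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        x_hat = np.exp(result.x)
    else:

        def resid_vec(x):
            try:
                res = residuals_list(x)
            except IntegrationError:
                return np.full(n_points, 1e6)
            return np.concatenate(
                [(r * w).ravel() for r, w in zip(res, w_arrays)]
            )

        result = least_squares(
            resid_vec,
            x0,
            bounds=(lo, hi),
            method="trf",
            x_scale=np.maximum(np.abs(x0), 1e-3),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        x_hat = result.x

    params = dict(init)
    params.update(zip(order, map(float, x_hat)))
    res_list = residuals_list(x_hat)
    ssr = float(sum((r**2).sum() for r in res_list))
    return FitResult(
        params=params,
        ssr=ssr,
        n_points=n_points,
        converged=bool(result.success),
        per_dataset_residuals=res_list,
        message=str(result.message),
    )


# ---------------------------------------------------------------------------
# Worst-case parameter search
# ---------------------------------------------------------------------------

PairObjective = Callable[[ExperimentalDesign, Mapping[str, float], Mapping[str, float]], float]


def make_pair_objective(
    modelA: KineticModel,
    modelB: KineticModel,
    cfg: ObjectiveConfig | None = None,
    settings: SolverSettings | None = None,
) -> PairObjective:
    """J(ξ, θ_A, θ_B) built from the simulator and the KL criterion."""
    cfg = cfg or ObjectiveConfig()
    settings = settings or SolverSettings()

    def J(design: ExperimentalDesign, pA: Mapping[str, float], pB: Mapping[str, float]) -> float:
        tA = simulate(modelA, pA, design, settings)
        tB = simulate(modelB, pB, design, settings)
        if cfg.symmetric:
            return symmetric_objective(tA, tB, design, cfg)
        return discrimination_objective(tA, tB, design, cfg)

    return J


def worst_case_params(
    modelA: KineticModel | None,
    modelB: KineticModel | None,
    design: ExperimentalDesign,
    boxes: tuple[ParameterBox | None, ParameterBox | None],
    nominal: tuple[Mapping[str, float], Mapping[str, float]],
    objective_cfg: ObjectiveConfig | None = None,
    n_starts: int = 5,
    seed: int = 0,
    objective_fn: PairObjective | None = None,
    warm_starts: Sequence[tuple[Mapping[str, float], Mapping[str, float]]] = (),
    settings: SolverSettings | None = None,
) -> WorstCaseResult:
    """Minimize the discrimination criterion over the free parameter boxes.

    ``boxes`` gives the feasible box per model (None = that model's
    parameters are fixed at their nominal values).  Multistart: the supplied
    ``warm_starts`` first, then uniform draws inside the boxes from a seeded
    stream, ``n_starts`` local solves in total (L-BFGS-B).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    boxA, boxB = boxes
    nomA, nomB = ({k: float(v) for k, v in nom.items()} for nom in nominal)
    J = objective_fn or make_pair_objective(modelA, modelB, objective_cfg, settings)

    labelsA = boxA.labels if boxA is not None else []
    labelsB = boxB.labels if boxB is not None else []
    if not labelsA and not labelsB:
        value = J(design, nomA, nomB)
        return WorstCaseResult(nomA, nomB, float(value), 1, [float(value)], seed)

    lo = np.concatenate(
        [boxA.arrays()[0] if labelsA else np.empty(0), boxB.arrays()[0] if labelsB else np.empty(0)]
    )
    hi = np.concatenate(
        [boxA.arrays()[1] if labelsA else np.empty(0), boxB.arrays()[1] if labelsB else np.empty(0)]
    )

    def split(x):
        pA = dict(nomA)
        pA.update(zip(labelsA, map(float, x[: len(labelsA)])))
        pB = dict(nomB)
        pB.update(zip(labelsB, map(float, x[len(labelsA) :])))
        return pA, pB

    def fun(x):
        try:
            return J(design, *split(x))
        except IntegrationError:
            return 1e10

    if np.all(hi - lo <= 0):
        x = lo
        value = fun(x)
        pA, pB = split(x)
        return WorstCaseResult(pA, pB, float(value), 1, [float(value)], seed)

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    for wA, wB in warm_starts:
        xA = [float(wA[k]) for k in labelsA]
        xB = [float(wB[k]) for k in labelsB]
        starts.append(np.clip(np.array(xA + xB), lo, hi))
    while len(starts) < n_starts:
        starts.append(rng.uniform(lo, hi))
    starts = starts[:n_starts]

    best = None
    values: list[float] = []
    failures: list[str] = []
    span = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
    for x0 in starts:
        try:
            res = minimize(
                fun,
                x0,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxiter": 500, "eps": 1e-7 * np.maximum(span, 1e-3)},
            )
        except Exception as exc:  # noqa: BLE001 - collected and reported below
            failures.append(str(exc))
            continue
        values.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} worst-case starts failed: {failures}")
    pA, pB = split(np.clip(best.x, lo, hi))
    return WorstCaseResult(pA, pB, float(best.fun), len(starts), values, seed)
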