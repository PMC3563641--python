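"""Design-phase optimization: maximize the discrimination criterion over Ξ.

Against a finite set of parameter pairs the problem is max-min; it is posed
in epigraph form — maximize the scalar s subject to J(ξ; θ_j) ≥ s for every
pair j, the duration equality Σ Δt_i = T and the design box constraints —
and solved with a sequential quadratic programming method (SLSQP).  For a
single pair this reduces to plain maximization of J.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize

from .design import DesignSpace, ExperimentalDesign
from .estimate import PairObjective
from .simulate import IntegrationError

__all__ = ["EpigraphProblem", "epigraph_reformulation", "optimal_design", "omitted_measurements"]

ParameterPair = tuple[Mapping[str, float], Mapping[str, float]]

#: Measurement points whose smooth weight falls below this threshold are
#: reported as omitted from the experiment.
OMISSION_THRESHOLD = 0.01


@dataclass
class EpigraphProblem:
    """max s  s.t.  J_j(ξ) − s ≥ 0 ∀j,  Σ Δt = T,  bounds — as a scipy problem."""

    objective: callable  # of z = [design vars, s]; returns −s
    constraints: list
    bounds: list[tuple[float, float]]
    space: DesignSpace
    template: ExperimentalDesign
    pair_objectives: list  # J_j(ξ) callables on the packed design vector

    def design_of(self, z: np.ndarray) -> ExperimentalDesign:
        return self.space.unpack(np.asarray(z)[:-1], self.template)


def _pair_evaluator(J: PairObjective, space, template, pair, weight, anchor):
    """J_j on the packed vector; optionally a homotopy blend toward an anchor pair."""
    pA, pB = pair
    if weight < 1.0 and anchor is not None:
        aA, aB = anchor
        pA = {k: weight * float(pA[k]) + (1 - weight) * float(aA[k]) for k in pA}
        pB = {k: weight * float(pB[k]) + (1 - weight) * float(aB[k]) for k in pB}

    def evaluate(x):
        design = space.unpack(x, template)
        try:
            return J(design, pA, pB)
        except IntegrationError:
            return -1e10

    return evaluate


def epigraph_reformulation(
    objective_fn: PairObjective,
    param_pairs: Sequence[ParameterPair],
    space: DesignSpace,
    template: ExperimentalDesign,
    blend_weights: Sequence[float] | None = None,
    blend_anchor: ParameterPair | None = None,
) -> EpigraphProblem:
    """Build the epigraph max-min problem over the packed design vector.

    ``blend_weights`` (one per pair, default all 1) implement the homotopy:
    a pair with weight w < 1 enters through the convex parameter blend
    w·θ_j + (1−w)·θ_anchor, ramping new constraints in gradually.
    """
    if not param_pairs:
        raise ValueError("param_pairs must be nonempty")
    weights = list(blend_weights) if blend_weights is not None else [1.0] * len(param_pairs)
    if len(weights) != len(param_pairs):
        raise ValueError("one blend weight per parameter pair required")
    evaluators = [
        _pair_evaluator(objective_fn, space, template, pair, w, blend_anchor)
        for pair, w in zip(param_pairs, weights)
    ]

    dim = space.dimension()

    def neg_s(z):
        return -z[-1]

    def neg_s_grad(z):
        g = np.zeros(dim + 1)
        g[-1] = -1.0
        return g

    constraints = [
        NonlinearConstraint(
            (lambda ev: (lambda z: ev(z[:-1]) - z[-1]))(ev), 0.0, np.inf
        )
        for ev in evaluators
    ]
    if space.optimize_intervals:
        start = len(space._x0_names)
        sel = np.zeros(dim + 1)
        sel[start : start + space.n_t] = 1.0

        def duration(z):
            return float(sel @ z) - space.horizon

        constraints.append(NonlinearConstraint(duration, 0.0, 0.0))

    bounds = list(space.bounds()) + [(-np.inf, np.inf)]
    return EpigraphProblem(
        objective=neg_s,
        constraints=constraints,
        bounds=bounds,
        space=space,
        template=template,
        pair_objectives=evaluators,
    )


def optimal_design(
    objective_fn: PairObjective,
    param_pairs: Sequence[ParameterPair],
    space: DesignSpace,
    init: ExperimentalDesign,
    blend_weights: Sequence[float] | None = None,
    blend_anchor: ParameterPair | None = None,
    maxiter: int = 120,
    ftol: float = 1e-8,
) -> tuple[ExperimentalDesign, float]:
    """Phase-two solve: a feasible local maximizer of min_j J(ξ; θ_j).

    Returns the design and the min-over-pairs objective at it (evaluated with
    the *unblended* pairs, which is the quantity the robust loop monitors).
    If the solver fails, the best feasible iterate found is returned.
    """
    if not space.is_feasible(init, tol=1e-6):
        raise ValueError("initial design is infeasible for the design space")
    problem = epigraph_reformulation(
        objective_fn, param_pairs, space, init, blend_weights, blend_anchor
    )

    x0 = space.pack(init)
    exact = [
        _pair_evaluator(objective_fn, space, init, pair, 1.0, None) for pair in param_pairs
    ]

    def min_over_pairs(x):
        return min(ev(x) for ev in exact)

    if space.dimension() == 0 or all(hi - lo <= 0 for lo, hi in space.bounds()):
        return init, float(min_over_pairs(x0))

    s0 = min(ev(x0) for ev in problem.pair_objectives)
    z0 = np.concatenate([x0, [s0]])
    res = minimize(
        problem.objective,
        z0,
        method="SLSQP",
        bounds=problem.bounds,
        constraints=problem.constraints,
        options={"maxiter": maxiter, "ftol": ftol},
    )
    candidate = problem.design_of(res.x)
    if space.is_feasible(candidate, tol=1e-6):
        x_best = np.asarray(res.x)[:-1]
        best_design = candidate
    else:  # solver wandered infeasible: fall back to the feasible start
        x_best, best_design = x0, init
    value = float(min_over_pairs(x_best))
    init_value = float(min_over_pairs(x0))
    if value < init_value - 1e-12:  # monotone safeguard: never return worse than init
        return init, init_value
    return best_design, value


def omitted_measurements(
    design: ExperimentalDesign,
    cfg,
    threshold: float = OMISSION_THRESHOLD,
) -> list[int]:
    """Indices of measurement points whose smooth weight is effectively zero."""
    from .objective import measurement_weight

    out = []
    for i in range(1, design.n_t + 1):
        w = measurement_weight(
            design.intervals[i - 1],
            design.perturbation_magnitude(i),
            cfg.dt_step,
            cfg.pert_step,
        )
        if w < threshold:
            out.append(i)
    return out
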