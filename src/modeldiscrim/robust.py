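"""The outer-approximation algorithm for robust (max-min) optimal design.

The robust design problem max_ξ min_θ J(ξ, θ) over a design space Ξ and
parameter boxes Θ is semi-infinite: infinitely many parameter constraints.
It is solved by alternating two phases.  Phase one re-estimates worst-case
parameters for the current design (a multistart box-constrained
minimization); the worst-case pair is appended to a growing finite set P_k.
Phase two computes a design that is optimal against *all* pairs in P_k
simultaneously.  The absolute difference between the phase-two objective and
the phase-one re-estimated objective — the robustification gap Δ_k — shrinks
as the two phases converge to the same saddle value and serves as the
stopping criterion.

A homotopy option stabilizes the late iterations: once the gap drops below a
trigger, each newly found worst-case pair enters phase two gradually, through
a convex parameter blend ramped from the previous worst-case pair to the new
one over a fixed number of sub-solves, so new constraints switch on slowly
instead of jolting the design problem.  The homotopy changes the path, not
the limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import DesignSpace, ExperimentalDesign
from .designopt import optimal_design
from .estimate import PairObjective, ParameterBox, WorstCaseResult, worst_case_params

__all__ = ["HomotopyConfig", "RobustState", "robustification_gap", "robust_design"]


def robustification_gap(j_design: float, j_worst: float) -> float:
    """Δ = |J_design − J_worst| ≥ 0, the convergence monitor of the loop."""
    if not (np.isfinite(j_design) and np.isfinite(j_worst)):
        raise ValueError("objective values must be finite")
    return abs(float(j_design) - float(j_worst))


@dataclass(frozen=True)
class HomotopyConfig:
    """Gradual introduction of new worst-case constraints.

    ``n_steps`` sub-solves ramp the blend weight 0 → 1; the homotopy starts
    once the robustification gap drops below ``trigger_gap``.
    """

    enabled: bool = False
    n_steps: int = 3
    trigger_gap: float = 0.1

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.trigger_gap <= 0:
            raise ValueError("trigger_gap must be positive")


@dataclass
class RobustState:
    """Full history of an outer-approximation run."""

    iteration: int = 0
    pairs: list = field(default_factory=list)  # P_k: list of (θA, θB) dicts
    designs: list = field(default_factory=list)  # ξ_k per iteration (phase-2 output)
    J_design: list = field(default_factory=list)
    J_worst: list = field(default_factory=list)
    gaps: list = field(default_factory=list)
    homotopy_used: list = field(default_factory=list)
    stopped: bool = False
    reason: str = ""
    errors: list = field(default_factory=list)

    @property
    def final_design(self) -> ExperimentalDesign:
        return self.designs[-1]

    @property
    def final_gap(self) -> float:
        return self.gaps[-1] if self.gaps else np.inf

    def history_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.gaps)),
                "J_design": self.J_design,
                "J_worst": self.J_worst,
                "gap": self.gaps,
                "n_pairs": np.arange(1, len(self.gaps) + 1),
                "homotopy": self.homotopy_used,
            }
        )


def _pair_is_duplicate(pair, pairs, rtol=1e-8):
    pA, pB = pair
    for qA, qB in pairs:
        same = True
        for p, q in ((pA, qA), (pB, qB)):
            for k in p:
                a, b = float(p[k]), float(q[k])
                if abs(a - b) > rtol * max(abs(a), abs(b), 1.0):
                    same = False
                    break
            if not same:
                break
        if same:
            return True
    return False


def robust_design(
    objective_fn: PairObjective,
    space: DesignSpace,
    boxes: tuple[ParameterBox | None, ParameterBox | None],
    nominal: tuple[Mapping[str, float], Mapping[str, float]],
    init_design: ExperimentalDesign,
    eps_stop: float = 1e-3,
    max_iter: int = 50,
    homotopy: HomotopyConfig = HomotopyConfig(),
    n_starts: int = 5,
    seed: int = 0,
    warm_start_previous: bool = True,
    log=None,
) -> RobustState:
    """Run the outer-approximation max-min loop until the gap closes.

    Each iteration k: phase one finds worst-case parameters at the current
    design ξ_k (ξ_0 is the user-supplied initial design) and appends them to
    P_k; phase two maximizes the min over P_k, yielding ξ_{k+1} and
    J_design[k]; the gap Δ_k = |J_design[k] − J_worst[k]| stops the loop at
    eps_stop.  Phase one warm-starts from the previous worst-case pair plus
    seeded random draws when ``warm_start_previous``.
    """
    if eps_stop <= 0:
        raise ValueError("eps_stop must be positive")
    if not space.is_feasible(init_design, tol=1e-6):
        raise ValueError("initial design is infeasible")

    state = RobustState()
    design = init_design
    rng = np.random.default_rng(seed)
    prev_wc: WorstCaseResult | None = None

    for k in range(max_iter):
        state.iteration = k
        sub_seed = int(rng.integers(0, 2**31 - 1))
        warm = (
            [(prev_wc.params1, prev_wc.params2)]
            if (warm_start_previous and prev_wc is not None)
            else []
        )
        try:
            wc = worst_case_params(
                None,
                None,
                design,
                boxes,
                nominal,
                n_starts=n_starts,
                seed=sub_seed,
                objective_fn=objective_fn,
                warm_starts=warm,
            )
        except Exception as exc:  # noqa: BLE001 - recorded, loop aborts with partial state
            state.errors.append(f"phase 1 failed at iteration {k}: {exc}")
            state.stopped = True
            state.reason = "phase-1 failure"
            break
        prev_wc = wc
        state.J_worst.append(wc.objective)
        new_pair = (wc.params1, wc.params2)
        if not _pair_is_duplicate(new_pair, state.pairs):
            state.pairs.append(new_pair)

        gap_known = state.gaps[-1] if state.gaps else np.inf
        use_homotopy = (
            homotopy.enabled
            and len(state.pairs) > 1
            and gap_known < homotopy.trigger_gap
        )
        state.homotopy_used.append(bool(use_homotopy))
        try:
            if use_homotopy:
                anchor = state.pairs[-2]
                for step in range(1, homotopy.n_steps + 1):
                    w = step / homotopy.n_steps
                    blend = [1.0] * (len(state.pairs) - 1) + [w]
                    design, j_design = optimal_design(
                        objective_fn,
                        state.pairs,
                        space,
                        design,
                        blend_weights=blend,
                        blend_anchor=anchor,
                    )
            else:
                design, j_design = optimal_design(
                    objective_fn, state.pairs, space, design
                )
        except Exception as exc:  # noqa: BLE001
            state.errors.append(f"phase 2 failed at iteration {k}: {exc}")
            state.stopped = True
            state.reason = "phase-2 failure"
            break
        state.designs.append(design)
        state.J_design.append(float(j_design))
        gap = robustification_gap(j_design, wc.objective)
        state.gaps.append(gap)
        if log is not None:
            log(
                f"iter={k} J_design={j_design:.6g} J_worst={wc.objective:.6g} "
                f"gap={gap:.3g} n_pairs={len(state.pairs)} homotopy={use_homotopy}"
            )
        if gap <= eps_stop:
            state.stopped = True
            state.reason = "converged"
            break
    else:
        state.stopped = True
        state.reason = "max_iter"

    if not state.designs:
        state.designs.append(init_design)
    return state
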