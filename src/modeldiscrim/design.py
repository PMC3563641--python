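"""Experimental designs and design spaces.

A design ξ collects everything the experimenter controls: initial
concentrations, the spacing of measurement time points, impulsive species
perturbations riding on the measurement grid, and piecewise-constant external
input profiles.  Time is parameterized by the intervals Δt_i between
consecutive measurements, so measurement i happens at t_i = Σ_{j<=i} Δt_j and
the intervals must sum to the fixed experimental duration T.  t = 0 is not a
measurement point: a design spanning 60 hours sampled every 2 hours has
exactly 30 measurement points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["ExperimentalDesign", "DesignSpace", "equispaced_design"]

_DURATION_TOL = 1e-9


@dataclass(frozen=True)
class ExperimentalDesign:
    """The design vector ξ.

    Parameters
    ----------
    x0 : mapping species label -> initial concentration (missing species are 0)
    intervals : the n_t inter-measurement intervals Δt_i (time units)
    perturbations : mapping measurement index (1-based) -> {label: magnitude};
        a species label means an impulsive concentration addition applied
        *after* the measurement at that index, an input label means the input
        switches to the given value from that point on.
    input_values : initial values of the external inputs.
    """

    x0: Mapping[str, float]
    intervals: np.ndarray
    perturbations: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    input_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "x0", dict(self.x0))
        object.__setattr__(
            self, "intervals", np.asarray(self.intervals, dtype=float).copy()
        )
        object.__setattr__(
            self,
            "perturbations",
            {int(i): dict(p) for i, p in dict(self.perturbations).items()},
        )
        object.__setattr__(self, "input_values", dict(self.input_values))
        if self.intervals.ndim != 1 or self.intervals.size < 1:
            raise ValueError("intervals must be a non-empty 1-D vector")
        if np.any(self.intervals < -_DURATION_TOL):
            raise ValueError("intervals must be nonnegative")
        if any(v < 0 for v in self.x0.values()):
            raise ValueError("initial concentrations must be nonnegative")
        for i in self.perturbations:
            if not (1 <= i <= self.n_t):
                raise ValueError(f"perturbation index {i} outside 1..{self.n_t}")

    @property
    def n_t(self) -> int:
        return int(self.intervals.size)

    @property
    def horizon(self) -> float:
        return float(self.intervals.sum())

    @property
    def times(self) -> np.ndarray:
        """Measurement times t_i = cumulative sums of the intervals."""
        return np.cumsum(self.intervals)

    def initial_state(self, species: tuple[str, ...]) -> np.ndarray:
        return np.array([float(self.x0.get(s, 0.0)) for s in species])

    def perturbation_magnitude(self, index: int) -> float:
        """Total absolute perturbation scheduled at a measurement index."""
        return float(sum(abs(v) for v in self.perturbations.get(index, {}).values()))

    def with_(self, **changes) -> "ExperimentalDesign":
        return replace(self, **changes)


def equispaced_design(
    n_t: int,
    horizon: float,
    x0: Mapping[str, float],
    perturbations: Mapping[int, Mapping[str, float]] | None = None,
    input_values: Mapping[str, float] | None = None,
) -> ExperimentalDesign:
    """A design with n_t equally spaced measurement points over ``horizon``."""
    return ExperimentalDesign(
        x0=x0,
        intervals=np.full(n_t, horizon / n_t),
        perturbations=perturbations or {},
        input_values=input_values or {},
    )


@dataclass(frozen=True)
class DesignSpace:
    """The feasible set Ξ, and the packing of a design into a flat vector.

    Only quantities listed here are optimized; everything else in a design is
    held fixed.  ``perturbation_bounds`` maps a target label (species to pulse
    or input to re-set) to its box; perturbations are allowed at the indices in
    ``allowed_perturbation_indices`` and their timing rides on the (movable)
    measurement grid.  ``input_bounds`` bounds the *initial* input values.
    """

    x0_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_t: int = 2
    horizon: float = 1.0
    interval_bounds: tuple[float, float] | None = None
    optimize_intervals: bool = True
    perturbation_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    allowed_perturbation_indices: tuple[int, ...] = ()
    input_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "x0_bounds", dict(self.x0_bounds))
        object.__setattr__(self, "perturbation_bounds", dict(self.perturbation_bounds))
        object.__setattr__(self, "input_bounds", dict(self.input_bounds))
        object.__setattr__(
            self,
            "allowed_perturbation_indices",
            tuple(int(i) for i in self.allowed_perturbation_indices),
        )
        if self.n_t < 1:
            raise ValueError("n_t must be >= 1")
        for name, (lo, hi) in list(self.x0_bounds.items()) + list(
            self.perturbation_bounds.items()
        ) + list(self.input_bounds.items()):
            if lo > hi:
                raise ValueError(f"bounds for {name!r} are reversed")
        lo, hi = self.effective_interval_bounds()
        if lo > hi:
            raise ValueError("interval bounds are reversed")

    def effective_interval_bounds(self) -> tuple[float, float]:
        if self.interval_bounds is None:
            return (0.0, self.horizon)
        return self.interval_bounds

    # -- packing ------------------------------------------------------------

    @property
    def _x0_names(self) -> list[str]:
        return sorted(self.x0_bounds)

    @property
    def _pert_slots(self) -> list[tuple[int, str]]:
        return [
            (i, label)
            for i in self.allowed_perturbation_indices
            for label in sorted(self.perturbation_bounds)
        ]

    @property
    def _input_names(self) -> list[str]:
        return sorted(self.input_bounds)

    def dimension(self) -> int:
        n = len(self._x0_names) + len(self._pert_slots) + len(self._input_names)
        if self.optimize_intervals:
            n += self.n_t
        return n

    def pack(self, design: ExperimentalDesign) -> np.ndarray:
        parts: list[float] = [design.x0.get(s, 0.0) for s in self._x0_names]
        if self.optimize_intervals:
            if design.n_t != self.n_t:
                raise ValueError("design has wrong number of intervals for this space")
            parts.extend(design.intervals)
        parts.extend(
            design.perturbations.get(i, {}).get(label, 0.0)
            for i, label in self._pert_slots
        )
        parts.extend(design.input_values.get(n, 0.0) for n in self._input_names)
        return np.asarray(parts, dtype=float)

    def unpack(self, vec: np.ndarray, template: ExperimentalDesign) -> ExperimentalDesign:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.dimension(),):
            raise ValueError(f"expected vector of length {self.dimension()}")
        pos = 0
        x0 = dict(template.x0)
        for s in self._x0_names:
            x0[s] = max(float(vec[pos]), 0.0)
            pos += 1
        if self.optimize_intervals:
            intervals = np.clip(vec[pos : pos + self.n_t], 0.0, None)
            pos += self.n_t
        else:
            intervals = template.intervals
        perts = {i: dict(p) for i, p in template.perturbations.items()}
        for i, label in self._pert_slots:
            perts.setdefault(i, {})[label] = float(vec[pos])
            pos += 1
        inputs = dict(template.input_values)
        for n in self._input_names:
            inputs[n] = float(vec[pos])
            pos += 1
        return ExperimentalDesign(
            x0=x0, intervals=intervals, perturbations=perts, input_values=inputs
        )

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = [self.x0_bounds[s] for s in self._x0_names]
        if self.optimize_intervals:
            b.extend([self.effective_interval_bounds()] * self.n_t)
        b.extend(self.perturbation_bounds[label] for _, label in self._pert_slots)
        b.extend(self.input_bounds[n] for n in self._input_names)
        return b

    def is_feasible(self, design: ExperimentalDesign, tol: float = 1e-6) -> bool:
        vec = self.pack(design)
        for v, (lo, hi) in zip(vec, self.bounds()):
            if v < lo - tol or v > hi + tol:
                return False
        if self.optimize_intervals and abs(design.horizon - self.horizon) > tol:
            return False
        return True
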