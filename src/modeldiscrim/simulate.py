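"""Initial-value-problem solving under an experimental design.

The simulator integrates a model piecewise between measurement times with a
stiff-capable integrator, applies impulsive species perturbations and input
switches at the scheduled grid indices, and returns the observed species at
the measurement times.  At a time point that carries both a measurement and a
perturbation, the measurement is taken *before* the impulse is applied, so the
pre-perturbation state is what the experiment records.

Parameter and design sensitivities are available either by central finite
differences of the simulator (default) or by integrating the forward
sensitivity ODEs alongside the states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .design import ExperimentalDesign
from .models import KineticModel, params_to_array

__all__ = ["SolverSettings", "TrajectorySet", "IntegrationError", "simulate", "sensitivities"]


#: States beyond this magnitude abort integration as a blow-up.
_STATE_BLOWUP = 1e12


class _StateBlowup(Exception):
    def __init__(self, t: float):
        self.t = t


class IntegrationError(RuntimeError):
    """Raised when the integrator fails; carries the failing time interval."""

    def __init__(self, message: str, interval: tuple[float, float]):
        super().__init__(f"{message} (interval {interval[0]:g}..{interval[1]:g})")
        self.interval = interval


@dataclass(frozen=True)
class SolverSettings:
    """Integrator tolerances and the sensitivity method."""

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    method: str = "LSODA"  # stiff-capable; "BDF" also accepted
    sensitivity_method: str = "finite_difference"  # or "forward_ode"
    max_step: float | None = None
    negative_tol: float = 1e-6

    def __post_init__(self):
        if not (0 < self.rel_tol < 1 and 0 < self.abs_tol < 1):
            raise ValueError("tolerances must lie in (0, 1)")
        if self.sensitivity_method not in ("finite_difference", "forward_ode"):
            raise ValueError(f"unknown sensitivity method {self.sensitivity_method!r}")


@dataclass
class TrajectorySet:
    """Model responses η at the measurement times for each observed species."""

    times: np.ndarray
    species: tuple[str, ...]
    values: np.ndarray  # (n_observed, n_times)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), self.times.size):
            raise ValueError("values shape inconsistent with species/times")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")

    def row(self, species: str) -> np.ndarray:
        return self.values[self.species.index(species)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, **{s: self.values[i] for i, s in enumerate(self.species)}}
        )


def _segment_times(design: ExperimentalDesign) -> np.ndarray:
    return np.concatenate([[0.0], design.times])


def simulate(
    model: KineticModel,
    params: Mapping[str, float] | Sequence[float],
    design: ExperimentalDesign,
    settings: SolverSettings | None = None,
) -> TrajectorySet:
    """Solve the IVP for ``model`` under ``design`` and sample the observables."""
    settings = settings or SolverSettings()
    p = params_to_array(model, params)
    if design.horizon <= 0:
        raise ValueError("design horizon must be positive")

    state = design.initial_state(model.species)
    inputs = dict(design.input_values)
    # an input "switch" scheduled at index 0 would be an initial value; those
    # live in design.input_values already.
    times = _segment_times(design)
    samples = np.empty((model.n_species, design.n_t))
    warnings: list[str] = []

    kwargs = dict(rtol=settings.rel_tol, atol=settings.abs_tol, method=settings.method)
    if settings.max_step is not None:
        kwargs["max_step"] = settings.max_step

    def rhs(t, y):
        if not np.all(np.isfinite(y)) or np.any(np.abs(y) > _STATE_BLOWUP):
            raise _StateBlowup(t)
        return model.rhs(y, p, inputs, t)

    for i in range(1, len(times)):
        t0, t1 = times[i - 1], times[i]
        if t1 > t0:
            try:
                sol = solve_ivp(rhs, (t0, t1), state, **kwargs)
            except _StateBlowup as blow:
                raise IntegrationError(
                    f"state blow-up near t={blow.t:g}", (t0, t1)
                ) from None
            if not sol.success:
                raise IntegrationError(sol.message, (t0, t1))
            state = sol.y[:, -1]
        samples[:, i - 1] = state  # measurement BEFORE any impulse at t1
        sched = design.perturbations.get(i)
        if sched:
            state = state.copy()
            for label, magnitude in sched.items():
                if label in model.species:
                    state[model.species_index(label)] += magnitude
                elif label in model.inputs:
                    inputs[label] = magnitude
                else:
                    raise KeyError(
                        f"perturbation target {label!r} is neither a species nor "
                        f"an input of model {model.name!r}"
                    )

    if np.any(samples < -settings.negative_tol):
        warnings.append(
            f"negative concentrations beyond tolerance (min {samples.min():.3e})"
        )

    obs = model.observed_indices()
    return TrajectorySet(
        times=design.times.copy(),
        species=model.observed,
        values=samples[obs],
        meta={
            "model": model.name,
            "params": {k: float(v) for k, v in zip(model.parameters, p)},
            "warnings": warnings,
        },
    )


# ---------------------------------------------------------------------------
# Sensitivities
# ---------------------------------------------------------------------------


def _perturbed_eval(model, params, design, settings, label, delta):
    p = dict(zip(model.parameters, params_to_array(model, params)))
    d = design
    if label in model.parameters:
        p[label] = p[label] + delta
    elif label.startswith("x0:"):
        sp = label.split(":", 1)[1]
        x0 = dict(d.x0)
        x0[sp] = x0.get(sp, 0.0) + delta
        d = d.with_(x0=x0)
    else:
        raise KeyError(
            f"unknown sensitivity variable {label!r}; use a parameter label or 'x0:<species>'"
        )
    return simulate(model, p, d, settings).values


def _fd_sensitivities(model, params, design, settings, wrt):
    base = params_to_array(model, params)
    bad = [
        lbl for lbl in wrt if lbl not in model.parameters and not lbl.startswith("x0:")
    ]
    if bad:
        raise KeyError(f"unknown sensitivity variables {bad}")
    out = np.empty((len(model.observed), design.n_t, len(wrt)))
    for j, label in enumerate(wrt):
        if label in model.parameters:
            scale = abs(base[model.parameters.index(label)])
        else:
            scale = abs(design.x0.get(label.split(":", 1)[1], 0.0))
        h = 1e-6 * max(scale, 1e-3)
        hi = _perturbed_eval(model, params, design, settings, label, +h)
        lo = _perturbed_eval(model, params, design, settings, label, -h)
        out[:, :, j] = (hi - lo) / (2 * h)
    return out


def _forward_ode_sensitivities(model, params, design, settings, wrt):
    """Integrate the forward sensitivity ODEs s' = J_x s + J_v alongside x.

    Jacobians of the right-hand side are formed by central differences of the
    rhs itself (cheap: no repeated IVP solves).
    """
    p = params_to_array(model, params)
    n, m = model.n_species, len(wrt)
    param_idx = {lbl: model.parameters.index(lbl) for lbl in wrt if lbl in model.parameters}
    x0_idx = {
        lbl: model.species_index(lbl.split(":", 1)[1]) for lbl in wrt if lbl.startswith("x0:")
    }
    unknown = [lbl for lbl in wrt if lbl not in param_idx and lbl not in x0_idx]
    if unknown:
        raise KeyError(f"unknown sensitivity variables {unknown}")

    inputs = dict(design.input_values)

    def jac_x(x, t):
        J = np.empty((n, n))
        for i in range(n):
            h = 1e-7 * max(abs(x[i]), 1e-3)
            xp = x.copy(); xp[i] += h
            xm = x.copy(); xm[i] -= h
            J[:, i] = (model.rhs(xp, p, inputs, t) - model.rhs(xm, p, inputs, t)) / (2 * h)
        return J

    def jac_v(x, t):
        J = np.zeros((n, m))
        for j, lbl in enumerate(wrt):
            if lbl in param_idx:
                k = param_idx[lbl]
                h = 1e-7 * max(abs(p[k]), 1e-3)
                pp = p.copy(); pp[k] += h
                pm = p.copy(); pm[k] -= h
                J[:, j] = (model.rhs(x, pp, inputs, t) - model.rhs(x, pm, inputs, t)) / (2 * h)
        return J

    def aug_rhs(t, z):
        x = z[:n]
        S = z[n:].reshape(n, m)
        dx = model.rhs(x, p, inputs, t)
        dS = jac_x(x, t) @ S + jac_v(x, t)
        return np.concatenate([dx, dS.ravel()])

    state = design.initial_state(model.species)
    S = np.zeros((n, m))
    for lbl, i in x0_idx.items():
        S[i, wrt.index(lbl)] = 1.0

    times = _segment_times(design)
    out = np.empty((n, design.n_t, m))
    kwargs = dict(rtol=settings.rel_tol, atol=settings.abs_tol, method=settings.method)
    for i in range(1, len(times)):
        t0, t1 = times[i - 1], times[i]
        if t1 > t0:
            sol = solve_ivp(aug_rhs, (t0, t1), np.concatenate([state, S.ravel()]), **kwargs)
            if not sol.success:
                raise IntegrationError(sol.message, (t0, t1))
            z = sol.y[:, -1]
            state, S = z[:n], z[n:].reshape(n, m)
        out[:, i - 1, :] = S
        sched = design.perturbations.get(i)
        if sched:
            state = state.copy()
            for label, magnitude in sched.items():
                if label in model.species:
                    state[model.species_index(label)] += magnitude
                else:
                    inputs[label] = magnitude
    return out[model.observed_indices()]


def sensitivities(
    model: KineticModel,
    params: Mapping[str, float] | Sequence[float],
    design: ExperimentalDesign,
    settings: SolverSettings | None = None,
    wrt: Sequence[str] = (),
) -> np.ndarray:
    """∂η/∂v for each requested variable v.

    ``wrt`` entries are parameter labels or ``"x0:<species>"`` design
    components.  Returns an array of shape (observed species, times, variables).
    """
    settings = settings or SolverSettings()
    wrt = list(wrt)
    if not wrt:
        raise ValueError("wrt must name at least one variable")
    if settings.sensitivity_method == "forward_ode":
        return _forward_ode_sensitivities(model, params, design, settings, wrt)
    return _fd_sensitivities(model, params, design, settings, wrt)
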