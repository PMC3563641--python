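"""Synthetic measurement generation and statistical diagnostics.

Noise models: *additive* Gaussian (y = η + ε, ε ~ N(0, σ²)) and *relative*
Gaussian (y = η·(1 + ε)) — the two measurement-error models used for the
enzyme and the chemostat discrimination studies respectively.

Diagnostics:

* a replicated-design lack-of-fit test that decomposes the residual variance
  around a fitted curve into lack-of-fit and pure-error components and
  compares their ratio to an F distribution;
* a residual-variance ratio test between two rival models (larger variance
  over smaller, F-distributed under the null of equal residual scatter);
* the KL-divergence robustness histogram: the discrimination objective
  evaluated at many random parameter draws inside the feasible boxes, used to
  verify that no feasible parameters discriminate worse than the worst-case
  value a robust design guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .design import ExperimentalDesign
from .estimate import PairObjective, ParameterBox
from .models import KineticModel
from .simulate import SolverSettings, simulate

__all__ = [
    "NoiseModel",
    "Dataset",
    "LackOfFitResult",
    "HistogramResult",
    "generate_data",
    "lack_of_fit_test",
    "variance_ratio_test",
    "kl_histogram",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description (σ = 0 means noiseless)."""

    kind: str = "additive"  # or "relative"
    sigma: float = 0.0
    mean: float = 0.0

    def __post_init__(self):
        if self.kind not in ("additive", "relative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0 and self.mean == 0:
            return values.copy()
        eps = rng.normal(self.mean, self.sigma, values.shape)
        if self.kind == "additive":
            return values + eps
        return values * (1.0 + eps)


@dataclass
class Dataset:
    """One replicate of measured (or synthetic) time-series data."""

    times: np.ndarray
    species: tuple[str, ...]
    values: np.ndarray  # (n_species, n_times)
    noise: NoiseModel = NoiseModel()
    replicate_id: int = 0
    seed: int = 0
    design: ExperimentalDesign | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), self.times.size):
            raise ValueError("values shape inconsistent with species/times")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dataset contains non-finite values")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, **{s: self.values[i] for i, s in enumerate(self.species)}}
        )


def generate_data(
    model: KineticModel,
    params: Mapping[str, float],
    design: ExperimentalDesign,
    noise: NoiseModel = NoiseModel(),
    n_datasets: int = 1,
    seed: int = 0,
    settings: SolverSettings | None = None,
) -> list[Dataset]:
    """Simulate the model under the design, then corrupt with seeded noise.

    Noise is applied independently per species, time point and replicate from
    one deterministic stream; negative results are clipped at zero and the
    number of clipped values recorded in each dataset's metadata.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    traj = simulate(model, params, design, settings)
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_datasets):
        values = noise.apply(traj.values, rng)
        clipped = int(np.sum(values < 0))
        values = np.clip(values, 0.0, None)
        out.append(
            Dataset(
                times=traj.times.copy(),
                species=traj.species,
                values=values,
                noise=noise,
                replicate_id=r,
                seed=seed,
                design=design,
                meta={"model": model.name, "clipped": clipped},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Lack-of-fit test
# ---------------------------------------------------------------------------


@dataclass
class LackOfFitResult:
    f_statistic: dict[str, float]
    df_lof: int
    df_pure: int
    critical_value: float
    reject: dict[str, bool]
    alpha: float
    ss_lof: dict[str, float] = field(default_factory=dict)
    ss_pure: dict[str, float] = field(default_factory=dict)

    @property
    def any_rejected(self) -> bool:
        return any(self.reject.values())


def lack_of_fit_test(
    model: KineticModel,
    params: Mapping[str, float],
    datasets: Sequence[Dataset],
    alpha: float = 0.05,
    n_params: int | None = None,
    settings: SolverSettings | None = None,
) -> LackOfFitResult:
    """Replicated-design lack-of-fit ANOVA per observed species.

    With r replicates on a shared grid of n_t points and a fitted curve η_t:
    SS_lof = Σ_t r (ȳ_t − η_t)², SS_pure = Σ_t Σ_rep (y − ȳ_t)²,
    F = (SS_lof/df_lof)/(SS_pure/df_pure), df_lof = n_t − p and
    df_pure = n_t (r − 1).  The null of an adequate model is rejected when F
    exceeds the F(df_lof, df_pure) quantile at 1 − α.
    """
    if len(datasets) < 2:
        raise ValueError("lack-of-fit needs >= 2 replicates (pure error undefined)")
    times = datasets[0].times
    species = datasets[0].species
    for ds in datasets[1:]:
        if not np.allclose(ds.times, times) or ds.species != species:
            raise ValueError("replicates must share the time grid and species")
    r = len(datasets)
    n_t = times.size
    p = n_params if n_params is not None else model.n_parameters
    df_lof = n_t - p
    df_pure = n_t * (r - 1)
    if df_lof <= 0:
        raise ValueError("not enough time points for the lack-of-fit degrees of freedom")

    design = datasets[0].design
    if design is None:
        raise ValueError("datasets must carry their design")
    traj = simulate(model, params, design, settings)
    rows = [traj.species.index(s) for s in species]
    eta = traj.values[rows]

    stacked = np.stack([ds.values for ds in datasets])  # (r, n_species, n_t)
    ybar = stacked.mean(axis=0)
    ss_pure_arr = ((stacked - ybar[None]) ** 2).sum(axis=(0, 2))
    ss_lof_arr = (r * (ybar - eta) ** 2).sum(axis=1)
    crit = float(sps.f.ppf(1 - alpha, df_lof, df_pure))

    f_stat, reject, ss_l, ss_p = {}, {}, {}, {}
    for i, s in enumerate(species):
        ms_pure = ss_pure_arr[i] / df_pure
        f = float((ss_lof_arr[i] / df_lof) / ms_pure) if ms_pure > 0 else np.inf
        f_stat[s] = f
        reject[s] = bool(f > crit)
        ss_l[s] = float(ss_lof_arr[i])
        ss_p[s] = float(ss_pure_arr[i])
    return LackOfFitResult(
        f_statistic=f_stat,
        df_lof=df_lof,
        df_pure=df_pure,
        critical_value=crit,
        reject=reject,
        alpha=alpha,
        ss_lof=ss_l,
        ss_pure=ss_p,
    )


# ---------------------------------------------------------------------------
# Residual-variance ratio test
# ---------------------------------------------------------------------------


def variance_ratio_test(
    residualsA: np.ndarray,
    residualsB: np.ndarray,
    alpha: float = 0.05,
    use_sd_ratio: bool = False,
) -> tuple[float, float, bool]:
    """F test on the ratio of residual variances of two rival models.

    The larger sample variance over the smaller is compared to the
    F(n_big, n_small) quantile at 1 − α, degrees of freedom taken as the
    residual counts.  ``use_sd_ratio`` compares the ratio of standard
    deviations instead of variances (a literal reproduction mode; the
    variance ratio is the statistically proper statistic).
    Returns (ratio, critical value, reject).
    """
    a = np.asarray(residualsA, float).ravel()
    b = np.asarray(residualsB, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("residual vectors must be nonempty")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        num, den, dfn, dfd = va, vb, a.size, b.size
    else:
        num, den, dfn, dfd = vb, va, b.size, a.size
    if den == 0:
        return np.inf, float(sps.f.ppf(1 - alpha, dfn, dfd)), True
    ratio = num / den
    if use_sd_ratio:
        ratio = float(np.sqrt(ratio))
    critical = float(sps.f.ppf(1 - alpha, dfn, dfd))
    return float(ratio), critical, bool(ratio > critical)


# ---------------------------------------------------------------------------
# KL robustness histogram
# ---------------------------------------------------------------------------


@dataclass
class HistogramResult:
    draws: int
    bin_edges: np.ndarray
    counts: np.ndarray
    min_objective: float
    worst_case_objective: float | None
    values: np.ndarray
    failures: int = 0

    @property
    def robust(self) -> bool | None:
        if self.worst_case_objective is None:
            return None
        return bool(self.min_objective >= self.worst_case_objective - 1e-9)


def kl_histogram(
    objective_fn: PairObjective,
    design: ExperimentalDesign,
    boxes: tuple[ParameterBox | None, ParameterBox | None],
    nominal: tuple[Mapping[str, float], Mapping[str, float]],
    n_draws: int = 1000,
    n_bins: int = 100,
    seed: int = 0,
    worst_case_value: float | None = None,
) -> HistogramResult:
    """Objective values at uniform parameter draws, binned into n_bins equal bins.

    Draws are uniform inside the free boxes (a model with box None stays at
    its nominal parameters).  Simulation failures are counted and excluded.
    The minimum observed objective, compared to ``worst_case_value``, is the
    robustness check: for a converged robust design no draw should fall below
    the worst-case objective.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    boxA, boxB = boxes
    nomA, nomB = nominal
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(n_draws):
        pA = dict(nomA)
        if boxA is not None:
            pA.update(boxA.sample(rng))
        pB = dict(nomB)
        if boxB is not None:
            pB.update(boxB.sample(rng))
        try:
            values.append(float(objective_fn(design, pA, pB)))
        except Exception:  # noqa: BLE001 - failed draws are counted and excluded
            failures += 1
    values = np.asarray(values)
    if values.size == 0:
        raise RuntimeError("all histogram draws failed")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + max(abs(lo), 1.0) * 1e-12
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return HistogramResult(
        draws=n_draws,
        bin_edges=edges,
        counts=counts,
        min_objective=float(values.min()),
        worst_case_objective=worst_case_value,
        values=values,
        failures=failures,
    )
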