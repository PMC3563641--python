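"""Serialization and run configuration.

Time series travel as delimited text (first column time, one column per
observed species) with an optional JSON sidecar carrying noise/seed
metadata.  Designs serialize to JSON (lossless round trip) and to a
plain-text matrix dump for downstream processing; robust-run histories
serialize to JSON with the gap/objective traces also exportable as
delimited text.

A :class:`RunConfig` is a validated YAML tree describing one pipeline stage;
validation collects *all* violations before reporting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .design import DesignSpace, ExperimentalDesign
from .estimate import ParameterBox
from .models import available_models, get_model
from .objective import ObjectiveConfig, StepFunctionConfig, VarianceModel
from .robust import HomotopyConfig, RobustState
from .simulate import SolverSettings, TrajectorySet
from .stats import Dataset, NoiseModel

__all__ = [
    "save_trajectory",
    "save_dataset",
    "load_dataset",
    "design_to_dict",
    "design_from_dict",
    "export_design",
    "import_design",
    "export_design_matrix",
    "save_history",
    "RunConfig",
    "ConfigError",
]


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------


def save_trajectory(traj: TrajectorySet, path: str | Path, sep: str = ",") -> None:
    traj.to_frame().to_csv(path, sep=sep, index=False)


def save_dataset(ds: Dataset, path: str | Path, sep: str = ",") -> None:
    path = Path(path)
    ds.to_frame().to_csv(path, sep=sep, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "noise": {"kind": ds.noise.kind, "sigma": ds.noise.sigma, "mean": ds.noise.mean},
                "replicate_id": ds.replicate_id,
                "seed": ds.seed,
                "meta": ds.meta,
            },
            indent=2,
        )
    )


def load_dataset(
    path: str | Path, design: ExperimentalDesign | None = None, sep: str = ","
) -> Dataset:
    path = Path(path)
    frame = pd.read_csv(path, sep=sep)
    if frame.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    species = tuple(frame.columns[1:])
    noise = NoiseModel()
    replicate_id, seed, meta = 0, 0, {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        n = info.get("noise", {})
        noise = NoiseModel(
            kind=n.get("kind", "additive"), sigma=n.get("sigma", 0.0), mean=n.get("mean", 0.0)
        )
        replicate_id = info.get("replicate_id", 0)
        seed = info.get("seed", 0)
        meta = info.get("meta", {})
    return Dataset(
        times=frame["time"].to_numpy(),
        species=species,
        values=frame[list(species)].to_numpy().T,
        noise=noise,
        replicate_id=replicate_id,
        seed=seed,
        design=design,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------


def design_to_dict(design: ExperimentalDesign) -> dict:
    return {
        "x0": {k: float(v) for k, v in design.x0.items()},
        "intervals": [float(v) for v in design.intervals],
        "perturbations": {
            str(i): {k: float(v) for k, v in p.items()}
            for i, p in design.perturbations.items()
        },
        "input_values": {k: float(v) for k, v in design.input_values.items()},
    }


def design_from_dict(data: Mapping[str, Any]) -> ExperimentalDesign:
    return ExperimentalDesign(
        x0=data.get("x0", {}),
        intervals=np.asarray(data["intervals"], dtype=float),
        perturbations={int(i): p for i, p in data.get("perturbations", {}).items()},
        input_values=data.get("input_values", {}),
    )


def export_design(design: ExperimentalDesign, path: str | Path) -> None:
    """JSON export; lossless (import_design(export_design(d)) == d)."""
    Path(path).write_text(json.dumps(design_to_dict(design), indent=2))


def import_design(path: str | Path) -> ExperimentalDesign:
    return design_from_dict(json.loads(Path(path).read_text()))


def export_design_matrix(design: ExperimentalDesign, path: str | Path | None = None) -> str:
    """Plain-text bracketed matrix dump of a design (one row per quantity)."""
    lines = []
    fmt = lambda vals: "[" + ", ".join(f"{float(v):.10g}" for v in vals) + "]"  # noqa: E731
    lines.append("intervals = " + fmt(design.intervals))
    lines.append("times = " + fmt(design.times))
    species = sorted(design.x0)
    lines.append("x0_labels = [" + ", ".join(species) + "]")
    lines.append("x0 = " + fmt([design.x0[s] for s in species]))
    targets = sorted({label for p in design.perturbations.values() for label in p})
    lines.append("perturbation_labels = [" + ", ".join(targets) + "]")
    for label in targets:
        row = [design.perturbations.get(i, {}).get(label, 0.0) for i in range(1, design.n_t + 1)]
        lines.append(f"perturbation_{label} = " + fmt(row))
    inputs = sorted(design.input_values)
    lines.append("input_labels = [" + ", ".join(inputs) + "]")
    lines.append("input_values = " + fmt([design.input_values[k] for k in inputs]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Robust-run history
# ---------------------------------------------------------------------------


def save_history(state: RobustState, path: str | Path) -> None:
    data = {
        "iterations": state.iteration + 1 if state.gaps else 0,
        "stopped": state.stopped,
        "reason": state.reason,
        "J_design": state.J_design,
        "J_worst": state.J_worst,
        "gaps": state.gaps,
        "homotopy_used": state.homotopy_used,
        "pairs": [
            [{k: float(v) for k, v in p.items()} for p in pair] for pair in state.pairs
        ],
        "designs": [design_to_dict(d) for d in state.designs],
        "errors": state.errors,
    }
    Path(path).write_text(json.dumps(data, indent=2))


def save_history_trace(state: RobustState, path: str | Path, sep: str = ",") -> None:
    state.history_table().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class ConfigError(ValueError):
    """Raised with the full list of validation violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid run configuration:\n  - " + "\n  - ".join(errors))


def _bounds_map(tree: Mapping[str, Any], errors: list[str], where: str):
    out = {}
    for key, pair in (tree or {}).items():
        try:
            lo, hi = float(pair[0]), float(pair[1])
        except (TypeError, ValueError, IndexError):
            errors.append(f"{where}.{key}: expected [lower, upper]")
            continue
        if lo > hi:
            errors.append(f"{where}.{key}: lower bound exceeds upper bound")
        out[key] = (lo, hi)
    return out


@dataclass
class RunConfig:
    """Validated configuration tree for one pipeline stage."""

    raw: dict
    path: str | None = None
    errors: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError([f"{path}: config must be a mapping"])
        cfg = cls(raw=raw, path=str(path))
        cfg.validate()
        return cfg

    # -- section accessors --------------------------------------------------

    def model(self, key: str = "model"):
        return get_model(self.raw[key])

    def model_pair(self):
        pair = self.raw.get("models", {})
        return get_model(pair["a"]), get_model(pair["b"])

    def params(self, key: str = "params") -> dict[str, float]:
        return {k: float(v) for k, v in (self.raw.get(key) or {}).items()}

    def design(self) -> ExperimentalDesign:
        tree = self.raw.get("design") or {}
        if "intervals" in tree:
            intervals = np.asarray(tree["intervals"], dtype=float)
        else:
            n_t = int(tree.get("n_t", 2))
            horizon = float(tree.get("horizon", 1.0))
            intervals = np.full(n_t, horizon / n_t)
        return ExperimentalDesign(
            x0=tree.get("x0", {}),
            intervals=intervals,
            perturbations={int(i): p for i, p in (tree.get("perturbations") or {}).items()},
            input_values=tree.get("input_values", {}),
        )

    def design_space(self) -> DesignSpace:
        tree = self.raw.get("space") or {}
        errors: list[str] = []
        space = DesignSpace(
            x0_bounds=_bounds_map(tree.get("x0_bounds"), errors, "space.x0_bounds"),
            n_t=int(tree.get("n_t", 2)),
            horizon=float(tree.get("horizon", 1.0)),
            interval_bounds=tuple(tree["interval_bounds"]) if "interval_bounds" in tree else None,
            optimize_intervals=bool(tree.get("optimize_intervals", True)),
            perturbation_bounds=_bounds_map(
                tree.get("perturbation_bounds"), errors, "space.perturbation_bounds"
            ),
            allowed_perturbation_indices=tuple(tree.get("allowed_perturbation_indices", ())),
            input_bounds=_bounds_map(tree.get("input_bounds"), errors, "space.input_bounds"),
        )
        if errors:
            raise ConfigError(errors)
        return space

    def boxes(self) -> tuple[ParameterBox | None, ParameterBox | None]:
        tree = self.raw.get("boxes") or {}

        def one(side):
            sub = tree.get(side)
            if not sub:
                return None
            return ParameterBox(
                {k: float(v[0]) for k, v in sub.items()},
                {k: float(v[1]) for k, v in sub.items()},
            )

        return one("a"), one("b")

    def objective_config(self) -> ObjectiveConfig:
        tree = self.raw.get("objective") or {}

        def step(sub, default):
            if not sub:
                return default
            return StepFunctionConfig(
                width=float(sub.get("width", default.width)),
                center=float(sub.get("center", default.center)),
                steepness=float(sub.get("steepness", default.steepness)),
            )

        from .objective import DEFAULT_DT_STEP, DEFAULT_PERT_STEP

        return ObjectiveConfig(
            variance=VarianceModel(kind="homoscedastic", sigma=float(tree.get("sigma", 1.0))),
            dt_step=step(tree.get("dt_step"), DEFAULT_DT_STEP),
            pert_step=step(tree.get("pert_step"), DEFAULT_PERT_STEP),
            symmetric=bool(tree.get("symmetric", False)),
        )

    def noise(self) -> NoiseModel:
        tree = self.raw.get("noise") or {}
        return NoiseModel(
            kind=tree.get("kind", "additive"),
            sigma=float(tree.get("sigma", 0.0)),
            mean=float(tree.get("mean", 0.0)),
        )

    def solver_settings(self) -> SolverSettings:
        tree = self.raw.get("solver") or {}
        return SolverSettings(
            rel_tol=float(tree.get("rel_tol", 1e-8)),
            abs_tol=float(tree.get("abs_tol", 1e-10)),
            method=str(tree.get("method", "LSODA")),
            sensitivity_method=str(tree.get("sensitivity_method", "finite_difference")),
        )

    def robust_options(self) -> dict:
        tree = self.raw.get("robust") or {}
        h = tree.get("homotopy") or {}
        return {
            "eps_stop": float(tree.get("eps_stop", 1e-3)),
            "max_iter": int(tree.get("max_iter", 50)),
            "n_starts": int(tree.get("n_starts", 5)),
            "seed": int(tree.get("seed", 0)),
            "homotopy": HomotopyConfig(
                enabled=bool(h.get("enabled", False)),
                n_steps=int(h.get("n_steps", 3)),
                trigger_gap=float(h.get("trigger_gap", 0.1)),
            ),
        }

    def provenance(self) -> dict:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return {
            "config_path": self.path,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": (self.raw.get("robust") or {}).get("seed", self.raw.get("seed", 0)),
        }

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        errors: list[str] = []
        raw = self.raw

        def check_model(name, where):
            if name not in available_models():
                errors.append(f"{where}: unknown model {name!r} (available: {available_models()})")
                return None
            return get_model(name)

        models = []
        if "model" in raw:
            m = check_model(raw["model"], "model")
            if m:
                models.append(m)
        if "models" in raw:
            pair = raw["models"]
            if not isinstance(pair, dict) or set(pair) - {"a", "b"} or {"a", "b"} - set(pair):
                errors.append("models: expected mapping with keys 'a' and 'b'")
            else:
                for side in ("a", "b"):
                    m = check_model(pair[side], f"models.{side}")
                    if m:
                        models.append(m)

        known_species = {s for m in models for s in m.species}
        known_params = {p for m in models for p in m.parameters}
        known_inputs = {i for m in models for i in m.inputs}

        for key in ("params", "params_a", "params_b"):
            for label in raw.get(key) or {}:
                if models and label not in known_params:
                    errors.append(f"{key}.{label}: not a parameter of the named model(s)")

        design_tree = raw.get("design") or {}
        for label in design_tree.get("x0") or {}:
            if models and label not in known_species:
                errors.append(f"design.x0.{label}: not a species of the named model(s)")
        for idx, sched in (design_tree.get("perturbations") or {}).items():
            try:
                int(idx)
            except (TypeError, ValueError):
                errors.append(f"design.perturbations: index {idx!r} is not an integer")
            for label in sched or {}:
                if models and label not in known_species | known_inputs:
                    errors.append(
                        f"design.perturbations[{idx}].{label}: neither species nor input"
                    )
        if "intervals" in design_tree:
            try:
                iv = np.asarray(design_tree["intervals"], dtype=float)
                if np.any(iv < 0):
                    errors.append("design.intervals: negative interval")
            except (TypeError, ValueError):
                errors.append("design.intervals: not a numeric list")

        boxes_tree = raw.get("boxes") or {}
        for side in boxes_tree:
            if side not in ("a", "b"):
                errors.append(f"boxes.{side}: expected sides 'a'/'b'")
                continue
            for label, pair in (boxes_tree[side] or {}).items():
                if models and label not in known_params:
                    errors.append(f"boxes.{side}.{label}: not a parameter of the named model(s)")
                try:
                    if float(pair[0]) > float(pair[1]):
                        errors.append(f"boxes.{side}.{label}: lower bound exceeds upper")
                except (TypeError, ValueError, IndexError):
                    errors.append(f"boxes.{side}.{label}: expected [lower, upper]")

        noise_tree = raw.get("noise") or {}
        if noise_tree.get("kind", "additive") not in ("additive", "relative"):
            errors.append(f"noise.kind: unknown kind {noise_tree.get('kind')!r}")
        if float(noise_tree.get("sigma", 0.0) or 0.0) < 0:
            errors.append("noise.sigma: must be nonnegative")

        self.errors = errors
        if errors:
            raise ConfigError(errors)
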