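"""Synthetic miniature forecast hub with closed-form ground truth.

Each component model is a parametric predictive distribution (normal,
lognormal, or point mass), optionally shifted per horizon, and is emitted
in all six output types over a declared task grid.  Observations are
drawn from a designated truth distribution.  Everything is deterministic
under the spec's seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import HubSpecError
from .schema import (
    ModelOutputTable,
    TargetSeries,
    validate_model_output,
    validate_target_series,
)

#: the 23 standard FluSight quantile levels
FLUSIGHT_LEVELS = (
    0.01, 0.025, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50,
    0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.975, 0.99,
)

FAMILIES = ("normal", "lognormal", "point")


@dataclass(frozen=True)
class ModelSpec:
    """One component model: a distribution family with parameters.

    ``normal``: params (mu, sigma); ``lognormal``: params (mu, sigma) of
    log-values; ``point``: params (c,).  ``horizon_drift`` shifts the
    location by drift * horizon when the task grid has a ``horizon``
    column, creating cross-horizon structure for joint samples.
    """

    model_id: str
    family: str
    params: tuple[float, ...]
    horizon_drift: float = 0.0

    def frozen(self, horizon: float = 0.0):
        shift = self.horizon_drift * horizon
        if self.family == "normal":
            mu, sigma = self.params
            return stats.norm(loc=mu + shift, scale=sigma)
        if self.family == "lognormal":
            mu, sigma = self.params
            return stats.lognorm(s=sigma, scale=float(np.exp(mu + shift)))
        if self.family == "point":
            (c,) = self.params
            # degenerate distribution approximated by a vanishing scale
            return stats.norm(loc=c + shift, scale=1e-12)
        raise HubSpecError(f"unknown family {self.family!r}")

    def mean(self, horizon: float = 0.0) -> float:
        return float(self.frozen(horizon).mean())

    def variance(self, horizon: float = 0.0) -> float:
        if self.family == "point":
            return 0.0
        return float(self.frozen(horizon).var())


@dataclass(frozen=True)
class HubSpec:
    """Specification of a synthetic forecast hub."""

    models: tuple[ModelSpec, ...]
    task_grid: Mapping[str, Sequence] = field(
        default_factory=lambda: {"location": ["A"], "horizon": [0]}
    )
    levels: tuple[float, ...] = FLUSIGHT_LEVELS
    cdf_value_grid: tuple[float, ...] = ()
    pmf_cut_points: tuple[float, ...] = ()
    pmf_categories: tuple[str, ...] = ()
    n_samples_per_model: int = 100
    truth: ModelSpec | None = None
    joint_across: str | None = None  # task column within which samples are joint
    seed: int = 0

    def __post_init__(self):
        if not self.models:
            raise HubSpecError("at least one model is required")
        for m in self.models:
            if m.family not in FAMILIES:
                raise HubSpecError(f"unknown family {m.family!r} for {m.model_id}")
            if m.family in ("normal", "lognormal") and m.params[1] <= 0:
                raise HubSpecError(f"scale must be positive for {m.model_id}")
        lv = np.asarray(self.levels, dtype=float)
        if ((lv <= 0) | (lv >= 1)).any():
            raise HubSpecError("levels must lie strictly in (0, 1)")
        mirrored = np.sort(1.0 - lv)
        if not np.allclose(np.sort(lv), mirrored, atol=1e-12):
            raise HubSpecError("level grid must be symmetric about 0.5")
        if self.pmf_cut_points and (np.diff(self.pmf_cut_points) <= 0).any():
            raise HubSpecError("pmf cut points must be strictly increasing")
        if self.pmf_cut_points:
            want = len(self.pmf_cut_points) + 1
            if self.pmf_categories and len(self.pmf_categories) != want:
                raise HubSpecError(
                    f"{want} pmf categories needed for {len(self.pmf_cut_points)} cut points"
                )
        if self.joint_across is not None and self.joint_across not in self.task_grid:
            raise HubSpecError(f"joint_across column {self.joint_across!r} not in task grid")

    @property
    def task_id_names(self) -> tuple[str, ...]:
        return tuple(self.task_grid)

    def tasks(self) -> list[dict]:
        names = list(self.task_grid)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.task_grid[n] for n in names))
        ]

    def pmf_category_labels(self) -> tuple[str, ...]:
        if self.pmf_categories:
            return self.pmf_categories
        n = len(self.pmf_cut_points) + 1
        return tuple(f"bin_{i + 1}" for i in range(n))

    @staticmethod
    def from_json(path: str | Path) -> "HubSpec":
        raw = json.loads(Path(path).read_text())
        models = tuple(
            ModelSpec(
                model_id=m["model_id"],
                family=m["family"],
                params=tuple(m["params"]),
                horizon_drift=m.get("horizon_drift", 0.0),
            )
            for m in raw["models"]
        )
        truth = raw.get("truth")
        if truth is not None:
            truth = ModelSpec(
                model_id="truth",
                family=truth["family"],
                params=tuple(truth["params"]),
                horizon_drift=truth.get("horizon_drift", 0.0),
            )
        return HubSpec(
            models=models,
            task_grid=raw.get("task_grid", {"location": ["A"], "horizon": [0]}),
            levels=tuple(raw.get("levels", FLUSIGHT_LEVELS)),
            cdf_value_grid=tuple(raw.get("cdf_value_grid", ())),
            pmf_cut_points=tuple(raw.get("pmf_cut_points", ())),
            pmf_categories=tuple(raw.get("pmf_categories", ())),
            n_samples_per_model=raw.get("n_samples_per_model", 100),
            truth=truth,
            joint_across=raw.get("joint_across"),
            seed=raw.get("seed", 0),
        )


def _task_horizon(task: Mapping) -> float:
    try:
        return float(task.get("horizon", 0))
    except (TypeError, ValueError):
        return 0.0


def generate_component_outputs(
    spec: HubSpec,
    output_types: Sequence[str] = ("mean", "median", "quantile", "cdf", "pmf", "sample"),
) -> ModelOutputTable:
    """Emit every model x task in the requested output types.

    Point rows and quantile/cdf/pmf rows are exact functionals of the
    model's distribution; sample rows are seeded pseudo-random draws.
    When ``spec.joint_across`` names a task column (e.g. ``horizon``),
    one uniform is drawn per sample index and transformed through each
    horizon's quantile function, giving genuinely joint samples.
    """
    output_types = list(output_types)
    unknown = set(output_types) - {"mean", "median", "quantile", "cdf", "pmf", "sample"}
    if unknown:
        raise HubSpecError(f"unknown output types: {sorted(unknown)}")
    if "pmf" in output_types and not spec.pmf_cut_points:
        output_types = [t for t in output_types if t != "pmf"]
    if "cdf" in output_types and not spec.cdf_value_grid:
        output_types = [t for t in output_types if t != "cdf"]

    rng = np.random.default_rng(spec.seed)
    names = list(spec.task_id_names)
    tasks = spec.tasks()
    records: list[dict] = []

    # group tasks into joint units (all tasks equal except joint_across)
    if spec.joint_across is not None and "sample" in output_types:
        other = [n for n in names if n != spec.joint_across]
        units: dict[tuple, list[dict]] = {}
        for t in tasks:
            units.setdefault(tuple(t[n] for n in other), []).append(t)
    else:
        units = {(i,): [t] for i, t in enumerate(tasks)}

    for model in spec.models:
        sample_counter = 0
        for t in tasks:
            h = _task_horizon(t)
            dist = model.frozen(h)
            base = {**{n: t[n] for n in names}, "model_id": model.model_id}
            if "mean" in output_types:
                records.append(
                    {**base, "output_type": "mean", "output_type_id": np.nan,
                     "value": float(dist.mean())}
                )
            if "median" in output_types:
                records.append(
                    {**base, "output_type": "median", "output_type_id": np.nan,
                     "value": float(dist.ppf(0.5))}
                )
            if "quantile" in output_types:
                for th in spec.levels:
                    records.append(
                        {**base, "output_type": "quantile", "output_type_id": float(th),
                         "value": float(dist.ppf(th))}
                    )
            if "cdf" in output_types:
                for x in spec.cdf_value_grid:
                    records.append(
                        {**base, "output_type": "cdf", "output_type_id": float(x),
                         "value": float(dist.cdf(x))}
                    )
            if "pmf" in output_types:
                cuts = np.asarray(spec.pmf_cut_points, dtype=float)
                cdf_at = dist.cdf(cuts)
                probs = np.diff(np.concatenate(([0.0], cdf_at, [1.0])))
                probs = probs / probs.sum()
                for label, p in zip(spec.pmf_category_labels(), probs):
                    records.append(
                        {**base, "output_type": "pmf", "output_type_id": label,
                         "value": float(p)}
                    )
        if "sample" in output_types:
            for unit_tasks in units.values():
                u = rng.uniform(size=spec.n_samples_per_model)
                for k in range(spec.n_samples_per_model):
                    idx = sample_counter + k
                    for t in unit_tasks:
                        dist = model.frozen(_task_horizon(t))
                        records.append(
                            {
                                **{n: t[n] for n in names},
                                "model_id": model.model_id,
                                "output_type": "sample",
                                "output_type_id": idx,
                                "value": float(dist.ppf(u[k])),
                            }
                        )
                sample_counter += spec.n_samples_per_model

    df = pd.DataFrame.from_records(records)
    df = df.loc[:, ["model_id", *names, "output_type", "output_type_id", "value"]]
    return validate_model_output(
        df, names,
        pmf_category_order=spec.pmf_category_labels() if spec.pmf_cut_points else None,
    )


def generate_target_series(spec: HubSpec) -> TargetSeries:
    """One seeded observation per task, drawn from the truth distribution."""
    if spec.truth is None:
        raise HubSpecError("HubSpec.truth is required to generate targets")
    rng = np.random.default_rng(spec.seed + 1)
    names = list(spec.task_id_names)
    records = []
    for t in spec.tasks():
        dist = spec.truth.frozen(_task_horizon(t))
        if spec.truth.family == "point":
            obs = spec.truth.params[0] + spec.truth.horizon_drift * _task_horizon(t)
        else:
            obs = float(dist.ppf(rng.uniform()))
        records.append({**{n: t[n] for n in names}, "observation": obs})
    return validate_target_series(pd.DataFrame.from_records(records), names)
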