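"""Linear opinion pool (mixture) ensembles.

For cdf/pmf/mean inputs the pool is the per-group weighted mean of
probabilities (delegated to :func:`simple_ensemble`).  For quantile
inputs each component distribution is reconstructed from its quantiles,
quasi-random samples are drawn from each, and the pooled samples'
empirical quantiles are extracted at the original level grid.  For
sample inputs, samples are pooled directly, optionally subsetted to a
target size by stratified random selection of joint-sample indices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CapabilityError,
    ConfigurationError,
    GridMismatchError,
    InsufficientSamplesError,
    UnsupportedTypeError,
    ValidationError,
)
from .quantile_distribution import canonical_tail, fit_distribution
from .schema import ModelOutputTable, canonical_id, validate_model_output, validate_weights
from .simple_ensemble import DEFAULT_ENSEMBLE_ID, simple_ensemble


@dataclass(frozen=True)
class LinearPoolConfig:
    """Configuration of a linear-pool run.

    n_samples is the per-model quasi-random sample budget used on the
    quantile path (total draws = n_samples * n_models, allocated to
    models proportionally to their weights by largest remainder).
    """

    n_samples: int = 10_000
    tail_dist: str = "normal"
    n_output_samples: int | None = None
    compound_taskid_set: tuple[str, ...] | None = None
    derived_tasks: tuple[str, ...] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.n_output_samples is not None and self.n_output_samples < 1:
            raise ConfigurationError("n_output_samples must be >= 1")
        canonical_tail(self.tail_dist)


def largest_remainder_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``:
    floors plus remainder units to the largest fractional parts (ties
    broken by position order)."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = raw - counts
        order = np.lexsort((np.arange(len(w)), -frac))
        counts[order[:remainder]] += 1
    return counts


def _level_grid(g: pd.DataFrame) -> tuple[float, ...]:
    return tuple(sorted(float(x) for x in g["output_type_id"]))


def linear_pool_quantile(
    table: ModelOutputTable,
    weights: pd.DataFrame | None,
    config: LinearPoolConfig,
    ensemble_model_id: str,
) -> pd.DataFrame:
    """Quantile path: reconstruct, quasi-sample, pool, re-extract.

    Returns raw output rows (not yet validated).
    """
    df = table.data[table.data["output_type"] == "quantile"]
    wmap = None
    if weights is not None:
        wtab = validate_weights(weights, replace(table, data=df.reset_index(drop=True)))
        wmap = dict(zip(wtab["model_id"], wtab["weight"]))

    records = []
    for tkey, g in df.groupby(list(table.task_ids), sort=False, dropna=False):
        if not isinstance(tkey, tuple):
            tkey = (tkey,)
        models = list(pd.unique(g["model_id"]))
        grids = {m: _level_grid(g[g["model_id"] == m]) for m in models}
        ref = grids[models[0]]
        for m, grid in grids.items():
            if grid != ref:
                raise GridMismatchError(
                    f"quantile level grids differ across models in task group {tkey}: "
                    f"{models[0]} vs {m}"
                )
        levels = np.array(ref)
        w = np.array([wmap[m] if wmap else 1.0 for m in models], dtype=float)
        n_total = config.n_samples * len(models)
        counts = largest_remainder_counts(w, n_total)

        pooled = []
        for m, n_m in zip(models, counts):
            if n_m == 0:
                continue
            gm = g[g["model_id"] == m].sort_values(
                "output_type_id", key=lambda s: s.astype(float), kind="mergesort"
            )
            try:
                dist = fit_distribution(
                    gm["output_type_id"].astype(float).to_numpy(),
                    gm["value"].to_numpy(dtype=float),
                    tail_dist=config.tail_dist,
                )
            except Exception as exc:
                raise type(exc)(f"model {m!r}, task group {tkey}: {exc}") from exc
            pooled.append(dist.quasi_random_samples(int(n_m)))
        pooled = np.concatenate(pooled)
        # empirical quantiles by linear interpolation of order statistics
        qs = np.quantile(pooled, levels, method="linear")
        for th, v in zip(levels, qs):
            rec = dict(zip(table.task_ids, tkey))
            rec.update(
                model_id=ensemble_model_id,
                output_type="quantile",
                output_type_id=float(th),
                value=float(v),
            )
            records.append(rec)
    return pd.DataFrame.from_records(records)


def validate_compound_taskids(
    table: ModelOutputTable,
    compound_taskid_set: Sequence[str],
    derived_tasks: Sequence[str] | None = None,
) -> bool:
    """Check that sample predictions are compatible with a compound task
    ID set.

    True iff, within each model and compound unit, every sample index
    spans the same complete cross-product of the non-compound,
    non-derived task IDs, and each derived task's value is a function of
    the remaining task IDs.
    """
    derived = list(derived_tasks or ())
    compound = list(compound_taskid_set)
    unknown = (set(compound) | set(derived)) - set(table.task_ids)
    if unknown:
        raise ConfigurationError(f"unknown task IDs: {sorted(unknown)}")
    df = table.data[table.data["output_type"] == "sample"]
    if df.empty:
        return True

    # derived tasks must be functions of the non-derived task IDs
    sources = [c for c in table.task_ids if c not in derived]
    for d in derived:
        if sources and (df.groupby(sources, dropna=False)[d].nunique() > 1).any():
            return False

    free = [c for c in table.task_ids if c not in compound and c not in derived]
    if not free:
        return True
    for _, unit in df.groupby(["model_id", *compound], sort=False, dropna=False):
        expected = None
        full = set(
            itertools.product(*(sorted(set(unit[c].astype(str))) for c in free))
        )
        for _, samp in unit.groupby(
            unit["output_type_id"].map(canonical_id), sort=False
        ):
            combos = set(zip(*(samp[c].astype(str) for c in free)))
            if len(combos) != len(samp):
                return False
            if expected is None:
                expected = combos
            if combos != expected or combos != full:
                return False
    return True


def pool_samples(
    table: ModelOutputTable,
    config: LinearPoolConfig,
    ensemble_model_id: str,
) -> pd.DataFrame:
    """Pool sample rows across models, optionally subsetting to
    ``config.n_output_samples`` per compound unit.

    Joint structure is preserved: all rows sharing a model's original
    sample index stay or go together.  Output sample indices are dense
    integers assigned in (model_id, original index) order.
    """
    df = table.data[table.data["output_type"] == "sample"].copy()
    if config.n_output_samples is not None:
        if config.compound_taskid_set is None:
            raise ConfigurationError(
                "n_output_samples requires compound_taskid_set"
            )
        if not validate_compound_taskids(
            table, config.compound_taskid_set, config.derived_tasks
        ):
            raise ValidationError(
                "compound_taskid_set inconsistent with the sample index structure"
            )

    df["_otk"] = df["output_type_id"].map(canonical_id)
    models = sorted(pd.unique(df["model_id"]))

    if config.n_output_samples is None:
        selected = df
    else:
        n_out = config.n_output_samples
        counts = largest_remainder_counts(np.ones(len(models)), n_out)
        rng = np.random.default_rng(config.seed)
        keep_keys: list[tuple[str, str]] = []
        compound = list(config.compound_taskid_set or ())
        unit_cols = ["model_id", *compound]
        # selection is per (model, compound unit): indices drawn uniformly
        # without replacement
        for (m, n_m) in zip(models, counts):
            sub = df[df["model_id"] == m]
            for _, unit in sub.groupby(unit_cols, sort=True, dropna=False):
                idx = sorted(pd.unique(unit["_otk"]))
                if len(idx) < n_m:
                    raise InsufficientSamplesError(
                        f"model {m!r} has {len(idx)} sample indices; "
                        f"{n_m} requested"
                    )
                chosen = rng.choice(len(idx), size=n_m, replace=False)
                keep_keys.extend((m, idx[j]) for j in sorted(chosen))
        keys = set(keep_keys)
        mask = [
            (m, k) in keys for m, k in zip(df["model_id"], df["_otk"])
        ]
        selected = df[np.array(mask, dtype=bool)]

    # dense re-indexing in (model_id, original index) order, per compound
    # unit when subsetting, globally otherwise
    pairs = sorted(set(zip(selected["model_id"], selected["_otk"])))
    new_index = {p: i for i, p in enumerate(pairs)}
    out = selected.copy()
    out["output_type_id"] = [
        new_index[(m, k)] for m, k in zip(out["model_id"], out["_otk"])
    ]
    out["model_id"] = ensemble_model_id
    return out.drop(columns="_otk")


def linear_pool(
    table: ModelOutputTable,
    weights: pd.DataFrame | None = None,
    config: LinearPoolConfig | None = None,
    ensemble_model_id: str = DEFAULT_ENSEMBLE_ID,
) -> ModelOutputTable:
    """Compute a linear opinion pool ensemble of a model-output table.

    Supports output types mean, quantile, cdf, pmf, and sample (median is
    rejected).  Weighted pooling of samples is not supported.
    """
    config = config or LinearPoolConfig()
    types = set(table.output_types)
    if "median" in types:
        raise UnsupportedTypeError(
            "linear_pool does not support the 'median' output type"
        )
    if "sample" in types and weights is not None:
        raise CapabilityError("only equally-weighted linear pools of samples are supported")

    frames = []
    direct = types & {"mean", "cdf", "pmf"}
    if direct:
        sub = table.filter_types(direct)
        ens = simple_ensemble(
            sub, weights=weights, agg="mean", ensemble_model_id=ensemble_model_id
        )
        frames.append(ens.data)
    if "quantile" in types:
        frames.append(
            linear_pool_quantile(table, weights, config, ensemble_model_id)
        )
    if "sample" in types:
        frames.append(pool_samples(table, config, ensemble_model_id))

    frames = [f.astype({"output_type_id": object}) for f in frames if len(f)]
    out = pd.concat(frames, ignore_index=True)
    out = out.loc[:, ["model_id", *table.task_ids, "output_type", "output_type_id", "value"]]
    return validate_model_output(out, table.task_ids, table.pmf_category_order)
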