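"""Per-group weighted aggregation of model outputs.

An ensemble row is produced for every unique combination of task IDs,
output type, and output type ID by applying an aggregation function to
the component models' values.  With the default mean aggregation this is
the quantile (Vincent) average for quantile inputs and the linear opinion
pool for cdf/pmf inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CapabilityError,
    DegenerateWeightsError,
    EmptyInputError,
    IncompleteGroupError,
    UnsupportedTypeError,
)
from .schema import ModelOutputTable, canonical_id, validate_model_output, validate_weights

DEFAULT_ENSEMBLE_ID = "hub-ensemble"


def weighted_median(values, weights=None) -> float:
    """Weighted median: smallest value whose cumulative normalized weight
    reaches 0.5; an exact 0.5 crossing averages the flanking values
    (matching the unweighted even-n convention)."""
    x = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise DegenerateWeightsError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("all weights are zero")
    order = np.argsort(x, kind="mergesort")
    x, w = x[order], w[order] / total
    cum = np.cumsum(w)
    j = int(np.searchsorted(cum, 0.5 - 1e-12))
    if np.isclose(cum[j], 0.5, atol=1e-12) and j + 1 < len(x):
        return float(0.5 * (x[j] + x[j + 1]))
    return float(x[j])


def _weighted_mean(x, w=None) -> float:
    return float(np.average(np.asarray(x, dtype=float), weights=w))


@dataclass(frozen=True)
class AggregationSpec:
    """Named aggregation function C(x, w) used to combine a group."""

    name: str
    function: Callable
    supports_weights: bool = True

    @staticmethod
    def mean() -> "AggregationSpec":
        return AggregationSpec("mean", _weighted_mean, True)

    @staticmethod
    def median() -> "AggregationSpec":
        return AggregationSpec("median", weighted_median, True)

    @staticmethod
    def custom(function: Callable, name: str = "custom",
               supports_weights: bool = False) -> "AggregationSpec":
        return AggregationSpec(name, function, supports_weights)


def resolve_agg(agg) -> AggregationSpec:
    if isinstance(agg, AggregationSpec):
        return agg
    if agg is None or agg == "mean":
        return AggregationSpec.mean()
    if agg == "median":
        return AggregationSpec.median()
    if callable(agg):
        return AggregationSpec.custom(agg)
    raise UnsupportedTypeError(f"unknown aggregation: {agg!r}")


def _check_complete_groups(df: pd.DataFrame, task_ids: Sequence[str]) -> None:
    """Within each (task_ids, output_type), every output_type_id must be
    predicted by the same set of models."""
    key = df["output_type_id"].map(canonical_id)
    grp = df.assign(_otk=key).groupby([*task_ids, "output_type"], sort=False, dropna=False)
    for gname, g in grp:
        per_id = g.groupby("_otk", sort=False)["model_id"].agg(frozenset)
        if per_id.nunique() > 1:
            raise IncompleteGroupError(
                f"model membership differs across output_type_ids in group {gname}; "
                "pass partial='renormalize' to average over present models"
            )


def simple_ensemble(
    table: ModelOutputTable,
    weights: pd.DataFrame | None = None,
    agg="mean",
    ensemble_model_id: str = DEFAULT_ENSEMBLE_ID,
    partial: str = "error",
) -> ModelOutputTable:
    """Combine model outputs group-by-group with an aggregation function.

    Parameters
    ----------
    table : ModelOutputTable
        Component predictions; the ``sample`` output type is rejected.
    weights : DataFrame, optional
        Weight table (``model_id``, ``weight``, optional stratum columns);
        normalized per stratum.  ``None`` means equal weights.
    agg : "mean", "median", callable, or AggregationSpec
        The aggregation function C.  Callables receive ``(x)`` or
        ``(x, w)``.
    ensemble_model_id : str
        model_id for the output rows (default ``"hub-ensemble"``).
    partial : {"error", "renormalize"}
        How to treat output-type-ID groups whose model membership differs:
        reject (default) or average over present models with renormalized
        weights.

    Returns
    -------
    ModelOutputTable
        One row per input group, re-validated (so an ensemble of valid
        CDF/PMF groups is itself checked for monotonicity/normalization).
    """
    if "sample" in table.output_types:
        raise UnsupportedTypeError(
            "simple_ensemble does not support the 'sample' output type"
        )
    if len(table) == 0:
        raise EmptyInputError("empty model output table")
    if partial not in ("error", "renormalize"):
        raise ValueError("partial must be 'error' or 'renormalize'")

    spec = resolve_agg(agg)
    wtab = None
    if weights is not None:
        wtab = validate_weights(weights, table)
        if not spec.supports_weights:
            raise CapabilityError(
                f"aggregation {spec.name!r} does not support weights"
            )
        strata = [c for c in wtab.columns if c not in ("model_id", "weight")]
        if strata:
            raise CapabilityError(
                "stratified weights are not supported by simple_ensemble"
            )

    df = table.data
    if partial == "error":
        _check_complete_groups(df, table.task_ids)

    wmap = None
    if wtab is not None:
        wvals = wtab["weight"].to_numpy(dtype=float)
        if not np.all(wvals == wvals[0]):  # equal weights collapse to unweighted
            wmap = dict(zip(wtab["model_id"], wtab["weight"]))

    group_cols = [*table.task_ids, "output_type", "output_type_id"]
    records = []
    key = df["output_type_id"].map(canonical_id)
    for _, g in df.assign(_otk=key).groupby(
        [*table.task_ids, "output_type", "_otk"], sort=False, dropna=False
    ):
        x = g["value"].to_numpy(dtype=float)
        if wmap is not None:
            w = np.array([wmap[m] for m in g["model_id"]], dtype=float)
            if partial == "renormalize":
                total = w.sum()
                if total <= 0:
                    raise DegenerateWeightsError(
                        "present models carry zero total weight in a group"
                    )
                w = w / total
            value = spec.function(x, w)
        else:
            try:
                value = spec.function(x)
            except TypeError:
                value = spec.function(x, None)
        rec = {c: g[c].iloc[0] for c in group_cols}
        rec["model_id"] = ensemble_model_id
        rec["value"] = float(value)
        records.append(rec)

    out = pd.DataFrame.from_records(records)
    out = out.loc[:, ["model_id", *group_cols, "value"]]
    # custom aggregations (e.g. geometric mean) need not yield normalized
    # probability tables, so only mean/median outputs get the group checks
    return validate_model_output(
        out,
        table.task_ids,
        table.pmf_category_order,
        check_distributions=spec.name in ("mean", "median"),
    )
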