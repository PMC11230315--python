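"""Tabular data model for model-output, weight, and target tables.

Predictions live in a tidy table with one row per prediction:

    model_id | <task id columns...> | output_type | output_type_id | value

``output_type`` is one of ``mean``, ``median``, ``quantile``, ``cdf``,
``pmf``, ``sample``; ``output_type_id`` carries type-specific metadata
(the quantile level, the CDF evaluation point, the PMF category, or the
sample index) and is empty for point predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DegenerateWeightsError,
    DomainError,
    DuplicateRowError,
    MonotonicityError,
    NormalizationError,
    SchemaError,
)

OUTPUT_TYPES = frozenset({"mean", "median", "quantile", "cdf", "pmf", "sample"})
POINT_TYPES = frozenset({"mean", "median"})
RESERVED_COLUMNS = ("model_id", "output_type", "output_type_id", "value")

PMF_SUM_TOL = 1e-6
#: CDF values are rounded to this many digits before the monotonicity check.
CDF_ROUND_DIGITS = 12


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    if x is pd.NA or x is pd.NaT:
        return True
    if isinstance(x, str) and x.strip() in {"", "NA", "NaN", "nan"}:
        return True
    return False


def _to_float(x):
    """Parse a scalar as float, returning None on failure."""
    if _is_missing(x):
        return None
    try:
        return float(x)
    except (TypeError, ValueError):
        return None


def canonical_id(x) -> str:
    """Canonical string form of an output_type_id for grouping/sorting.

    Numerics are rendered at 10 significant digits so that 0.5, "0.5" and
    0.5000000000001 collate identically; everything else is str().
    """
    if _is_missing(x):
        return ""
    v = _to_float(x)
    if v is not None:
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return f"{v:.10g}"
    return str(x)


def _sort_key_factory(pmf_category_order: Sequence[str] | None):
    order = {c: i for i, c in enumerate(pmf_category_order or ())}

    def key(output_type: str, otid) -> tuple:
        if _is_missing(otid):
            return (0, 0.0, "")
        v = _to_float(otid)
        if v is not None:
            return (1, v, "")
        s = str(otid)
        if output_type == "pmf" and s in order:
            return (2, float(order[s]), s)
        return (3, 0.0, s)

    return key


@dataclass(frozen=True)
class ModelOutputTable:
    """A validated model-output table.

    Attributes
    ----------
    data : pandas.DataFrame
        Rows in canonical sort order, columns exactly
        ``model_id, *task_ids, output_type, output_type_id, value``.
    task_ids : tuple of str
        Names of the task-ID columns, in declared order.
    pmf_category_order : tuple of str or None
        Ordered PMF category vocabulary used for sorting, if declared.
    """

    data: pd.DataFrame
    task_ids: tuple[str, ...]
    pmf_category_order: tuple[str, ...] | None = None

    @property
    def columns(self) -> tuple[str, ...]:
        return ("model_id", *self.task_ids, "output_type", "output_type_id", "value")

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["model_id"]))

    @property
    def output_types(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["output_type"]))

    def filter_types(self, types: Iterable[str]) -> "ModelOutputTable":
        types = set(types)
        sub = self.data[self.data["output_type"].isin(types)].reset_index(drop=True)
        return replace(self, data=sub)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class TargetSeries:
    """Observed values keyed by task variables."""

    data: pd.DataFrame
    key_columns: tuple[str, ...]


def _canonical_sort(df: pd.DataFrame, task_ids: Sequence[str],
                    pmf_category_order: Sequence[str] | None) -> pd.DataFrame:
    key = _sort_key_factory(pmf_category_order)
    otid_keys = [key(t, o) for t, o in zip(df["output_type"], df["output_type_id"])]
    tmp = df.assign(
        _k0=[k[0] for k in otid_keys],
        _k1=[k[1] for k in otid_keys],
        _k2=[k[2] for k in otid_keys],
    )
    cols = ["model_id", *task_ids, "output_type", "_k0", "_k1", "_k2"]
    tmp = tmp.sort_values(cols, kind="mergesort").drop(columns=["_k0", "_k1", "_k2"])
    return tmp.reset_index(drop=True)


def validate_model_output(
    table: pd.DataFrame,
    task_id_names: Sequence[str],
    pmf_category_order: Sequence[str] | None = None,
    check_distributions: bool = True,
) -> ModelOutputTable:
    """Validate and canonicalize a raw prediction table.

    Parameters
    ----------
    table : pandas.DataFrame
        Raw input with the four structural column groups.
    task_id_names : sequence of str
        Names of task-ID columns; must be disjoint from the reserved names
        ``model_id, output_type, output_type_id, value``.
    pmf_category_order : sequence of str, optional
        Ordered vocabulary for PMF categories (used for canonical sorting).
    check_distributions : bool
        When False, skip the per-group CDF-monotonicity and PMF-sum checks
        (used for ensembles built with custom aggregation functions, whose
        outputs need not be normalized probability tables).

    Returns
    -------
    ModelOutputTable

    Raises
    ------
    SchemaError, DomainError, MonotonicityError, NormalizationError,
    DuplicateRowError
    """
    task_id_names = list(task_id_names)
    clash = set(task_id_names) & set(RESERVED_COLUMNS)
    if clash:
        raise SchemaError(f"task_id_names clash with reserved columns: {sorted(clash)}")

    required = ["model_id", *task_id_names, "output_type", "output_type_id", "value"]
    for col in required:
        if col not in table.columns:
            raise SchemaError(f"missing required column: {col!r}")
    extra = [c for c in table.columns if c not in required]
    if extra:
        raise SchemaError(f"unexpected columns: {extra}")

    df = table.loc[:, required].copy()
    df["model_id"] = df["model_id"].astype(str)
    df["output_type"] = df["output_type"].astype(str)

    bad_types = sorted(set(df["output_type"]) - OUTPUT_TYPES)
    if bad_types:
        raise DomainError(f"unknown output_type values: {bad_types}")

    try:
        df["value"] = pd.to_numeric(df["value"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"non-numeric entries in 'value': {exc}") from exc
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise DomainError("non-finite entries in 'value'")

    # per-row output_type_id canonicalization
    otids: list = []
    for ot, otid in zip(df["output_type"], df["output_type_id"]):
        if ot in POINT_TYPES:
            if not _is_missing(otid):
                raise DomainError(
                    f"output_type={ot!r} requires missing output_type_id, got {otid!r}"
                )
            otids.append(np.nan)
        elif ot == "quantile":
            v = _to_float(otid)
            if v is None:
                raise DomainError(f"quantile output_type_id not numeric: {otid!r}")
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"quantile level outside [0, 1]: {v}")
            otids.append(v)
        else:
            if _is_missing(otid):
                raise DomainError(f"output_type={ot!r} requires an output_type_id")
            if ot == "cdf":
                v = _to_float(otid)
                otids.append(v if v is not None else str(otid))
            else:
                otids.append(str(otid) if not isinstance(otid, (int, np.integer)) else int(otid))
    df["output_type_id"] = pd.Series(otids, index=df.index, dtype=object)

    # duplicate detection on canonical keys
    keys = list(
        zip(
            df["model_id"],
            *(df[c].astype(str) for c in task_id_names),
            df["output_type"],
            (canonical_id(x) for x in df["output_type_id"]),
        )
    )
    if len(set(keys)) != len(keys):
        seen: set = set()
        for k in keys:
            if k in seen:
                raise DuplicateRowError(f"duplicate prediction row for key {k}")
            seen.add(k)

    # group-level checks for cdf and pmf
    group_cols = ["model_id", *task_id_names]
    skey = _sort_key_factory(pmf_category_order)

    cdf = df[df["output_type"] == "cdf"] if check_distributions else df.iloc[0:0]
    if len(cdf):
        vals = cdf["value"].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise DomainError("cdf values must lie in [0, 1]")
        for gkey, g in cdf.groupby(group_cols, sort=False):
            order = sorted(range(len(g)), key=lambda i: skey("cdf", g["output_type_id"].iloc[i]))
            v = np.round(g["value"].to_numpy(dtype=float)[order], CDF_ROUND_DIGITS)
            if (np.diff(v) < 0).any():
                raise MonotonicityError(f"non-monotone cdf group {gkey}")

    pmf = df[df["output_type"] == "pmf"] if check_distributions else df.iloc[0:0]
    if len(pmf):
        vals = pmf["value"].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise DomainError("pmf values must lie in [0, 1]")
        sums = pmf.groupby(group_cols, sort=False)["value"].sum()
        bad = sums[(sums - 1.0).abs() > PMF_SUM_TOL]
        if len(bad):
            raise NormalizationError(
                f"pmf group does not sum to 1 (tol {PMF_SUM_TOL}): {bad.index[0]} -> {bad.iloc[0]}"
            )

    df = _canonical_sort(df, task_id_names, pmf_category_order)
    return ModelOutputTable(
        data=df,
        task_ids=tuple(task_id_names),
        pmf_category_order=tuple(pmf_category_order) if pmf_category_order else None,
    )


def standardize_table(
    table: pd.DataFrame,
    column_mapping: Mapping[str, str],
    task_id_names: Sequence[str],
    pmf_category_order: Sequence[str] | None = None,
    drop_unmapped: bool = True,
) -> ModelOutputTable:
    """Rename columns of a foreign-format table and validate the result.

    ``column_mapping`` maps source column names to standard names and must
    cover ``model_id``, ``output_type``, ``output_type_id`` and ``value``
    (identity entries may be omitted when the source already uses the
    standard name).
    """
    mapping = dict(column_mapping)
    for src in mapping:
        if src not in table.columns:
            raise SchemaError(f"column mapping references absent column: {src!r}")
    renamed = table.rename(columns=mapping)
    required = ["model_id", *task_id_names, "output_type", "output_type_id", "value"]
    missing = [c for c in required if c not in renamed.columns]
    if missing:
        raise SchemaError(f"standardized table is missing columns: {missing}")
    if drop_unmapped:
        renamed = renamed.loc[:, required]
    return validate_model_output(renamed, task_id_names, pmf_category_order)


def validate_weights(
    weights: pd.DataFrame,
    table: ModelOutputTable,
) -> pd.DataFrame:
    """Check a weight table against a prediction table and normalize it.

    Weights must cover every model in ``table``; optional stratum columns
    (a subset of the table's task IDs) partition the weights, and each
    stratum is normalized to sum to one.

    Returns the normalized weight table (``model_id``, optional strata,
    ``weight``).
    """
    if "model_id" not in weights.columns or "weight" not in weights.columns:
        raise SchemaError("weight table requires 'model_id' and 'weight' columns")
    strata = [c for c in weights.columns if c not in ("model_id", "weight")]
    unknown = set(strata) - set(table.task_ids)
    if unknown:
        raise SchemaError(f"stratum columns not among task IDs: {sorted(unknown)}")

    w = weights.copy()
    w["model_id"] = w["model_id"].astype(str)
    w["weight"] = pd.to_numeric(w["weight"])
    if (w["weight"] < 0).any():
        raise DomainError("weights must be nonnegative")

    if w.duplicated(subset=["model_id", *strata]).any():
        raise SchemaError("duplicate model_id within a stratum in weight table")

    table_models = set(table.models)
    w = w[w["model_id"].isin(table_models)].reset_index(drop=True)
    missing = table_models - set(w["model_id"])
    if missing:
        raise CoverageError(f"models missing from weight table: {sorted(missing)}")

    if strata:
        for skey, g in w.groupby(strata, sort=False):
            if set(g["model_id"]) != table_models:
                raise CoverageError(f"stratum {skey} does not cover all models")
            total = g["weight"].sum()
            if total <= 0:
                raise DegenerateWeightsError(f"all-zero weights in stratum {skey}")
            w.loc[g.index, "weight"] = g["weight"] / total
    else:
        total = w["weight"].sum()
        if total <= 0:
            raise DegenerateWeightsError("all weights are zero")
        w["weight"] = w["weight"] / total

    return w.loc[:, ["model_id", *strata, "weight"]]


def validate_target_series(
    table: pd.DataFrame,
    key_columns: Sequence[str],
    observation_column: str = "observation",
) -> TargetSeries:
    """Validate a target (observed) time-series table."""
    key_columns = list(key_columns)
    for col in [*key_columns, observation_column]:
        if col not in table.columns:
            raise SchemaError(f"missing target-series column: {col!r}")
    df = table.loc[:, [*key_columns, observation_column]].copy()
    df = df.rename(columns={observation_column: "observation"})
    df["observation"] = pd.to_numeric(df["observation"])
    if not np.isfinite(df["observation"].to_numpy(dtype=float)).all():
        raise DomainError("non-finite observation values")
    if df.duplicated(subset=key_columns).any():
        raise SchemaError("duplicate task keys in target series")
    df = df.sort_values(key_columns, kind="mergesort").reset_index(drop=True)
    return TargetSeries(data=df, key_columns=tuple(key_columns))


# ---------------------------------------------------------------------------
# delimited-text I/O (UTF-8 CSV with header; full-precision floats)

def read_model_output(
    path: str | Path,
    task_id_names: Sequence[str],
    pmf_category_order: Sequence[str] | None = None,
) -> ModelOutputTable:
    df = pd.read_csv(
        path,
        dtype={"output_type_id": object},
        keep_default_na=True,
        float_precision="round_trip",
    )
    return validate_model_output(df, task_id_names, pmf_category_order)


def write_model_output(table: ModelOutputTable, path: str | Path) -> None:
    _write_csv(table.data, path)


def read_weights(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_target_series(
    path: str | Path,
    key_columns: Sequence[str],
    observation_column: str = "observation",
) -> TargetSeries:
    return validate_target_series(
        pd.read_csv(path, float_precision="round_trip"), key_columns, observation_column
    )


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return ""
        return repr(float(x))
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return str(x)


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in out.columns:
        out[col] = [_fmt(x) for x in out[col]]
    out.to_csv(path, index=False, encoding="utf-8")
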