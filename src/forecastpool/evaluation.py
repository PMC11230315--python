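"""Scoring of quantile-format forecasts against observations.

Implements the weighted interval score (WIS) with its dispersion /
over-prediction / under-prediction decomposition, absolute error of the
median, central prediction-interval coverage, and relative metrics
against a named baseline model.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GridError, JoinError, MissingBaselineError
from .schema import ModelOutputTable, TargetSeries

_LEVEL_TOL = 1e-9


def _pair_levels(levels: np.ndarray) -> tuple[list[tuple[int, int]], int]:
    """Return index pairs (lower, upper) for a symmetric grid containing 0.5.

    Raises GridError if 0.5 is absent or any level lacks its mirror.
    """
    med = np.flatnonzero(np.abs(levels - 0.5) <= _LEVEL_TOL)
    if len(med) != 1:
        raise GridError("quantile grid must contain the level 0.5 exactly once")
    pairs = []
    for i, th in enumerate(levels):
        if th >= 0.5 - _LEVEL_TOL:
            continue
        j = np.flatnonzero(np.abs(levels - (1.0 - th)) <= _LEVEL_TOL)
        if len(j) != 1:
            raise GridError(f"level {th} has no mirror level {1 - th} in the grid")
        pairs.append((i, int(j[0])))
    if 1 + 2 * len(pairs) != len(levels):
        raise GridError("quantile grid is not symmetric about 0.5")
    return pairs, int(med[0])


def wis(levels, values, y: float) -> tuple[float, float, float, float]:
    """Weighted interval score of a quantile forecast.

    With K central intervals of nominal coverage 1 - alpha_k and median m:

        wis = (0.5 |y - m| + sum_k (alpha_k / 2) IS_k) / (K + 0.5)
        IS_k = (u - l) + (2/alpha_k)(l - y) 1[y < l] + (2/alpha_k)(y - u) 1[y > u]

    Returns ``(wis, overprediction, underprediction, dispersion)``; the
    three components sum to wis.  Over-prediction accumulates penalties
    for y below the forecast (y < l, and the median term when y < m);
    under-prediction symmetrically.
    """
    levels = np.asarray(levels, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(levels)
    levels, values = levels[order], values[order]
    pairs, med_idx = _pair_levels(levels)
    m = values[med_idx]
    K = len(pairs)

    disp = 0.0
    over = 0.0
    under = 0.0
    # median term, weight 0.5
    if y < m:
        over += 0.5 * (m - y)
    else:
        under += 0.5 * (y - m)
    for i, j in pairs:
        alpha = 2.0 * levels[i]
        l, u = values[i], values[j]
        disp += (alpha / 2.0) * (u - l)
        if y < l:
            over += (l - y)
        elif y > u:
            under += (y - u)
    norm = K + 0.5
    disp /= norm
    over /= norm
    under /= norm
    return disp + over + under, over, under, disp


def pi_coverage(levels, values, y: float, nominal: float) -> bool:
    """Whether the closed central interval at ``nominal`` coverage
    (e.g. 0.5 or 0.95) contains the observation."""
    levels = np.asarray(levels, dtype=float)
    values = np.asarray(values, dtype=float)
    lo_th = (1.0 - nominal) / 2.0
    hi_th = (1.0 + nominal) / 2.0
    i = np.flatnonzero(np.abs(levels - lo_th) <= _LEVEL_TOL)
    j = np.flatnonzero(np.abs(levels - hi_th) <= _LEVEL_TOL)
    if len(i) != 1 or len(j) != 1:
        raise GridError(
            f"grid lacks the bounding pair ({lo_th}, {hi_th}) for {nominal:.0%} coverage"
        )
    return bool(values[i[0]] <= y <= values[j[0]])


def score_forecasts(
    forecasts: ModelOutputTable,
    targets: TargetSeries,
    join_keys: Sequence[str],
) -> pd.DataFrame:
    """Score every quantile forecast group against its observation.

    ``join_keys`` are task-ID columns of the forecasts that match the
    target series' key columns by name.  Each (model, task) group must
    match exactly one observation.

    Returns a per-prediction score table with columns: model_id, the task
    IDs, wis, wis_overprediction, wis_underprediction, wis_dispersion,
    abs_error, covered_50, covered_95.
    """
    join_keys = list(join_keys)
    missing = set(join_keys) - set(forecasts.task_ids)
    if missing:
        raise JoinError(f"join keys not among forecast task IDs: {sorted(missing)}")
    missing = set(join_keys) - set(targets.key_columns)
    if missing:
        raise JoinError(f"join keys not among target key columns: {sorted(missing)}")

    df = forecasts.data[forecasts.data["output_type"] == "quantile"]
    if df.empty:
        raise JoinError("no quantile forecasts to score")

    tgt = targets.data.copy()
    obs_index: dict[tuple, float] = {}
    for row in tgt.itertuples(index=False):
        d = row._asdict()
        obs_index[tuple(str(d[k]) for k in join_keys)] = float(d["observation"])

    records = []
    group_cols = ["model_id", *forecasts.task_ids]
    for gkey, g in df.groupby(group_cols, sort=False, dropna=False):
        rec = dict(zip(group_cols, gkey))
        tkey = tuple(str(rec[k]) for k in join_keys)
        if tkey not in obs_index:
            raise JoinError(f"no observation for forecast group keys {dict(zip(join_keys, tkey))}")
        y = obs_index[tkey]
        levels = g["output_type_id"].astype(float).to_numpy()
        values = g["value"].to_numpy(dtype=float)
        w, over, under, disp = wis(levels, values, y)
        rec.update(
            wis=w,
            wis_overprediction=over,
            wis_underprediction=under,
            wis_dispersion=disp,
            abs_error=abs(y - values[np.argmin(np.abs(levels - 0.5))]),
            covered_50=pi_coverage(levels, values, y, 0.5),
            covered_95=pi_coverage(levels, values, y, 0.95),
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize_scores(
    scores: pd.DataFrame,
    baseline_model_id: str | None = None,
) -> pd.DataFrame:
    """Aggregate per-prediction scores by model.

    Adds mean WIS and components, MAE, coverage rates, and — when a
    baseline is named — rWIS and rMAE computed on the task set common to
    the baseline and each comparator.
    """
    agg = (
        scores.groupby("model_id", sort=True)
        .agg(
            wis=("wis", "mean"),
            wis_overprediction=("wis_overprediction", "mean"),
            wis_underprediction=("wis_underprediction", "mean"),
            wis_dispersion=("wis_dispersion", "mean"),
            mae=("abs_error", "mean"),
            cov50=("covered_50", "mean"),
            cov95=("covered_95", "mean"),
            n=("wis", "size"),
        )
        .reset_index()
    )
    if baseline_model_id is not None:
        agg["rwis"] = relative_metric(scores, baseline_model_id, "wis")[
            agg["model_id"]
        ].to_numpy()
        agg["rmae"] = relative_metric(scores, baseline_model_id, "mae")[
            agg["model_id"]
        ].to_numpy()
    return agg


def relative_metric(
    scores: pd.DataFrame,
    baseline_model_id: str,
    metric: str,
) -> pd.Series:
    """Per-model ratio of mean metric to the baseline's, computed on the
    intersection of scored tasks (inner join on task keys).

    ``metric`` is ``"wis"`` or ``"mae"``; the baseline's ratio is exactly 1.
    """
    col = {"wis": "wis", "mae": "abs_error"}.get(metric)
    if col is None:
        raise ValueError("metric must be 'wis' or 'mae'")
    models = list(pd.unique(scores["model_id"]))
    if baseline_model_id not in models:
        raise MissingBaselineError(f"baseline {baseline_model_id!r} not in score table")
    task_cols = [
        c
        for c in scores.columns
        if c
        not in (
            "model_id",
            "wis",
            "wis_overprediction",
            "wis_underprediction",
            "wis_dispersion",
            "abs_error",
            "covered_50",
            "covered_95",
        )
    ]
    base = scores[scores["model_id"] == baseline_model_id]
    out = {}
    for m in models:
        if m == baseline_model_id:
            out[m] = 1.0
            continue
        mine = scores[scores["model_id"] == m]
        joined = mine.merge(base, on=task_cols, suffixes=("", "_base"))
        if joined.empty:
            raise JoinError(
                f"no common tasks between {m!r} and baseline {baseline_model_id!r}"
            )
        out[m] = float(joined[col].mean() / joined[f"{col}_base"].mean())
    return pd.Series(out, name=f"r{metric}")
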