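# forecastpool

Multi-model probabilistic forecast ensembling and evaluation over a
standardized tabular "model output" format.

Predictions from several models — points, quantiles, CDF/PMF values, or
samples — are stored one prediction per row:

    model_id | <task id columns...> | output_type | output_type_id | value

and combined into ensemble forecasts by either of the two classic methods:

- **Quantile (Vincent) averaging** — average component quantile values at
  each fixed quantile level (`simple_ensemble`, any aggregation function,
  optional model weights).
- **Linear opinion pool (LOP)** — average component probabilities at each
  fixed target value (`linear_pool`). Quantile-format inputs are handled by
  reconstructing each component CDF (monotone cubic spline interior,
  normal/lognormal/Cauchy location-scale tails), drawing quasi-random
  samples, pooling them, and re-extracting the original quantile levels.
  Sample-format inputs are pooled directly, with optional stratified
  subsetting of joint-sample indices.

Quantile forecasts can be scored against observations with the weighted
interval score (WIS, with over-/under-prediction/dispersion decomposition),
MAE of the median, central-interval coverage, and relative WIS/MAE versus a
baseline model. A synthetic-hub generator emits component models with known
parametric predictive distributions in all six output types, so every
method can be tested against closed-form ground truth.

## Library quick start

```python
import forecastpool as fp

table = fp.read_model_output("forecasts.csv", task_id_names=["location", "horizon"])
mean_ens = fp.simple_ensemble(table, ensemble_model_id="mean-ensemble")
lop = fp.linear_pool(table.filter_types({"quantile"}),
                     config=fp.LinearPoolConfig(n_samples=10_000, tail_dist="norm"))

targets = fp.read_target_series("targets.csv", key_columns=["location", "horizon"])
scores = fp.score_forecasts(lop, targets, join_keys=["location", "horizon"])
summary = fp.summarize_scores(scores, baseline_model_id="baseline")
```

## CLI

The `forecastpool` entry point exposes four subcommands:

```sh
# check a CSV against the model-output schema
forecastpool validate forecasts.csv --task-ids location,horizon

# quantile-average / weighted-mean / median ensembles
forecastpool ensemble simple forecasts.csv ens.csv \
    --task-ids location,horizon --agg mean --weights weights.csv

# linear opinion pool (sample subsetting needs --compound-taskids and --seed)
forecastpool ensemble lop forecasts.csv lop.csv \
    --task-ids location,horizon --n-samples 10000 --tail-dist norm

# WIS / MAE / coverage scoring with optional relative metrics
forecastpool score lop.csv scores.csv --task-ids location,horizon \
    --targets targets.csv --join-keys location,horizon --baseline baseline

# generate a synthetic hub (model_output.csv, targets.csv, weights.csv)
forecastpool simulate --spec hubspec.json --out-dir hub/
```

All tables are UTF-8 CSVs with a header row; floats are written with full
round-trip precision and rows in a canonical sort order, so repeated runs
under a fixed seed produce byte-identical files.

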