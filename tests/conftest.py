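import numpy as np
import pandas as pd
import pytest

import forecastpool as fp

PMF_CATEGORIES = ["low", "moderate", "high", "very high"]

# the worked three-model PMF example (printed to three decimals)
PMF_EXAMPLE = {
    "Flusight-baseline": [0.000, 0.003, 0.073, 0.924],
    "MOBS-GLEAM_FLUH": [0.000, 0.002, 0.163, 0.835],
    "PSI-DICE": [0.013, 0.065, 0.218, 0.704],
}


@pytest.fixture
def pmf_example_df() -> pd.DataFrame:
    rows = []
    for model, vals in PMF_EXAMPLE.items():
        for cat, v in zip(PMF_CATEGORIES, vals):
            rows.append(
                dict(
                    model_id=model,
                    target="wk flu hosp rate category",
                    horizon=1,
                    output_type="pmf",
                    output_type_id=cat,
                    value=v,
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture
def pmf_example_table(pmf_example_df) -> fp.ModelOutputTable:
    return fp.validate_model_output(
        pmf_example_df, ["target", "horizon"], pmf_category_order=PMF_CATEGORIES
    )


def make_quartile_example_df() -> pd.DataFrame:
    """The 12-row single-model quartile forecast table."""
    rows = []
    quartiles = {
        0: [514, 596, 713],
        1: [563, 664, 803],
        2: [469, 575, 705],
        3: [324, 408, 512],
    }
    for h, vals in quartiles.items():
        for th, v in zip([0.25, 0.5, 0.75], vals):
            rows.append(
                dict(
                    model_id="team1-mod",
                    loc="MA",
                    ref_date="2022-12-17",
                    h=h,
                    target="wk flu hosp",
                    output_type="quantile",
                    output_type_id=th,
                    value=v,
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture
def quartile_example_df() -> pd.DataFrame:
    return make_quartile_example_df()


TASK_IDS_QUARTILE = ["loc", "ref_date", "h", "target"]


@pytest.fixture
def two_normal_hub() -> fp.HubSpec:
    """N(100,10) + N(120,5): mixture mean 110, variance 162.5."""
    return fp.HubSpec(
        models=(
            fp.ModelSpec("mod-a", "normal", (100.0, 10.0)),
            fp.ModelSpec("mod-b", "normal", (120.0, 5.0)),
        ),
        truth=fp.ModelSpec("truth", "normal", (110.0, 12.0)),
    )


def quantile_table_from_normals(params, levels=None, task=None) -> fp.ModelOutputTable:
    """Exact quantile rows for a set of normal models at a shared grid."""
    from scipy.stats import norm

    levels = np.asarray(levels if levels is not None else fp.FLUSIGHT_LEVELS)
    task = task or {"location": "A", "horizon": 0}
    rows = []
    for model_id, (mu, sigma) in params.items():
        for th in levels:
            rows.append(
                dict(
                    model_id=model_id,
                    **task,
                    output_type="quantile",
                    output_type_id=float(th),
                    value=float(norm(mu, sigma).ppf(th)),
                )
            )
    return fp.validate_model_output(pd.DataFrame(rows), list(task))
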