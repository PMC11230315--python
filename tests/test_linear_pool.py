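import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import forecastpool as fp
from forecastpool import errors
from forecastpool.linear_pool import largest_remainder_counts

from conftest import quantile_table_from_normals


def mixture_quantiles_bruteforce(params, weights, levels, grid_lo, grid_hi, n_grid=100_000):
    """Oracle: average the exact normal CDFs on a dense grid and invert by
    bisection on the grid (independent of the package's sampling path)."""
    xs = np.linspace(grid_lo, grid_hi, n_grid)
    F = np.zeros_like(xs)
    for (mu, sigma), w in zip(params, weights):
        F += w * norm(mu, sigma).cdf(xs)
    out = []
    for th in levels:
        j = int(np.searchsorted(F, th))
        j = min(max(j, 1), len(xs) - 1)
        # linear interpolation between bracketing grid points
        x0, x1 = xs[j - 1], xs[j]
        f0, f1 = F[j - 1], F[j]
        out.append(x0 + (th - f0) * (x1 - x0) / (f1 - f0))
    return np.array(out)


def _sample_table(n_models=3, n_samples=100, task=None):
    task = task or {"location": "A"}
    rows = []
    rng = np.random.default_rng(0)
    for i in range(n_models):
        for k in range(n_samples):
            rows.append(
                dict(model_id=f"m{i}", **task, output_type="sample",
                     output_type_id=k, value=float(rng.normal()))
            )
    return fp.validate_model_output(pd.DataFrame(rows), list(task))


class TestDispatch:
    def test_pmf_path_equals_simple_ensemble(self, pmf_example_table):
        lp = fp.linear_pool(pmf_example_table, ensemble_model_id="ens")
        se = fp.simple_ensemble(pmf_example_table, ensemble_model_id="ens")
        pd.testing.assert_frame_equal(lp.data, se.data)

    def test_median_rejected(self):
        df = pd.DataFrame(
            [dict(model_id="m", loc="A", output_type="median",
                  output_type_id=np.nan, value=1.0)]
        )
        table = fp.validate_model_output(df, ["loc"])
        with pytest.raises(errors.UnsupportedTypeError):
            fp.linear_pool(table)

    def test_weighted_samples_rejected(self):
        table = _sample_table()
        w = pd.DataFrame(dict(model_id=["m0", "m1", "m2"], weight=[1, 2, 3]))
        with pytest.raises(errors.CapabilityError):
            fp.linear_pool(table, weights=w)


class TestQuantilePath:
    def test_single_model_reproduced(self):
        table = quantile_table_from_normals({"only": (100.0, 10.0)})
        lp = fp.linear_pool(table, config=fp.LinearPoolConfig(n_samples=100_000),
                            ensemble_model_id="ens")
        levels = lp.data["output_type_id"].astype(float).to_numpy()
        orig = table.data["value"].to_numpy()
        got = lp.data["value"].to_numpy()
        # sampling resolution limits accuracy in the far tails
        central = (levels >= 0.025) & (levels <= 0.975)
        assert np.max(np.abs(got - orig)[central]) < 2e-3
        assert np.max(np.abs(got - orig)) < 5e-3

    def test_identical_components_reproduced(self):
        table = quantile_table_from_normals(
            {"a": (100.0, 10.0), "b": (100.0, 10.0), "c": (100.0, 10.0)}
        )
        lp = fp.linear_pool(table, config=fp.LinearPoolConfig(n_samples=100_000))
        orig = table.data[table.data["model_id"] == "a"]["value"].to_numpy()
        got = lp.data["value"].to_numpy()
        assert np.max(np.abs(got - orig)) < 5e-3

    def test_two_normal_mixture_against_bruteforce_oracle(self):
        params = [(100.0, 10.0), (120.0, 5.0)]
        table = quantile_table_from_normals({"a": params[0], "b": params[1]})
        lp = fp.linear_pool(table, config=fp.LinearPoolConfig(n_samples=100_000))
        levels = lp.data["output_type_id"].astype(float).to_numpy()
        oracle = mixture_quantiles_bruteforce(
            params, [0.5, 0.5], levels, 40.0, 180.0
        )
        assert np.max(np.abs(lp.data["value"].to_numpy() - oracle)) <= 0.5

    def test_mixture_mean_identity(self):
        table = quantile_table_from_normals({"a": (100.0, 10.0), "b": (120.0, 5.0)})
        lp = fp.linear_pool(table, config=fp.LinearPoolConfig(n_samples=100_000))
        levels = lp.data["output_type_id"].astype(float).to_numpy()
        values = lp.data["value"].to_numpy()
        # mean from the quantile function: integral of F^-1 over (0,1),
        # approximated on the reported grid by trapezoid
        d = fp.fit_distribution(levels, values)
        mean = d.quasi_random_samples(20_000).mean()
        assert mean == pytest.approx(110.0, abs=0.3)

    def test_mixture_variance_identity(self):
        table = quantile_table_from_normals({"a": (100.0, 10.0), "b": (120.0, 5.0)})
        lp = fp.linear_pool(table, config=fp.LinearPoolConfig(n_samples=100_000))
        levels = lp.data["output_type_id"].astype(float).to_numpy()
        d = fp.fit_distribution(levels, lp.data["value"].to_numpy())
        s = d.quasi_random_samples(20_000)
        # sigma2_LOP = mean of variances + spread of means
        expected = 0.5 * (100 + 25) + 0.5 * (100 + 100)
        assert s.var() == pytest.approx(expected, rel=0.02)

    def test_variance_ordering_quantile_average_leq_lop(self):
        table = quantile_table_from_normals({"a": (100.0, 10.0), "b": (120.0, 5.0)})
        qa = fp.simple_ensemble(table)
        lp = fp.linear_pool(table, config=fp.LinearPoolConfig(n_samples=50_000))
        levels = qa.data["output_type_id"].astype(float).to_numpy()
        var_qa = fp.fit_distribution(levels, qa.data["value"].to_numpy()) \
            .quasi_random_samples(20_000).var()
        var_lp = fp.fit_distribution(levels, lp.data["value"].to_numpy()) \
            .quasi_random_samples(20_000).var()
        assert var_qa <= var_lp

    def test_weighted_quantile_pool(self):
        params = [(100.0, 10.0), (120.0, 5.0)]
        table = quantile_table_from_normals({"a": params[0], "b": params[1]})
        w = pd.DataFrame(dict(model_id=["a", "b"], weight=[0.8, 0.2]))
        lp = fp.linear_pool(table, weights=w,
                            config=fp.LinearPoolConfig(n_samples=100_000))
        levels = lp.data["output_type_id"].astype(float).to_numpy()
        oracle = mixture_quantiles_bruteforce(params, [0.8, 0.2], levels, 40.0, 180.0)
        assert np.max(np.abs(lp.data["value"].to_numpy() - oracle)) <= 0.5

    def test_grid_mismatch_rejected(self):
        rows = []
        for m, levels in [("a", [0.25, 0.5, 0.75]), ("b", [0.1, 0.5, 0.9])]:
            for th in levels:
                rows.append(dict(model_id=m, loc="A", output_type="quantile",
                                 output_type_id=th, value=float(th * 10)))
        table = fp.validate_model_output(pd.DataFrame(rows), ["loc"])
        with pytest.raises(errors.GridMismatchError):
            fp.linear_pool(table)

    def test_tail_dist_sensitivity_localized(self):
        # switching norm -> lnorm on a strictly positive hub changes central
        # quantiles (within [0.025, 0.975]) by less than 1e-3 of scale
        table = quantile_table_from_normals({"a": (100.0, 5.0), "b": (110.0, 4.0)})
        lp_n = fp.linear_pool(table, config=fp.LinearPoolConfig(n_samples=50_000))
        lp_l = fp.linear_pool(
            table, config=fp.LinearPoolConfig(n_samples=50_000, tail_dist="lnorm")
        )
        levels = lp_n.data["output_type_id"].astype(float).to_numpy()
        central = (levels >= 0.025) & (levels <= 0.975)
        diff = np.abs(
            lp_n.data["value"].to_numpy() - lp_l.data["value"].to_numpy()
        )
        assert np.max(diff[central]) < 1e-3 * 100.0


class TestLargestRemainder:
    def test_equal_split(self):
        assert list(largest_remainder_counts(np.ones(3), 100)) == [34, 33, 33]

    def test_exact_division(self):
        assert list(largest_remainder_counts(np.ones(4), 100)) == [25, 25, 25, 25]

    def test_total_preserved(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            w = rng.uniform(0.1, 1.0, size=rng.integers(2, 8))
            total = int(rng.integers(1, 1000))
            counts = largest_remainder_counts(w, total)
            assert counts.sum() == total
            assert (counts >= 0).all()

    def test_proportionality(self):
        counts = largest_remainder_counts(np.array([0.5, 0.25, 0.25]), 1000)
        assert list(counts) == [500, 250, 250]


class TestPoolSamples:
    def test_concatenation_count(self):
        table = _sample_table(n_models=3, n_samples=100)
        lp = fp.linear_pool(table, ensemble_model_id="ens")
        assert len(lp) == 300
        assert lp.data["output_type_id"].nunique() == 300

    def test_values_preserved(self):
        table = _sample_table(n_models=2, n_samples=50)
        lp = fp.linear_pool(table)
        assert sorted(lp.data["value"]) == sorted(table.data["value"])

    def test_subset_allocation_34_33_33(self):
        table = _sample_table(n_models=3, n_samples=100)
        cfg = fp.LinearPoolConfig(
            n_output_samples=100, compound_taskid_set=("location",), seed=42
        )
        lp = fp.linear_pool(table, config=cfg)
        assert len(lp) == 100

    def test_subset_requires_compound_taskids(self):
        table = _sample_table()
        with pytest.raises(errors.ConfigurationError):
            fp.linear_pool(table, config=fp.LinearPoolConfig(n_output_samples=10))

    def test_insufficient_samples(self):
        table = _sample_table(n_models=2, n_samples=5)
        cfg = fp.LinearPoolConfig(
            n_output_samples=100, compound_taskid_set=("location",), seed=1
        )
        with pytest.raises(errors.InsufficientSamplesError):
            fp.linear_pool(table, config=cfg)

    def test_deterministic_under_seed(self):
        table = _sample_table(n_models=3, n_samples=50)
        cfg = fp.LinearPoolConfig(
            n_output_samples=30, compound_taskid_set=("location",), seed=7
        )
        lp1 = fp.linear_pool(table, config=cfg)
        lp2 = fp.linear_pool(table, config=cfg)
        pd.testing.assert_frame_equal(lp1.data, lp2.data)


def _joint_sample_table(n_indices=20, horizons=(0, 1, 2, 3)):
    spec = fp.HubSpec(
        models=(
            fp.ModelSpec("m1", "normal", (100.0, 10.0), horizon_drift=5.0),
            fp.ModelSpec("m2", "normal", (110.0, 8.0), horizon_drift=5.0),
        ),
        task_grid={"reference_date": ["2022-12-17"], "location": ["25"],
                   "target": ["wk flu hosp"], "horizon": list(horizons)},
        n_samples_per_model=n_indices,
        joint_across="horizon",
        seed=11,
    )
    return generate_samples_only(spec)


def generate_samples_only(spec):
    return fp.generate_component_outputs(spec, output_types=["sample"])


class TestJointSamples:
    def test_joint_integrity_under_subsetting(self):
        table = _joint_sample_table()
        cfg = fp.LinearPoolConfig(
            n_output_samples=10,
            compound_taskid_set=("reference_date", "location", "target"),
            seed=5,
        )
        lp = fp.linear_pool(table, config=cfg)
        # each selected joint index contributes exactly one row per horizon
        counts = lp.data.groupby("output_type_id")["horizon"].agg(
            lambda s: sorted(s)
        )
        assert all(c == [0, 1, 2, 3] for c in counts)
        assert lp.data["output_type_id"].nunique() == 10

    def test_validate_compound_marginal_true(self):
        table = _sample_table()
        assert fp.validate_compound_taskids(table, ["location"])

    def test_validate_compound_joint_true(self):
        table = _joint_sample_table()
        assert fp.validate_compound_taskids(
            table, ["reference_date", "location", "target"]
        )

    def test_incomplete_cross_product_false(self):
        table = _joint_sample_table()
        df = table.data
        # drop one horizon row from one sample index of one model
        mask = (
            (df["model_id"] == "m1")
            & (df["output_type_id"] == 0)
            & (df["horizon"] == 2)
        )
        broken = fp.validate_model_output(
            df[~mask].reset_index(drop=True), table.task_ids
        )
        assert not fp.validate_compound_taskids(
            broken, ["reference_date", "location", "target"]
        )

    def test_derived_task_consistent_true(self):
        table = _joint_sample_table()
        df = table.data.copy()
        df["target_end_date"] = [
            f"2022-12-17+{h}" for h in df["horizon"]
        ]
        t = fp.validate_model_output(
            df, [*table.task_ids, "target_end_date"]
        )
        assert fp.validate_compound_taskids(
            t, ["reference_date", "location", "target"],
            derived_tasks=["target_end_date"],
        )

    def test_derived_task_contradiction_false(self):
        table = _joint_sample_table()
        df = table.data.copy()
        dd = [f"2022-12-17+{h}" for h in df["horizon"]]
        dd[0] = "wrong-date"
        df["target_end_date"] = dd
        t = fp.validate_model_output(df, [*table.task_ids, "target_end_date"])
        assert not fp.validate_compound_taskids(
            t, ["reference_date", "location", "target"],
            derived_tasks=["target_end_date"],
        )
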