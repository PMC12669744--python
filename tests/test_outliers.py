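import numpy as np
import pandas as pd
import pytest

from phenoload import (
    call_outliers,
    compute_gene_loads,
    fit_load_regression,
    quartiles,
)
from phenoload.errors import DegenerateInputError, UsageError
from phenoload.outliers import RegressionFit, find_outliers, outlier_table

from tests.oracles import brute_ols, brute_outliers, brute_quartile


def loads_frame(pairs, genes=None):
    genes = genes or [f"G{i}" for i in range(len(pairs))]
    return pd.DataFrame(
        {"gene": genes, "load_control": [p[0] for p in pairs], "load_case": [p[1] for p in pairs]}
    )


def fit_from_residuals(residuals):
    """A RegressionFit with prescribed residuals, for testing the fence rule."""
    res = pd.Series(residuals, index=[f"G{i}" for i in range(len(residuals))])
    q1, q3 = quartiles(res.to_numpy())
    d = q3 - q1
    return RegressionFit(
        slope=0.0, intercept=0.0, residuals=res,
        q1=q1, q3=q3, d=d,
        lower_threshold=q1 - 6 * d, upper_threshold=q3 + 6 * d,
    )


class TestGeneLoads:
    def test_presence_counting(self, variants_factory):
        df = variants_factory(
            [
                {"gene": "G", "carriers_normal": 2, "carriers_impaired": 0},
                {"gene": "G", "carriers_normal": 1, "carriers_impaired": 1},
                {"gene": "G", "carriers_normal": 0, "carriers_impaired": 5},
            ]
        )
        loads = compute_gene_loads(df)
        assert loads.iloc[0].tolist() == ["G", 2, 2]

    def test_case_only_variant(self, variants_factory):
        df = variants_factory([{"gene": "G", "carriers_impaired": 1}])
        loads = compute_gene_loads(df)
        assert loads.iloc[0].tolist() == ["G", 0, 1]

    def test_gene_with_no_presence_absent(self, variants_factory):
        df = variants_factory(
            [
                {"gene": "A", "carriers_normal": 1},
                {"gene": "B", "carriers_normal": 0, "carriers_impaired": 0},
            ]
        )
        assert compute_gene_loads(df)["gene"].tolist() == ["A"]

    def test_duplicate_variant_gene_records_count_once(self, variants_factory):
        df = variants_factory(
            [
                {"gene": "G", "carriers_normal": 1},
                {"gene": "G", "carriers_normal": 3},
            ]
        )
        df.loc[1, "variant_id"] = df.loc[0, "variant_id"]
        assert compute_gene_loads(df)["load_control"].iloc[0] == 1

    def test_multi_gene_variant_counts_in_each_gene(self, variants_factory):
        df = variants_factory(
            [
                {"gene": "A", "carriers_normal": 1},
                {"gene": "B", "carriers_normal": 1},
            ]
        )
        df["variant_id"] = "chr1:1:A:G"
        assert compute_gene_loads(df)["load_control"].tolist() == [1, 1]

    def test_unknown_group_label(self, variants_factory):
        df = variants_factory([{"gene": "G", "carriers_normal": 1}])
        with pytest.raises(UsageError, match="hearing"):
            compute_gene_loads(df, control_group="hearing")


class TestQuartiles:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((1, 2, 3, 4, 5), (2.0, 4.0)),
            ((0, 100), (25.0, 75.0)),
            ((7, 7, 7, 7), (7.0, 7.0)),
            ((-1, -0.5, 0, 0, 0, 0.5, 1, 100), (-0.125, 0.625)),
        ],
    )
    def test_linear_interpolation_convention(self, values, expected):
        assert quartiles(values) == pytest.approx(expected)

    def test_single_value_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            quartiles([1.0])

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            values = rng.normal(size=rng.integers(2, 40)).tolist()
            q1, q3 = quartiles(values)
            assert q1 == pytest.approx(brute_quartile(values, 0.25))
            assert q3 == pytest.approx(brute_quartile(values, 0.75))


class TestRegression:
    def test_perfect_fit_gives_zero_residuals(self):
        table = loads_frame([(x, 2 * x + 1) for x in range(5)])
        fit = fit_load_regression(table)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.d == pytest.approx(0.0)
        assert np.allclose(fit.residuals, 0.0)

    def test_residuals_sum_to_zero(self, rng):
        table = loads_frame(
            [(int(x), int(y)) for x, y in rng.integers(0, 30, size=(40, 2))]
        )
        fit = fit_load_regression(table)
        assert abs(fit.residuals.sum()) < 1e-9 * len(table)

    def test_five_point_blowout_matches_oracle(self):
        # With only five genes the blowout inflates D itself (residuals
        # 18.4, 0, -18.4, -36.8, 36.8; fence at 239.2), so the strict
        # 6D rule calls nothing — and the brute-force oracle agrees.
        table = loads_frame([(0, 0), (1, 2), (2, 4), (3, 6), (4, 100)])
        fit = fit_load_regression(table)
        assert fit.residuals.tolist() == pytest.approx([18.4, 0.0, -18.4, -36.8, 36.8])
        calls = call_outliers(fit)
        expected_case, expected_control = brute_outliers(
            table["gene"].tolist(),
            table["load_control"].tolist(),
            table["load_case"].tolist(),
        )
        assert list(calls.outliers_case) == expected_case == []
        assert list(calls.outliers_control) == expected_control == []

    def test_blowout_among_many_well_fit_genes_is_called(self):
        # With enough near-line genes, D stays small and the blowout gene
        # clears the fence.
        pairs = [(x, 2 * x + (x % 3) - 1) for x in range(20)] + [(4, 100)]
        table = loads_frame(pairs)
        calls = call_outliers(fit_load_regression(table))
        expected_case, _ = brute_outliers(
            table["gene"].tolist(),
            table["load_control"].tolist(),
            table["load_case"].tolist(),
        )
        assert list(calls.outliers_case) == expected_case == ["G20"]

    def test_ols_matches_normal_equations(self, rng):
        x = rng.integers(0, 50, size=30).astype(float)
        x[0] += 1  # guard against constant degenerate draw
        y = rng.integers(0, 50, size=30).astype(float)
        table = loads_frame(list(zip(x, y)))
        fit = fit_load_regression(table)
        slope, intercept = brute_ols(list(x), list(y))
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)

    def test_order_invariance(self, rng):
        table = loads_frame(
            [(int(x), int(y)) for x, y in rng.integers(0, 30, size=(25, 2))]
        )
        shuffled = table.sample(frac=1, random_state=3)
        a = call_outliers(fit_load_regression(table))
        b = call_outliers(fit_load_regression(shuffled))
        assert a.outliers_case == b.outliers_case
        assert a.outliers_control == b.outliers_control
        assert a.fit.upper_threshold == pytest.approx(b.fit.upper_threshold)

    def test_too_few_genes(self):
        with pytest.raises(DegenerateInputError, match="3 genes"):
            fit_load_regression(loads_frame([(1, 2), (3, 4)]))

    def test_constant_predictor(self):
        with pytest.raises(DegenerateInputError, match="constant"):
            fit_load_regression(loads_frame([(2, 1), (2, 5), (2, 9)]))


class TestFenceRule:
    def test_equal_residuals_give_no_outliers(self):
        calls = call_outliers(fit_from_residuals([3.0] * 10))
        assert calls.fit.d == 0.0
        assert calls.outliers_case == () and calls.outliers_control == ()

    def test_spec_residual_fixture_thresholds(self):
        fit = fit_from_residuals([-1, -0.5, 0, 0, 0, 0.5, 1, 100])
        assert (fit.q1, fit.q3) == pytest.approx((-0.125, 0.625))
        assert fit.upper_threshold == pytest.approx(5.125)
        assert fit.lower_threshold == pytest.approx(-4.625)
        calls = call_outliers(fit)
        assert list(calls.outliers_case) == ["G7"]
        assert calls.outliers_control == ()

    def test_exactly_at_threshold_is_not_an_outlier(self):
        fit = fit_from_residuals([-1, -0.5, 0, 0, 0, 0.5, 1, 100])
        at_threshold = fit_from_residuals([-1, -0.5, 0, 0, 0, 0.5, 1, 100])
        res = at_threshold.residuals.copy()
        res["G7"] = at_threshold.upper_threshold  # sits exactly on the fence
        pinned = RegressionFit(
            slope=0.0, intercept=0.0, residuals=res,
            q1=fit.q1, q3=fit.q3, d=fit.d,
            lower_threshold=fit.lower_threshold, upper_threshold=fit.upper_threshold,
        )
        assert call_outliers(pinned).outliers_case == ()

    def test_negating_residuals_swaps_directions(self, rng):
        residuals = rng.normal(size=30).tolist() + [40.0, -35.0]
        a = call_outliers(fit_from_residuals(residuals))
        b = call_outliers(fit_from_residuals([-r for r in residuals]))
        assert set(a.outliers_case) == set(b.outliers_control)
        assert set(a.outliers_control) == set(b.outliers_case)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 50))
            x = rng.integers(0, 40, size=n).astype(float)
            if np.ptp(x) == 0:
                x[0] += 1
            y = rng.integers(0, 40, size=n).astype(float)
            # sprinkle big deviations so outliers actually occur sometimes
            if rng.random() < 0.5:
                y[rng.integers(n)] += rng.integers(50, 500)
            genes = [f"G{i}" for i in range(n)]
            calls = call_outliers(fit_load_regression(loads_frame(list(zip(x, y)), genes)))
            expected = brute_outliers(genes, list(x), list(y))
            assert (sorted(calls.outliers_case), sorted(calls.outliers_control)) == expected

    def test_single_injected_blowout_changes_calls_by_at_most_itself(self, rng):
        x = rng.integers(0, 30, size=40).astype(float)
        y = x + rng.normal(scale=2.0, size=40)
        genes = [f"G{i}" for i in range(40)]
        base = call_outliers(fit_load_regression(loads_frame(list(zip(x, y)), genes)))
        assert base.fit.d > 0
        x2 = np.append(x, 15.0)
        y2 = np.append(y, 10 * y.max())
        genes2 = genes + ["INJECTED"]
        spiked = call_outliers(fit_load_regression(loads_frame(list(zip(x2, y2)), genes2)))
        assert set(spiked.outliers_case) - set(base.outliers_case) <= {"INJECTED"}


def test_find_outliers_and_table(variants_factory):
    rows = []
    for g in range(40):
        for v in range(2 + g % 7):
            rows.append({"gene": f"G{g:02d}", "carriers_normal": 1, "carriers_impaired": 1})
    for v in range(30):  # one gene loaded with case-only variants
        rows.append({"gene": "G00", "carriers_impaired": 2})
    df = variants_factory(rows)
    calls = find_outliers(df)
    assert "G00" in calls.outliers_case
    loads = compute_gene_loads(df)
    table = outlier_table(calls, loads)
    assert table.loc[table["gene"] == "G00", "is_outlier_case"].item()
    assert len(table) == len(loads)
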