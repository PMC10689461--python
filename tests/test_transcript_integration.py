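import numpy as np
import pandas as pd
import pytest
from scipy.stats import gmean

from bileflow.io_model import BileflowError
from bileflow.transcript_integration import (
    median_ratio_size_factors,
    normalize_counts,
    protein_transcript_regression,
    rin_filter,
    simple_linear_regression,
)


class TestRinFilter:
    def test_threshold_is_strict(self):
        rin = pd.Series({"L1": 7.0, "L2": 7.1})
        assert rin_filter(rin) == ["L2"]

    def test_cohort_count(self):
        rin = pd.Series({"L1": 6.5, "L2": 7.0, "L3": 8.2, "L4": 9.0})
        assert len(rin_filter(rin)) == 2

    def test_missing_rin_excluded_with_warning(self, caplog):
        rin = pd.Series({"L1": np.nan, "L2": 8.0})
        with caplog.at_level("WARNING", logger="bileflow"):
            kept = rin_filter(rin)
        assert kept == ["L2"] and "L1" in caplog.text

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        rin = pd.Series(rng.uniform(4, 10, 30), index=[f"L{i}" for i in range(30)])
        sizes = [len(rin_filter(rin, t)) for t in (5, 6, 7, 8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_out_of_range_rin_rejected(self):
        with pytest.raises(BileflowError):
            rin_filter(pd.Series({"L1": 11.0}))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(median_ratio_size_factors(counts), 1.0)

    def test_doubled_column_has_double_factor(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, 500) + 1
        counts = pd.DataFrame({"a": base, "b": 2 * base, "c": base})
        f = median_ratio_size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0, abs=1e-10)

    def test_matches_step_by_step_recomputation(self):
        """Direct formula oracle: per-sample median of count / geometric
        mean, restricted to genes nonzero everywhere."""
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.3, (200, 6)),
            columns=[f"L{i}" for i in range(6)],
        )
        f = median_ratio_size_factors(counts)
        sub = counts[(counts > 0).all(axis=1)]
        geo = gmean(sub, axis=1)
        for j, col in enumerate(counts.columns):
            ref = np.median(sub[col] / geo)
            assert f[col] == pytest.approx(ref, rel=1e-10)

    def test_scale_equivariance_of_factor_ratios(self):
        """Scaling one sample by c multiplies its factor, relative to any
        other sample, by c (the geometric-mean reference itself shifts by
        c^(1/n), so only factor ratios are scale-equivariant)."""
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, (300, 4)) + 1, columns=list("abcd"))
        f1 = median_ratio_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        f2 = median_ratio_size_factors(scaled)
        assert (f2["c"] / f2["a"]) / (f1["c"] / f1["a"]) == pytest.approx(
            3.0, rel=1e-10
        )

    def test_no_common_gene_is_an_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(BileflowError, match="pseudo-reference"):
            median_ratio_size_factors(counts)


def oracle_ols(x, y):
    """Normal-equations OLS with the classic slope t-test."""
    import math

    from scipy.stats import t as tdist

    n = len(x)
    xm, ym = np.mean(x), np.mean(y)
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    s2 = np.sum(resid**2) / (n - 2)
    se = math.sqrt(s2 / sxx)
    t = slope / se
    p = 2 * tdist.sf(abs(t), n - 2)
    ss_tot = np.sum((y - ym) ** 2)
    r2 = 1 - np.sum(resid**2) / ss_tot
    return slope, intercept, r2, p


class TestRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = simple_linear_regression(x, 2 * x + 1)
        assert fit["slope"] == pytest.approx(2.0, abs=1e-12)
        assert fit["intercept"] == pytest.approx(1.0, abs=1e-12)
        assert fit["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 12)
        y = 0.5 * x + rng.normal(0, 1, 12)
        fit = simple_linear_regression(x, y)
        slope, intercept, r2, p = oracle_ols(x, y)
        assert fit["slope"] == pytest.approx(slope, abs=1e-10)
        assert fit["intercept"] == pytest.approx(intercept, abs=1e-10)
        assert fit["r2"] == pytest.approx(r2, abs=1e-10)
        assert fit["p"] == pytest.approx(p, abs=1e-10)

    def test_null_relationship_p_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 20)
            ps.append(simple_linear_regression(x, y)["p"])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_p_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 15)
        y = 0.7 * x + rng.normal(0, 1, 15)
        p0 = simple_linear_regression(x, y)["p"]
        p1 = simple_linear_regression(3 * x - 2, 0.5 * y + 4)["p"]
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(BileflowError, match="variance"):
            simple_linear_regression([1, 1, 1], [1, 2, 3])

    def test_grouped_regression_table(self):
        rng = np.random.default_rng(7)
        livers = [f"L{i}" for i in range(8)]
        counts = pd.DataFrame(
            rng.poisson(100, (3, 8)) + 1.0, index=["g1", "g2", "g3"], columns=livers
        )
        prot = pd.DataFrame(
            rng.normal(20, 1, (3, 8)), index=["g1", "g2", "g3"], columns=livers
        )
        res = protein_transcript_regression(
            counts, prot, {"all": livers, "first4": livers[:4]}, genes=["g1", "g2"]
        )
        assert set(res["group"]) == {"all", "first4"}
        assert set(res["gene"]) == {"g1", "g2"}
        assert ((res["r2"] >= 0) & (res["r2"] <= 1)).all()
        assert (res.loc[res["group"] == "all", "n"] == 8).all()
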