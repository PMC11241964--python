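"""Crude/adjusted reporting odds ratios, signal rule, and VIF diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal.disproportionality import NO_SIGNAL, SIGNAL


def expand_table(a, b, c, d):
    """75-row-style expansion of a 2x2 table into case/exposure vectors."""
    y = [1] * a + [1] * b + [0] * c + [0] * d
    x = [1] * a + [0] * b + [1] * c + [0] * d
    idx = pd.Index([f"R{i}" for i in range(len(y))], name="report_id")
    return pd.Series(y, index=idx), pd.DataFrame({"exposed": x}, index=idx)


class TestTabulate:
    def test_enumeration(self):
        idx = pd.Index(list("wxyz"), name="report_id")
        t = pv.tabulate(pd.Series([1, 1, 0, 0], index=idx), pd.Series([1, 0, 1, 0], index=idx))
        assert t.cells() == (1, 1, 1, 1)

    def test_no_cases_degenerate(self):
        idx = pd.Index(["a", "b"], name="report_id")
        t = pv.tabulate(pd.Series([0, 0], index=idx), pd.Series([1, 0], index=idx))
        assert (t.a, t.b) == (0, 0)

    def test_fixture_counts(self):
        y, X = expand_table(10, 20, 5, 40)
        t = pv.tabulate(y, X["exposed"])
        assert t.cells() == (10, 20, 5, 40)
        assert t.n == 75

    def test_index_mismatch_rejected(self):
        a = pd.Series([1], index=pd.Index(["r1"]))
        b = pd.Series([1], index=pd.Index(["r2"]))
        with pytest.raises(pv.PvSignalError, match="mismatch"):
            pv.tabulate(a, b)


class TestCrudeRor:
    def test_worked_example(self):
        est = pv.crude_ror(pv.ContingencyTable(10, 20, 5, 40))
        assert est.point == pytest.approx(4.000, abs=5e-4)
        assert est.ci_low == pytest.approx(1.204, abs=5e-4)
        assert est.ci_high == pytest.approx(13.284, abs=5e-4)
        assert est.n_exposed_cases == 10

    def test_identity_table_no_signal(self):
        est = pv.crude_ror(pv.ContingencyTable(5, 5, 5, 5))
        assert est.point == pytest.approx(1.0)
        assert est.signal == NO_SIGNAL

    def test_zero_cell_haldane_anscombe(self):
        est = pv.crude_ror(pv.ContingencyTable(0, 10, 5, 100))
        assert est.point == pytest.approx((0.5 * 100.5) / (10.5 * 5.5), rel=1e-9)
        assert est.low_count_flag
        assert est.n_exposed_cases == 0

    def test_zero_cell_without_correction_errors(self):
        with pytest.raises(pv.EstimateError):
            pv.crude_ror(pv.ContingencyTable(0, 10, 5, 100), zero_cell_correction="none")

    def test_low_count_flag_below_ten_exposed_cases(self):
        assert pv.crude_ror(pv.ContingencyTable(9, 50, 50, 500)).low_count_flag
        assert not pv.crude_ror(pv.ContingencyTable(10, 50, 50, 500)).low_count_flag

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.integers(1, 200), st.integers(1, 200), st.integers(1, 200), st.integers(1, 200)
    )
    def test_monotone_in_exposed_cases(self, a, b, c, d):
        lo = pv.crude_ror(pv.ContingencyTable(a, b, c, d))
        hi = pv.crude_ror(pv.ContingencyTable(a + 1, b, c, d))
        assert hi.point > lo.point

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        y, X = expand_table(7, 13, 11, 42)
        perm = rng.permutation(len(y))
        t1 = pv.tabulate(y, X["exposed"])
        t2 = pv.tabulate(y.iloc[perm], X["exposed"].iloc[perm])
        assert t1 == t2


class TestLogisticFit:
    def test_saturated_2x2_closed_form(self):
        y, X = expand_table(10, 20, 5, 40)
        fit = pv.fit_logistic(X, y)
        assert np.exp(fit.params["exposed"]) == pytest.approx(4.000, abs=1e-6)
        assert fit.params["(Intercept)"] == pytest.approx(np.log(20 / 40), abs=1e-6)
        assert fit.converged

    def test_intercept_only_matches_case_fraction(self):
        idx = pd.Index(range(100))
        y = pd.Series([1] * 30 + [0] * 70, index=idx)
        x = pd.Series([0, 1] * 50, index=idx, name="z")  # balanced noise covariate
        fit = pv.fit_logistic(pd.DataFrame({"z": x}), y)
        p0 = 1 / (1 + np.exp(-fit.params["(Intercept)"] - 0.5 * 0))
        # with a balanced independent covariate the intercept reproduces ~30% odds
        assert 1 / (1 + np.exp(-fit.params["(Intercept)"])) == pytest.approx(0.3, abs=0.05)

    def test_perfect_separation_detected(self):
        y, X = expand_table(20, 0, 0, 20)
        with pytest.raises(pv.SeparationError) as exc:
            pv.fit_logistic(X, y)
        assert exc.value.column == "exposed"

    def test_constant_column_rejected(self):
        idx = pd.Index(range(4))
        with pytest.raises(pv.PvSignalError, match="constant"):
            pv.fit_logistic(
                pd.DataFrame({"k": [1, 1, 1, 1]}, index=idx),
                pd.Series([0, 1, 0, 1], index=idx),
            )

    def test_matches_statsmodels_oracle(self):
        """Independent ML route: statsmodels GLM on a multi-covariate fit."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        n = 600
        X = pd.DataFrame(
            {
                "x1": rng.integers(0, 2, n),
                "x2": rng.integers(0, 2, n),
                "x3": rng.normal(size=n),
            }
        )
        eta = -1.0 + 0.8 * X["x1"] - 0.4 * X["x2"] + 0.3 * X["x3"]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int), index=X.index)
        fit = pv.fit_logistic(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert fit.params["x1"] == pytest.approx(ref.params["x1"], abs=1e-6)
        assert fit.se("x1") == pytest.approx(ref.bse["x1"], abs=1e-6)
        assert fit.params["(Intercept)"] == pytest.approx(ref.params["const"], abs=1e-6)


class TestAdjustedRor:
    def test_univariate_equals_crude_without_correction(self):
        y, X = expand_table(10, 20, 5, 40)
        fit = pv.fit_logistic(X, y)
        adj = pv.adjusted_ror(fit, "exposed", 10)
        crude = pv.crude_ror(pv.ContingencyTable(10, 20, 5, 40), "none")
        assert adj.point == pytest.approx(crude.point, abs=1e-6)
        assert adj.ci_low == pytest.approx(crude.ci_low, abs=1e-6)
        assert adj.ci_high == pytest.approx(crude.ci_high, abs=1e-6)

    def test_null_coefficient_interval(self):
        fit = pv.LogisticFit(
            params=pd.Series({"(Intercept)": -2.0, "drug": 0.0}),
            cov=pd.DataFrame(
                [[0.01, 0.0], [0.0, 0.01]],
                index=["(Intercept)", "drug"],
                columns=["(Intercept)", "drug"],
            ),
            converged=True,
            n_iterations=5,
            deviance=1.0,
        )
        est = pv.adjusted_ror(fit, "drug", 50)
        assert est.point == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(0.822, abs=5e-4)
        assert est.ci_high == pytest.approx(1.217, abs=5e-4)
        assert est.signal == NO_SIGNAL

    def test_unknown_term_rejected(self):
        y, X = expand_table(10, 20, 5, 40)
        fit = pv.fit_logistic(X, y)
        with pytest.raises(pv.PvSignalError, match="nope"):
            pv.adjusted_ror(fit, "nope")

    def test_reference_level_invariance(self):
        """Exposure estimate unchanged when an adjustment dummy is recoded."""
        rng = np.random.default_rng(3)
        n = 400
        exposed = rng.integers(0, 2, n)
        grp = rng.integers(0, 2, n)
        y = pd.Series(
            (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 0.7 * exposed + 0.5 * grp)))).astype(int)
        )
        X1 = pd.DataFrame({"exposed": exposed, "grp_b": grp})
        X2 = pd.DataFrame({"exposed": exposed, "grp_a": 1 - grp})  # flipped reference
        b1 = pv.fit_logistic(X1, y).params["exposed"]
        b2 = pv.fit_logistic(X2, y).params["exposed"]
        assert b1 == pytest.approx(b2, abs=1e-8)


class TestSignalRule:
    @pytest.mark.parametrize(
        "point,lo,hi,expected",
        [
            (3.35, 3.25, 3.44, SIGNAL),  # positive-control pattern
            (1.04, 0.99, 1.09, NO_SIGNAL),  # negative-control pattern
            (0.80, 0.70, 0.92, NO_SIGNAL),  # below 1 is never "protective"
            (1.5, 1.0, 2.25, NO_SIGNAL),  # boundary: lower bound must exceed 1
        ],
    )
    def test_rule(self, point, lo, hi, expected):
        est = pv.RorEstimate(
            point=point, ci_low=lo, ci_high=hi, se_log=0.1, method="adjusted",
            n_exposed_cases=100,
        )
        assert pv.classify_signal(est) == expected
        assert est.signal == expected


class TestOracleEquivalence:
    """exp(univariate logistic beta) == ad/bc and Wald CI == Woolf CI."""

    def test_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 60, size=4)
            y, X = expand_table(int(a), int(b), int(c), int(d))
            fit = pv.fit_logistic(X, y)
            adj = pv.adjusted_ror(fit, "exposed", int(a))
            crude = pv.crude_ror(pv.ContingencyTable(int(a), int(b), int(c), int(d)), "none")
            assert adj.point == pytest.approx(crude.point, abs=1e-6, rel=1e-6)
            assert adj.ci_low == pytest.approx(crude.ci_low, abs=1e-6, rel=1e-6)
            assert adj.ci_high == pytest.approx(crude.ci_high, abs=1e-6, rel=1e-6)


class TestVif:
    def test_orthogonal_columns_vif_one(self):
        X = pd.DataFrame({"x1": [1, 1, -1, -1], "x2": [1, -1, 1, -1]})
        vif = pv.compute_vif(X)
        assert vif["vif"].tolist() == pytest.approx([1.0, 1.0])
        assert not vif["flagged"].any()

    def test_worked_example_vif_two(self):
        X = pd.DataFrame({"x1": [0, 0, 1, 1], "x2": [0, 1, 1, 2]})
        vif = pv.compute_vif(X)
        assert vif.loc["x1", "vif"] == pytest.approx(2.0, abs=1e-9)
        assert vif.loc["x2", "vif"] == pytest.approx(2.0, abs=1e-9)

    def test_duplicated_column_infinite(self):
        X = pd.DataFrame({"x1": [0, 1, 0, 1], "x2": [0, 1, 0, 1], "x3": [0, 0, 1, 1]})
        vif = pv.compute_vif(X)
        assert np.isinf(vif.loc["x1", "vif"])
        assert np.isinf(vif.loc["x2", "vif"])

    def test_matches_statsmodels_oracle(self):
        smo = pytest.importorskip("statsmodels.stats.outliers_influence")
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        X["b"] = X["b"] + 0.8 * X["a"]
        mine = pv.compute_vif(X)
        design = np.column_stack([np.ones(len(X)), X.to_numpy()])
        for j, name in enumerate(X.columns):
            ref = smo.variance_inflation_factor(design, j + 1)
            assert mine.loc[name, "vif"] == pytest.approx(ref, rel=1e-8)
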