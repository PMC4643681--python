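"""Per-tract regression: OLS oracle, Bonferroni bookkeeping, significance flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hodomap.disconnection import DisconnectionTable
from hodomap.trackwise import (
    RegressionSpec,
    bonferroni_alpha,
    DegenerateDesignError,
    fit_tract_regression,
    flag_significant,
    results_to_frame,
    run_trackwise_analysis,
    TractRegressionResult,
)


def make_table(overlaps_by_column, hemispheres, outcome_values=None, n=None, seed=0):
    cols = list(overlaps_by_column)
    n = n if n is not None else len(next(iter(overlaps_by_column.values())))
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "lesion_volume_cc": rng.uniform(5, 40, n),
            "age": rng.normal(72, 13, n),
            "sex": rng.choice(["M", "F"], n),
            "handedness": rng.choice(["R", "L"], n),
            "vf_miss_left": rng.poisson(0.5, n),
            "vf_miss_right": rng.poisson(0.5, n),
            "global_pct": rng.normal(85, 5, n),
            "local_pct": rng.normal(85, 5, n),
        }
    )
    for col, values in overlaps_by_column.items():
        data[col] = values
        data["lesion_volume_cc"] = np.maximum(
            data["lesion_volume_cc"], np.asarray(values, float)
        )
    if outcome_values is not None:
        for k, v in outcome_values.items():
            data[k] = v
    return DisconnectionTable(data, cols, hemispheres)


class TestOlsOracle:
    def test_matches_normal_equations_on_12_rows(self):
        rng = np.random.default_rng(42)
        n = 12
        x = rng.uniform(0, 3, n)
        table = make_table({"t_left": x}, {"t_left": "left"}, n=n, seed=1)
        y = table.data["local_pct"].to_numpy()
        res = fit_tract_regression(
            table, RegressionSpec(outcome="local_pct", tract="t_left", hemisphere="left")
        )
        # independent route: normal equations + t distribution
        X = np.column_stack(
            [
                np.ones(n),
                x,
                table.data["lesion_volume_cc"],
                table.data["age"],
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        df = n - X.shape[1]
        s2 = resid @ resid / df
        cov = s2 * np.linalg.inv(X.T @ X)
        t_stat = beta[1] / np.sqrt(cov[1, 1])
        p = 2 * stats.t.sf(abs(t_stat), df)
        beta_std = beta[1] * np.std(x, ddof=1) / np.std(y, ddof=1)
        assert res.beta_std == pytest.approx(beta_std, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-8)
        assert res.n == n

    def test_perfect_linear_relationship(self):
        n = 20
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 3, n)
        table = make_table(
            {"t_left": x},
            {"t_left": "left"},
            outcome_values={"local_pct": 90.0 - 5.0 * x},
            n=n,
        )
        res = fit_tract_regression(
            table, RegressionSpec(outcome="local_pct", tract="t_left", hemisphere="left")
        )
        assert res.p_value < 1e-10
        assert res.beta_std == pytest.approx(-1.0, abs=1e-6)

    def test_beta_std_invariant_under_unit_change(self):
        n = 30
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 3, n)
        y = 90 - 4 * x + rng.normal(0, 3, n)
        t_cc = make_table(
            {"t_left": x}, {"t_left": "left"}, outcome_values={"local_pct": y}, n=n
        )
        res_cc = fit_tract_regression(
            t_cc, RegressionSpec(outcome="local_pct", tract="t_left", hemisphere="left")
        )
        data_l = t_cc.data.copy()
        data_l["t_left"] = data_l["t_left"] * 1e-3  # cm3 -> litres
        t_l = DisconnectionTable(data_l, ["t_left"], {"t_left": "left"})
        res_l = fit_tract_regression(
            t_l, RegressionSpec(outcome="local_pct", tract="t_left", hemisphere="left")
        )
        assert res_cc.beta_std == pytest.approx(res_l.beta_std, abs=1e-10)
        assert res_cc.p_value == pytest.approx(res_l.p_value, abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        table = make_table({"t_left": np.zeros(15)}, {"t_left": "left"}, n=15)
        with pytest.raises(DegenerateDesignError, match="zero variance"):
            fit_tract_regression(
                table,
                RegressionSpec(outcome="local_pct", tract="t_left", hemisphere="left"),
            )


class TestRunAnalysis:
    def _paired_table(self, n=40, seed=4):
        rng = np.random.default_rng(seed)
        cols = {}
        hemis = {}
        for name in ("a", "b", "c", "d"):
            for side in ("left", "right"):
                col = f"{name}_{side}"
                cols[col] = rng.exponential(1.0, n) * (rng.random(n) < 0.5)
                hemis[col] = side
        return make_table(cols, hemis, n=n, seed=seed)

    def test_four_pairs_give_eight_results(self):
        results = run_trackwise_analysis(self._paired_table(), "local_pct")
        assert len(results) == 8
        assert {r.hemisphere for r in results} == {"left", "right"}

    def test_vf_covariates_extend_every_design(self):
        results = run_trackwise_analysis(
            self._paired_table(), "global_pct", include_vf=True
        )
        for r in results:
            assert set(r.covariates) == {
                "lesion_volume_cc",
                "age",
                "vf_miss_left",
                "vf_miss_right",
            }

    def test_hemisphere_runs_restrict_to_lesioned_side(self):
        n = 40
        rng = np.random.default_rng(11)
        side = rng.random(n) < 0.5
        overlaps = rng.exponential(1.0, n)
        table = make_table(
            {"a_left": np.where(side, overlaps, 0.0), "a_right": np.where(~side, overlaps, 0.0)},
            {"a_left": "left", "a_right": "right"},
            n=n,
        )
        table.data["lesion_volume_left_cc"] = np.where(side, 10.0, 0.0)
        table.data["lesion_volume_right_cc"] = np.where(~side, 10.0, 0.0)
        results = run_trackwise_analysis(table, "local_pct")
        by_col = {r.tract: r for r in results}
        assert by_col["a_left"].n == int(side.sum())
        assert by_col["a_right"].n == int((~side).sum())

    def test_all_zero_tract_is_skipped_not_fitted(self):
        table = self._paired_table()
        table.data["a_left"] = 0.0
        results = run_trackwise_analysis(table, "local_pct")
        skipped = [r for r in results if r.skipped]
        assert [r.tract for r in skipped] == ["a_left"]
        assert "zero variance" in skipped[0].skip_reason
        frame = results_to_frame(results)
        assert frame["skipped"].sum() == 1


class TestBonferroni:
    def test_sixteen_tract_family(self):
        assert bonferroni_alpha(16, 0.05) == pytest.approx(0.003125, abs=1e-12)

    @pytest.mark.parametrize("n,alpha,expected", [(1, 0.05, 0.05), (10, 0.05, 0.005)])
    def test_simple_families(self, n, alpha, expected):
        assert bonferroni_alpha(n, alpha) == pytest.approx(expected)

    @pytest.mark.parametrize("n,alpha", [(0, 0.05), (16, 0.0), (16, 1.0)])
    def test_invalid_inputs(self, n, alpha):
        with pytest.raises(ValueError):
            bonferroni_alpha(n, alpha)


class TestFlagging:
    def _result(self, p):
        return TractRegressionResult(
            tract="t", hemisphere="left", outcome="local_pct",
            n=60, beta_std=-0.2, p_value=p, covariates=("lesion_volume_cc", "age"),
        )

    def test_strict_inequality_at_the_corrected_level(self):
        alpha = bonferroni_alpha(16, 0.05)
        flagged = flag_significant([self._result(0.001), self._result(0.004)], alpha)
        assert flagged[0].significant is True
        assert flagged[1].significant is False

    def test_flags_never_alter_estimates_and_preserve_order(self):
        results = [self._result(p) for p in (0.5, 0.0001, 0.01)]
        flagged = flag_significant(results, 0.003125)
        assert [r.p_value for r in flagged] == [0.5, 0.0001, 0.01]
        assert [r.beta_std for r in flagged] == [-0.2] * 3

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            flag_significant([], 0.003)
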