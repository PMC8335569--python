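import numpy as np
import pandas as pd
import pytest

import mutcell as mc
from mutcell.errors import ValidationError


def _cohort(seed=3, n=400, betas={"C001": 1.0, "C002": -1.0}):
    truth = mc.make_truth(2, 5, frequency=0.3, survival_betas=betas, seed=seed)
    return mc.generate_cohort(n, 5, 2, truth)


class TestFitCox:
    def test_matches_lifelines_on_continuous_times(self):
        from lifelines import CoxPHFitter

        cohort = _cohort()
        sub = cohort.abundance.loc[["C001", "C002"]]
        fit = mc.fit_cox(sub, cohort.survival)
        df = pd.DataFrame({"time": cohort.survival["time"],
                           "event": cohort.survival["event"],
                           "C001": sub.loc["C001"], "C002": sub.loc["C002"]})
        cph = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(fit.params.to_numpy(), cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.bse.to_numpy(),
                                   cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_efron_matches_lifelines_on_tied_times(self, rng):
        from lifelines import CoxPHFitter

        ab = pd.DataFrame(rng.standard_normal((2, 80)), index=["A", "B"],
                          columns=[f"s{i}" for i in range(80)])
        surv = pd.DataFrame({"time": rng.integers(1, 8, 80).astype(float),
                             "event": rng.integers(0, 2, 80)}, index=ab.columns)
        fit = mc.fit_cox(ab, surv, ties="efron")
        df = pd.DataFrame({"time": surv["time"], "event": surv["event"],
                           "A": ab.loc["A"], "B": ab.loc["B"]})
        cph = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(fit.params.to_numpy(), cph.params_.to_numpy(), atol=1e-5)

    def test_null_cell_beta_near_zero(self):
        cohort = _cohort(seed=9, n=600, betas={"C001": 1.0})
        sub = cohort.abundance.loc[["C001", "C003"]]  # C003 has no survival effect
        fit = mc.fit_cox(sub, cohort.survival)
        ci = fit.conf_int()
        assert ci.loc["C003", "lower"] <= 0 <= ci.loc["C003", "upper"]

    def test_duplicating_every_sample_leaves_beta_unchanged(self):
        cohort = _cohort(n=150)
        sub = cohort.abundance.loc[["C001", "C002"]]
        fit1 = mc.fit_cox(sub, cohort.survival)
        sub2 = pd.concat([sub, sub.add_suffix("_dup")], axis=1)
        surv2 = pd.concat([cohort.survival,
                           cohort.survival.set_axis(cohort.survival.index + "_dup")])
        fit2 = mc.fit_cox(sub2, surv2)
        np.testing.assert_allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-5)

    def test_zero_variance_cell_dropped_with_warning(self):
        cohort = _cohort(n=150)
        sub = cohort.abundance.loc[["C001", "C002"]].copy()
        sub.loc["FLAT"] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            fit = mc.fit_cox(sub, cohort.survival)
        assert "FLAT" not in fit.params.index

    def test_collinear_duplicate_column_dropped(self):
        cohort = _cohort(n=150)
        sub = cohort.abundance.loc[["C001", "C002"]].copy()
        sub.loc["C001_copy"] = sub.loc["C001"] * 2.0
        with pytest.warns(UserWarning, match="collinear"):
            fit = mc.fit_cox(sub, cohort.survival)
        assert "C001_copy" not in fit.params.index


class TestRiskScores:
    def test_exact_linear_combination(self, rng):
        beta = pd.Series([1.0, -1.0], index=["a", "b"])
        ab = pd.DataFrame([[2.0], [3.0]], index=["a", "b"], columns=["S1"])
        assert mc.risk_scores(beta, ab)["S1"] == -1.0

    def test_zero_beta_gives_zero_scores(self, rng):
        beta = pd.Series([0.0, 0.0], index=["a", "b"])
        ab = pd.DataFrame(rng.standard_normal((2, 6)), index=["a", "b"])
        assert (mc.risk_scores(beta, ab) == 0).all()

    def test_linear_in_abundance(self, rng):
        beta = pd.Series(rng.standard_normal(3), index=["a", "b", "c"])
        ab = pd.DataFrame(rng.standard_normal((3, 5)), index=["a", "b", "c"])
        np.testing.assert_allclose(mc.risk_scores(beta, 2.5 * ab),
                                   2.5 * mc.risk_scores(beta, ab), atol=1e-12)

    def test_cell_mismatch_rejected(self):
        beta = pd.Series([1.0], index=["a"])
        ab = pd.DataFrame([[1.0]], index=["other"])
        with pytest.raises(ValidationError):
            mc.risk_scores(beta, ab)


class TestMedianSplit:
    def test_even_split(self):
        groups = mc.median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert list(groups) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        groups = mc.median_split(pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd")))
        assert list(groups) == ["low", "low", "low", "high"]

    def test_translation_invariance(self, rng):
        scores = pd.Series(rng.standard_normal(21))
        a = mc.median_split(scores)
        b = mc.median_split(scores + 100.0)
        assert (a == b).all()

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            mc.median_split(pd.Series([2.0] * 8))


def logrank_hand_oracle(time, event, group):
    """At-risk-table computation of the two-group log-rank statistic."""
    df = pd.DataFrame({"time": time, "event": event, "group": group})
    labels = sorted(df["group"].unique())
    o1 = e1 = v = 0.0
    for t in sorted(df.loc[df["event"] == 1, "time"].unique()):
        at_risk = df[df["time"] >= t]
        n = len(at_risk)
        n1 = (at_risk["group"] == labels[0]).sum()
        dead = df[(df["time"] == t) & (df["event"] == 1)]
        d = len(dead)
        d1 = (dead["group"] == labels[0]).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


class TestLogRank:
    def test_identical_groups_give_null_statistic(self):
        surv = pd.DataFrame({"time": [1, 2, 3, 1, 2, 3], "event": [1, 1, 0, 1, 1, 0]},
                            index=list("abcdef")).astype({"time": float})
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=surv.index)
        chi2, p = mc.log_rank(groups, surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_patient_worked_example_matches_hand_table(self):
        time = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        event = [1, 1, 0, 1, 0, 1]
        group = ["A", "A", "A", "B", "B", "B"]
        surv = pd.DataFrame({"time": time, "event": event},
                            index=[f"p{i}" for i in range(6)])
        groups = pd.Series(group, index=surv.index)
        chi2, _ = mc.log_rank(groups, surv)
        assert chi2 == pytest.approx(logrank_hand_oracle(time, event, group), rel=1e-9)

    def test_symmetric_under_label_swap(self):
        cohort = _cohort(n=100)
        scores = mc.risk_scores(pd.Series([1.0], index=["C001"]),
                                cohort.abundance.loc[["C001"]])
        groups = mc.median_split(scores)
        chi2_a, p_a = mc.log_rank(groups, cohort.survival)
        swapped = groups.map({"high": "low", "low": "high"})
        chi2_b, p_b = mc.log_rank(swapped, cohort.survival)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-9)
        assert p_a == pytest.approx(p_b, rel=1e-9)

    def test_single_group_rejected(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            mc.log_rank(pd.Series(["high", "high"], index=["a", "b"]), surv)


class TestKmCurve:
    def test_shape_properties(self):
        cohort = _cohort(n=80)
        curve = mc.km_curve(cohort.survival["time"], cohort.survival["event"])
        surv = curve["survival"].to_numpy()
        assert (np.diff(surv) <= 1e-12).all()  # nonincreasing
        assert surv[0] == pytest.approx(1.0)  # 1 before the first event


class TestCellRiskModel:
    def test_results_carry_signature_components(self, planted_cohort):
        res = mc.MutationImmuneModel(
            planted_cohort.abundance, planted_cohort.mutations, planted_cohort.survival
        ).fit(n_perm=300, seed=3)
        gene = res.summary()["gene"].iloc[0]
        risk = res.risk_model(gene).fit()
        assert set(risk.params.index) <= set(planted_cohort.abundance.index)
        assert set(risk.groups.unique()) == {"high", "low"}
        assert abs(risk.groups.value_counts()["high"]
                   - risk.groups.value_counts()["low"]) <= 1
        assert 0 <= risk.logrank_p <= 1
        summary = risk.summary()
        assert {"beta", "se", "hazard_ratio", "ci_lower", "ci_upper", "p"} <= set(summary.columns)
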