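"""Log-NTCP ANOVA, scenario factors, rank correlation and normality tests."""

import numpy as np
import pandas as pd
import pytest

from scalpdose.stats import (
    cohort_summary,
    ks_normality,
    log_ntcp_anova,
    scenario_factor,
    spearman_rank,
)


def balanced_table(rng, n_patients=7, scenario_effects=(0.0, 1.0, 1.7),
                   patient_sd=2.0, resid_sd=0.3, mu=-7.0):
    rows = []
    for ip in range(n_patients):
        pe = rng.normal(0, patient_sd)
        for s, se in enumerate(scenario_effects, start=1):
            rows.append({
                "patient": f"P{ip}", "scenario": s,
                "ntcp_fraction": float(np.exp(mu + pe + se
                                              + rng.normal(0, resid_sd))),
            })
    return pd.DataFrame(rows)


class TestLogNtcpAnova:
    def test_identical_scenarios_have_zero_effects(self):
        rng = np.random.default_rng(0)
        t = balanced_table(rng, scenario_effects=(0, 0, 0), resid_sd=0.0)
        fit = log_ntcp_anova(t)
        assert all(abs(e) < 1e-12 for e in fit.scenario_effects.values())

    def test_balanced_effects_are_cell_means_minus_grand_mean(self):
        rng = np.random.default_rng(1)
        t = balanced_table(rng)
        fit = log_ntcp_anova(t)
        ln = np.log(t.pivot_table(index="patient", columns="scenario",
                                  values="ntcp_fraction"))
        expected = ln.mean(axis=0) - ln.to_numpy().mean()
        for s, e in fit.scenario_effects.items():
            assert e == pytest.approx(expected[s])

    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(2)
        t = balanced_table(rng)
        t["log_ntcp"] = np.log(t["ntcp_fraction"])
        fit = log_ntcp_anova(t)
        ols = smf.ols("log_ntcp ~ C(patient) + C(scenario)", data=t).fit()
        import statsmodels.api as sm

        table = sm.stats.anova_lm(ols, typ=2)
        assert fit.anova_table.loc["patient", "F"] == pytest.approx(
            table.loc["C(patient)", "F"]
        )
        assert fit.anova_table.loc["scenario", "p_value"] == pytest.approx(
            table.loc["C(scenario)", "PR(>F)"]
        )
        # contrast: scenario 2 vs 1 equals the OLS coefficient
        est = scenario_factor(fit, 2, 1)
        assert np.log(est.factor) == pytest.approx(
            ols.params["C(scenario)[T.2]"]
        )

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(3)
        t = balanced_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            log_ntcp_anova(t)

    def test_zero_ntcp_floored_with_warning_or_rejected(self):
        rng = np.random.default_rng(4)
        t = balanced_table(rng)
        t.loc[0, "ntcp_fraction"] = 0.0
        with pytest.warns(UserWarning, match="floor"):
            log_ntcp_anova(t)
        with pytest.raises(ValueError, match="floor"):
            log_ntcp_anova(t, floor=None)


class TestScenarioFactor:
    def test_equals_geometric_mean_of_patient_ratios(self):
        rng = np.random.default_rng(5)
        t = balanced_table(rng)
        fit = log_ntcp_anova(t)
        by = t.pivot_table(index="patient", columns="scenario",
                           values="ntcp_fraction")
        gm = float(np.exp(np.mean(np.log(by[3] / by[1]))))
        assert scenario_factor(fit, 3, 1).factor == pytest.approx(gm)

    def test_self_contrast_is_degenerate_one(self):
        rng = np.random.default_rng(6)
        fit = log_ntcp_anova(balanced_table(rng))
        est = scenario_factor(fit, 2, 2)
        assert est.factor == 1.0
        assert est.ci95[0] <= 1.0 <= est.ci95[1]

    def test_ci_is_ordered_and_positive(self):
        rng = np.random.default_rng(7)
        fit = log_ntcp_anova(balanced_table(rng))
        est = scenario_factor(fit, 3, 1)
        assert 0 < est.ci95[0] <= est.factor <= est.ci95[1]

    def test_ci_coverage_under_known_effects(self):
        """95% CI covers the true factor at close to nominal rate."""
        rng = np.random.default_rng(8)
        true_log = 1.2
        covered = 0
        n_sim = 400
        for _ in range(n_sim):
            t = balanced_table(rng, scenario_effects=(0.0, 0.5, true_log),
                               resid_sd=0.4)
            fit = log_ntcp_anova(t)
            lo, hi = scenario_factor(fit, 3, 1).ci95
            covered += lo <= np.exp(true_log) <= hi
        assert 0.93 * n_sim <= covered <= 0.97 * n_sim


class TestSpearman:
    def test_reversed_ordering_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman_rank(x, -x) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.random(20)
        y = rng.random(20)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rank(x, y) == pytest.approx(oracle)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(10)
        x = rng.random(30)
        y = rng.random(30)
        base = spearman_rank(x, y)
        assert spearman_rank(np.exp(x), y) == pytest.approx(base)
        assert spearman_rank(x, y**3 + 5) == pytest.approx(base)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rank([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKsNormality:
    def test_normal_sample_lands_in_upper_band(self):
        rng = np.random.default_rng(11)
        _, band = ks_normality(rng.normal(0, 1, 500))
        assert band == ">0.15"

    def test_skewed_ntcp_like_sample_rejected(self):
        rng = np.random.default_rng(12)
        _, band = ks_normality(np.exp(rng.normal(0, 2.5, 500)))
        assert band == "<0.01"

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            ks_normality([1.0, 2.0, 3.0])


class TestCohortSummary:
    def test_order_statistics_in_percent(self):
        t = pd.DataFrame({
            "patient": list("ABC"), "scenario": [1, 1, 1],
            "ntcp_fraction": [0.001, 0.01, 0.0001],
        })
        s = cohort_summary(t, 1)
        assert s == {"min_pct": 0.01, "median_pct": 0.1, "max_pct": 1.0}

    def test_single_row_degenerate(self):
        t = pd.DataFrame({"patient": ["A"], "scenario": [2],
                          "ntcp_fraction": [0.005]})
        s = cohort_summary(t, 2)
        assert s["min_pct"] == s["median_pct"] == s["max_pct"] == 0.5
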