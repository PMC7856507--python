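"""Statistical layer: log-NTCP ANOVA, scenario factors, rank correlation.

Skin NTCPs span orders of magnitude across patients and are strongly
right-skewed, so the analysis of variance operates on the natural
logarithm of the NTCP (the log values are compatible with normality,
the raw values are not). The model is the two-way additive fixed-effects
fit

    ln NTCP_{ps} = mu + patient_p + scenario_s + eps_{ps}

on a complete balanced patient x scenario design. The multiplicative
effect of scenario a relative to scenario b is exp(effect_a - effect_b),
which on a balanced design equals the geometric mean over patients of
the per-patient NTCP ratios; its confidence interval uses the residual
mean square of the fit with (P-1)(S-1) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "LogNtcpFit",
    "FactorEstimate",
    "log_ntcp_anova",
    "scenario_factor",
    "spearman_rank",
    "ks_normality",
    "cohort_summary",
    "NTCP_FLOOR",
]

#: Probabilities below this are floored before taking logarithms (with a
#: warning); protects against underflow in synthetic cohorts with very
#: deep targets.
NTCP_FLOOR = 1e-12


@dataclass(frozen=True)
class LogNtcpFit:
    """Two-way additive fixed-effects fit of ln NTCP."""

    grand_mean: float
    patient_effects: dict[str, float]
    scenario_effects: dict[int, float]
    residual_ms: float
    df_residual: int
    n_patients: int
    n_scenarios: int
    anova_table: pd.DataFrame

    @property
    def patient_p_value(self) -> float:
        return float(self.anova_table.loc["patient", "p_value"])

    @property
    def scenario_p_value(self) -> float:
        return float(self.anova_table.loc["scenario", "p_value"])


@dataclass(frozen=True)
class FactorEstimate:
    """Multiplicative NTCP effect of one scenario relative to another."""

    scenario_pair: tuple[int, int]
    factor: float
    ci95: tuple[float, float]
    p_value: float
    se_log: float


def _pivot_log_ntcp(table: pd.DataFrame, scenarios, floor: float | None):
    required = {"patient", "scenario", "ntcp_fraction"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"result table lacks columns {sorted(missing)}")
    sub = table[table["scenario"].isin(scenarios)]
    pivot = sub.pivot_table(index="patient", columns="scenario",
                            values="ntcp_fraction", aggfunc="first")
    if pivot.isna().any().any() or set(pivot.columns) != set(scenarios):
        raise ValueError(
            "incomplete design: every patient x scenario cell is required"
        )
    values = pivot.to_numpy(dtype=float)
    if np.any(values <= 0):
        if floor is None:
            raise ValueError(
                "NTCP values must be positive to take logarithms; pass a "
                "positive floor to clip underflowing probabilities"
            )
        warnings.warn(
            f"flooring {int((values < floor).sum())} NTCP value(s) at {floor}",
            stacklevel=3,
        )
    if floor is not None:
        values = np.maximum(values, floor)
    return pivot.index.tolist(), list(pivot.columns), np.log(values)


def log_ntcp_anova(
    table: pd.DataFrame,
    scenarios=None,
    floor: float | None = NTCP_FLOOR,
) -> LogNtcpFit:
    """Two-way ANOVA of ln NTCP with patient and scenario as factors.

    Requires a complete balanced design over the chosen scenarios (all
    by default). On a balanced design the least-squares effects are the
    row/column means of ln NTCP minus the grand mean; F-tests for both
    factors are reported against the residual (interaction) mean square.
    """
    if scenarios is None:
        scenarios = sorted(table["scenario"].unique())
    patients, scenario_ids, ln = _pivot_log_ntcp(table, scenarios, floor)
    n_p, n_s = ln.shape
    if n_p < 2 or n_s < 2:
        raise ValueError("need at least two patients and two scenarios")
    grand = ln.mean()
    p_eff = ln.mean(axis=1) - grand
    s_eff = ln.mean(axis=0) - grand
    resid = ln - grand - p_eff[:, None] - s_eff[None, :]
    ss_p = n_s * float(np.sum(p_eff**2))
    ss_s = n_p * float(np.sum(s_eff**2))
    ss_r = float(np.sum(resid**2))
    df_p, df_s = n_p - 1, n_s - 1
    df_r = df_p * df_s
    ms_r = ss_r / df_r
    rows = {}
    for name, ss, df in (("patient", ss_p, df_p), ("scenario", ss_s, df_s)):
        ms = ss / df
        f = ms / ms_r if ms_r > 0 else np.inf
        rows[name] = {"sum_sq": ss, "df": df, "F": f,
                      "p_value": float(sps.f.sf(f, df, df_r))}
    rows["residual"] = {"sum_sq": ss_r, "df": df_r, "F": np.nan, "p_value": np.nan}
    return LogNtcpFit(
        grand_mean=float(grand),
        patient_effects=dict(zip(patients, p_eff)),
        scenario_effects={int(s): float(e) for s, e in zip(scenario_ids, s_eff)},
        residual_ms=ms_r,
        df_residual=df_r,
        n_patients=n_p,
        n_scenarios=n_s,
        anova_table=pd.DataFrame(rows).T,
    )


def scenario_factor(fit: LogNtcpFit, a: int, b: int = 1) -> FactorEstimate:
    """Multiplicative NTCP effect of scenario ``a`` relative to ``b``.

    factor = exp(effect_a - effect_b); the 95% CI is
    exp(contrast +- t_{0.975,df} * SE) with SE = sqrt(2 * MS_resid / P),
    and the p-value is the two-sided t-test of a zero contrast.
    """
    for s in (a, b):
        if s not in fit.scenario_effects:
            raise ValueError(f"scenario {s} not in the fitted scenario set")
    contrast = fit.scenario_effects[a] - fit.scenario_effects[b]
    se = float(np.sqrt(2.0 * fit.residual_ms / fit.n_patients))
    if se > 0:
        t_crit = float(sps.t.ppf(0.975, fit.df_residual))
        lo, hi = contrast - t_crit * se, contrast + t_crit * se
        p = float(2 * sps.t.sf(abs(contrast) / se, fit.df_residual))
    else:   # degenerate: no residual variance
        lo = hi = contrast
        p = 0.0 if contrast != 0 else 1.0
    return FactorEstimate(
        scenario_pair=(a, b),
        factor=float(np.exp(contrast)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p_value=p,
        se_log=se,
    )


def spearman_rank(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least three observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation is undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def ks_normality(values, n_min: int = 5) -> tuple[float, str]:
    """Lilliefors-corrected Kolmogorov-Smirnov test for normality.

    One-sample KS against a normal with mean and SD estimated from the
    data. Returns the statistic and a p-value band ('<0.01',
    '0.01-0.15' or '>0.15'), the granularity at which such tests are
    customarily reported.
    """
    values = np.asarray(values, dtype=float)
    if values.size < n_min:
        raise ValueError(f"need at least {n_min} observations")
    stat, p = lilliefors(values, dist="norm")
    if p < 0.01:
        band = "<0.01"
    elif p <= 0.15:
        band = "0.01-0.15"
    else:
        band = ">0.15"
    return float(stat), band


def cohort_summary(table: pd.DataFrame, scenario: int) -> dict[str, float]:
    """Min, median and max NTCP (in percent) for one scenario."""
    sub = table.loc[table["scenario"] == scenario, "ntcp_fraction"]
    if sub.empty:
        raise ValueError(f"no rows for scenario {scenario}")
    pct = sub.to_numpy(dtype=float) * 100.0
    return {
        "min_pct": float(pct.min()),
        "median_pct": float(np.median(pct)),
        "max_pct": float(pct.max()),
    }
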