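"""Cohort survival statistics for the instability-score analysis.

Covers the clinical layer: covariate association tests between
instability groups, Kaplan-Meier curves with log-rank tests, Cox
proportional-hazards models (univariable and multivariable with backward
elimination), Harrell's concordance index, and the Contal-O'Quigley
maximal log-rank cutpoint that dichotomizes a continuous marker.

Model fitting is delegated to lifelines (Efron tie handling); the
cutpoint scan and its standardization are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index

from ._stats import RiskSets


def association_tests(
    cohort: pd.DataFrame,
    group_col: str,
    covariates: list[str],
) -> pd.DataFrame:
    """Per-covariate association with a binary grouping.

    Numeric covariates use a pooled-variance two-sample t-test;
    categorical ones a Pearson chi-square without continuity correction,
    falling back to Fisher's exact test when the table is 2x2 and any
    expected cell count is below 5.  Missing values are dropped per
    covariate.
    """
    groups = cohort[group_col]
    levels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(levels) != 2:
        raise ValueError("grouping must have exactly two levels")
    rows = []
    for cov in covariates:
        sub = cohort[[cov, group_col]].dropna()
        if sub[group_col].nunique() < 2:
            rows.append({"covariate": cov, "test": "none", "p": np.nan})
            continue
        if pd.api.types.is_numeric_dtype(sub[cov]) and sub[cov].nunique() > 6:
            a = sub.loc[sub[group_col] == levels[0], cov]
            b = sub.loc[sub[group_col] == levels[1], cov]
            p = stats.ttest_ind(a, b, equal_var=True).pvalue
            rows.append({"covariate": cov, "test": "t", "p": float(p)})
        else:
            table = pd.crosstab(sub[cov], sub[group_col]).to_numpy()
            expected = stats.contingency.expected_freq(table)
            if table.shape == (2, 2) and (expected < 5).any():
                p = stats.fisher_exact(table).pvalue
                rows.append({"covariate": cov, "test": "fisher", "p": float(p)})
            else:
                p = stats.chi2_contingency(table, correction=False)[1]
                rows.append({"covariate": cov, "test": "chi2", "p": float(p)})
    return pd.DataFrame(rows)


def km_logrank(times, events, groups) -> dict:
    """Kaplan-Meier curves per group plus a two-group log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    if events.sum() == 0:
        raise ValueError("no events in the cohort")
    fitters = {}
    for g in pd.unique(groups):
        kmf = KaplanMeierFitter(label=str(g))
        sel = groups == g
        kmf.fit(times[sel], events[sel])
        fitters[g] = kmf
    out = {"fitters": fitters, "p": None, "statistic": None}
    levels = pd.unique(groups)
    if len(levels) == 2:
        sel = groups == levels[0]
        res = logrank_test(times[sel], times[~sel], events[sel], events[~sel])
        out["p"] = float(res.p_value)
        out["statistic"] = float(res.test_statistic)
    return out


def cox_fit(
    cohort: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    backward: bool = False,
    alpha_stay: float = 0.05,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) with optional backward step.

    Backward elimination repeatedly drops the covariate with the largest
    Wald p >= ``alpha_stay`` and refits.  Returns a table with
    ``covariate, hr, ci_low, ci_high, p`` on the retained covariates.
    """
    n_events = int(cohort[event_col].sum())
    if n_events < 10 * len(covariates):
        warnings.warn(
            f"{n_events} events for {len(covariates)} covariates; "
            "estimates may be unstable"
        )
    kept = list(covariates)
    while True:
        cph = CoxPHFitter()
        try:
            cph.fit(cohort[[duration_col, event_col] + kept],
                    duration_col=duration_col, event_col=event_col)
        except Exception as exc:  # noqa: BLE001 - surface the covariate set
            raise RuntimeError(f"Cox fit failed for covariates {kept}: {exc}") from exc
        if not backward or len(kept) == 1:
            break
        pvals = cph.summary["p"]
        worst = pvals.idxmax()
        if pvals[worst] < alpha_stay:
            break
        kept.remove(worst)
    s = cph.summary
    return pd.DataFrame(
        {
            "covariate": s.index,
            "hr": np.exp(s["coef"]).to_numpy(),
            "ci_low": np.exp(s["coef lower 95%"]).to_numpy(),
            "ci_high": np.exp(s["coef upper 95%"]).to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)


@dataclass
class CutpointResult:
    cutpoint: float
    max_statistic: float
    candidates_evaluated: int


def contal_oquigley(
    marker, times, events, trim: float = 0.10
) -> CutpointResult:
    """Optimal dichotomization of a continuous marker by maximal log-rank.

    Every observed marker value inside the [trim, 1-trim] quantile window
    is a candidate cut c; the log-rank score statistic S_c for the split
    ``marker > c`` is standardized by sqrt(s^2 (D - 1)), where D is the
    number of distinct event times and s^2 the Contal-O'Quigley variance
    built from the scores a_i = 1 - sum_{j<=i} 1/(D - j + 1).  The
    cutpoint is the candidate maximizing |S_c| (ties -> smaller cut).
    """
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if len(marker) < 20:
        raise ValueError("need at least 20 subjects")
    if events.sum() < 10:
        raise ValueError("need at least 10 events")
    lo, hi = np.quantile(marker, [trim, 1 - trim])
    candidates = np.unique(marker[(marker >= lo) & (marker <= hi)])
    candidates = candidates[candidates < marker.max()]  # both sides non-empty
    if len(candidates) == 0:
        raise ValueError("no interior candidate cutpoints")
    rs = RiskSets(times, events)
    D = rs.n_event_times
    if D < 2:
        raise ValueError("need at least 2 distinct event times")
    a = 1.0 - np.cumsum(1.0 / (D - np.arange(1, D + 1) + 1))
    s2 = (a**2).sum() / (D - 1)
    scale = np.sqrt(s2 * (D - 1))
    best_q, best_c = -np.inf, candidates[0]
    for c in candidates:
        q = abs(rs.score(marker > c)) / scale
        if q > best_q + 1e-12:
            best_q, best_c = q, c
    return CutpointResult(
        cutpoint=float(best_c),
        max_statistic=float(best_q),
        candidates_evaluated=len(candidates),
    )


def c_index(risk, times, events) -> float:
    """Harrell's concordance index for a risk score (higher = worse)."""
    return float(concordance_index(times, -np.asarray(risk, dtype=float), events))
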