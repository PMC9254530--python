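"""Cohort-level statistics for the heterogeneity-index survival study.

Implements the analysis pipeline applied to a per-patient table of
clinical covariates, extracted imaging features and event-free-survival
outcome: baseline descriptives, subgroup comparison of the AUC-CSH
indices, univariate and backward-stepwise multivariate Cox regression,
ROC/Youden dichotomisation of AUC-CSH_total, and Kaplan-Meier / log-rank
analysis including the combined AUC-CSH x bone-marrow-involvement
three-group stratification.

Statistical conventions:

* Cox models use Breslow tie handling (lifelines' default);
* backward elimination drops the largest Wald p above a removal
  threshold of 0.10 unless configured otherwise;
* two-group comparisons use Welch's t-test when both groups pass a
  Shapiro-Wilk normality screen at alpha = 0.05, and the Mann-Whitney
  rank-sum test otherwise;
* no multiple-testing correction is applied — all p-values are raw;
* hazard ratios for AUC-CSH are per unit of the index on its natural
  (0, 1] scale, which is why their confidence bounds can sit very close
  to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import ConvergenceWarning
from scipy import stats

__all__ = [
    "CoxResult",
    "StratificationRule",
    "KMResult",
    "subgroup_compare",
    "univariate_cox",
    "multivariate_cox_backward",
    "roc_optimal_cutoff",
    "km_logrank",
    "baseline_table",
]

DURATION_COL = "followup_months"
EVENT_COL = "event"

#: Derived binary groupings accepted by :func:`subgroup_compare` and
#: :func:`km_logrank` in addition to any existing 0/1 column.
_DERIVED_GROUPS = {
    # high-risk COG vs low + intermediate
    "cog_risk": lambda t: (t["cog_risk"] >= 2).astype(int),
    # MYCN acquired/amplified vs normal (already binary in simulated data)
    "mycn": lambda t: (t["mycn"] != 0).astype(int),
}


def _binary_groups(table: pd.DataFrame, grouping: str) -> pd.Series:
    values = table[grouping]
    if values.nunique() > 2:
        if grouping in _DERIVED_GROUPS:
            return _DERIVED_GROUPS[grouping](table)
        raise ValueError(f"grouping column {grouping!r} is not binary")
    if values.nunique() == 2:
        return (values != values.min()).astype(int)
    return values.astype(int)


def subgroup_compare(table: pd.DataFrame, grouping: str, feature: str) -> dict:
    """Compare a feature between two patient subgroups.

    ``grouping`` is a binary column (``bmi``, ``event``, ``mycn``) or
    ``"cog_risk"``, which is binarised high vs low/intermediate. Both
    groups need >= 2 members. Returns group descriptives (n, mean, sd),
    the test used (Welch t if both groups pass Shapiro-Wilk at 0.05,
    Mann-Whitney otherwise), the statistic and the two-tailed p.
    Identical constant values in both groups are reported as a
    degenerate comparison with p = 1.
    """
    groups = _binary_groups(table, grouping)
    x0 = table.loc[groups == 0, feature].to_numpy(dtype=float)
    x1 = table.loc[groups == 1, feature].to_numpy(dtype=float)
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError(f"grouping {grouping!r}: each group needs >= 2 members")

    out = {
        "grouping": grouping,
        "feature": feature,
        "n0": len(x0), "n1": len(x1),
        "mean0": float(x0.mean()), "sd0": float(x0.std(ddof=1)),
        "mean1": float(x1.mean()), "sd1": float(x1.std(ddof=1)),
    }
    if np.ptp(np.concatenate([x0, x1])) == 0:
        out.update(test="degenerate", statistic=np.nan, p=1.0)
        return out

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0 or len(x) < 3:
            return False
        return stats.shapiro(x).pvalue > 0.05

    if _normal(x0) and _normal(x1):
        res = stats.ttest_ind(x0, x1, equal_var=False)
        out.update(test="welch_t", statistic=float(res.statistic), p=float(res.pvalue))
    else:
        res = stats.mannwhitneyu(x0, x1, alternative="two-sided")
        out.update(test="mann_whitney", statistic=float(res.statistic), p=float(res.pvalue))
    return out


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratios from one Cox proportional-hazards fit."""

    stage: str                       # "univariate" or "multivariate"
    table: pd.DataFrame              # variable, hr, ci_low, ci_high, p
    retained: tuple[str, ...]        # variables in the final model
    diagnostics: tuple[str, ...] = ()
    elimination_path: tuple[tuple[str, float], ...] = ()

    def hr(self, variable: str) -> float:
        return float(self.table.set_index("variable").loc[variable, "hr"])

    def p(self, variable: str) -> float:
        return float(self.table.set_index("variable").loc[variable, "p"])


def _fit_cox(table: pd.DataFrame, variables: list[str],
             stage: str) -> CoxResult:
    data = table[[*variables, DURATION_COL, EVENT_COL]].dropna()
    if data[EVENT_COL].sum() < 1:
        raise ValueError("Cox fit needs at least one event")
    constant = [v for v in variables if data[v].nunique() < 2]
    if constant:
        raise ValueError(f"constant covariates cannot be fitted: {constant}")

    diagnostics: list[str] = []
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(data, duration_col=DURATION_COL, event_col=EVENT_COL)
        except ConvergenceError as exc:
            raise ValueError(
                f"Cox model for {variables} failed to converge "
                f"(possible complete separation): {exc}"
            ) from exc
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            diagnostics.append(str(w.message))

    summary = cph.summary
    rows = [{
        "variable": v,
        "hr": float(summary.loc[v, "exp(coef)"]),
        "ci_low": float(summary.loc[v, "exp(coef) lower 95%"]),
        "ci_high": float(summary.loc[v, "exp(coef) upper 95%"]),
        "p": float(summary.loc[v, "p"]),
    } for v in variables]
    return CoxResult(stage=stage, table=pd.DataFrame(rows),
                     retained=tuple(variables),
                     diagnostics=tuple(diagnostics))


def univariate_cox(table: pd.DataFrame, variable: str) -> CoxResult:
    """Single-covariate Cox partial-likelihood fit (Breslow ties)."""
    return _fit_cox(table, [variable], stage="univariate")


def multivariate_cox_backward(table: pd.DataFrame,
                              candidates: list[str],
                              removal_threshold: float = 0.10) -> CoxResult:
    """Backward-stepwise multivariate Cox regression on Wald p-values.

    Starting from all candidates, iteratively refit and drop the
    variable with the largest Wald p above ``removal_threshold``; stop
    when every retained variable has p <= threshold. If the last
    remaining variable also exceeds the threshold the final model is
    empty. The elimination order and the p at removal are recorded.
    """
    if not candidates:
        raise ValueError("no candidate variables")
    current = list(candidates)
    path: list[tuple[str, float]] = []
    diagnostics: list[str] = []
    while current:
        result = _fit_cox(table, current, stage="multivariate")
        diagnostics.extend(result.diagnostics)
        pvals = result.table.set_index("variable")["p"]
        worst = pvals.idxmax()
        if pvals[worst] <= removal_threshold:
            return CoxResult(stage="multivariate", table=result.table,
                             retained=tuple(current),
                             diagnostics=tuple(dict.fromkeys(diagnostics)),
                             elimination_path=tuple(path))
        path.append((str(worst), float(pvals[worst])))
        current.remove(worst)
    return CoxResult(stage="multivariate",
                     table=pd.DataFrame(columns=["variable", "hr", "ci_low",
                                                 "ci_high", "p"]),
                     retained=(), diagnostics=tuple(dict.fromkeys(diagnostics)),
                     elimination_path=tuple(path))


def roc_optimal_cutoff(table: pd.DataFrame,
                       feature: str = "auccsh_total",
                       outcome: str = EVENT_COL) -> dict:
    """ROC-derived optimal dichotomisation cutoff by Youden's J.

    The orientation (whether events sit below or above the cutoff) is
    chosen from the data. J = sensitivity + specificity - 1 is evaluated
    at every observed feature value; among values attaining the maximal
    J the midpoint of the maximising region is returned (for perfectly
    separated groups this is the midpoint of the gap).
    """
    y = table[outcome].to_numpy(dtype=int)
    x = table[feature].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    events = x[y == 1]
    nonevents = x[y == 0]
    # events-below-cutoff orientation iff events tend to have lower values
    events_low = events.mean() <= nonevents.mean()

    candidates = np.unique(x)
    if events_low:
        sens = np.array([(events <= c).mean() for c in candidates])
        spec = np.array([(nonevents > c).mean() for c in candidates])
    else:
        sens = np.array([(events >= c).mean() for c in candidates])
        spec = np.array([(nonevents < c).mean() for c in candidates])
    j = sens + spec - 1.0
    best = j.max()
    attaining = np.flatnonzero(np.isclose(j, best, atol=1e-12))

    # first contiguous run of maximising candidates
    run_start = run_end = attaining[0]
    for idx in attaining[1:]:
        if idx == run_end + 1:
            run_end = idx
        else:
            break
    if events_low:
        # J(c) for the "x <= c" rule is constant on [v_i, v_{i+1}), so the
        # maximising region runs from the first attaining value up to the
        # next observed value (the gap midpoint for separated groups)
        lo = candidates[run_start]
        hi = candidates[run_end + 1] if run_end + 1 < candidates.size else candidates[run_end]
    else:
        # mirrored for the "x >= c" rule: constant on (v_{i-1}, v_i]
        lo = candidates[run_start - 1] if run_start > 0 else candidates[run_start]
        hi = candidates[run_end]
    return {
        "cutoff": float((lo + hi) / 2.0),
        "youden_j": float(best),
        "events_low": bool(events_low),
        "sensitivity": float(sens[attaining[0]]),
        "specificity": float(spec[attaining[0]]),
    }


@dataclass(frozen=True)
class StratificationRule:
    """Three-group risk stratification on AUC-CSH_total and BMI.

    Group I: index above the cutoff and no bone-marrow involvement;
    Group II: exactly one risk factor (low index or BMI);
    Group III: both risk factors. The groups partition the cohort.
    """

    auccsh_cutoff: float = 0.49
    feature: str = "auccsh_total"
    bmi_col: str = "bmi"

    def assign(self, table: pd.DataFrame) -> pd.Series:
        low_index = table[self.feature] <= self.auccsh_cutoff
        bmi = table[self.bmi_col].astype(bool)
        n_factors = low_index.astype(int) + bmi.astype(int)
        return pd.Series(np.array(["I", "II", "III"])[n_factors],
                         index=table.index, name="risk_group")


@dataclass(frozen=True)
class KMResult:
    """Kaplan-Meier curves per group with the k-group log-rank test."""

    curves: dict                       # group -> DataFrame(timeline, survival)
    group_sizes: dict
    statistic: float
    p: float
    degenerate: bool = False           # no events anywhere: p undefined


def km_logrank(table: pd.DataFrame,
               grouping: str | StratificationRule) -> KMResult:
    """Product-limit survival per group plus the log-rank test.

    ``grouping`` is a binary column name (or ``cog_risk``/``mycn``,
    binarised as in :func:`subgroup_compare`) or a
    :class:`StratificationRule`. When every observation in every group
    is censored the log-rank p is undefined and reported as NaN with
    ``degenerate=True``.
    """
    if isinstance(grouping, StratificationRule):
        groups = grouping.assign(table)
    else:
        groups = _binary_groups(table, grouping)
    if groups.nunique() < 2:
        raise ValueError("need at least two non-empty groups")

    curves: dict = {}
    sizes: dict = {}
    for label, sub in table.groupby(groups):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[DURATION_COL], sub[EVENT_COL], label=str(label))
        curves[label] = pd.DataFrame({
            "timeline": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
        sizes[label] = len(sub)

    if table[EVENT_COL].sum() == 0:
        return KMResult(curves=curves, group_sizes=sizes,
                        statistic=np.nan, p=np.nan, degenerate=True)
    res = multivariate_logrank_test(table[DURATION_COL], groups, table[EVENT_COL])
    return KMResult(curves=curves, group_sizes=sizes,
                    statistic=float(res.test_statistic), p=float(res.p_value))


_CONTINUOUS_BASELINE = ["age_years", "nse", "ldh", "phox2b",
                        "suv_max", "suv_mean", "suv_peak",
                        "mtv_total", "mtv_40", "tlg_total", "tlg_40",
                        "auccsh_total", "auccsh_40"]
_CATEGORICAL_BASELINE = ["sex_male", "site_abdomen", "inss_stage",
                         "cog_risk", "mycn", "del_1p", "del_11q", "bmi"]


def baseline_table(table: pd.DataFrame, group_col: str = EVENT_COL) -> pd.DataFrame:
    """Baseline-characteristics summary compared between outcome groups.

    Continuous variables: mean +/- sd (median and IQR when a
    Shapiro-Wilk screen rejects normality) with a Mann-Whitney rank-sum
    p. Categorical variables: n (%) per level with a chi-square p.
    Zero-variance continuous columns are flagged as degenerate.
    """
    if table.empty:
        raise ValueError("cohort is empty")
    g = table[group_col].to_numpy(dtype=int)
    rows = []
    for col in _CONTINUOUS_BASELINE:
        if col not in table.columns:
            continue
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"variable": col, "kind": "continuous",
                         "summary": f"{x.mean():.3g} +/- 0", "p": np.nan,
                         "degenerate": True})
            continue
        normal = len(x) >= 3 and stats.shapiro(x).pvalue > 0.05
        if normal:
            summary = f"{x.mean():.3f} +/- {x.std(ddof=1):.3f}"
        else:
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            summary = f"{med:.3f} ({q1:.3f}, {q3:.3f})"
        p = stats.mannwhitneyu(x[g == 0], x[g == 1],
                               alternative="two-sided").pvalue \
            if 0 < g.sum() < len(g) else np.nan
        rows.append({"variable": col, "kind": "continuous",
                     "summary": summary, "p": float(p), "degenerate": False})
    for col in _CATEGORICAL_BASELINE:
        if col not in table.columns:
            continue
        counts = table[col].value_counts().sort_index()
        summary = "; ".join(f"{level}: {n} ({100 * n / len(table):.1f}%)"
                            for level, n in counts.items())
        if 0 < g.sum() < len(g) and counts.size > 1:
            crosstab = pd.crosstab(table[col], g)
            p = float(stats.chi2_contingency(crosstab.to_numpy()).pvalue)
        else:
            p = np.nan
        rows.append({"variable": col, "kind": "categorical",
                     "summary": summary, "p": p, "degenerate": counts.size < 2})
    return pd.DataFrame(rows)
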