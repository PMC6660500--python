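"""Outcome statistics for arrhythmic-event analysis.

Endpoint adjudication for a composite arrhythmic endpoint (sustained
ventricular tachycardia, resuscitated cardiac arrest, appropriate ICD
therapy, sudden cardiac death), group comparisons, Kaplan-Meier incidence,
uni-/multivariable Cox proportional-hazards models with sequential
likelihood-ratio (change-chi-square) reporting and a residual-based
proportionality check, time-dependent ROC curves for censored data by the
Kaplan-Meier method (cumulative cases / dynamic controls), categorization of
the late H/M ratio with a combined-extremes ("bell-shape") comparison, and
two-way random-effects intraclass correlation with clinical agreement bands.

Cohorts are plain pandas DataFrames; see the column dictionary in the
package documentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "EVENT_TYPES",
    "AE_EVENT_TYPES",
    "HM_CATEGORY_CUTS",
    "adjudicate",
    "ComparisonResult",
    "compare_groups",
    "KMResult",
    "km_curve",
    "FitResult",
    "cox_fit",
    "TdRocResult",
    "td_roc",
    "categorize_late_hm",
    "BellshapeResult",
    "bellshape_test",
    "IccResult",
    "agreement_band",
    "icc",
]

#: Recognized per-patient event types; exactly one per record.
EVENT_TYPES = ("none", "sustained_VT", "appropriate_ICD_therapy", "resuscitated_arrest", "SCD")

#: Event types composing the primary arrhythmic endpoint.
AE_EVENT_TYPES = frozenset(
    ("sustained_VT", "appropriate_ICD_therapy", "resuscitated_arrest", "SCD")
)

#: Late H/M cut points: < low -> "low", [low, high] -> "intermediate",
#: > high -> "high" (the intermediate interval is closed on both sides).
HM_CATEGORY_CUTS = (1.2, 1.6)


# ---------------------------------------------------------------------------
# endpoint adjudication
# ---------------------------------------------------------------------------

def adjudicate(records: pd.DataFrame) -> pd.DataFrame:
    """Adjudicate the composite arrhythmic endpoint and the ICD-therapy
    secondary endpoint.

    Requires columns ``event_type``, ``event_month``, ``followup_months``.
    Returns a copy with ``ae_flag``/``ae_time`` (any of the four arrhythmic
    event types; time of event, else censoring at end of follow-up) and
    ``icd_therapy_flag``/``icd_therapy_time`` (appropriate ICD therapy only).

    Raises
    ------
    ValueError
        On an unknown event type or an event without an event month.
    """
    df = records.copy()
    bad = ~df["event_type"].isin(EVENT_TYPES)
    if bad.any():
        raise ValueError(f"unknown event types: {sorted(df.loc[bad, 'event_type'].unique())}")
    is_ae = df["event_type"].isin(AE_EVENT_TYPES)
    if (is_ae & df["event_month"].isna()).any():
        raise ValueError("records with an event must carry event_month")
    if (is_ae & (df["event_month"] > df["followup_months"] + 1e-9)).any():
        raise ValueError("event_month cannot exceed followup_months")

    df["ae_flag"] = is_ae
    df["ae_time"] = np.where(is_ae, df["event_month"], df["followup_months"])
    is_icd = df["event_type"] == "appropriate_ICD_therapy"
    df["icd_therapy_flag"] = is_icd
    df["icd_therapy_time"] = np.where(is_icd, df["event_month"], df["followup_months"])
    return df


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str  # "t-test" | "mann-whitney" | "chi2" | "fisher"
    statistic: float
    p_value: float
    n_per_group: tuple


def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == bool or isinstance(series.dtype, pd.CategoricalDtype):
        return True
    if series.dtype == object:
        return True
    return series.nunique(dropna=True) <= 2


def _chi2_or_fisher(table: np.ndarray) -> tuple:
    """Chi-square without continuity correction when all expected counts are
    >= 5, otherwise Fisher's exact test (2x2) or corrected chi-square."""
    chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    if (expected >= 5).all():
        return "chi2", float(chi2), float(p)
    if table.shape == (2, 2):
        odds, p = sps.fisher_exact(table)
        return "fisher", float(odds), float(p)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    return "chi2", float(chi2), float(p)


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_flag: str,
    normality_alpha: float = 0.05,
) -> ComparisonResult:
    """Two-group comparison choosing the test the data support.

    Categorical variables use the chi-square test (Fisher's exact for sparse
    2x2 tables); continuous variables use Student's t-test when Shapiro-Wilk
    accepts normality in both groups at ``normality_alpha``, otherwise the
    Mann-Whitney U test.
    """
    flag = cohort[group_flag].astype(bool)
    values = cohort[variable]
    g1, g0 = values[flag], values[~flag]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("need >= 2 observations in each group")
    if values.nunique(dropna=True) < 2:
        raise ValueError(f"variable {variable!r} is constant")

    if _is_categorical(values):
        table = pd.crosstab(values, flag).to_numpy()
        test, stat, p = _chi2_or_fisher(table)
        return ComparisonResult(variable, test, stat, p, (len(g1), len(g0)))

    g1 = g1.dropna().to_numpy(dtype=float)
    g0 = g0.dropna().to_numpy(dtype=float)
    normal = all(
        len(np.unique(g)) > 2 and sps.shapiro(g).pvalue > normality_alpha for g in (g1, g0)
    )
    if normal:
        stat, p = sps.ttest_ind(g1, g0, equal_var=True)
        return ComparisonResult(variable, "t-test", float(stat), float(p), (len(g1), len(g0)))
    stat, p = sps.mannwhitneyu(g1, g0, alternative="two-sided")
    return ComparisonResult(variable, "mann-whitney", float(stat), float(p), (len(g1), len(g0)))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMResult:
    timeline: np.ndarray
    survival: np.ndarray
    median: float
    n: int
    n_events: int

    def survival_at(self, t: Union[float, Sequence[float]]) -> np.ndarray:
        """Right-continuous step-function evaluation of S(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if out.size > 1 else out


def km_curve(times: Sequence[float], events: Sequence[bool]) -> KMResult:
    """Product-limit (Kaplan-Meier) estimate of the event-free curve."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return KMResult(
        timeline=timeline,
        survival=survival,
        median=float(kmf.median_survival_time_),
        n=len(times),
        n_events=int(events.sum()),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Cox model fit: per-covariate hazard ratios with CI and p, the model
    likelihood-ratio chi-square, per-covariate change-chi-square when fitted
    sequentially, and the proportional-hazards residual check."""

    summary: pd.DataFrame  # index: covariate; columns: hr, ci_lower, ci_upper, p[, change_chi2]
    model_chi2: float
    model_p: float
    log_likelihood: float
    n: int
    n_events: int
    ph_pvalues: pd.Series
    ph_ok: bool

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple:
        row = self.summary.loc[covariate]
        return (float(row["ci_lower"]), float(row["ci_upper"]))


def _fit_cph(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(
            "Cox model failed to converge (possible separation or collinear "
            f"covariates {list(df.columns)}): {err}"
        ) from err
    return cph


def cox_fit(
    cohort: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    sequential: bool = False,
    min_events: int = 10,
    ph_alpha: float = 0.05,
) -> FitResult:
    """Cox proportional-hazards regression via partial likelihood.

    When ``sequential`` is true, covariates are added one at a time in the
    given order and each one's change-chi-square — twice the gain in partial
    log-likelihood over the preceding model — is reported alongside its
    hazard ratio. Proportionality is checked with a scaled-residual trend
    test; ``ph_ok`` is false if any covariate violates it at ``ph_alpha``.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"unknown covariates: {missing}")
    data = cohort[[duration_col, event_col] + covariates].copy()
    data[event_col] = data[event_col].astype(bool)
    n_events = int(data[event_col].sum())
    if n_events < min_events:
        raise ValueError(f"only {n_events} events; need >= {min_events}")
    for c in covariates:
        if data[c].nunique(dropna=True) < 2:
            raise ValueError(f"covariate {c!r} is constant")

    cph = _fit_cph(data, duration_col, event_col)
    llr = cph.log_likelihood_ratio_test()
    model_chi2 = float(llr.test_statistic)
    model_p = float(llr.p_value)

    summ = cph.summary
    summary = pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    summary.index.name = "covariate"

    if sequential:
        change = {}
        ll_prev = None
        for k in range(1, len(covariates) + 1):
            sub = data[[duration_col, event_col] + covariates[:k]]
            cph_k = _fit_cph(sub, duration_col, event_col)
            ll_k = float(cph_k.log_likelihood_)
            if ll_prev is None:
                # chi2 of the first model vs the null model
                change[covariates[0]] = float(cph_k.log_likelihood_ratio_test().test_statistic)
            else:
                change[covariates[k - 1]] = 2.0 * (ll_k - ll_prev)
            ll_prev = ll_k
        summary["change_chi2"] = pd.Series(change)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ph = proportional_hazard_test(cph, data, time_transform="rank")
    ph_pvalues = ph.summary["p"]
    if isinstance(ph_pvalues.index, pd.MultiIndex):
        ph_pvalues = ph_pvalues.droplevel(-1)
    ph_pvalues = ph_pvalues.groupby(level=0).min()

    return FitResult(
        summary=summary,
        model_chi2=model_chi2,
        model_p=model_p,
        log_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=n_events,
        ph_pvalues=ph_pvalues,
        ph_ok=bool((ph_pvalues > ph_alpha).all()),
    )


# ---------------------------------------------------------------------------
# time-dependent ROC (Kaplan-Meier method)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TdRocResult:
    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _km_survival_at(times: np.ndarray, events: np.ndarray, t: float) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return float(kmf.survival_function_at_times(t).iloc[0])


def td_roc(
    times: Sequence[float],
    events: Sequence[bool],
    marker: Sequence[float],
    horizon: float,
) -> TdRocResult:
    """Time-dependent ROC at a follow-up horizon, Kaplan-Meier method.

    Cumulative-case / dynamic-control definition: a case has an event by the
    horizon, a control is event-free past it. Censored status probabilities
    are estimated with Kaplan-Meier curves within the marker strata, giving

        Se(c) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
        Sp(c) =      S(t | X <= c) P(X <= c) /      S(t)

    for each marker threshold ``c``. Without censoring this reduces exactly
    to the empirical ROC of the marker against event-by-horizon status. The
    AUC integrates the (FPR, TPR) path by the trapezoid rule.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    marker = np.asarray(marker, dtype=float)
    if not (len(times) == len(events) == len(marker)):
        raise ValueError("times, events and marker must have equal length")
    if not ((times <= horizon) & events).any():
        raise ValueError("no events before the horizon; td-ROC undefined")

    s_all = _km_survival_at(times, events, horizon)
    if s_all <= 0:
        raise ValueError("no controls at the horizon (S(t) = 0); td-ROC undefined")
    f_all = 1.0 - s_all

    thresholds = np.unique(marker)
    sens = [1.0]  # threshold -inf: everyone test-positive
    spec = [0.0]
    for c in thresholds:
        pos = marker > c
        p_pos = pos.mean()
        if pos.any():
            s_pos = _km_survival_at(times[pos], events[pos], horizon)
            se = (1.0 - s_pos) * p_pos / f_all
        else:
            se = 0.0
        neg = ~pos
        s_neg = _km_survival_at(times[neg], events[neg], horizon)
        sp = s_neg * (1.0 - p_pos) / s_all
        sens.append(float(np.clip(se, 0.0, 1.0)))
        spec.append(float(np.clip(sp, 0.0, 1.0)))

    sens_arr = np.asarray(sens)
    spec_arr = np.asarray(spec)
    fpr = 1.0 - spec_arr
    # lexicographic order keeps vertical runs of the ROC staircase intact so
    # the trapezoid rule integrates the exact path; sort keys are quantized
    # so float noise in the KM products cannot break ties
    order = np.lexsort((np.round(sens_arr, 10), np.round(fpr, 10)))
    auc = float(np.trapezoid(sens_arr[order], fpr[order]))
    return TdRocResult(
        horizon=float(horizon),
        thresholds=thresholds,
        sensitivity=sens_arr,
        specificity=spec_arr,
        auc=auc,
    )


# ---------------------------------------------------------------------------
# late H/M categories and combined-extremes comparison
# ---------------------------------------------------------------------------

def categorize_late_hm(
    value: Union[float, Sequence[float]], cuts: tuple = HM_CATEGORY_CUTS
) -> Union[str, np.ndarray]:
    """Assign late H/M ratio(s) to low / intermediate / high categories.

    ``< cuts[0]`` is low, ``> cuts[1]`` is high and the closed interval
    ``[cuts[0], cuts[1]]`` is intermediate, so the three bins partition the
    positive reals. Non-positive ratios raise.
    """
    low, high = cuts
    if not 0 < low < high:
        raise ValueError("cuts must satisfy 0 < low < high")
    arr = np.asarray(value, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("late H/M ratios must be positive and finite")
    out = np.where(arr < low, "low", np.where(arr > high, "high", "intermediate"))
    return str(out[0]) if scalar else out


@dataclass(frozen=True)
class BellshapeResult:
    table: pd.DataFrame  # 2x2: extremes/intermediate x endpoint no/yes
    category_counts: dict
    test: str
    statistic: float
    p_value: float


def bellshape_test(
    cohort: pd.DataFrame,
    endpoint_flag: str,
    hm_col: str = "late_hm",
    cuts: tuple = HM_CATEGORY_CUTS,
) -> BellshapeResult:
    """Combined-extremes comparison behind the bell-shaped risk pattern.

    Pools the low and high late-H/M categories and compares the pooled group
    against the intermediate category on the given endpoint flag with a 2x2
    chi-square (Fisher's exact when expected counts are sparse). A small p
    with a higher event rate in the intermediate bin indicates risk peaking
    at intermediate innervation values.
    """
    cats = categorize_late_hm(cohort[hm_col].to_numpy(), cuts=cuts)
    pooled = np.where(cats == "intermediate", "intermediate", "extremes")
    flag = cohort[endpoint_flag].astype(bool).to_numpy()
    table = pd.crosstab(
        pd.Series(pooled, name="hm_group"), pd.Series(flag, name=endpoint_flag)
    )
    if table.shape != (2, 2):
        raise ValueError("both pooled-extreme and intermediate groups must be non-empty")
    test, stat, p = _chi2_or_fisher(table.to_numpy())
    counts = {k: int((cats == k).sum()) for k in ("low", "intermediate", "high")}
    return BellshapeResult(table=table, category_counts=counts, test=test, statistic=stat, p_value=p)


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

#: Clinical agreement interpretation of ICC point estimates.
_AGREEMENT_BANDS = ((0.40, "poor"), (0.60, "fair"), (0.75, "good"), (np.inf, "excellent"))


def agreement_band(value: float) -> str:
    """Agreement label: < .40 poor, .40-.59 fair, .60-.74 good, >= .75 excellent."""
    for upper, label in _AGREEMENT_BANDS:
        if value < upper:
            return label
    return "excellent"


@dataclass(frozen=True)
class IccResult:
    value: float
    ci_lower: float
    ci_upper: float
    p_value: float
    band: str
    model: str = "ICC2"


def icc(score_table: Union[pd.DataFrame, np.ndarray]) -> IccResult:
    """Two-way random-effects, absolute-agreement, single-rater ICC(2,1).

    ``score_table`` is a complete wide table with one row per subject and one
    column per reader (no missing cells). The 95% CI is F-based; the point
    estimate is labelled with the clinical agreement band.

    Raises
    ------
    ValueError
        With fewer than 2 readers or 5 subjects, missing cells, or zero
        between-subject variance (ICC degenerate).
    """
    import pingouin as pg

    table = pd.DataFrame(score_table)
    n_subjects, n_readers = table.shape
    if n_readers < 2:
        raise ValueError("ICC needs >= 2 readers")
    if n_subjects < 5:
        raise ValueError("ICC needs >= 5 subjects")
    if table.isna().any().any():
        raise ValueError("ICC table must have no missing cells")
    subject_means = table.mean(axis=1)
    if float(np.var(subject_means.to_numpy())) == 0.0:
        raise ValueError("zero between-subject variance: ICC undefined")

    long = table.reset_index(names="subject").melt(
        id_vars="subject", var_name="reader", value_name="rating"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(
            data=long, targets="subject", raters="reader", ratings="rating"
        ).set_index("Type")
    # absolute-agreement single-rater ICC; label varies across pingouin versions
    key = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
    row = res.loc[key]
    value = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci_lower, ci_upper = (float(x) for x in row[ci_col])
    return IccResult(
        value=value,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        p_value=float(row["pval"]),
        band=agreement_band(value),
    )


# ---------------------------------------------------------------------------
# descriptive group-comparison table
# ---------------------------------------------------------------------------

def summarize_by_group(
    cohort: pd.DataFrame, variables: Sequence[str], group_flag: str
) -> pd.DataFrame:
    """Baseline-characteristics table: per-variable summaries in each group
    with the comparison p-value (test chosen by :func:`compare_groups`)."""
    flag = cohort[group_flag].astype(bool)
    rows = []
    for var in variables:
        values = cohort[var]
        if _is_categorical(values):
            v = values.astype(bool) if values.dtype != bool else values

            def fmt(sub):
                return f"{int(sub.sum())} ({100.0 * sub.mean():.1f}%)"

            with_s, without_s = fmt(v[flag]), fmt(v[~flag])
            all_s = fmt(v)
        else:

            def fmt(sub):
                return f"{sub.mean():.2f} ± {sub.std(ddof=1):.2f}"

            with_s, without_s = fmt(values[flag]), fmt(values[~flag])
            all_s = fmt(values)
        comp = compare_groups(cohort, var, group_flag)
        rows.append(
            {
                "variable": var,
                "all": all_s,
                "with_event": with_s,
                "without_event": without_s,
                "test": comp.test,
                "p_value": comp.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
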