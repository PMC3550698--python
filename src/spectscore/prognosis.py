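"""Outcome statistics for scored cohorts.

Implements the risk-stratification toolkit applied to summed SPECT
scores: 2x2 contingency tables and predictive values (with AND/OR
combination of two abnormality flags), Kaplan-Meier survival with the
log-rank test, univariable/multivariable Cox proportional-hazards fits
with global chi-square increments, ROC AUC with the DeLong test for
paired AUCs, and a baseline characteristics table (t-test / Pearson
chi-square group comparisons).

Event classes: ALL counts both soft events (late revascularization,
refractory-angina admission) and hard events (cardiac death, non-fatal
infarction, heart-failure admission); HARD counts hard events only. For
HARD analyses, soft events are by default censored at their event time
(``SoftEventPolicy.CENSOR_AT_SOFT``); the alternative policy drops those
patients entirely.

Kaplan-Meier, log-rank and Cox fits (Efron tie handling) are delegated
to lifelines; AUC to scikit-learn; the DeLong paired-AUC variance is
computed here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "EventClass",
    "SoftEventPolicy",
    "COHORT_COLUMNS",
    "validate_cohort",
    "survival_arrays",
    "ContingencyTable",
    "make_contingency",
    "PredictiveValues",
    "predictive_values",
    "combine_flags",
    "KMEstimate",
    "km_estimate",
    "logrank_test",
    "SurvivalFit",
    "cox_fit",
    "chi2_increment",
    "RocResult",
    "roc_auc",
    "delong_compare",
    "baseline_table",
]


class EventClass(str, enum.Enum):
    ALL = "ALL"
    HARD = "HARD"


class SoftEventPolicy(str, enum.Enum):
    CENSOR_AT_SOFT = "CENSOR_AT_SOFT"
    DROP_SOFT = "DROP_SOFT"


COHORT_COLUMNS = [
    "id", "age", "sex", "dm", "lvef", "htn", "dyslipidemia", "smoking",
    "uap", "ace", "bb", "ccb", "sss", "srs", "sds", "sbs",
    "followup_days", "event",
]

_EVENT_VALUES = {"none", "soft", "hard"}


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort CSV schema; returns the frame with ordered columns."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("cohort table is empty")
    bad_event = set(df["event"].unique()) - _EVENT_VALUES
    if bad_event:
        raise ValueError(f"invalid event values: {sorted(bad_event)}")
    if (df["followup_days"] < 0).any():
        raise ValueError("followup_days must be non-negative")
    if ((df["lvef"] <= 0) | (df["lvef"] > 100)).any():
        raise ValueError("lvef must lie in (0, 100]")
    return df[COHORT_COLUMNS]


def survival_arrays(
    df: pd.DataFrame,
    event_class: EventClass = EventClass.ALL,
    policy: SoftEventPolicy = SoftEventPolicy.CENSOR_AT_SOFT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(durations, event indicator, kept-row boolean mask) for an event class."""
    event_class = EventClass(event_class)
    keep = np.ones(len(df), dtype=bool)
    if event_class is EventClass.ALL:
        observed = (df["event"] != "none").to_numpy()
    else:
        observed = (df["event"] == "hard").to_numpy()
        if SoftEventPolicy(policy) is SoftEventPolicy.DROP_SOFT:
            keep = (df["event"] != "soft").to_numpy()
    durations = df["followup_days"].to_numpy(dtype=float)
    return durations[keep], observed[keep], keep


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: positive = abnormal score, outcome = cardiac event."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def make_contingency(
    df: pd.DataFrame,
    score_flag: np.ndarray,
    event_class: EventClass = EventClass.ALL,
) -> ContingencyTable:
    """Cross-tabulate an abnormality flag against event occurrence."""
    if len(df) == 0:
        raise ValueError("empty cohort")
    flag = np.asarray(score_flag, dtype=bool)
    if flag.shape != (len(df),):
        raise ValueError("score_flag must align with the cohort rows")
    if EventClass(event_class) is EventClass.ALL:
        event = (df["event"] != "none").to_numpy()
    else:
        event = (df["event"] == "hard").to_numpy()
    return ContingencyTable(
        tp=int((flag & event).sum()),
        fp=int((flag & ~event).sum()),
        fn=int((~flag & event).sum()),
        tn=int((~flag & ~event).sum()),
    )


@dataclass(frozen=True)
class PredictiveValues:
    """PPV and NPV in percent; None where the denominator is empty."""

    ppv: float | None
    npv: float | None

    @property
    def ppv_rounded(self) -> int | None:
        return None if self.ppv is None else round(self.ppv)

    @property
    def npv_rounded(self) -> int | None:
        return None if self.npv is None else round(self.npv)


def predictive_values(table: ContingencyTable) -> PredictiveValues:
    """PPV = TP/(TP+FP) x 100; NPV = TN/(TN+FN) x 100."""
    if table.total == 0:
        raise ValueError("empty contingency table")
    ppv = 100.0 * table.tp / (table.tp + table.fp) if table.tp + table.fp > 0 else None
    npv = 100.0 * table.tn / (table.tn + table.fn) if table.tn + table.fn > 0 else None
    return PredictiveValues(ppv=ppv, npv=npv)


def combine_flags(a, b, mode: str = "OR"):
    """Elementwise AND/OR combination of two abnormality flags."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if mode == "OR":
        out = a | b
    elif mode == "AND":
        out = a & b
    else:
        raise ValueError("mode must be 'AND' or 'OR'")
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate evaluated at the event/censor times."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator; censoring = no event."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if times.size == 0:
        raise ValueError("no subjects")
    if np.any(times < 0):
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    return KMEstimate(timeline=timeline, survival=survival, at_risk=at_risk)


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test (1 df): (chi-square statistic, p-value)."""
    (ta, ea), (tb, eb) = group_a, group_b
    ta = np.asarray(ta, dtype=float)
    tb = np.asarray(tb, dtype=float)
    ea = np.asarray(ea, dtype=bool)
    eb = np.asarray(eb, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if not ea.any() and not eb.any():
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class SurvivalFit:
    """Cox proportional-hazards fit summary.

    ``summary`` has one row per covariate with columns hr, ci_lower,
    ci_upper, coef, se, p. ``global_chi2`` is the likelihood-ratio
    statistic of the model against the null (no-covariate) model.
    """

    summary: pd.DataFrame
    log_likelihood: float
    log_likelihood_null: float
    global_chi2: float
    n: int
    n_events: int
    covariates: tuple[str, ...]
    event_class: EventClass

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_lower"]), float(row["ci_upper"])

    def p_value(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    event_class: EventClass = EventClass.ALL,
    policy: SoftEventPolicy = SoftEventPolicy.CENSOR_AT_SOFT,
) -> SurvivalFit:
    """Cox partial-likelihood fit (Efron ties) with Wald 95 % CIs.

    Raises on zero events, constant covariates, exact collinearity, and
    non-convergence (with the underlying diagnostic message).
    """
    if not covariates:
        raise ValueError("at least one covariate required")
    durations, observed, keep = survival_arrays(df, event_class, policy)
    if observed.sum() == 0:
        raise ValueError("no events in cohort for this event class")
    X = df.loc[keep, covariates].astype(float)
    for c in covariates:
        if X[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    if np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(axis=0)) < len(covariates):
        raise ValueError("covariates are exactly collinear")

    fit_df = X.copy()
    fit_df["_T"] = durations
    fit_df["_E"] = observed.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col="_T", event_col="_E")
    except ConvergenceError as err:
        raise ValueError(f"Cox fit did not converge: {err}") from err

    s = cph.summary
    summary = pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "coef": s["coef"],
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    ll = float(cph.log_likelihood_)
    lrt = cph.log_likelihood_ratio_test()
    global_chi2 = float(lrt.test_statistic)
    ll_null = ll - global_chi2 / 2.0
    return SurvivalFit(
        summary=summary,
        log_likelihood=ll,
        log_likelihood_null=ll_null,
        global_chi2=global_chi2,
        n=int(len(fit_df)),
        n_events=int(observed.sum()),
        covariates=tuple(covariates),
        event_class=EventClass(event_class),
    )


def chi2_increment(base_fit: SurvivalFit, extended_fit: SurvivalFit) -> tuple[float, float]:
    """Added prognostic value of the extended model over the nested base.

    Returns (delta global chi-square, p-value from chi-square with df =
    number of added covariates).
    """
    if not set(base_fit.covariates) <= set(extended_fit.covariates):
        raise ValueError("extended model must nest the base model")
    if base_fit.n != extended_fit.n or base_fit.n_events != extended_fit.n_events:
        raise ValueError("models were fitted on different data")
    df_added = len(set(extended_fit.covariates) - set(base_fit.covariates))
    if df_added == 0:
        return 0.0, 1.0
    delta = extended_fit.global_chi2 - base_fit.global_chi2
    return float(delta), float(stats.chi2.sf(max(delta, 0.0), df_added))


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> RocResult:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return RocResult(auc=float(roc_auc_score(labels, scores)), n_pos=n_pos, n_neg=n_neg)


def _delong_structural_components(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    # placement values: V10[i] = P(score_neg < pos_i) + 0.5 P(=); V01 analogous
    m, n = pos.size, neg.size
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, x in enumerate(pos):
        v10[i] = ((neg < x).sum() + 0.5 * (neg == x).sum()) / n
    for j, y in enumerate(neg):
        v01[j] = ((pos > y).sum() + 0.5 * (pos == y).sum()) / m
    return v10, v01, float(v10.mean())


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Returns (auc_a, auc_b, z statistic, two-sided p-value).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not labels.any() or labels.all():
        raise ValueError("both classes must be present")
    pos_a, neg_a = scores_a[labels], scores_a[~labels]
    pos_b, neg_b = scores_b[labels], scores_b[~labels]
    v10a, v01a, auc_a = _delong_structural_components(pos_a, neg_a)
    v10b, v01b, auc_b = _delong_structural_components(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


_CONTINUOUS_VARS = ["age", "lvef", "sss", "srs", "sds", "sbs"]
_CATEGORICAL_VARS = ["sex", "uap", "smoking", "dm", "htn", "dyslipidemia", "ace", "bb", "ccb"]


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    A zero row or column margin makes the statistic degenerate; that
    case returns (0, 1) rather than an error.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def baseline_table(df: pd.DataFrame, event_class: EventClass = EventClass.ALL) -> pd.DataFrame:
    """Group comparison of baseline variables between event and no-event groups.

    Continuous variables: mean +/- SD per group, unpaired t-test.
    Categorical variables and score >= 4 flags: counts/%, Pearson
    chi-square without continuity correction.
    """
    if EventClass(event_class) is EventClass.ALL:
        event = (df["event"] != "none").to_numpy()
    else:
        event = (df["event"] == "hard").to_numpy()
    g1, g0 = df[event], df[~event]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each group needs at least 2 patients")

    rows = []
    for var in _CONTINUOUS_VARS:
        t, p = stats.ttest_ind(g1[var], g0[var], equal_var=True)
        rows.append(
            dict(variable=var, kind="continuous",
                 event_mean=g1[var].mean(), event_sd=g1[var].std(ddof=1),
                 noevent_mean=g0[var].mean(), noevent_sd=g0[var].std(ddof=1),
                 statistic=float(t), p=float(p))
        )
    cat_flags = {v: df[v].to_numpy(dtype=bool) for v in _CATEGORICAL_VARS}
    for score in ("sss", "srs", "sds", "sbs"):
        cat_flags[f"{score}_ge4"] = (df[score] >= 4).to_numpy()
    for var, flag in cat_flags.items():
        a, b = int((flag & event).sum()), int((flag & ~event).sum())
        c, d = int((~flag & event).sum()), int((~flag & ~event).sum())
        stat, p = pearson_chi2_2x2(a, b, c, d)
        rows.append(
            dict(variable=var, kind="categorical",
                 event_mean=a, event_sd=100.0 * a / len(g1),
                 noevent_mean=b, noevent_sd=100.0 * b / len(g0),
                 statistic=stat, p=p)
        )
    return pd.DataFrame(rows).set_index("variable")
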