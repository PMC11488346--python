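"""Post hoc cohort statistics: response rates, 2x2 contingency tests, and
Kaplan–Meier / log-rank survival comparisons.

The typical use is a small immunotherapy cohort stratified by peritoneal
metastasis status: objective response (complete + partial response, CR+PR,
versus stable/progressive disease) forms a 2x2 table against the stratum,
and immune-related progression-free survival (irPFS — time from treatment
initiation to progression, death, or end of follow-up) is compared between
strata. For tables this small the exact Fisher test is the default (any
expected count below 5); Pearson chi-square (with optional Yates correction)
is provided for larger tables. The two-sided Fisher p-value follows the
probability-mass convention: the sum over all tables with the observed
margins whose point hypergeometric probability does not exceed the observed
table's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import UndefinedTestError, ValidationError
from .groupstats import TestResult


def proportion(k: int, n: int, decimals: int = 0) -> float:
    """Percentage 100*k/n rounded to ``decimals`` places (0 for whole-cohort
    descriptors, 1 for response rates)."""
    if n <= 0:
        raise UndefinedTestError("proportion undefined for n = 0")
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    return round(100.0 * k / n, decimals)


@dataclass
class ResponseTable:
    """2x2 counts: rows = stratum (e.g. GCPM_pos / GCPM_neg), columns =
    responder (CR+PR) / non-responder (SD+PD)."""

    counts: np.ndarray
    row_labels: tuple = ("GCPM_pos", "GCPM_neg")
    col_labels: tuple = ("responder", "non_responder")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValidationError(f"need a 2x2 table, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def margins(self):
        return self.counts.sum(axis=1), self.counts.sum(axis=0)

    def response_rates(self, decimals: int = 1):
        """Per-stratum responder percentage."""
        rows = self.counts.sum(axis=1)
        return tuple(proportion(int(self.counts[i, 0]), int(rows[i]), decimals)
                     for i in range(2))


def _check_margins(table: ResponseTable) -> None:
    rows, cols = table.margins
    if (rows == 0).any() or (cols == 0).any():
        raise UndefinedTestError("zero margin: association test undefined")


def fisher_exact(table: ResponseTable, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on the 2x2 table (probability-mass two-sided
    convention); the sample odds ratio is reported in ``extra``."""
    _check_margins(table)
    odds, p = stats.fisher_exact(table.counts, alternative=alternative)
    return TestResult(statistic=float(odds), p_value=float(p), method="exact",
                      n=tuple(int(x) for x in table.counts.sum(axis=1)),
                      extra={"odds_ratio": float(odds)})


def chi_square(table: ResponseTable, yates: bool = False) -> TestResult:
    """Pearson chi-square on df=1, optional Yates continuity correction.

    Warns when any expected count is below 5 — Fisher's exact test is the
    appropriate default there.
    """
    _check_margins(table)
    chi2, p, dof, expected = stats.chi2_contingency(table.counts,
                                                    correction=yates)
    if (expected < 5).any():
        warnings.warn("expected count < 5; prefer fisher_exact", stacklevel=2)
    return TestResult(statistic=float(chi2), p_value=float(p),
                      method="approximate",
                      n=tuple(int(x) for x in table.counts.sum(axis=1)),
                      extra={"expected": expected, "dof": int(dof),
                             "yates": yates})


def response_rate_test(table: ResponseTable) -> TestResult:
    """Small-sample default: Fisher's exact test whenever any expected count
    is below 5, otherwise uncorrected chi-square."""
    _check_margins(table)
    expected = stats.chi2_contingency(table.counts, correction=False)[3]
    if (expected < 5).any():
        return fisher_exact(table)
    return chi_square(table)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalRecord:
    """One subject's time-to-event row (time in days; event 1 = progression
    or death, 0 = censored)."""

    time: float
    event: int
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError("time must be >= 0")
        if self.event not in (0, 1):
            raise ValidationError("event must be 0 or 1")


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([{"time": r.time, "event": r.event, "group": r.group}
                         for r in records])


@dataclass
class KMEstimate:
    """Kaplan–Meier product-limit curve.

    ``median`` is the earliest time at which the survival curve reaches 0.5
    or below, NaN when the curve never crosses 0.5.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records) -> KMEstimate:
    """Kaplan–Meier estimate from survival records (list of
    :class:`SurvivalRecord` or a DataFrame with time/event columns)."""
    df = _to_frame(records)
    if df.empty:
        raise UndefinedTestError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    surv = kmf.survival_function_["KM_estimate"]
    median = kmf.median_survival_time_
    return KMEstimate(times=surv.index.to_numpy(dtype=float),
                      survival=surv.to_numpy(dtype=float),
                      median=float("nan") if np.isinf(median) else float(median),
                      n=len(df), n_events=int(df["event"].sum()))


def logrank_test(records) -> TestResult:
    """Two-group log-rank test (hypergeometric variance at each event time)."""
    df = _to_frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    if df["event"].sum() == 0:
        raise UndefinedTestError("no events: log-rank undefined")
    a = df[df["group"] == groups[0]]
    b = df[df["group"] == groups[1]]
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"], event_observed_B=b["event"])
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value), method="approximate",
                      n=(len(a), len(b)), extra={"groups": tuple(groups)})


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Summarize a cohort table (columns: patient_id, group, response,
    time_days, event): per-group objective response rates with the
    small-sample test, and per-group KM medians with the log-rank p.

    ``response`` uses the CR/PR/SD/PD categories; CR and PR count as
    objective response.
    """
    responders = cohort["response"].isin(["CR", "PR"])
    groups = sorted(cohort["group"].unique())
    if len(groups) != 2:
        raise ValidationError("cohort_summary expects exactly 2 groups")
    counts = np.array([
        [int((responders & (cohort["group"] == g)).sum()),
         int((~responders & (cohort["group"] == g)).sum())]
        for g in groups])
    table = ResponseTable(counts, row_labels=tuple(groups))
    out = {
        "groups": groups,
        "response_rates_pct": table.response_rates(),
        "response_test": response_rate_test(table),
    }
    if {"time_days", "event"}.issubset(cohort.columns):
        records = cohort.rename(columns={"time_days": "time"})[
            ["time", "event", "group"]]
        out["km"] = {g: km_estimate(records[records["group"] == g])
                     for g in groups}
        out["logrank"] = logrank_test(records)
    return out
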