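"""Persistence classification, cohort summaries and the exact Fisher test.

Engineered-cell persistence is called from a longitudinal %-of-CD8 series:
a day-28 landmark crossing of the 3% threshold and sustained >3% levels
beyond day 100 (long-term persistence).  The association between long-term
persistence and clinical high-risk factors (detectable disease within two
weeks pre-infusion, or relapse within 3 months post-HCT) is tested with a
two-sided Fisher exact test implemented from first principles via
hypergeometric enumeration in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from tcellfate.dataio import PatientCourse, ValidationError

logger = logging.getLogger("tcellfate")

#: relative tolerance when collecting tables "at most as probable" as observed
FISHER_RELATIVE_TOL = 1e-7


@dataclass
class ContingencyTable2x2:
    """Counts (rows: persistent / not; columns: high-risk / not)."""

    a: int  # persistent & high-risk
    b: int  # persistent & not high-risk
    c: int  # not persistent & high-risk
    d: int  # not persistent & not high-risk

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class PersistenceCall:
    patient_id: str
    crossed_28d: bool
    long_term: bool


def classify_persistence(
    course: PatientCourse,
    threshold_pct: float = 3.0,
    early_day: float = 28.0,
    late_day: float = 100.0,
    window_days: float = 7.0,
) -> PersistenceCall:
    """Landmark persistence call from a (day, %CD8) series.

    The day-28 landmark uses the measurement nearest ``early_day`` within
    +/- ``window_days`` (no measurement -> the landmark is uncalled ->
    False).  Long-term persistence requires the landmark crossing AND a
    measurement above threshold at some day > ``late_day``.
    """
    if not course.series:
        raise ValidationError(f"{course.patient_id}: empty series")
    days = np.array([d for d, _ in course.series], dtype=float)
    vals = np.array([v for _, v in course.series], dtype=float)

    near = np.abs(days - early_day) <= window_days
    if near.any():
        idx = np.flatnonzero(near)[np.argmin(np.abs(days[near] - early_day))]
        crossed = bool(vals[idx] > threshold_pct)
    else:
        logger.info("%s: no measurement near day %g", course.patient_id, early_day)
        crossed = False
    late = bool(np.any((days > late_day) & (vals > threshold_pct)))
    return PersistenceCall(course.patient_id, crossed, crossed and late)


def build_risk_table(
    courses: list[PatientCourse],
    virus: str | None = "EBV",
    require_wt1_data: bool = True,
    reclassify: dict[str, str] | None = None,
    calls: dict[str, bool] | None = None,
) -> ContingencyTable2x2:
    """Cross long-term persistence with clinical high-risk factors.

    High-risk = detectable disease pre-infusion OR early relapse post-HCT.
    ``reclassify`` maps patient_id -> "highrisk"/"lowrisk" overrides;
    ``calls`` maps patient_id -> persistence call, defaulting to the
    course's transcribed ``long_term_persist`` flag or, when a series is
    present, to :func:`classify_persistence`.
    """
    reclassify = reclassify or {}
    a = b = c = d = 0
    kept = 0
    for course in courses:
        if virus is not None and course.virus_specificity != virus:
            continue
        if require_wt1_data and not course.wt1_data_available:
            continue
        kept += 1
        if calls and course.patient_id in calls:
            persist = calls[course.patient_id]
        elif course.long_term_persist is not None:
            persist = course.long_term_persist
        elif course.series:
            persist = classify_persistence(course).long_term
        else:
            raise ValidationError(f"{course.patient_id}: no persistence information")
        risk = course.detectable_disease_preinfusion or course.early_relapse_postHCT
        override = reclassify.get(course.patient_id)
        if override == "highrisk":
            risk = True
        elif override == "lowrisk":
            risk = False
        elif override is not None:
            raise ValueError(f"unknown reclassification {override!r}")
        if persist and risk:
            a += 1
        elif persist:
            b += 1
        elif risk:
            c += 1
        else:
            d += 1
    if kept == 0:
        raise ValidationError("empty cohort after filtering")
    return ContingencyTable2x2(a, b, c, d)


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(A = a) for a 2x2 table with fixed margins (rows r1, r2; col c1)."""
    n = r1 + r2

    def logc(m, k):
        return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    return logc(r1, a) + logc(r2, c1 - a) - logc(n, c1)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    p is the sum of the probabilities of every table with the observed
    margins whose probability is at most the observed table's probability
    (within a 1 + 1e-7 relative tolerance, the convention of standard
    statistical environments).  Degenerate margins give p = 1.
    """
    a, b, c, d = table.as_tuple()
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, r1, r2, c1)
    log_obs = float(_log_hypergeom_pmf(np.array([a]), r1, r2, c1)[0])
    include = logp <= log_obs + np.log1p(FISHER_RELATIVE_TOL)
    # log-sum-exp accumulation of the included probabilities
    m = logp[include].max()
    return float(min(1.0, np.exp(m + np.log(np.exp(logp[include] - m).sum()))))


def summarize_cohort(courses: list[PatientCourse]) -> pd.DataFrame:
    """Cohort counts by virus specificity, infusion number and risk flags."""
    rows = []
    n = len(courses)
    for virus in sorted({c.virus_specificity for c in courses}):
        rows.append(
            ("virus_specificity", virus,
             sum(c.virus_specificity == virus for c in courses))
        )
    for label, pred in [
        ("1", lambda c: c.n_infusions == 1),
        ("2", lambda c: c.n_infusions == 2),
        (">2", lambda c: c.n_infusions > 2),
    ]:
        rows.append(("n_infusions", label, sum(pred(c) for c in courses)))
    rows.append(
        ("flags", "detectable_disease_preinfusion",
         sum(c.detectable_disease_preinfusion for c in courses))
    )
    rows.append(
        ("flags", "early_relapse_postHCT",
         sum(c.early_relapse_postHCT for c in courses))
    )
    rows.append(
        ("flags", "wt1_data_available", sum(c.wt1_data_available for c in courses))
    )
    out = pd.DataFrame(rows, columns=["category", "value", "count"])
    out["total"] = n
    return out


def interval_duration(course: PatientCourse) -> float:
    """Length in days of the course's reported control interval."""
    if course.interval_days is None:
        raise ValidationError(f"{course.patient_id}: no interval recorded")
    start, end = course.interval_days
    if end < start:
        raise ValidationError("interval end precedes start")
    return float(end - start)
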