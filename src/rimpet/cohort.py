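"""EDSS-based progression labels and cohort-level group comparisons.

Disability progression is judged against the EDSS at the time of PET
imaging: an increase of more than 1.5 points if the imaging EDSS was 0,
more than 1.0 for imaging EDSS 1-5.5, and more than 0.5 for imaging EDSS
of 6 or above, confirmed by a later assessment at least 6 months after the
qualifying one that still meets the increase against the same baseline.

Progressor speed over the natural history: reaching EDSS >= 4 within 12
years of onset is "fast"; staying below EDSS 2 after 12 years is "slow";
anything else is intermediate.

Group comparisons use exact or rank-based tests: Fisher's exact test
(2x2 and 2x3 by full enumeration of tables with fixed margins),
Mann-Whitney U and Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import LabelError, StatisticError
from .phenotype import PatientPhenotypeSummary

log = logging.getLogger("rimpet")

DAYS_PER_MONTH = 30.4375  # mean Gregorian month
DAYS_PER_YEAR = 365.25

#: Patient categories used in the three-group comparisons.
CAT_RBRL = "rBRL"
CAT_RIM_ACTIVE = "non-rBRL rim-active"
CAT_NEITHER = "neither"
CATEGORIES = (CAT_RBRL, CAT_RIM_ACTIVE, CAT_NEITHER)

#: Valid EDSS values: 0 and 1.0 ... 10 in half steps (0.5 is not used).
_VALID_EDSS = {0.0} | {1.0 + 0.5 * k for k in range(19)}


def _check_edss(value: float) -> float:
    v = float(value)
    if v not in _VALID_EDSS:
        raise ValueError(f"invalid EDSS value {value}; use 0 or 1.0-10 in half steps")
    return v


@dataclass
class EdssTimeline:
    """A patient's EDSS assessments plus onset and imaging dates."""

    assessments: list[tuple[date, float]]
    onset_date: date
    imaging_date: date

    def __post_init__(self) -> None:
        self.assessments = [(d, _check_edss(e)) for d, e in self.assessments]
        dates = [d for d, _ in self.assessments]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError("assessment dates must be non-decreasing")

    def baseline_at_imaging(self) -> float | None:
        """EDSS of the last assessment at or before the imaging date."""
        prior = [e for d, e in self.assessments if d <= self.imaging_date]
        return prior[-1] if prior else None


@dataclass
class ProgressionLabel:
    progressed: bool
    baseline_edss: float
    delta_edss: float
    confirmed: bool

    def __post_init__(self) -> None:
        if self.progressed and not self.confirmed:
            raise ValueError("progression requires confirmation")


@dataclass
class PatientRecord:
    patient_id: str
    timeline: EdssTimeline
    phenotype: PatientPhenotypeSummary
    category: str = field(init=False)

    def __post_init__(self) -> None:
        self.category = categorize_patient(self.phenotype)


def categorize_patient(phenotype: PatientPhenotypeSummary) -> str:
    """rBRL > non-rBRL rim-active > neither, in that precedence."""
    if phenotype.has_rbrl:
        return CAT_RBRL
    if phenotype.n_rim_active >= 1:
        return CAT_RIM_ACTIVE
    return CAT_NEITHER


def required_increase(baseline_edss: float) -> float:
    """Minimum EDSS increase (exclusive) that counts as progression.

    1.5 for baseline 0; 1.0 for baseline 1-5.5; 0.5 for baseline >= 6
    (the 6.0 boundary is assigned to the 0.5-point rule for contiguity).
    """
    if baseline_edss == 0.0:
        return 1.5
    if baseline_edss < 6.0:
        return 1.0
    return 0.5


def classify_progression(
    timeline: EdssTimeline, confirmation_window_months: float = 6.0
) -> ProgressionLabel:
    """Confirmed-progression label against the EDSS at imaging.

    A patient progressed if some post-imaging assessment exceeds the
    baseline by more than the required increase AND a later assessment at
    least `confirmation_window_months` months after the qualifying one
    still meets the increase against the same baseline.
    """
    baseline = timeline.baseline_at_imaging()
    if baseline is None:
        raise LabelError("no EDSS assessment at or before the imaging date")
    delta_star = required_increase(baseline)
    window = timedelta(days=confirmation_window_months * DAYS_PER_MONTH)
    post = [(d, e) for d, e in timeline.assessments if d > timeline.imaging_date]
    best_delta = max((e - baseline for _, e in post), default=0.0)
    progressed = confirmed = False
    for i, (d_event, e_event) in enumerate(post):
        if e_event - baseline > delta_star:
            for d_conf, e_conf in post[i + 1:]:
                if d_conf >= d_event + window and e_conf - baseline > delta_star:
                    progressed = confirmed = True
                    break
        if progressed:
            break
    return ProgressionLabel(progressed, baseline, max(best_delta, 0.0), confirmed)


def label_progressor_speed(timeline: EdssTimeline, milestone_edss: float = 4.0,
                           horizon_years: float = 12.0) -> str:
    """fast / slow / intermediate progressor over the disease course.

    fast: any assessment with EDSS >= `milestone_edss` within
    `horizon_years` of onset; slow: at least one assessment after the
    horizon and all of them below EDSS 2; otherwise intermediate.
    """
    horizon = timeline.onset_date + timedelta(days=horizon_years * DAYS_PER_YEAR)
    within = [e for d, e in timeline.assessments if d <= horizon]
    after = [e for d, e in timeline.assessments if d > horizon]
    if any(e >= milestone_edss for e in within):
        return "fast"
    if after and all(e < 2.0 for e in after):
        return "slow"
    if not after:
        log.warning("label_progressor_speed: no assessments beyond the horizon "
                    "and no early milestone; labelling intermediate")
    return "intermediate"


def reached_milestone(timeline: EdssTimeline, milestone_edss: float,
                      horizon_years: float = 12.0, comparator: str = "ge") -> bool:
    """Did the patient reach the EDSS milestone within the horizon from onset?

    `comparator` is "ge" (reached the milestone value, the operational
    reading) or "gt" (strictly exceeded it).
    """
    horizon = timeline.onset_date + timedelta(days=horizon_years * DAYS_PER_YEAR)
    op = (lambda e: e >= milestone_edss) if comparator == "ge" else (lambda e: e > milestone_edss)
    return any(op(e) for d, e in timeline.assessments if d <= horizon)


def milestone_category_table(
    patients: list[PatientRecord],
    milestone_edss: float = 4.0,
    horizon_years: float = 12.0,
    comparator: str = "ge",
) -> np.ndarray:
    """2x3 contingency table: milestone reached (rows) x category (columns).

    Row 0 = milestone reached within the horizon, row 1 = not reached;
    columns follow CATEGORIES (rBRL, non-rBRL rim-active, neither).
    """
    table = np.zeros((2, 3), dtype=int)
    for rec in patients:
        row = 0 if reached_milestone(rec.timeline, milestone_edss, horizon_years, comparator) else 1
        col = CATEGORIES.index(rec.category)
        table[row, col] += 1
    return table


# ---------------------------------------------------------------------------
# Exact and rank statistics


def _log_table_prob(table: np.ndarray, row_sums, col_sums, n) -> float:
    """Log multivariate hypergeometric probability of a 2xk table with fixed margins."""
    lp = (
        sum(gammaln(r + 1) for r in row_sums)
        + sum(gammaln(c + 1) for c in col_sums)
        - gammaln(n + 1)
        - gammaln(table + 1.0).sum()
    )
    return float(lp)


def fisher_exact_2xk(table) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 or 2x3 table.

    Full enumeration of all tables with the observed margins; the p-value
    sums the probabilities of tables no more probable than the observed one
    (with a small relative tolerance against floating-point ties).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise StatisticError(f"need a 2x2 or 2x3 table, got shape {t.shape}")
    if np.any(t < 0):
        raise StatisticError("table counts must be non-negative")
    n = int(t.sum())
    if n == 0:
        raise StatisticError("empty table")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if 0 in row_sums or np.all(col_sums == 0):
        return 1.0
    lp_obs = _log_table_prob(t, row_sums, col_sums, n)
    r0 = int(row_sums[0])
    total = 0.0
    k = t.shape[1]
    if k == 2:
        a_range = range(max(0, r0 - col_sums[1]), min(r0, col_sums[0]) + 1)
        candidates = ((a, r0 - a) for a in a_range)
    else:
        candidates = (
            (a, b, r0 - a - b)
            for a in range(min(r0, col_sums[0]) + 1)
            for b in range(min(r0 - a, col_sums[1]) + 1)
            if 0 <= r0 - a - b <= col_sums[2]
        )
    for row0 in candidates:
        cand = np.array([row0, col_sums - np.array(row0)])
        lp = _log_table_prob(cand, row_sums, col_sums, n)
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return float(min(total, 1.0))


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U, p)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatisticError("both groups must be non-empty")
    if len(np.unique(np.concatenate([a, b]))) == 1:
        raise StatisticError("all observations tied; U test undefined")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation; returns (rho, p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatisticError("need >= 3 paired observations")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise StatisticError("a constant variable has no rank correlation")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
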