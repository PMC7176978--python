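"""Diagnostic accuracy statistics for qPCR positivity calls.

Group-level machinery downstream of the caller: positive detection rates
(PDR) with Wilson score intervals, pooling of stage-stratified counts,
sensitivity/specificity, paired-specimen concordance, two-proportion
comparisons (Fisher exact / chi-square), Welch's t for group mean-Cp
differences, and ROC analysis on censored mean-Cp scores.

ROC orientation: a lower Cp means more target DNA, so a sample is
test-positive at threshold ``c`` iff its score is <= ``c``.  Samples with no
marker signal enter with the censor value (50.0 cycles), producing the large
tie group at the top of the curve typical of non-detect-heavy assays.  The
AUC is the Mann-Whitney rank estimator (ties count 1/2) and its confidence
interval comes from DeLong's structural-components variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .calling import CallResult

__all__ = [
    "ProportionEstimate",
    "ConcordanceTable",
    "RocResult",
    "WelchResult",
    "pdr",
    "proportion_from_counts",
    "pool_counts",
    "sens_spec",
    "build_pairs",
    "concordance",
    "compare_proportions",
    "welch_t",
    "roc_censored",
    "auc_ci",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with a Wilson score confidence interval."""

    numerator: int
    denominator: int
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Rate as a percentage rounded to one decimal (report convention)."""
        return round(100.0 * self.rate, 1)

    def complement(self) -> "ProportionEstimate":
        """The proportion of the complementary outcome (1 - rate), with the
        interval flipped accordingly.  Used for specificity = 1 - PDR(normals)."""
        return ProportionEstimate(
            numerator=self.denominator - self.numerator,
            denominator=self.denominator,
            ci_low=1.0 - self.ci_high,
            ci_high=1.0 - self.ci_low,
            level=self.level,
        )

    def __str__(self) -> str:
        return f"{self.percent}%({self.numerator}/{self.denominator})"


def proportion_from_counts(
    numerator: int, denominator: int, level: float = 0.95
) -> ProportionEstimate:
    """Wilson-interval proportion from raw counts."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    low, high = proportion_confint(
        numerator, denominator, alpha=1.0 - level, method="wilson"
    )
    # Wilson bounds are exactly 0 at k=0 and 1 at k=n; clamp float noise
    low = 0.0 if numerator == 0 else min(max(float(low), 0.0), 1.0)
    high = 1.0 if numerator == denominator else min(max(float(high), 0.0), 1.0)
    return ProportionEstimate(numerator, denominator, low, high, level)


def pdr(calls: Sequence[CallResult], level: float = 0.95) -> ProportionEstimate:
    """Positive detection rate of a group of valid calls.

    Invalid samples must be excluded upstream (they have no evaluable call);
    passing one raises ``ValueError``.
    """
    if not calls:
        raise ValueError("empty group")
    if any(not c.valid for c in calls):
        raise ValueError("pdr() requires valid calls only; exclude invalid samples")
    n_pos = sum(bool(c.positive) for c in calls)
    return proportion_from_counts(n_pos, len(calls), level)


def pool_counts(
    stage_counts: Iterable[tuple[int, int]], level: float = 0.95
) -> ProportionEstimate:
    """Pool (numerator, denominator) pairs — e.g. per-stage detection counts —
    into one proportion."""
    counts = list(stage_counts)
    if not counts:
        raise ValueError("no counts to pool")
    num = den = 0
    for n, d in counts:
        if n < 0 or d <= 0 or n > d:
            raise ValueError(f"bad count pair ({n}, {d})")
        num += n
        den += d
    return proportion_from_counts(num, den, level)


def sens_spec(
    case_calls: Sequence[CallResult],
    control_calls: Sequence[CallResult],
    level: float = 0.95,
) -> tuple[ProportionEstimate, ProportionEstimate]:
    """Sensitivity and specificity from case and control call groups.

    Sensitivity is the PDR of the diseased group; specificity is one minus
    the PDR of the normal group (equivalently the negative-call rate among
    controls), with the confidence interval transformed accordingly.
    """
    sensitivity = pdr(case_calls, level)
    specificity = pdr(control_calls, level).complement()
    return sensitivity, specificity


@dataclass(frozen=True)
class ConcordanceTable:
    """Paired 2x2 agreement table between two tests on the same subjects.

    ``n_pp`` counts pairs positive on both tests, ``n_pn`` positive on the
    first only, ``n_np`` positive on the second only, ``n_nn`` negative on
    both.
    """

    n_pp: int
    n_pn: int
    n_np: int
    n_nn: int

    @property
    def total(self) -> int:
        return self.n_pp + self.n_pn + self.n_np + self.n_nn

    @property
    def concordance_rate(self) -> float:
        return (self.n_pp + self.n_nn) / self.total

    @property
    def pdr_test1(self) -> ProportionEstimate:
        return proportion_from_counts(self.n_pp + self.n_pn, self.total)

    @property
    def pdr_test2(self) -> ProportionEstimate:
        return proportion_from_counts(self.n_pp + self.n_np, self.total)

    def swapped(self) -> "ConcordanceTable":
        """The table with the two tests exchanged (concordance is unchanged)."""
        return ConcordanceTable(self.n_pp, self.n_np, self.n_pn, self.n_nn)


def build_pairs(
    calls_test1: Sequence[CallResult],
    calls_test2: Sequence[CallResult],
    subject_of: dict[str, str],
) -> list[tuple[CallResult, CallResult]]:
    """Match two call sets into per-subject pairs.

    ``subject_of`` maps sample_id -> subject_id.  Subjects present in only
    one set, or with an invalid call on either side, are excluded with a
    logged warning (paired analyses need both calls evaluable).
    """
    by_subject_1 = {subject_of[c.sample_id]: c for c in calls_test1}
    by_subject_2 = {subject_of[c.sample_id]: c for c in calls_test2}
    pairs = []
    for subject in by_subject_1:
        if subject not in by_subject_2:
            logger.warning("subject %s present for only one specimen; excluded", subject)
            continue
        c1, c2 = by_subject_1[subject], by_subject_2[subject]
        if not (c1.valid and c2.valid):
            logger.warning("subject %s has an invalid call; excluded from pairing", subject)
            continue
        pairs.append((c1, c2))
    for subject in by_subject_2:
        if subject not in by_subject_1:
            logger.warning("subject %s present for only one specimen; excluded", subject)
    return pairs


def concordance(
    paired: Iterable[tuple[CallResult, CallResult]]
) -> ConcordanceTable:
    """Cross-tabulate paired binary calls into a :class:`ConcordanceTable`."""
    n_pp = n_pn = n_np = n_nn = 0
    for c1, c2 in paired:
        if c1.positive is None or c2.positive is None:
            raise ValueError("concordance requires valid calls on both sides")
        if c1.positive and c2.positive:
            n_pp += 1
        elif c1.positive:
            n_pn += 1
        elif c2.positive:
            n_np += 1
        else:
            n_nn += 1
    table = ConcordanceTable(n_pp, n_pn, n_np, n_nn)
    if table.total == 0:
        raise ValueError("no pairs")
    return table


def compare_proportions(
    a: tuple[int, int],
    b: tuple[int, int],
    method: str = "fisher_exact",
) -> float:
    """Two-sided p-value comparing two binomial proportions.

    ``a`` and ``b`` are (numerator, denominator) pairs.  ``fisher_exact``
    (default) suits the small strata of subgroup tables; ``chi_square`` is
    the large-sample alternative (with continuity correction).
    """
    (n1, d1), (n2, d2) = a, b
    if d1 <= 0 or d2 <= 0:
        raise ValueError("denominators must be positive")
    table = [[n1, d1 - n1], [n2, d2 - n2]]
    if method == "fisher_exact":
        return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    if method == "chi_square":
        return float(stats.chi2_contingency(table).pvalue)
    raise ValueError(f"unknown method {method!r}")


class WelchResult(NamedTuple):
    statistic: float
    pvalue: float
    df: float


def welch_t(
    cp_group1: Sequence[float], cp_group2: Sequence[float]
) -> WelchResult:
    """Welch's unequal-variance two-sample t-test on (censored mean) Cps.

    When both groups are constant with equal means there is no evidence of a
    difference and the test degenerates; by convention t = 0, p = 1.
    """
    x = np.asarray(cp_group1, dtype=float)
    y = np.asarray(cp_group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return WelchResult(0.0, 1.0, float(len(x) + len(y) - 2))
        # constant but different: infinitely strong evidence
        return WelchResult(np.inf if x.mean() > y.mean() else -np.inf, 0.0, float(len(x) + len(y) - 2))
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.pvalue), float(res.df))


@dataclass(frozen=True)
class RocResult:
    """ROC curve and AUC for censored Cp scores (lower score = more diseased).

    ``thresholds`` are the candidate decision values ``c`` ("positive iff
    score <= c"); ``sensitivities``/``specificities`` are the operating
    points.  ``auc`` is the Mann-Whitney estimate with ``auc_se`` its DeLong
    standard error and ``auc_ci_low``/``auc_ci_high`` the normal-theory
    interval truncated to [0, 1].
    """

    thresholds: tuple[float, ...]
    sensitivities: tuple[float, ...]
    specificities: tuple[float, ...]
    auc: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float
    level: float = 0.95
    degenerate: bool = False


def _delong_auc_se(case_scores: np.ndarray, control_scores: np.ndarray) -> tuple[float, float]:
    """AUC and DeLong standard error.

    Structural components: for each case, the fraction of controls it beats
    (score strictly lower, ties count 1/2); symmetrically for controls.  The
    variance estimate is var(V10)/m + var(V01)/n with sample variances.
    """
    x = case_scores[:, None]
    y = control_scores[None, :]
    # lower Cp = more diseased: a case "wins" against a control when x < y
    wins = (x < y).astype(float) + 0.5 * (x == y)
    v10 = wins.mean(axis=1)  # per-case placement, length m
    v01 = wins.mean(axis=0)  # per-control placement, length n
    auc = float(wins.mean())
    m, n = len(case_scores), len(control_scores)
    var10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    var01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = float(np.sqrt(var10 / m + var01 / n))
    return auc, se


def roc_censored(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    level: float = 0.95,
) -> RocResult:
    """ROC analysis on per-sample censored mean-Cp scores.

    Scores must already carry the censor value (e.g. 50.0) for samples with
    no marker signal.  The curve enumerates every observed score as a
    threshold; the AUC equals the probability that a random case scores
    below a random control (ties 1/2), estimated via ranks.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both score groups must be non-empty")

    thresholds = np.unique(np.concatenate([cases, controls]))
    sens = np.array([(cases <= c).mean() for c in thresholds])
    spec = np.array([(controls > c).mean() for c in thresholds])

    auc, se = _delong_auc_se(cases, controls)
    all_tied = len(np.unique(np.concatenate([cases, controls]))) == 1
    if all_tied:
        warnings.warn(
            "all scores identical: AUC is the tie convention 0.5 and the "
            "confidence interval is uninformative [0, 1]",
            stacklevel=2,
        )
        low, high = 0.0, 1.0
    else:
        z = stats.norm.ppf(0.5 + level / 2.0)
        low = max(0.0, auc - z * se)
        high = min(1.0, auc + z * se)
    return RocResult(
        thresholds=tuple(float(c) for c in thresholds),
        sensitivities=tuple(float(s) for s in sens),
        specificities=tuple(float(s) for s in spec),
        auc=auc,
        auc_se=se,
        auc_ci_low=low,
        auc_ci_high=high,
        level=level,
        degenerate=bool(all_tied),
    )


def auc_ci(roc: RocResult, level: float = 0.95) -> tuple[float, float]:
    """DeLong confidence interval for the AUC at an arbitrary level,
    truncated to [0, 1].  Degenerate (all-tied) curves yield [0, 1]."""
    if roc.degenerate:
        warnings.warn("degenerate ROC (all scores tied): returning [0, 1]", stacklevel=2)
        return 0.0, 1.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        max(0.0, roc.auc - z * roc.auc_se),
        min(1.0, roc.auc + z * roc.auc_se),
    )
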