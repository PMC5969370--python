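"""Diagnostic-accuracy statistics for paired triage-tool evaluation.

Everything operates on the strict binary collapse of triage output: P1 is the
positive call, P2/P3/DEAD are all negative, and truth is the LSI-defined
Priority One label.  Point estimates come with 95% intervals: Wilson score for
proportions, Woolf (log) for the diagnostic odds ratio.  Undertriage is
1 - sensitivity (a genuine P1 labelled less urgent); overtriage is 1 - PPV
(a non-P1 labelled P1).  Paired tools are compared with McNemar's test on
correct/incorrect discordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .records import TriageCategory

__all__ = [
    "ConfusionTable",
    "MetricEstimate",
    "PairedComparison",
    "UndefinedMetricError",
    "confusion",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "diagnostic_odds_ratio",
    "dor_from_rates",
    "ppv_from_rates",
    "undertriage",
    "overtriage",
    "number_needed_to_assess",
    "mcnemar",
    "report",
]

#: Discordant-pair count below which McNemar switches to the exact binomial test.
EXACT_MCNEMAR_THRESHOLD = 25


class UndefinedMetricError(ZeroDivisionError):
    """The margin needed for a metric is zero (e.g. no true positives + false negatives)."""


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of predicted-P1 against LSI-defined true-P1."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion or ratio with a 95% confidence interval and method label."""

    value: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")


@dataclass(frozen=True)
class PairedComparison:
    """McNemar comparison of two tools on identical records.

    ``b`` counts records where tool A is correct and tool B wrong; ``c`` the
    reverse.  ``method`` records whether the chi-square approximation or the
    exact binomial was used.
    """

    b: int
    c: int
    statistic: float
    p_value: float
    method: str


def _collapse(predictions: Sequence) -> np.ndarray:
    """Binary collapse: P1 -> True, {P2, P3, DEAD} -> False."""
    out = np.empty(len(predictions), dtype=bool)
    for i, p in enumerate(predictions):
        if isinstance(p, TriageCategory):
            out[i] = p.is_p1
        else:
            out[i] = str(p) == TriageCategory.P1.value
    return out


def confusion(predicted: Sequence, truth: Sequence[bool]) -> ConfusionTable:
    """Cross-tabulate binary-collapsed predictions against true P1 status."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    if len(predicted) == 0:
        raise ValueError("cannot build a confusion table from an empty cohort")
    pred = _collapse(predicted)
    tru = np.asarray(truth, dtype=bool)
    return ConfusionTable(
        tp=int(np.sum(pred & tru)),
        fp=int(np.sum(pred & ~tru)),
        fn=int(np.sum(~pred & tru)),
        tn=int(np.sum(~pred & ~tru)),
    )


def _wilson_proportion(successes: int, margin: int, what: str) -> MetricEstimate:
    if margin == 0:
        raise UndefinedMetricError(f"{what} undefined: relevant margin is zero")
    lo, hi = proportion_confint(successes, margin, alpha=0.05, method="wilson")
    return MetricEstimate(value=successes / margin, ci_low=float(lo),
                          ci_high=float(hi), method="wilson")


def sensitivity(t: ConfusionTable) -> MetricEstimate:
    """TP / (TP + FN) with Wilson 95% CI."""
    return _wilson_proportion(t.tp, t.tp + t.fn, "sensitivity")


def specificity(t: ConfusionTable) -> MetricEstimate:
    """TN / (TN + FP) with Wilson 95% CI."""
    return _wilson_proportion(t.tn, t.tn + t.fp, "specificity")


def ppv(t: ConfusionTable) -> MetricEstimate:
    """TP / (TP + FP) with Wilson 95% CI."""
    return _wilson_proportion(t.tp, t.tp + t.fp, "ppv")


def npv(t: ConfusionTable) -> MetricEstimate:
    """TN / (TN + FN) with Wilson 95% CI."""
    return _wilson_proportion(t.tn, t.tn + t.fn, "npv")


def diagnostic_odds_ratio(t: ConfusionTable) -> MetricEstimate:
    """(TP*TN)/(FP*FN) with a Woolf (log-method) 95% CI.

    Requires all four cells positive; a zero off-diagonal cell makes the odds
    ratio infinite or undefined.
    """
    if min(t.tp, t.fp, t.fn, t.tn) == 0:
        raise UndefinedMetricError(
            "diagnostic odds ratio undefined: a confusion cell is zero")
    or_ = (t.tp * t.tn) / (t.fp * t.fn)
    se_log = math.sqrt(1 / t.tp + 1 / t.fp + 1 / t.fn + 1 / t.tn)
    z = stats.norm.ppf(0.975)
    return MetricEstimate(
        value=or_,
        ci_low=math.exp(math.log(or_) - z * se_log),
        ci_high=math.exp(math.log(or_) + z * se_log),
        method="woolf-log",
    )


def dor_from_rates(sens: float, spec: float) -> float:
    """Diagnostic odds ratio implied by a (sensitivity, specificity) pair.

    DOR = [sens/(1-sens)] * [spec/(1-spec)]; prevalence-free, so it can be
    recovered from published operating points without the underlying 2x2 table.
    """
    if not (0 < sens < 1 and 0 < spec < 1):
        raise ValueError("sensitivity and specificity must lie strictly in (0, 1)")
    return (sens / (1 - sens)) * (spec / (1 - spec))


def ppv_from_rates(sens: float, spec: float, prevalence: float) -> float:
    """Positive predictive value via the Bayes identity.

    PPV = sens*prev / (sens*prev + (1-spec)*(1-prev)).
    """
    if not (0 < sens <= 1 and 0 < spec <= 1):
        raise ValueError("sensitivity and specificity must lie in (0, 1]")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie strictly in (0, 1)")
    num = sens * prevalence
    return num / (num + (1 - spec) * (1 - prevalence))


def undertriage(t: ConfusionTable) -> float:
    """1 - sensitivity: the rate at which genuine P1 casualties are missed."""
    return 1.0 - sensitivity(t).value


def overtriage(t: ConfusionTable) -> float:
    """1 - PPV: the fraction of P1 calls that are not genuine P1 casualties."""
    return 1.0 - ppv(t).value


def number_needed_to_assess(delta_sensitivity: float) -> float:
    """Genuine P1 casualties assessed per additional undertriage.

    The reciprocal of an absolute sensitivity difference between two tools:
    a 3.2-point drop means ~31 genuine P1 patients per extra missed casualty.
    """
    if delta_sensitivity <= 0:
        raise ValueError("sensitivity difference must be positive")
    return 1.0 / delta_sensitivity


def mcnemar(
    pred_a: Sequence,
    pred_b: Sequence,
    truth: Sequence[bool],
    correction: bool = False,
) -> PairedComparison:
    """McNemar's test on paired correct/incorrect calls of two tools.

    A call is "correct" when its binary collapse (P1 vs not-P1) matches the
    LSI truth.  With ``b + c >= 25`` discordant pairs the chi-square statistic
    ``(b - c)^2 / (b + c)`` is used (optionally continuity-corrected); below
    that, the exact two-sided binomial test.  No discordance gives p = 1.
    """
    if not (len(pred_a) == len(pred_b) == len(truth)):
        raise ValueError("pred_a, pred_b and truth must have equal lengths")
    tru = np.asarray(truth, dtype=bool)
    correct_a = _collapse(pred_a) == tru
    correct_b = _collapse(pred_b) == tru
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    n_disc = b + c
    if n_disc == 0:
        return PairedComparison(b=0, c=0, statistic=0.0, p_value=1.0,
                                method="no-discordance")
    if n_disc < EXACT_MCNEMAR_THRESHOLD:
        p = stats.binomtest(min(b, c), n_disc, 0.5).pvalue
        return PairedComparison(b=b, c=c, statistic=float(min(b, c)),
                                p_value=float(min(p, 1.0)), method="exact-binomial")
    diff = abs(b - c) - (1 if correction else 0)
    statistic = max(diff, 0) ** 2 / n_disc
    p = float(stats.chi2.sf(statistic, df=1))
    return PairedComparison(b=b, c=c, statistic=float(statistic), p_value=p,
                            method="chi-square" + ("-corrected" if correction else ""))


def report(
    records,
    truth: Sequence[bool],
    tools: Sequence[str],
    missing_policy: str = "exclude",
    assume_non_ambulant: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate a set of tools on one cohort.

    Returns an evaluation table (one row per tool: 2x2 cells, sensitivity,
    specificity, DOR and PPV with 95% CIs, under/overtriage, exclusion count)
    and a pairwise McNemar p-value matrix.  Records a tool cannot classify
    under the ``exclude`` policy are dropped for that tool; McNemar pairs are
    formed on records classified by both tools of each pair.

    ``assume_non_ambulant`` defaults to True: the evaluation emulates hospital
    trauma-registry populations in which every casualty is treated as
    non-ambulant.
    """
    from .tools import classify_cohort

    truth = list(truth)
    if len(records) != len(truth):
        raise ValueError("records and truth must have equal lengths")
    predictions: Dict[str, List[Optional[TriageCategory]]] = {}
    rows = []
    for tool in tools:
        cats, n_excluded = classify_cohort(
            records, tool, missing_policy=missing_policy,
            assume_non_ambulant=assume_non_ambulant)
        predictions[tool] = cats
        kept = [(c, t) for c, t in zip(cats, truth) if c is not None]
        tab = confusion([c for c, _ in kept], [t for _, t in kept])
        sens, spec, pp = sensitivity(tab), specificity(tab), ppv(tab)
        try:
            dor = diagnostic_odds_ratio(tab)
            dor_cells = (dor.value, dor.ci_low, dor.ci_high)
        except UndefinedMetricError:
            dor_cells = (float("nan"),) * 3
        rows.append({
            "tool": tool, "n": tab.total, "n_excluded": n_excluded,
            "tp": tab.tp, "fp": tab.fp, "fn": tab.fn, "tn": tab.tn,
            "sensitivity": sens.value, "sens_ci_low": sens.ci_low,
            "sens_ci_high": sens.ci_high,
            "specificity": spec.value, "spec_ci_low": spec.ci_low,
            "spec_ci_high": spec.ci_high,
            "dor": dor_cells[0], "dor_ci_low": dor_cells[1],
            "dor_ci_high": dor_cells[2],
            "ppv": pp.value, "ppv_ci_low": pp.ci_low, "ppv_ci_high": pp.ci_high,
            "undertriage": 1.0 - sens.value, "overtriage": 1.0 - pp.value,
        })
    table = pd.DataFrame(rows).set_index("tool")

    pmat = pd.DataFrame(np.ones((len(tools), len(tools))), index=list(tools),
                        columns=list(tools))
    for i, a in enumerate(tools):
        for bname in list(tools)[i + 1:]:
            paired = [
                (pa, pb, t) for pa, pb, t
                in zip(predictions[a], predictions[bname], truth)
                if pa is not None and pb is not None
            ]
            cmp_ = mcnemar([x[0] for x in paired], [x[1] for x in paired],
                           [x[2] for x in paired])
            pmat.loc[a, bname] = pmat.loc[bname, a] = cmp_.p_value
    return table, pmat
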