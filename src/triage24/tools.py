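"""Primary major-incident triage decision trees.

Three tools are implemented as scikit-learn-style classifiers over casualty
records:

* ``MPTTClassifier`` — the Modified Physiological Triage Tool: P1 on GCS < 14,
  RR < 12, RR >= 22 or HR >= 100 (after the walking and airway/breathing steps).
* ``MPTT24Classifier`` — the MPTT-24 variant: upper RR threshold raised to
  >= 24 breaths/min (enabling a 15-s count multiplied by four), conscious level
  assessed on the AVPU scale (P1 if not Alert), and a catastrophic external
  haemorrhage step ahead of the walking step.
* ``MilitarySieveClassifier`` — the UK Military Sieve: catastrophic
  haemorrhage, walking, airway/breathing, then P1 on RR outside 10-29
  breaths/min (inclusive band) or HR > 120.

``RespiratoryRateClassifier`` is the bare-threshold pseudo-tool used to study a
single RR cut-off in isolation.

All thresholds are estimator hyper-parameters, so any tool can be reproduced
from any other by re-parameterisation: the trees differ only in configuration,
not code.  The step order is haemorrhage -> walking -> airway/breathing ->
consciousness -> RR -> HR, short-circuiting at the first decisive step.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .records import (
    AVPU,
    CasualtyRecord,
    MissingDataError,
    TriageCategory,
    _GCS_ALERT_THRESHOLD,
)

__all__ = [
    "TriageTreeClassifier",
    "MPTTClassifier",
    "MPTT24Classifier",
    "MilitarySieveClassifier",
    "RespiratoryRateClassifier",
    "classify_mptt",
    "classify_mptt24",
    "classify_uk_military_sieve",
    "classify_cohort",
    "make_classifier",
    "TOOL_NAMES",
]

MISSING_POLICIES = ("exclude", "treat-missing-as-normal", "treat-missing-as-abnormal")
CONSCIOUS_RULES = ("gcs_lt_14", "not_alert", "none")


def _resolve(value: Optional[bool], policy: str, field: str, record_id: str,
             normal: bool, abnormal: bool) -> bool:
    """Apply the missing-data policy to one boolean predicate input."""
    if value is not None:
        return value
    if policy == "treat-missing-as-normal":
        return normal
    if policy == "treat-missing-as-abnormal":
        return abnormal
    raise MissingDataError(f"record {record_id!r}: {field} missing")


class TriageTreeClassifier(ClassifierMixin, BaseEstimator):
    """Configurable primary-triage decision tree.

    Parameters
    ----------
    rr_low : int
        P1 if respiratory rate < ``rr_low`` breaths/min.
    rr_high : int
        Upper respiratory-rate threshold, breaths/min.
    rr_high_inclusive : bool
        If True (MPTT family) P1 on RR >= ``rr_high``; if False (Sieve
        convention) P1 on RR > ``rr_high``.
    hr_high : int
        Upper heart-rate threshold, beats/min.
    hr_high_inclusive : bool
        If True P1 on HR >= ``hr_high`` (MPTT family); if False on
        HR > ``hr_high`` (Sieve).
    conscious_rule : {"gcs_lt_14", "not_alert", "none"}
        Conscious-level step.  ``gcs_lt_14`` prefers the GCS (P1 if
        GCS < 14, falling back to AVPU when GCS is absent); ``not_alert``
        prefers AVPU (P1 unless Alert, falling back to GCS >= 14); ``none``
        skips the step (Sieve).
    use_catastrophic_haemorrhage : bool
        Whether an initial catastrophic-external-haemorrhage step precedes
        everything else (immediate P1).
    missing_policy : {"exclude", "treat-missing-as-normal", "treat-missing-as-abnormal"}
        What to do when a field needed to reach a decision is absent:
        exclude the record (``predict`` emits None), or resolve the missing
        predicate towards its non-triggering ("normal") or triggering
        ("abnormal") side.
    assume_non_ambulant : bool
        Force ``can_walk = False`` for every record, the assumption used when
        evaluating on hospital trauma-registry populations whose inclusion
        criteria make ambulation unobservable.
    """

    def __init__(
        self,
        rr_low: int = 12,
        rr_high: int = 24,
        rr_high_inclusive: bool = True,
        hr_high: int = 100,
        hr_high_inclusive: bool = True,
        conscious_rule: str = "not_alert",
        use_catastrophic_haemorrhage: bool = True,
        missing_policy: str = "exclude",
        assume_non_ambulant: bool = False,
    ):
        self.rr_low = rr_low
        self.rr_high = rr_high
        self.rr_high_inclusive = rr_high_inclusive
        self.hr_high = hr_high
        self.hr_high_inclusive = hr_high_inclusive
        self.conscious_rule = conscious_rule
        self.use_catastrophic_haemorrhage = use_catastrophic_haemorrhage
        self.missing_policy = missing_policy
        self.assume_non_ambulant = assume_non_ambulant

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, X=None, y=None):
        """Validate hyper-parameters; the tree has nothing to learn from data."""
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
        if self.conscious_rule not in CONSCIOUS_RULES:
            raise ValueError(f"conscious_rule must be one of {CONSCIOUS_RULES}")
        if not (0 < self.rr_low < self.rr_high):
            raise ValueError("thresholds must satisfy 0 < rr_low < rr_high")
        if self.hr_high <= 0:
            raise ValueError("hr_high must be positive")
        self.classes_ = np.array([c.value for c in TriageCategory])
        return self

    def predict(self, X) -> np.ndarray:
        """Classify records; excluded records (missing data) map to None."""
        check_is_fitted(self)
        records = _as_records(X)
        out = np.empty(len(records), dtype=object)
        for i, rec in enumerate(records):
            try:
                out[i] = self.classify_record(rec).value
            except MissingDataError:
                out[i] = None
        return out

    # -- the decision tree --------------------------------------------------
    def classify_record(self, record: CasualtyRecord) -> TriageCategory:
        """Run one casualty through the tree.

        Raises
        ------
        MissingDataError
            Under the ``exclude`` policy, when a field needed to reach a
            decision is absent.  Steps after a decisive one are never
            consulted, so their fields may be missing without consequence.
        """
        policy = self.missing_policy
        rid = record.id
        if self.use_catastrophic_haemorrhage:
            if _resolve(record.catastrophic_haemorrhage, policy,
                        "catastrophic_haemorrhage", rid, normal=False, abnormal=True):
                return TriageCategory.P1
        # Missing ambulation never routes to P3: under either lenient policy the
        # casualty proceeds to the physiological assessment (the conservative
        # reading of the non-ambulant registry assumption).
        walking = False if self.assume_non_ambulant else _resolve(
            record.can_walk, policy, "can_walk", rid, normal=False, abnormal=False)
        if walking:
            return TriageCategory.P3
        breathing = _resolve(record.breathing_after_airway_opened, policy,
                             "breathing_after_airway_opened", rid,
                             normal=True, abnormal=False)
        if not breathing:
            return TriageCategory.DEAD
        if self.conscious_rule != "none" and not self._alert(record):
            return TriageCategory.P1
        if self._rr_positive(record):
            return TriageCategory.P1
        if self._hr_positive(record):
            return TriageCategory.P1
        return TriageCategory.P2

    def _alert(self, record: CasualtyRecord) -> bool:
        if self.conscious_rule == "gcs_lt_14":
            if record.gcs_total is not None:
                return record.gcs_total >= _GCS_ALERT_THRESHOLD
            if record.avpu is not None:
                return record.avpu is AVPU.ALERT
        else:  # not_alert: AVPU takes precedence
            if record.avpu is not None:
                return record.avpu is AVPU.ALERT
            if record.gcs_total is not None:
                return record.gcs_total >= _GCS_ALERT_THRESHOLD
        return _resolve(None, self.missing_policy, "conscious level", record.id,
                        normal=True, abnormal=False)

    def _rr_positive(self, record: CasualtyRecord) -> bool:
        rr = record.rr_bpm
        if rr is None:
            return not _resolve(None, self.missing_policy, "rr_bpm", record.id,
                                normal=True, abnormal=False)
        if rr < self.rr_low:
            return True
        return rr >= self.rr_high if self.rr_high_inclusive else rr > self.rr_high

    def _hr_positive(self, record: CasualtyRecord) -> bool:
        hr = record.hr_bpm
        if hr is None:
            return not _resolve(None, self.missing_policy, "hr_bpm", record.id,
                                normal=True, abnormal=False)
        return hr >= self.hr_high if self.hr_high_inclusive else hr > self.hr_high


class MPTTClassifier(TriageTreeClassifier):
    """Modified Physiological Triage Tool: GCS < 14, RR < 12 or >= 22, HR >= 100."""

    def __init__(self, missing_policy: str = "exclude",
                 assume_non_ambulant: bool = False):
        super().__init__(
            rr_low=12, rr_high=22, rr_high_inclusive=True,
            hr_high=100, hr_high_inclusive=True,
            conscious_rule="gcs_lt_14", use_catastrophic_haemorrhage=False,
            missing_policy=missing_policy, assume_non_ambulant=assume_non_ambulant,
        )


class MPTT24Classifier(TriageTreeClassifier):
    """MPTT-24: catastrophic haemorrhage step, AVPU conscious level, RR >= 24."""

    def __init__(self, missing_policy: str = "exclude",
                 assume_non_ambulant: bool = False):
        super().__init__(
            rr_low=12, rr_high=24, rr_high_inclusive=True,
            hr_high=100, hr_high_inclusive=True,
            conscious_rule="not_alert", use_catastrophic_haemorrhage=True,
            missing_policy=missing_policy, assume_non_ambulant=assume_non_ambulant,
        )


class MilitarySieveClassifier(TriageTreeClassifier):
    """UK Military Sieve: RR band 10-29 inclusive passes, P1 on HR > 120."""

    def __init__(self, missing_policy: str = "exclude",
                 assume_non_ambulant: bool = False):
        super().__init__(
            rr_low=10, rr_high=29, rr_high_inclusive=False,
            hr_high=120, hr_high_inclusive=False,
            conscious_rule="none", use_catastrophic_haemorrhage=True,
            missing_policy=missing_policy, assume_non_ambulant=assume_non_ambulant,
        )


class RespiratoryRateClassifier(ClassifierMixin, BaseEstimator):
    """Bare RR-threshold pseudo-tool: P1 iff RR >= ``rr_high``, else P2.

    Used to study an upper respiratory-rate cut-off in isolation, independent
    of the rest of any triage tree.
    """

    def __init__(self, rr_high: int = 24, missing_policy: str = "exclude"):
        self.rr_high = rr_high
        self.missing_policy = missing_policy

    def fit(self, X=None, y=None):
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
        if self.rr_high <= 0:
            raise ValueError("rr_high must be positive")
        self.classes_ = np.array([TriageCategory.P1.value, TriageCategory.P2.value])
        return self

    def classify_record(self, record: CasualtyRecord) -> TriageCategory:
        rr = record.rr_bpm
        if rr is None:
            positive = not _resolve(None, self.missing_policy, "rr_bpm", record.id,
                                    normal=True, abnormal=False)
        else:
            positive = rr >= self.rr_high
        return TriageCategory.P1 if positive else TriageCategory.P2

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        records = _as_records(X)
        out = np.empty(len(records), dtype=object)
        for i, rec in enumerate(records):
            try:
                out[i] = self.classify_record(rec).value
            except MissingDataError:
                out[i] = None
        return out


# -- functional surface ------------------------------------------------------

TOOL_NAMES = ("mptt", "mptt24", "uk_military_sieve", "rr22", "rr24")

_FACTORIES = {
    "mptt": lambda **kw: MPTTClassifier(**kw),
    "mptt24": lambda **kw: MPTT24Classifier(**kw),
    "uk_military_sieve": lambda **kw: MilitarySieveClassifier(**kw),
    "sieve": lambda **kw: MilitarySieveClassifier(**kw),
    "rr22": lambda **kw: RespiratoryRateClassifier(
        rr_high=22, missing_policy=kw.get("missing_policy", "exclude")),
    "rr24": lambda **kw: RespiratoryRateClassifier(
        rr_high=24, missing_policy=kw.get("missing_policy", "exclude")),
}


def make_classifier(tool: str, **kwargs):
    """Instantiate and fit a triage classifier by short name."""
    try:
        factory = _FACTORIES[tool]
    except KeyError:
        raise ValueError(
            f"unknown tool {tool!r}; expected one of {sorted(_FACTORIES)}") from None
    return factory(**kwargs).fit()


def _as_records(X) -> Sequence[CasualtyRecord]:
    if isinstance(X, CasualtyRecord):
        return [X]
    if hasattr(X, "columns"):  # DataFrame
        from .io import records_from_frame
        return records_from_frame(X)
    return list(X)


def classify_mptt(record: CasualtyRecord, **kwargs) -> TriageCategory:
    """Classify one casualty with the MPTT."""
    return MPTTClassifier(**kwargs).fit().classify_record(record)


def classify_mptt24(record: CasualtyRecord, **kwargs) -> TriageCategory:
    """Classify one casualty with the MPTT-24."""
    return MPTT24Classifier(**kwargs).fit().classify_record(record)


def classify_uk_military_sieve(record: CasualtyRecord, **kwargs) -> TriageCategory:
    """Classify one casualty with the UK Military Sieve."""
    return MilitarySieveClassifier(**kwargs).fit().classify_record(record)


def classify_cohort(
    records: Iterable[CasualtyRecord],
    tool: str,
    missing_policy: str = "exclude",
    assume_non_ambulant: bool = False,
) -> Tuple[List[Optional[TriageCategory]], int]:
    """Classify a cohort element-wise, preserving order.

    Returns
    -------
    categories : list of TriageCategory or None
        One entry per record; None marks a record excluded under the
        ``exclude`` missing-data policy.
    n_excluded : int
        Number of excluded records.
    """
    kwargs = dict(missing_policy=missing_policy)
    if tool not in ("rr22", "rr24"):
        kwargs["assume_non_ambulant"] = assume_non_ambulant
    clf = make_classifier(tool, **kwargs)
    categories: List[Optional[TriageCategory]] = []
    n_excluded = 0
    for rec in records:
        try:
            categories.append(clf.classify_record(rec))
        except MissingDataError:
            categories.append(None)
            n_excluded += 1
    return categories, n_excluded
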