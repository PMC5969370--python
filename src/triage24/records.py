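"""Casualty records, the LSI-defined Priority One ground truth, and the GCS/AVPU bridge.

A casualty record carries the handful of observations that primary major-incident
triage tools consume: ambulatory status, catastrophic external haemorrhage,
breathing after an airway-opening manoeuvre, respiratory rate (breaths/min),
heart rate (beats/min), and conscious level as either a total Glasgow Coma Scale
score (3-15) or an AVPU level.  Ground truth for "Priority One" is defined by
receipt of at least one life-saving intervention (LSI) from a consensus-derived
vocabulary, which ships as an editable YAML registry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional

import yaml

__all__ = [
    "AVPU",
    "TriageCategory",
    "CasualtyRecord",
    "LSIRegistry",
    "MissingDataError",
    "is_priority_one",
    "is_alert",
    "rr_from_count",
    "load_default_lsi_registry",
]


class MissingDataError(ValueError):
    """A field required to reach a triage decision is absent from the record."""


class AVPU(str, Enum):
    """Four-level conscious-level scale: Alert / Voice / Pain / Unresponsive."""

    ALERT = "A"
    VOICE = "V"
    PAIN = "P"
    UNRESPONSIVE = "U"


class TriageCategory(str, Enum):
    """Ordinal outcome of a primary triage tool.

    The binary collapse used throughout the diagnostic-accuracy analysis maps
    P1 to positive and everything else (P2, P3, DEAD) to negative.
    """

    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    DEAD = "DEAD"

    @property
    def is_p1(self) -> bool:
        return self is TriageCategory.P1


_GCS_ALERT_THRESHOLD = 14  # GCS >= 14 corresponds to Alert; GCS < 14 to not-Alert


@dataclass
class CasualtyRecord:
    """One casualty's triage-relevant observations and received interventions.

    All physiological fields are optional: registry extracts are incomplete and
    the missing-data policy of the evaluation layer decides what to do with
    records that cannot be classified.

    Parameters
    ----------
    id : str
        Opaque record identifier.
    age_years : float, optional
        Age in years; must be non-negative when present.
    can_walk : bool, optional
        Whether the casualty is ambulatory.
    catastrophic_haemorrhage : bool, optional
        Exsanguinating external haemorrhage controllable by tourniquet or
        haemostatic dressing.
    breathing_after_airway_opened : bool, optional
        Whether the casualty breathes once the airway is opened.
    rr_bpm : int, optional
        Respiratory rate, breaths per minute (>= 0).
    hr_bpm : int, optional
        Heart rate, beats per minute (>= 0).
    gcs_total : int, optional
        Total Glasgow Coma Scale score, 3-15.
    avpu : AVPU or str, optional
        Conscious level on the AVPU scale.
    interventions : frozenset of str
        Codes of interventions the casualty received (possibly empty).
    """

    id: str
    age_years: Optional[float] = None
    can_walk: Optional[bool] = None
    catastrophic_haemorrhage: Optional[bool] = None
    breathing_after_airway_opened: Optional[bool] = None
    rr_bpm: Optional[int] = None
    hr_bpm: Optional[int] = None
    gcs_total: Optional[int] = None
    avpu: Optional[AVPU] = None
    interventions: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"age_years must be non-negative, got {self.age_years}")
        if self.rr_bpm is not None and self.rr_bpm < 0:
            raise ValueError(f"rr_bpm must be non-negative, got {self.rr_bpm}")
        if self.hr_bpm is not None and self.hr_bpm < 0:
            raise ValueError(f"hr_bpm must be non-negative, got {self.hr_bpm}")
        if self.gcs_total is not None and not (3 <= self.gcs_total <= 15):
            raise ValueError(f"gcs_total must lie in [3, 15], got {self.gcs_total}")
        if self.avpu is not None and not isinstance(self.avpu, AVPU):
            self.avpu = AVPU(str(self.avpu).upper())
        self.interventions = frozenset(self.interventions)
        # AVPU and GCS should agree on the alert split; a mismatch is a
        # data-quality warning, not an error (AVPU wins downstream).
        if self.avpu is not None and self.gcs_total is not None:
            avpu_alert = self.avpu is AVPU.ALERT
            gcs_alert = self.gcs_total >= _GCS_ALERT_THRESHOLD
            if avpu_alert != gcs_alert:
                warnings.warn(
                    f"record {self.id!r}: AVPU={self.avpu.value} disagrees with "
                    f"GCS={self.gcs_total} on the alert/GCS>=14 split; "
                    "AVPU takes precedence",
                    UserWarning,
                    stacklevel=2,
                )


@dataclass(frozen=True)
class LSIRegistry:
    """Vocabulary of life-saving-intervention codes with human-readable labels."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("LSI registry must not be empty")

    @property
    def codes(self) -> frozenset:
        return frozenset(self.labels)

    def __contains__(self, code: str) -> bool:
        return code in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_yaml(cls, path) -> "LSIRegistry":
        """Load a registry from a YAML file of ``{interventions: {code: label}}``."""
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(labels=dict(payload["interventions"]))


def load_default_lsi_registry() -> LSIRegistry:
    """Load the packaged default LSI vocabulary.

    The default is a reconstruction of the published consensus list of
    life-saving interventions that defines the Priority One casualty; registries
    encode interventions differently, so in real use the registry file is
    expected to be replaced or mapped to local codes.
    """
    ref = resources.files("triage24.data").joinpath("lsi_registry.yaml")
    with resources.as_file(ref) as path:
        return LSIRegistry.from_yaml(path)


def is_priority_one(record: CasualtyRecord, registry: LSIRegistry) -> bool:
    """True iff the casualty received at least one registry-listed LSI.

    This is the ground-truth definition of a Priority One casualty: an empty
    intervention set, or a set disjoint from the registry, is a valid negative.
    """
    return bool(record.interventions & registry.codes)


def is_alert(record: CasualtyRecord) -> bool:
    """Binary conscious-level split used by the triage tools.

    AVPU takes precedence when present (``avpu == A``); otherwise the legacy
    GCS pathway is used with the equivalent split ``gcs_total >= 14`` (the
    alert / responds-to-voice division sits at a median GCS of 13, so GCS < 14
    is the not-alert side).

    Raises
    ------
    MissingDataError
        If neither AVPU nor GCS is recorded.
    """
    if record.avpu is not None:
        return record.avpu is AVPU.ALERT
    if record.gcs_total is not None:
        return record.gcs_total >= _GCS_ALERT_THRESHOLD
    raise MissingDataError(f"record {record.id!r}: neither AVPU nor GCS recorded")


def rr_from_count(breath_count: int, window_seconds: int) -> int:
    """Convert a breath count over a short window to breaths per minute.

    Field practice is a 15-second count multiplied by four (or 10 seconds
    multiplied by six); only windows dividing 60 s are meaningful.
    """
    if window_seconds not in (10, 15, 30, 60):
        raise ValueError(f"unsupported counting window: {window_seconds} s")
    if breath_count < 0:
        raise ValueError("breath_count must be non-negative")
    return breath_count * (60 // window_seconds)


def truth_labels(records: Iterable[CasualtyRecord], registry: LSIRegistry) -> list:
    """LSI-defined Priority One labels for a cohort, in input order."""
    return [is_priority_one(r, registry) for r in records]
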