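"""Synthetic registry-like casualty cohorts with analytically known operating points.

The real evaluation populations are governed trauma registries (a deployed
military registry and a national civilian trauma audit) that cannot be
redistributed, so this module generates cohorts that emulate their coarse
structure: a Priority One prevalence (47.6% military-like, 19.5%
civilian-like) and class-conditional physiology distributions chosen so that
the triage tools land near published operating points.

The generative model is deliberately simple and fully enumerable:

* true P1 status ~ Bernoulli(prevalence);
* given class, RR and HR are independent discretised normals (a normal
  rounded to the nearest integer, clipped at zero) and conscious level,
  catastrophic haemorrhage, apnoea and ambulation are independent Bernoullis;
* true-P1 casualties receive a sentinel life-saving-intervention code, so the
  LSI ground-truth pathway is exercised end to end rather than bypassed.

Class-conditional independence of the physiology fields is an assumption (the
emulated registries publish only marginal summaries); see the methods note for
what this simulator does and does not reproduce.  Because every field is
discrete, each tool's sensitivity and specificity under the model can be
computed exactly by summation (`analytic_operating_point`), giving an
independent oracle for the Monte-Carlo evaluation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml
from scipy import stats

from .records import AVPU, CasualtyRecord

__all__ = [
    "ClassParams",
    "CohortParams",
    "generate",
    "analytic_operating_point",
    "load_preset",
    "PRESET_NAMES",
    "SENTINEL_LSI_CODE",
]

#: Intervention code injected into generated true-P1 records.
SENTINEL_LSI_CODE = "lsi_sentinel"

PRESET_NAMES = ("jttr-like", "tarn-like")


@dataclass(frozen=True)
class ClassParams:
    """Physiology distribution for one class (true P1 or not).

    RR and HR are discretised normals: integer k has the probability mass of
    the normal on [k-1/2, k+1/2), with all negative mass collected at 0.
    """

    rr_mean: float
    rr_sd: float
    hr_mean: float
    hr_sd: float
    alert_prob: float
    cathaem_prob: float = 0.0
    apnoea_prob: float = 0.0
    walking_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_sd <= 0 or self.hr_sd <= 0:
            raise ValueError("rr_sd and hr_sd must be positive")
        for name in ("alert_prob", "cathaem_prob", "apnoea_prob", "walking_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of a registry-like population."""

    n: int
    p1_prevalence: float
    p1: ClassParams
    not_p1: ClassParams
    missing_rates: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 < self.p1_prevalence < 1:
            raise ValueError("p1_prevalence must lie strictly in (0, 1)")
        for f, p in self.missing_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missing rate for {f!r} must lie in [0, 1]")


_MISSABLE_FIELDS = (
    "can_walk", "catastrophic_haemorrhage", "breathing_after_airway_opened",
    "rr_bpm", "hr_bpm", "gcs_total", "avpu",
)


def _discretised_normal_pmf(mean: float, sd: float) -> np.ndarray:
    """Probability mass over integers 0..K for a rounded, zero-clipped normal."""
    hi = int(np.ceil(mean + 10 * sd))
    edges = np.arange(0, hi + 1) + 0.5
    cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
    pmf = np.diff(np.concatenate([[0.0], cdf]))
    pmf[0] = cdf[0]  # all negative mass lands on 0
    pmf[-1] += 1.0 - cdf[-1]
    return pmf


def generate(params: CohortParams) -> Tuple[List[CasualtyRecord], List[bool]]:
    """Draw a cohort of casualty records plus their generative P1 labels.

    The returned labels coincide with the LSI-defined ground truth because
    true-P1 records carry the sentinel LSI code.  Reproducible: the same
    ``params`` (including seed) yields the identical cohort.
    """
    rng = np.random.default_rng(params.seed)
    truth = rng.random(params.n) < params.p1_prevalence
    records: List[CasualtyRecord] = []
    for i in range(params.n):
        cls = params.p1 if truth[i] else params.not_p1
        rr = int(max(0, np.rint(rng.normal(cls.rr_mean, cls.rr_sd))))
        hr = int(max(0, np.rint(rng.normal(cls.hr_mean, cls.hr_sd))))
        alert = rng.random() < cls.alert_prob
        fields = dict(
            can_walk=bool(rng.random() < cls.walking_prob),
            catastrophic_haemorrhage=bool(rng.random() < cls.cathaem_prob),
            breathing_after_airway_opened=not bool(rng.random() < cls.apnoea_prob),
            rr_bpm=rr,
            hr_bpm=hr,
            gcs_total=15 if alert else 10,
            avpu=AVPU.ALERT if alert else AVPU.VOICE,
        )
        for name in _MISSABLE_FIELDS:
            rate = params.missing_rates.get(name, 0.0)
            if rate and rng.random() < rate:
                fields[name] = None
        records.append(CasualtyRecord(
            id=f"syn-{i:06d}",
            interventions=frozenset({SENTINEL_LSI_CODE}) if truth[i] else frozenset(),
            **fields,
        ))
    return records, [bool(t) for t in truth]


def _p1_probability(cls: ClassParams, clf, assume_non_ambulant: bool) -> float:
    """Exact P(tool says P1 | class) under the generative model."""
    rr_pmf = _discretised_normal_pmf(cls.rr_mean, cls.rr_sd)
    hr_pmf = _discretised_normal_pmf(cls.hr_mean, cls.hr_sd)
    rr_k = np.arange(rr_pmf.size)
    hr_k = np.arange(hr_pmf.size)

    if not hasattr(clf, "rr_low"):  # bare RR-threshold pseudo-tool
        return float(rr_pmf[rr_k >= clf.rr_high].sum())

    if clf.rr_high_inclusive:
        rr_in_band = (rr_k >= clf.rr_low) & (rr_k < clf.rr_high)
    else:
        rr_in_band = (rr_k >= clf.rr_low) & (rr_k <= clf.rr_high)
    p_rr_ok = float(rr_pmf[rr_in_band].sum())
    hr_ok = hr_k < clf.hr_high if clf.hr_high_inclusive else hr_k <= clf.hr_high
    p_hr_ok = float(hr_pmf[hr_ok].sum())
    p_alert = cls.alert_prob if clf.conscious_rule != "none" else 1.0

    p = 0.0
    survive = 1.0
    if clf.use_catastrophic_haemorrhage:
        p += survive * cls.cathaem_prob
        survive *= 1.0 - cls.cathaem_prob
    if not assume_non_ambulant:
        survive *= 1.0 - cls.walking_prob  # walkers exit as P3
    survive *= 1.0 - cls.apnoea_prob  # apnoeic casualties exit as DEAD
    p += survive * (1.0 - p_alert * p_rr_ok * p_hr_ok)
    return p


def analytic_operating_point(
    params: CohortParams,
    tool: str,
    assume_non_ambulant: bool = True,
) -> Tuple[float, float]:
    """Exact (sensitivity, specificity) of a tool under the generative model.

    Computed by summation over the discrete joint physiology distribution
    (fields independent given class), with no simulation: the oracle against
    which Monte-Carlo evaluation on generated cohorts converges.
    """
    from .tools import make_classifier

    clf = make_classifier(tool)
    sens = _p1_probability(params.p1, clf, assume_non_ambulant)
    spec = 1.0 - _p1_probability(params.not_p1, clf, assume_non_ambulant)
    return sens, spec


def load_preset(name: str, n: int = 10_000, seed: int = 0,
                missing_rates: Optional[Dict[str, float]] = None) -> CohortParams:
    """Load a packaged cohort preset ("jttr-like" or "tarn-like")."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    ref = resources.files("triage24.data.cohorts").joinpath(
        name.replace("-", "_") + ".yaml")
    with resources.as_file(ref) as path:
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
    return CohortParams(
        n=n,
        p1_prevalence=payload["p1_prevalence"],
        p1=ClassParams(**payload["p1"]),
        not_p1=ClassParams(**payload["not_p1"]),
        missing_rates=missing_rates or {},
        seed=seed,
    )
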