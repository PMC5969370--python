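"""CSV/YAML I/O: casualty-record tables, rejects reporting, threshold configs.

Casualty CSVs have one column per record field, with missing values as empty
cells and the intervention list as a ``|``-separated code string.  Column names
can be remapped via a schema dictionary because registry exports vary.
Malformed rows are not fatal: they are collected into a rejects table with row
numbers and reasons.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .records import AVPU, CasualtyRecord
from .tools import TriageTreeClassifier

__all__ = [
    "read_casualties",
    "write_casualties",
    "records_from_frame",
    "frame_from_records",
    "load_thresholds",
    "classifier_from_config",
    "INTERVENTION_SEPARATOR",
]

INTERVENTION_SEPARATOR = "|"

_BOOL_FIELDS = ("can_walk", "catastrophic_haemorrhage", "breathing_after_airway_opened")
_INT_FIELDS = ("rr_bpm", "hr_bpm", "gcs_total")
_COLUMNS = ("id", "age_years", *_BOOL_FIELDS, *_INT_FIELDS, "avpu", "interventions")

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(raw: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _row_to_record(row: pd.Series, index) -> CasualtyRecord:
    kwargs: Dict[str, object] = {}
    rid = row.get("id")
    kwargs["id"] = str(rid) if not _is_missing(rid) else f"row-{index}"
    if not _is_missing(row.get("age_years")):
        kwargs["age_years"] = float(row["age_years"])
    for f in _BOOL_FIELDS:
        if f in row and not _is_missing(row[f]):
            kwargs[f] = _parse_bool(row[f])
    for f in _INT_FIELDS:
        if f in row and not _is_missing(row[f]):
            kwargs[f] = int(float(row[f]))
    if "avpu" in row and not _is_missing(row["avpu"]):
        kwargs["avpu"] = AVPU(str(row["avpu"]).strip().upper())
    iv = row.get("interventions")
    if not _is_missing(iv):
        codes = [c.strip() for c in str(iv).split(INTERVENTION_SEPARATOR)]
        kwargs["interventions"] = frozenset(c for c in codes if c)
    return CasualtyRecord(**kwargs)


def records_from_frame(
    frame: pd.DataFrame,
    schema: Optional[Dict[str, str]] = None,
) -> List[CasualtyRecord]:
    """Convert a DataFrame to records, raising on the first malformed row.

    ``schema`` maps canonical field names to the frame's column names.
    """
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    return [_row_to_record(row, idx) for idx, row in frame.iterrows()]


def read_casualties(
    path,
    schema: Optional[Dict[str, str]] = None,
) -> Tuple[List[CasualtyRecord], pd.DataFrame]:
    """Read a casualty CSV, separating well-formed records from rejects.

    Returns
    -------
    records : list of CasualtyRecord
        Successfully parsed rows, in file order.
    rejects : DataFrame
        One row per malformed input row: ``row`` (0-based data-row number)
        and ``reason``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    if "id" not in frame.columns:
        raise ValueError(f"{path}: mandatory column 'id' missing")
    records: List[CasualtyRecord] = []
    rejects: List[Dict[str, object]] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            records.append(_row_to_record(row, i))
        except (ValueError, KeyError) as exc:
            rejects.append({"row": i, "reason": str(exc)})
    return records, pd.DataFrame(rejects, columns=["row", "reason"])


def frame_from_records(records: Iterable[CasualtyRecord]) -> pd.DataFrame:
    """Tabulate records with one column per field (inverse of parsing)."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "age_years": r.age_years,
            "can_walk": r.can_walk,
            "catastrophic_haemorrhage": r.catastrophic_haemorrhage,
            "breathing_after_airway_opened": r.breathing_after_airway_opened,
            "rr_bpm": r.rr_bpm,
            "hr_bpm": r.hr_bpm,
            "gcs_total": r.gcs_total,
            "avpu": r.avpu.value if r.avpu is not None else None,
            "interventions": INTERVENTION_SEPARATOR.join(sorted(r.interventions)),
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_casualties(records: Sequence[CasualtyRecord], path) -> None:
    """Write records as CSV; booleans as true/false, missing as empty cells."""
    frame = frame_from_records(records)
    for f in _BOOL_FIELDS:
        frame[f] = frame[f].map(
            lambda v: "" if _is_missing(v) else ("true" if v else "false"))
    for f in _INT_FIELDS:
        frame[f] = frame[f].map(lambda v: "" if _is_missing(v) else str(int(v)))
    frame.to_csv(path, index=False)


def load_thresholds(path=None) -> Dict[str, dict]:
    """Load a tool-threshold config; the packaged default if ``path`` is None."""
    if path is None:
        ref = resources.files("triage24.data").joinpath("thresholds.yaml")
        with resources.as_file(ref) as p:
            with open(p, "r", encoding="utf-8") as fh:
                return yaml.safe_load(fh)
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def classifier_from_config(
    tool: str,
    path=None,
    missing_policy: str = "exclude",
    assume_non_ambulant: bool = False,
) -> TriageTreeClassifier:
    """Build a fitted triage tree from a threshold-config block."""
    config = load_thresholds(path)
    if tool not in config:
        raise ValueError(f"tool {tool!r} not present in threshold config")
    return TriageTreeClassifier(
        **config[tool],
        missing_policy=missing_policy,
        assume_non_ambulant=assume_non_ambulant,
    ).fit()
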