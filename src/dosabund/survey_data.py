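"""Data model, tabular I/O, validation, and collar-detection matching.

A double-observer sightability (DOS) survey records, for every detected
bison group, which of the two observers saw it, the group size each
observer counted, a photo-confirmed best size, whether the group carried a
GPS telemetry collar (the "radio observer" pseudo-occasion), and sighting
covariates.  Uncollared groups missed by both observers never enter the
data — that observation filter is the reason the estimator conditions on
detection.  Collared groups are always in the sample because the radio
occasion detects them with probability 1.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupRecord",
    "SurveyDataset",
    "TelemetryFix",
    "TableDialect",
    "MatchResult",
    "SurveyValidationError",
    "read_survey_table",
    "write_survey_table",
    "validate_dataset",
    "match_collar_detections",
    "read_telemetry_table",
]

#: Canonical column order of the survey CSV.  ``size_source`` is an optional
#: provenance column: it names where ``size_best`` came from for groups that
#: neither observer saw (e.g. the other survey platform, or telemetry).
CSV_COLUMNS = [
    "group_id",
    "survey_id",
    "detected_obs1",
    "detected_obs2",
    "collared",
    "size_obs1",
    "size_obs2",
    "size_best",
    "forest",
    "pct_conceal",
    "pct_snow",
    "moving",
    "size_imputed",
    "size_source",
]

_BINARY_FIELDS = ("detected_obs1", "detected_obs2", "collared", "size_imputed")
_OPTIONAL_BINARY_FIELDS = ("forest", "moving")
_FRACTION_FIELDS = ("pct_conceal", "pct_snow")


class SurveyValidationError(ValueError):
    """Raised when a survey table contains invalid rows.

    Carries the full list of row-indexed messages in ``issues``.
    """

    def __init__(self, issues: Sequence[str]):
        self.issues = list(issues)
        super().__init__("; ".join(self.issues))


@dataclass
class GroupRecord:
    """One surveyed bison group: capture history, sizes, covariates.

    The capture history over the three occasions (radio observer,
    observer 1, observer 2) is encoded by ``collared``, ``detected_obs1``
    and ``detected_obs2``.  An uncollared group missed by both observers
    is unobservable and therefore invalid as a record.
    """

    group_id: str
    survey_id: str = ""
    detected_obs1: int = 0
    detected_obs2: int = 0
    collared: int = 0
    size_obs1: int | None = None
    size_obs2: int | None = None
    size_best: int = 1
    forest: int | None = None
    pct_conceal: float | None = None
    pct_snow: float | None = None
    moving: int | None = None
    size_imputed: int = 0
    size_source: str | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        issues: list[str] = []
        gid = self.group_id
        for name in _BINARY_FIELDS:
            v = getattr(self, name)
            if v not in (0, 1):
                issues.append(f"group {gid!r}: {name} must be 0 or 1, got {v!r}")
        for name in _OPTIONAL_BINARY_FIELDS:
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                issues.append(f"group {gid!r}: {name} must be 0, 1 or missing, got {v!r}")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                issues.append(f"group {gid!r}: {name} must lie in [0, 1], got {v!r}")
        for name in ("size_obs1", "size_obs2"):
            v = getattr(self, name)
            if v is not None and (v != int(v) or v < 0):
                issues.append(f"group {gid!r}: {name} must be a nonnegative integer")
        if self.size_best is None or self.size_best != int(self.size_best) or self.size_best < 1:
            issues.append(f"group {gid!r}: size_best must be a positive integer")
        if issues:
            return issues  # skip logical checks on malformed fields
        if not (self.detected_obs1 or self.detected_obs2 or self.collared):
            issues.append(
                f"group {gid!r}: unobservable record — detected by neither observer "
                "and not collared"
            )
        if not self.detected_obs1 and not self.detected_obs2:
            if not self.size_imputed and not self.size_source:
                issues.append(
                    f"group {gid!r}: undetected by both observers but size_best has "
                    "no source (set size_imputed=1 or declare size_source)"
                )
        return issues

    @property
    def detected_any(self) -> bool:
        return bool(self.detected_obs1 or self.detected_obs2)


@dataclass
class SurveyDataset:
    """An ordered, validated collection of :class:`GroupRecord` for one fit."""

    records: list[GroupRecord]
    survey_label: str = ""

    @property
    def n_groups(self) -> int:
        return len(self.records)

    @property
    def n_collared(self) -> int:
        return sum(r.collared for r in self.records)

    @property
    def total_size_best(self) -> int:
        """Minimum number of individuals known present (the count M)."""
        return int(sum(r.size_best for r in self.records))

    def validate(self) -> list[str]:
        issues: list[str] = []
        seen: set[str] = set()
        for r in self.records:
            if r.group_id in seen:
                issues.append(f"duplicate group_id {r.group_id!r}")
            seen.add(r.group_id)
            issues.extend(r.validate())
        return issues

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, survey_label: str = "") -> "SurveyDataset":
        records = []
        for _, row in df.iterrows():
            records.append(_record_from_mapping(row))
        return cls(records=records, survey_label=survey_label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyDataset):
            return NotImplemented
        return self.records == other.records and self.survey_label == other.survey_label


@dataclass(frozen=True)
class TelemetryFix:
    """One GPS collar location fix (planar coordinates, metres)."""

    collar_id: str
    timestamp: pd.Timestamp
    x: float
    y: float


@dataclass
class TableDialect:
    """How a survey/telemetry table on disk maps to the canonical schema."""

    delimiter: str = ","
    #: file column name -> canonical column name
    column_map: dict[str, str] = field(default_factory=dict)
    #: timezone applied to naive timestamps ("local" accepts naive as-is)
    timezone: str = "local"


def _to_int(value, *, allow_missing: bool) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if allow_missing:
            return None
        raise ValueError("missing value where an integer is required")
    f = float(value)
    if f != int(f):
        raise ValueError(f"non-integer value {value!r}")
    return int(f)


def _to_float(value) -> float | None:
    if value is None or value == "":
        return None
    f = float(value)
    if math.isnan(f):
        return None
    return f


def _record_from_mapping(row: Mapping) -> GroupRecord:
    def get(name):
        v = row.get(name) if hasattr(row, "get") else row[name]
        if isinstance(v, float) and math.isnan(v):
            return None
        return v

    src = get("size_source")
    if src is not None:
        src = str(src).strip() or None
    return GroupRecord(
        group_id=str(get("group_id")),
        survey_id=str(get("survey_id") or ""),
        detected_obs1=_to_int(get("detected_obs1"), allow_missing=False),
        detected_obs2=_to_int(get("detected_obs2"), allow_missing=False),
        collared=_to_int(get("collared"), allow_missing=False),
        size_obs1=_to_int(get("size_obs1"), allow_missing=True),
        size_obs2=_to_int(get("size_obs2"), allow_missing=True),
        size_best=_to_int(get("size_best"), allow_missing=False),
        forest=_to_int(get("forest"), allow_missing=True),
        pct_conceal=_to_float(get("pct_conceal")),
        pct_snow=_to_float(get("pct_snow")),
        moving=_to_int(get("moving"), allow_missing=True),
        size_imputed=_to_int(get("size_imputed"), allow_missing=True) or 0,
        size_source=src,
    )


_REQUIRED_COLUMNS = ("group_id", "detected_obs1", "detected_obs2", "collared", "size_best")


def read_survey_table(
    path: str | Path, dialect: TableDialect | None = None, survey_label: str = ""
) -> SurveyDataset:
    """Read and validate a survey CSV into a :class:`SurveyDataset`.

    Rows violating record invariants are collected and reported together in
    a :class:`SurveyValidationError` whose messages carry the offending row
    number and group id.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    if dialect.column_map:
        df = df.rename(columns=dialect.column_map)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyValidationError([f"missing required column(s): {', '.join(missing)}"])
    for col in CSV_COLUMNS:
        if col not in df.columns:
            df[col] = ""

    issues: list[str] = []
    records: list[GroupRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            rec = _record_from_mapping(row)
        except (ValueError, TypeError) as exc:
            issues.append(f"row {i + 1}: {exc}")
            continue
        rec_issues = rec.validate()
        if rec_issues:
            issues.extend(f"row {i + 1}: {msg}" for msg in rec_issues)
        else:
            records.append(rec)

    dataset = SurveyDataset(records=records, survey_label=survey_label or str(path))
    seen: set[str] = set()
    for i, r in enumerate(records):
        if r.group_id in seen:
            issues.append(f"row {i + 1}: duplicate group_id {r.group_id!r}")
        seen.add(r.group_id)
    if issues:
        raise SurveyValidationError(issues)
    return dataset


def write_survey_table(dataset: SurveyDataset, path: str | Path,
                       dialect: TableDialect | None = None) -> None:
    """Write a dataset to CSV; missing cells are encoded as empty strings.

    Round-trips: ``read_survey_table(write_survey_table(d)) == d``.
    """
    dialect = dialect or TableDialect()
    df = dataset.to_frame()
    out = df.copy()
    for col in ("size_obs1", "size_obs2", "forest", "moving"):
        out[col] = out[col].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(int(v)))
    for col in ("pct_conceal", "pct_snow"):
        out[col] = out[col].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v)))
    out["size_source"] = out["size_source"].map(lambda v: "" if v is None else str(v))
    out.to_csv(path, sep=dialect.delimiter, index=False)


def validate_dataset(dataset: SurveyDataset, spec=None) -> list[str]:
    """Check dataset invariants and, if ``spec`` is given, covariate completeness.

    ``spec`` is any object exposing ``required_record_fields()`` (a
    :class:`~dosabund.detection.DetectionModelSpec` in practice).  Issues are
    returned, never raised.
    """
    issues = dataset.validate()
    if spec is not None:
        for fname in spec.required_record_fields():
            for r in dataset.records:
                if getattr(r, fname) is None:
                    issues.append(
                        f"group {r.group_id!r}: covariate field {fname!r} required by "
                        f"model {spec.label!r} is missing"
                    )
    return issues


@dataclass
class MatchResult:
    """Outcome of collar-detection matching.

    ``matches`` maps detection group_id -> sorted list of collar ids;
    ``missed_collars`` lists collars with fixes in the window but no
    detection within the time/distance thresholds (missed groups).
    """

    matches: dict[str, list[str]]
    missed_collars: list[str]

    @property
    def n_matched(self) -> int:
        return sum(len(v) for v in self.matches.values())


def _as_timestamp(value) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    return ts


def match_collar_detections(
    detections: Iterable[tuple[str, object, float, float]],
    fixes: Iterable[TelemetryFix],
    max_time_gap: pd.Timedelta | str = "2h",
    max_distance: float = 1000.0,
) -> MatchResult:
    """Match survey detections to GPS-collared groups.

    A detection matches a collar iff some fix within ``max_time_gap`` of the
    detection timestamp lies within ``max_distance`` (planar metres) of the
    detection location.  Each collar is assigned to at most one detection:
    the candidate pair nearest in space wins, ties broken by smaller time
    gap, then by group id (so the result is deterministic and invariant to
    input ordering).  Collars with fixes but no admissible detection are
    reported as missed groups.

    Defaults mirror the study's 2-hour collar fix interval and a 1-km
    spatial window; both are caller-tunable conventions.
    """
    fixes = list(fixes)
    if not fixes:
        raise ValueError("empty telemetry fixes sequence")
    gap = pd.Timedelta(max_time_gap)
    if gap <= pd.Timedelta(0):
        raise ValueError("max_time_gap must be positive")
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")

    dets = sorted(
        ((str(g), _as_timestamp(t), float(x), float(y)) for g, t, x, y in detections),
        key=lambda d: d[0],
    )
    by_collar: dict[str, list[TelemetryFix]] = {}
    for f in fixes:
        by_collar.setdefault(str(f.collar_id), []).append(f)

    matches: dict[str, list[str]] = {}
    missed: list[str] = []
    for collar_id in sorted(by_collar):
        best: tuple[float, float, str] | None = None  # (distance, |dt| seconds, group_id)
        for gid, dt_ts, dx, dy in dets:
            for f in by_collar[collar_id]:
                tdiff = abs(_as_timestamp(f.timestamp) - dt_ts)
                if tdiff > gap:
                    continue
                dist = math.hypot(f.x - dx, f.y - dy)
                if dist > max_distance:
                    continue
                key = (dist, tdiff.total_seconds(), gid)
                if best is None or key < best:
                    best = key
        if best is None:
            missed.append(collar_id)
        else:
            matches.setdefault(best[2], []).append(collar_id)
    for gid in matches:
        matches[gid].sort()
    return MatchResult(matches=matches, missed_collars=missed)


def read_telemetry_table(path: str | Path, dialect: TableDialect | None = None) -> list[TelemetryFix]:
    """Read a telemetry CSV (collar_id, timestamp ISO-8601, x, y)."""
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.delimiter)
    required = ("collar_id", "timestamp", "x", "y")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyValidationError([f"missing telemetry column(s): {', '.join(missing)}"])
    ts = pd.to_datetime(df["timestamp"], errors="raise")
    fixes = [
        TelemetryFix(collar_id=str(c), timestamp=t, x=float(x), y=float(y))
        for c, t, x, y in zip(df["collar_id"], ts, df["x"], df["y"])
    ]
    fixes.sort(key=lambda f: (f.collar_id, f.timestamp))
    return fixes
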