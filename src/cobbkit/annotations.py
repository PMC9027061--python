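"""Measurement-session files and the long-format study table.

A *measurement session* is one observer's landmark selections for every
curve of one radiograph study, in one round, with one method.  Sessions
are stored as versioned JSON (schema documented in ``docs/formats.md``);
the study table aggregating all sessions is a long-format pandas
DataFrame (one row per curve × observer × round × method) stored as
CSV.  Manual film measurements carry no landmarks and enter as
angle-only curve entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .geometry import CAUDAL, CRANIAL, EndplateLine, Landmark, measure_curve

__all__ = [
    "SCHEMA_VERSION",
    "GROUPS",
    "METHODS",
    "ROUNDS",
    "TABLE_COLUMNS",
    "CurveAnnotation",
    "MeasurementSession",
    "SessionFormatError",
    "read_session",
    "write_session",
    "sessions_to_study_table",
    "read_study_table",
    "write_study_table",
    "missing_cells",
]

SCHEMA_VERSION = 1
GROUPS = ("expert", "novice")
METHODS = ("software", "manual")
ROUNDS = (1, 2, 3)
TABLE_COLUMNS = [
    "curve_id",
    "observer_id",
    "group",
    "method",
    "round",
    "cobb_deg",
    "cranial_vertebra",
    "caudal_vertebra",
]


class SessionFormatError(ValueError):
    """Schema violation in a session file; the message names the field."""


@dataclass(frozen=True)
class CurveAnnotation:
    """Candidate endplates for one curve (or a bare angle for manual).

    Software entries hold at least one cranial and one caudal candidate
    endplate; manual (film) entries hold only the angle the observer
    read off the protractor.
    """

    curve_id: str
    cranial_candidates: tuple[EndplateLine, ...] = ()
    caudal_candidates: tuple[EndplateLine, ...] = ()
    cobb_deg: float | None = None

    @property
    def angle_only(self) -> bool:
        return self.cobb_deg is not None and not self.cranial_candidates


@dataclass(frozen=True)
class MeasurementSession:
    observer_id: str
    group: str
    method: str
    round: int
    radiograph_id: str
    curves: tuple[CurveAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SessionFormatError(f"group: {self.group!r} not in {GROUPS}")
        if self.method not in METHODS:
            raise SessionFormatError(f"method: {self.method!r} not in {METHODS}")
        if self.round not in ROUNDS:
            raise SessionFormatError(f"round: {self.round!r} not in {ROUNDS}")
        seen: set[str] = set()
        for curve in self.curves:
            if curve.curve_id in seen:
                raise SessionFormatError(f"curves: duplicate curve_id {curve.curve_id!r}")
            seen.add(curve.curve_id)
            if curve.angle_only:
                if self.method != "manual":
                    raise SessionFormatError(
                        f"curves[{curve.curve_id}]: angle-only entries are only "
                        "valid for method=manual"
                    )
                continue
            if not curve.cranial_candidates or not curve.caudal_candidates:
                raise SessionFormatError(
                    f"curves[{curve.curve_id}]: needs >=1 cranial and >=1 caudal "
                    "candidate (or cobb_deg for manual)"
                )
            for role, cands in (
                ("cranial_candidates", curve.cranial_candidates),
                ("caudal_candidates", curve.caudal_candidates),
            ):
                labels = [c.vertebra for c in cands]
                if len(labels) != len(set(labels)):
                    raise SessionFormatError(
                        f"curves[{curve.curve_id}].{role}: duplicate vertebra entry"
                    )


def _require(obj: dict, key: str, ctx: str) -> Any:
    if key not in obj:
        raise SessionFormatError(f"{ctx}{key}: missing required field")
    return obj[key]


def _parse_line(obj: dict, role: str, ctx: str) -> EndplateLine:
    vertebra = _require(obj, "vertebra", ctx)
    try:
        p1 = Landmark(*map(float, _require(obj, "p1", ctx)))
        p2 = Landmark(*map(float, _require(obj, "p2", ctx)))
    except (TypeError, ValueError) as exc:
        raise SessionFormatError(f"{ctx}p1/p2: {exc}") from exc
    return EndplateLine(vertebra=str(vertebra), role=role, p1=p1, p2=p2)


def read_session(path: str | Path) -> MeasurementSession:
    """Read and fully validate a session JSON file.

    Every invariant of the data model is enforced; violations raise
    :class:`SessionFormatError` naming the offending field.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise SessionFormatError(f"{path}: top level must be an object")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SessionFormatError(f"schema_version: unsupported version {version!r}")

    curves = []
    for i, cobj in enumerate(_require(raw, "curves", "")):
        ctx = f"curves[{i}]."
        curve_id = str(_require(cobj, "curve_id", ctx))
        if "cobb_deg" in cobj and "cranial_candidates" not in cobj:
            curves.append(
                CurveAnnotation(curve_id=curve_id, cobb_deg=float(cobj["cobb_deg"]))
            )
            continue
        cranial = tuple(
            _parse_line(o, CRANIAL, f"{ctx}cranial_candidates[{j}].")
            for j, o in enumerate(_require(cobj, "cranial_candidates", ctx))
        )
        caudal = tuple(
            _parse_line(o, CAUDAL, f"{ctx}caudal_candidates[{j}].")
            for j, o in enumerate(_require(cobj, "caudal_candidates", ctx))
        )
        curves.append(
            CurveAnnotation(
                curve_id=curve_id, cranial_candidates=cranial, caudal_candidates=caudal
            )
        )

    return MeasurementSession(
        observer_id=str(_require(raw, "observer_id", "")),
        group=str(_require(raw, "group", "")),
        method=str(_require(raw, "method", "")),
        round=int(_require(raw, "round", "")),
        radiograph_id=str(_require(raw, "radiograph_id", "")),
        curves=tuple(curves),
    )


def _line_to_json(line: EndplateLine) -> dict:
    return {
        "vertebra": line.vertebra,
        "p1": [float(round(line.p1.x, 4)), float(round(line.p1.y, 4))],
        "p2": [float(round(line.p2.x, 4)), float(round(line.p2.y, 4))],
    }


def write_session(session: MeasurementSession, path: str | Path) -> Path:
    """Write a session as canonical JSON (fixed key order, 4-decimal
    coordinates, sorted keys) so output is byte-stable."""
    if not session.curves:
        raise ValueError("refusing to write a session with no curves")
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "observer_id": session.observer_id,
        "group": session.group,
        "method": session.method,
        "round": session.round,
        "radiograph_id": session.radiograph_id,
        "curves": [],
    }
    for curve in session.curves:
        if curve.angle_only:
            doc["curves"].append(
                {"curve_id": curve.curve_id, "cobb_deg": round(curve.cobb_deg, 1)}
            )
        else:
            doc["curves"].append(
                {
                    "curve_id": curve.curve_id,
                    "cranial_candidates": [
                        _line_to_json(x) for x in curve.cranial_candidates
                    ],
                    "caudal_candidates": [
                        _line_to_json(x) for x in curve.caudal_candidates
                    ],
                }
            )
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def sessions_to_study_table(
    sessions: Sequence[MeasurementSession],
    pixel_spacing: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Aggregate sessions into the long-format study table.

    Software curves are measured via the geometry pipeline; manual
    curves contribute their recorded angle.  One row per
    (curve, observer, round, method); a complete factorial design with
    35 curves, 8 observers, 3 rounds and 2 methods yields 1680 rows.
    Duplicate cells with conflicting angles raise; missing cells are
    simply absent (use :func:`missing_cells` to list them).
    """
    rows = []
    for s in sessions:
        for curve in s.curves:
            if curve.angle_only:
                angle = round(float(curve.cobb_deg), 1)
                cranial = caudal = ""
            else:
                m = measure_curve(
                    curve.curve_id,
                    curve.cranial_candidates,
                    curve.caudal_candidates,
                    pixel_spacing,
                )
                angle, cranial, caudal = m.cobb_deg, m.cranial_vertebra, m.caudal_vertebra
            rows.append(
                (curve.curve_id, s.observer_id, s.group, s.method, s.round,
                 angle, cranial, caudal)
            )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if len(table):
        key = ["curve_id", "observer_id", "method", "round"]
        dup = table.duplicated(subset=key, keep=False)
        if dup.any():
            cells = table.loc[dup, key].drop_duplicates().to_records(index=False)
            raise ValueError(f"conflicting duplicate measurements for cells: {list(cells)}")
    return table


def read_study_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"curve_id": str, "observer_id": str})
    missing = [c for c in TABLE_COLUMNS[:6] if c not in table.columns]
    if missing:
        raise ValueError(f"study table is missing columns: {missing}")
    return table


def write_study_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.1f")
    return path


def missing_cells(table: pd.DataFrame) -> list[tuple]:
    """List (curve, observer, method, round) cells absent from the full
    factorial implied by the values present in the table."""
    if not len(table):
        return []
    have = set(
        map(tuple, table[["curve_id", "observer_id", "method", "round"]].values)
    )
    out = []
    for c in sorted(table["curve_id"].unique()):
        for o in sorted(table["observer_id"].unique()):
            for m in sorted(table["method"].unique()):
                for r in sorted(table["round"].unique()):
                    if (c, o, m, r) not in have:
                        out.append((c, o, m, r))
    return out
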