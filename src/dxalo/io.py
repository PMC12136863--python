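"""CSV readers/writers for scans, clinical labels, results and configuration.

Interchange formats (all UTF-8, comma-separated, header row):

``scans.csv``
    ``patient_id,region,side,fat_mass_g,lean_mass_g,bmc_g`` — one row per
    patient x region x side; masses in grams as exported by DXA region
    analysis.
``labels.csv``
    ``patient_id,diagnosis,region,side,affected`` — clinical LO labels;
    unlabeled region-sides default to not-affected.
``results.csv``
    one row per scored (patient, region) pair plus one ``scope=aggregate``
    row per labeled patient; full-precision columns plus 1-decimal
    display columns.

Validation is total: every malformed row raises a classified
:class:`ValidationError` carrying the file line number — inputs are never
silently skipped.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    AggregateResult,
    Diagnosis,
    PatientScan,
    Region,
    RegionMeasurement,
    RegionPairResult,
    Side,
    TissueMasses,
)

__all__ = [
    "ValidationError",
    "SCAN_COLUMNS",
    "LABEL_COLUMNS",
    "read_scans",
    "read_labels",
    "write_scans",
    "write_labels",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["patient_id", "region", "side", "fat_mass_g", "lean_mass_g", "bmc_g"]
LABEL_COLUMNS = ["patient_id", "diagnosis", "region", "side", "affected"]

_REGIONS = {r.value: r for r in Region}
_SIDES = {s.value: s for s in Side}
_DIAGNOSES = {d.value: d for d in Diagnosis}
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


class ValidationError(ValueError):
    """Malformed input; message carries the file and line number."""


def _fail(path: Path | str, line: int, message: str) -> None:
    raise ValidationError(f"{path}:{line}: {message}")


def _parse_mass(token: str, column: str, path: Path | str, line: int) -> float:
    try:
        value = float(token)
    except (TypeError, ValueError):
        _fail(path, line, f"malformed number {token!r} in column {column}")
    if not math.isfinite(value):
        _fail(path, line, f"non-finite mass {token!r} in column {column}")
    if value < 0:
        _fail(path, line, f"negative mass {value} in column {column}")
    return value


def _read_rows(
    path: Path | str, required: list[str], column_map: Mapping[str, str] | None
) -> Iterable[tuple[int, dict[str, str]]]:
    """Yield (line_number, row-dict) with canonical column names.

    ``column_map`` maps vendor header names to canonical ones, so exports
    with e.g. ``Fat (g)`` headers can be ingested without rewriting.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            _fail(path, 1, "empty file, expected a header row")
        rename = dict(column_map or {})
        header = [rename.get(name, name) for name in reader.fieldnames]
        missing = [c for c in required if c not in header]
        if missing:
            _fail(path, 1, f"missing required column(s): {', '.join(missing)}")
        for line, raw in enumerate(reader, start=2):
            row = {
                rename.get(k, k): (v.strip() if isinstance(v, str) else v)
                for k, v in raw.items()
                if k is not None
            }
            if all(not v for v in row.values()):
                continue  # blank line
            yield line, row


def read_scans(
    path: Path | str, column_map: Mapping[str, str] | None = None
) -> dict[str, PatientScan]:
    """Read a scan table into one :class:`PatientScan` per patient.

    Rows are grouped by ``patient_id``; region and side tokens come from
    closed vocabularies and duplicates are rejected with line numbers.
    """
    measurements: dict[str, list[RegionMeasurement]] = {}
    seen: set[tuple[str, Region, Side]] = set()
    order: list[str] = []
    for line, row in _read_rows(path, SCAN_COLUMNS, column_map):
        pid = row.get("patient_id") or ""
        if not pid:
            _fail(path, line, "empty patient_id")
        region_token = row.get("region", "")
        if region_token not in _REGIONS:
            _fail(path, line, f"unknown region token {region_token!r}")
        side_token = row.get("side", "")
        if side_token not in _SIDES:
            _fail(path, line, f"unknown side token {side_token!r}")
        region, side = _REGIONS[region_token], _SIDES[side_token]
        key = (pid, region, side)
        if key in seen:
            _fail(path, line, f"duplicate record for {pid}/{region.value}/{side.value}")
        seen.add(key)
        masses = TissueMasses(
            adipose_g=_parse_mass(row.get("fat_mass_g", ""), "fat_mass_g", path, line),
            muscle_g=_parse_mass(row.get("lean_mass_g", ""), "lean_mass_g", path, line),
            bone_g=_parse_mass(row.get("bmc_g", ""), "bmc_g", path, line),
        )
        if pid not in measurements:
            measurements[pid] = []
            order.append(pid)
        measurements[pid].append(RegionMeasurement(region, side, masses))
    scans = {pid: PatientScan(patient_id=pid, measurements=measurements[pid]) for pid in order}
    logger.info("read %d patients (%d rows) from %s", len(scans), len(seen), path)
    return scans


def read_labels(
    path: Path | str,
    scans: dict[str, PatientScan],
    column_map: Mapping[str, str] | None = None,
) -> dict[str, PatientScan]:
    """Attach clinical labels and diagnoses to already-read scans.

    Every labeled (patient, region, side) must exist in ``scans``;
    unlabeled region-sides stay not-affected.  Returns ``scans`` mutated
    in place.
    """
    for line, row in _read_rows(path, LABEL_COLUMNS, column_map):
        pid = row.get("patient_id") or ""
        if pid not in scans:
            _fail(path, line, f"label for unknown patient {pid!r}")
        scan = scans[pid]
        diag_token = row.get("diagnosis", "")
        if diag_token not in _DIAGNOSES:
            _fail(path, line, f"unknown diagnosis token {diag_token!r}")
        scan.diagnosis = _DIAGNOSES[diag_token]
        region_token, side_token = row.get("region", ""), row.get("side", "")
        if region_token not in _REGIONS:
            _fail(path, line, f"unknown region token {region_token!r}")
        if side_token not in _SIDES:
            _fail(path, line, f"unknown side token {side_token!r}")
        region, side = _REGIONS[region_token], _SIDES[side_token]
        if scan.lookup(region, side) is None:
            _fail(
                path,
                line,
                f"label references unmeasured region-side {region.value}/{side.value} "
                f"for patient {pid}",
            )
        affected_token = (row.get("affected") or "").lower()
        if affected_token in _TRUE:
            if any(r is region for r, _ in scan.clinical_affected):
                _fail(path, line, f"both sides of {region.value} labeled affected for {pid}")
            scan.clinical_affected.add((region, side))
        elif affected_token not in _FALSE:
            _fail(path, line, f"malformed affected flag {row.get('affected')!r}")
    logger.info("labels attached from %s", path)
    return scans


def write_scans(scans: dict[str, PatientScan], path: Path | str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCAN_COLUMNS)
        for pid in scans:
            for m in scans[pid].measurements:
                writer.writerow(
                    [
                        pid,
                        m.region.value,
                        m.side.value,
                        repr(m.masses.adipose_g),
                        repr(m.masses.muscle_g),
                        repr(m.masses.bone_g),
                    ]
                )


def write_labels(scans: dict[str, PatientScan], path: Path | str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LABEL_COLUMNS)
        for pid in scans:
            scan = scans[pid]
            for region, side in sorted(
                scan.clinical_affected, key=lambda rs: (rs[0].value, rs[1].value)
            ):
                writer.writerow([pid, scan.diagnosis.value, region.value, side.value, 1])


RESULT_COLUMNS = [
    "patient_id",
    "scope",
    "region",
    "affected_side",
    "anchor",
    "diagnosis",
    "mt_affected_g",
    "mt_contra_g",
    "discrepancy_ratio",
    "rc_affected_adipose",
    "rc_affected_muscle",
    "rc_affected_bone",
    "rc_contra_adipose",
    "rc_contra_muscle",
    "rc_contra_bone",
    "delta_rc_adipose_pp",
    "delta_rc_muscle_pp",
    "delta_rc_bone_pp",
    "lo_call",
    "predominant_tissue",
    "discrepancy_display",
]


def _result_row(
    pid: str,
    diagnosis: Diagnosis,
    res: RegionPairResult | AggregateResult,
) -> list:
    if isinstance(res, AggregateResult):
        scope = "aggregate"
        region = ";".join(
            f"{r.value}:{s.value}"
            for r, s in sorted(res.regions, key=lambda rs: (rs[0].value, rs[1].value))
        )
        side, anchor = "", "clinical"
        predominant = res.predominant_tissue.value
    else:
        scope = "region"
        region = res.region.value
        side, anchor = res.affected_side.value, res.anchor
        predominant = ""
    return [
        pid,
        scope,
        region,
        side,
        anchor,
        diagnosis.value,
        repr(res.mt_affected_g),
        repr(res.mt_contra_g),
        repr(res.discrepancy_ratio),
        repr(res.rc_affected.rc_adipose),
        repr(res.rc_affected.rc_muscle),
        repr(res.rc_affected.rc_bone),
        repr(res.rc_contra.rc_adipose),
        repr(res.rc_contra.rc_muscle),
        repr(res.rc_contra.rc_bone),
        repr(res.delta_rc.d_adipose),
        repr(res.delta_rc.d_muscle),
        repr(res.delta_rc.d_bone),
        int(res.lo_call),
        predominant,
        f"{res.discrepancy_ratio * 100:.1f}%",
    ]


def write_results(
    results: dict[str, tuple[list[RegionPairResult], AggregateResult | None]],
    path: Path | str,
    diagnoses: Mapping[str, Diagnosis] | None = None,
) -> None:
    """Write scored results with deterministic column order.

    Values are written at full precision (``repr``) next to 1-decimal
    display columns, so re-reading reproduces them bit-exactly.
    """
    diagnoses = diagnoses or {}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for pid, (per_region, aggregate) in results.items():
            diag = diagnoses.get(pid, Diagnosis.OTHER)
            for res in per_region:
                writer.writerow(_result_row(pid, diag, res))
            if aggregate is not None:
                writer.writerow(_result_row(pid, diag, aggregate))


def read_results(path: Path | str) -> pd.DataFrame:
    """Read a results file back as a DataFrame (full-precision columns)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing result column(s): {', '.join(missing)}")
    return df
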