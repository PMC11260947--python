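"""Structuring step (tree builder): flat source directory -> four-level tree.

Takes a drop-off directory of loose files — NIfTI volumes named per the
filename grammar, per-patient clinical JSONs, and optionally one clinical
CSV — and files each volume under ``MAIN/<patient>/<acquisition>/<phase>/``,
creating directories as needed. Files whose names do not parse are
quarantined in place and reported; a curation batch always completes.

The clinical CSV (one row per patient) is converted to one
``<patient>.json`` per patient at level two, so each patient directory
carries its own de-identified record.

All moves are audited to a plain-text log in the MAIN directory.
"""

from __future__ import annotations

import csv
import datetime
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    CollisionError,
    DuplicatePatientRow,
    MalformedId,
    MalformedName,
    MissingIdColumn,
    SourceMissing,
)
from .naming import PATIENT_RE, parse_filename, target_path

__all__ = [
    "StructureReport",
    "structure_tree",
    "clinical_csv_to_json",
    "AUDIT_LOG_NAME",
]

AUDIT_LOG_NAME = "mds_audit.log"


@dataclass
class StructureReport:
    """Outcome of one structuring run.

    ``moved`` and ``quarantined`` partition the non-CSV files found in the
    source directory; quarantined files stay where they are.
    """

    moved: list[tuple[str, Path]] = field(default_factory=list)
    created_dirs: list[Path] = field(default_factory=list)
    quarantined: list[tuple[str, str]] = field(default_factory=list)
    json_written: int = 0

    @property
    def n_moved(self) -> int:
        return len(self.moved)

    def summary(self) -> str:
        return (
            f"moved={len(self.moved)} quarantined={len(self.quarantined)} "
            f"dirs_created={len(self.created_dirs)} json_written={self.json_written}"
        )


def _audit(main: Path, lines: list[str]) -> None:
    if not lines:
        return
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with (main / AUDIT_LOG_NAME).open("a", encoding="utf-8") as fh:
        for line in lines:
            fh.write(f"{stamp}\t{line}\n")


def _iter_source_files(source: Path):
    # Recursive scan; any directory layout inside the drop-off is ignored,
    # only the bare filename decides the destination.
    for path in sorted(source.rglob("*")):
        if path.is_file():
            yield path


def _ensure_dir(path: Path, created: list[Path]) -> None:
    missing = []
    probe = path
    while not probe.exists():
        missing.append(probe)
        probe = probe.parent
    path.mkdir(parents=True, exist_ok=True)
    created.extend(reversed(missing))


def structure_tree(
    source: Path,
    main: Path,
    collision_policy: str = "error",
    dry_run: bool = False,
) -> StructureReport:
    """Move every parseable file from ``source`` into the tree under ``main``.

    Parameters
    ----------
    source
        Drop-off directory, scanned recursively. CSV files are left alone
        (they are clinical tables handled by :func:`clinical_csv_to_json`).
        JSON files named ``<patient>.json`` move to the patient's level-two
        directory; any other JSON is quarantined.
    main
        Level-one root of the structured dataset; created if absent.
    collision_policy
        ``error`` (default; raise and stop — silently overwriting patient
        data is unacceptable), ``skip`` (leave the source file in place,
        report as quarantined), or ``overwrite``.
    dry_run
        Compute the full report without touching any file.

    Re-running on an emptied source is a no-op: the operation is idempotent.
    """
    source = Path(source)
    main = Path(main)
    if not source.is_dir():
        raise SourceMissing(f"source directory {source} does not exist")
    if collision_policy not in ("error", "skip", "overwrite"):
        raise ValueError(f"unknown collision policy {collision_policy!r}")
    if not dry_run:
        main.mkdir(parents=True, exist_ok=True)

    report = StructureReport()
    audit_lines: list[str] = []
    for path in _iter_source_files(source):
        name = path.name
        suffix = path.suffix.lower()
        if suffix == ".csv":
            continue
        if suffix == ".json":
            stem = path.stem
            if PATIENT_RE.fullmatch(stem):
                dest_dir = main / stem
            else:
                report.quarantined.append((name, "JSON not named after a patient"))
                audit_lines.append(f"QUARANTINE\t{name}\tJSON not named after a patient")
                continue
        else:
            try:
                key = parse_filename(name)
            except MalformedName as exc:
                report.quarantined.append((name, str(exc)))
                audit_lines.append(f"QUARANTINE\t{name}\t{exc}")
                continue
            dest_dir = target_path(key, main)

        dest = dest_dir / name
        if dest.exists():
            if collision_policy == "error":
                _audit(main, audit_lines)
                raise CollisionError(
                    f"{dest} already exists (from source file {name}); "
                    f"partial report: {report.summary()}"
                )
            if collision_policy == "skip":
                report.quarantined.append((name, f"destination exists: {dest}"))
                audit_lines.append(f"SKIP\t{name}\tdestination exists")
                continue
        if not dry_run:
            _ensure_dir(dest_dir, report.created_dirs)
            shutil.move(str(path), str(dest))
        else:
            probe = dest_dir
            pending = []
            while not probe.exists():
                pending.append(probe)
                probe = probe.parent
            report.created_dirs.extend(reversed(pending))
        report.moved.append((name, dest))
        audit_lines.append(f"MOVE\t{name}\t{dest}")

    if not dry_run:
        _audit(main, audit_lines)
    return report


def _coerce_cell(value: str):
    """Clinical cells stay text unless they are cleanly numeric; empty -> null."""
    if value == "":
        return None
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        return value


def clinical_csv_to_json(
    csv_path: Path,
    main: Path,
    id_column: str | None = None,
) -> int:
    """Split a one-row-per-patient clinical CSV into per-patient JSONs.

    Each row is written as ``MAIN/<patient>/<patient>.json`` with the CSV
    header as keys, in column order. ``id_column`` defaults to the first
    column. Returns the number of JSON files written.

    Raises :class:`MissingIdColumn`, :class:`MalformedId`, or
    :class:`DuplicatePatientRow` (two rows for one patient are never merged
    silently).
    """
    csv_path = Path(csv_path)
    main = Path(main)
    with csv_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if not header:
            raise MissingIdColumn(f"{csv_path} has no header row")
        if id_column is None:
            id_column = header[0]
        if id_column not in header:
            raise MissingIdColumn(
                f"id column {id_column!r} not in header {header}"
            )
        rows = list(reader)

    seen: set[str] = set()
    records: list[tuple[str, dict]] = []
    for lineno, row in enumerate(rows, start=2):
        pid = (row[id_column] or "").strip()
        if not PATIENT_RE.fullmatch(pid):
            raise MalformedId(f"{csv_path}:{lineno}: bad patient id {pid!r}")
        if pid in seen:
            raise DuplicatePatientRow(f"{csv_path}:{lineno}: duplicate row for {pid}")
        seen.add(pid)
        records.append((pid, {col: _coerce_cell(row[col]) for col in header}))

    for pid, record in records:
        patient_dir = main / pid
        patient_dir.mkdir(parents=True, exist_ok=True)
        with (patient_dir / f"{pid}.json").open("w", encoding="utf-8") as fh:
            json.dump(record, fh, indent=2, ensure_ascii=False)
            fh.write("\n")
    return len(records)
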