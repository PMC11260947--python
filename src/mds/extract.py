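"""Pseudonymized data extraction from the structured tree.

A researcher's data request is a CSV with one row per patient image
(columns ``Pat, Mod, Phase, Cl 1[, Cl 2, ...]``: patient, acquisition,
phase, and the requested image/label tags). The extractor copies each
matching file out of the tree into an output tree of the same four-level
shape, replacing the patient token with a ``CaseNNN`` pseudonym drawn from
a randomly shuffled sequence 1..N — so the order of the pseudonyms bears no
relation to the order of the request.

Two modes:

* ``anonymize`` — no key is written anywhere and the in-memory mapping is
  discarded; the export can never be linked back.
* ``deidentify`` — the patient->Case key table is written to a CSV log
  (kept in the secured system) so corrected annotations can be re-linked
  later by the reintegration step.

The source tree is never modified: extraction copies, it does not move.
"""

from __future__ import annotations

import csv
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    AmbiguousExtension,
    BadHeader,
    DuplicatePatient,
    KeyPathMissing,
    MalformedToken,
    NotAnMdsTree,
    OutputNotEmpty,
)
from .naming import ACQUISITION_RE, CASE_RE, PATIENT_RE, CaseKey, format_filename, target_path

__all__ = [
    "RequestRow",
    "KeyRow",
    "KeyTable",
    "ExtractReport",
    "read_request",
    "make_key_table",
    "write_key_table",
    "read_key_table",
    "extract_dataset",
]

@dataclass(frozen=True)
class RequestRow:
    """One line of a data request: which image/labels of which acquisition."""

    patient_id: str
    acquisition_id: str
    phase: str
    tags: tuple[str, ...]


@dataclass(frozen=True)
class KeyRow:
    patient_id: str
    acquisition_id: str
    phase: str
    tag: str
    case_id: str


@dataclass
class KeyTable:
    """The de-identification key: patient IDs <-> Case pseudonyms.

    ``rows`` mirror the request they were generated for (one row per
    requested patient/acquisition/phase/tag); the patient -> case mapping
    they induce is a bijection onto ``Case001..CaseNNN``.
    """

    rows: list[KeyRow] = field(default_factory=list)
    mode: str = "deidentify"
    seed_record: int | None = None

    @property
    def mapping(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for row in self.rows:
            prev = out.setdefault(row.patient_id, row.case_id)
            if prev != row.case_id:
                raise ValueError(
                    f"inconsistent key: {row.patient_id} maps to both {prev} and {row.case_id}"
                )
        return out

    @property
    def inverse(self) -> dict[str, str]:
        mapping = self.mapping
        inv = {case: pat for pat, case in mapping.items()}
        if len(inv) != len(mapping):
            raise ValueError("key table is not a bijection")
        return inv


@dataclass
class ExtractReport:
    """What an extraction run copied and what it could not find."""

    copied: list[tuple[Path, Path]] = field(default_factory=list)
    missing: list[tuple[RequestRow, str]] = field(default_factory=list)
    n_patients: int = 0


_HEADER_PREFIX = ("pat", "mod", "phase")


def _is_class_column(name: str) -> bool:
    n = name.strip().lower().replace(" ", "")
    return n.startswith("cl") and (n == "cl" or n[2:].isdigit())


def read_request(csv_path: Path) -> list[RequestRow]:
    """Parse a data-request CSV.

    The header must be ``Pat, Mod, Phase`` followed by one or more class
    columns (``Cl 1``, ``Cl 2``, ... — the ``Cl1`` spelling is also
    accepted). The class-column count varies with the request: an
    annotation request may ask only for the image, a training request for
    the image plus labels. Empty class cells in a row are simply absent
    requests.
    """
    csv_path = Path(csv_path)
    with csv_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise BadHeader(f"{csv_path} is empty") from None
        lines = [(i, row) for i, row in enumerate(reader, start=2) if any(c.strip() for c in row)]

    if len(header) < 4:
        raise BadHeader(f"{csv_path}: expected at least 4 columns, got {header}")
    if tuple(h.strip().lower() for h in header[:3]) != _HEADER_PREFIX:
        raise BadHeader(f"{csv_path}: header must start with Pat, Mod, Phase (got {header[:3]})")
    if not all(_is_class_column(h) for h in header[3:]):
        raise BadHeader(f"{csv_path}: columns after Phase must be class columns (got {header[3:]})")

    rows: list[RequestRow] = []
    for lineno, cells in lines:
        cells = [c.strip() for c in cells]
        if len(cells) < 4:
            raise MalformedToken(f"{csv_path}:{lineno}: row has fewer than 4 cells")
        pat, mod, phase = cells[:3]
        tags = tuple(t for t in cells[3 : len(header)] if t)
        if not PATIENT_RE.fullmatch(pat):
            raise MalformedToken(f"{csv_path}:{lineno}: bad patient token {pat!r}")
        if not ACQUISITION_RE.fullmatch(mod):
            raise MalformedToken(f"{csv_path}:{lineno}: bad acquisition token {mod!r}")
        if not phase or "_" in phase:
            raise MalformedToken(f"{csv_path}:{lineno}: bad phase token {phase!r}")
        if not tags:
            raise MalformedToken(f"{csv_path}:{lineno}: no tags requested")
        for tag in tags:
            if "_" in tag:
                raise MalformedToken(f"{csv_path}:{lineno}: bad tag token {tag!r}")
        rows.append(RequestRow(pat, mod, phase, tags))
    return rows


def _case_token(number: int, n_total: int) -> str:
    width = max(3, len(str(n_total)))
    return f"Case{number:0{width}d}"


def make_key_table(
    patient_ids: list[str],
    seed: int,
    mode: str = "deidentify",
    context: list[tuple[str, str, str, str]] | None = None,
) -> KeyTable:
    """Assign a Case pseudonym to each patient by shuffled-sequence draw.

    The sequence 1..N is shuffled with a seeded generator and consumed
    front-first in patient order; each number is used once. The result is a
    bijection patient -> Case pseudonym, deterministic for a fixed seed.

    ``context`` optionally supplies (patient, acquisition, phase, tag)
    tuples so the table's rows mirror a concrete request; without it each
    patient gets a single minimal row.
    """
    if len(set(patient_ids)) != len(patient_ids):
        dupes = sorted({p for p in patient_ids if patient_ids.count(p) > 1})
        raise DuplicatePatient(f"duplicate patient ids: {dupes}")
    if not patient_ids:
        return KeyTable(rows=[], mode=mode, seed_record=seed)

    n = len(patient_ids)
    rng = np.random.default_rng(seed)
    shuffled = [int(x) for x in rng.permutation(np.arange(1, n + 1))]
    mapping = {
        pat: _case_token(num, n) for pat, num in zip(patient_ids, shuffled)
    }

    rows: list[KeyRow] = []
    if context is None:
        for pat in patient_ids:
            rows.append(KeyRow(pat, "", "", "", mapping[pat]))
    else:
        for pat, acq, phase, tag in context:
            rows.append(KeyRow(pat, acq, phase, tag, mapping[pat]))
    return KeyTable(rows=rows, mode=mode, seed_record=seed)


_KEY_HEADER = ["Pat", "Mod", "Phase", "Cl 1", "Ns"]


def write_key_table(kt: KeyTable, path: Path) -> None:
    """Write the key log as a CSV (``Pat, Mod, Phase, Cl 1, Ns``).

    The generator seed, when recorded, is stored in a ``# seed=`` comment
    line above the header so the draw is auditable; readers that only know
    the plain dialect can skip it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if kt.seed_record is not None:
            fh.write(f"# seed={kt.seed_record}\n")
        writer = csv.writer(fh)
        writer.writerow(_KEY_HEADER)
        for row in kt.rows:
            writer.writerow([row.patient_id, row.acquisition_id, row.phase, row.tag, row.case_id])


def read_key_table(path: Path) -> KeyTable:
    """Inverse of :func:`write_key_table`."""
    path = Path(path)
    seed_record: int | None = None
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# seed="):
            seed_record = int(first.strip().split("=", 1)[1])
            first = fh.readline()
        header = next(csv.reader([first]), None)
        if header is None or [h.strip().lower() for h in header] != [
            h.lower() for h in _KEY_HEADER
        ]:
            raise BadHeader(f"{path}: expected header {_KEY_HEADER}, got {header}")
        rows = [
            KeyRow(*(c.strip() for c in cells))
            for cells in csv.reader(fh)
            if any(c.strip() for c in cells)
        ]
    return KeyTable(rows=rows, mode="deidentify", seed_record=seed_record)


def extract_dataset(
    main: Path,
    request: list[RequestRow],
    out_root: Path,
    mode: str,
    seed: int,
    key_path: Path | None = None,
) -> ExtractReport:
    """Serve a data request: copy matching files out under Case pseudonyms.

    For every requested (row, tag) the file
    ``MAIN/pat/acq/phase/pat_acq_phase_tag.<ext>`` is looked up (any
    extension; several matching extensions are an error) and copied to
    ``out_root/case/acq/phase/case_acq_phase_tag.<ext>``. Requested but
    absent files are reported as missing, never fabricated — a cohort may
    legitimately lack data for some patients.

    In ``deidentify`` mode the key table is written to ``key_path``; in
    ``anonymize`` mode no key is written anywhere.
    """
    main = Path(main)
    out_root = Path(out_root)
    if mode not in ("anonymize", "deidentify"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "deidentify" and key_path is None:
        raise KeyPathMissing("deidentify mode requires a key_path for the key log")
    if not main.is_dir():
        raise NotAnMdsTree(f"{main} is not a directory")
    if out_root.exists() and any(out_root.iterdir()):
        raise OutputNotEmpty(f"output directory {out_root} is not empty")

    patients: list[str] = []
    for row in request:
        if row.patient_id not in patients:
            patients.append(row.patient_id)
    context = [
        (row.patient_id, row.acquisition_id, row.phase, tag)
        for row in request
        for tag in row.tags
    ]
    kt = make_key_table(patients, seed, mode=mode, context=context)
    mapping = kt.mapping

    report = ExtractReport(n_patients=len(patients))
    out_root.mkdir(parents=True, exist_ok=True)
    for row in request:
        src_dir = main / row.patient_id / row.acquisition_id / row.phase
        for tag in row.tags:
            stem = f"{row.patient_id}_{row.acquisition_id}_{row.phase}_{tag}."
            matches = (
                sorted(p for p in src_dir.iterdir() if p.name.startswith(stem))
                if src_dir.is_dir()
                else []
            )
            if not matches:
                report.missing.append((row, tag))
                continue
            if len(matches) > 1:
                raise AmbiguousExtension(
                    f"multiple extensions match {stem}*: {[m.name for m in matches]}"
                )
            src = matches[0]
            ext = src.name[len(stem):]
            case = mapping[row.patient_id]
            case_key = CaseKey(case, row.acquisition_id, row.phase, tag, ext)
            dest = target_path(case_key, out_root) / format_filename(case_key)
            dest.parent.mkdir(parents=True, exist_ok=True)
            shutil.copy2(src, dest)
            report.copied.append((src, dest))

    if mode == "deidentify":
        write_key_table(kt, Path(key_path))
    # anonymize mode: kt goes out of scope here; nothing persists the mapping.
    return report
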