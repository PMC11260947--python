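"""Re-integration of manually corrected ground-truth labels.

Corrected label volumes come back from annotators named under Case
pseudonyms (they were exported de-identified, e.g.
``Case005_CT001_Porto_IM.nii.gz``). Using the key table written at
extraction time, each file is renamed back to its patient ID, the ``IM``
tag is replaced with the label's structure code (e.g. ``LP``), and the
result is staged in the drop-off directory of the structuring step — which
then files it next to the image it annotates.

Corrections are irreplaceable manual work, so every staged copy is
checksum-verified before it is reported as staged, and a file whose
pseudonym is not in the key table is skipped and reported, never guessed.
"""

from __future__ import annotations

import hashlib
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from .errors import MalformedName, TagCollision
from .extract import KeyTable
from .naming import FileKey, format_filename, parse_case_filename

__all__ = ["ReintegrationReport", "reintegrate_labels"]


@dataclass
class ReintegrationReport:
    staged: list[tuple[Path, Path]] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.staged)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def reintegrate_labels(
    corrected_dir: Path,
    key: KeyTable,
    staging_dir: Path,
    label_tag: str | None = None,
    tag_map: dict[str, str] | None = None,
) -> ReintegrationReport:
    """Map corrected Case-named label files back to patient-named files.

    Parameters
    ----------
    corrected_dir
        Directory of corrected volumes, scanned recursively; originals are
        never modified.
    key
        The de-identification key table from the extraction that produced
        the batch; its inverse maps Case pseudonyms back to patients.
    staging_dir
        Where renamed files are placed — the drop-off directory of the
        structuring step, which completes the round trip.
    label_tag
        Structure code applied to files whose tag is ``IM`` (an exported
        image copy that was painted over). Files already carrying a label
        tag keep it, supporting re-corrected labels.
    tag_map
        Optional per-file override, corrected filename -> tag; takes
        precedence over ``label_tag``.

    Returns a report whose ``count`` is the number of files staged.
    Unmappable files (unparseable name, unknown pseudonym, ``IM`` with no
    tag to apply) are skipped and reported. A staged name that already
    exists raises :class:`TagCollision`: one slot per label per image.
    """
    corrected_dir = Path(corrected_dir)
    staging_dir = Path(staging_dir)
    staging_dir.mkdir(parents=True, exist_ok=True)
    inverse = key.inverse
    tag_map = tag_map or {}

    report = ReintegrationReport()
    for path in sorted(corrected_dir.rglob("*")):
        if not path.is_file():
            continue
        try:
            case_key = parse_case_filename(path.name)
        except MalformedName as exc:
            report.skipped.append((path.name, f"unparseable: {exc}"))
            continue
        patient_id = inverse.get(case_key.case_id)
        if patient_id is None:
            report.skipped.append((path.name, f"unknown pseudonym {case_key.case_id}"))
            continue
        if path.name in tag_map:
            tag = tag_map[path.name]
        elif case_key.tag != "IM":
            tag = case_key.tag
        elif label_tag is not None:
            tag = label_tag
        else:
            report.skipped.append((path.name, "tag IM and no label tag supplied"))
            continue

        staged_key = FileKey(
            patient_id, case_key.acquisition_id, case_key.phase, tag, case_key.extension
        )
        dest = staging_dir / format_filename(staged_key)
        if dest.exists():
            raise TagCollision(f"staged file {dest.name} already exists")
        shutil.copy2(path, dest)
        if _sha256(dest) != _sha256(path):
            dest.unlink()
            report.skipped.append((path.name, "checksum mismatch after copy"))
            continue
        report.staged.append((path, dest))
    return report
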