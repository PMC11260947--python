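"""Filename grammar of the Medical Data Structure (MDS).

Every image or label file in the structured dataset is named

    <PatientID>_<AcquisitionID>_<Phase>_<Tag>.<extension>

e.g. ``H001_CT001_Porto_IM.nii.gz``: patient H001, first CT acquisition,
portal-venous phase, the image itself (tag ``IM``), compressed NIfTI. Label
files replace ``IM`` with a structure code (``LP`` liver parenchyma, ``HV``
hepatic vein, ``PV`` portal vein, ``LV`` liver veins combined, ``LL`` liver
lesion, ``BD`` bile duct, ...). The filename alone determines where the file
belongs in the four-level tree ``MAIN/<patient>/<acquisition>/<phase>/``;
the tag and extension never affect placement.

De-identified exports use the same grammar with the patient token replaced
by a ``CaseNNN`` pseudonym (:class:`CaseKey`).

This module is pure: it parses, formats, and maps names to paths, and does
no file I/O.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path, PurePath

from .errors import InvalidKey, InvalidTag, MalformedName

__all__ = [
    "FileKey",
    "CaseKey",
    "parse_filename",
    "parse_case_filename",
    "format_filename",
    "target_path",
    "relabel",
    "PATIENT_RE",
    "ACQUISITION_RE",
    "CASE_RE",
]

# Patient numbers are zero-padded to three digits but may grow beyond 999.
PATIENT_RE = re.compile(r"H\d{3,}\Z")
ACQUISITION_RE = re.compile(r"(?:CT|MR)\d{3,}\Z")
CASE_RE = re.compile(r"Case\d{3,}\Z")
# Phase and tag tokens: alphanumeric, no underscore (the field separator),
# no dot (the extension separator), no path separators.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+\Z")

# Extensions that themselves contain a dot. Matched first so that
# ``x.nii.gz`` does not degrade to extension ``gz``.
COMPOUND_EXTENSIONS = ("nii.gz", "tar.gz")


@dataclass(frozen=True)
class FileKey:
    """Parsed identity of one structured-dataset file."""

    patient_id: str
    acquisition_id: str
    phase: str
    tag: str
    extension: str

    @property
    def subject_id(self) -> str:
        return self.patient_id

    def validate(self) -> None:
        if not PATIENT_RE.fullmatch(self.patient_id):
            raise InvalidKey(f"bad patient token {self.patient_id!r}")
        _validate_common(self)


@dataclass(frozen=True)
class CaseKey:
    """Identity of a de-identified (pseudonymized) export file."""

    case_id: str
    acquisition_id: str
    phase: str
    tag: str
    extension: str

    @property
    def subject_id(self) -> str:
        return self.case_id

    def validate(self) -> None:
        if not CASE_RE.fullmatch(self.case_id):
            raise InvalidKey(f"bad case token {self.case_id!r}")
        _validate_common(self)


def _validate_common(key: FileKey | CaseKey) -> None:
    if not ACQUISITION_RE.fullmatch(key.acquisition_id):
        raise InvalidKey(f"bad acquisition token {key.acquisition_id!r}")
    for field in ("phase", "tag"):
        token = getattr(key, field)
        if not _TOKEN_RE.fullmatch(token):
            raise InvalidKey(f"bad {field} token {token!r}")
    if not key.extension or key.extension.startswith(".") or "_" in key.extension:
        raise InvalidKey(f"bad extension {key.extension!r}")


def split_extension(name: str) -> tuple[str, str]:
    """Split ``name`` into (stem, extension) honouring compound extensions.

    ``H001_CT001_Porto_IM.nii.gz`` -> (``H001_CT001_Porto_IM``, ``nii.gz``).
    Raises :class:`MalformedName` if there is no extension at all.
    """
    for ext in COMPOUND_EXTENSIONS:
        suffix = "." + ext
        if name.endswith(suffix) and len(name) > len(suffix):
            return name[: -len(suffix)], ext
    stem, dot, ext = name.rpartition(".")
    if not dot or not stem or not ext:
        raise MalformedName(f"{name!r} has no extension")
    return stem, ext


def _split_tokens(name: str) -> tuple[list[str], str]:
    if PurePath(name).name != name or "/" in name or "\\" in name:
        raise MalformedName(f"{name!r} contains directory components")
    stem, ext = split_extension(name)
    tokens = stem.split("_")
    if len(tokens) != 4:
        raise MalformedName(
            f"{name!r}: expected 4 underscore-separated tokens, got {len(tokens)}"
        )
    if any(not t for t in tokens):
        raise MalformedName(f"{name!r} has an empty token")
    return tokens, ext


def parse_filename(name: str) -> FileKey:
    """Parse a bare filename into a :class:`FileKey`.

    Rejects (with :class:`MalformedName`) anything that does not have exactly
    four underscore-separated tokens with a valid patient and acquisition
    token — such files must be quarantined, not guessed at.
    """
    tokens, ext = _split_tokens(name)
    key = FileKey(*tokens, extension=ext)
    try:
        key.validate()
    except InvalidKey as exc:
        raise MalformedName(f"{name!r}: {exc}") from exc
    return key


def parse_case_filename(name: str) -> CaseKey:
    """Parse a pseudonymized export filename into a :class:`CaseKey`."""
    tokens, ext = _split_tokens(name)
    key = CaseKey(*tokens, extension=ext)
    try:
        key.validate()
    except InvalidKey as exc:
        raise MalformedName(f"{name!r}: {exc}") from exc
    return key


def format_filename(key: FileKey | CaseKey) -> str:
    """Inverse of :func:`parse_filename`: join the tokens back into a name."""
    key.validate()
    return (
        f"{key.subject_id}_{key.acquisition_id}_{key.phase}_{key.tag}"
        f".{key.extension}"
    )


def target_path(key: FileKey | CaseKey, root: Path) -> Path:
    """Destination directory of ``key`` inside the four-level tree.

    ``root`` is the level-one MAIN directory; the result is
    ``root/<subject>/<acquisition>/<phase>/``. Placement depends only on the
    first three tokens — tag and extension are ignored, so an image and all
    its labels land in the same directory.
    """
    return Path(root) / key.subject_id / key.acquisition_id / key.phase


def relabel(key: FileKey | CaseKey, new_tag: str):
    """Return a copy of ``key`` with the tag replaced.

    Used when an AI-inferred image copy becomes a corrected label: the ``IM``
    tag is swapped for the structure code (e.g. ``LP``).
    """
    if not _TOKEN_RE.fullmatch(new_tag or ""):
        raise InvalidTag(f"invalid tag {new_tag!r}")
    return replace(key, tag=new_tag)
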