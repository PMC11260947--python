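"""Synthetic fixtures: source trees, clinical CSVs, and mask pairs.

Everything the curation workflow consumes can be generated here, so the
whole package is exercisable without any real patient data. The generator
emulates the shape of a liver-surgery CT/MR cohort: patients ``H001..``,
acquisitions ``CT001``/``MR001``, contrast phases such as ``Porto`` (portal
venous) or ``T1``, and per-structure label tags (``IM`` image, ``LP`` liver
parenchyma, ``HV`` hepatic vein, ...). A ``missing_fraction`` (or an
explicit list) drops whole patients, mirroring cohorts where some enrolled
patients have no usable imaging.

Volumes are tiny (8³ by default) compressed NIfTI files with an identity
affine: big enough to move, copy, and checksum, small enough that full
workflow tests run in seconds. Mask pairs are generated with *exact*
prescribed confusion counts (TP, FP, FN), so metric values are known in
closed form.

All generation is driven by a seeded NumPy generator; the same spec and
seed reproduce byte-identical trees.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InfeasibleCounts, OutputNotEmpty
from .metrics import Mask
from .naming import FileKey, format_filename, target_path

__all__ = [
    "TreeSpec",
    "generate_source_tree",
    "generate_clinical_csv",
    "generate_mask_pair",
]


@dataclass(frozen=True)
class TreeSpec:
    """Shape of a synthetic cohort.

    Defaults mirror a small single-phase CT liver cohort: seven patients,
    one CT acquisition each, portal-venous phase, an image plus liver and
    hepatic-vein labels.
    """

    n_patients: int = 7
    acquisitions_per_patient: int = 1
    phases: tuple[str, ...] = ("Porto",)
    tags: tuple[str, ...] = ("IM", "LP", "HV")
    modalities: tuple[str, ...] = ("CT",)
    missing_fraction: float = 0.0
    missing_patients: tuple[str, ...] = ()
    shape: tuple[int, int, int] = (8, 8, 8)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.phases or not self.tags:
            raise ValueError("phases and tags must be non-empty")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")


def _acquisition_ids(spec: TreeSpec) -> list[str]:
    counters = {m: 0 for m in spec.modalities}
    ids = []
    for i in range(spec.acquisitions_per_patient):
        mod = spec.modalities[i % len(spec.modalities)]
        counters[mod] += 1
        ids.append(f"{mod}{counters[mod]:03d}")
    return ids


def generate_source_tree(spec: TreeSpec, out: Path) -> list[dict]:
    """Write a flat drop-off directory of synthetic volumes.

    Every present patient gets one file per (acquisition, phase, tag)
    combination, named per the filename grammar. Returns the manifest: one
    entry per file with its parsed key and the destination directory the
    structuring step must move it to (relative to a MAIN root).
    """
    out = Path(out)
    if out.exists() and any(out.iterdir()):
        raise OutputNotEmpty(f"{out} is not empty")
    out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(spec.seed)
    acq_ids = _acquisition_ids(spec)
    manifest: list[dict] = []
    for p in range(1, spec.n_patients + 1):
        patient = f"H{p:03d}"
        # Whole-patient dropout: some enrolled patients have no usable data.
        absent = patient in spec.missing_patients or (
            spec.missing_fraction > 0 and rng.random() < spec.missing_fraction
        )
        if absent:
            continue
        for acq in acq_ids:
            for phase in spec.phases:
                for tag in spec.tags:
                    key = FileKey(patient, acq, phase, tag, "nii.gz")
                    name = format_filename(key)
                    data = rng.integers(0, 256, size=spec.shape, dtype=np.int16)
                    nib.save(nib.Nifti1Image(data, np.eye(4)), str(out / name))
                    manifest.append(
                        {
                            "filename": name,
                            "key": key,
                            "destination": str(Path(patient) / acq / phase),
                            "seed": spec.seed,
                        }
                    )
    return manifest


def generate_clinical_csv(
    n_patients: int, n_columns: int, seed: int, out: Path
) -> Path:
    """Write a synthetic clinical CSV: header plus one row per patient.

    First column ``Pat`` holds the patient token; the remaining columns mix
    integer, decimal, categorical, and occasionally empty cells, the value
    types a real clinical export contains.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    categories = ["A", "B", "C", "unknown"]
    columns = ["Pat"] + [f"var_{i:02d}" for i in range(1, n_columns)]
    with out.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for p in range(1, n_patients + 1):
            row = [f"H{p:03d}"]
            for _ in columns[1:]:
                kind = rng.integers(0, 4)
                if kind == 0:
                    row.append(str(int(rng.integers(0, 100))))
                elif kind == 1:
                    row.append(f"{rng.random() * 10:.3f}")
                elif kind == 2:
                    row.append(categories[rng.integers(0, len(categories))])
                else:
                    row.append("")
            writer.writerow(row)
    return out


def generate_mask_pair(
    shape: tuple[int, int, int],
    tp: int,
    fp: int,
    fn: int,
    seed: int,
) -> tuple[Mask, Mask]:
    """Generate a (ground truth, prediction) pair with exact confusion counts.

    ``tp`` voxels are set in both masks, ``fp`` in the prediction only, and
    ``fn`` in the ground truth only, at positions drawn without replacement
    by a seeded generator. The realized ``confusion_counts`` equal the
    requested triple exactly, so every metric value is known in closed form
    from the three integers.
    """
    n_vox = int(np.prod(shape))
    if min(tp, fp, fn) < 0 or tp + fp + fn > n_vox:
        raise InfeasibleCounts(
            f"counts ({tp}, {fp}, {fn}) do not fit in a grid of {n_vox} voxels"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(n_vox, size=tp + fp + fn, replace=False)
    gt = np.zeros(n_vox, dtype=bool)
    pred = np.zeros(n_vox, dtype=bool)
    both, pred_only, gt_only = (
        picks[:tp],
        picks[tp : tp + fp],
        picks[tp + fp :],
    )
    gt[both] = True
    gt[gt_only] = True
    pred[both] = True
    pred[pred_only] = True
    return (
        Mask(gt.reshape(shape), affine=np.eye(4)),
        Mask(pred.reshape(shape), affine=np.eye(4)),
    )
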