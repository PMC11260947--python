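"""Segmentation-quality metrics for 3D binary label volumes.

Given a ground-truth mask GT and a predicted mask Pred on the same voxel
grid, with TP = |GT ∩ Pred|, FP = |Pred \\ GT|, FN = |GT \\ Pred|:

    DSC = 2·TP / (|GT| + |Pred|)          Dice similarity coefficient
    Dice loss = 1 − DSC
    OS  = 2·FP / (|GT| + |Pred|)          over-segmentation
    US  = 2·FN / (|GT| + |Pred|)          under-segmentation

All three share the denominator |GT| + |Pred| (the sum of cardinalities, as
in the standard Dice coefficient), which gives the exact algebraic identity

    OS + US = 2·(1 − DSC)

checked at runtime on every evaluated pair. DSC lies in [0, 1]; OS and US
lie in [0, 2] (OS reaches 2 when the prediction marks voxels but the ground
truth is empty, and symmetrically for US).

Convention for degenerate inputs: when both masks are empty, DSC = 1 and
OS = US = 0 (perfect agreement on absence); when exactly one is empty,
DSC = 0.

Volumes are read from NIfTI files and binarized at value > 0; multi-label
files must be split into one file per structure upstream, matching the
one-file-per-structure dataset layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import OverlapWithoutPriority, ShapeMismatch, UnreadableVolume

__all__ = [
    "Mask",
    "SegMetrics",
    "confusion_counts",
    "dice",
    "dice_loss",
    "over_segmentation",
    "under_segmentation",
    "compute_metrics",
    "evaluate_pair",
    "evaluate_pairs",
    "fuse_labels",
]

_IDENTITY_TOL = 1e-12


@dataclass
class Mask:
    """A 3D binary label volume with its spatial metadata carried opaquely."""

    voxels: np.ndarray
    affine: np.ndarray | None = None
    header: object | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ShapeMismatch(f"mask must be 3D, got shape {self.voxels.shape}")
        self.voxels = self.voxels.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def volume(self) -> int:
        """Number of labeled voxels."""
        return int(self.voxels.sum())

    @classmethod
    def from_nifti(cls, path: Path) -> "Mask":
        """Load a NIfTI volume and binarize it at value > 0."""
        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
        except Exception as exc:
            raise UnreadableVolume(f"cannot read {path}: {exc}") from exc
        if data.ndim != 3:
            raise UnreadableVolume(f"{path}: expected a 3D volume, got shape {data.shape}")
        return cls(data > 0, affine=img.affine, header=img.header)

    def to_nifti(self, path: Path) -> None:
        affine = self.affine if self.affine is not None else np.eye(4)
        img = nib.Nifti1Image(self.voxels.astype(np.uint8), affine)
        nib.save(img, str(path))


@dataclass(frozen=True)
class SegMetrics:
    """All metrics for one (ground truth, prediction) pair."""

    dsc: float
    dice_loss: float
    over_seg: float
    under_seg: float
    tp: int
    fp: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "dice_loss": self.dice_loss,
            "over_seg": self.over_seg,
            "under_seg": self.under_seg,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


def _as_bool(mask: "Mask | np.ndarray") -> np.ndarray:
    if isinstance(mask, Mask):
        return mask.voxels
    return np.asarray(mask).astype(bool)


def _pair(gt, pred) -> tuple[np.ndarray, np.ndarray]:
    g, p = _as_bool(gt), _as_bool(pred)
    if g.shape != p.shape:
        raise ShapeMismatch(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    return g, p


def confusion_counts(gt, pred) -> tuple[int, int, int]:
    """Exact voxel counts (TP, FP, FN) shared by all three metrics."""
    g, p = _pair(gt, pred)
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    return tp, fp, fn


def _denominator(tp: int, fp: int, fn: int) -> int:
    # |GT| + |Pred| = (tp + fn) + (tp + fp)
    return 2 * tp + fp + fn


def dice(gt, pred) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    tp, fp, fn = confusion_counts(gt, pred)
    denom = _denominator(tp, fp, fn)
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def dice_loss(gt, pred) -> float:
    return 1.0 - dice(gt, pred)


def over_segmentation(gt, pred) -> float:
    """Normalized false-positive burden 2·FP/(|GT|+|Pred|); 0 when both empty."""
    tp, fp, fn = confusion_counts(gt, pred)
    denom = _denominator(tp, fp, fn)
    if denom == 0:
        return 0.0
    return 2.0 * fp / denom


def under_segmentation(gt, pred) -> float:
    """Normalized false-negative burden 2·FN/(|GT|+|Pred|); 0 when both empty."""
    tp, fp, fn = confusion_counts(gt, pred)
    denom = _denominator(tp, fp, fn)
    if denom == 0:
        return 0.0
    return 2.0 * fn / denom


def compute_metrics(gt, pred) -> SegMetrics:
    """All metrics for one pair, with the OS + US = 2·(1−DSC) identity checked."""
    tp, fp, fn = confusion_counts(gt, pred)
    denom = _denominator(tp, fp, fn)
    if denom == 0:
        m = SegMetrics(1.0, 0.0, 0.0, 0.0, 0, 0, 0)
    else:
        dsc = 2.0 * tp / denom
        m = SegMetrics(dsc, 1.0 - dsc, 2.0 * fp / denom, 2.0 * fn / denom, tp, fp, fn)
    residual = abs(m.over_seg + m.under_seg - 2.0 * m.dice_loss)
    if residual > _IDENTITY_TOL:
        raise AssertionError(
            f"metric identity violated: OS+US={m.over_seg + m.under_seg} "
            f"vs 2·(1−DSC)={2.0 * m.dice_loss}"
        )
    return m


def evaluate_pair(gt_path: Path, pred_path: Path) -> SegMetrics:
    """Load a (ground truth, prediction) NIfTI pair and compute all metrics."""
    gt = Mask.from_nifti(gt_path)
    pred = Mask.from_nifti(pred_path)
    return compute_metrics(gt, pred)


def evaluate_pairs(pairs: list[tuple[Path, Path]]):
    """Evaluate many pairs; returns a DataFrame with one row per pair plus
    the unweighted arithmetic mean of every metric across pairs (the usual
    cohort-level summary)."""
    import pandas as pd

    records = []
    for gt_path, pred_path in pairs:
        m = evaluate_pair(gt_path, pred_path)
        records.append({"gt": str(gt_path), "pred": str(pred_path), **m.as_dict()})
    frame = pd.DataFrame.from_records(records)
    means = (
        frame[["dsc", "dice_loss", "over_seg", "under_seg"]].mean()
        if len(frame)
        else None
    )
    return frame, means


def fuse_labels(
    masks: list,
    mode: str = "union",
    priority: list[int] | None = None,
):
    """Fuse several per-structure masks of the same image.

    ``union`` mode: voxelwise OR (element-wise addition clipped at 1) —
    returns a :class:`Mask`. ``multilabel`` mode: an integer volume where
    voxels of ``masks[i]`` carry label ``i+1``; overlapping masks require a
    ``priority`` order (list of mask indices, later entries win), otherwise
    :class:`OverlapWithoutPriority` is raised.
    """
    if not masks:
        raise ValueError("need at least one mask")
    arrays = [_as_bool(m) for m in masks]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ShapeMismatch("all masks must share one voxel grid")
    meta = masks[0] if isinstance(masks[0], Mask) else None

    if mode == "union":
        fused = np.zeros(shape, dtype=bool)
        for a in arrays:
            fused |= a
        return Mask(fused, affine=meta.affine if meta else None)
    if mode != "multilabel":
        raise ValueError(f"unknown fusion mode {mode!r}")

    overlap = np.zeros(shape, dtype=np.int64)
    for a in arrays:
        overlap += a
    if priority is None:
        if int(overlap.max(initial=0)) > 1:
            raise OverlapWithoutPriority(
                "masks overlap; a priority order is required in multilabel mode"
            )
        priority = list(range(len(arrays)))
    elif sorted(priority) != list(range(len(arrays))):
        raise ValueError("priority must be a permutation of the mask indices")

    labeled = np.zeros(shape, dtype=np.int16)
    for idx in priority:  # later in priority wins
        labeled[arrays[idx]] = idx + 1
    return labeled
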