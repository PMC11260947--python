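"""Shared fixtures and the independent brute-force metric oracle."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pytest

from mds.synthetic import TreeSpec, generate_source_tree


def brute_force_counts(gt_voxels, pred_voxels) -> tuple[int, int, int]:
    """Triple-loop voxel counter, deliberately independent of the vectorized
    implementation under test."""
    nx, ny, nz = gt_voxels.shape
    tp = fp = fn = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = bool(gt_voxels[x, y, z])
                p = bool(pred_voxels[x, y, z])
                if g and p:
                    tp += 1
                elif p:
                    fp += 1
                elif g:
                    fn += 1
    return tp, fp, fn


def sha256_of(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def tree_checksums(root: Path) -> dict[str, str]:
    """Relative-path -> checksum map of every file under ``root``."""
    return {
        str(p.relative_to(root)): sha256_of(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


@pytest.fixture
def small_cohort(tmp_path):
    """A structured 7-patient cohort (H006 has no data) plus its manifest."""
    from mds.structure import structure_tree

    source = tmp_path / "source"
    main = tmp_path / "MAIN"
    spec = TreeSpec(n_patients=7, missing_patients=("H006",), seed=7)
    manifest = generate_source_tree(spec, source)
    structure_tree(source, main)
    return main, manifest
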