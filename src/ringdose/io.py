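"""NIfTI volume and cohort-CSV readers/writers.

Masks and dose grids travel as NIfTI-1 files (one structure per file, 0/1 for
masks, Gy for dose) with the lattice in the affine; the cohort is a CSV with
the schema of :func:`ringdose.features.cohort_columns`.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ringdose.grid import VoxelGrid
from ringdose.features import cohort_columns


def write_volume(path, grid: VoxelGrid, values: np.ndarray) -> None:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} does not match grid {grid.shape}")
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    affine[:3, 3] = grid.origin_mm
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    nib.save(img, str(path))


def read_volume(path, expect_mask: bool = False) -> tuple[VoxelGrid, np.ndarray]:
    """Load a 3D NIfTI volume; with ``expect_mask`` the values must be 0/1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got {data.ndim}D")
    affine = img.affine
    spacing = tuple(float(np.linalg.norm(affine[:3, a])) for a in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    grid = VoxelGrid(shape=data.shape, spacing_mm=spacing, origin_mm=origin)
    if expect_mask:
        vals = np.unique(data)
        bad = vals[~np.isin(vals, (0.0, 1.0))]
        if bad.size:
            raise ValueError(f"{path}: mask contains non-binary value(s) {bad[:5].tolist()}")
        data = data.astype(bool)
    return grid, data


def require_same_lattice(a: VoxelGrid, b: VoxelGrid, what: str = "volumes") -> None:
    if a.shape != b.shape or not np.allclose(a.spacing_mm, b.spacing_mm) \
            or not np.allclose(a.origin_mm, b.origin_mm):
        raise ValueError(f"mismatched lattices between paired {what}: {a} vs {b}")


def write_cohort(path, table: pd.DataFrame) -> None:
    cols = [c for c in cohort_columns() if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (name-keyed; column order free)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort file: {path}")
    table = pd.read_csv(path)
    missing = [c for c in cohort_columns() if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing cohort column(s) {missing}")
    numeric = [c for c in cohort_columns()]
    for col in numeric:
        bad = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric cell at row {row}, column '{col}'")
        if table[col].isna().any():
            row = int(np.flatnonzero(table[col].isna())[0])
            raise ValueError(f"{path}: empty cell at row {row}, column '{col}'")
    return table
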