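"""Voxel-lattice containers shared by every stage of the pipeline.

All volumes (structure masks and dose grids) live on one axis-aligned lattice.
World coordinates are millimetres, voxel indices are 0-based, and a voxel's
value is located at its centre.  Volumes are reported in cm3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OAR_LABELS = ("bladder", "rectum", "sigmoid")
STRUCTURE_LABELS = ("hrctv",) + OAR_LABELS


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D lattice: shape (voxels), spacing (mm/voxel), origin (mm)."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"grid spacing must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm3."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis (1D arrays)."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def mm_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)


def _check_mask(grid: VoxelGrid, mask: np.ndarray, label: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != grid.shape:
        raise ValueError(f"mask '{label}' shape {mask.shape} does not match grid {grid.shape}")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        bad = [v for v in vals if v not in (0, 1)]
        raise ValueError(f"mask '{label}' contains non-binary value(s) {bad}")
    return mask.astype(bool)


@dataclass
class StructureSet:
    """HR-CTV plus OAR binary masks on a shared lattice."""

    grid: VoxelGrid
    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.masks = {lbl: _check_mask(self.grid, m, lbl) for lbl, m in self.masks.items()}
        if "hrctv" not in self.masks:
            raise ValueError("StructureSet requires an 'hrctv' mask")
        if not self.masks["hrctv"].any():
            raise ValueError("HR-CTV mask is empty")

    def mask(self, label: str) -> np.ndarray:
        if label not in self.masks:
            raise KeyError(f"no structure '{label}'; have {sorted(self.masks)}")
        return self.masks[label]

    def volume_cc(self, label: str) -> float:
        return float(self.mask(label).sum()) * self.grid.voxel_volume_cc


@dataclass
class DoseGrid:
    """Per-fraction absorbed dose (Gy) on the structure-set lattice."""

    grid: VoxelGrid
    dose_gy: np.ndarray

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        if self.dose_gy.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.dose_gy.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.dose_gy)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(self.dose_gy < 0):
            raise ValueError("dose grid contains negative values")


@dataclass
class DwellPlan:
    """Source dwell positions (mm) with relative weights for one fraction."""

    dwell_positions_mm: np.ndarray  # (n, 3)
    dwell_weights: np.ndarray  # (n,)
    n_needles: int
    prescription_gy: float

    def __post_init__(self) -> None:
        self.dwell_positions_mm = np.atleast_2d(np.asarray(self.dwell_positions_mm, dtype=float))
        self.dwell_weights = np.asarray(self.dwell_weights, dtype=float)
        if self.dwell_positions_mm.shape[0] != self.dwell_weights.shape[0]:
            raise ValueError("dwell positions and weights differ in length")
        if np.any(self.dwell_weights < 0):
            raise ValueError("dwell weights must be nonnegative")
        if not 2 <= self.n_needles <= 8:
            raise ValueError(f"n_needles must be in [2, 8], got {self.n_needles}")

    @property
    def n_dwells(self) -> int:
        return int(self.dwell_positions_mm.shape[0])
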