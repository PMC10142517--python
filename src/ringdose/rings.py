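"""Sub-organ decomposition: concentric exterior distance rings around the HR-CTV.

The HR-CTV is expanded outward into rings of width 3 mm (0.3 cm); the
intersection of ring k with an OAR is sub-organ k, and its volume divided by
the whole-OAR volume is the normalized sub-organ volume used as a geometric
feature.  At most 15 rings are kept.

Distances are centre-to-region Euclidean distances on the voxel lattice,
computed with an anisotropic distance transform (no resampling).  Ring k is
the half-open distance band ((k-1)*w, k*w]; OAR voxels inside the HR-CTV
(distance 0) are booked separately and are not a model feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ringdose.grid import StructureSet

MAX_RINGS = 15
DEFAULT_RING_WIDTH_MM = 3.0


@dataclass
class SubOrganDecomposition:
    """Ring volumes of one OAR around the HR-CTV, absolute and normalized."""

    oar_label: str
    ring_width_mm: float
    n_rings: int
    ring_volumes_cc: np.ndarray  # length n_rings, ring k at index k-1
    normalized_volumes: np.ndarray  # ring_volumes_cc / oar_volume_cc
    oar_volume_cc: float
    hrctv_volume_cc: float
    inside_volume_cc: float  # OAR voxels at distance 0 (inside the HR-CTV)
    far_volume_cc: float  # OAR voxels beyond ring n_rings

    def __post_init__(self) -> None:
        self.ring_volumes_cc = np.asarray(self.ring_volumes_cc, dtype=float)
        self.normalized_volumes = np.asarray(self.normalized_volumes, dtype=float)
        if len(self.ring_volumes_cc) != self.n_rings:
            raise ValueError("ring volume vector length does not match n_rings")
        if self.n_rings > MAX_RINGS:
            raise ValueError(f"n_rings must be <= {MAX_RINGS}")


# The voxel-centre distance transform measures to the outermost region voxel
# CENTRES; for smooth anatomical surfaces the region boundary lies on average
# ~0.3 voxel beyond them (measured 0.27-0.35 across sphere radii 8-30 mm and
# spacings 1-2.5 mm), so exterior distances carry a +0.3-voxel bias that at CT
# resolution shifts ring volumes by several percent.
DEFAULT_BOUNDARY_OFFSET_VOXELS = 0.3


def exterior_distance_map(structures: StructureSet,
                          boundary_offset_voxels: float = DEFAULT_BOUNDARY_OFFSET_VOXELS,
                          ) -> np.ndarray:
    """Euclidean distance (mm) from each voxel centre to the HR-CTV region.

    Zero for voxels inside the HR-CTV.  Computed as an anisotropic Euclidean
    distance transform minus a sub-voxel boundary offset
    (``boundary_offset_voxels`` x mean spacing, capped below half the
    smallest spacing so exterior voxels stay strictly positive); pass 0 for
    the raw voxel-centre transform.
    """
    hrctv = structures.mask("hrctv")
    if not hrctv.any():
        raise ValueError("HR-CTV mask is empty; cannot build a distance map")
    if boundary_offset_voxels < 0:
        raise ValueError("boundary_offset_voxels must be >= 0")
    sp = np.asarray(structures.grid.spacing_mm, dtype=float)
    d = ndimage.distance_transform_edt(~hrctv, sampling=sp)
    off = min(boundary_offset_voxels * sp.mean(), 0.49 * sp.min())
    if off > 0:
        np.subtract(d, off, out=d, where=~hrctv)
    return d


def ring_label_volume(
    structures: StructureSet,
    ring_width_mm: float = DEFAULT_RING_WIDTH_MM,
    n_rings: int = MAX_RINGS,
    distance_map: np.ndarray | None = None,
) -> np.ndarray:
    """Integer volume labelling each voxel with its ring index (0 = no ring).

    Ring k covers exterior distances in ((k-1)*w, k*w].  Useful for exporting
    a visual check of the expansion.
    """
    if distance_map is None:
        distance_map = exterior_distance_map(structures)
    labels = np.ceil(distance_map / ring_width_mm).astype(np.int32)
    labels[(distance_map <= 0) | (labels > n_rings)] = 0
    return labels


def derive_sub_organs(
    structures: StructureSet,
    oar_label: str,
    ring_width_mm: float = DEFAULT_RING_WIDTH_MM,
    n_rings: int = MAX_RINGS,
    distance_map: np.ndarray | None = None,
) -> SubOrganDecomposition:
    """Intersect exterior HR-CTV rings with one OAR and tally volumes.

    Parameters
    ----------
    structures
        Structure set holding the HR-CTV and the OAR on one lattice.
    oar_label
        One of ``bladder``, ``rectum``, ``sigmoid`` (any mask label works).
    ring_width_mm
        Ring width; 3 mm by default.
    n_rings
        Number of rings kept (<= 15); absent rings have zero volume.
    distance_map
        Precomputed :func:`exterior_distance_map`, to share across OARs.
    """
    if not 1 <= n_rings <= MAX_RINGS:
        raise ValueError(f"n_rings must be in [1, {MAX_RINGS}], got {n_rings}")
    if ring_width_mm <= 0:
        raise ValueError("ring_width_mm must be positive")
    oar = structures.mask(oar_label)
    if not oar.any():
        raise ValueError(f"OAR mask '{oar_label}' is empty")

    if distance_map is None:
        distance_map = exterior_distance_map(structures)
    vv = structures.grid.voxel_volume_cc
    d = distance_map[oar]

    inside = int(np.count_nonzero(d <= 0))
    # ring index via ceil(d / w): d in ((k-1)w, kw] -> k, robust to float noise at 0
    k = np.ceil(d / ring_width_mm).astype(np.int64)
    k[d <= 0] = 0
    ring_counts = np.bincount(k[(k >= 1) & (k <= n_rings)], minlength=n_rings + 1)[1:]
    far = int(d.size - inside - ring_counts.sum())

    oar_volume = float(d.size) * vv
    ring_volumes = ring_counts.astype(float) * vv
    return SubOrganDecomposition(
        oar_label=oar_label,
        ring_width_mm=float(ring_width_mm),
        n_rings=int(n_rings),
        ring_volumes_cc=ring_volumes,
        normalized_volumes=ring_volumes / oar_volume,
        oar_volume_cc=oar_volume,
        hrctv_volume_cc=structures.volume_cc("hrctv"),
        inside_volume_cc=inside * vv,
        far_volume_cc=far * vv,
    )
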