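"""Synthetic pelvic phantom cohort: geometry, dwell plans, inverse-square dose.

Each phantom plan mimics one needle-insertion brachytherapy fraction: a
voxelized ellipsoidal HR-CTV with a bladder (anterior ellipsoid), rectum
(posterior tube) and sigmoid colon (superior curved tube) placed at sampled
surface gaps; an intrauterine tandem plus 2-8 intratumoral needles carrying
point-source dwells; and a dose grid from a bare inverse-square kernel,
rescaled so HR-CTV D90 equals the prescription (6 or 7 Gy).  The D2cm3/D90
targets are therefore driven purely by the OAR-to-target stand-off geometry,
which is the signal the ring features are meant to capture.

Axis convention: axis 0 = left-right (x), axis 1 = anterior-posterior (y,
anterior = -y), axis 2 = inferior-superior (z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ringdose.grid import DoseGrid, DwellPlan, StructureSet, VoxelGrid, OAR_LABELS
from ringdose.rings import MAX_RINGS, DEFAULT_RING_WIDTH_MM, exterior_distance_map, derive_sub_organs
from ringdose.dvh import dose_at_volume_fraction, dvh_metrics
from ringdose import features as ft

# Needle-count law: integers 2..8 with mean 3.74, bracketing the clinical
# average of 3.7 needles per fraction.
NEEDLE_COUNTS = np.arange(2, 9)
NEEDLE_PROBS = np.array([0.25, 0.28, 0.20, 0.12, 0.08, 0.04, 0.03])


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings; defaults define the study conditions of the cohort."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # HR-CTV: compact ovoid; a base radius scaled by modest per-axis
    # eccentricity multipliers (cervix + residual tumour is roughly ovoid)
    hrctv_semiaxis_mm: tuple[float, float] = (15.0, 35.0)
    hrctv_eccentricity: tuple[float, float] = (0.85, 1.15)
    hrctv_center_mm: tuple[float, float, float] = (96.0, 104.0, 88.0)
    hrctv_center_jitter_mm: float = 4.0
    # bladder: anterior ellipsoid, per-axis semi-axis ranges (mm)
    bladder_semiaxis_x_mm: tuple[float, float] = (25.0, 40.0)
    bladder_semiaxis_y_mm: tuple[float, float] = (15.0, 25.0)
    bladder_semiaxis_z_mm: tuple[float, float] = (20.0, 35.0)
    # rectum: posterior straight tube along z
    rectum_radius_mm: tuple[float, float] = (10.0, 16.0)
    rectum_length_mm: tuple[float, float] = (60.0, 100.0)
    # sigmoid: superior curved tube
    sigmoid_radius_mm: tuple[float, float] = (8.0, 14.0)
    sigmoid_length_mm: tuple[float, float] = (60.0, 100.0)
    sigmoid_curvature_per_mm: tuple[float, float] = (0.002, 0.008)
    # HR-CTV-to-OAR surface gap (mm): triangular with mode at the lower
    # bound — OARs usually abut the target, larger stand-offs are rarer
    gap_mm: tuple[float, float] = (0.0, 12.0)
    # dwells: weights are conformally optimized (NNLS to a uniform HR-CTV
    # surface dose), emulating the repeated manual/graphic optimization of
    # clinical planning; log-normal noise then injects planner variability
    dwell_step_mm: float = 5.0
    optimize_weights: bool = True
    n_surface_points: int = 256
    # planner variability: the graphic-optimization surrogate aims at a
    # smoothly modulated (not uniform) surface dose, plan by plan
    surface_dose_variability: float = 0.12
    weight_noise_sigma: float = 0.1
    # dose
    kernel_constant: float = 1.0  # Gy mm^2 per unit dwell weight, pre-rescaling
    r_min_mm: float = 1.0
    prescriptions_gy: tuple[float, ...] = (6.0, 7.0)
    seed: int = 42

    def grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.shape, spacing_mm=self.spacing_mm)


def _plan_rng(params: PhantomParams, index: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, plan index, stage)."""
    return np.random.default_rng(np.random.SeedSequence([params.seed, index, stream]))


def _ellipsoid_mask(grid: VoxelGrid, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    xs, ys, zs = grid.voxel_centers_mm()
    u = (xs - center[0]) / semi[0]
    v = (ys - center[1]) / semi[1]
    w = (zs - center[2]) / semi[2]
    return (u[:, None, None] ** 2 + v[None, :, None] ** 2 + w[None, None, :] ** 2) <= 1.0


def _tube_mask(grid: VoxelGrid, centerline: np.ndarray, radius: float) -> np.ndarray:
    """Union of spheres of ``radius`` stamped along a sampled centerline."""
    mask = np.zeros(grid.shape, dtype=bool)
    sp = np.asarray(grid.spacing_mm)
    orig = np.asarray(grid.origin_mm)
    rvox = np.ceil(radius / sp).astype(int)
    axes = [np.arange(-r, r + 1) for r in rvox]
    ball = (
        (axes[0][:, None, None] * sp[0]) ** 2
        + (axes[1][None, :, None] * sp[1]) ** 2
        + (axes[2][None, None, :] * sp[2]) ** 2
    ) <= radius**2
    shape = np.asarray(grid.shape)
    for p in centerline:
        c = np.rint((p - orig) / sp).astype(int)
        lo = c - rvox
        hi = c + rvox + 1
        blo = np.maximum(lo, 0)
        bhi = np.minimum(hi, shape)
        if np.any(blo >= bhi):
            continue
        sub = tuple(slice(blo[a] - lo[a], ball.shape[a] - (hi[a] - bhi[a])) for a in range(3))
        mask[tuple(slice(blo[a], bhi[a]) for a in range(3))] |= ball[sub]
    return mask


def _min_exterior_distance(dist_map: np.ndarray, mask: np.ndarray) -> float:
    """Smallest HR-CTV distance over a mask; 0 means overlap with the HR-CTV."""
    return float(dist_map[mask].min())


def _place_at_gap(grid, dist_map, build, center0, direction, gap, organ,
                  tol_mm: float) -> np.ndarray:
    """Shift an organ along ``direction`` until its nearest surface sits at ``gap``.

    ``build`` voxelizes the organ for a trial centre.  Convergence is to
    within ``tol_mm`` of the requested centre-to-region gap; overlap with the
    HR-CTV is never accepted.
    """
    center = np.asarray(center0, dtype=float)
    direction = np.asarray(direction, dtype=float)
    extent = np.asarray(grid.spacing_mm) * np.asarray(grid.shape)
    mask = None
    for _ in range(16):
        mask = build(center)
        if not mask.any():
            raise ValueError(f"phantom grid too small: organ '{organ}' fell outside the lattice")
        dmin = _min_exterior_distance(dist_map, mask)
        if dmin <= 0:
            center = center + direction * max(grid.spacing_mm[0], gap - dmin + 1.0)
            continue
        err = gap - dmin
        if abs(err) <= tol_mm:
            break
        center = center + direction * err
        if np.any(center < -0.25 * extent) or np.any(center > 1.25 * extent):
            raise ValueError(f"phantom grid too small to place organ '{organ}'")
    if mask is None or not mask.any():
        raise ValueError(f"phantom grid too small to place organ '{organ}'")
    if _min_exterior_distance(dist_map, mask) <= 0:
        raise ValueError(f"could not place organ '{organ}' without HR-CTV overlap")
    return mask


def sample_structures(params: PhantomParams, index: int) -> StructureSet:
    """Draw one phantom anatomy; deterministic given (params.seed, index)."""
    grid = params.grid()
    rng = _plan_rng(params, index, 0)

    base = rng.uniform(*params.hrctv_semiaxis_mm)
    semi = base * rng.uniform(*params.hrctv_eccentricity, size=3)
    center = np.asarray(params.hrctv_center_mm) + rng.uniform(
        -params.hrctv_center_jitter_mm, params.hrctv_center_jitter_mm, size=3
    )
    hrctv = _ellipsoid_mask(grid, center, semi)
    if not hrctv.any():
        raise ValueError("phantom grid too small: organ 'hrctv' fell outside the lattice")

    dist_map = exterior_distance_map(StructureSet(grid=grid, masks={"hrctv": hrctv}))
    tol = 0.75 * float(np.linalg.norm(grid.spacing_mm))
    lo, hi = params.gap_mm
    gaps = {lbl: (rng.triangular(lo, lo, hi) if hi > lo else lo) for lbl in OAR_LABELS}

    # bladder: anterior (-y) ellipsoid
    bsemi = np.array([
        rng.uniform(*params.bladder_semiaxis_x_mm),
        rng.uniform(*params.bladder_semiaxis_y_mm),
        rng.uniform(*params.bladder_semiaxis_z_mm),
    ])
    c0 = center + np.array([0.0, -(semi[1] + gaps["bladder"] + bsemi[1]), 0.0])
    bladder = _place_at_gap(grid, dist_map, lambda c: _ellipsoid_mask(grid, c, bsemi),
                            c0, np.array([0.0, -1.0, 0.0]), gaps["bladder"], "bladder", tol)

    # rectum: posterior (+y) straight tube along z
    r_rad = rng.uniform(*params.rectum_radius_mm)
    r_len = rng.uniform(*params.rectum_length_mm)
    t = np.arange(-r_len / 2, r_len / 2 + 1e-9, min(grid.spacing_mm))

    def build_rectum(c):
        line = np.column_stack([np.full_like(t, c[0]), np.full_like(t, c[1]), c[2] + t])
        return _tube_mask(grid, line, r_rad)

    c0 = center + np.array([0.0, semi[1] + gaps["rectum"] + r_rad, 0.0])
    rectum = _place_at_gap(grid, dist_map, build_rectum, c0,
                           np.array([0.0, 1.0, 0.0]), gaps["rectum"], "rectum", tol)

    # sigmoid: a tube draped over the superior HR-CTV dome, running along x
    # and arching in z (the sigmoid colon loops across the uterine fundus)
    s_rad = rng.uniform(*params.sigmoid_radius_mm)
    s_len = rng.uniform(*params.sigmoid_length_mm)
    curv = rng.uniform(*params.sigmoid_curvature_per_mm)
    u = np.arange(-s_len / 2, s_len / 2 + 1e-9, min(grid.spacing_mm))

    def build_sigmoid(c):
        # ends curve down around the dome so the tube hugs the fundus
        line = np.column_stack([c[0] + u, np.full_like(u, c[1]), c[2] - curv * u**2])
        return _tube_mask(grid, line, s_rad)

    c0 = center + np.array([0.0, 0.0, semi[2] + gaps["sigmoid"] + s_rad])
    sigmoid = _place_at_gap(grid, dist_map, build_sigmoid, c0,
                            np.array([0.0, 0.0, 1.0]), gaps["sigmoid"], "sigmoid", tol)

    # enforce pairwise OAR disjointness (HR-CTV overlap already excluded)
    rectum &= ~bladder
    sigmoid &= ~(bladder | rectum)
    masks = {"hrctv": hrctv, "bladder": bladder, "rectum": rectum, "sigmoid": sigmoid}
    for lbl in OAR_LABELS:
        if not masks[lbl].any():
            raise ValueError(f"phantom grid too small: organ '{lbl}' fell outside the lattice")
    return StructureSet(grid=grid, masks=masks)


def sample_needle_count(rng: np.random.Generator) -> int:
    return int(rng.choice(NEEDLE_COUNTS, p=NEEDLE_PROBS))


def _conformal_weights(structures: StructureSet, positions: np.ndarray,
                       params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Dwell weights from NNLS to a uniform dose on the HR-CTV surface.

    Stands in for the planner's manual/graphic optimization: with the
    prescription isodose hugging the target surface, the dose outside becomes
    (approximately) a function of surface distance alone, which is the signal
    the ring features encode.
    """
    from scipy import ndimage, optimize

    hrctv = structures.mask("hrctv")
    grid = structures.grid
    surface = hrctv & ~ndimage.binary_erosion(hrctv)
    pts_idx = np.argwhere(surface)
    if len(pts_idx) > params.n_surface_points:
        sel = rng.choice(len(pts_idx), params.n_surface_points, replace=False)
        pts_idx = pts_idx[sel]
    pts = np.asarray(grid.origin_mm) + pts_idx * np.asarray(grid.spacing_mm)
    r2 = np.sum((pts[:, None, :] - positions[None, :, :]) ** 2, axis=2)
    A = 1.0 / np.maximum(r2, params.r_min_mm**2)
    # manual/graphic optimization never achieves a uniform surface dose:
    # modulate the objective with a smooth stationary random field (equal
    # variance everywhere on the surface; RMS amplitude = the config value)
    target = np.ones(len(pts))
    if params.surface_dose_variability > 0:
        rel = pts - pts.mean(axis=0)
        scale = np.linalg.norm(rel, axis=1).mean() or 1.0
        m = 4
        dirs = rng.standard_normal((m, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        freqs = rng.uniform(0.5, 1.5, m) / scale
        phases = rng.uniform(0, 2 * np.pi, m)
        field = np.sin((rel @ dirs.T) * freqs + phases).sum(axis=1)
        field /= np.sqrt(m / 2.0)  # unit RMS
        target = np.maximum(target + params.surface_dose_variability * field, 0.2)
    w, _ = optimize.nnls(A, target)
    if not np.any(w > 0):
        return np.ones(len(positions))
    # keep every dwell faintly active so superposition stays well-posed
    return np.maximum(w / w[w > 0].mean(), 0.02)


def sample_dwell_plan(structures: StructureSet, params: PhantomParams, index: int) -> DwellPlan:
    """Tandem through the HR-CTV centroid plus 2-8 straight intratumoral needles.

    Dwells step every ``dwell_step_mm`` along each track and are kept only
    where they fall inside the HR-CTV mask; weights carry multiplicative
    log-normal noise (sigma = ``weight_noise_sigma``).
    """
    rng = _plan_rng(params, index, 1)
    grid = structures.grid
    hrctv = structures.mask("hrctv")
    sp = np.asarray(grid.spacing_mm)
    orig = np.asarray(grid.origin_mm)

    idx = np.argwhere(hrctv)
    centroid = orig + idx.mean(axis=0) * sp

    def track_dwells(x_mm: float, y_mm: float) -> np.ndarray:
        """Dwell positions stepping in z along a vertical track, inside the HR-CTV."""
        zs = orig[2] + np.arange(grid.shape[2]) * sp[2]
        pts = []
        for z in np.arange(zs.min(), zs.max() + 1e-9, params.dwell_step_mm):
            i = np.rint(([x_mm, y_mm, z] - orig) / sp).astype(int)
            if np.all(i >= 0) and np.all(i < grid.shape) and hrctv[tuple(i)]:
                pts.append([x_mm, y_mm, z])
        return np.asarray(pts)

    tandem = track_dwells(centroid[0], centroid[1])
    if tandem.size == 0:
        raise ValueError("cannot place tandem dwells inside the HR-CTV")

    n_needles = sample_needle_count(rng)
    # template-style placement: needles at equal angles around the tandem,
    # at ~60% of the local HR-CTV radius, with a random angular offset and a
    # small positional jitter (clinical implants follow a regular template)
    zc = int(np.rint((centroid[2] - orig[2]) / sp[2]))
    zlo, zhi = max(zc - 3, 0), min(zc + 4, grid.shape[2])
    slab = hrctv[:, :, zlo:zhi].any(axis=2)
    cols = np.argwhere(slab)
    phi0 = rng.uniform(0, 2 * np.pi)
    tracks = []
    for k in range(n_needles):
        phi = phi0 + 2 * np.pi * k / n_needles
        u = np.array([np.cos(phi), np.sin(phi)])
        # radial extent of the HR-CTV slab along this direction from the centroid
        rel = (orig[:2] + cols * sp[:2]) - centroid[:2]
        proj = rel @ u
        perp = np.abs(rel @ np.array([-u[1], u[0]]))
        along = proj[(proj > 0) & (perp < 2 * max(sp[:2]))]
        rmax = along.max() if along.size else 0.0
        placed = False
        for frac in (0.6, 0.45, 0.3, 0.15):
            xy = centroid[:2] + u * (frac * rmax) + rng.uniform(-1.0, 1.0, size=2)
            pts = track_dwells(xy[0], xy[1])
            if len(pts) >= 1:
                tracks.append(pts)
                placed = True
                break
        if not placed:
            # fall back to the tandem column; tumour too thin along this angle
            pts = track_dwells(centroid[0] + rng.uniform(-1, 1), centroid[1] + rng.uniform(-1, 1))
            if len(pts) == 0:
                raise ValueError(f"cannot place {n_needles} needles inside the HR-CTV")
            tracks.append(pts)

    positions = np.vstack([tandem] + tracks)
    if params.optimize_weights:
        base = _conformal_weights(structures, positions, params, rng)
    else:
        base = np.ones(len(positions))
    weights = base * np.exp(params.weight_noise_sigma * rng.standard_normal(len(positions)))
    prescription = float(rng.choice(params.prescriptions_gy))
    return DwellPlan(dwell_positions_mm=positions, dwell_weights=weights,
                     n_needles=n_needles, prescription_gy=prescription)


def point_kernel_dose(grid: VoxelGrid, positions_mm: np.ndarray, weights: np.ndarray,
                      kernel_constant: float = 1.0, r_min_mm: float = 1.0) -> np.ndarray:
    """Unnormalized inverse-square superposition:
    dose(v) = sum_i w_i * K / max(r_vi, r_min)^2."""
    xs, ys, zs = grid.voxel_centers_mm()
    dose = np.zeros(grid.shape)
    rmin2 = r_min_mm**2
    for p, w in zip(np.atleast_2d(positions_mm), np.atleast_1d(weights)):
        r2 = (
            (xs - p[0])[:, None, None] ** 2
            + (ys - p[1])[None, :, None] ** 2
            + (zs - p[2])[None, None, :] ** 2
        )
        np.maximum(r2, rmin2, out=r2)
        dose += (w * kernel_constant) / r2
    return dose


def compute_dose(structures: StructureSet, plan: DwellPlan,
                 kernel_constant: float | None = None,
                 r_min_mm: float = 1.0) -> DoseGrid:
    """Superpose inverse-square point-kernel dwells and normalize to D90.

    The kernel carries no anisotropy or radial dose function; geometry alone
    shapes the DVH.  After superposition the whole grid is rescaled so HR-CTV
    D90 equals the plan prescription, which also makes the kernel constant
    immaterial.
    """
    if plan.n_dwells == 0:
        raise ValueError("dwell plan is empty")
    K = 1.0 if kernel_constant is None else float(kernel_constant)
    grid = structures.grid
    dose = point_kernel_dose(grid, plan.dwell_positions_mm, plan.dwell_weights, K, r_min_mm)
    dg = DoseGrid(grid=grid, dose_gy=dose)
    d90 = dose_at_volume_fraction(dg, structures.mask("hrctv"), 0.9)
    dg.dose_gy *= plan.prescription_gy / d90
    return dg


def _patient_ids(n_plans: int, seed: int) -> list[int]:
    """Assign consecutive plans to patients of 2-5 fractions each."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    ids, pid, i = [], 0, 0
    while i < n_plans:
        k = int(rng.integers(2, 6))
        ids.extend([pid] * min(k, n_plans - i))
        i += k
        pid += 1
    return ids


def generate_plan_record(params: PhantomParams, index: int,
                         ring_width_mm: float = DEFAULT_RING_WIDTH_MM,
                         n_rings: int = MAX_RINGS) -> dict:
    """Run one plan end to end: anatomy -> dwells -> dose -> rings -> targets."""
    structures = sample_structures(params, index)
    plan = sample_dwell_plan(structures, params, index)
    dose = compute_dose(structures, plan, params.kernel_constant, params.r_min_mm)
    dist_map = exterior_distance_map(structures)
    decomps = {
        lbl: derive_sub_organs(structures, lbl, ring_width_mm, n_rings, distance_map=dist_map)
        for lbl in OAR_LABELS
    }
    metrics = {
        lbl: dvh_metrics(dose, structures.mask(lbl), structures.mask("hrctv"))
        for lbl in OAR_LABELS
    }
    return ft.assemble_plan_record(
        decomps, metrics, plan_id=index, patient_id=-1,
        prescription_gy=plan.prescription_gy,
        d90_gy=metrics["bladder"].d90_gy,
        n_needles=plan.n_needles,
    )


def generate_cohort(params: PhantomParams, n_plans: int,
                    ring_width_mm: float = DEFAULT_RING_WIDTH_MM,
                    n_rings: int = MAX_RINGS,
                    progress: bool = False) -> pd.DataFrame:
    """Generate the full synthetic cohort table (one row per fraction plan).

    Consecutive groups of 2-5 plans share a patient_id, mimicking
    multi-fraction patients.  Fully reproducible from ``params.seed``.
    """
    if n_plans < 1:
        raise ValueError("n_plans must be >= 1")
    pids = _patient_ids(n_plans, params.seed)
    rows = []
    for i in range(n_plans):
        try:
            rec = generate_plan_record(params, i, ring_width_mm, n_rings)
        except ValueError as exc:
            raise ValueError(f"plan {i} failed: {exc}") from exc
        rec["patient_id"] = pids[i]
        rows.append(rec)
        if progress and (i + 1) % 20 == 0:
            print(f"  generated {i + 1}/{n_plans} plans")
    return pd.DataFrame(rows)
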