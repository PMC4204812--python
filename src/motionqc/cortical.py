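"""Average cortical distance (d_avg) from a gray-matter mask.

d_avg is the mean Euclidean distance from the image's world origin to the
voxels on the *outer* cortical surface.  It is the lever arm that converts
rotation angles into millimetres of displacement, so it must reflect the
brain's outer envelope: surface voxels are found by flood-filling the
background from the volume border (6-connectivity) and keeping mask voxels
adjacent to that exterior background — interior cavities (ventricles, closed
sulci) are thereby excluded.  A naive boundary mode (any mask voxel touching
any background) is available for comparison.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateDesignError, EmptyMaskError
from .volume import VolumeGrid, reslice_isotropic

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclasses.dataclass(frozen=True)
class CorticalDistanceResult:
    d_avg: float
    surface_voxel_count: int
    origin_world: tuple[float, float, float]


def outer_surface_voxels(
    mask: VolumeGrid, exterior_only: bool = True
) -> np.ndarray:
    """Voxel indices (N x 3) of the mask's outer surface.

    ``exterior_only=True`` (default): mask voxels 6-adjacent to background
    reachable from the volume border — interior cavities are excluded.
    ``exterior_only=False``: naive boundary (adjacent to any background).
    """
    m = mask.astype_mask()
    if not np.any(m):
        raise EmptyMaskError("mask is empty")
    background = ~m
    if exterior_only:
        labels, _ = ndimage.label(background, structure=_FACE_STRUCT)
        border_labels = set()
        for axis in range(3):
            for face in (0, -1):
                border_labels |= set(np.unique(np.take(labels, face, axis=axis)))
        border_labels.discard(0)
        if border_labels:
            exterior = np.isin(labels, sorted(border_labels))
        else:  # mask fills the whole volume: every face voxel is surface
            exterior = np.zeros_like(m)
    else:
        exterior = background
    # mask voxels touching the exterior, or lying on the volume border
    touching = m & ndimage.binary_dilation(exterior, structure=_FACE_STRUCT)
    border = np.zeros_like(m)
    for axis in range(3):
        sl = [slice(None)] * 3
        for face in (0, -1):
            sl[axis] = face
            border[tuple(sl)] = True
        sl[axis] = slice(None)
    touching |= m & border
    return np.argwhere(touching)


def average_cortical_distance(
    mask: VolumeGrid,
    origin=(0.0, 0.0, 0.0),
    exterior_only: bool = True,
) -> CorticalDistanceResult:
    """Mean Euclidean distance (mm) from ``origin`` to the outer-surface voxels.

    ``origin`` is a world-space point in mm; the default (0, 0, 0) is the
    image volume's point of origin as encoded in the affine.
    """
    origin = np.asarray(origin, dtype=float)
    surf = outer_surface_voxels(mask, exterior_only=exterior_only)
    world = mask.world(surf)
    lo = world.min(axis=0)
    hi = world.max(axis=0)
    if np.any(origin < lo - 1e-9) or np.any(origin > hi + 1e-9):
        warnings.warn(
            f"origin {tuple(origin)} lies outside the mask's field of view",
            stacklevel=2,
        )
    dists = np.linalg.norm(world - origin, axis=1)
    return CorticalDistanceResult(
        d_avg=float(dists.mean()),
        surface_voxel_count=int(surf.shape[0]),
        origin_world=tuple(float(v) for v in origin),
    )


def cortical_distance_pipeline(
    gm: VolumeGrid,
    origin=(0.0, 0.0, 0.0),
    probability_threshold: float = 0.5,
    spacing: float = 1.0,
    spline_order: int = 7,
    exterior_only: bool = True,
) -> CorticalDistanceResult:
    """Full d_avg pipeline from a gray-matter partition.

    Probability maps are binarized at ``probability_threshold``, resliced to
    isotropic resolution (default 1 mm), and passed through surface
    extraction and distance averaging.
    """
    mask = VolumeGrid(gm.data >= probability_threshold, gm.affine)
    lin = mask.affine[:3, :3]
    already_target = np.allclose(mask.spacing, spacing, atol=1e-9) and np.allclose(
        lin, np.diag(np.diag(lin)), atol=1e-9
    )
    if not already_target:
        mask = reslice_isotropic(
            mask, spacing=spacing, spline_order=spline_order, is_mask=True
        )
    return average_cortical_distance(mask, origin=origin, exterior_only=exterior_only)


@dataclasses.dataclass(frozen=True)
class CohortTrend:
    slope_mm_per_year: float
    intercept_mm: float
    spearman_rho: float
    spearman_p: float
    n: int


def cohort_trend(results) -> CohortTrend:
    """Age trend of d_avg across a cohort.

    Parameters
    ----------
    results
        Iterable of ``(age_months, d_avg_mm)`` pairs, n >= 3 with non-constant
        ages.

    Returns the least-squares slope converted to mm/year plus Spearman's rank
    correlation (the field's standard nonparametric association measure).
    """
    arr = np.asarray(list(results), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DegenerateDesignError("need >= 3 (age_months, d_avg) pairs")
    ages, davgs = arr[:, 0], arr[:, 1]
    if np.ptp(ages) == 0:
        raise DegenerateDesignError("ages are constant; trend is undefined")
    fit = stats.linregress(ages, davgs)
    if np.ptp(davgs) == 0:  # flat outcome: no rank association by definition
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(ages, davgs)
    return CohortTrend(
        slope_mm_per_year=float(fit.slope * 12.0),
        intercept_mm=float(fit.intercept),
        spearman_rho=float(rho),
        spearman_p=float(p),
        n=arr.shape[0],
    )
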