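"""Phantom-timeseries motion replay and motion-fingerprint traces.

To isolate the purely geometric signal change a recorded head trajectory
induces, the first volume of a series is replicated T times and each copy is
resampled through the inverse of that volume's rigid motion transform
(high-order B-spline interpolation, zero fill outside the field of view).
Signal change is scored in 9 automatically derived regions of interest: 8 at
the brain/non-brain interface near the corners of the volume (where the
lever-arm effect of rotation is largest) and 1 at the brain's center.  The
ROI timecourses also serve as motion-fingerprint nuisance regressors.

Susceptibility-by-motion (motion x B0) interactions are NOT modelled: the
replay is purely geometric, and every score carries that statement in its
metadata.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .bspline import SplineInterpolator
from .errors import GeometryError, MotionQCError
from .kinematics import params_to_transform
from .params import RealignmentParams
from .volume import VolumeGrid, resample_rigid

ROI_LABELS = tuple(f"corner_{i}" for i in range(1, 9)) + ("center",)

#: Signal-change scores describe geometric resampling effects only.
REPLAY_MODEL_NOTE = "geometric replay; motion x B0 interaction not modelled"


@dataclasses.dataclass
class FmriSeries:
    """4-D fMRI series: VolumeGrid data with time as the 4th axis."""

    data: np.ndarray
    affine: np.ndarray
    tr: float = 2.0  # repetition time, seconds (metadata only)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise GeometryError(f"fMRI series must be 4-D, got shape {self.data.shape}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def volume(self, t: int) -> VolumeGrid:
        return VolumeGrid(self.data[..., t], self.affine)


@dataclasses.dataclass(frozen=True)
class RoiSet:
    """9 pairwise-disjoint ROIs: 8 corner-interface + 1 center."""

    masks: dict  # label -> boolean array
    affine: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.masks) != ROI_LABELS:
            raise GeometryError(f"expected ROI labels {ROI_LABELS}")
        claimed = None
        for label, m in self.masks.items():
            if not np.any(m):
                raise GeometryError(f"ROI {label} is empty")
            if claimed is None:
                claimed = np.zeros_like(m)
            if np.any(claimed & m):
                raise GeometryError(f"ROI {label} overlaps an earlier ROI")
            claimed = claimed | m

    def __len__(self) -> int:
        return len(self.masks)

    def labelled_volume(self) -> VolumeGrid:
        """All ROIs in one integer-labelled volume (labels 1-9)."""
        first = next(iter(self.masks.values()))
        out = np.zeros(first.shape, dtype=np.int16)
        for i, m in enumerate(self.masks.values(), start=1):
            out[m] = i
        return VolumeGrid(out, self.affine)


@dataclasses.dataclass(frozen=True)
class SignalChangeScore:
    """Mean absolute ROI signal change induced by a replayed trajectory."""

    per_roi_trace: np.ndarray  # 9 x T
    score: float
    parameter_set: str
    model_note: str = REPLAY_MODEL_NOTE


def build_phantom(
    series: FmriSeries, params: RealignmentParams, spline_order: int = 7
) -> FmriSeries:
    """Replay a trajectory in a motion-free phantom timeseries.

    Volume t of the output is the first volume of ``series`` resampled
    through the inverse of volume t's rigid motion transform, so the phantom
    moves exactly as the recorded head did while carrying no physiological
    signal.
    """
    if params.volume_count != series.n_volumes:
        raise GeometryError(
            f"parameter rows ({params.volume_count}) must match "
            f"volume count ({series.n_volumes})"
        )
    first = series.volume(0)
    if not np.all(np.isfinite(first.data)):
        raise GeometryError("first volume contains non-finite values")
    interp = SplineInterpolator(first.data, degree=spline_order, cval=0.0)
    out = np.empty_like(series.data)
    for t in range(series.n_volumes):
        row = params.values[t]
        if np.allclose(row, 0.0):
            out[..., t] = first.data
            continue
        moved = resample_rigid(
            first, params_to_transform(row), spline_order=spline_order,
            interpolator=interp,
        )
        out[..., t] = moved.data
    return FmriSeries(out, series.affine.copy(), tr=series.tr)


def _boundary_shell(mask: np.ndarray) -> np.ndarray:
    """Two-sided shell around the mask boundary (inner + just-outside layer)."""
    struct = ndimage.generate_binary_structure(3, 1)
    inner = mask & ~ndimage.binary_erosion(mask, structure=struct)
    return ndimage.binary_dilation(inner, structure=struct)


def _ball(shape, center, radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius**2


def derive_rois(brain_mask: VolumeGrid, radius_vox: float = 2.0) -> RoiSet:
    """Derive the 9 interface/center ROIs from a brain mask.

    For each of the 8 volume corners, the corner-to-centroid ray is walked to
    the first in-mask voxel; the ROI is a ball of ``radius_vox`` around that
    entry point, intersected with a two-sided shell of the mask boundary (the
    brain/non-brain interface).  The 9th ROI is a ball at the mask centroid.
    Overlaps are resolved by first-claim priority; an empty ROI after
    trimming raises a geometry error.
    """
    m = brain_mask.astype_mask()
    if not np.any(m):
        raise GeometryError("brain mask is empty")
    shape = np.asarray(m.shape)
    if np.any(shape < 8):
        raise GeometryError("mask volume too small for ROI derivation (< 8 voxels/axis)")
    centroid = np.asarray(ndimage.center_of_mass(m))
    shell = _boundary_shell(m)
    masks: dict[str, np.ndarray] = {}
    claimed = np.zeros_like(m)
    corners = [
        np.array([i * (shape[0] - 1), j * (shape[1] - 1), k * (shape[2] - 1)], dtype=float)
        for i in (0, 1) for j in (0, 1) for k in (0, 1)
    ]
    for idx, corner in enumerate(corners, start=1):
        direction = centroid - corner
        length = np.linalg.norm(direction)
        if length == 0:
            raise GeometryError("mask centroid coincides with a volume corner")
        direction = direction / length
        seed = None
        for step in np.arange(0.0, length, 0.5):
            vox = np.round(corner + step * direction).astype(int)
            if np.all(vox >= 0) and np.all(vox < shape) and m[tuple(vox)]:
                seed = vox
                break
        if seed is None:
            raise GeometryError(f"corner ray {idx} never enters the mask")
        roi = _ball(m.shape, seed, radius_vox) & shell & ~claimed
        if not np.any(roi):
            raise GeometryError(f"corner ROI {idx} is empty after trimming")
        masks[f"corner_{idx}"] = roi
        claimed = claimed | roi
    center_roi = _ball(m.shape, centroid, radius_vox) & m & ~claimed
    if not np.any(center_roi):
        raise GeometryError("center ROI is empty after trimming")
    masks["center"] = center_roi
    return RoiSet(masks=masks, affine=brain_mask.affine.copy())


def roi_traces(series: FmriSeries, rois: RoiSet) -> np.ndarray:
    """9 x T matrix of mean ROI intensity per timepoint."""
    spatial = series.data.shape[:3]
    traces = np.empty((len(rois), series.n_volumes))
    for r, (label, m) in enumerate(rois.masks.items()):
        if m.shape != spatial:
            raise GeometryError(
                f"ROI {label} shape {m.shape} does not match series {spatial}"
            )
        traces[r] = series.data[m].mean(axis=0)
    return traces


def signal_change_score(
    traces: np.ndarray,
    parameter_set: str = "complete",
    baseline: str = "first",
) -> SignalChangeScore:
    """Score motion-induced signal change from the 9 ROI timecourses.

    Each trace is converted to its absolute deviation from baseline (the t=0
    value by default, the replay's reference volume; ``baseline="mean"`` uses
    the trace mean); the score is the mean of those deviations over all ROIs
    and timepoints t >= 1.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[1] < 2:
        raise MotionQCError("need a 2-D ROI x time matrix with T >= 2")
    if baseline == "first":
        ref = traces[:, :1]
    elif baseline == "mean":
        ref = traces.mean(axis=1, keepdims=True)
    else:
        raise MotionQCError(f"unknown baseline {baseline!r}")
    dev = np.abs(traces - ref)
    score = float(dev[:, 1:].mean())
    return SignalChangeScore(
        per_roi_trace=dev, score=score, parameter_set=parameter_set
    )


def fingerprint_traces(
    traces: np.ndarray, k: int = 3, include_shifted: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Motion-fingerprint regressor columns from the 9 ROI traces.

    ``k=9``: the mean-centered traces themselves; ``k=3``: the first three
    principal-component score series of the centered traces.  With
    ``include_shifted`` each column's one-timepoint-back-shifted copy is
    appended (first entry zero-padded), giving ``k * 2`` columns.

    Returns ``(T x columns array, column names)``.  PC signs are fixed so the
    largest-magnitude loading is positive.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] != 9:
        raise MotionQCError("expected a 9 x T trace matrix")
    if traces.shape[1] < 3:
        raise MotionQCError("need T >= 3 timepoints")
    if k not in (3, 9):
        raise MotionQCError(f"k must be 3 or 9, got {k}")
    x = traces.T - traces.T.mean(axis=0, keepdims=True)  # T x 9
    if k == 9:
        cols = x
        names = list(ROI_LABELS)
    else:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        scores = u[:, :3] * s[:3]
        for j in range(3):
            lead = vt[j, np.argmax(np.abs(vt[j]))]
            if lead < 0:
                scores[:, j] = -scores[:, j]
        cols = scores
        names = [f"mfp_pc{j + 1}" for j in range(3)]
    if include_shifted:
        shifted = np.vstack([np.zeros((1, cols.shape[1])), cols[:-1]])
        cols = np.hstack([cols, shifted])
        names = names + [f"{n}_lag1" for n in names]
    return cols, names
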