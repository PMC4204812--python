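"""Rigid-body kinematics: transforms, total displacement, sensitivity sweeps.

The six realignment parameters only describe head motion jointly.  Translations
are already millimetres; rotations (radians) become millimetres only at a
reference distance from the rotation origin — the *average cortical distance*
``d_avg`` (65 mm is the field's representative adult value).  Total
displacement (TD) collapses a parameter row into a single scalar in mm.

Three scalarizations are provided:

``fig1_vector_sum``
    TD = ||(tx, ty, tz) + d_avg * (rx, ry, rz)||_2 — each rotation angle is
    converted to an arc length at d_avg and paired component-wise with the
    translation along the same axis before taking the Euclidean norm.  This is
    the package default.
``sphere_mean``
    Mean displacement of points sampled uniformly on a sphere of radius d_avg
    under the full rigid transform — the geometrically exact reference.
``reference_point``
    Displacement of a single probe point at distance d_avg along a
    configurable unit direction.

Absolute motion references the first volume (whose parameters are zero by
realignment convention); relative motion is scan-to-scan, computed by
differencing consecutive parameter rows (a transform-composition variant is
available via ``relative_via_transforms``).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MotionQCError
from .params import PARAMETER_SETS, RealignmentParams, reduce_params

DISPLACEMENT_METHODS = ("fig1_vector_sum", "sphere_mean", "reference_point")
DISPLACEMENT_MODES = ("absolute", "relative")

#: Rotation composition order for building a rigid transform from parameters:
#: M = Translate(tx,ty,tz) @ Rx(rx) @ Ry(ry) @ Rz(rz).  SPM's spm_matrix
#: order, since the parameter files this package consumes come from SPM-style
#: realignment.  Centralized here: change this constant to change convention.
ROTATION_ORDER = "xyz"


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """A 4 x 4 homogeneous world-space rigid-body transform (mm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise InvalidParameterError(f"rigid transform must be 4x4, got {m.shape}")
        if not np.allclose(m[3], (0.0, 0.0, 0.0, 1.0), atol=1e-9):
            raise InvalidParameterError("last row of a rigid transform must be (0,0,0,1)")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-9
        ):
            raise InvalidParameterError(
                "upper-left 3x3 block must be a proper rotation (orthonormal, det +1)"
            )
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform(_homogeneous(r, -r @ self.translation))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (..., 3) array of world-space points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other`` (other applied first)."""
        return RigidTransform(self.matrix @ other.matrix)


@dataclasses.dataclass(frozen=True)
class DisplacementSeries:
    """Per-volume scalar displacement in mm, with its defining metadata."""

    values: np.ndarray
    mode: str
    method: str
    d_avg: float
    parameter_set: str = "complete"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidParameterError("displacement values must be a 1-D vector")
        if not np.all(np.isfinite(v)) or np.any(v < -1e-12):
            raise InvalidParameterError("displacements must be finite and non-negative")
        v = np.maximum(v, 0.0)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        if self.mode not in DISPLACEMENT_MODES:
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.method not in DISPLACEMENT_METHODS:
            raise InvalidParameterError(f"unknown method {self.method!r}")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass(frozen=True)
class SignDiscordanceCount:
    """Per-axis counts of rows where shift and rotation have opposite signs."""

    per_axis: tuple[int, int, int]
    total_datapoints: int

    def __post_init__(self) -> None:
        if any(c < 0 or c > self.total_datapoints for c in self.per_axis):
            raise InvalidParameterError("counts must lie in [0, total_datapoints]")


def _homogeneous(r: np.ndarray, t: np.ndarray) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = t
    return m


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]], dtype=float)
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]], dtype=float)
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]], dtype=float)
    return mx @ my @ mz


def params_to_transform(p) -> RigidTransform:
    """Build the rigid transform M = T(tx,ty,tz) @ Rx @ Ry @ Rz from one row."""
    p = np.asarray(p, dtype=float).reshape(-1)
    if p.shape != (6,):
        raise InvalidParameterError(f"expected a length-6 parameter row, got {p.shape}")
    if not np.all(np.isfinite(p)):
        raise InvalidParameterError("parameter row contains non-finite entries")
    return RigidTransform(_homogeneous(_rotation_matrix(*p[3:]), p[:3]))


def transform_to_params(transform: RigidTransform) -> np.ndarray:
    """Recover the length-6 row (tx ty tz rx ry rz) from a rigid transform.

    Exact inverse of :func:`params_to_transform` for |ry| < pi/2 (head motion
    is far below gimbal lock).
    """
    m = transform.matrix
    r = m[:3, :3]
    ry = np.arcsin(np.clip(r[0, 2], -1.0, 1.0))
    rz = np.arctan2(-r[0, 1], r[0, 0])
    rx = np.arctan2(-r[1, 2], r[2, 2])
    return np.array([m[0, 3], m[1, 3], m[2, 3], rx, ry, rz])


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic lattice)."""
    i = np.arange(n)
    golden = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _displacement_rows(
    rows: np.ndarray,
    d_avg: float,
    method: str,
    sphere_points: np.ndarray | None,
    reference_direction: np.ndarray,
) -> np.ndarray:
    if method == "fig1_vector_sum":
        return np.linalg.norm(rows[:, :3] + d_avg * rows[:, 3:], axis=1)
    out = np.empty(rows.shape[0])
    if method == "sphere_mean":
        pts = d_avg * sphere_points
        for t, row in enumerate(rows):
            m = params_to_transform(row)
            out[t] = np.mean(np.linalg.norm(m.apply(pts) - pts, axis=1))
        return out
    # reference_point
    probe = d_avg * reference_direction
    for t, row in enumerate(rows):
        out[t] = np.linalg.norm(params_to_transform(row).apply(probe) - probe)
    return out


def displacement_series(
    params: RealignmentParams,
    d_avg: float = 65.0,
    mode: str = "absolute",
    method: str = "fig1_vector_sum",
    parameter_set: str = "complete",
    n_sphere_points: int = 500,
    reference_direction=(1.0, 0.0, 0.0),
    relative_via_transforms: bool = False,
) -> DisplacementSeries:
    """Total displacement (absolute) or scan-to-scan displacement (relative).

    Parameters
    ----------
    d_avg
        Average cortical distance in mm (> 0); the lever arm converting
        rotation angles to millimetres.
    parameter_set
        ``complete`` | ``translation_only`` | ``rotation_only``: the reduced
        sets zero the complementary columns before any displacement is
        computed.
    relative_via_transforms
        Relative mode variant: compose M_t @ M_{t-1}^-1 instead of
        differencing parameter rows (default is row differencing).
    """
    if d_avg <= 0:
        raise MotionQCError(f"d_avg must be > 0 mm, got {d_avg}")
    if mode not in DISPLACEMENT_MODES:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if parameter_set not in PARAMETER_SETS:
        raise InvalidParameterError(f"unknown parameter set {parameter_set!r}")
    if parameter_set != "complete":
        params = reduce_params(params, parameter_set)
    rows = params.values
    if mode == "relative":
        if relative_via_transforms:
            mats = [params_to_transform(r) for r in rows]
            deltas = [np.zeros(6)] + [
                transform_to_params(mats[t].compose(mats[t - 1].inverse()))
                for t in range(1, len(mats))
            ]
            rows = np.asarray(deltas)
        else:
            rows = np.vstack([np.zeros((1, 6)), np.diff(rows, axis=0)])
    pts = fibonacci_sphere(n_sphere_points) if method == "sphere_mean" else None
    ref_dir = np.asarray(reference_direction, dtype=float)
    nrm = np.linalg.norm(ref_dir)
    if nrm == 0:
        raise InvalidParameterError("reference_direction must be non-zero")
    ref_dir = ref_dir / nrm
    values = _displacement_rows(rows, d_avg, method, pts, ref_dir)
    if mode == "relative":
        values[0] = 0.0
    return DisplacementSeries(
        values, mode=mode, method=method, d_avg=d_avg, parameter_set=parameter_set
    )


def davg_sensitivity_sweep(
    params: RealignmentParams,
    d_min: float = 50.0,
    d_max: float = 80.0,
    step: float = 0.5,
    d_ref: float = 65.0,
    method: str = "fig1_vector_sum",
    n_sphere_points: int = 500,
) -> pd.DataFrame:
    """Sweep d_avg over [d_min, d_max] and express the per-d median
    displacement as a percentage of the median at the d_ref reference.

    Returns a DataFrame with columns ``d_avg``, ``percent_absolute``,
    ``percent_relative``; the summary statistic is the median over timepoints.
    The row at ``d_ref`` is exactly 100%.
    """
    if not (d_min < d_ref < d_max) or step <= 0:
        raise MotionQCError(
            f"degenerate sweep range: need d_min < d_ref < d_max and step > 0, "
            f"got ({d_min}, {d_ref}, {d_max}, step={step})"
        )
    grid = np.arange(d_min, d_max + step / 2.0, step)
    if not np.any(np.isclose(grid, d_ref)):
        grid = np.sort(np.append(grid, d_ref))
    refs = {}
    for mode in DISPLACEMENT_MODES:
        med = float(
            np.median(
                displacement_series(
                    params, d_ref, mode, method, n_sphere_points=n_sphere_points
                ).values
            )
        )
        if med == 0.0:
            warnings.warn(
                f"median {mode} displacement at d_ref={d_ref} is zero; "
                "sweep percentages are undefined (NaN)",
                stacklevel=2,
            )
        refs[mode] = med
    rows = []
    for d in grid:
        rec = {"d_avg": float(d)}
        for mode in DISPLACEMENT_MODES:
            if np.isclose(d, d_ref):
                pct = 100.0 if refs[mode] > 0 else np.nan
            elif refs[mode] == 0.0:
                pct = np.nan
            else:
                med = float(
                    np.median(
                        displacement_series(
                            params, float(d), mode, method,
                            n_sphere_points=n_sphere_points,
                        ).values
                    )
                )
                pct = 100.0 * med / refs[mode]
            rec[f"percent_{mode}"] = pct
        rows.append(rec)
    return pd.DataFrame(rows)


def sign_discordance(params: RealignmentParams) -> SignDiscordanceCount:
    """Count rows where the same-axis shift and rotation have opposite signs.

    For each axis pair (tx, rx), (ty, ry), (tz, rz) a row is discordant when
    the product of the two values is strictly negative; rows where either
    member is exactly zero count as concordant (zero has no sign).
    """
    products = params.translations * params.rotations
    counts = (products < 0.0).sum(axis=0)
    return SignDiscordanceCount(
        per_axis=tuple(int(c) for c in counts),
        total_datapoints=params.volume_count,
    )
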