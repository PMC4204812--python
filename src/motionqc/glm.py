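"""Motion-regressor design matrices and voxel-wise GLM variance partitioning.

Design sets
-----------
``rps_complete`` / ``rps_to`` / ``rps_ro``
    The 6 realignment parameters (complete, translation-only, rotation-only).
``volterra24``
    The Friston 24-parameter expansion: the 6 parameters, their
    one-timepoint-back-shifted copies, and the squares of all twelve —
    24 columns.  This set explains the most motion variance and serves as
    the 100% reference.
``mfp_complete`` / ``mfp_to`` / ``mfp_ro``
    Motion fingerprint: 3 principal-component traces of the 9 phantom-replay
    ROI timecourses plus their shifted copies (6 columns).
``mfp9_shifted``
    All 9 ROI traces plus shifted copies (18 columns).

"Shifted back in time" means column t holds the value from t-1 with the
first row zero-padded (the standard lagged-regressor construction).  All
columns are mean-centered; the intercept is appended at fit time.  No
drift/high-pass regressors are included by default (``add_drift`` adds
polynomial drift columns for realistic synthetic tests).  "Variance
explained" is operationalized as mean R^2 over the analysis mask (median
also reported); no adjusted-R^2 correction is applied, so larger sets
explain more variance by construction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg

from .errors import DegenerateDesignError, MotionQCError
from .params import PARAM_NAMES, RealignmentParams, reduce_params
from .phantom import FmriSeries, fingerprint_traces
from .volume import VolumeGrid

DESIGN_SETS = (
    "rps_complete", "rps_to", "rps_ro", "volterra24",
    "mfp_complete", "mfp_to", "mfp_ro", "mfp9_shifted",
)

_RPS_REDUCTION = {
    "rps_complete": "complete",
    "rps_to": "translation_only",
    "rps_ro": "rotation_only",
    "mfp_complete": "complete",
    "mfp_to": "translation_only",
    "mfp_ro": "rotation_only",
}


@dataclasses.dataclass(frozen=True)
class DesignMatrix:
    """T x K regressor matrix tagged with its parameter-set identity."""

    columns: np.ndarray
    set_id: str
    column_names: tuple
    includes_intercept: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.columns, dtype=float)
        if c.ndim != 2:
            raise MotionQCError("design columns must form a 2-D matrix")
        if len(self.column_names) != c.shape[1]:
            raise MotionQCError("column_names length must match column count")
        c = c.copy()
        c.flags.writeable = False
        object.__setattr__(self, "columns", c)

    @property
    def n_timepoints(self) -> int:
        return self.columns.shape[0]

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


def shift_back(x: np.ndarray, lag: int = 1) -> np.ndarray:
    """Lagged copy: row t holds row t-lag; leading rows zero-padded."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    if lag < x.shape[0]:
        out[lag:] = x[:-lag] if lag > 0 else x
    return out


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def build_design(
    params: RealignmentParams | None,
    set_id: str,
    traces: np.ndarray | None = None,
    add_drift: int = 0,
) -> DesignMatrix:
    """Build a mean-centered motion design matrix.

    ``rps*`` and ``volterra24`` sets need ``params``; ``mfp*`` sets need the
    9 x T phantom-replay ROI ``traces`` (computed from the correspondingly
    reduced parameter set — the set_id records that identity).  ``add_drift``
    appends Legendre polynomial drift columns of that order.
    """
    if set_id not in DESIGN_SETS:
        raise MotionQCError(f"unknown design set {set_id!r}; expected one of {DESIGN_SETS}")
    if set_id.startswith("mfp"):
        if traces is None:
            raise MotionQCError(f"design set {set_id} requires ROI traces")
        k = 9 if set_id == "mfp9_shifted" else 3
        cols, names = fingerprint_traces(traces, k=k, include_shifted=True)
    else:
        if params is None:
            raise MotionQCError(f"design set {set_id} requires realignment parameters")
        reduced = reduce_params(params, _RPS_REDUCTION.get(set_id, "complete"))
        p = reduced.values
        names = list(PARAM_NAMES)
        if set_id == "volterra24":
            lagged = shift_back(p)
            cols = np.hstack([p, lagged, p**2, lagged**2])
            names = (
                names
                + [f"{n}_lag1" for n in PARAM_NAMES]
                + [f"{n}_sq" for n in PARAM_NAMES]
                + [f"{n}_lag1_sq" for n in PARAM_NAMES]
            )
        else:
            cols = p.copy()
    t = cols.shape[0]
    if add_drift > 0:
        x = np.linspace(-1.0, 1.0, t)
        drift = np.column_stack([np.polynomial.legendre.Legendre.basis(d)(x)
                                 for d in range(1, add_drift + 1)])
        cols = np.hstack([cols, drift])
        names = list(names) + [f"drift_{d}" for d in range(1, add_drift + 1)]
    cols = _center(cols)
    if t < cols.shape[1] + 2:
        raise DegenerateDesignError(
            f"too few timepoints (T={t}) for {cols.shape[1]} regressors"
        )
    if np.all(np.abs(cols) < 1e-12):
        warnings.warn(
            f"design {set_id} is all-zero after centering "
            "(degenerate source parameter set)",
            stacklevel=2,
        )
    return DesignMatrix(cols, set_id=set_id, column_names=tuple(names))


@dataclasses.dataclass(frozen=True)
class GlmResult:
    """Voxel-wise OLS fit summary for one design set."""

    r2: np.ndarray            # per voxel
    f: np.ndarray             # per voxel omnibus F
    df_num: int               # effective K
    df_den: int               # T - K_eff - 1
    mean_r2: float
    median_r2: float
    mean_f: float
    set_id: str
    n_voxels: int


def _extract_timeseries(series, mask) -> np.ndarray:
    """Return a T x V data matrix from a series/matrix plus optional mask."""
    if isinstance(series, FmriSeries):
        m = None
        if mask is not None:
            m = mask.astype_mask() if isinstance(mask, VolumeGrid) else np.asarray(mask, bool)
        if m is None:
            m = np.ones(series.data.shape[:3], dtype=bool)
        return series.data[m].T  # T x V
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2:
        raise MotionQCError("expected an FmriSeries or a T x V matrix")
    return arr


def fit_glm(series, design: DesignMatrix, mask=None) -> GlmResult:
    """Voxel-wise OLS with intercept; omnibus F and R^2 per voxel.

    Rank-deficient designs are reduced via pivoted QR; degrees of freedom use
    the effective column count K_eff.  For each voxel
    ``R^2 = 1 - SSE/SST`` and ``F = (R^2/K_eff) / ((1-R^2)/(T-K_eff-1))``.
    """
    y = _extract_timeseries(series, mask)
    t, v = y.shape
    x0 = _center(np.asarray(design.columns, dtype=float))
    if x0.shape[0] != t:
        raise MotionQCError(
            f"design has {x0.shape[0]} rows but data has {t} timepoints"
        )
    # pivoted QR to find an independent column subset
    q, r, piv = linalg.qr(x0, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(x0.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank == 0:
        raise DegenerateDesignError(f"design {design.set_id} has rank 0 after centering")
    keep = np.sort(piv[:rank])
    x = x0[:, keep]
    k_eff = rank
    df_den = t - k_eff - 1
    if df_den < 1:
        raise DegenerateDesignError(
            f"non-positive residual dof (T={t}, K_eff={k_eff})"
        )
    xf = np.column_stack([np.ones(t), x])
    beta, *_ = np.linalg.lstsq(xf, y, rcond=None)
    resid = y - xf @ beta
    sse = np.sum(resid**2, axis=0)
    ybar = y.mean(axis=0, keepdims=True)
    sst = np.sum((y - ybar) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(r2 < 1.0, (r2 / k_eff) / ((1.0 - r2) / df_den), np.inf)
    return GlmResult(
        r2=r2,
        f=f,
        df_num=k_eff,
        df_den=df_den,
        mean_r2=float(r2.mean()),
        median_r2=float(np.median(r2)),
        mean_f=float(np.mean(f[np.isfinite(f)])) if np.any(np.isfinite(f)) else float("inf"),
        set_id=design.set_id,
        n_voxels=v,
    )


def percent_of_reference(
    result: GlmResult, reference: GlmResult, statistic: str = "mean"
) -> float | None:
    """Variance explained as a percentage of the reference set's (typically
    volterra24's) mean R^2 over the same mask; None when the reference
    explains nothing."""
    if statistic == "mean":
        num, den = result.mean_r2, reference.mean_r2
    elif statistic == "median":
        num, den = result.median_r2, reference.median_r2
    else:
        raise MotionQCError(f"unknown statistic {statistic!r}")
    if result.n_voxels != reference.n_voxels:
        raise MotionQCError("result and reference must share the same mask")
    if den == 0:
        return None
    return 100.0 * num / den
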