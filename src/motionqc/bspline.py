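"""B-spline interpolation of volumetric data, spline orders 0-7.

Orders up to 5 delegate to :func:`scipy.ndimage.map_coordinates`.  Orders 6
and 7 are evaluated natively with the classic two-step scheme: a recursive
inverse filter turns samples into B-spline coefficients (so interpolation is
exact at lattice points), then the tensor-product cardinal B-spline kernel is
evaluated at the requested coordinates.  Kernel and filter poles are derived
numerically from :class:`scipy.interpolate.BSpline`, not hard-coded.

Out-of-field behaviour is "constant": the volume is padded with ``cval``
before prefiltering and coordinates beyond the padded support return
``cval``.  This suits phantoms embedded in a zero background.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline

MAX_ORDER = 7


@lru_cache(maxsize=None)
def bspline_kernel(degree: int) -> BSpline:
    """Centered cardinal B-spline of the given degree (support (-(d+1)/2, (d+1)/2))."""
    knots = np.arange(degree + 2, dtype=float) - (degree + 1) / 2.0
    return BSpline.basis_element(knots, extrapolate=False)


def _kernel_values(degree: int, x: np.ndarray) -> np.ndarray:
    k = bspline_kernel(degree)
    out = k(x)
    return np.nan_to_num(out, nan=0.0, copy=False)


@lru_cache(maxsize=None)
def _tap_poly_coeffs(degree: int) -> np.ndarray:
    """Per-tap kernel weights as exact polynomials in the fractional part.

    Row o holds coefficients (ascending powers) of the degree-d polynomial
    P_o(u) = B_d(u + c0 - o) on u in [0, 1), which stays within a single
    polynomial piece of the kernel; c0 centers the tap window.
    """
    taps = degree + 1
    c0 = (degree - 1) // 2 if degree % 2 else degree / 2.0 - 0.5
    u = (np.arange(taps) + 0.5) / taps
    vander = np.vander(u, taps, increasing=True)
    coeffs = np.empty((taps, taps))
    for o in range(taps):
        coeffs[o] = np.linalg.solve(vander, _kernel_values(degree, u + c0 - o))
    return coeffs


@lru_cache(maxsize=None)
def prefilter_poles(degree: int) -> tuple[float, ...]:
    """Poles (|z| < 1) of the inverse filter for the given spline degree."""
    if degree < 2:
        return ()
    half = degree // 2
    xi = np.arange(-half, half + 1, dtype=float)
    b = _kernel_values(degree, xi)
    roots = np.roots(b)
    poles = sorted(
        float(r.real) for r in roots if abs(r) < 1.0 - 1e-12 and abs(r.imag) < 1e-9
    )
    return tuple(poles)


def _filter_axis(c: np.ndarray, pole: float, axis: int) -> np.ndarray:
    """Causal/anti-causal recursion along one axis (mirror boundary)."""
    cw = np.moveaxis(c, axis, -1)
    n = cw.shape[-1]
    flat = np.ascontiguousarray(cw).reshape(-1, n)
    horizon = min(n, int(np.ceil(np.log(1e-16) / np.log(abs(pole)))) + 1)
    if horizon > 1:
        zk = pole ** np.arange(1, horizon)
        flat[:, 0] = flat[:, 0] + flat[:, 1:horizon] @ zk
    for i in range(1, n):
        flat[:, i] += pole * flat[:, i - 1]
    flat[:, n - 1] = (pole / (pole * pole - 1.0)) * (
        flat[:, n - 1] + pole * flat[:, n - 2]
    )
    for i in range(n - 2, -1, -1):
        flat[:, i] = pole * (flat[:, i + 1] - flat[:, i])
    return np.moveaxis(flat.reshape(cw.shape), -1, axis)


def spline_filter(data: np.ndarray, degree: int) -> np.ndarray:
    """Convert samples to B-spline coefficients (any supported degree)."""
    c = np.asarray(data, dtype=float).copy()
    poles = prefilter_poles(degree)
    if not poles:
        return c
    gain = 1.0
    for z in poles:
        gain *= (1.0 - z) * (1.0 - 1.0 / z)
    for axis in range(c.ndim):
        c *= gain
        for z in poles:
            c = _filter_axis(c, z, axis)
    return c


class SplineInterpolator:
    """Reusable interpolator: prefilter once, evaluate at many coordinate sets.

    Parameters
    ----------
    data
        3-D volume (voxel samples).
    degree
        Spline order, 0-7.
    cval
        Constant fill value outside the field of view.
    """

    def __init__(self, data: np.ndarray, degree: int = 7, cval: float = 0.0):
        if not 0 <= degree <= MAX_ORDER:
            raise ValueError(f"spline degree must be in 0..{MAX_ORDER}, got {degree}")
        self.degree = degree
        self.cval = float(cval)
        data = np.asarray(data, dtype=float)
        self.shape = data.shape
        if degree <= 5:
            self._coeff = data  # scipy handles prefilter + boundary itself
        else:
            self.pad = degree + 1
            padded = np.pad(data, self.pad, constant_values=self.cval)
            self._coeff = spline_filter(padded, degree)

    def __call__(self, coords: np.ndarray, chunk: int = 1 << 15) -> np.ndarray:
        """Evaluate at ``coords`` of shape (ndim, N) in voxel units."""
        coords = np.asarray(coords, dtype=float)
        if self.degree <= 5:
            return ndimage.map_coordinates(
                self._coeff, coords, order=self.degree, mode="constant",
                cval=self.cval, prefilter=self.degree > 1,
            )
        n = coords.shape[1]
        out = np.empty(n)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            out[sl] = self._eval_chunk(coords[:, sl])
        return out

    def _eval_chunk(self, coords: np.ndarray) -> np.ndarray:
        d = self.degree
        taps = d + 1
        x = coords + self.pad  # into padded coefficient grid
        # Valid window: every tap index in range without clipping.  Points
        # outside are >= 4 voxels beyond the data and return cval.
        inside = np.ones(x.shape[1], dtype=bool)
        lower = taps // 2 - 1 if d % 2 else taps // 2 - 0.5
        for ax in range(3):
            inside &= (x[ax] >= lower) & (
                x[ax] <= self._coeff.shape[ax] - taps // 2 - 1
            )
        xs = np.where(inside, x, float(taps))  # safe dummy coordinate
        if d % 2:
            base = np.floor(xs).astype(np.int64) - (d - 1) // 2
            frac = xs - np.floor(xs)
        else:  # even degree: taps centered on the nearest integer
            shifted = np.floor(xs + 0.5)
            base = shifted.astype(np.int64) - d // 2
            frac = xs + 0.5 - shifted
        ctab = _tap_poly_coeffs(d)  # taps x (d+1) polynomial coefficients
        c = self._coeff
        cflat = np.ascontiguousarray(c).ravel()
        strides = np.array(
            [c.shape[1] * c.shape[2], c.shape[2], 1], dtype=np.int64
        )
        n = x.shape[1]
        wts = []
        lins = []
        powers = np.empty((n, d + 1))
        for ax in range(3):
            u = frac[ax]
            powers[:, 0] = 1.0
            for p in range(1, d + 1):
                np.multiply(powers[:, p - 1], u, out=powers[:, p])
            wts.append(powers @ ctab.T)  # N x taps
            lins.append(base[ax][:, None] * strides[ax]
                        + np.arange(taps, dtype=np.int64)[None, :] * strides[ax])
        out = np.zeros(n)
        wx, wy, wz = wts
        lx, ly, lz = lins
        for j in range(taps):
            lj = lx[:, j]
            wj = wx[:, j]
            for k in range(taps):
                ljk = (lj + ly[:, k])[:, None] + lz  # N x taps
                gathered = cflat[ljk]
                out += (wj * wy[:, k]) * np.einsum("ij,ij->i", wz, gathered)
        out[~inside] = self.cval
        return out


def map_coordinates(
    data: np.ndarray, coords: np.ndarray, degree: int = 7, cval: float = 0.0
) -> np.ndarray:
    """One-shot interpolation of ``data`` at ``coords`` (voxel units)."""
    return SplineInterpolator(data, degree=degree, cval=cval)(coords)
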