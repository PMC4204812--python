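"""Synthetic inputs: motion trajectories, brain phantoms, cohorts, fMRI series.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is exercisable without real data.  All generators are
seed-deterministic: the same config yields bitwise-identical output.

What is emulated — and what is not: trajectories are a slow random-walk
drift plus sparse discrete spikes with controllable translation/rotation
sign coupling (no scanner-specific spectral structure); brains are smooth
ellipsoids with internal intensity gradients and a gray-matter shell (no
real anatomy, gyrification or multi-tissue structure); fMRI noise is white
Gaussian (no physiological or scanner drift components).
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np

from .errors import GeometryError, MotionQCError
from .kinematics import params_to_transform
from .params import RealignmentParams
from .phantom import FmriSeries
from .bspline import SplineInterpolator
from .volume import VolumeGrid, resample_rigid


@dataclasses.dataclass(frozen=True)
class MotionSimConfig:
    """Configuration for a simulated realignment trajectory.

    Drift is a Gaussian random walk (per-step increment SDs in mm / rad);
    spikes are discrete events: ``step`` spikes (default) are sustained
    repositionings — the head moves and stays, so each produces exactly one
    large scan-to-scan displacement — while ``transient`` spikes affect a
    single volume only.  ``sign_concordance`` in [-1, 1] sets the probability
    ((1+c)/2) that a spike's same-axis rotation shares the translation's
    sign; 0 means independent signs.  Rotation spike amplitudes are drawn in
    radians as (mm amplitude) / ``lever_arm_mm`` so both parameter halves
    contribute commensurately to displacement at the lever arm.
    """

    n_volumes: int = 200
    drift_sd_mm: float = 0.03
    drift_sd_rad: float = 0.0005
    spike_probability: float = 0.02
    spike_amplitude_mm: tuple[float, float] = (0.3, 1.5)
    sign_concordance: float = 0.0
    lever_arm_mm: float = 65.0
    spike_shape: str = "step"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 2:
            raise MotionQCError("need at least 2 volumes")
        if not 0.0 <= self.spike_probability <= 1.0:
            raise MotionQCError("spike_probability must lie in [0, 1]")
        if not -1.0 <= self.sign_concordance <= 1.0:
            raise MotionQCError("sign_concordance must lie in [-1, 1]")
        if self.spike_shape not in ("step", "transient"):
            raise MotionQCError("spike_shape must be 'step' or 'transient'")


def simulate_motion(cfg: MotionSimConfig):
    """Simulate a realignment trajectory with ground truth.

    Returns ``(RealignmentParams, spike_log)`` where the spike log is a list
    of ``{"index": t, "translation_mm": [...], "rotation_rad": [...]}``
    records.  The first row is all zeros (the realignment reference).
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.n_volumes
    inc = np.zeros((t, 6))
    inc[1:, :3] = rng.normal(0.0, cfg.drift_sd_mm, (t - 1, 3))
    inc[1:, 3:] = rng.normal(0.0, cfg.drift_sd_rad, (t - 1, 3))
    spike_rows = np.zeros((t, 6))
    spike_log = []
    spike_at = rng.random(t) < cfg.spike_probability
    spike_at[0] = False
    p_same = (1.0 + cfg.sign_concordance) / 2.0
    lo, hi = cfg.spike_amplitude_mm
    for idx in np.flatnonzero(spike_at):
        amp_mm = rng.uniform(lo, hi, 3) * rng.choice((-1.0, 1.0), 3)
        same = rng.random(3) < p_same
        rot_sign = np.where(same, np.sign(amp_mm), -np.sign(amp_mm))
        amp_rad = rng.uniform(lo, hi, 3) / cfg.lever_arm_mm * rot_sign
        spike_rows[idx, :3] = amp_mm
        spike_rows[idx, 3:] = amp_rad
        spike_log.append(
            {
                "index": int(idx),
                "translation_mm": amp_mm.tolist(),
                "rotation_rad": amp_rad.tolist(),
            }
        )
    if cfg.spike_shape == "step":
        vals = np.cumsum(inc + spike_rows, axis=0)
    else:  # transient: spike affects its own row only
        vals = np.cumsum(inc, axis=0) + spike_rows
    vals[0] = 0.0
    return RealignmentParams(vals, source_label=f"simulated(seed={cfg.seed})"), spike_log


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Configuration for the ellipsoidal brain phantom.

    The phantom is an ellipsoid with a smooth radial intensity gradient plus
    seeded smooth texture (scaled by ``contrast``; zero contrast yields an
    identically-zero image, hence zero motion-induced signal change).  The
    affine places the world origin at the ellipsoid center shifted by
    ``center_offset_mm``.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: float = 1.0
    semi_axes_mm: tuple[float, float, float] = (18.0, 16.0, 14.0)
    shell_thickness_mm: float = 3.0
    contrast: float = 1.0
    texture_amplitude: float = 0.2
    noise_sd: float = 0.0
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        axes = np.asarray(self.semi_axes_mm, dtype=float)
        fov = np.asarray(self.shape) * self.spacing_mm
        if np.any(axes <= 0) or np.any(2 * axes >= fov):
            raise GeometryError("semi-axes must be positive and fit the field of view")
        if self.shell_thickness_mm >= min(axes):
            raise GeometryError("shell thickness must be smaller than the smallest semi-axis")


def synthetic_brain(cfg: PhantomConfig):
    """Ellipsoidal brain phantom.

    Returns ``(brain, mask, shell)`` VolumeGrids: a float intensity volume
    with internal gradients (so motion produces edge signal), the binary
    brain mask, and a gray-matter shell mask of the configured thickness
    (outer rind of the ellipsoid).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape)
    center_vox = (np.asarray(shape) - 1) / 2.0
    affine = np.eye(4)
    affine[:3, :3] *= cfg.spacing_mm
    affine[:3, 3] = np.asarray(cfg.center_offset_mm) - cfg.spacing_mm * center_vox
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    world = [
        cfg.spacing_mm * grids[i].astype(float)
        + affine[i, 3]
        - cfg.center_offset_mm[i]
        for i in range(3)
    ]  # mm relative to ellipsoid center (broadcastable)
    axes = np.asarray(cfg.semi_axes_mm, dtype=float)
    rho = np.sqrt(sum((world[i] / axes[i]) ** 2 for i in range(3)))
    mask = rho <= 1.0
    inner_axes = axes - cfg.shell_thickness_mm
    inner = np.sqrt(sum((world[i] / inner_axes[i]) ** 2 for i in range(3)))
    shell = mask & (inner > 1.0)
    intensity = np.zeros(shape)
    base = 1000.0 * (1.0 - 0.5 * rho**2)
    if cfg.texture_amplitude > 0:
        from scipy import ndimage as ndi

        texture = ndi.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
        scale = np.max(np.abs(texture)) or 1.0
        base = base * (1.0 + cfg.texture_amplitude * texture / scale)
    intensity[mask] = cfg.contrast * base[mask]
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, shape)
    return (
        VolumeGrid(intensity, affine),
        VolumeGrid(mask, affine),
        VolumeGrid(shell, affine),
    )


def simulate_cohort(
    n: int,
    age_range_years: tuple[float, float] = (4.0, 18.0),
    slope_mm_per_year: float = 0.18,
    noise_sd_mm: float = 0.5,
    seed: int = 0,
    davg_at_midpoint_mm: float = 60.0,
    shell_thickness_mm: float = 3.0,
):
    """Synthetic developmental cohort of spherical gray-matter shells.

    Each subject's shell radius is set so the expected d_avg is linear in
    age with the requested slope (Gaussian scatter ``noise_sd_mm``), around
    ``davg_at_midpoint_mm`` at the age-range midpoint.  Returns a list of
    ``(age_months, shell VolumeGrid)`` and the ground-truth radii.
    """
    if n < 3:
        raise MotionQCError("need n >= 3 subjects")
    rng = np.random.default_rng(seed)
    lo, hi = age_range_years
    ages_years = rng.uniform(lo, hi, n)
    mid = (lo + hi) / 2.0
    radii = (
        davg_at_midpoint_mm
        + slope_mm_per_year * (ages_years - mid)
        + rng.normal(0.0, noise_sd_mm, n)
    )
    subjects = []
    for age_y, radius in zip(ages_years, radii):
        half = int(np.ceil(radius)) + 4
        dim = 2 * half + 1
        cfg = PhantomConfig(
            shape=(dim, dim, dim),
            semi_axes_mm=(radius, radius, radius),
            shell_thickness_mm=shell_thickness_mm,
            contrast=0.0,
            texture_amplitude=0.0,
        )
        _, _, shell = synthetic_brain(cfg)
        subjects.append((float(age_y * 12.0), shell))
    return subjects, radii.tolist()


def simulate_fmri(
    brain: VolumeGrid,
    params: RealignmentParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    spline_order: int = 7,
    tr: float = 2.0,
) -> FmriSeries:
    """Motion-corrupted 4-D series: volume t is the brain moved by the
    rigid transform of parameter row t, plus white Gaussian noise."""
    if brain.data.ndim != 3:
        raise GeometryError("brain volume must be 3-D")
    rng = np.random.default_rng(seed)
    t = params.volume_count
    out = np.empty(brain.data.shape + (t,))
    interp = SplineInterpolator(brain.data.astype(float), degree=spline_order, cval=0.0)
    for i in range(t):
        row = params.values[i]
        if np.allclose(row, 0.0):
            out[..., i] = brain.data
        else:
            out[..., i] = resample_rigid(
                brain, params_to_transform(row), spline_order=spline_order,
                interpolator=interp,
            ).data
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return FmriSeries(out, brain.affine.copy(), tr=tr)


def write_ground_truth(path: str | os.PathLike, **records) -> None:
    """Dump generator ground truth (spike log, true d_avg, true slope) as JSON."""
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)
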