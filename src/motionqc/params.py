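"""Rigid-body realignment parameter series.

A realignment run produces, per volume, 3 translations (mm) and 3 rotations
(radians): the columns ``tx ty tz rx ry rz`` of SPM-style ``rp_*.txt`` files.
The first volume is the registration reference, so by convention its row is
all zeros.  Rotations are stored in radians internally; degree input is
converted at read time only when explicitly requested — there is no silent
unit heuristic.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np

from .errors import InvalidParameterError

#: Canonical column order of a parameter series.
PARAM_NAMES = ("tx", "ty", "tz", "rx", "ry", "rz")

#: Recognized reduced parameter sets.  ``translation_only`` zeroes the
#: rotation columns, ``rotation_only`` zeroes the translations.
PARAMETER_SETS = ("complete", "translation_only", "rotation_only")


@dataclasses.dataclass(frozen=True)
class RealignmentParams:
    """A T x 6 motion trajectory: translations in mm, rotations in radians.

    Parameters
    ----------
    values
        Array of shape ``(T, 6)`` with columns ``tx ty tz rx ry rz``.
    source_label
        Free-text provenance tag (file name, simulation config, ...).
    """

    values: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.values, dtype=float))
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise InvalidParameterError(
                f"expected a T x 6 parameter array, got shape {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise InvalidParameterError("parameter series must contain >= 1 volume")
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("parameter series contains non-finite entries")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def volume_count(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.volume_count

    @property
    def translations(self) -> np.ndarray:
        """T x 3 translation block (mm)."""
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        """T x 3 rotation block (radians)."""
        return self.values[:, 3:]

    def reduced(self, parameter_set: str) -> "RealignmentParams":
        return reduce_params(self, parameter_set)


def reduce_params(params: RealignmentParams, mode: str) -> RealignmentParams:
    """Zero out the complementary half of the parameter set.

    ``translation_only`` keeps translations and sets every rotation to 0;
    ``rotation_only`` does the converse; ``complete`` returns an unchanged
    copy.  The input is never modified.
    """
    vals = params.values.copy()
    if mode == "complete":
        pass
    elif mode == "translation_only":
        vals[:, 3:] = 0.0
    elif mode == "rotation_only":
        vals[:, :3] = 0.0
    else:
        raise InvalidParameterError(
            f"unknown parameter set {mode!r}; expected one of {PARAMETER_SETS}"
        )
    label = params.source_label
    if mode != "complete":
        label = f"{label}[{mode}]" if label else mode
    return RealignmentParams(vals, source_label=label)


def read_realignment(
    path: str | os.PathLike, angles: str = "radians"
) -> RealignmentParams:
    """Read an SPM-style ``rp_*.txt`` file (whitespace-delimited, 6 columns).

    Parameters
    ----------
    angles
        ``"radians"`` (default, SPM convention) or ``"degrees"``; with
        ``"degrees"`` the rotation columns are converted to radians.
    """
    if angles not in ("radians", "degrees"):
        raise InvalidParameterError(f"angles must be 'radians' or 'degrees', got {angles!r}")
    arr = np.loadtxt(path, ndmin=2)
    if arr.size == 0:
        raise InvalidParameterError(f"{path}: empty realignment parameter file")
    if arr.shape[1] != 6:
        raise InvalidParameterError(
            f"{path}: expected 6 columns (tx ty tz rx ry rz), found {arr.shape[1]}"
        )
    if angles == "degrees":
        arr = arr.copy()
        arr[:, 3:] = np.deg2rad(arr[:, 3:])
    return RealignmentParams(arr, source_label=os.fspath(path))


def write_realignment(params: RealignmentParams, path: str | os.PathLike) -> None:
    """Write a parameter series in the ``rp_*.txt`` dialect (no header)."""
    np.savetxt(path, params.values, fmt="%.10g", delimiter=" ")
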