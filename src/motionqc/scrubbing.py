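"""Motion scrubbing: censor timepoints whose displacement exceeds a cutoff.

A timepoint is discarded when its displacement strictly exceeds the
admissible-motion cutoff ("exceeding": ties at the cutoff are kept).  The
first volume is its own reference (zero displacement by convention) and is
never censored, but it is included in the total count T.  Reduced-set counts
are reported relative to the complete-set reference (complete = 100%); when
the complete count is zero the percentage is undefined and reported as None
(``—`` in text output), never as 0.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MotionQCError
from .kinematics import DISPLACEMENT_MODES, DisplacementSeries, displacement_series
from .params import PARAMETER_SETS, RealignmentParams

DEFAULT_CUTOFFS_MM = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclasses.dataclass(frozen=True)
class CensorResult:
    """Censoring mask for one displacement series at one cutoff."""

    mask: np.ndarray  # True = discarded
    cutoff_mm: float
    mode: str
    parameter_set: str

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        m.flags.writeable = False
        object.__setattr__(self, "mask", m)

    @property
    def discarded_count(self) -> int:
        return int(self.mask.sum())

    @property
    def total(self) -> int:
        return int(self.mask.shape[0])


def censor(series: DisplacementSeries, cutoff: float) -> CensorResult:
    """Flag timepoints with displacement strictly above ``cutoff`` mm."""
    if cutoff <= 0:
        raise MotionQCError(f"cutoff must be > 0 mm, got {cutoff}")
    mask = series.values > cutoff
    mask[0] = False  # first volume is the reference, never censored
    return CensorResult(
        mask=mask,
        cutoff_mm=float(cutoff),
        mode=series.mode,
        parameter_set=series.parameter_set,
    )


def scrub_table(
    params: RealignmentParams | Iterable[RealignmentParams],
    d_avg: float = 65.0,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS_MM,
    method: str = "fig1_vector_sum",
    parameter_sets: Sequence[str] = PARAMETER_SETS,
    modes: Sequence[str] = DISPLACEMENT_MODES,
) -> pd.DataFrame:
    """Discarded-datapoint table: parameter set x mode x cutoff.

    Accepts one parameter series or an iterable of them; with several,
    datapoints are pooled (exceedance counts sum across subjects, which is
    identical to thresholding the pooled datapoints).  Columns:
    ``parameter_set``, ``mode``, ``cutoff_mm``, ``discarded``, ``total``,
    ``percent_of_complete`` (NaN when the complete-set count is zero).
    """
    if isinstance(params, RealignmentParams):
        params_list = [params]
    else:
        params_list = list(params)
    if not params_list:
        raise MotionQCError("no parameter series given")
    cutoffs = [float(c) for c in cutoffs]
    if not cutoffs:
        raise MotionQCError("no cutoffs given")

    counts: dict[tuple[str, str, float], int] = {}
    total = 0
    for p in params_list:
        total += p.volume_count
        for pset in parameter_sets:
            for mode in modes:
                series = displacement_series(
                    p, d_avg=d_avg, mode=mode, method=method, parameter_set=pset
                )
                for cutoff in cutoffs:
                    key = (pset, mode, cutoff)
                    counts[key] = counts.get(key, 0) + censor(series, cutoff).discarded_count

    rows = []
    for pset in parameter_sets:
        for mode in modes:
            for cutoff in cutoffs:
                n = counts[(pset, mode, cutoff)]
                ref = counts.get(("complete", mode, cutoff))
                if ref is None or ref == 0:
                    pct = 100.0 if pset == "complete" and ref == n and n > 0 else np.nan
                else:
                    pct = 100.0 * n / ref
                rows.append(
                    {
                        "parameter_set": pset,
                        "mode": mode,
                        "cutoff_mm": cutoff,
                        "discarded": n,
                        "total": total,
                        "percent_of_complete": pct,
                    }
                )
    return pd.DataFrame(rows)


def scrub_table_wide(table: pd.DataFrame, value: str = "discarded") -> pd.DataFrame:
    """Pivot the long scrub table to the familiar layout: rows = parameter
    set x mode, columns = cutoffs."""
    return table.pivot_table(
        index=["parameter_set", "mode"], columns="cutoff_mm", values=value,
        sort=False,
    )


def format_scrub_cell(count: int, percent: float) -> str:
    """Human-readable cell: ``69.4% (11749)``; undefined percent renders as em dash."""
    pct = "—" if percent is None or (isinstance(percent, float) and np.isnan(percent)) else f"{percent:.1f}%"
    return f"{pct} ({count})"
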