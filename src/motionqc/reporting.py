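"""Tabular/JSON writers for pipeline outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import numpy as np
import pandas as pd

from .glm import DesignMatrix
from .kinematics import DisplacementSeries
from .scrubbing import CensorResult


def write_displacement_tsv(
    series: DisplacementSeries,
    path: str | os.PathLike,
    censored: CensorResult | None = None,
) -> None:
    """TSV with columns volume_index, displacement_mm and optionally censored (0/1)."""
    cols = {
        "volume_index": np.arange(len(series)),
        "displacement_mm": series.values,
    }
    if censored is not None:
        cols["censored"] = censored.mask.astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_scrub_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Long-format scrub table as TSV (or JSON for a .json suffix; undefined
    percentages are emitted as null)."""
    path = os.fspath(path)
    if path.endswith(".json"):
        records = table.to_dict(orient="records")
        for rec in records:
            pct = rec.get("percent_of_complete")
            if pct is not None and isinstance(pct, float) and np.isnan(pct):
                rec["percent_of_complete"] = None
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)
    else:
        table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_design_tsv(design: DesignMatrix, path: str | os.PathLike) -> None:
    """Design matrix as TSV with one named header column per regressor."""
    pd.DataFrame(design.columns, columns=list(design.column_names)).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def write_json(obj, path: str | os.PathLike) -> None:
    """JSON writer that understands dataclasses and numpy scalars/arrays."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return None if np.isnan(o) else float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping, for run provenance."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
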