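"""Rodent tail-volume morphometry from serial circumference measurements.

Tail volume is estimated from circumferences C1..C4 measured with calipers
at 1-cm intervals distal to the surgical site, via the truncated-cone
(frustum) formula

    V = h / (4 pi) * (C1*C2 + C2*C3 + C3*C4)

with segment height h = 10 mm. Each pairwise term h*Ci*Cj/(4 pi) is the
volume of a cylinder of radius sqrt(r_i * r_j) — the geometric-mean-radius
approximation of one frustum — so circumferences in mm give volume in mm^3.
Longitudinal swelling curves are normalized as treated/control ratios per
timepoint.

Note the measurements are circumferences, not diameters: the formula's
symbols are circumference-valued even though calipers nominally read
diameter (a caliper reading d converts as C = pi * d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from kerastate.errors import KerastateError

__all__ = ["TailMeasurement", "tail_volume", "relative_volume", "volume_table", "relative_volume_table"]

#: Measurement interval along the tail, in mm.
SEGMENT_HEIGHT_MM = 10.0


@dataclass(frozen=True)
class TailMeasurement:
    """One animal-timepoint set of serial circumferences (mm)."""

    circumferences: tuple[float, ...]
    animal_id: str = ""
    group: str = ""
    timepoint: str = ""


def tail_volume(measurement, segment_height: float = SEGMENT_HEIGHT_MM) -> float:
    """Truncated-cone tail volume (mm^3) from serial circumferences (mm).

    Accepts a :class:`TailMeasurement` or a plain sequence. The printed
    protocol uses four circumferences (three segments); longer or shorter
    series are supported by summing consecutive-pair terms.
    """
    if isinstance(measurement, TailMeasurement):
        c = np.asarray(measurement.circumferences, dtype=float)
    else:
        c = np.asarray(measurement, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise KerastateError("tail_volume: need at least two circumferences")
    if np.any(c < 0):
        raise KerastateError("tail_volume: circumferences must be non-negative")
    return float(segment_height / (4.0 * np.pi) * np.sum(c[:-1] * c[1:]))


def relative_volume(treated: Sequence[float], control: Sequence[float]) -> np.ndarray:
    """Elementwise treated/control volume ratio over aligned timepoints."""
    t = np.asarray(treated, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if t.shape != ctl.shape:
        raise KerastateError("relative_volume: series lengths differ")
    zero = np.flatnonzero(ctl == 0)
    if zero.size:
        raise KerastateError(f"relative_volume: control volume is zero at timepoint(s) {zero.tolist()}")
    return t / ctl


def volume_table(df: pd.DataFrame, segment_height: float = SEGMENT_HEIGHT_MM) -> pd.DataFrame:
    """Add a ``volume_mm3`` column to a (animal, group, timepoint, C1..C4) table."""
    ccols = [c for c in df.columns if c.upper().startswith("C") and c[1:].isdigit()]
    if not ccols:
        raise KerastateError("volume_table: no circumference columns (C1, C2, ...)")
    ccols = sorted(ccols, key=lambda c: int(c[1:]))
    out = df.copy()
    out["volume_mm3"] = [
        tail_volume(row, segment_height) for row in df[ccols].to_numpy(dtype=float)
    ]
    return out


def relative_volume_table(volumes: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-group mean volume relative to the control group at each timepoint."""
    mean = (
        volumes.groupby(["group", "timepoint"], observed=True)["volume_mm3"]
        .mean()
        .unstack("group")
    )
    if control_group not in mean.columns:
        raise KerastateError(f"relative_volume_table: unknown control group {control_group!r}")
    rel = mean.div(mean[control_group], axis=0)
    return rel.reset_index().melt(
        id_vars="timepoint", var_name="group", value_name="relative_volume"
    )
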