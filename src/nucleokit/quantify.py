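"""Control normalisation and fluorescence → duplex-length conversion.

Sample traces are first normalised to their matched no-enzyme control —
F_norm(t) = F_sample(t) / F_control(t) × F_control(0) — which cancels
photobleaching exactly when bleaching is multiplicative and shared across
wells, so that any remaining signal loss is enzymatic.  Normalised
fluorescence is then inverted through the standard curve,
L(t) = (F_norm(t) − c(t)) / m(t), giving remaining duplex length in bp
(or nt for single-strand assays, or bp synthesised for polymerase mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import StandardCurveSeries
from .simulate import PlateRun

__all__ = [
    "QuantifyError",
    "FluorescenceTrace",
    "ResectionCurve",
    "normalize_to_control",
    "to_length",
    "plate_traces",
    "convert_plate",
]


class QuantifyError(ValueError):
    pass


@dataclass
class FluorescenceTrace:
    """One well's fluorescence time series plus its well-map metadata."""

    well: str
    time_s: np.ndarray
    fluorescence: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.size != self.fluorescence.size:
            raise QuantifyError("time and fluorescence lengths differ")
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise QuantifyError("timepoints must be strictly increasing")


@dataclass
class ResectionCurve:
    """Remaining length (bp or nt) vs time for one well/condition.

    ``length_bp`` is clipped to [0, length_cap]; ``raw_length_bp`` keeps the
    pre-clip values for QC.
    """

    well: str
    time_s: np.ndarray
    length_bp: np.ndarray
    raw_length_bp: np.ndarray
    meta: dict = field(default_factory=dict)
    dropped_timepoints: int = 0


def normalize_to_control(sample: FluorescenceTrace, control: FluorescenceTrace) -> FluorescenceTrace:
    """Ratio-to-control normalisation rescaled to the control's t=0 value.

    Requires identical time bases (no resampling); a control containing
    zeros cannot be used as a denominator.
    """
    if sample.time_s.size != control.time_s.size or not np.allclose(sample.time_s, control.time_s):
        raise QuantifyError(
            f"time-base mismatch between {sample.well} and control {control.well}"
        )
    if np.any(control.fluorescence == 0):
        raise QuantifyError(f"control {control.well} contains zero fluorescence")
    f = sample.fluorescence / control.fluorescence * control.fluorescence[0]
    meta = dict(sample.meta)
    meta["normalized_to"] = control.well
    return FluorescenceTrace(sample.well, sample.time_s.copy(), f, meta)


def to_length(
    trace: FluorescenceTrace,
    curve: StandardCurveSeries,
    length_cap: float | None = None,
    max_dropped_fraction: float = 0.2,
) -> ResectionCurve:
    """Invert the standard curve: L(t) = (F(t) − c(t)) / m(t).

    Timepoints flagged in the curve (non-positive gradient, late heavily
    bleached reads) are dropped with a warning; more than
    ``max_dropped_fraction`` dropped is an error.  Values are clipped to
    [0, length_cap] (cap defaults to the substrate length in the trace
    metadata, if present); pre-clip values are retained for QC.
    """
    ct = curve.timepoints_s
    idx = _align(trace.time_s, ct)
    valid = curve.valid[idx]
    n_drop = int((~valid).sum())
    if n_drop:
        warnings.warn(
            f"dropping {n_drop} timepoints with unusable standard-curve fit",
            stacklevel=2,
        )
    if n_drop > max_dropped_fraction * trace.time_s.size:
        raise QuantifyError(
            f"{n_drop}/{trace.time_s.size} timepoints excluded by the standard curve"
        )
    keep = np.flatnonzero(valid)
    t = trace.time_s[keep]
    m = curve.m[idx][keep]
    c = curve.c[idx][keep]
    raw = (trace.fluorescence[keep] - c) / m
    if length_cap is None:
        length_cap = trace.meta.get("substrate_length")
    clipped = raw.copy()
    if length_cap is not None:
        clipped = np.clip(raw, 0.0, float(length_cap))
    else:
        clipped = np.clip(raw, 0.0, None)
    return ResectionCurve(trace.well, t, clipped, raw, dict(trace.meta), n_drop)


def _align(times: np.ndarray, curve_times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(curve_times, times)
    idx = np.clip(idx, 0, curve_times.size - 1)
    if not np.allclose(curve_times[idx], times):
        raise QuantifyError("standard-curve timepoints do not cover the trace")
    return idx


# ---------------------------------------------------------------------------
# plate-level helpers


def plate_traces(plate: PlateRun) -> dict[str, FluorescenceTrace]:
    """All wells of a plate as FluorescenceTrace objects with metadata."""
    times = plate.times
    out = {}
    for row in plate.wellmap.itertuples():
        meta = {
            "role": row.role,
            "substrate": row.substrate,
            "enzyme": row.enzyme,
            "enzyme_conc_nM": row.enzyme_conc_nM,
            "replicate_group": row.replicate_group,
            "replicate": row.replicate,
            "control_well": row.control_well,
        }
        sub = plate.substrates.get(row.substrate)
        if sub is not None:
            length = max(sub.duplex_length, sub.ss_length)
            meta["substrate_length"] = float(length) if length else None
        out[row.well] = FluorescenceTrace(
            row.well, times, plate.data[row.well].to_numpy(dtype=float), meta
        )
    return out


def convert_plate(
    plate: PlateRun,
    curve: StandardCurveSeries,
    normalize: bool = True,
    include_controls: bool = True,
) -> dict[str, ResectionCurve]:
    """Normalise every sample well to its matched control and convert to bp.

    Control wells, when included, are normalised against the *next*
    replicate's control on the same substrate (cyclically), which measures
    the no-enzyme noise floor without dividing a trace by itself.
    """
    traces = plate_traces(plate)
    out: dict[str, ResectionCurve] = {}
    wm = plate.wellmap
    for row in wm.itertuples():
        if row.role == "sample":
            tr = traces[row.well]
            if normalize:
                ctrl = row.control_well
                if not ctrl:
                    raise QuantifyError(f"sample well {row.well} has no matched control")
                tr = normalize_to_control(tr, traces[ctrl])
            out[row.well] = to_length(tr, curve)
        elif row.role == "control" and include_controls:
            tr = traces[row.well]
            if normalize:
                mates = wm[
                    (wm["role"] == "control") & (wm["substrate"] == row.substrate)
                ].sort_values("replicate")
                wells = list(mates["well"])
                if len(wells) > 1:
                    partner = wells[(wells.index(row.well) + 1) % len(wells)]
                    tr = normalize_to_control(tr, traces[partner])
            out[row.well] = to_length(tr, curve)
    return out
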