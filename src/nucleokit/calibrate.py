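"""Per-timepoint standard curves and linear-range characterisation.

The assay converts fluorescence to remaining duplex length through a
standard curve: an ordinary least-squares fit of fluorescence against
duplex length over the ladder wells, performed independently at every
timepoint so that the gradient m(t) and intercept c(t) track shared,
multiplicative effects such as photobleaching.  The fully single-stranded
full-length oligomer is plotted at 0 bp: it is the end product of complete
resection, so conversion reports bp of duplex remaining relative to that
end state and the residual ss fluorescence is absorbed into c(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PlateRun

__all__ = [
    "CalibrationError",
    "StandardCurveSeries",
    "fit_standard_curve",
    "LinearRangeResult",
    "linear_range",
]


class CalibrationError(ValueError):
    pass


@dataclass
class StandardCurveSeries:
    """Gradient m(t), intercept c(t) and fit quality per timepoint."""

    timepoints_s: np.ndarray
    m: np.ndarray  # fluorescence units per bp
    c: np.ndarray  # fluorescence units
    r_squared: np.ndarray
    ladder_lengths: np.ndarray
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self):
        n = len(self.timepoints_s)
        if not (len(self.m) == len(self.c) == len(self.r_squared) == n):
            raise CalibrationError("series arrays must have equal length")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of timepoints with a usable (m > 0) fit."""
        mask = np.ones(len(self.m), dtype=bool)
        mask[self.flagged] = False
        return mask

    def to_dict(self) -> dict:
        return {
            "timepoints_s": self.timepoints_s.tolist(),
            "m": self.m.tolist(),
            "c": self.c.tolist(),
            "r_squared": self.r_squared.tolist(),
            "ladder_lengths": self.ladder_lengths.tolist(),
            "flagged": self.flagged.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardCurveSeries":
        return cls(
            np.asarray(d["timepoints_s"], dtype=float),
            np.asarray(d["m"], dtype=float),
            np.asarray(d["c"], dtype=float),
            np.asarray(d["r_squared"], dtype=float),
            np.asarray(d["ladder_lengths"], dtype=float),
            np.asarray(d.get("flagged", []), dtype=int),
        )


def fit_standard_curve(plate: PlateRun, normalize: bool = True) -> StandardCurveSeries:
    """OLS of fluorescence vs ladder length, independently per timepoint.

    Replicate ladder wells are averaged per length before fitting.  With
    ``normalize`` (the default, matching normalisation of samples to their
    no-enzyme controls), each ladder well — which is its own no-enzyme
    control — is divided by its own bleaching profile and rescaled to its
    t=0 value, making m and c constant at their t=0 fit.  Timepoints where
    the fitted gradient is non-positive are flagged and excluded from
    conversion; more than 20% flagged is an error.
    """
    stds = plate.wellmap[plate.wellmap["role"] == "standard"]
    if stds.empty:
        raise CalibrationError("plate has no standard wells")
    lengths = sorted(stds["length_bp"].dropna().unique())
    if len(lengths) < 3:
        raise CalibrationError(f"need >= 3 distinct ladder lengths, found {len(lengths)}")

    times = plate.times
    Y = np.empty((len(lengths), times.size))
    for i, L in enumerate(lengths):
        wells = stds.loc[stds["length_bp"] == L, "well"]
        Y[i] = plate.data[list(wells)].to_numpy(dtype=float).mean(axis=1)
    if normalize:
        # each ladder well is its own control: ratio-to-self × t0 pins the
        # trace at its t=0 value, exactly as sample/control normalisation
        # cancels shared bleaching
        Y = np.repeat(Y[:, :1], times.size, axis=1)

    x = np.asarray(lengths, dtype=float)
    xm = x.mean()
    dx = x - xm
    sxx = float((dx**2).sum())
    ym = Y.mean(axis=0)
    m = (dx[:, None] * (Y - ym)).sum(axis=0) / sxx
    c = ym - m * xm
    resid = Y - (m[None, :] * x[:, None] + c[None, :])
    sstot = ((Y - ym) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sstot > 0, 1.0 - (resid**2).sum(axis=0) / sstot, 1.0)

    flagged = np.flatnonzero(m <= 0)
    if flagged.size > 0.2 * times.size:
        raise CalibrationError(
            f"non-positive gradient at {flagged.size}/{times.size} timepoints"
        )
    return StandardCurveSeries(times, m, c, r2, x, flagged)


@dataclass
class LinearRangeResult:
    max_linear_conc: float
    no_plateau: bool
    r_squared: float
    details: pd.DataFrame | None = None


def linear_range(
    concentrations,
    fluorescence,
    r2_threshold: float = 0.98,
    k_sigma: float = 3.0,
) -> LinearRangeResult:
    """Maximal concentration over which the calibration stays linear.

    Scans cutoffs from low to high: the linear range ends at the largest
    concentration c such that the fit over [0, c] keeps R² ≥ threshold and
    the next point falls more than ``k_sigma`` fit-residual SDs below the
    line.  A series that never saturates returns the top concentration
    flagged ``no_plateau``.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.size != y.size:
        raise CalibrationError("concentration and fluorescence lengths differ")
    if x.size < 5:
        raise CalibrationError("need >= 5 concentrations spanning the plateau")
    order = np.argsort(x)
    x, y = x[order], y[order]

    rows = []
    best_j = x.size - 1
    no_plateau = True
    for j in range(2, x.size):  # fit over points 0..j
        xs, ys = x[: j + 1], y[: j + 1]
        m, c = np.polyfit(xs, ys, 1)
        pred = m * xs + c
        ss_tot = ((ys - ys.mean()) ** 2).sum()
        r2 = 1.0 - ((ys - pred) ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
        sigma = float(np.std(ys - pred, ddof=min(2, j - 1)))
        broke = False
        if j + 1 < x.size:
            nxt_resid = y[j + 1] - (m * x[j + 1] + c)
            broke = r2 >= r2_threshold and abs(nxt_resid) > k_sigma * max(sigma, 1e-12)
        rows.append({"cutoff": x[j], "r_squared": r2, "sigma": sigma, "break_after": broke})
        if r2 >= r2_threshold:
            best_j = j
        if broke:
            no_plateau = False
            best_j = j
            break
        if r2 < r2_threshold:
            # linearity already lost: the previous cutoff was the range
            no_plateau = False
            break
    details = pd.DataFrame(rows)
    r2_final = float(details.iloc[-1]["r_squared"]) if rows else float("nan")
    return LinearRangeResult(float(x[best_j]), no_plateau, r2_final, details)
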