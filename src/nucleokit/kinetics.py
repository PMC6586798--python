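"""Rate extraction and condition comparison.

The operational reaction rate is the *maximum gradient*: the steepest OLS
slope of the converted length-vs-time progress curve over a sliding window
of ``window_points`` samples.  Dividing by enzyme concentration gives the
per-nM rate; regressing max gradients against a concentration titration
through the origin gives the per-nM rate together with a linearity R² as a
first-order diagnostic (zero enzyme ⇒ zero rate).  Completion time is the
earliest time the curve settles within epsilon of its final level.  Groups
of replicate rates are compared by one-way ANOVA with Tukey's HSD post-hoc
test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ResectionCurve

__all__ = [
    "KineticsError",
    "RateEstimate",
    "PerNMRate",
    "ComparisonResult",
    "max_gradient",
    "per_nM_rate",
    "completion_time",
    "compare_conditions",
]


class KineticsError(ValueError):
    pass


@dataclass
class RateEstimate:
    """Maximum-gradient rate for one well."""

    well: str
    max_gradient: float  # |bp s^-1|
    window: tuple  # (t_start, t_end)
    sign: int  # -1 digestion, +1 synthesis, 0 flat
    per_nM_rate: float | None = None
    completion_time_s: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class PerNMRate:
    rate: float  # bp (or nt) nM^-1 s^-1
    r_squared: float | None
    n_concentrations: int
    all_zero: bool = False


@dataclass
class ComparisonResult:
    labels: list
    group_means: dict
    group_sems: dict
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame | None
    fold_changes: dict
    degenerate: bool = False


def _window_slopes(t: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """OLS slope of every contiguous window of ``w`` points."""
    n = t.size
    slopes = np.empty(n - w + 1)
    for i in range(n - w + 1):
        ts = t[i : i + w]
        ys = y[i : i + w]
        dt = ts - ts.mean()
        denom = (dt**2).sum()
        slopes[i] = (dt * (ys - ys.mean())).sum() / denom if denom > 0 else 0.0
    return slopes


def max_gradient(
    curve: ResectionCurve, window_points: int = 5, smooth_points: int = 1
) -> RateEstimate:
    """Steepest window slope of a progress curve.

    Returns the maximum |slope| over all contiguous windows of
    ``window_points`` samples; ties resolve to the earliest window.  A flat
    curve gives slope 0 — the negative-control phenotype, not an error.
    ``smooth_points`` > 1 applies a centred moving average before the
    window scan (conversion output itself is never smoothed).
    """
    if window_points < 3:
        raise KineticsError("window_points must be >= 3")
    t = np.asarray(curve.time_s, dtype=float)
    y = np.asarray(curve.length_bp, dtype=float)
    if t.size < window_points:
        raise KineticsError(
            f"curve has {t.size} samples, fewer than window_points={window_points}"
        )
    if smooth_points > 1:
        kern = np.ones(smooth_points) / smooth_points
        y = np.convolve(y, kern, mode="same")
        # trim edge effects of the moving average
        h = smooth_points // 2
        t, y = t[h : t.size - h], y[h : y.size - h]
        if t.size < window_points:
            raise KineticsError("curve too short after smoothing")
    slopes = _window_slopes(t, y, window_points)
    i = int(np.argmax(np.abs(slopes)))
    s = slopes[i]
    est = RateEstimate(
        well=curve.well,
        max_gradient=float(abs(s)),
        window=(float(t[i]), float(t[i + window_points - 1])),
        sign=int(np.sign(s)),
        meta=dict(curve.meta),
    )
    conc = curve.meta.get("enzyme_conc_nM")
    if conc:
        est.per_nM_rate = est.max_gradient / float(conc)
    return est


def per_nM_rate(gradients_by_conc: dict) -> PerNMRate:
    """Per-nM rate and first-order diagnostic from a titration.

    ``gradients_by_conc`` maps enzyme concentration (nM) to a max gradient
    or an iterable of replicate max gradients.  A single non-zero
    concentration gives gradient/conc without an R².  With ≥2 non-zero
    concentrations, the per-nM rate is the slope of a regression through
    the origin (zero enzyme ⇒ zero rate) and R² is reported against that
    origin-constrained model as the first-order linearity check.
    """
    concs, grads = [], []
    for conc, g in gradients_by_conc.items():
        vals = np.atleast_1d(np.asarray(g, dtype=float))
        for v in vals:
            concs.append(float(conc))
            grads.append(v)
    x = np.asarray(concs)
    y = np.asarray(grads)
    if x.size == 0:
        raise KineticsError("no titration points")
    if np.allclose(y, 0.0):
        return PerNMRate(0.0, None, int(np.unique(x).size), all_zero=True)
    nz = x > 0
    if np.unique(x[nz]).size == 1:
        c = x[nz][0]
        return PerNMRate(float(y[nz].mean() / c), None, int(np.unique(x).size))
    slope = float((x * y).sum() / (x**2).sum())
    resid = y - slope * x
    ss_tot = float((y**2).sum())  # uncentered: the model has no intercept
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return PerNMRate(slope, r2, int(np.unique(x).size))


def completion_time(
    curve: ResectionCurve,
    epsilon_bp: float | None = None,
    hold_points: int = 3,
    final_fraction: float = 0.1,
) -> float | None:
    """Earliest time the curve plateaus at its end state.

    The end state is the median of the last ``final_fraction`` of samples;
    completion is the earliest time from which the curve stays within
    ``epsilon_bp`` of it for ``hold_points`` consecutive samples (and
    onward to the end, so transient crossings do not count).  ``epsilon_bp``
    defaults to 5% of the substrate length.  Too-short traces return None.
    """
    if hold_points < 2:
        raise KineticsError("hold_points must be >= 2")
    t = np.asarray(curve.time_s, dtype=float)
    y = np.asarray(curve.length_bp, dtype=float)
    if t.size < max(hold_points, 3):
        return None
    if epsilon_bp is None:
        L0 = curve.meta.get("substrate_length") or max(abs(y.max()), 1.0)
        epsilon_bp = 0.05 * float(L0)
    if not epsilon_bp > 0:
        raise KineticsError("epsilon_bp must be > 0")
    n_final = max(1, int(np.ceil(final_fraction * t.size)))
    final = float(np.median(y[-n_final:]))
    within = np.abs(y - final) <= epsilon_bp
    # earliest index from which the curve remains within epsilon to the end
    idx = None
    for i in range(t.size - hold_points + 1):
        if within[i:].all():
            idx = i
            break
    if idx is None:
        return None
    return float(t[idx])


def compare_conditions(groups: dict, fold_pairs: list | None = None) -> ComparisonResult:
    """One-way ANOVA + Tukey HSD across named groups of replicate rates.

    ``fold_pairs`` lists (numerator, denominator) label pairs for
    fold-change reporting; by default all ordered pairs.  All-tied data
    (zero variance within and between every group) is reported as
    degenerate with F undefined rather than raising.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise KineticsError("need >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, a in zip(labels, arrays):
        if a.size < 2:
            raise KineticsError(f"group {k!r} needs >= 2 replicates")
    means = {k: float(a.mean()) for k, a in zip(labels, arrays)}
    sems = {
        k: float(a.std(ddof=1) / np.sqrt(a.size)) for k, a in zip(labels, arrays)
    }

    allvals = np.concatenate(arrays)
    degenerate = bool(np.all(allvals == allvals[0]))
    if degenerate:
        f_stat, p_val, tukey_df = float("nan"), float("nan"), None
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        f_stat, p_val = float(f_stat), float(p_val)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = np.concatenate(arrays)
        grp = np.concatenate([[k] * a.size for k, a in zip(labels, arrays)])
        res = pairwise_tukeyhsd(data, grp)
        tukey_df = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )

    if fold_pairs is None:
        fold_pairs = list(itertools.combinations(labels, 2))
    folds = {}
    for a, b in fold_pairs:
        denom = means[b]
        folds[(a, b)] = means[a] / denom if denom != 0 else float("inf")
    return ComparisonResult(
        labels, means, sems, f_stat, p_val, tukey_df, folds, degenerate
    )


def tukey_p(pair_labels: tuple, result: ComparisonResult) -> float:
    """Adjusted p-value for one pair from a ComparisonResult."""
    if result.tukey is None:
        return float("nan")
    a, b = pair_labels
    df = result.tukey
    hit = df[((df["group1"] == a) & (df["group2"] == b)) | ((df["group1"] == b) & (df["group2"] == a))]
    if hit.empty:
        return float("nan")
    return float(hit.iloc[0]["p-adj"])
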