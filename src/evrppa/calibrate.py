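"""Absolute quantification against peptide dilution curves and LOD estimation.

A reference curve is a dilution series of a synthetic peptide printed alongside
the samples; normalized intensity is log10-linear in the spotted amount over
the calibrated range, so ordinary least squares of log10(intensity) on
log10(amount) — with technical replicates entered individually — gives an
invertible calibration.  Sample intensities are converted to absolute amounts
(pg) by inverse prediction, flagging queries that fall outside the calibrated
amount range (notably serum-EV levels below the lowest dilution point).

The limit of detection of a two-source EV mixture series is defined by a
background-threshold rule: a mixture fraction is detected when at least
``min_detect_reps`` replicates exceed background mean + k*SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_data import ReferenceCurveData

logger = logging.getLogger(__name__)

IN_RANGE = "in_range"
BELOW_CURVE = "below_curve"
ABOVE_CURVE = "above_curve"
NOT_DETECTABLE = "not_detectable"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ReferenceCurveFit:
    """Log10-domain linear calibration of a dilution series."""

    analyte: str
    slope: float          # log10-A.U. per log10-pg
    intercept: float      # log10-A.U.
    adj_r2: float
    p_value: float
    amount_range: tuple[float, float]  # (min pg, max pg) calibrated
    n_points: int


@dataclass(frozen=True)
class MixtureSeries:
    """Replicate intensities per positive-source fraction, with a background reference."""

    fractions: tuple[float, ...]              # percent, ascending
    intensities: tuple[tuple[float, ...], ...]
    background_stats: tuple[float, float] | None = None  # (mean, sd); default: 0% replicates

    def __post_init__(self):
        object.__setattr__(self, "fractions", tuple(float(f) for f in self.fractions))
        object.__setattr__(
            self, "intensities", tuple(tuple(map(float, row)) for row in self.intensities)
        )
        if any(f < 0 or f > 100 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 100]")
        if list(self.fractions) != sorted(self.fractions):
            raise ValueError("fractions must be sorted ascending")
        if len(self.fractions) != len(self.intensities):
            raise ValueError("fractions and intensities length mismatch")

    def background(self) -> tuple[float, float]:
        if self.background_stats is not None:
            return self.background_stats
        for f, reps in zip(self.fractions, self.intensities):
            if f == 0:
                arr = np.asarray(reps, dtype=float)
                return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        raise ValueError("mixture series has no background reference (0% fraction or explicit stats)")


def fit_reference_curve(data: ReferenceCurveData) -> ReferenceCurveFit:
    """OLS of log10(intensity) on log10(amount) over individual replicate points.

    Non-positive replicate intensities are dropped (with a warning) rather than
    floored, since they have no log transform.
    """
    x, y = [], []
    dropped = 0
    for amount, reps in zip(data.amounts, data.intensities):
        for v in reps:
            if v > 0:
                x.append(np.log10(amount))
                y.append(np.log10(v))
            else:
                dropped += 1
    if dropped:
        logger.warning("dropped %d non-positive intensities from curve fit", dropped)
    x = np.asarray(x)
    y = np.asarray(y)
    usable_amounts = np.unique(x)
    if usable_amounts.size < 2:
        raise ValueError("fewer than 2 distinct usable amounts after dropping non-positive intensities")
    n = x.size
    if np.allclose(y, y[0]):
        # flat curve: slope 0, no explanatory power
        slope, intercept, r2, p = 0.0, float(y.mean()), 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.linregress(x, y)
        slope, intercept, p = float(res.slope), float(res.intercept), float(res.pvalue)
        r2 = float(res.rvalue) ** 2
        if np.isnan(p):  # perfect fit -> p numerically 0
            p = 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    amt = [10.0 ** a for a in (usable_amounts.min(), usable_amounts.max())]
    return ReferenceCurveFit(
        analyte=data.analyte,
        slope=slope,
        intercept=intercept,
        adj_r2=float(adj_r2),
        p_value=min(max(p, 0.0), 1.0),
        amount_range=(float(amt[0]), float(amt[1])),
        n_points=n,
    )


def predict_amount(fit: ReferenceCurveFit, intensity: float) -> tuple[float, str]:
    """Inverse prediction: amount = 10**((log10(intensity) - intercept) / slope).

    Returns (amount in pg, status).  Status flags extrapolation outside the
    calibrated amount range — e.g. EV levels falling below the lowest dilution
    point — without suppressing the extrapolated estimate.
    """
    if intensity <= 0 or not np.isfinite(intensity):
        raise ValueError("intensity must be positive and finite")
    if fit.slope == 0:
        raise ValueError("zero-slope calibration is not invertible")
    amount = 10.0 ** ((np.log10(intensity) - fit.intercept) / fit.slope)
    lo, hi = fit.amount_range
    if amount < lo:
        status = BELOW_CURVE
    elif amount > hi:
        status = ABOVE_CURVE
    else:
        status = IN_RANGE
    return float(amount), status


def estimate_lod(
    series: MixtureSeries, k: float = 3.0, min_detect_reps: int = 2
) -> tuple[float | str, dict[float, bool]]:
    """Smallest reliably detected positive-EV fraction.

    A fraction is detected when >= ``min_detect_reps`` replicates exceed
    background mean + k*SD.  The LOD is the smallest detected nonzero fraction
    such that every larger fraction is also detected; ``"not_detectable"``
    if no such fraction exists.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if min_detect_reps < 1:
        raise ValueError("min_detect_reps must be >= 1")
    bg_mean, bg_sd = series.background()
    threshold = bg_mean + k * bg_sd
    flags: dict[float, bool] = {}
    for f, reps in zip(series.fractions, series.intensities):
        n_above = sum(1 for v in reps if v > threshold)
        flags[f] = n_above >= min_detect_reps
    nonzero = [f for f in series.fractions if f > 0]
    lod: float | str = NOT_DETECTABLE
    for i, f in enumerate(nonzero):
        if all(flags[g] for g in nonzero[i:]):
            lod = f
            break
    return lod, flags


def mixture_linearity(series: MixtureSeries) -> tuple[float | str, float, float | str]:
    """Pearson correlation and least-squares slope of mean intensity vs fraction.

    Constant series have undefined correlation and are reported as
    ``"not_applicable"`` with slope 0.
    """
    fracs = np.asarray(series.fractions, dtype=float)
    if np.unique(fracs).size < 3:
        raise ValueError("mixture linearity needs >= 3 distinct fractions")
    means = np.asarray([np.mean(reps) for reps in series.intensities])
    if np.allclose(means, means[0]):
        return NOT_APPLICABLE, 0.0, NOT_APPLICABLE
    res = stats.linregress(fracs, means)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 0.0
    return float(res.rvalue), float(res.slope), p
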