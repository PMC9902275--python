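"""Insulin immunosensor calibration: detectivity curve, LOD, inversion.

The in-gel sandwich assay reports a fluorescence ratio (signal over
background) that saturates with insulin concentration as capture sites fill.
The default calibration model is a one-site saturation (Langmuir) curve

    R(C) = r0 + r_max * C / (kd + C)

with a linear fallback for narrow concentration ranges. The limit of
detection follows the blank-based convention: the concentration whose fitted
response equals the blank mean plus twice the blank standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CalibrationCurve",
    "LODResult",
    "SaturationCalibration",
    "fit_calibration",
    "limit_of_detection",
    "invert_concentration",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted detectivity model with blank statistics.

    For ``model="saturation"``: params (r0, r_max, kd); for
    ``model="linear"``: params (intercept, slope). ``blank_sd`` is the
    replicate standard deviation at concentration zero (ddof=1).
    """

    model: str
    r0: float
    r_max: float | None
    kd: float | None
    slope: float | None
    blank_mean: float
    blank_sd: float
    residual_sd: float
    n: int

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if self.model == "saturation":
            return self.r0 + self.r_max * c / (self.kd + c)
        return self.r0 + self.slope * c

    def invert(self, ratio: float) -> float:
        return invert_concentration(self, ratio)


@dataclass(frozen=True)
class LODResult:
    """Limit of detection under the 2x blank-SD convention."""

    lod_pg_ml: float
    threshold_ratio: float
    convention: str = "blank_mean_plus_2sd"


class SaturationCalibration(RegressorMixin, BaseEstimator):
    """Detectivity-curve regressor (scikit-learn estimator API).

    Fits fluorescence ratio against insulin concentration (pg/mL) with a
    one-site saturation curve (default) or a straight line, records blank
    replicate statistics, and exposes prediction, closed-form inversion and
    the 2x-blank-SD limit of detection.

    Parameters
    ----------
    model : {"saturation", "linear"}

    Attributes
    ----------
    r0_ : float          fitted blank (zero-concentration) ratio
    r_max_ : float       fitted saturating ratio increment (saturation model)
    kd_ : float          fitted half-saturation concentration, pg/mL
    slope_ : float       fitted slope, ratio per pg/mL (linear model)
    blank_mean_, blank_sd_ : float   blank replicate statistics
    curve_ : CalibrationCurve        frozen view of the fit
    """

    def __init__(self, model: str = "saturation"):
        self.model = model

    # -- sklearn plumbing ---------------------------------------------------
    def _more_tags(self):  # pragma: no cover - sklearn internals
        return {"X_types": ["1darray"], "requires_y": True}

    def fit(self, X, y) -> "SaturationCalibration":
        c = np.asarray(X, dtype=float).reshape(-1)
        r = np.asarray(y, dtype=float).reshape(-1)
        if c.shape != r.shape:
            raise ValueError("X and y must have the same length")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        uniq = np.unique(c)
        if self.model == "saturation" and uniq.size < 3:
            raise ValueError("saturation fit needs >= 3 distinct concentrations")
        if self.model == "linear" and uniq.size < 2:
            raise ValueError("linear fit needs >= 2 distinct concentrations")
        if np.ptp(r) == 0:
            raise ValueError("no response: all ratios are equal")

        blanks = r[c == 0]
        if blanks.size:
            blank_mean = float(blanks.mean())
            blank_sd = float(blanks.std(ddof=1)) if blanks.size > 1 else 0.0
        else:
            lowest = r[c == uniq[0]]
            blank_mean = float(lowest.mean())
            blank_sd = float(lowest.std(ddof=1)) if lowest.size > 1 else 0.0
            warnings.warn("no blank replicates; using lowest concentration's "
                          "spread as blank SD", stacklevel=2)

        if self.model == "saturation":
            r0_0 = blank_mean
            span = max(float(r.max() - r0_0), 1e-6)
            kd_0 = max(float(np.median(uniq[uniq > 0])) if (uniq > 0).any() else 1.0, 1e-6)
            try:
                popt, _ = curve_fit(
                    lambda cc, r0, rmax, kd: r0 + rmax * cc / (kd + cc),
                    c, r, p0=[r0_0, span, kd_0],
                    bounds=([-np.inf, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
                    maxfev=20000)
            except RuntimeError as exc:
                raise ValueError(f"saturation fit failed to converge: {exc}") from exc
            r0, r_max, kd = (float(p) for p in popt)
            if r_max <= 0 or kd <= 0:
                raise ValueError(
                    f"non-monotone saturation fit (r_max={r_max:.3g}, kd={kd:.3g})")
            self.r0_, self.r_max_, self.kd_, self.slope_ = r0, r_max, kd, None
        elif self.model == "linear":
            slope, r0 = np.polyfit(c, r, 1)
            if slope <= 0:
                raise ValueError(f"non-increasing linear fit (slope={slope:.3g})")
            self.r0_, self.slope_ = float(r0), float(slope)
            self.r_max_, self.kd_ = None, None
        else:
            raise ValueError(f"unknown model {self.model!r}")

        resid = r - self._predict_arr(c)
        dof = max(r.size - (3 if self.model == "saturation" else 2), 1)
        self.blank_mean_, self.blank_sd_ = blank_mean, blank_sd
        self.residual_sd_ = float(np.sqrt((resid ** 2).sum() / dof))
        self.n_ = int(r.size)
        self.curve_ = CalibrationCurve(
            model=self.model, r0=self.r0_, r_max=self.r_max_, kd=self.kd_,
            slope=self.slope_, blank_mean=self.blank_mean_,
            blank_sd=self.blank_sd_, residual_sd=self.residual_sd_, n=self.n_)
        return self

    def _predict_arr(self, c: np.ndarray) -> np.ndarray:
        if self.model == "saturation":
            return self.r0_ + self.r_max_ * c / (self.kd_ + c)
        return self.r0_ + self.slope_ * c

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "r0_"):
            raise RuntimeError("estimator is not fitted")
        return self._predict_arr(np.asarray(X, dtype=float).reshape(-1))

    def limit_of_detection(self, blank_sd_override: float | None = None) -> LODResult:
        return limit_of_detection(self.curve_, blank_sd_override)

    def invert(self, ratio: float) -> float:
        return invert_concentration(self.curve_, ratio)


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        return (points["concentration_pg_ml"].to_numpy(dtype=float),
                points["ratio"].to_numpy(dtype=float))
    arr = np.asarray(points, dtype=float)
    return arr[:, 0], arr[:, 1]


def fit_calibration(points, model: str = "saturation") -> CalibrationCurve:
    """Fit a detectivity curve to (concentration pg/mL, ratio) points.

    ``points`` is a DataFrame with columns ``concentration_pg_ml, ratio`` or
    an (n, 2) array of the same.
    """
    c, r = _as_points(points)
    est = SaturationCalibration(model=model).fit(c, r)
    return est.curve_


def limit_of_detection(curve: CalibrationCurve,
                       blank_sd_override: float | None = None) -> LODResult:
    """Concentration whose fitted response exceeds the blank by 2 blank SDs."""
    sd = curve.blank_sd if blank_sd_override is None else float(blank_sd_override)
    if sd < 0:
        raise ValueError("blank SD must be non-negative")
    delta = 2.0 * sd
    threshold = curve.r0 + delta
    if curve.model == "saturation":
        if delta >= curve.r_max:
            raise ValueError(
                f"LOD unreachable: 2*blank_sd = {delta:.3g} >= r_max = {curve.r_max:.3g}")
        lod = curve.kd * delta / (curve.r_max - delta)
    else:
        lod = delta / curve.slope
    return LODResult(lod_pg_ml=float(lod), threshold_ratio=float(threshold))


def invert_concentration(curve: CalibrationCurve, ratio: float) -> float:
    """Unique inverse of the monotone calibration curve, pg/mL.

    Ratios below the blank level clamp to 0 with a warning; ratios at or
    above the saturation asymptote have no finite inverse.
    """
    ratio = float(ratio)
    if ratio < curve.r0:
        warnings.warn(f"ratio {ratio:.4g} below blank level {curve.r0:.4g}; "
                      "clamping concentration to 0", stacklevel=2)
        return 0.0
    if curve.model == "saturation":
        asymptote = curve.r0 + curve.r_max
        if ratio >= asymptote:
            raise ValueError(
                f"ratio {ratio:.4g} at/above saturation asymptote {asymptote:.4g}")
        return float(curve.kd * (ratio - curve.r0) / (asymptote - ratio))
    return float((ratio - curve.r0) / curve.slope)
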