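"""Ratiometric stack arithmetic and ROI time series.

The Fura-2 ratio is the 340 nm excitation intensity divided by the 380 nm
intensity, pixel by pixel; it cancels dye loading and is the calcium proxy
every downstream step consumes. ROI means (also used for single-channel ATP
intensity traces), endpoint detrending ("leveling"), baseline-to-peak
deltas, and the insulin signal/background fluorescence ratio live here too.

Coordinate convention: 0-based, row-major, origin top-left; ROI rectangles
are half-open [x0, x1) x [y0, y1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RatioStack",
    "RatioTrace",
    "RoiSpec",
    "compute_ratio_stack",
    "roi_mean_trace",
    "detrend_endpoints",
    "delta_ratio",
    "fluorescence_ratio",
]


@dataclass(frozen=True)
class RatioStack:
    """T x Y x X stack of unitless ratios with a per-pixel validity mask.

    ``mask`` is True where the pixel is valid; masked (False) pixels are
    excluded from every downstream statistic rather than clipped, so
    acquisition artifacts stay visible.
    """

    values: np.ndarray
    times: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mask", m)
        if v.ndim != 3:
            raise ValueError("values must be T x Y x X")
        if t.shape != (v.shape[0],):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if m.shape != v.shape[1:]:
            raise ValueError("mask must be Y x X")
        if m.any() and not np.all(np.isfinite(v[:, m])):
            raise ValueError("unmasked values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RatioTrace:
    """Time series of a ROI mean: ratio units for Fura, raw intensity for ATP."""

    times: np.ndarray
    values: np.ndarray
    roi_area_um2: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular ROI, half-open pixel bounds, with physical pixel size."""

    x0: int
    x1: int
    y0: int
    y1: int
    pixel_size_um: float = 1.0

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("ROI must be non-empty")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI bounds must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_pixels(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size_um ** 2


def compute_ratio_stack(ch_num: np.ndarray, ch_den: np.ndarray,
                        times: np.ndarray, eps: float | None = None) -> RatioStack:
    """Per-pixel quotient stack (e.g. Fura 340/380).

    Pixels whose denominator falls at or below ``eps`` in any frame are
    masked out (never infinite). Default ``eps`` is 1e-6 of the denominator
    channel's dynamic range.
    """
    num = np.asarray(ch_num, dtype=float)
    den = np.asarray(ch_den, dtype=float)
    if num.shape != den.shape:
        raise ValueError(f"channel shapes differ: {num.shape} vs {den.shape}")
    if num.ndim != 3:
        raise ValueError("stacks must be T x Y x X")
    times = np.asarray(times, dtype=float)
    if times.shape != (num.shape[0],):
        raise ValueError("times must have one entry per frame")
    if eps is None:
        rng = float(den.max() - den.min())
        eps = 1e-6 * (rng if rng > 0 else abs(float(den.max())) or 1.0)
    bad = (den <= eps).any(axis=0)
    values = np.empty_like(num)
    ok = ~bad
    values[:, ok] = num[:, ok] / den[:, ok]
    values[:, bad] = np.nan
    return RatioStack(values=values, times=times, mask=ok)


def roi_mean_trace(stack, roi: RoiSpec,
                   times: np.ndarray | None = None) -> RatioTrace:
    """Frame-by-frame mean over the unmasked ROI pixels.

    ``stack`` may be a :class:`RatioStack` or a bare T x Y x X array (e.g. a
    single-channel ATP stack), in which case ``times`` must be supplied and
    all pixels count as valid.
    """
    if isinstance(stack, RatioStack):
        values, mask, t = stack.values, stack.mask, stack.times
    else:
        values = np.asarray(stack, dtype=float)
        if values.ndim != 3:
            raise ValueError("stack must be T x Y x X")
        if times is None:
            raise ValueError("times required for a bare array stack")
        t = np.asarray(times, dtype=float)
        mask = np.ones(values.shape[1:], dtype=bool)
    _, H, W = values.shape
    if roi.x1 > W or roi.y1 > H:
        raise ValueError(f"ROI {roi} exceeds image bounds {W}x{H}")
    sub = values[:, roi.y0:roi.y1, roi.x0:roi.x1]
    submask = mask[roi.y0:roi.y1, roi.x0:roi.x1]
    if not submask.any():
        raise ValueError("ROI contains no unmasked pixels")
    trace = sub[:, submask].mean(axis=1)
    bad = ~np.isfinite(trace)
    if bad.any():
        raise ValueError(f"ROI mean undefined at frame {int(np.argmax(bad))}")
    return RatioTrace(times=t, values=trace, roi_area_um2=roi.area_um2)


def detrend_endpoints(trace: RatioTrace) -> RatioTrace:
    """Level a trace by subtracting the line through its first and last points.

    This is the standard "leveling" step for slow drifts (photobleaching,
    focus): the returned trace is exactly zero at both endpoints, the
    operation is linear and idempotent.
    """
    if len(trace) < 2:
        raise ValueError("detrending needs at least 2 points")
    t, v = trace.times, trace.values
    slope = (v[-1] - v[0]) / (t[-1] - t[0])
    line = v[0] + slope * (t - t[0])
    return replace(trace, values=v - line)


def detrend_endpoints_array(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Endpoint detrend along axis 0 of a T x ... array (vectorized form)."""
    t = np.asarray(times, dtype=float)
    shape = (-1,) + (1,) * (values.ndim - 1)
    w = ((t - t[0]) / (t[-1] - t[0])).reshape(shape)
    return values - (values[0] + (values[-1] - values[0]) * w)


def delta_ratio(trace: RatioTrace, baseline_window: tuple[float, float],
                stim_window: tuple[float, float]) -> float:
    """Baseline-to-peak change: max over the stimulation window minus the
    mean over the baseline window (both windows inclusive, in minutes)."""
    t = trace.times
    b = (t >= baseline_window[0]) & (t <= baseline_window[1])
    s = (t >= stim_window[0]) & (t <= stim_window[1])
    if not b.any():
        raise ValueError("baseline window selects no frames")
    if not s.any():
        raise ValueError("stimulation window selects no frames")
    return float(trace.values[s].max() - trace.values[b].mean())


def fluorescence_ratio(signal_roi_mean: float, background_roi_mean: float) -> float:
    """Immunosensor readout: signal ROI mean over background ROI mean."""
    if background_roi_mean <= 0:
        raise ValueError("background intensity must be positive")
    return float(signal_roi_mean) / float(background_roi_mean)
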