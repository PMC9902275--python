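"""Per-pixel spectral-centroid frequency mapping.

The core computation: restrict the ratio stack to the glucose-stimulation
window, endpoint-detrend each pixel's trace, take the DFT magnitude
spectrum, and summarize it by its center of gravity (the magnitude-weighted
mean of the positive frequency grid). Flattening the resulting map
column-wise and mapping columns to oxygen gives the frequency-versus-oxygen
profile whose peak locates the oxygen level of fastest calcium oscillation.

Conventions (stated because the centroid is undefined without them):

* DC (k = 0) is excluded and traces are endpoint-detrended first; otherwise
  baseline offsets drag every centroid toward zero.
* Weights are DFT *magnitudes*, not powers.
* Real-input spectrum uses bins k = 1 ... floor(N/2); for even N the
  Nyquist bin is included once.
* No taper/window function is applied, so off-bin tones leak; the centroid
  of a short pure tone is therefore biased (see docs/methods.md).
* Display normalization (min-max to [0, 1]) is for visualization only;
  profiles and peaks are computed on unnormalized frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .ratio import RatioStack, detrend_endpoints_array
from .synthetic import GradientMap

__all__ = [
    "AnalysisWindow",
    "FrequencyMap",
    "FrequencyProfile",
    "PeakResult",
    "FrequencyMapper",
    "select_analysis_window",
    "cog_frequency",
    "frequency_map",
    "profile_vs_position",
    "peak_frequency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisWindow:
    """Contiguous run of frames (0-based indices) with their times (min)."""

    indices: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "times", t)
        if idx.size < 2:
            raise ValueError("analysis window needs at least 2 frames")
        if np.any(np.diff(idx) != 1):
            raise ValueError("window frames must be contiguous")
        dts = np.diff(t)
        if not np.allclose(dts, dts[0]):
            raise ValueError("window frame times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class FrequencyMap:
    """Y x X nominal (center-of-gravity) frequencies, oscillations/hour."""

    values: np.ndarray
    mask: np.ndarray
    dt: float  # window frame interval, minutes

    @property
    def nyquist_per_hr(self) -> float:
        return 60.0 / (2.0 * self.dt)

    def normalized(self) -> np.ndarray:
        """Min-max display copy in [0, 1] over unmasked pixels (NaN elsewhere)."""
        out = np.full(self.values.shape, np.nan)
        v = self.values[self.mask]
        if v.size:
            lo, hi = v.min(), v.max()
            out[self.mask] = 0.0 if hi == lo else (self.values[self.mask] - lo) / (hi - lo)
        return out


@dataclass(frozen=True)
class FrequencyProfile:
    """Column-averaged frequencies (per hour) vs position, optionally vs %O2."""

    freq_per_hr: np.ndarray
    columns: np.ndarray
    o2_percent: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __len__(self) -> int:
        return self.freq_per_hr.size


@dataclass(frozen=True)
class PeakResult:
    """Location of the profile maximum on the oxygen axis."""

    o2_percent: float
    freq_per_hr: float
    period_min: float
    column: int
    unique: bool = True


def select_analysis_window(frame_times: np.ndarray, stim_start: float,
                           stim_end: float, drop_first: bool = False) -> AnalysisWindow:
    """Frames with stim_start <= t <= stim_end (inclusive); optionally drop
    the earliest selected frame (the stimulation-onset overshoot)."""
    t = np.asarray(frame_times, dtype=float)
    sel = np.flatnonzero((t >= stim_start) & (t <= stim_end))
    if drop_first and sel.size:
        sel = sel[1:]
    if sel.size < 2:
        raise ValueError("stimulation window selects fewer than 2 frames")
    return AnalysisWindow(indices=sel, times=t[sel])


def _cog_along_axis0(values: np.ndarray, dt: float) -> np.ndarray:
    """Center-of-gravity frequency (per hour) along axis 0 of a T x ... array."""
    n = values.shape[0]
    mag = np.abs(np.fft.rfft(values, axis=0))[1:]  # bins 1 .. floor(N/2)
    k = np.arange(1, mag.shape[0] + 1, dtype=float)
    f_per_min = (k / (n * dt)).reshape((-1,) + (1,) * (values.ndim - 1))
    total = mag.sum(axis=0)
    num = (f_per_min * mag).sum(axis=0)
    out = np.zeros_like(total)
    nz = total > 0
    out[nz] = 60.0 * num[nz] / total[nz]
    return out


def cog_frequency(values: np.ndarray, dt: float) -> float:
    """Magnitude-weighted mean of the positive DFT frequency grid, per hour.

    With DFT magnitudes |X_k| at f_k = k/(N*dt) cycles/min for
    k = 1 ... floor(N/2) (DC excluded), returns 60 * sum(f_k |X_k|) /
    sum(|X_k|); 0 when the spectrum is identically zero. Input samples must
    be uniformly spaced ``dt`` minutes apart.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 4:
        raise ValueError("need a 1-D series of at least 4 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(_cog_along_axis0(v, dt))


class FrequencyMapper(TransformerMixin, BaseEstimator):
    """Stack -> frequency-map transformer (scikit-learn estimator API).

    ``fit`` learns the analysis window from the stack's frame times;
    ``transform`` endpoint-detrends each unmasked pixel's windowed trace and
    reduces its DFT magnitude spectrum to a center-of-gravity frequency.

    Parameters
    ----------
    stim_start, stim_end : float
        Stimulation window bounds in minutes (frames selected inclusively).
    drop_first : bool
        Drop the earliest selected frame (stimulation-onset overshoot).
    detrend : bool
        Endpoint-detrend each windowed trace before the DFT.
    block_height : int or None
        Process the image in row blocks of this height to bound memory on
        collage-scale stacks; None processes all rows at once.
    """

    def __init__(self, stim_start: float = 12.0, stim_end: float = 36.0,
                 drop_first: bool = True, detrend: bool = True,
                 block_height: int | None = None):
        self.stim_start = stim_start
        self.stim_end = stim_end
        self.drop_first = drop_first
        self.detrend = detrend
        self.block_height = block_height

    def fit(self, X: RatioStack, y=None) -> "FrequencyMapper":
        if not isinstance(X, RatioStack):
            raise TypeError("FrequencyMapper expects a RatioStack")
        self.window_ = select_analysis_window(
            X.times, self.stim_start, self.stim_end, self.drop_first)
        self.n_frames_ = len(self.window_)
        return self

    def transform(self, X: RatioStack) -> FrequencyMap:
        if not hasattr(self, "window_"):
            raise RuntimeError("FrequencyMapper is not fitted")
        if not isinstance(X, RatioStack):
            raise TypeError("FrequencyMapper expects a RatioStack")
        w = self.window_
        if w.indices[-1] >= X.shape[0]:
            raise ValueError("analysis window exceeds stack length")
        _, H, W = X.shape
        out = np.full((H, W), np.nan)
        step = H if self.block_height is None else max(1, int(self.block_height))
        for y0 in range(0, H, step):
            y1 = min(H, y0 + step)
            sub = X.values[w.indices[0]:w.indices[-1] + 1, y0:y1, :]
            if self.detrend:
                sub = detrend_endpoints_array(sub, w.times)
            block = _cog_along_axis0(np.nan_to_num(sub, nan=0.0), w.dt)
            out[y0:y1] = block
        out[~X.mask] = np.nan
        return FrequencyMap(values=out, mask=X.mask.copy(), dt=w.dt)


def frequency_map(ratio_stack: RatioStack, window: AnalysisWindow,
                  detrend: bool = True, block_height: int | None = None) -> FrequencyMap:
    """Per-pixel center-of-gravity frequency map over an analysis window."""
    mapper = FrequencyMapper(detrend=detrend, block_height=block_height)
    mapper.window_ = window
    mapper.n_frames_ = len(window)
    return mapper.transform(ratio_stack)


def profile_vs_position(fmap: FrequencyMap,
                        gradient: GradientMap | None = None) -> FrequencyProfile:
    """Column means over unmasked pixels ("averaged and flattened vertically").

    Columns with no unmasked pixel get a NaN entry, flagged in ``valid`` and
    logged as a warning.
    """
    masked = np.where(fmap.mask, fmap.values, np.nan)
    counts = fmap.mask.sum(axis=0)
    valid = counts > 0
    prof = np.full(fmap.values.shape[1], np.nan)
    if valid.any():
        with np.errstate(invalid="ignore"):
            prof[valid] = np.nanmean(masked[:, valid], axis=0)
    if not valid.all():
        logger.warning("%d fully-masked columns in frequency profile",
                       int((~valid).sum()))
    o2 = None
    if gradient is not None:
        if len(gradient) != prof.size:
            raise ValueError("gradient length != image width")
        o2 = gradient.o2.copy()
    return FrequencyProfile(freq_per_hr=prof,
                            columns=np.arange(prof.size),
                            o2_percent=o2, valid=valid)


def peak_frequency(profile: FrequencyProfile, gradient: GradientMap | None = None,
                   smooth_width: int = 1) -> PeakResult:
    """Locate the profile maximum and report its oxygen level and period.

    ``smooth_width`` > 1 applies a centered moving average before
    peak-picking (off by default). Ties resolve to the lowest column index,
    i.e. toward lower oxygen on a monotone half-gradient, and the result is
    flagged non-unique.
    """
    if gradient is None:
        if profile.o2_percent is None:
            raise ValueError("need a gradient or a profile with an O2 axis")
        o2 = profile.o2_percent
    else:
        if len(gradient) != len(profile):
            raise ValueError("gradient length != profile length")
        o2 = gradient.o2
    f = profile.freq_per_hr.astype(float)
    ok = np.isfinite(f)
    if not ok.any():
        raise ValueError("profile is fully masked")
    if smooth_width > 1:
        kernel = np.ones(int(smooth_width))
        filled = np.where(ok, f, 0.0)
        sm = np.convolve(filled, kernel, mode="same") / np.maximum(
            np.convolve(ok.astype(float), kernel, mode="same"), 1e-12)
        f = np.where(ok, sm, np.nan)
    best = np.nanmax(f)
    idx = int(np.nanargmax(f))  # first occurrence = lowest column
    unique = int(np.sum(np.isclose(f[ok], best, rtol=0, atol=0))) == 1
    freq = float(f[idx])
    period = 60.0 / freq if freq > 0 else float("inf")
    return PeakResult(o2_percent=float(o2[idx]), freq_per_hr=freq,
                      period_min=period, column=idx, unique=unique)
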