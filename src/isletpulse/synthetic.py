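"""Seeded synthetic inputs for the oxygen-gradient imaging pipeline.

Real acquisitions in this kind of experiment are time-lapse two-channel
(340/380 nm excitation) fluorescence collages of beta cells cultured over a
microfluidic oxygen gradient, plus in-gel immunosensor calibration series.
No raw data ship with the package, so this module generates stacks and
calibration tables with the statistical structure the downstream analysis
assumes: an oxygen gradient along the image x-axis, cells whose detrended
Fura-2 ratio oscillates at an oxygen-dependent frequency peaking near 12%
O2, a stimulation-onset overshoot frame, slow photobleaching, additive
noise, tile-stitching banding, and a saturating insulin detectivity curve
with replicate noise.

Everything is driven by one integer seed; identical seeds give bit-for-bit
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "GradientMap",
    "StackConfig",
    "DetectivityConfig",
    "FuraStack",
    "make_oxygen_gradient",
    "oxygen_frequency",
    "target_ratio_trace",
    "simulate_fura_stack",
    "simulate_detectivity",
    "write_stack",
    "read_stack",
    "write_detectivity_csv",
]


@dataclass(frozen=True)
class GradientMap:
    """Oxygen concentration (%) as a function of image column.

    ``mode`` is ``"half"`` (monotone 0 -> o2_max left to right) or ``"full"``
    (mirror-symmetric, 0 at both edges). ``positions`` are 0-based column
    indices, leftmost column = 0.
    """

    o2: np.ndarray
    mode: str

    def __post_init__(self):
        o2 = np.asarray(self.o2, dtype=float)
        object.__setattr__(self, "o2", o2)
        if o2.ndim != 1 or o2.size < 2:
            raise ValueError("gradient needs at least 2 columns")
        if np.any(o2 < 0):
            raise ValueError("oxygen fractions must be non-negative")
        if self.mode == "half":
            if np.any(np.diff(o2) < 0):
                raise ValueError("half-gradient must be non-decreasing")
        elif self.mode == "full":
            if not np.allclose(o2, o2[::-1]):
                raise ValueError("full gradient must be mirror-symmetric")
        else:
            raise ValueError(f"unknown gradient mode {self.mode!r}")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.o2.size)

    def __len__(self) -> int:
        return self.o2.size


def make_oxygen_gradient(length: int, o2_max: float = 20.0,
                         mode: str = "half", shape: str = "linear") -> GradientMap:
    """Build the column -> %O2 map imposed by the gas-channel device.

    ``shape="linear"`` interpolates linearly between the 0 and ``o2_max``
    endpoints; ``shape="logistic"`` uses a smooth sigmoid with the same
    endpoints (the measured gradient is smooth but no functional form is
    published, so linear is the default).
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if o2_max <= 0:
        raise ValueError("o2_max must be positive")
    x = np.arange(length, dtype=float)
    if mode == "half":
        u = x / (length - 1)
    elif mode == "full":
        # triangular coordinate: 0 at both edges, 1 at the midline
        u = 1.0 - np.abs(2.0 * x / (length - 1) - 1.0)
    else:
        raise ValueError(f"unknown gradient mode {mode!r}")
    if shape == "linear":
        o2 = o2_max * u
    elif shape == "logistic":
        # rescaled logistic pinned to 0 and o2_max at u = 0, 1
        z = 1.0 / (1.0 + np.exp(-8.0 * (u - 0.5)))
        z0, z1 = 1.0 / (1.0 + np.exp(4.0)), 1.0 / (1.0 + np.exp(-4.0))
        o2 = o2_max * (z - z0) / (z1 - z0)
    else:
        raise ValueError(f"unknown gradient shape {shape!r}")
    return GradientMap(o2=o2, mode=mode)


@dataclass(frozen=True)
class StackConfig:
    """Acquisition + physiology parameters for a synthetic Fura stack.

    Times are minutes; frequencies oscillations/hour; ratio quantities are
    unitless Fura (340/380) ratio units. The oxygen-frequency relation is a
    Gaussian bump: f(O2) = f_base + (f_peak - f_base) *
    exp(-(O2 - o2_peak)^2 / (2 * profile_width^2)), peaking at ``o2_peak``.
    """

    n_frames: int = 46
    dt: float = 1.0
    stim_start: float = 12.0
    stim_end: float = 36.0
    width: int = 640
    height: int = 128
    o2_peak: float = 12.0
    f_peak: float = 13.5
    f_base: float = 6.0
    profile_width: float = 4.0
    baseline: float = 1.0
    amplitude: float = 0.15
    bleach_slope: float = -0.002
    overshoot_gain: float = 3.0
    noise_sd: float = 0.02
    banding_amplitude: float = 0.03
    tile_width: int = 80
    plateau: float = 1000.0
    plateau_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.stim_start < self.stim_end <= (self.n_frames - 1) * self.dt):
            raise ValueError("stimulation window must lie within the timeline")
        if self.f_base > self.f_peak:
            raise ValueError("f_base must not exceed f_peak")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.width < 1 or self.height < 1 or self.tile_width < 1:
            raise ValueError("width, height and tile_width must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class FuraStack:
    """Two-channel T x Y x X stack with frame timestamps (minutes)."""

    ch340: np.ndarray
    ch380: np.ndarray
    times: np.ndarray
    config: StackConfig | None = None
    gradient: GradientMap | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ch340.shape


def oxygen_frequency(o2, cfg: StackConfig) -> np.ndarray:
    """Oscillation frequency (per hour) at oxygen level(s) ``o2`` (%)."""
    o2 = np.asarray(o2, dtype=float)
    return cfg.f_base + (cfg.f_peak - cfg.f_base) * np.exp(
        -((o2 - cfg.o2_peak) ** 2) / (2.0 * cfg.profile_width ** 2))


def target_ratio_trace(cfg: StackConfig, o2: float,
                       times: np.ndarray | None = None) -> np.ndarray:
    """Closed-form noise-free ratio trace of a pixel at oxygen level ``o2``.

    baseline + bleach_slope*t, plus during the stimulation window an
    oscillation amplitude*sin(2*pi*f*(t - stim_start)) (phase locked to the
    glucose bolus), plus an overshoot spike amplitude*overshoot_gain on the
    first stimulated frame. Banding and noise are excluded: this is the
    oracle the imaging pipeline should recover.
    """
    t = cfg.times if times is None else np.asarray(times, dtype=float)
    r = cfg.baseline + cfg.bleach_slope * t
    stim = (t >= cfg.stim_start) & (t <= cfg.stim_end)
    f_per_min = float(oxygen_frequency(o2, cfg)) / 60.0
    r = r + np.where(
        stim, cfg.amplitude * np.sin(2.0 * np.pi * f_per_min * (t - cfg.stim_start)), 0.0)
    if stim.any():
        first = np.argmax(stim)
        r[first] += cfg.amplitude * cfg.overshoot_gain
    return r


def _banding_offset(cfg: StackConfig) -> np.ndarray:
    """Per-column square-wave offset emulating collage-stitching bands."""
    tiles = np.arange(cfg.width) // cfg.tile_width
    return cfg.banding_amplitude * np.where(tiles % 2 == 0, 1.0, -1.0)


def simulate_fura_stack(cfg: StackConfig, gradient: GradientMap) -> FuraStack:
    """Generate a two-channel stack whose 340/380 quotient follows the model.

    The 380 nm channel is a constant plateau plus detector noise; the 340 nm
    channel is (target ratio + ratio noise + banding) times the 380 channel,
    so the quotient equals the target exactly in the noise-free case.
    """
    if len(gradient) != cfg.width:
        raise ValueError(
            f"gradient length {len(gradient)} != stack width {cfg.width}")
    t = cfg.times
    # clean ratio: T x X (identical down each column)
    f_per_min = oxygen_frequency(gradient.o2, cfg) / 60.0
    stim = (t >= cfg.stim_start) & (t <= cfg.stim_end)
    osc = cfg.amplitude * np.sin(
        2.0 * np.pi * f_per_min[None, :] * (t[:, None] - cfg.stim_start))
    ratio_tx = (cfg.baseline + cfg.bleach_slope * t)[:, None] + np.where(
        stim[:, None], osc, 0.0)
    if stim.any():
        ratio_tx[np.argmax(stim)] += cfg.amplitude * cfg.overshoot_gain
    ratio = np.broadcast_to(
        ratio_tx[:, None, :], (cfg.n_frames, cfg.height, cfg.width)).copy()
    ratio += _banding_offset(cfg)[None, None, :]

    ss = np.random.SeedSequence(cfg.seed)
    rng_ratio, rng_den = (np.random.default_rng(s) for s in ss.spawn(2))
    if cfg.noise_sd > 0:
        ratio += rng_ratio.normal(0.0, cfg.noise_sd, size=ratio.shape)
    den = np.full(ratio.shape, cfg.plateau)
    if cfg.plateau_noise_sd > 0:
        den += rng_den.normal(0.0, cfg.plateau_noise_sd, size=den.shape)
    ch340 = (ratio * den).astype(np.float32)
    ch380 = den.astype(np.float32)
    return FuraStack(ch340=ch340, ch380=ch380, times=t,
                     config=cfg, gradient=gradient)


@dataclass(frozen=True)
class DetectivityConfig:
    """Parameters of the synthetic insulin detectivity (calibration) series.

    Replicate fluorescence ratios follow a one-site saturation curve
    r0 + r_max*C/(kd + C) with additive Gaussian noise. With the defaults
    the concentration whose clean response exceeds the blank by twice the
    noise SD is exactly 25 pg/mL (2.0*25/(475+25) = 0.1 = 2*0.05), which is
    the closed-form truth the sensor-calibration tests recover.
    """

    r0: float = 1.0
    r_max: float = 2.0
    kd: float = 475.0
    noise_sd: float = 0.05
    concentrations: tuple[float, ...] = (0.0, 50.0, 100.0, 250.0, 500.0, 1000.0)
    replicates: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def clean_response(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.r0 + self.r_max * c / (self.kd + c)


def simulate_detectivity(cfg: DetectivityConfig) -> pd.DataFrame:
    """Replicate calibration points as a table (concentration_pg_ml, ratio)."""
    rng = np.random.default_rng(cfg.seed)
    conc = np.repeat(np.asarray(cfg.concentrations, dtype=float), cfg.replicates)
    ratio = cfg.clean_response(conc)
    if cfg.noise_sd > 0:
        ratio = ratio + rng.normal(0.0, cfg.noise_sd, size=conc.size)
    return pd.DataFrame({"concentration_pg_ml": conc, "ratio": ratio})


# ---------------------------------------------------------------------------
# disk round trip: one multi-page float32 TIFF per channel + YAML sidecar

def write_stack(stack: FuraStack, outdir: str | Path, stem: str = "stack") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ch340": outdir / f"{stem}_ch340.tif",
        "ch380": outdir / f"{stem}_ch380.tif",
        "meta": outdir / f"{stem}_meta.yaml",
    }
    tifffile.imwrite(paths["ch340"], stack.ch340)
    tifffile.imwrite(paths["ch380"], stack.ch380)
    meta = {"times_min": [float(t) for t in stack.times]}
    if stack.config is not None:
        meta["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in asdict(stack.config).items()}
    if stack.gradient is not None:
        meta["gradient"] = {"mode": stack.gradient.mode,
                            "o2": [float(v) for v in stack.gradient.o2]}
    paths["meta"].write_text(yaml.safe_dump(meta))
    return {k: str(v) for k, v in paths.items()}


def read_stack(outdir: str | Path, stem: str = "stack") -> FuraStack:
    outdir = Path(outdir)
    meta = yaml.safe_load((outdir / f"{stem}_meta.yaml").read_text())
    ch340 = tifffile.imread(outdir / f"{stem}_ch340.tif")
    ch380 = tifffile.imread(outdir / f"{stem}_ch380.tif")
    cfg = StackConfig(**meta["config"]) if "config" in meta else None
    grad = None
    if "gradient" in meta:
        grad = GradientMap(o2=np.asarray(meta["gradient"]["o2"]),
                           mode=meta["gradient"]["mode"])
    return FuraStack(ch340=ch340, ch380=ch380,
                     times=np.asarray(meta["times_min"], dtype=float),
                     config=cfg, gradient=grad)


def write_detectivity_csv(points: pd.DataFrame, path: str | Path) -> None:
    points.to_csv(path, index=False)
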