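"""Configuration objects for the simulation and estimation pipeline.

All configurations are plain frozen dataclasses validated on construction,
with JSON round-tripping (``to_dict`` / ``from_dict``) so that every run can
log the exact parameters that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SPEED_OF_LIGHT = 299_792_458.0  # m/s

#: Physiologic heart-rate band, BPM.
HR_BPM_RANGE = (60.0, 240.0)
#: Physiologic breathing-rate band, BPM.
BR_BPM_RANGE = (12.0, 36.0)
#: Chest-wall breathing displacement amplitude range, mm.
BREATH_AMPLITUDE_RANGE_MM = (4.0, 12.0)
#: Chest-wall heartbeat displacement amplitude range, mm.
HEART_AMPLITUDE_RANGE_MM = (0.1, 0.5)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-linear rate trajectory, BPM as a function of time.

    The instantaneous rate is linearly interpolated between breakpoints and
    held constant outside them, so the simulator can integrate it into a
    continuous phase without frequency jumps.
    """

    times_s: tuple[float, ...]
    bpm: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.bpm, dtype=float)
        if t.size == 0 or t.size != v.size:
            raise ConfigError("trajectory needs equal, nonzero numbers of times and rates")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ConfigError("trajectory breakpoint times must be strictly increasing")
        object.__setattr__(self, "times_s", tuple(t.tolist()))
        object.__setattr__(self, "bpm", tuple(v.tolist()))

    @classmethod
    def constant(cls, bpm: float) -> "Trajectory":
        return cls((0.0,), (float(bpm),))

    @classmethod
    def ramp(cls, bpm_start: float, bpm_end: float, duration_s: float) -> "Trajectory":
        return cls((0.0, float(duration_s)), (float(bpm_start), float(bpm_end)))

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        """Rate in BPM at time(s) ``t`` (seconds)."""
        return np.interp(np.asarray(t, dtype=float), self.times_s, self.bpm)

    def hz(self, t: np.ndarray | float) -> np.ndarray:
        """Instantaneous frequency in Hz at time(s) ``t``."""
        return self(t) / 60.0

    def bounds(self, duration_s: float) -> tuple[float, float]:
        """Min/max rate attained on [0, duration_s]."""
        grid = np.unique(np.concatenate([[0.0, duration_s], np.asarray(self.times_s)]))
        grid = grid[(grid >= 0.0) & (grid <= duration_s)]
        vals = self(grid)
        return float(vals.min()), float(vals.max())


@dataclass(frozen=True)
class MotionEvent:
    """A transient body-motion artefact.

    On the radar branch the event is an additive raised-cosine displacement
    bump; on the video branch it is a smooth transient intensity excursion of
    the same shape.  ``amplitude`` is mm for radar, sensor intensity units
    for video.
    """

    time_s: float
    duration_s: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("motion event duration must be positive")

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Raised-cosine bump evaluated at times ``t`` (zero outside)."""
        u = (np.asarray(t, dtype=float) - self.time_s) / self.duration_s
        inside = (u >= 0.0) & (u <= 1.0)
        out = np.zeros_like(u)
        out[inside] = 0.5 * self.amplitude * (1.0 - np.cos(2.0 * np.pi * u[inside]))
        return out


@dataclass(frozen=True)
class DriftConfig:
    """Slow baseline wander: a sinusoid of given amplitude and period."""

    amplitude: float = 0.0
    period_s: float = 60.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ConfigError("drift period must be positive")

    def profile(self, t: np.ndarray) -> np.ndarray:
        if self.amplitude == 0.0:
            return np.zeros_like(np.asarray(t, dtype=float))
        return self.amplitude * np.sin(2.0 * np.pi * np.asarray(t, dtype=float) / self.period_s)


@dataclass(frozen=True)
class ScenarioConfig:
    """A synthetic recording scenario with known HR/BR ground truth.

    Displacement amplitudes default to mid-range chest-motion values: the
    breathing component of chest movement spans 4-12 mm and the heartbeat
    component 0.1-0.5 mm.  Noise is white Gaussian per sample;
    ``noise_sd_mm`` applies to the radar displacement, ``rppg_noise_sd`` to
    each colour channel.
    """

    duration_s: float = 300.0
    fs_radar: float = 20.0
    fs_video: float = 30.0
    hr_trajectory: Trajectory = field(default_factory=lambda: Trajectory.constant(72.0))
    br_trajectory: Trajectory = field(default_factory=lambda: Trajectory.constant(15.0))
    breath_amplitude_mm: float = 6.0
    heart_amplitude_mm: float = 0.3
    noise_sd_mm: float = 0.0
    drift: DriftConfig = field(default_factory=DriftConfig)
    motion_events: tuple[MotionEvent, ...] = ()
    # rPPG trace parameters (sensor intensity units on an 8-bit-like scale)
    rppg_dc: float = 120.0
    rppg_pulse_amplitude: float = 1.0
    rppg_resp_amplitude: float = 0.3
    rppg_noise_sd: float = 0.0
    rppg_drift: DriftConfig = field(default_factory=DriftConfig)
    rppg_motion_events: tuple[MotionEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.fs_radar <= 0 or self.fs_video <= 0:
            raise ConfigError("sampling rates must be positive")
        for label, traj, (lo, hi) in (
            ("HR", self.hr_trajectory, HR_BPM_RANGE),
            ("BR", self.br_trajectory, BR_BPM_RANGE),
        ):
            tmin, tmax = traj.bounds(self.duration_s)
            if tmin < lo or tmax > hi:
                raise ConfigError(
                    f"{label} trajectory [{tmin:.1f}, {tmax:.1f}] BPM leaves the "
                    f"physiologic band [{lo:.0f}, {hi:.0f}] BPM"
                )
        lo, hi = BREATH_AMPLITUDE_RANGE_MM
        if not (lo <= self.breath_amplitude_mm <= hi):
            raise ConfigError(f"breath_amplitude_mm must lie in [{lo}, {hi}] mm")
        lo, hi = HEART_AMPLITUDE_RANGE_MM
        if not (lo <= self.heart_amplitude_mm <= hi):
            raise ConfigError(f"heart_amplitude_mm must lie in [{lo}, {hi}] mm")
        if self.noise_sd_mm < 0 or self.rppg_noise_sd < 0:
            raise ConfigError("noise standard deviations must be nonnegative")
        if isinstance(self.motion_events, list):
            object.__setattr__(self, "motion_events", tuple(self.motion_events))
        if isinstance(self.rppg_motion_events, list):
            object.__setattr__(self, "rppg_motion_events", tuple(self.rppg_motion_events))

    # -- JSON round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("hr_trajectory", "br_trajectory"):
            if key in d and isinstance(d[key], dict):
                d[key] = Trajectory(tuple(d[key]["times_s"]), tuple(d[key]["bpm"]))
        for key in ("drift", "rppg_drift"):
            if key in d and isinstance(d[key], dict):
                d[key] = DriftConfig(**d[key])
        for key in ("motion_events", "rppg_motion_events"):
            if key in d:
                d[key] = tuple(
                    MotionEvent(**e) if isinstance(e, dict) else e for e in d[key]
                )
        return cls(**d)


@dataclass(frozen=True)
class RadarConfig:
    """FMCW radar parameters.

    Only the chirp repetition period (slow-time sampling) and the carrier
    wavelength enter the signal model; chirp duration, slope and bandwidth
    are carried as metadata.  Defaults follow a 77-81 GHz automotive-band
    sensor chirping every 50 ms.
    """

    center_frequency_hz: float = 79e9
    chirp_period_s: float = 0.05
    chirp_duration_s: float = 50e-6
    slope_hz_per_s: float = 70e12
    bandwidth_hz: float = 4e9

    def __post_init__(self) -> None:
        if self.center_frequency_hz <= 0:
            raise ConfigError("center frequency must be positive")
        if self.chirp_period_s <= 0:
            raise ConfigError("chirp period must be positive")

    @property
    def wavelength_m(self) -> float:
        return SPEED_OF_LIGHT / self.center_frequency_hz

    @property
    def fs(self) -> float:
        """Slow-time sampling rate in Hz (one phase sample per chirp)."""
        return 1.0 / self.chirp_period_s

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RadarConfig":
        return cls(**d)


@dataclass(frozen=True)
class BandConfig:
    """A vital-sign extraction band for the Butterworth band-pass filter."""

    label: str  # "HR" or "BR"
    low_hz: float
    high_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        if self.label not in ("HR", "BR"):
            raise ConfigError("band label must be 'HR' or 'BR'")
        if not (0 < self.low_hz < self.high_hz):
            raise ConfigError("band edges must satisfy 0 < low < high")
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")

    @property
    def bpm_range(self) -> tuple[float, float]:
        return 60.0 * self.low_hz, 60.0 * self.high_hz

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BandConfig":
        return cls(**d)


def hr_band() -> BandConfig:
    """Heart-rate band, 1-4 Hz (60-240 BPM)."""
    return BandConfig("HR", 1.0, 4.0)


def br_band() -> BandConfig:
    """Breathing-rate band, 0.2-0.6 Hz (12-36 BPM)."""
    return BandConfig("BR", 0.2, 0.6)


def band_for(label: str) -> BandConfig:
    if label == "HR":
        return hr_band()
    if label == "BR":
        return br_band()
    raise ConfigError(f"unknown band label {label!r}")


@dataclass(frozen=True)
class SpectrogramConfig:
    """Sliding-window STFT parameters.

    A rectangular 20-s window (half-width 10 s) hops by 1 s; each segment is
    zero-padded with three times its own length before the FFT, and the
    frequency axis is converted to BPM and restricted to the display band.
    """

    window_s: float = 20.0
    hop_s: float = 1.0
    pad_factor: int = 3
    dt: float = 0.05
    bpm_min: float = 60.0
    bpm_max: float = 240.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.hop_s <= 0 or self.dt <= 0:
            raise ConfigError("window_s, hop_s and dt must be positive")
        if self.pad_factor < 0:
            raise ConfigError("pad_factor must be nonnegative")
        if not self.bpm_min < self.bpm_max:
            raise ConfigError("bpm_min must be < bpm_max")

    @property
    def half_width_s(self) -> float:
        return self.window_s / 2.0

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @classmethod
    def for_band(cls, band: BandConfig, fs: float, **kw) -> "SpectrogramConfig":
        lo, hi = band.bpm_range
        return cls(dt=1.0 / fs, bpm_min=lo, bpm_max=hi, **kw)

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SpectrogramConfig":
        return cls(**d)


@dataclass(frozen=True)
class GraphWeightConfig:
    """Graph construction parameters for the ridge-segmentation estimator.

    ``polarity`` chooses the gradient image the weights are built from:
    ``dark-to-bright`` / ``bright-to-dark`` use the signed vertical first
    difference of the spectrogram (tracking a band edge), while
    ``intensity-ridge`` uses the normalized magnitudes themselves (tracking
    the band centre).  ``mode='exponential'`` replaces the gradient weight
    with the general intensity/distance exponential weight parameterised by
    ``sigma_i``, ``sigma_p`` and cutoff ``radius``.
    """

    w_min: float = 1e-5
    connectivity: int = 8
    polarity: str = "intensity-ridge"
    mode: str = "gradient"
    sigma_i: float = 1.0
    sigma_p: float = 1.0
    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.w_min <= 0:
            raise ConfigError("w_min must be positive")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.polarity not in ("dark-to-bright", "bright-to-dark", "intensity-ridge"):
            raise ConfigError(f"unknown polarity {self.polarity!r}")
        if self.mode not in ("gradient", "exponential"):
            raise ConfigError(f"unknown weight mode {self.mode!r}")
        if self.mode == "exponential" and (self.sigma_i <= 0 or self.sigma_p <= 0 or self.radius <= 0):
            raise ConfigError("exponential-mode parameters must be positive")

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GraphWeightConfig":
        return cls(**d)


def _asdict(obj) -> dict:
    """dataclasses.asdict with tuples rendered as lists for JSON."""

    def convert(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: convert(getattr(v, k)) for k in (f.name for f in dataclasses.fields(v))}
        if isinstance(v, (tuple, list)):
            return [convert(x) for x in v]
        return v

    return convert(obj)
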