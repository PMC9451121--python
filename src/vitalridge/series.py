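"""In-memory containers for signals, spectrograms and estimates.

One-dimensional series travel as delimited text (a header row naming the
columns, one sample per line) so that every intermediate of the pipeline is
diffable and inspectable; spectrograms use ``.npz`` with a JSON sidecar for
the axes and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vitalridge.config import BandConfig, SpectrogramConfig


class DataError(ValueError):
    """Raised when input data violates a series invariant."""


def _check_uniform(times: np.ndarray, fs: float, what: str) -> None:
    if times.size >= 2:
        dt = np.diff(times)
        if not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
            raise DataError(f"{what}: sample times are not uniform at fs={fs} Hz")


@dataclass
class PhaseSeries:
    """Radar slow-time phase at the subject's range bin, radians."""

    times: np.ndarray
    values: np.ndarray
    fs: float
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise DataError("phase series: times and values must be equal-length 1-D")
        if self.times.size == 0:
            raise DataError("phase series: empty")
        _check_uniform(self.times, self.fs, "phase series")
        if self.wrapped and (np.any(self.values <= -np.pi) or np.any(self.values > np.pi)):
            raise DataError("wrapped phase must lie in (-pi, pi]")

    def to_text(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "phase_rad": self.values}).to_csv(path, index=False)

    @classmethod
    def from_text(cls, path: str | Path, wrapped: bool = True) -> "PhaseSeries":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise DataError(f"{path}: need at least two samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["phase_rad"].to_numpy(float), fs=fs, wrapped=wrapped)


@dataclass
class DisplacementSeries:
    """Chest-wall displacement, millimetres."""

    times: np.ndarray
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise DataError("displacement series: times and values must be equal-length 1-D")
        if not np.all(np.isfinite(self.values)):
            raise DataError("displacement series: non-finite values")
        _check_uniform(self.times, self.fs, "displacement series")

    def to_text(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "displacement_mm": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_text(cls, path: str | Path) -> "DisplacementSeries":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["displacement_mm"].to_numpy(float), fs=fs)


@dataclass
class RGBTrace:
    """Per-frame ROI-averaged colour means at the camera frame rate."""

    times: np.ndarray
    r_mean: np.ndarray
    g_mean: np.ndarray
    b_mean: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in (self.times, self.r_mean, self.g_mean, self.b_mean)]
        self.times, self.r_mean, self.g_mean, self.b_mean = arrs
        n = self.times.size
        if any(a.shape != (n,) for a in arrs):
            raise DataError("rgb trace: all channels must match the time axis")
        if n == 0:
            raise DataError("rgb trace: empty")
        _check_uniform(self.times, self.fs, "rgb trace")

    def to_text(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.times, "r_mean": self.r_mean, "g_mean": self.g_mean, "b_mean": self.b_mean}
        ).to_csv(path, index=False)

    @classmethod
    def from_text(cls, path: str | Path) -> "RGBTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise DataError(f"{path}: need at least two samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["r_mean"].to_numpy(float), df["g_mean"].to_numpy(float),
                   df["b_mean"].to_numpy(float), fs=fs)


@dataclass
class GroundTruthSeries:
    """Reference per-second HR and BR readings (BPM), 1 Hz."""

    times: np.ndarray
    hr_bpm: np.ndarray
    br_bpm: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        self.br_bpm = np.asarray(self.br_bpm, dtype=float)
        if not (self.times.shape == self.hr_bpm.shape == self.br_bpm.shape):
            raise DataError("ground truth: unequal lengths")
        if np.any(self.hr_bpm <= 0) or np.any(self.br_bpm <= 0):
            raise DataError("ground truth: rates must be strictly positive")

    def rate(self, band_label: str) -> np.ndarray:
        return self.hr_bpm if band_label == "HR" else self.br_bpm

    def to_text(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "hr_bpm": self.hr_bpm, "br_bpm": self.br_bpm}).to_csv(
            path, index=False
        )

    @classmethod
    def from_text(cls, path: str | Path) -> "GroundTruthSeries":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(float), df["hr_bpm"].to_numpy(float),
                   df["br_bpm"].to_numpy(float))


@dataclass
class VitalWaveform:
    """A band-limited 1-D waveform ready for the STFT stage."""

    values: np.ndarray
    fs: float
    band: BandConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise DataError("waveform must be nonempty 1-D")
        if not np.all(np.isfinite(self.values)):
            raise DataError("waveform contains non-finite values")


@dataclass
class Spectrogram:
    """STFT magnitude matrix, frequency (BPM) x time (s).

    Column ``j`` holds the zero-padded FFT magnitude of the window whose
    right edge sits at ``time_axis[j]`` seconds.
    """

    magnitudes: np.ndarray  # [n_freq, n_time]
    freq_axis_bpm: np.ndarray
    time_axis_s: np.ndarray
    config: SpectrogramConfig
    source: str = "radar"
    band: str = "HR"

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.freq_axis_bpm = np.asarray(self.freq_axis_bpm, dtype=float)
        self.time_axis_s = np.asarray(self.time_axis_s, dtype=float)
        if self.magnitudes.ndim != 2:
            raise DataError("spectrogram must be a 2-D matrix")
        nf, nt = self.magnitudes.shape
        if self.freq_axis_bpm.shape != (nf,) or self.time_axis_s.shape != (nt,):
            raise DataError("spectrogram axes do not match the matrix")
        if np.any(self.magnitudes < 0):
            raise DataError("spectrogram magnitudes must be nonnegative")
        if nf > 1 and np.any(np.diff(self.freq_axis_bpm) <= 0):
            raise DataError("frequency axis must be strictly increasing")

    @property
    def n_freq(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_time(self) -> int:
        return self.magnitudes.shape[1]

    def save(self, path: str | Path) -> None:
        """Write the matrix to ``path`` (.npz) with a JSON axis sidecar."""
        path = Path(path)
        np.savez(path, magnitudes=self.magnitudes, freq_axis_bpm=self.freq_axis_bpm,
                 time_axis_s=self.time_axis_s)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"source": self.source, "band": self.band, "config": self.config.to_dict()}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Spectrogram":
        path = Path(path)
        data = np.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(data["magnitudes"], data["freq_axis_bpm"], data["time_axis_s"],
                   SpectrogramConfig.from_dict(meta["config"]), source=meta["source"],
                   band=meta["band"])


@dataclass
class VitalEstimate:
    """Per-second BPM estimate with provenance labels.

    ``bpm`` may contain NaN where an estimator declined to report (e.g. an
    all-zero spectrum column under the spectral-magnitude baseline).
    """

    times: np.ndarray
    bpm: np.ndarray
    band: str = "HR"
    method: str = "segmentation"
    source: str = "radar"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.times.shape != self.bpm.shape:
            raise DataError("estimate: times and bpm must align")

    def to_text(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "bpm": self.bpm, "band": self.band,
                      "method": self.method, "source": self.source}).to_csv(path, index=False)

    @classmethod
    def from_text(cls, path: str | Path) -> "VitalEstimate":
        df = pd.read_csv(path)
        kw = {}
        for col in ("band", "method", "source"):
            if col in df.columns and len(df):
                kw[col] = str(df[col].iloc[0])
        return cls(df["time_s"].to_numpy(float), df["bpm"].to_numpy(float), **kw)
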