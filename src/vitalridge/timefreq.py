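"""Band-pass filtering and sliding-window STFT spectrogram construction.

Shared by the radar and video branches: a 4th-order Butterworth band-pass
isolates the heart (1-4 Hz) or breathing (0.2-0.6 Hz) oscillation, then a
20-s rectangular window hopping by 1 s produces one zero-padded FFT
magnitude spectrum per second.  Stacking the spectra column-wise and
converting the frequency axis to BPM yields the spectrogram image on which
ridge segmentation operates.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from vitalridge.config import BandConfig, SpectrogramConfig
from vitalridge.series import DataError, Spectrogram, VitalWaveform


def bandpass(
    x: np.ndarray,
    fs: float,
    band: BandConfig,
    zero_phase: bool = False,
) -> VitalWaveform:
    """Butterworth band-pass of the configured order and edges.

    The default is a single causal pass of the designed filter, which keeps
    in-band tones within a few percent of unit gain; ``zero_phase=True``
    applies it forward-backward instead (no group delay, but the magnitude
    response is squared).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DataError("cannot filter an empty sequence")
    if band.high_hz >= fs / 2.0:
        raise DataError(
            f"band edge {band.high_hz} Hz is at or above the Nyquist rate {fs / 2.0} Hz"
        )
    sos = signal.butter(band.order, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x) if zero_phase else signal.sosfilt(sos, x)
    return VitalWaveform(filtered, fs=fs, band=band)


def windowed_spectrum(
    segment: np.ndarray,
    cfg: SpectrogramConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded FFT magnitude of one window, on a BPM axis.

    The segment of N samples is extended with ``pad_factor * N`` zeros
    (4N points in total at the default), the one-sided FFT magnitude is
    taken, and the axis is converted to BPM and restricted to
    [bpm_min, bpm_max].  Bin spacing is 60 / (N * (1 + pad_factor) * dt) BPM.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.size
    if n < 2:
        raise DataError("spectrum needs at least two samples")
    n_fft = n * (1 + cfg.pad_factor)
    mags = np.abs(np.fft.rfft(segment, n=n_fft))
    bpm = np.fft.rfftfreq(n_fft, d=cfg.dt) * 60.0
    keep = (bpm >= cfg.bpm_min) & (bpm <= cfg.bpm_max)
    return bpm[keep], mags[keep]


def n_columns(n_samples: int, cfg: SpectrogramConfig) -> int:
    """Number of sliding-window positions for a record of given length."""
    w_len = int(round(cfg.window_s / cfg.dt))
    hop = int(round(cfg.hop_s / cfg.dt))
    return (n_samples - w_len) // hop


def build_spectrogram(
    w: VitalWaveform,
    cfg: SpectrogramConfig,
    source: str = "radar",
) -> Spectrogram:
    """Stack per-window spectra into the time-frequency spectrogram.

    Windows are stamped at their right edge: column k covers samples
    [(k + 1) * hop, window + (k + 1) * hop) and is labelled with the time of
    its (exclusive) right edge, so the first column of a 1-s-hop, 20-s-window
    spectrogram sits at t = 21 s and a 300-s record yields 280 columns.
    Each column equals ``windowed_spectrum`` of its raw segment.
    """
    if abs(1.0 / w.fs - cfg.dt) > 1e-9 * cfg.dt:
        raise DataError(f"waveform rate {w.fs} Hz does not match config dt {cfg.dt} s")
    w_len = int(round(cfg.window_s / cfg.dt))
    hop = int(round(cfg.hop_s / cfg.dt))
    n = w.values.size
    k = n_columns(n, cfg)
    if k < 1:
        raise DataError("record shorter than one full window plus hop")
    starts = (np.arange(k) + 1) * hop
    segments = np.stack([w.values[s : s + w_len] for s in starts])
    n_fft = w_len * (1 + cfg.pad_factor)
    mags = np.abs(np.fft.rfft(segments, n=n_fft, axis=1))
    bpm = np.fft.rfftfreq(n_fft, d=cfg.dt) * 60.0
    keep = (bpm >= cfg.bpm_min) & (bpm <= cfg.bpm_max)
    time_axis = (starts + w_len) * cfg.dt
    return Spectrogram(mags[:, keep].T, bpm[keep], time_axis, cfg,
                       source=source, band=w.band.label)
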