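"""Radar branch: wrapped slow-time phase -> clean displacement waveform.

Processing order follows the usual FMCW vital-sign chain: unwrap the phase,
take the first difference between consecutive chirps (suppresses phase
randomness and slow drift), gate out spike outliers, and scale to chest
displacement in millimetres via the quarter-wavelength relation.
"""

from __future__ import annotations

import numpy as np

from vitalridge.config import RadarConfig
from vitalridge.series import DataError, DisplacementSeries, PhaseSeries


def unwrap_phase(p: PhaseSeries) -> PhaseSeries:
    """Remove 2*pi discontinuities so consecutive differences are <= pi.

    Idempotent on already-unwrapped input; each output sample differs from
    its input by an integer multiple of 2*pi.
    """
    if p.values.size == 0:
        raise DataError("cannot unwrap an empty phase series")
    return PhaseSeries(p.times, np.unwrap(p.values), fs=p.fs, wrapped=False)


def phase_difference(p: PhaseSeries) -> np.ndarray:
    """First difference between consecutive chirps, length len(p) - 1."""
    if p.values.size < 2:
        raise DataError("phase difference needs at least two samples")
    return np.diff(p.values)


def remove_spikes(x: np.ndarray, k_mad: float = 6.0) -> np.ndarray:
    """Replace outlier samples by linear interpolation over their neighbours.

    A sample is an outlier when its distance from the median exceeds
    ``k_mad`` times the median absolute deviation (MAD).  When MAD is zero
    the majority of samples sit exactly at the median: a constant signal is
    returned unchanged, while any sample departing from that constant level
    is treated as a spike.  Flagged samples at the edges take the value of
    the nearest kept sample.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    bad = dev > k_mad * mad if mad > 0.0 else dev > 0.0
    if bad.all():
        raise DataError("all samples flagged as spikes; signal unusable")
    if not bad.any():
        return x.copy()
    idx = np.arange(x.size)
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def phase_to_displacement(
    dphi: np.ndarray,
    radar: RadarConfig,
    times: np.ndarray | None = None,
) -> DisplacementSeries:
    """Scale phase (rad) to displacement (mm): dR = lambda / (4 pi) * dphi."""
    dphi = np.asarray(dphi, dtype=float)
    lam_mm = radar.wavelength_m * 1e3
    values = lam_mm / (4.0 * np.pi) * dphi
    if times is None:
        times = np.arange(dphi.size) / radar.fs
    return DisplacementSeries(np.asarray(times, dtype=float), values, fs=radar.fs)


def radar_waveform(
    phase: PhaseSeries,
    radar: RadarConfig,
    k_mad: float = 6.0,
    use_phase_difference: bool = True,
) -> DisplacementSeries:
    """Full radar front-end: unwrap, difference, despike, scale to mm.

    With ``use_phase_difference=False`` the unwrapped phase itself (despiked)
    is scaled instead; differencing is the default because it suppresses
    slow phase drift before band-pass filtering.
    """
    unwrapped = unwrap_phase(phase) if phase.wrapped else phase
    if use_phase_difference:
        seq = phase_difference(unwrapped)
        times = unwrapped.times[1:]
    else:
        seq = unwrapped.values
        times = unwrapped.times
    cleaned = remove_spikes(seq, k_mad=k_mad)
    return phase_to_displacement(cleaned, radar, times=times)
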