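"""Video branch: ROI colour traces -> clean pulsatile waveform.

The blood-volume pulse appears as a sub-percent intensity modulation of the
skin, strongest in the green channel.  The chain is: spatially average the
region of interest per frame, select green, remove the slowly varying
baseline with a smoothness-priors detrender, and suppress frame noise with a
short moving average.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from vitalridge.series import DataError, RGBTrace


def spatial_average_roi(
    frames: np.ndarray,
    roi: tuple[int, int, int, int],
    fs: float,
) -> RGBTrace:
    """Average each colour channel over a rectangular ROI, one value/frame.

    Parameters
    ----------
    frames : array, shape (n_frames, height, width, 3)
        RGB frame stack.
    roi : (row0, col0, n_rows, n_cols)
        Rectangle in pixel coordinates; must be nonempty and inside frames.
    fs : frame rate, Hz.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise DataError("frames must have shape (n_frames, height, width, 3)")
    r0, c0, nr, nc = roi
    if nr <= 0 or nc <= 0:
        raise DataError("ROI must be nonempty")
    if r0 < 0 or c0 < 0 or r0 + nr > frames.shape[1] or c0 + nc > frames.shape[2]:
        raise DataError("ROI exceeds frame bounds")
    patch = frames[:, r0 : r0 + nr, c0 : c0 + nc, :]
    means = patch.mean(axis=(1, 2))  # (n_frames, 3)
    times = np.arange(frames.shape[0]) / fs
    return RGBTrace(times, means[:, 0], means[:, 1], means[:, 2], fs=fs)


def select_green(trace: RGBTrace) -> np.ndarray:
    """The green channel, which carries the strongest pulsatile signal."""
    return np.asarray(trace.g_mean, dtype=float).copy()


def detrend(x: np.ndarray, fs: float = 30.0, lambda_d: float = 300.0) -> np.ndarray:
    """Smoothness-priors detrending: subtract a regularized trend estimate.

    The trend z minimizes ||x - z||^2 + lambda_d^2 ||D2 z||^2 with D2 the
    second-difference operator; the output x - z behaves as a high-pass
    filter whose cut-off frequency decreases as ``lambda_d`` grows.  At the
    default lambda_d = 300 and fs = 30 Hz the cut-off sits well below the
    breathing band, so both vital-sign bands pass essentially unattenuated.
    """
    if lambda_d <= 0:
        raise ValueError("lambda_d must be positive")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise DataError("detrending needs at least three samples")
    d2 = sp.diags_array([np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
                        offsets=[0, 1, 2], shape=(n - 2, n), format="csc")
    a = sp.eye_array(n, format="csc") + (lambda_d**2) * (d2.T @ d2)
    trend = spla.spsolve(a, x)
    return x - trend


def moving_average(x: np.ndarray, k: int = 5) -> np.ndarray:
    """Centered moving average with truncated (shorter) windows at the edges.

    ``k`` must be odd so the window is symmetric; length is preserved.
    """
    if k <= 0 or k % 2 == 0:
        raise ValueError("window length k must be a positive odd integer")
    x = np.asarray(x, dtype=float)
    if k > x.size:
        raise DataError("window longer than the signal")
    sums = np.convolve(x, np.ones(k), mode="same")
    counts = np.convolve(np.ones(x.size), np.ones(k), mode="same")
    return sums / counts


def rppg_waveform(
    trace: RGBTrace,
    lambda_d: float = 300.0,
    smooth_k: int = 5,
) -> np.ndarray:
    """Full video front-end: green channel, detrended, moving-averaged."""
    g = select_green(trace)
    return moving_average(detrend(g, fs=trace.fs, lambda_d=lambda_d), k=smooth_k)
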