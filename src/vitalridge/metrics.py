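"""Agreement metrics between estimated and reference BPM series.

Four headline metrics — RMSE, the area under the success-rate-vs-tolerance
curve (AUC-SR, T in [0, 10] BPM, normalized to [0, 1]), coverage at +/-3 BPM
and the Pearson correlation coefficient — plus Bland-Altman bias and 95%
limits of agreement (bias +/- 1.96 SD of the pairwise differences).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from vitalridge.series import DataError, GroundTruthSeries, VitalEstimate

#: Tolerance grid for the success-rate curve, BPM.
SR_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("metric inputs must be equal-length 1-D sequences")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise DataError("no overlapping finite samples to compare")
    return a, b


def rmse(a, b) -> float:
    """Root-mean-square error in BPM; 0 only for an exact match."""
    a, b = _paired(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def success_rate(a, b, tolerance: float) -> float:
    """Fraction of points with |a - b| within ``tolerance`` BPM."""
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    a, b = _paired(a, b)
    return float(np.mean(np.abs(a - b) <= tolerance))


def auc_sr(a, b) -> float:
    """Area under the success-rate curve over T in [0, 10] BPM, in [0, 1].

    The success rate as a function of the tolerance T is a step function
    with jumps at the observed absolute errors, so its integral has the
    exact closed form mean(clip(10 - |err|, 0, 10)); dividing by the full
    area (10) normalizes a perfect estimator to 1.  ``success_rate_curve``
    exposes the sampled curve itself for plotting.
    """
    a, b = _paired(a, b)
    err = np.abs(a - b)
    return float(np.mean(np.clip(10.0 - err, 0.0, 10.0)) / 10.0)


def success_rate_curve(a, b, grid: np.ndarray = SR_GRID) -> tuple[np.ndarray, np.ndarray]:
    """Success rate sampled on a tolerance grid (default 0-10 BPM by 0.1)."""
    a, b = _paired(a, b)
    err = np.abs(a - b)
    return grid, np.array([np.mean(err <= t) for t in grid])


def coverage3(a, b) -> float:
    """Percentage of points within 3 BPM of the reference."""
    return 100.0 * success_rate(a, b, 3.0)


def pcc(a, b) -> float:
    """Pearson correlation coefficient; undefined for constant input."""
    a, b = _paired(a, b)
    if a.size < 2:
        raise DataError("correlation needs at least two samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DataError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(a, b).statistic)


def bland_altman(a, b) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """Bland-Altman agreement: bias and 95% limits of agreement.

    Differences d = a - b; bias is mean(d) and the limits are
    bias +/- 1.96 * SD(d) with the sample (n-1) standard deviation.
    Returns (bias, loa_low, loa_high, per-point means, per-point diffs).
    """
    a, b = _paired(a, b)
    if a.size < 2:
        raise DataError("Bland-Altman needs at least two samples")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, (a + b) / 2.0, d


@dataclass
class EvaluationReport:
    """All agreement statistics for one estimate/reference pair."""

    rmse: float
    auc_sr: float
    coverage3: float
    pcc: float | None
    bias_dbar: float
    loa_low: float
    loa_high: float
    n: int
    n_dropped: int = 0
    tolerance_grid: tuple[float, float, float] = (0.0, 10.0, 0.1)
    labels: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        d = json.loads(Path(path).read_text())
        d["tolerance_grid"] = tuple(d["tolerance_grid"])
        return cls(**d)


def align(estimate: VitalEstimate, truth: GroundTruthSeries) -> tuple[np.ndarray, np.ndarray, int]:
    """Join estimate and reference on integer-second timestamps.

    Unmatched or non-finite seconds are dropped; returns the paired arrays
    and the number of dropped estimate samples.
    """
    est_t = np.rint(estimate.times).astype(int)
    ref_t = np.rint(truth.times).astype(int)
    ref_rate = truth.rate(estimate.band)
    lookup = {int(t): float(v) for t, v in zip(ref_t, ref_rate)}
    a, b = [], []
    dropped = 0
    for t, v in zip(est_t, estimate.bpm):
        if int(t) in lookup and np.isfinite(v):
            a.append(v)
            b.append(lookup[int(t)])
        else:
            dropped += 1
    if not a:
        raise DataError("estimate and reference share no timestamps")
    return np.asarray(a), np.asarray(b), dropped


def evaluate(estimate: VitalEstimate, truth: GroundTruthSeries) -> EvaluationReport:
    """Compute the full report for an estimate against a reference series."""
    a, b, dropped = align(estimate, truth)
    try:
        r = pcc(a, b)
    except DataError:
        r = None  # constant reference or estimate: correlation undefined
    bias, lo, hi, _, _ = bland_altman(a, b)
    return EvaluationReport(
        rmse=rmse(a, b),
        auc_sr=auc_sr(a, b),
        coverage3=coverage3(a, b),
        pcc=r,
        bias_dbar=bias,
        loa_low=lo,
        loa_high=hi,
        n=int(a.size),
        n_dropped=dropped,
        labels={"band": estimate.band, "method": estimate.method, "source": estimate.source},
    )
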