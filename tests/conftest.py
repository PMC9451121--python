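import numpy as np
import pytest

from vitalridge.config import BandConfig, RadarConfig, ScenarioConfig, SpectrogramConfig, Trajectory
from vitalridge.series import Spectrogram


@pytest.fixture
def radar_cfg() -> RadarConfig:
    return RadarConfig()


@pytest.fixture
def clean_72_15() -> ScenarioConfig:
    """Noise-free scenario: constant HR 72 BPM, BR 15 BPM, 60 s."""
    return ScenarioConfig(
        duration_s=60.0,
        hr_trajectory=Trajectory.constant(72.0),
        br_trajectory=Trajectory.constant(15.0),
        seed=0,
    )


def tone_spectrogram(bpm: float, n_cols: int = 30, fs: float = 20.0,
                     band: BandConfig | None = None) -> Spectrogram:
    """Spectrogram of a clean sinusoid at the given BPM, built by the package."""
    from vitalridge.config import hr_band
    from vitalridge.timefreq import build_spectrogram
    from vitalridge.series import VitalWaveform

    band = band or hr_band()
    cfg = SpectrogramConfig.for_band(band, fs)
    duration = cfg.window_s + n_cols * cfg.hop_s
    t = np.arange(int(duration * fs)) / fs
    wave = VitalWaveform(np.sin(2 * np.pi * (bpm / 60.0) * t), fs=fs, band=band)
    return build_spectrogram(wave, cfg)


def synthetic_spectrogram(mags: np.ndarray, bpm_axis: np.ndarray | None = None) -> Spectrogram:
    """Wrap an arbitrary magnitude matrix as a Spectrogram for estimator tests."""
    mags = np.asarray(mags, dtype=float)
    nf, nt = mags.shape
    if bpm_axis is None:
        bpm_axis = 60.0 + 0.75 * np.arange(nf)
    cfg = SpectrogramConfig(bpm_min=float(bpm_axis[0]), bpm_max=float(bpm_axis[-1]))
    return Spectrogram(mags, bpm_axis, 21.0 + np.arange(nt), cfg)
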