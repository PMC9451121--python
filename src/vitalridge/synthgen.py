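"""Synthetic radar-phase and rPPG signal generation with known ground truth.

The generator emulates the physical measurement chain: chest displacement is
the sum of a breathing component (4-12 mm) and a much smaller heartbeat
component (0.1-0.5 mm), each a sinusoid whose instantaneous frequency
follows a piecewise-linear BPM trajectory; the radar observes this
displacement as a (wrapped) phase via the quarter-wavelength relation
``displacement = wavelength / (4 pi) * phase``.  The camera branch produces
ROI-averaged colour traces in which the green channel carries the strongest
pulsatile modulation.  Slow baseline drift, white Gaussian sensor noise and
transient raised-cosine motion artefacts are all optional and seeded.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from vitalridge.config import (
    ConfigError,
    DriftConfig,
    MotionEvent,
    RadarConfig,
    ScenarioConfig,
    Trajectory,
)
from vitalridge.series import DisplacementSeries, GroundTruthSeries, PhaseSeries, RGBTrace

# Pulsatile fraction of the red/blue channels relative to green: haemoglobin
# absorbs green light most strongly, so the cardiac modulation is weaker in
# the other channels.
RED_PULSE_FRACTION = 0.5
BLUE_PULSE_FRACTION = 0.3


def integrated_phase(traj: Trajectory, times: np.ndarray) -> np.ndarray:
    """Oscillator phase 2*pi * integral of the instantaneous frequency.

    The trajectory is piecewise linear in BPM, so the integral is piecewise
    quadratic and is evaluated in closed form (no quadrature error); the
    resulting chirp is phase-continuous across breakpoints.
    """
    times = np.asarray(times, dtype=float)
    t_end = float(times.max(initial=0.0))
    knots = np.unique(np.concatenate([[0.0], np.asarray(traj.times_s), [t_end + 1.0]]))
    knots = knots[knots >= 0.0]
    f = traj.hz(knots)
    # cumulative integral of the piecewise-linear frequency at each knot
    seg = 0.5 * (f[:-1] + f[1:]) * np.diff(knots)
    F_knot = np.concatenate([[0.0], np.cumsum(seg)])
    idx = np.clip(np.searchsorted(knots, times, side="right") - 1, 0, knots.size - 2)
    t0 = knots[idx]
    dt_seg = knots[idx + 1] - t0
    slope = (f[idx + 1] - f[idx]) / dt_seg
    u = times - t0
    F = F_knot[idx] + f[idx] * u + 0.5 * slope * u * u
    return 2.0 * np.pi * F


def _ground_truth(cfg: ScenarioConfig) -> GroundTruthSeries:
    times = np.arange(0.0, np.floor(cfg.duration_s) + 1.0)
    return GroundTruthSeries(times, cfg.hr_trajectory(times), cfg.br_trajectory(times))


def displacement_components(cfg: ScenarioConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free (breath, heart) displacement components and their times.

    Exposed so the heart and breathing chirps can be inspected in isolation,
    e.g. for instantaneous-frequency checks by zero-crossing counting.
    """
    n = int(round(cfg.duration_s * cfg.fs_radar))
    t = np.arange(n) / cfg.fs_radar
    breath = cfg.breath_amplitude_mm * np.sin(integrated_phase(cfg.br_trajectory, t))
    heart = cfg.heart_amplitude_mm * np.sin(integrated_phase(cfg.hr_trajectory, t))
    return breath, heart, t


def simulate_displacement(cfg: ScenarioConfig) -> tuple[DisplacementSeries, GroundTruthSeries]:
    """Simulate chest displacement (mm) at the radar slow-time rate.

    The output is breath + heart sinusoids with time-varying frequency,
    plus drift, motion transients and white Gaussian noise as configured.
    Identical configurations (including seed) give identical samples.
    """
    breath, heart, t = displacement_components(cfg)
    d = breath + heart + cfg.drift.profile(t)
    for ev in cfg.motion_events:
        d = d + ev.profile(t)
    if cfg.noise_sd_mm > 0:
        rng = np.random.default_rng([cfg.seed, 0])
        d = d + rng.normal(0.0, cfg.noise_sd_mm, t.size)
    return DisplacementSeries(t, d, fs=cfg.fs_radar), _ground_truth(cfg)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Fold phase values into (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = np.remainder(phi + np.pi, 2.0 * np.pi) - np.pi  # [-pi, pi)
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


def displacement_to_phase(
    d: DisplacementSeries,
    radar: RadarConfig,
    wrap: bool = True,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PhaseSeries:
    """Radar phase observed for a displacement series: phi = 4 pi / lambda * d.

    ``noise_sd`` is phase noise in radians added before wrapping; ``seed``
    makes it reproducible.
    """
    lam_mm = radar.wavelength_m * 1e3
    if lam_mm <= 0:
        raise ConfigError("radar wavelength must be positive")
    phi = (4.0 * np.pi / lam_mm) * d.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        phi = phi + rng.normal(0.0, noise_sd, phi.size)
    if wrap:
        phi = wrap_phase(phi)
    return PhaseSeries(d.times, phi, fs=d.fs, wrapped=wrap)


def simulate_rppg(cfg: ScenarioConfig) -> tuple[RGBTrace, GroundTruthSeries]:
    """Simulate ROI-averaged RGB traces at the camera frame rate.

    The green channel carries the full cardiac pulse amplitude and a weaker
    respiratory modulation; red and blue carry reduced pulsatile fractions.
    Illumination drift and motion transients hit all channels equally, and
    each channel has independent sensor noise.
    """
    n = int(round(cfg.duration_s * cfg.fs_video))
    t = np.arange(n) / cfg.fs_video
    pulse = np.sin(integrated_phase(cfg.hr_trajectory, t))
    resp = np.sin(integrated_phase(cfg.br_trajectory, t))
    common = cfg.rppg_drift.profile(t)
    for ev in cfg.rppg_motion_events:
        common = common + ev.profile(t)
    a, b = cfg.rppg_pulse_amplitude, cfg.rppg_resp_amplitude
    g = cfg.rppg_dc + a * pulse + b * resp + common
    r = cfg.rppg_dc + RED_PULSE_FRACTION * (a * pulse + b * resp) + common
    bl = cfg.rppg_dc + BLUE_PULSE_FRACTION * (a * pulse + b * resp) + common
    if cfg.rppg_noise_sd > 0:
        rng = np.random.default_rng([cfg.seed, 1])
        r = r + rng.normal(0.0, cfg.rppg_noise_sd, n)
        g = g + rng.normal(0.0, cfg.rppg_noise_sd, n)
        bl = bl + rng.normal(0.0, cfg.rppg_noise_sd, n)
    return RGBTrace(t, r, g, bl, fs=cfg.fs_video), _ground_truth(cfg)


def motion_events_for_window_fraction(
    duration_s: float,
    target_fraction: float,
    amplitude: float,
    seed: int,
    window_s: float = 20.0,
    event_duration_s: float = 1.0,
) -> tuple[MotionEvent, ...]:
    """Place random motion events until ~``target_fraction`` of the sliding
    windows overlap at least one event.

    Windows are the right-edge-stamped spans [t - window_s, t) for integer t
    from window_s + 1 up to the duration, matching the STFT column layout.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(window_s + 1.0, np.floor(duration_s) + 1.0)
    if edges.size == 0:
        raise ConfigError("duration too short for any sliding window")
    affected = np.zeros(edges.size, dtype=bool)
    events: list[MotionEvent] = []
    # cap iterations in case one event already exceeds the target
    for _ in range(100):
        if affected.mean() >= target_fraction:
            break
        start = float(rng.uniform(0.0, duration_s - event_duration_s))
        events.append(MotionEvent(start, event_duration_s, amplitude))
        affected |= (edges - window_s < start + event_duration_s) & (edges > start)
    return tuple(events)


def noise_sd_for_inband_snr(
    amplitude: float,
    snr_db: float,
    band_low_hz: float,
    band_high_hz: float,
    fs: float,
) -> float:
    """White-noise SD giving the requested in-band SNR for a sinusoid.

    The sinusoid of the given amplitude has power A^2/2; white noise of
    variance sd^2 spreads uniformly over [0, fs/2], of which the fraction
    inside the analysis band competes with the tone.
    """
    band_fraction = (band_high_hz - band_low_hz) / (fs / 2.0)
    return float(amplitude / np.sqrt(2.0) / (np.sqrt(10.0 ** (snr_db / 10.0) * band_fraction)))


def reference_scenario(seed: int, duration_s: float = 300.0, snr_db: float = 10.0) -> ScenarioConfig:
    """The resting reference condition: constant HR 72 / BR 15 BPM.

    Mid-range displacement amplitudes and white noise set for the requested
    in-band SNR (default ~10 dB) on the cardiac component of both branches.
    """
    heart_mm = 0.3
    pulse = 1.0
    return ScenarioConfig(
        duration_s=duration_s,
        hr_trajectory=Trajectory.constant(72.0),
        br_trajectory=Trajectory.constant(15.0),
        heart_amplitude_mm=heart_mm,
        noise_sd_mm=noise_sd_for_inband_snr(heart_mm, snr_db, 1.0, 4.0, 20.0),
        rppg_pulse_amplitude=pulse,
        rppg_noise_sd=noise_sd_for_inband_snr(pulse, snr_db, 1.0, 4.0, 30.0),
        seed=seed,
    )


def recovery_scenario(seed: int, duration_s: float = 300.0) -> ScenarioConfig:
    """Post-exercise recovery: HR ramping 120 -> 80 BPM over the record."""
    base = reference_scenario(seed, duration_s=duration_s)
    return dataclasses.replace(
        base,
        hr_trajectory=Trajectory.ramp(120.0, 80.0, duration_s),
        br_trajectory=Trajectory.constant(18.0),
    )


def motion_corrupted_scenario(
    seed: int,
    duration_s: float = 300.0,
    window_fraction: float = 0.15,
) -> ScenarioConfig:
    """The motion-robustness study condition.

    A weak cardiac return (0.1 mm, the low end of the heartbeat displacement
    range) with ~10 dB in-band SNR, disrupted by 2-s, 20-mm raised-cosine
    body-motion transients placed so that ~15% of the sliding windows are
    affected.  The rapid large excursions defeat phase unwrapping and leave
    broadband spike noise in the affected windows, emulating the signal
    losses that unconscious body movements cause.
    """
    heart_mm = 0.1
    events = motion_events_for_window_fraction(
        duration_s, window_fraction, amplitude=20.0, seed=seed, event_duration_s=2.0
    )
    return ScenarioConfig(
        duration_s=duration_s,
        hr_trajectory=Trajectory.constant(72.0),
        br_trajectory=Trajectory.constant(15.0),
        heart_amplitude_mm=heart_mm,
        noise_sd_mm=noise_sd_for_inband_snr(heart_mm, 10.0, 1.0, 4.0, 20.0),
        motion_events=events,
        seed=seed,
    )


def simulate_to_dir(
    cfg: ScenarioConfig,
    out_dir: str | Path,
    radar: RadarConfig | None = None,
    phase_noise_sd: float = 0.0,
) -> dict[str, Path]:
    """Run both branches of the simulator and write all outputs as text.

    Produces the wrapped radar phase series, the RGB trace, the ground-truth
    BPM series and the resolved scenario JSON (for provenance); returns the
    paths written.
    """
    radar = radar or RadarConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    disp, truth = simulate_displacement(cfg)
    phase = displacement_to_phase(disp, radar, wrap=True, noise_sd=phase_noise_sd,
                                  seed=cfg.seed + 7 if phase_noise_sd > 0 else None)
    trace, _ = simulate_rppg(cfg)
    paths = {
        "radar_phase": out / "radar_phase.csv",
        "rppg_trace": out / "rppg_trace.csv",
        "ground_truth": out / "ground_truth.csv",
        "scenario": out / "scenario.json",
    }
    phase.to_text(paths["radar_phase"])
    trace.to_text(paths["rppg_trace"])
    truth.to_text(paths["ground_truth"])
    scenario = {"scenario": cfg.to_dict(), "radar": radar.to_dict(),
                "phase_noise_sd": phase_noise_sd}
    paths["scenario"].write_text(json.dumps(scenario, indent=2))
    return paths
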