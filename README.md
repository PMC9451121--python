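# vitalridge

Contactless heart-rate (HR) and breathing-rate (BR) estimation from
FMCW-radar phase signals and camera rPPG traces, using graph-based
spectrogram ridge segmentation.

## The problem

Cardiac and respiratory activity move the chest wall by fractions of a
millimetre (heartbeat, ~0.1–0.5 mm) up to several millimetres (breathing,
~4–12 mm). Two remote sensors can pick this up:

- **FMCW radar** — chest displacement modulates the slow-time phase of the
  reflected chirps: `ΔR = λ/(4π)·Δφ`. At 79 GHz, a full ±π phase swing is
  under a millimetre, so the phase wraps and must be unwrapped; at a 50-ms
  chirp period the slow-time sampling rate is 20 Hz.
- **Camera rPPG** — the blood volume pulse slightly modulates skin colour;
  spatially averaging a face region of interest and taking the green channel
  yields a weak periodic trace on a large, drifting baseline.

Both signals are narrow-band oscillations buried in noise, drift and motion
artefacts. A per-window FFT argmax (the conventional estimator) fails
whenever a single window is corrupted. This package instead treats the
short-time Fourier spectrogram as an image, builds a weighted graph over its
pixels, and extracts the bright ridge as a minimum-weight source-to-sink path
with Dijkstra's algorithm. The path must advance one column (one second) at a
time with a bounded row step, so the estimate is continuous in time —
corrupted windows are bridged rather than producing outliers.

The package contains the full chain for both modalities, the
spectral-magnitude baseline, the standard agreement metrics (RMSE, AUC of the
success-rate curve, coverage at ±3 BPM, Pearson correlation, Bland–Altman
limits), a command-line interface, and a synthetic-signal generator with
exact ground truth for end-to-end validation. See
[docs/methods.md](docs/methods.md) for the mathematical details.

## Worked example (Python API)

```python
from vitalridge import (RadarConfig, displacement_to_phase, estimate_vitals,
                        evaluate, reference_scenario, simulate_displacement)

cfg = reference_scenario(seed=5)          # constant 72 BPM heart, 15 BPM breathing
disp, truth = simulate_displacement(cfg)  # chest displacement + ground truth
phase = displacement_to_phase(disp, RadarConfig())  # wrapped 79-GHz radar phase

est, spec = estimate_vitals(phase, band="HR")
print("first five HR estimates (BPM):", est.bpm[:5])
print("spectrogram:", spec.magnitudes.shape, "(freq bins x time columns)")
report = evaluate(est, truth)
print(f"RMSE {report.rmse:.3f} BPM, coverage(3 BPM) {report.coverage3:.1f}%")
```

Output:

```
first five HR estimates (BPM): [72. 72. 72. 72. 72.]
spectrogram: (241, 279) (freq bins x time columns)
RMSE 0.000 BPM, coverage(3 BPM) 100.0%
```

`estimate_vitals` accepts a `PhaseSeries` (radar) or an `RGBTrace` (video),
runs the matching front end, band-pass filters to the HR band (1–4 Hz) or BR
band (0.2–0.6 Hz), builds the spectrogram (20-s window, 1-s hop, 4× zero
padding → 0.75 BPM bins), and returns one BPM estimate per second. Pass
`method="spectral-magnitude"` for the per-window argmax baseline.

## Worked example (CLI)

```sh
$ python - <<'EOF'
from vitalridge import reference_scenario, simulate_to_dir
simulate_to_dir(reference_scenario(seed=5), "demo")
EOF
$ vitalridge estimate --input demo/radar_phase.csv --source radar --band HR --out demo/hr_est.csv
$ vitalridge evaluate --estimate demo/hr_est.csv --truth demo/ground_truth.csv --out demo/report.json
{
  "rmse": 1.0231815394945443e-12,
  "auc_sr": 0.9999999999998976,
  "coverage3": 100.0,
  "pcc": null,
  "bias_dbar": -1.0231815394945443e-12,
  ...
  "n": 279,
  "labels": {"band": "HR", "method": "segmentation", "source": "radar"}
}
```

(`pcc` is `null` here because the reference rate is constant, so correlation
is undefined.) Other subcommands: `vitalridge simulate` (scenario JSON →
synthetic CSVs), `extract-radar` / `extract-video` (raw series → filtered
waveform). Exit codes: 0 success, 2 configuration error, 3 data error.

## Repository layout

```
src/vitalridge/
  config.py          frozen config dataclasses + validation
  series.py          typed series containers with CSV round-trip
  synthgen.py        synthetic scenario generator (exact ground truth)
  radar_frontend.py  unwrap → phase difference → despike → mm
  video_frontend.py  ROI average → green → detrend → moving average
  timefreq.py        Butterworth band-pass, STFT spectrogram
  ridge_seg.py       graph construction, Dijkstra ridge path, baseline
  metrics.py         RMSE, AUC-SR, coverage, PCC, Bland–Altman
  cli.py             click command-line interface
tests/               unit + property + end-to-end acceptance tests
scripts/acceptance.py  headline-numbers reproduction script
docs/methods.md      model, algorithms, parameters, design decisions
```
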