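# mirrorvitals

Contactless vital-sign estimation from facial video, packaged as a streaming
library and CLI. The pipeline:

1. **Spatial averaging** — per-frame face-ROI means of the R/G/B channels form
   a 3×N temporal trace.
2. **Chrominance pulse extraction** — the trace is projected onto two
   chrominance axes (`Xs = 3R − 2G`, `Ys = 1.5R + G − 1.5B`), bandpass
   filtered to the cardiac band (default 0.6–4.0 Hz, windowed-sinc FIR), and
   combined into the pulse `S = Xf − αYf` with `α = σ(Xf)/σ(Yf)`.
3. **Heart rate** — dominant in-band spectral frequency of the pulse
   (zero-padded, Hann-tapered DFT with quadratic peak interpolation),
   `HR = 60·f_h`.
4. **SpO2** — ratio-of-ratios of raw red/blue AC/DC components,
   `SpO2 = 125 − 26·(AC_R/DC_R)/(AC_B/DC_B)`, clamped to [0, 100].
5. **Streaming gating** — 2-s rolling windows at a 1-s stride after a 26-s
   stabilization phase; a window counts as valid only when its SNR exceeds
   0.7 and face confidence exceeds 70%. A wellness-chatbot trigger fires once
   ≥ 8 s of valid signal, good face confidence, and at least one affect label
   with > 50% confidence are available.
6. **Prompt assembly & agreement evaluation** — bilingual (en/ko) prompt
   construction from the vitals/affect snapshot, and MAE / Pearson /
   Bland–Altman comparison against a reference HR series.

A synthetic scene generator (`mirrorvitals.synthetic_scene`) produces traces
and frame sequences with analytically known heart rate and encoded SpO2, so
the entire chain is testable without a camera.

## Modules

| Module | Purpose |
| --- | --- |
| `synthetic_scene` | Seeded synthetic ROI traces/frames with ground truth |
| `signal_core` | ROI averaging, chrominance transform, FIR bandpass, pulse |
| `vitals` | HR, SpO2, and SNR estimation per window |
| `streaming_session` | Push-driven session, gating, chatbot trigger, batch twin |
| `affect_geometry` | Cosine-rule alignment angle, prototype classification, majority vote |
| `prompt_builder` | Bilingual prompt templates + pluggable chat transport |
| `agreement_eval` | MAE, Pearson r, Bland–Altman bias and 95% LoA |
| `io_cli` | CSV/PNG/JSON formats, validated config, CLI |

## CLI

```bash
# synthetic trace with known ground truth (CSV: time_s,R,G,B)
mirrorvitals simulate --hr-bpm 78 --spo2-target 98 --duration 60 --seed 7 --out trace.csv

# batch per-window vitals as JSON lines
mirrorvitals vitals --in trace.csv

# streaming replay with session report (per-window estimates + trigger log)
mirrorvitals stream --in trace.csv --report report.json

# agreement between two HR series (CSV: time_s,bpm)
mirrorvitals evaluate --est est.csv --ref ref.csv --max-gap 0.5 --out agreement.json

# bilingual chatbot prompt from a snapshot
mirrorvitals prompt --age 25 --emotion happy --bpm 78 --spo2 98 --lang en
```

Configuration is a JSON file (unknown keys rejected) passed via `--config`;
see `mirrorvitals.io_cli.AppConfig` for all keys and defaults
(`band_low_hz`, `band_high_hz`, `window_s`, `stride_s`, `stabilization_s`,
`min_valid_s`, `snr_gate`, `face_conf_gate`, `spo2_A`, `spo2_B`, ...).

## Notes

- Frames are handled as `H×W×3` float arrays; PNG frame directories carry a
  `rois.json` sidecar with per-frame face boxes and confidences.
- The streaming and batch paths share the per-window estimator and are
  bit-identical on identical input; causal filtering uses group-delay
  compensation (order/2 samples), so estimates lag the stream tip by half
  the filter length.
- The SNR score is a fundamental+harmonic band-power ratio with a
  resolution-adaptive mask (half-width `max(0.1, 1/T)` Hz for a T-second
  window).
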