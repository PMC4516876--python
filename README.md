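# sleepsift

Joint detection of **sleep spindles** and **K-complexes** in single-channel
sleep EEG.

Each 30-s segment is band-pass filtered (0.2–40 Hz) and split into an
*oscillatory* and a *transient* component by morphological component
analysis over two tunable Q-factor wavelet transform (TQWT) dictionaries —
a high-Q transform (Q=5.5, r=3) tuned to spindle-like sustained
oscillations and a low-Q transform (Q=1, r=3) tuned to transient waves.
Spindles are then detected as thresholded 8-neighbour local maxima of a
complex frequency-B-spline CWT map (11–16 Hz) of the oscillatory
component; K-complexes as thresholded local minima of the FIR-filtered
(0.5–5 Hz) transient component, with a 2-s minimum separation. Detection
thresholds are trained on annotated segments by sweeping the threshold and
maximising sensitivity − FDR.

## Layout

| module | contents |
| --- | --- |
| `sleepsift.tqwt` | TQWT filter bank: (Q, r) → (α, β) scalings, J_max, equivalent frequency responses, perfect-reconstruction forward/inverse transform (Parseval frame) |
| `sleepsift.mca` | dual-Q basis-pursuit denoising via SALSA: objective, per-sub-band λ weights, 500-iteration solver |
| `sleepsift.spindles` | fbsp wavelet, CWT time-frequency map, strict 8-neighbour maxima, spindle event construction, wavelet cross-correlation ranking |
| `sleepsift.kcomplexes` | zero-phase FIR band-pass, strict local minima, trough thresholding with 2-s separation |
| `sleepsift.metrics` | event matching (greedy any-overlap), sensitivity & FDR, threshold sweeps with argmax(Sen−FDR), percent agreement & Cohen's κ, RMS baseline detector |
| `sleepsift.synthetic` | 1/f background + injected spindle/K-complex templates with exact ground truth |
| `sleepsift.io` / `sleepsift.pipeline` / `sleepsift.cli` | EDF and annotation-TSV I/O, preprocessing, per-segment pipeline, training, CLI |

## CLI

```bash
# synthetic recording + ground truth
sleepsift simulate --seed 1 --n-segments 10 --out rec.edf --annotations truth.tsv

# train detection thresholds against annotations
sleepsift train rec.edf truth.tsv --out thresholds.json

# detect with trained thresholds (add --no-mca to skip the decomposition)
sleepsift detect rec.edf --thresholds thresholds.json --out events.tsv --report report.json

# evaluate detections against a reference annotation
sleepsift evaluate events.tsv truth.tsv --n-segments 10

# standard RMS spindle detector for comparison
sleepsift baseline rec.edf --threshold 8 --out baseline.tsv

# write oscillatory / transient components
sleepsift decompose rec.edf --out-prefix components
```

`--config config.yaml` accepts any `PipelineConfig` field
(`n_iterations`, `spindle_threshold`, `kc_threshold`, `use_mca`,
`theta_osc`, …).

Annotation files are tab-separated:
`segment_number  event_type  start_s  end_s  start_sample  end_sample`
with 1-based segment numbers.

## Notes

- Thresholds are in μV² (time-frequency map) and μV (filtered transient);
  both depend on sampling rate and CWT normalisation, so they are always
  trained, never transplanted between datasets.
- Everything is deterministic given seeds; the solver contains no
  randomness.
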