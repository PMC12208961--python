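# beatmatch

ECG-free heartbeat detection in cardiomechanical signals by fully
automatic template matching.

Wearable inertial and force sensors on the chest record the mechanical
activity of the heart: seismocardiography (SCG, linear acceleration),
gyrocardiography (GCG, angular velocity), and forcecardiography (FCG,
chest-wall force). Each heartbeat appears in these signals as a short
oscillatory wave packet concentrated in the 7–30 Hz band. `beatmatch`
locates those packets without any simultaneous ECG: it automatically
extracts a subject-specific heartbeat template from a reliable stretch of
the recording, then slides that template along the whole signal with
normalized cross-correlation (NCC) and takes sufficiently prominent,
well-separated correlation peaks as heartbeats.

## Method in one paragraph

The signal is band-passed to 7–30 Hz with a zero-lag (forward–backward)
4th-order Butterworth filter. A smoothed envelope — the normalized 4th
power of the filtered signal, low-passed at 3 Hz — highlights one bump
per heartbeat; envelope peaks with topographic prominence ≥ 0.25 are
candidate beats. The recording is scanned in consecutive 10 s windows and
the first *reliable* window is kept: at least 5 candidate beats whose
inter-beat intervals (IBIs) have a mean absolute deviation (MAD) below
335 ms. That bound is the mean + 3 SD of published IBI-variability
statistics for atrial fibrillation, the most variable rhythm (117.9 +
3·72.2 = 334.5 ms), so even highly arrhythmic but genuine beat sequences
pass while windows corrupted by spurious envelope peaks fail. Within the
reliable window each candidate beat is cut from 200 ms before to 500 ms
after its envelope peak, all candidates are correlated pairwise, and the
one with the highest mean-to-SD ratio of its correlations with the others
becomes the template. NCC of the template against the whole record is a
sliding Pearson correlation bounded in [−1, 1]; its peaks with prominence
≥ 0.5 and spacing ≥ 0.5 s are the detected heartbeats. Performance
against a reference (ECG R peaks or simulation ground truth) is scored
per cardiac cycle (TP/FP/FN → sensitivity and PPV), and detected-vs-
reference IBIs are compared by ordinary least squares regression with
confidence intervals and Bland–Altman limits of agreement, falling back
to median/percentile limits when the differences are non-normal.

## Running the tests

```bash
python -m pytest -q
```

The suite includes `tests/test_acceptance.py`, one test per release
criterion. Two cells of the end-to-end recovery grid (heart rate 50 bpm)
fail by a documented limitation of the fixed-threshold NCC stage at long
inter-beat gaps, not by an implementation error — see
`docs/methods.md` ("Low heart rates") for the analysis. All other tests
pass.

## Worked example

Simulate a 60 s record with known ground truth, detect heartbeats on its
SCG channel, and evaluate against the ECG channel:

```console
$ beatmatch simulate --duration 60 --seed 7 --out sim
simulated 70 beats -> sim
$ beatmatch detect --input sim/waveform.csv --channel scg --out beats.csv
detected 70 beats -> beats.csv
$ beatmatch evaluate --beats beats.csv --reference sim/waveform.csv \
      --reference-kind ecg --out report.csv
report -> report.csv
$ head -5 beats.csv
sample,time_s,label
502,0.502000,
1359,1.359000,
2244,2.244000,
3105,3.105000,
$ cat report.csv
n_detected,n_reference,tp,fp,fn,sensitivity_pct,ppv_pct,n_ibi_pairs,slope,intercept_ms,r_squared,ba_method,bias_ms,loa_low_ms,loa_high_ms
70,70,70,0,0,100.0,100.0,69,0.999,0.83,0.9995,percentile,0.0,-1.0,1.0
```

All 70 simulated beats are recovered (sensitivity = PPV = 100%) and the
detected IBIs agree with the ECG-derived IBIs to ±1 ms.

The same pipeline is available as a library:

```python
from beatmatch import SynthParams, generate_record, detect_heartbeats

synth = generate_record(SynthParams(duration_s=60.0, seed=7))
beats, template, ncc = detect_heartbeats(synth.record, "scg")
print(len(beats), "beats; template from window", template.source_window_index)
```

Exit codes of the CLI: `0` success, `2` no reliable template window in
the recording, `3` malformed input file or inconsistent sampling rate,
`1` any other error.

## Layout

- `src/beatmatch/preprocess.py` — zero-lag filters, respiration removal,
  channel-role dispatch
- `src/beatmatch/template.py` — envelope, reliability gate, template
  selection
- `src/beatmatch/matching.py` — NCC, peak pruning, the end-to-end detector
- `src/beatmatch/evaluation.py` — R-peak reference, cycle scoring,
  regression, Bland–Altman
- `src/beatmatch/synthetic.py` — seedable generator of paired
  cardiomechanical + ECG records with ground truth
- `src/beatmatch/cli.py` — `beatmatch` command-line interface
- `docs/methods.md` — full description of the model, parameters, and
  numerical choices
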