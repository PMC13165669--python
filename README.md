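# radarecg

Reconstructing the ECG waveform from contactless millimeter-wave radar
measurements of chest micro-motion.

A continuous-wave Doppler radar pointed at a person's chest sees the tiny
surface displacement produced by each heartbeat (plus the much larger
respiratory motion) as a phase modulation of its echo.  Because cardiac
electrical activity and mechanical contraction are tightly coupled
(excitation–contraction coupling), a learned nonlinear mapping can recover
the full ECG morphology — P wave, QRS complex, T wave — from that mechanical
trace.  This package implements the complete stack, exercisable end-to-end on
synthetic data:

1. **Simulator** (`radarecg.synthdata`) — paired 10-s, 100 Hz segments:
   a five-Gaussian phase-domain ECG with AR(1)-correlated RR intervals,
   chest displacement (scenario-dependent respiration + a damped ~20 Hz
   cardiac ring at the R-peak times), and quadrature radar channels
   `I = A cos(4πx/λ₀ + θ)`, `Q = A sin(4πx/λ₀ + θ)` for a 94 GHz / 3 mm
   system, with phase and channel noise.  Seven posture/breathing scenarios
   (sitting, lateral decubitus, supine; eupnea, apnea, hypoxic,
   rapid-shallow) with realistic dataset proportions.
2. **Demodulation** (`radarecg.demod`) — four-quadrant arctangent phase
   extraction, unwrapping, and `x = (λ₀/4π)(w − θ)` displacement recovery.
3. **Preprocessing** (`radarecg.preprocess`) — shift-invariant db4 wavelet
   decomposition with spectral-energy level selection to suppress
   respiration; innovation-adaptive Kalman smoothing; fifth-order polynomial
   baseline removal and MAD-calibrated universal soft-threshold wavelet
   denoising for the reference ECG.
4. **Network** (`radarecg.model`) — an encoder–decoder: three parallel
   multi-scale conv branches (~0.1/0.25/0.5 s receptive fields) alongside a
   lightweight gated transformer, convolutionally fused; decoded by causal
   dilated temporal-convolution blocks with *spectral attention* — an
   FFT-domain amplitude mask that holds the 0.5–40 Hz ECG band at unit gain
   and floors everything else at 0.1, modulated by learned per-bin weights,
   phase preserved.  Ablation toggles disable either encoder branch, chain
   them sequentially, or drop the spectral attention.  The network and its
   optimizer run on a small numpy reverse-mode autodiff engine bundled with
   the package (`radarecg.autodiff`).
5. **Training & evaluation** (`radarecg.training`, `radarecg.evaluation`) —
   subject-disjoint k-fold cross-validation (a subject's segments never
   straddle a split), Adam with cosine annealing and early stopping, RMSE
   loss; metrics are Pearson correlation (PCC), RMSE, MAE and per-wave
   Q/R/S/T localization errors (median / 90th percentile, CDF tables,
   per-scenario breakdowns) from a built-in Pan-Tompkins-style detector.

## Worked example

```python
import numpy as np
import radarecg as rg
from radarecg import autodiff as ad

# 8 subjects, 200 paired segments across the seven scenarios
ds = rg.generate_dataset(n_subjects=8, n_segments=200, seed=11)
for seg in ds.segments:
    x = rg.demodulate_displacement(seg.i_chan, seg.q_chan,
                                   ds.radar_config.wavelength)
    seg.x_card = rg.preprocess_radar(x)
    seg.ecg_clean = rg.preprocess_ecg(seg.ecg)

folds = rg.split_subject_kfold(ds.subject_ids, 4, seed=11)
tcfg = rg.TrainConfig(epochs=30, batch_size=4, k_folds=4, seed=11)
with ad.use_dtype(np.float32):          # fast desk-scale training
    model, hist = rg.train_fold(ds, folds[0], tcfg,
                                rg.ModelConfig.desk_scale())
    test = ds.subset(folds[0][1]).segments
    y_hat = rg.predict(model, test)
report = rg.evaluate_segments(y_hat, test)
print(f"held-out PCC {report.mean_pcc:.3f}  RMSE {report.mean_rmse:.3f}")
print(report.wave_stats)
```

Output of this exact run:

```
held-out PCC 0.895  RMSE 0.439
  wave  median   p90    n  misses
0    q    0.01  0.02  520      33
1    r    0.00  0.01  520      33
2    s    0.01  0.02  520      33
3    t    0.03  0.07  516      37
```

PCC ≈ 0.9 means the reconstructed waveform tracks the held-out subjects'
normalized ECG morphology closely; the R-wave median localization error of
0.00 s (at the 10 ms sample grid) shows beat timing is recovered essentially
exactly, with Q/S flanks within one or two samples.  These numbers are on
synthetic data at desk scale and are package-defined verification bars, not
clinical results.

The same pipeline is scriptable from the shell:

```sh
radarecg run --config smoke.yaml --seed 3 --out runs/
radarecg simulate --n-subjects 8 --n-segments 200 --seed 11 --out data/
```

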