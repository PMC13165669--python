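# Methods

This note documents the models, algorithms and design choices in `radarecg`:
what the synthetic data emulates, how each processing stage works, which
parameters matter, and what the package's tests do and do not demonstrate.

## Radar signal model and demodulation

A continuous-wave radar at carrier f₀ = 94 GHz (λ₀ = 3 mm; the exact
c/f₀ = 3.19 mm is deliberately overridden by the printed system wavelength,
configurable) illuminates the chest at standoff d₀.  Chest displacement
x(t) (mm) phase-modulates the echo; after quadrature downconversion the
baseband channels are

    I(t) = A cos(4π x(t)/λ₀ + θ(t)),   Q(t) = A sin(4π x(t)/λ₀ + θ(t)),

where θ collapses the standoff phase 4πd₀/λ₀ and receiver offsets, plus
residual phase noise.  Quadrature reception avoids the detection nulls of a
single-channel receiver; accordingly the demodulator uses the four-quadrant
arctangent of (Q, I) rather than the literal ratio Q/I, which would discard
quadrant information and reintroduce those nulls.  Unwrapping applies the
standard ±2π correction at adjacent-sample jumps exceeding π; at 100 Hz
sampling and chest motion of a few millimetres the per-sample phase step is
far below π, so aliasing cannot occur.  θ is estimated as the unwrapped-trace
mean — slow phase drift is left to the downstream wavelet/Kalman stages —
and displacement is x = (λ₀/4π)(w − θ), zero-mean by construction.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure of a multi-scenario
radar/ECG acquisition campaign:

* **ECG** — five Gaussian bumps (P, Q, R, S, T) on a wrapped cardiac phase;
  per-beat RR intervals are lognormal with AR(1) correlation (default
  ρ = 0.6) around 60/hr_mean.  Default amplitudes (0.12, −0.10, 1.00, −0.17,
  0.30), widths (0.25, 0.10, 0.10, 0.10, 0.40) rad and angles (−π/3, −π/12,
  0, π/12, π/2) give a realistic normal morphology with the R deflection
  dominant.  The generator reports exact R-peak times — ground truth for
  localization scoring.
* **Chest motion** — respiration (sinusoid at the scenario's rate/depth;
  apnea inserts one 3–6 s breath-hold; hypoxic breathing deepens amplitude
  ×1.5; rapid-shallow scales rate ×2.5 and amplitude ×0.4) plus a cardiac
  component: an impulse train at the R times convolved with a decaying
  20 Hz sinusoid (50 ms time constant, unit-peak normalized) — a
  seismocardiogram-like ring, evaluated analytically at fractional-sample
  peak times.
* **Scenarios** — seven posture/orientation/breathing combinations with
  orientation gains 1.0 (chest facing), 0.5 (chest side) and 0.3 (back),
  monotone in how much cardiac wall motion each antenna orientation sees,
  and heart-rate shifts +15/+20/+25 bpm for the apnea / hypoxic /
  rapid-shallow states (sympathetic compensation).  Scenario proportions
  default to the empirical campaign mix (37.44 %, 15.94 %, 14.32 %, 12.87 %,
  7.59 %, 6.09 %, 5.74 %), stored as exact count fractions of the reference
  7521-segment campaign so they sum to one; per-scenario segment counts are
  the largest-remainder apportionment (ties broken by scenario order).
* **Subjects** — per-subject baselines drawn once: hr_mean ~ U(55, 85) bpm,
  hr_sd ~ U(1, 4) bpm, cardiac amplitude ~ U(0.1, 0.5) mm, respiration
  scale ~ U(0.8, 1.2).  These priors are literature-plausible, not fitted.
* **Noise** — Gaussian residual phase noise (sd 0.02 rad) and additive
  channel noise (sd 0.05 on unit amplitude) by default.

Not emulated: radar clutter, multipath, multiple targets, range processing,
I/Q imbalance, electrode artifacts beyond additive noise, or pathological
ECG morphologies.  Passing tests therefore demonstrate correctness of the
processing chain and learnability of the synthetic mapping — not clinical
performance on real recordings.

All randomness derives from one seed via `SeedSequence` spawning; dataset
regeneration is bit-identical.

## Preprocessing

**Respiration suppression.** The displacement is decomposed with a
shift-invariant (maximal-overlap-style, non-decimated) db4 wavelet transform
at J = 6 levels, giving additive detail bands D1…D6 covering 0.78–50 Hz and
a smooth.  Signals are reflect-padded to a multiple of 2^J and trimmed, so
reconstruction is exact at retained samples and edges do not ring.  A level
is kept when ≥ 50 % of its periodogram energy falls inside the cardiac band
(default 0.8–10 Hz, fundamental plus harmonics); if no level qualifies the
fallback keeps levels whose nominal dyadic band intersects the cardiac band.
Selection runs per segment.  The smooth (respiratory trend) is always
discarded.  On pure tones the defaults retain ≥ 95 % of 1.2 Hz energy and
attenuate 0.25 Hz by > 20 dB.

**Adaptive Kalman filter.** Scalar random-walk state space (state = true
displacement, identity transition).  The measurement-noise covariance is
re-estimated from innovations with exponential forgetting λ = 0.99
(configurable, λ = 1 disables adaptation and reproduces the fixed-covariance
filter exactly); the estimate is floored at a small ε for positivity.  The
process noise q₀ (default 1e-3) is modulated by (1 + w·b(t)), w = 0.3, where
b(t) is the normalized amplitude of the input band-passed around the
cardiac-rate estimate ±0.3 Hz — tracking loosens during cardiac transients.
q₀ = 1e-3 with r₀ = 1e-2 was chosen so the filter clearly denoises a
0.1-noise 1.2 Hz component without lagging it.

**ECG cleaning.** A fifth-order least-squares polynomial (in normalized
time) removes baseline wander; electrode noise is suppressed by soft
thresholding of db4 detail coefficients with the universal threshold
σ̂·√(2 ln N), σ̂ = median(|d₁|)/0.6745 (MAD of the finest details).  Soft
thresholding is a contraction and strongly suppresses broadband noise; on
spiky QRS complexes it introduces a small amplitude bias, the usual price of
the universal threshold.

## Network

Input: one 10-s segment (L = 1000 samples), z-normalized per segment (both
input and target — the network predicts normalized morphology; absolute
amplitude calibration is out of scope, and the dimensionless RMSE/MAE scale
of the evaluation depends on this convention).

**Encoder.**
* *Multi-scale branch stack*: three parallel branches of four conv blocks
  each (conv + batch norm + ReLU), with (kernel, padding, dilation, stride)
  = (3,1,1,1), (7,3,1,1) and (7,6,2,1).  Composite receptive fields are
  1 + 4·(k−1)·d = 9, 25 and 49 samples — 0.09, 0.25 and 0.49 s at 100 Hz,
  i.e. ≈ 0.1/0.25/0.5 s: wave-detail, QRS-complex and rhythm scales.  Branch
  outputs are channel-concatenated, fused by a two-stage 1×1 convolution,
  and max-pooled (kernel 2, stride 2) to l = 500.
* *Global relation branch*: per-timestep linear embedding to d_model = 64,
  learnable positional encoding, dropout, then m = 2 layers of multi-head
  self-attention (h = 4 heads × d_head = 16, scaled dot-product, residual +
  layer norm) followed by a sigmoid-gated feed-forward stage
  G = σ(W₂ ReLU(W₁X)), output LN(X + Dropout(G ⊙ X)) — the gate reweights
  features multiplicatively; there is no separate position-wise expansion,
  keeping the branch lightweight.  Time is average-pooled by 2 and channels
  projected to match the fusion width.  A `grmm_pool_pre` option
  (default 1) lets the embedding be average-pooled *before* attention for
  quadratic-cost savings on small machines; the reduced desk-scale preset
  uses 4.
* *Fusion*: each stream projected by 1×1 conv + ReLU, concatenated,
  compressed (1×1 conv + BN + ReLU) and mixed by a final 1×1 conv.

**Decoder.** A 1×1 conv maps the fused features to the TCN width (64); then
3 stacked blocks, each a causal dilated convolution (kernel 3, dilations
1, 2, 4, left-padded (k−1)·d, batch norm, ReLU, residual) followed by
spectral attention; a long residual adds the decoder input back; a 1×1 conv
collapses channels and ×2 linear interpolation restores length 1000.

**Spectral attention.** The feature sequence (length 500 over 10 s, so an
effective rate of 50 Hz) is real-FFT'd; the amplitude spectrum is multiplied
by (i) a fixed mask equal to 1 inside 0.5–40 Hz and 0.1 elsewhere, evaluated
on the actual rfft bin frequencies (at 50 Hz effective rate the band
truncates at the 25 Hz Nyquist, so the mask principally floors sub-0.5 Hz
respiratory residue), and (ii) a learned per-bin channel attention
(conv → BN → ReLU → conv → sigmoid over the frequency axis); the original
phase is preserved and the signal inverse-transformed, with a residual add.
With the mask forced to 1 and weights to unity the block is exactly 2×
identity; an out-of-band tone through the mask path scales by exactly the
floor.  The block API takes the effective rate explicitly so it can be
exercised at 100 Hz.

**Ablations.** `model1` removes the transformer branch, `model2` the conv
branches, `model3` chains conv → transformer sequentially (bypassing
fusion), `model4` removes spectral attention from the decoder.

**Loss.** Per-segment RMSE (root form), averaged over the batch; a config
switch selects plain MSE.  The root form is the default because the loss is
named for it even where typeset without the radical.

**Autodiff engine.** The network runs on a bundled numpy reverse-mode
autodiff engine (tape-based; broadcast-aware arithmetic, im2col dilated
convolution, batch/layer norm, softmax attention, real-FFT ops with
analytically derived adjoints verified against finite differences, pooling
and linear upsampling, Adam).  A dtype context lets training run in float32
(≈6× faster) while exactness tests run in float64.

## Training protocol

Subject-disjoint k-fold cross-validation: subjects are shuffled once
(seeded) and partitioned; all of a subject's segments fall on one side of
every split, preventing identity leakage.  Default hyperparameters: Adam,
initial lr 0.001, 300 epochs, batch 64, 5 folds (24 train / 6 test subjects
at 30 subjects), cosine annealing to lr_min = 1e-6, early stopping with
patience 20 on a held-out validation slice of 10 % of the *training*
subjects (at least one) — test subjects never influence stopping.  Training
aborts on a non-finite loss.  Under a fixed seed, training is bit-for-bit
reproducible.

## Desk-scale verification experiment

The package's end-to-end bar runs entirely on synthetic data at a size a
single CPU handles in about a minute: 8 subjects, 200 segments, the full
simulate → demodulate → preprocess chain, one fold of a 4-fold subject
split (6 train / 2 test subjects), 30 epochs at batch 4, and the reduced
network preset (branch width 8, fusion 16, d_model 16, 2 heads, 1
transformer layer with pre-pool 4, TCN width 16, 2 TCN-SA blocks, dilations
1–2) in float32.  Bars: held-out mean PCC ≥ 0.85 and median R-wave
localization error ≤ 0.02 s; the seeded reference run reaches PCC ≈ 0.90
with R-median 0.00 s.  These bars are package-defined properties of the
synthetic task, not reproductions of any clinical dataset result.

The ablation check trains the two single-branch encoder variants on the
same seeded split and requires the full model's PCC to be at least each
variant's minus 0.01.  At this scale the synthetic radar-to-ECG mapping is
dominated by local structure, so the conv-only encoder is essentially as
good as the full model (occasionally fractionally better, within the tie
band); the transformer-only encoder is clearly worse.  A larger, more
heterogeneous dataset is where global rhythm context would be expected to
separate the variants further.

## Evaluation conventions

* PCC/RMSE/MAE per segment on the z-normalized traces; zero-variance
  segments are excluded from aggregates and counted.
* Wave detection: built-in Pan-Tompkins-style R detector (5–20 Hz bandpass,
  squared derivative, 150 ms moving-window integration, adaptive threshold,
  250 ms refractory, ±40 ms refinement to the raw extremum, polarity chosen
  by the dominant deflection); Q/S are the local minima within 60 ms before/
  after R; T the maximum 100–400 ms after R.  The detector is pluggable — an
  external ECG toolkit can be swapped in for parity checks — but everything
  in the package uses the built-in one, keeping the suite hermetic.
* Localization errors: reconstructed peaks matched greedily to reference
  peaks by proximity within ±0.15 s, each peak used once; unmatched
  reference peaks are reported as misses, not folded into the error
  statistics.  Percentiles use linear interpolation between closest ranks;
  CDF tables are sorted values against rank/n.

## Numerical choices and degenerate inputs

* Wavelet transforms use reflection boundary handling throughout.
* The demodulator raises on samples where I = Q = 0 (phase undefined),
  naming the index.
* The innovation-variance estimate in the AKF is floored at 1e-12.
* Softmax subtracts the row maximum before exponentiation; layer/batch norm
  use ε = 1e-5; the RMSE loss adds 1e-12 under the square root.
* The largest-remainder apportionment breaks remainder ties by list order,
  and always sums exactly to the requested total.

## Known limitations

* The synthetic cardiac kernel is beat-invariant per segment; real
  seismocardiographic waveforms vary with posture, load and disease.
* T-wave localization on reconstructed traces is noticeably weaker than
  QRS timing (broad, low-amplitude deflection under an RMSE-trained model).
* No I/Q imbalance or DC-offset calibration is modelled or corrected.
* The full-width network is CPU-trainable only at small dataset sizes; the
  engine is single-threaded numpy without GPU support.
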