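# Methods

This note documents the models implemented in `dinmodel`, the parameters
that matter, the design choices made where the design was genuinely open,
and the limits of what the synthetic pipeline can show.

## Stimuli

Tokens are built from ten hand-designed templates of 2–3 segments:
"vowel" segments synthesized additively from a harmonic source (F0 with a
12% declination) shaped by time-varying F1/F2 resonance peaks plus fixed
fill formants near 2.85 and 3.6 kHz, and "consonant" segments realized as
band-passed noise bursts. Templates caricature the English digit names so
that the classes are well separated in (F1, F2, burst-band) space; token
durations fall in [0.3, 0.7] s. A talker profile sets the fundamental
(roughly 100–145 Hz or 175–240 Hz halves of the roster) and a vocal-tract
length proxy that multiplies all formant frequencies (0.94–1.14). Per-token
jitter (±3% F0, ±5% segment duration) is drawn from a generator seeded by
(talker, digit, utterance), so every token is bit-reproducible.

Calibration uses a fixed digital-to-pascal convention: amplitude 1.0 ≡ 1 Pa,
so full-scale RMS is 94 dB SPL re 20 µPa. Speech is presented at 70 dB SPL;
flat-spectrum Gaussian noise at 0–100 dB SPL fills a 700-ms window in which
the token is placed at the start; SNR is by definition speech level minus
noise level. A separate behavioral-protocol preset (speech 65 dB SPL, SNRs
−30..0) exists as a configuration, not a different code path.

What the generator does **not** emulate: coarticulation, natural prosody,
talker idiosyncrasies beyond F0/formant scaling, recording-channel effects.
Consequently the synthetic task is easier than natural digit recognition at
matched SNR, and absolute accuracies or thresholds from this pipeline are
not comparable to human values — only orderings, shapes, and shifts are
meaningful, and the tests assert exactly those.

## Periphery

Per CF channel (grid: log-spaced, 100 Hz–8 kHz; 128 CFs at full scale,
32 in the desk preset):

* **Filtering.** Frequency-domain Gaussian filters with ERB(f) = 24.7·
  (4.37 f/1000 + 1) bandwidth, widened by up to 150% as static OHC health
  falls (broadened tuning with OHC loss). The analytic envelope is
  block-averaged to a 1-kHz control rate.
* **OHC stage.** Drive (dB) = band level + 40 dB · cohc_eff(t). The MOC
  reflex reduces cohc inside the 1–4 kHz band (placed on the cochlear
  position axis via the Greenwood map F = 165.4·(10^{2.1x} − 0.88)):
  cohc_eff = cohc·(1 − mocr_max·σ(d)), σ(d) = d/(d + 0.02 Pa), with the
  drive smoothed by asymmetric first-order kinetics (onset τ = 60 ms,
  offset τ = 200 ms — plausible published MOC kinetics). The 20-dB MOC
  gain knob converts to mocr_max = 20/40 = 0.5 (the fraction of
  full-health OHC gain the reflex may remove); 0 dB disables the reflex.
* **Audiogram fitting.** Thresholds at [0.125…8] kHz are interpolated
  log-linearly onto the CF grid; 2/3 of the shift is attributed to OHC and
  1/3 to IHC loss; each attributed shift maps linearly over [0, 105] dB to
  health in [1, 0]. The map is a documented monotone stand-in for an
  external fitting routine; it preserves the 2/3–1/3 contract and
  full-health at 0 dB HL. The three study audiograms are NH (0 dB HL),
  flat loss (30 dB HL), and sloping loss ([0,0,0,10,25,40,55] dB HL) —
  the latter two chosen as representative of the profiles such studies
  depict graphically.
* **Transduction and rates.** Each spontaneous-rate class c has rate
  spont_c + cihc·(250 − spont_c)·logistic((drive − θ_c)/(DR_c/6)), with
  spont = (0.1, 5, 60) spikes/s, thresholds θ = 55 + (30, 18, 0) dB, and
  dynamic ranges DR = (40, 30, 20) dB for (low, medium, high)-SR classes:
  high-SR fibers have low thresholds and narrow dynamic ranges, low-SR the
  reverse. All are configuration values, not constants.
* **Spiking and binning.** Population counts per (CF, 10-ms frame) are
  Poisson with mean fiber_count · mean-rate · 10 ms, summed over classes —
  equivalent to summing independent Poisson fibers. 10-ms bins land
  exactly on the 100-Hz frame rate, giving 70 frames per 700-ms window;
  an 8-ms alternative cannot simultaneously satisfy the 100-Hz frame rate
  and the 70-frame trim, so the 10-ms frame is used throughout.
* **Finalization.** Onset is the first frame whose 3-frame-smoothed
  population count exceeds the analytic spontaneous baseline by 3 Poisson
  SDs (frame 0 if never exceeded or no state is supplied); the window
  [onset, onset+70) is kept, zero-padded if short, then z-scored to global
  mean 0, SD 1. A constant neurogram returns all zeros with a `degenerate`
  flag rather than dividing by zero.

This periphery is deliberately phenomenological: it exposes exactly the
manipulated parameters (cohc, cihc, MOC gain/mocr_max, fiber census) while
omitting middle-ear transfer, refractoriness, power-law synaptic
adaptation, and suppression. Degradation effects on neurograms are
therefore qualitatively faithful (lower counts, broadened tuning, reduced
anti-masking) but not quantitatively matched to biophysical models.

## Neurogram metrics

NSIM uses 3×3 Gaussian-weighted (σ = 0.5) local windows and scores
intensity × structure, l·s with l = (2μrμd + C1)/(μr² + μd² + C1) and
s = (σrd + C3)/(σrσd + C3), C1 = (0.01 L)², C3 = (0.03 L)²/2, L the
reference dynamic range (set to 1 when the reference is constant so the
0/0 limit is 1). STMI projects both neurograms onto 2-D Fourier modulation
energy restricted to rates 2–32 Hz and scales 0.25–8 cyc/oct and returns
1 − ‖T − N‖²/‖T‖², clamped to [0, 1]; a windowed 2-D spectrum stands in
for a cortical filter cascade at desk scale. Both metrics are invariant to
joint positive rescaling (NSIM because its constants scale with L; STMI
exactly). The reference is always the same token through the NH periphery
with no background noise. Neither metric is treated as a calibrated
intelligibility predictor.

## Classifier

C1 (5×5) → LRN → pool → C2 (3×3) → LRN → pool → C3 → C4 → C5 (3×3) →
pool → F1…F5 → 10 log-probabilities. Channel depths are
[C, 2C, 4C, 2C, C] (C = 16 full scale, 8 desk); FC widths decrease
geometrically from the flattened size to 10; LRN uses size 5, α = 1e-4,
β = 0.75, k = 2; pooling is 2×2 stride 2; ReLU nonlinearities; no dropout
or batch normalization beyond the z-scored input and the two LRN layers.
Training: Adam, learning rate 1e-3, weight decay 1e-3 (L2 term in the
gradient), batch 256 full scale / 32 desk, cross-entropy on log-softmax
outputs. Exact layer widths, pooling geometry, and LRN constants are
declared defaults of this implementation, canonical for the architecture
family it follows.

Initialization is normally distributed per tensor with fan-in scaling
(std = √(2/fan_in)). A fixed small std (configurable via `init_std`) makes
activations vanish through the ten-layer stack and stalls learning at
chance, so the fan-in-scaled normal is the default.

The forward and backward passes are written directly in numpy (im2col
convolutions, channel-window LRN with its exact gradient, one-hot maxpool
scatter) and are verified against central finite differences in the test
suite. A trainable mask names which of the 20 parameter tensors a step may
update; masked-out tensors (parameters and optimizer moments) are
untouched, so frozen layers are bit-identical after any number of steps —
the mechanism behind constrained adaptation.

## Adaptation framework

Folds permute talkers (seeded per fold) and split them 70/10/20 into
train/validation/test; utterances follow their talkers, so train and test
talkers are disjoint and every subset contains all SNRs. The same fold is
reused across phases and paradigms, so the evaluation talkers are
identical whichever paradigm is compared. The split is talker-stratified
by construction; an utterance-stratified split with talker exclusion would
satisfy the same constraints but was not chosen because talker-level
permutation implements both requirements with one mechanism. Validation
data are kept for monitoring only; training duration is fixed by budget,
not early stopping.

Phase budgets are 250,000 samples at full scale and 16,000/8,000
(phase 1/phase 2) in the desk preset — sizes chosen so a desk run
exercises the qualitative findings (sigmoidal NH curve, large
degradation-induced threshold shift, adaptation recovering part of it,
constrained adaptation confined to F5) rather than absolute accuracies.

Layer change is reported per tensor as the mean magnitude of per-parameter
change in units of the baseline tensor's SD, (1/n)Σ|P_i − B_i|/σ_B. This
per-element-referenced form is used because it makes an unchanged tensor
report exactly 0 (the property the constrained paradigm's bookkeeping
needs); the mean-referenced scalar form (1/n)Σ|(v_i − μ_B)/σ_B| is exposed
separately as `normalized_mean_difference` for direct use. σ_B = 0 yields
a flagged NaN, never a silent 0.

## Psychometrics

Sigmoid fits hold the asymptotes fixed — (0.10, 0.90) human, (0.09, 0.88)
model — and estimate slope a > 0 and inflection b by trust-region least
squares, with the initial inflection at the empirical half-rise point.
Flat-at-chance curves are rejected as non-identifiable rather than fitted.
Thresholds invert the fitted sigmoid in closed form,
x = b − ln(span/(t − floor) − 1)/a; fitted sigmoids are used instead of
linear interpolation so the threshold inherits the fit's noise averaging.

The human-space remap multiplies the model curve by f_human(x)/f_model(x)
and clips to [0, 1]. A multiplicative ratio was chosen over an additive or
parameter-shift variant because it is exact on the model mean curve
(mapping it onto the human fit), order-preserving, and isolated behind one
operation so an alternative can be swapped in. Note that the ratio of two
rising sigmoids is not itself monotone, so the remap is only guaranteed to
preserve monotonicity for curves of the calibration family, not for
arbitrary monotone curves.

Threshold tables are analyzed with a factorial OLS ANOVA (main effects and
two-way interactions of audiometric loss, ANF census, MOC gain, paradigm)
with cross-validation fold included as a blocking factor, approximating a
repeated-measures design with folds as the random unit; unbalanced designs
are rejected.

## Numerical notes and degenerate inputs

* All randomness flows through `numpy.random.default_rng` with explicit
  seed lists; identical inputs and seeds give bit-identical outputs at
  every stage (tokens, noise, spikes, splits, init, batch order).
* All-zero waveforms cannot be calibrated (undefined gain) and are
  rejected; all-zero neurogram references make STMI undefined and are
  rejected; constant neurograms z-score to zeros with a flag.
* Sigmoid targets at or beyond the asymptotes are rejected (the inverse
  does not exist); slope is bounded into (1e-4, 10) 1/dB.
* Pooling floors odd spatial dimensions (trailing row/column dropped);
  configurations whose feature maps collapse are rejected at build time
  with a layer-by-layer shape report.

## Known limitations

* The synthetic corpus is far more regular than natural speech; desk-scale
  thresholds sit tens of dB above human ones and only their orderings and
  shifts are interpretable.
* The periphery omits biophysical detail (see above); NSIM/STMI values are
  not comparable to published figures computed with cortical filter banks
  on biophysical neurograms.
* The MOC reflex model is quasi-static per control step with first-order
  kinetics; it cannot express fast binaural or anti-phasic efferent
  effects.
* Full-scale (94,500-stimulus, 128-CF, 250,000-sample) runs are supported
  by the same code paths but are cluster-scale jobs; no attempt is made to
  reproduce them here.
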