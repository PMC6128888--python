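# Methods

`sonostage` estimates macro sleep stages — wake (W), REM (R) and NREM (N) at
the standard 30-s epoch resolution — from a single non-contact microphone
recording of a night's sleep, and derives the standard sleep-quality report
from the resulting hypnogram. This note documents the model, the numerical
choices, and what the synthetic-data experiments do and do not demonstrate.

## Signal model and processing chain

The input is mono PCM audio at 44.1 kHz. The chain is strictly causal through
the real-time pass:

1. **Framing.** Audio is cut into contiguous, non-overlapping 50-ms frames
   (2205 samples); 600 frames form one 30-s epoch. Trailing partial frames
   and epochs are discarded, never padded: no fabricated audio enters the
   features. Amplitudes are normalized to full scale ±1 on read, so all
   intensities are dB relative to full scale (dBFS, floor −80 dB); absolute
   SPL calibration is out of scope.

2. **Noise suppression.** Sleep sounds sit barely above the room's
   stationary noise (fans, air conditioning). Once per epoch the noise power
   spectrum is re-estimated from the lowest 20% of frames by energy and
   blended with the running profile, `0.9·previous + 0.1·current`. Each
   frame then receives a per-bin power-domain Wiener-type gain

       G_k = max(1 − α·P_noise,k / P_frame,k, g_floor),

   applied to the complex spectrum (phase preserved), with oversubtraction
   α = 2 and amplitude floor g_floor = 10^(−25/20). The 50-ms frame is the
   transform block (rectangular window), so enhancement is exactly
   invertible. α = 2 was chosen analytically: for converged stationary
   Gaussian noise the expected residual power is
   ∫₂^∞ (1 − 2/e)² e·e^(−e) de ≈ 0.06 of the input (≈ 12 dB suppression),
   while a transient 20 dB above the floor loses under 0.2 dB — transients
   are deliberately left for the event detectors. The tracker uses current
   and past epochs only.

3. **Event detection.** A multinomial logistic-regression classifier (a
   linear softmax model — one unified 4-class model in place of separate
   breathing and movement detectors, so the four outputs share one
   normalization) maps 17 per-frame descriptors (dBFS log energy, normalized
   spectral entropy, centroid, 85% roll-off, zero-crossing rate, 4
   band-energy ratios at 0–200/200–1000/1000–4000/4000–22050 Hz, real
   cepstrum coefficients 1–8) to per-frame probabilities of inhalation,
   exhalation, body movement and "other". Features are z-scored with
   training-set statistics stored in the model; classes are inverse-frequency
   weighted. All-zero frames map deterministically to a fixed silence vector
   (energy at floor, entropy 1). Each frame is classified from its own
   descriptors only, so inference is causal at frame level.

4. **Epoch features.** 67 features in five frozen families
   (33/12/10/8/4): within-breathing (detected breath events: counts,
   durations, intensities, spectral shape of breath frames), between-
   breathing (inter-breath intervals, autocorrelation periodicity, dominant
   respiratory frequency, duty-cycle stability), body movement (event
   statistics plus night-level recency), background noise (transient events
   above the tracked floor, floor level and its epoch-to-epoch delta), and
   personalization (age, gender, BMI, epoch index t). The registry order is
   versioned and hashed into every serialized model. Breath/movement events
   are maximal argmax runs with probability ≥ 0.5 and at least 3 frames
   (150 ms); "other" events additionally require intensity ≥ 10 dB above the
   noise floor, so quiet ambience is not an event. Undefined statistics
   (e.g. breath-interval spread without breaths) carry NaN sentinels,
   replaced by registry defaults in standalone use and by training-set
   medians (stored in the cascade) in the classifier path — a neutral
   imputation that avoids biasing any stage. History features (noise-floor
   delta, trailing-5-epoch transient rate, frames since last movement) look
   strictly backward.

5. **Breathing periodicity.** The autocorrelation of the mean-removed
   inhalation curve uses the *unbiased* normalization (an exactly periodic
   curve scores 1.0 at its period); the reported peak is the first local
   maximum with positive correlation at lag ≥ 1 s, searched up to half the
   epoch. Local bumps inside the negative trough (e.g. at half period) are
   not periodicity peaks. A constant curve is flagged degenerate — exactly
   the wake situation. NREM breathing is strongly periodic, REM less, wake
   hardly at all; the test suite verifies this ordering on simulator output.

## The staging cascades

Both classifiers are cascades of one-hidden-layer feedforward networks with
hyperbolic-tangent hidden units and softmax outputs, one sub-classifier per
night period. The real-time cascade C(r)(X, t) classifies epoch t from the
concatenated feature vectors of epochs t−k…t (current epoch included):

| period | epochs      | lookback k | hidden units |
|--------|-------------|-----------:|-------------:|
| 1      | t ≤ 5       | — (rule: W)| 0 |
| 2      | 5 < t ≤ 20  | 5          | 100 |
| 3      | 20 < t ≤ 50 | 20         | 400 |
| 4      | 50 < t ≤ 100| 50         | 1000 |
| 5      | 100 < t ≤ 200| 100       | 1000 |
| 6      | 200 < t     | 200        | 1000 |

Epochs 1–5 are declared wake outright: recordings start with lights off and
the subject in bed but awake. The longest window spans a whole ~100-min
sleep cycle. The offline cascade C(o)(C(r), t) runs backward over the
completed night's real-time score sequence; its input is the flattened score
triplets of epochs t…t+k plus the epoch index t, and the last five epochs
keep their real-time estimate:

| period | epochs            | lookahead k | hidden units |
|--------|-------------------|------------:|-------------:|
| 1      | T−5 ≤ t           | — (pass-through) | 0 |
| 2      | T−20 ≤ t < T−5    | 5           | 20 |
| 3      | T−50 ≤ t < T−20   | 20          | 50 |
| 4      | T−100 ≤ t < T−50  | 50          | 100 |
| 5      | T−200 ≤ t < T−100 | 100         | 200 |
| 6      | 0 < t < T−200     | 200         | 200 |

Period conditions are evaluated first-match in table order, which makes the
boundaries exact for long nights and automatically degrades to the largest
fitting window for short nights (a property the test suite checks for all
t, T). Raw concatenation of windowed features is the default input; hidden
sizes can be scaled down uniformly (`hidden_scale`) for quick runs while the
canonical sizes above remain the architecture of record.

**Training.** Design nights are split 80/20 at the subject (night) level —
never epoch-level — with the development fifth driving early stopping of
the real-time sub-classifiers. Each real-time sub-classifier trains on its
period's epochs across training nights with minibatch Adam (lr 10⁻³, batch
128, weight decay 10⁻⁴) on weighted cross-entropy; class weights are inverse
class frequency *clipped to [0.25, 4]* — unclipped weights explode when a
stage is nearly absent from a period (wake mid-night can have a handful of
epochs against thousands of NREM) and let those few epochs dominate the
loss.

The offline sub-classifiers train afterward on the trained real-time
cascade's score sequences of the *whole* design set, training and
development nights together. This matters: real-time scores on its own
training nights are optimistically clean, and an offline refinement shown
only those learns brittle mappings that degrade genuine nights — the
development nights, which the real-time stage never fit directly,
contribute realistically noisy score sequences. The offline nets are small
and train for a fixed 120-iteration budget without class reweighting (the
weighted real-time stage has already corrected the stage imbalance;
reweighting the probability inputs would double-correct). On held-out
simulated nights this configuration reproduces the expected ordering —
offline accuracy above real-time on nearly every night — whereas
dev-early-stopped, reweighted offline training inverted it.

All randomness is seeded; identical configuration and seed reproduce
identical parameters bit-for-bit.

Ties in the final argmax are broken N > R > W (toward the prior-dominant
stage).

## Sleep report

Eight parameters from the hypnogram, epochs of 30 s: TST (minutes of R+N),
SL (start of recording to first non-wake epoch; the recording is assumed to
begin in bed), SE = 100·TST/recording, WASO (wake strictly between sleep
onset and final awakening), RL (start to first R epoch; missing without
REM), RP = 100·R/TST, NP = 100·N/TST, and RC. The identity
SL + WASO + TST + terminal wake = recording length holds exactly. REM
cycles merge maximal R runs separated by fewer than 60 epochs (30 min) of
non-R and discard clusters with fewer than 2 R epochs; both are config
values, chosen to give the clinically observed 0–4 cycles per night on
realistic hypnograms. RP/NP use the TST denominator by default (the
textbook definition); `percent_denominator="recording"` switches to time in
bed, preserved because published summary tables are sometimes internally
consistent only under that convention.

## Agreement statistics

Epoch-by-epoch confusion matrices (rows = reference, columns = estimate),
percent agreement, Cohen's kappa from the count matrix, the wake/sleep
2-class collapse, Lin's concordance correlation
2·cov/(var x + var y + Δmean²) and Bland–Altman bias ± 1.96·SD for the
continuous report parameters. Pooled (summed matrix) and per-subject
(mean ± SD across subjects) aggregations are both computed and labeled.
Internally everything is full precision; display rounding is one decimal for
percentages, three for kappa/CCC.

## The night simulator

The simulator provides complete ground truth — hypnogram, audio, per-frame
event labels, metadata — for training and testing without patient
recordings. Its defaults encode the physiological regularities the method
exploits:

* architecture: wake latency N(15, 5) min floored at 3 min (so the first
  five epochs are always wake), NREM/REM cycles with period N(95, 10) min,
  REM bouts N(18, 5) min, brief awakenings (Poisson 0.7/cycle, ~1.5 min)
  replacing NREM epochs in place so REM-onset intervals keep the cycle
  period; the first cycle skips REM with probability 0.25 (a first-night-
  effect-like delayed REM onset); terminal wake N(5, 2) min;
* breathing: NREM 14 breaths/min with small within-epoch spread (interval
  CV ≈ 0.036), REM 16 breaths/min with four-fold larger spread, wake
  breathing mostly inaudible (15% of breaths, 8 dB fainter);
* movement: Poisson events/epoch 2.5 (wake), 0.15 (NREM), 0 (REM — atonia);
* sound: stationary Gaussian background at −45 dBFS RMS; breath bursts are
  Hann-enveloped band noise (inhale 300–2000 Hz, exhale 200–1000 Hz) 15 dB
  above the floor; movements broadband 100–8000 Hz at +25 dB; sparse
  transients (0.05/epoch, 100–400 ms) at +30 dB remain in the "other"
  class. The bands overlap deliberately so detection is learnable but not
  trivial.

One night-level seed drives everything through per-epoch substreams
(`SeedSequence.spawn`), so a night is bit-identical whether materialized or
streamed epoch by epoch; long nights are streamed because materialized
audio costs ≈ 5.3 MB/epoch.

**What the simulator does not emulate:** real snore acoustics and their
spectral richness, apnea events, room reverberation, position-dependent
intensity changes, a second person in the room, or non-stationary noise
(traffic ramps). Consequently, passing the recovery experiments shows that
the pipeline extracts and exploits breathing periodicity, breathing-rate
variability and movement patterns end-to-end — it does not certify clinical
performance on patient audio.

## Scaled experiment sizes

The recovery protocol in the test suite runs 50 nights of 300 epochs
(2.5 h) each, trains on 40 and tests on 10, with hidden layers at one
tenth of the canonical sizes; the detector trains on two further 30-epoch
nights. `scripts/acceptance.py` runs the same protocol at 40 nights
(32 train / 8 test). These sizes keep a full run in the tens of minutes on
a single CPU while still exercising every cascade period (including
lookback 200). The full-size architecture (840-epoch nights, canonical
hidden layers) is the package default outside the test harness.

## Known limitations

* The 67-feature registry is this package's reconstruction from the family
  descriptions and counts; the original feature table is not public. The
  registry is frozen, hashed and addressed by name so alternatives can be
  swapped in deliberately.
* The offline cascade's training inputs include the development nights'
  real-time scores, so the reported development accuracy of the offline
  pass is mildly optimistic; only a fresh test night measures it without
  bias (the training report documents this).
* Logistic regression is a deliberately shallow event detector; on the
  simulator it exceeds 97% frame accuracy, but richer acoustics may warrant
  the full original detector architecture, which is not reproduced here.
* Kappa is undefined (NaN) for degenerate marginals; downstream averaging
  excludes such subjects and reports how many were excluded.
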