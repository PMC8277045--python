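# Methods

## Problem and signal model

A belt-worn tri-axial accelerometer on the maternal abdomen records at
280 samples/s in AMU, the device's uncalibrated linear acceleration unit.
The Z axis (normal to the abdomen) carries the informative variation; X
and Y record in-plane motion and are discarded for analysis.  Three event
classes are distinguished:

1. **fetal (limb) movement** — a transient burst, roughly 0.3–0.7 s;
2. **maternal laugh** — the artifact whose time-domain shape most
   resembles a kick, lasting seconds;
3. **maternal respiratory movement** — quasi-periodic 0.2–0.4 Hz
   background, the "nothing is happening" class.

Two annotation buttons provide weak labels during recording sessions:
button 1 for felt fetal movements, button 2 for the mother's own
movements.  Presses lag the true event by a reaction delay of a few
seconds.

## Pipeline

Stage order for the four variants:

| variant | filter | feature fed to the CNN |
|---------|--------|------------------------|
| A1      | none   | 64×26 spectrogram image |
| A2      | high-pass | 64×26 spectrogram image |
| A3      | high-pass | NNMF basis W (64×r) |
| A4      | high-pass | NNMF abundance H (r×26) |

**High-pass filter.**  4th-order Butterworth, cutoff 1.0 Hz, applied
forward–backward (zero phase) with reflect padding of 3×order samples.
The source system cites an external filter design without reproducing its
parameters, so the cutoff/order here are this package's own choice: the
design removes the 0.2–0.4 Hz respiration band by ≥ 40 dB single-pass
(≈ 84 dB effective) and passes the 5–20 Hz kick band with < 0.01 dB droop.
All parameters are configurable.

**Segmentation.**  A realization is 200 samples of (filtered) Z axis with
its amplitude peak at 0-based index 100 (window = peak−100 … peak+99; with
an even width both "median" positions are defensible — one convention is
fixed here).  In training mode the peak is the largest |z| in a 5 s
backward vicinity of a button press (mothers react late, so only the
backward direction is searched), followed by a hill-climb re-centring step
so the chosen index is the argmax of its own window — without it, a long
laugh can out-peak the press-side burst inside the extracted window.
Respiratory realizations are quiet windows drawn uniformly (seeded) at
least 2 s away from any press-derived window.  Edge-adjacent windows are
dropped, never padded.  In application mode, candidate peaks are local
maxima of |z| above a threshold with ≥ 200 samples separation (windows
never overlap; the larger peak wins conflicts).

**Application threshold.**  Default is adaptive per session:
median(|z|) + 7·σ̂ with σ̂ = 1.4826·MAD(z).  The margin follows from a
false-alarm analysis: the expected maximum of |noise| over a 20-min
280 Hz session is ≈ 5σ for Gaussian noise, so thresholds near 3σ (e.g. a
median + 6·MAD(|z|) rule, which sits at ≈ 2.9σ) fire hundreds of times on
an event-free session, while 7σ stays silent with margin yet remains far
below kick amplitudes at workable SNR.  An absolute AMU threshold can be
supplied instead.  Note that a high-pass-filtered posture step is itself a
genuine above-threshold transient: detector specificity is defined against
the respiration+noise background, and step transients reaching the
classifier are expected to be rejected there.

**STFT.**  Each 200-sample realization is zero-padded to 201 samples and
transformed with a periodic Hann window of length 126, hop 3, one-sided
FFT of length 126: exactly 64 frequency bins × 26 frames, the classifier's
input size, with no resampling.  This is the unique simple configuration
with that property; bin 18 is exactly 40 Hz.

**Rendering.**  Matrices become RGB images by scaling to peak 1 (exact
invariance to positive rescaling), log compression log1p(1000·x)/log1p(1000)
(~60 dB dynamic range), and a fixed 256-entry colour table generated in
closed form (R = t, G = t^0.8, B = 0.35+0.3t) whose luminance is strictly
increasing, so brighter always means larger magnitude and images are
bit-stable across machines.

**NNMF.**  V ≈ WH is fitted by the classical multiplicative updates for
the Frobenius objective from seeded uniform random init (defaults: rank 5,
≤ 200 sweeps, relative-decrease tolerance 1e-4).  The objective is
recorded every sweep and is non-increasing.  The factorization runs on the
magnitude matrix V, not on the rendered image: non-negativity is the
natural frame for magnitudes, and the rendering is a visualization step.
Caveat learned while testing: from random init the updates plateau well
above machine precision even when an exact factorization exists (at full
rank a ~7% relative residual remains, matching scikit-learn's `mu` solver
on the same data), so exact-recovery expectations only hold for planted
low-rank structure.

**Classifier.**  Three valid (unpadded) convolution stages — kernels 5×3,
5×2, 5×2 with 60/50/40 filters — each followed by ReLU, then flatten and a
dense 3-way softmax head.  Training is plain minibatch SGD (batch 32, no
momentum, no weight decay) at learning rate 1e-4 for 300 epochs by
default; the published per-layer epoch schedule (80/150/300) is read as an
end-to-end epoch budget, the only unambiguous interpretation.  The split
is stratified per class at 80/20 with floor rounding on the train side and
no rebalancing, preserving the natural class imbalance.  For the NNMF
variants the input is the rendered W (64×r) or H (r×26) image; where a
factor matrix is thinner than a kernel in one dimension, that kernel
dimension is clamped so the valid convolution stays defined.

Desk-scale experiments use `CNNSpec.small()`: the same kernel geometry
with 8/6/4 filters at learning rate 1e-3 for 50 epochs — the point where
the training loss plateaus on corpora of ~1500 realizations — so a full
variant run takes ~2.5 min on one CPU.  The network is implemented
directly in numpy (im2col convolutions, analytic backprop); given the
fixed seeds for init and shuffling, the whole train/predict path is
bit-reproducible on a machine.

## Synthetic study generator

No recordings ship with the package, so the generator emulates the signal
phenomenology with known ground truth:

* **kick**: exponentially damped oscillation, carrier drawn 5–20 Hz,
  decay constant 0.1 s, duration 0.3–0.7 s, peak amplitude 12 AMU by
  default;
* **laugh**: amplitude-modulated oscillation train (raised-cosine envelope
  4–6 Hz over an 8–14 Hz carrier), 1.5–4 s, peak 10 AMU — deliberately
  kick-like in band and amplitude but longer and modulated;
* **background**: white noise (σ = 1 AMU), a respiration sinusoid
  (0.3 Hz, 5 AMU), and piecewise-constant baseline levels (jumps at
  ~2/min, level sd 8 AMU) standing in for posture shifts;
* X/Y axes are 0.2× copies of the clean Z content plus independent noise
  (only the Z-dominance ordering is physical);
* button presses lag each event onset by Uniform(0.5 s, 5 s).

The waveform families are invented: the source system shows example
morphologies without parameterizing them, so these are the minimal shapes
reproducing the "kick ≈ laugh ≫ respiration" separability structure.
Amplitudes are set only to make the classes separable-but-confusable;
no clinical amplitude statistics exist to match.

Multi-subject corpora apportion a prescribed class mix (default the
clinical tabulation 1022:276:1563) across sessions by largest remainder,
keeping realized proportions within rounding of the target at desk scale,
while per-subject log-normal jitter (sd 0.2 on amplitudes, 0.05 on rates)
provides the between-subject variation that makes global-vs-per-subject
training comparisons meaningful.  Standalone sessions default to Poisson
event counts instead.  Everything derives from one integer seed.

What the generator does **not** emulate: real kick biomechanics and their
gestational-age dependence, sensor nonlinearity and belt slippage, fetal
hiccups/rotations/whole-body movements, overlapping events, or annotation
errors (every synthetic press corresponds to a real event).  Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
its stages behave as designed on signals with the assumed structure — not
that clinical accuracy figures would be reproduced on real recordings.

## Study sizes used by tests and the acceptance script

The default synthetic study is 10 subjects × one 20-min session
(~1700 realizations after segmentation), the package's own desk-scale
choice mirroring the phase-2 protocol's 15 × 20 min volume.  On it, A2
(filter + spectrogram) reaches class-1 TPR ≥ 0.85 at FPR ≤ 0.10 and a
lower class-1 FPR than A1 (no filter) on drift/respiration-contaminated
data — the qualitative counterparts of the clinical headline results,
which are themselves out of reach because the clinical recordings were
never deposited.

## Evaluation conventions

Rates are one-vs-rest per class: TPR(c) = cm[c,c]/row-sum, FPR(c) =
(col-sum − cm[c,c])/(total − row-sum); zero denominators yield an explicit
undefined marker, never NaN.  This is the only reading that reconciles a
single scalar "false positive rate" with a 3-class confusion matrix.  The
three-method agreement table greedily matches device and maternal events
one-to-one to ultrasound-role truth events within a 5 s tolerance (the
matching tolerance is this package's choice) and prints percentages with
half-up 2-decimal rounding.  Gestational-age tabulation uses the bands
27–31, 32–35, 36–40+; ages of 26 weeks fold into the first band; totals
are column sums.

## Known limitations

* The AMU→m/s² calibration is unknown; all amplitudes are relative.
* Application-mode counting can emit multiple windows per long event
  (laughs), since candidates only need 200 samples of separation.
* Per-subject training on desk-scale corpora leaves very few laugh
  realizations per subject; subjects whose classes cannot be split are
  skipped with a warning rather than imputed.
* The published class-3 tabulation is internally inconsistent (per-bin
  entries sum to 1577, printed total 1563); the package reports the
  arithmetically consistent column sum.
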