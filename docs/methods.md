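# Methods

`emgforce` implements a complete high-density surface-EMG (HD-sEMG) muscle
force estimation workflow: a synthetic data generator with known
EMG–force coupling, a four-stage preprocessing chain that reduces a
64/128-channel grid recording to a one-dimensional activation envelope, a
stacked-LSTM regressor from envelope windows to normalized force, transfer
calibration by layer freezing, and a deviation-score assessment of abnormal
EMG–force relationships with rank-based group statistics.

## Signal model of the simulator

Each synthetic channel is an amplitude-modulated noise process

    semg[ch, t] = gain[ch] · w[ch] · f(t)^α · carrier[ch, t]
                  + n[ch, t] + c · m[ch] · shared[t]

* `f(t)` — commanded force as a fraction of maximum voluntary contraction
  (MVC), in [0, 1]. Force modes: increasing-plateau (default 3 s linear
  ramp + 3 s plateau), half-rectified sine, constant (embedded in a brief
  rise/release when generated inside a cohort, because a perfectly flat
  measured force would make min–max normalization degenerate), and a seeded
  band-limited (≤ 1 Hz) random trajectory.
* `w[ch]` — spatial activation: a Gaussian bump over the electrode grid
  (per-subject random center and width σ ∈ [1.2, 2.2] electrode pitches,
  over a 0.05 crosstalk floor). Child montage: 4 grids of 4×4 (64
  channels); adult montage: one 8×16 grid (128 channels).
* `α ∈ [0.8, 1.5]` — per-subject envelope–force exponent, covering linear
  and mildly nonlinear EMG–force relationships. Adults draw from the lower
  half U(0.8, 1.15) and children from the upper half U(1.15, 1.5): children
  exhibit systematically different EMG–force scaling than adults, and this
  developmental shift is the domain gap that adult-to-child transfer
  calibration bridges. Without a group-level difference the simulated
  source and target domains coincide and transfer has nothing to correct.
* `carrier` — unit-RMS Gaussian noise band-limited to the analysis band
  (20 Hz to min(500, 0.45·fs) Hz). Rectifying and low-pass filtering a
  channel therefore recovers `gain · w · f^α` up to noise.
* `n` — white noise at a fixed per-channel SNR; the default
  `noise_sd = 10^(−10/20) ≈ 0.316` is 10 dB per channel.
* `shared` — a grid-wide common-mode interference source (cable motion,
  far-field crosstalk, powerline residue) at amplitude `c = 0.35` of the
  clean-signal RMS with near-uniform coupling `m[ch] = 1 ± 0.1`. This term
  is force-independent and is the redundancy the PCA spatial filter removes;
  without it a simulated grid would have no common-mode structure and the
  filter stage would be meaningless (see "PCA spatial filter" below).

Pathologies distort the coupling between neural drive and measured force;
each scales with a `pathology_strength` parameter:

* **tremor** — 5 Hz multiplicative ripple of depth `0.4 · strength` on the
  drive; the measured force carries the mechanically low-pass filtered
  (3 Hz Butterworth, limb mechanics) version, producing the characteristic
  "M"-shaped effort trace. The drive/force mismatch is what elevates
  estimation error.
* **shifted_activation** — the activation bump moves to a different grid
  (proximal compensation); a force-independent tonic drive component
  (`0.35 · strength` mixing fraction, emulating stiffness/abnormal tone) is
  mixed into the modulation, and the compensatory drive carries a slow
  (≤ 1.5 Hz) force-independent wander (`0.3 · strength` relative depth) —
  a remote compensating muscle's activation is inconsistently coupled to
  the output force.
* **coactivation** — a second, wider bump in the same grid, overlapping the
  primary activation, whose amplitude does not follow force
  (`0.5 · strength` of the mean gain).

Cohort generation draws one profile per subject from these ranges,
repetition-level force amplitudes from U(0.5, 0.7) MVC, and is fully
reproducible from a single seed (profiles, amplitudes, carriers, noise).
CP subjects additionally receive a pathology (cycled through the three
types), a MACS-like grade g ∈ {1..4} with strength 0.25 + 0.25·g, and a
symptom-type label tied to the pathology.

What the generator does **not** model: motor-unit action potentials and
recruitment, volume-conductor geometry, electrode-skin impedance drift,
fatigue, or inter-session electrode shift. Passing tests therefore
demonstrate the pipeline's correctness and the direction of group effects
under a controlled coupling model — not clinical performance on real
recordings.

## Preprocessing chain

1. **Channel screening.** A channel is defective when its variance is below
   `1e-12` (flatline), more than 10 % of samples sit at its absolute
   maximum (saturation), or its RMS differs from the median RMS of its
   4-neighbourhood on the grid by more than a factor 5 (gross noise, loose
   electrode). The amplitude test is deliberately *local*: focal muscle
   activation makes strong channels legitimate global outliers on every
   healthy grid, so a global median/MAD rule would flag the activation bump
   itself. Flagged channels are replaced by the mean of their valid
   4-neighbours; a recording with more than 50 % flagged channels is
   rejected as unusable.
2. **Resampling.** Lower-rate sources are upsampled by per-channel linear
   interpolation in time (for one spatial dimension per channel, bilinear
   interpolation degenerates to linear). Downsampling is refused.
3. **Band-pass filtering.** 100th-order Hann-window FIR, 20–500 Hz, applied
   forward–backward for zero phase (phase alignment between envelope and
   force is essential for regression targets). The upper edge is clipped to
   `0.45·fs` so the design stays valid for 1 kHz sources.
4. **PCA spatial filter.** Principal components are computed across
   channels (time samples as observations) and the signal is reconstructed
   without the components of highest and lowest explained variance: the
   highest carries redundant common-mode information, the lowest carries
   measurement noise.
5. **Envelope extraction.** Full-wave rectification, 100th-order 5 Hz FIR
   low-pass (zero phase), then per-channel min–max normalization
   `x' = (x − x_min)/(x_max − x_min)`. A constant channel maps to all
   zeros with a warning. The pre-normalization bounds are retained.
6. **NMF channel optimization.** Multiplicative-update NMF (Frobenius
   objective, seeded nonnegative uniform initialization, rank 2 by default,
   tolerance 1e-5 relative objective change, ≤ 500 iterations; the
   objective is recorded per iteration and is non-increasing by
   construction) decomposes the envelope matrix into activation modes
   (spatial weights) and activation coefficients (time courses). The mode
   with the largest summed coefficient row is the primary activation mode.
   NMF operates on the *de-normalized* envelope: per-channel unit-range
   scaling erases spatial amplitude information and makes every channel
   look equally active, which would randomize channel selection.
7. **Channel selection and collapse.** The top quarter (⌈C/4⌉) of channels
   by primary-mode weight are kept (ties broken toward the lower channel
   index), their *normalized* envelopes averaged with the primary-mode
   weights renormalized to sum to one, and the average re-normalized to
   [0, 1].
8. **Force conditioning and segmentation.** The measured force is smoothed
   with a zero-phase 0.05 s moving average, min–max normalized, and both
   signals are cut into 500-sample windows with a 500-sample step. Each
   window's regression target is the mean normalized force over the window
   (a single scalar; the temporal resolution of the estimate is one window).
   Trailing partial windows are discarded.

Normalization bounds are computed per recording (per repetition); MVC-based
cross-repetition scaling is not modelled.

## Force estimator

Up to three LSTM layers (default 256–128–64 units), each followed by batch
normalization and dropout (default 0.4), then a dense single-output layer
reading the last timestep. Input is the raw 500-sample envelope window as a
univariate sequence. Loss is the RMSE on normalized force; the optimizer is
Adam at learning rate 0.001 with batch size 100, gradient-norm clipping at
5, early stopping on validation loss (patience 20, maximum 300 epochs,
best-validation weights restored). All stochasticity (initialization,
shuffling, dropout) flows from one run seed.

The backend is a self-contained NumPy implementation (float32 by default;
float64 available for gradient checking, and the backward pass is verified
against central finite differences in the test suite). Batch-norm layers
normalize per feature over batch and time; forget-gate biases are
initialized to 1 and the output-head bias to 0.5, the centre of the
normalized force range.

Metrics: RMSE in percent of the normalized force scale,
`RMSE = √(Σ(yᵢ−ŷᵢ)²/N) × 100 %`, and the squared Pearson correlation
`R² = (Σ(xᵢ−x̄)(yᵢ−ȳ))² / (Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²)` between estimated and
measured force.

Data splits: the default 8:1:1 train/validation/test split is drawn at the
window level, mirroring the source-network protocol; a subject-level split
is available (`by_subject=True`) because the window-level split shares
subject identity across splits and overstates subject-independent accuracy.

## Transfer calibration

Strategies: TL1 (transfer all parameters, all trainable), TL2 (freeze the
first LSTM block), TL3 (freeze the first two), non-TL (same architecture,
fresh parameters), and source-only (no calibration). Freezing excludes a
block's parameters from gradient updates *and* pins its batch-norm layers
to running statistics — otherwise running-statistic drift would leak
target-domain information into "frozen" layers. Every array of a frozen
block is bit-identical before and after calibration. Calibration runs a
fixed 50-epoch budget by default, with early stopping only when a
validation set is supplied (the ratio experiments use none).

Harnesses: leave-one-subject-out evaluation (one fold per subject, 9:1
window-level train/validation split within each fold) and the
training:test-ratio experiment (subject-level resampling without
replacement at ratios such as 15:1 … 1:15, 16 resamples per cell by
default). Gesture-specific models are obtained by calibrating once per
gesture label; pooling gestures into a single calibration is available as
an ablation flag.

Calibrating on a *single* subject's handful of windows is the regime where
freezing earns its keep: with all layers trainable the calibrated network
tracks the calibration subject's idiosyncrasies and its cross-subject error
becomes seed-dependent, while freezing the early recurrent layers (or,
alternatively, fine-tuning at a reduced learning rate via the ``lr``
argument of ``calibrate``) confines adaptation to the output mapping and
yields a stable improvement over both the raw source network and fresh
training. The scaled benchmarks therefore calibrate with the
first-layer-frozen strategy on the two-layer scaled network — the analogue
of the most-frozen strategy the full three-layer network uses for its
small-data gestures.

## Deviation-score assessment

A gesture-specific estimator trained on healthy data is applied to a new
subject: each repetition runs through the full preprocessing chain, its
RMSE between predicted and measured normalized force is recorded, and the
subject's deviation score is the mean over repetitions. Group comparisons
follow the grouping's scheme: Mann–Whitney U for two groups (exact
enumeration when the combined n ≤ 12 and tie-free, otherwise the normal
approximation with tie correction), Kruskal–Wallis plus Dunn's post-hoc
pairwise z-tests for three or more. Dunn's adjusted significance level is
0.05/C(k,2) computed exactly (0.0167 for 3 comparisons, 0.00833 for 6;
printed thresholds such as 0.016 are roundings of these). Friedman's
repeated-measures test uses the tie-corrected statistic
`(k−1)·Σ(R_j − n(k+1)/2)² / (Σr²_ij − nk(k+1)²/4)` and returns statistic 0
with p = 1 on a fully tied table instead of dividing by zero. All tests are
two-sided with mid-rank tie handling. A Welch t-test utility covers
interval covariates (e.g., group age).

Mann–Whitney U and Kruskal–Wallis delegate to scipy.stats behind this
module's surface; Friedman and Dunn are implemented here (scipy's Friedman
statistic is undefined on fully tied tables, and no installed package
provides Dunn's test). All four are checked against brute-force
enumeration/permutation oracles in the test suite.

## Problem sizes used in tests and the acceptance script

The packaged benchmarks run scaled-down study conditions chosen so a full
pipeline executes on a single CPU in minutes: 1 kHz sampling, 6 s efforts
(3 s ramp + 3 s plateau), cohorts of 3–4 subjects with 1–2 gestures and 4–6
repetitions, a 32–16-unit estimator, and ≤ 50 training epochs. All other
values (filter orders and edges, window/step 500/500, dropout 0.4, batch
100, learning rate 0.001, NMF rank 2, top-quarter selection) are the
production defaults. At these sizes the held-out window-level RMSE of the
scaled estimator lands in the mid-single digits — the same regime the full
framework targets.

## Numerical choices and degenerate inputs

* Min–max normalization of a constant sequence returns zeros plus a warning
  (envelope channels and force alike).
* `filtfilt` pad length is capped at the signal length for short traces.
* NMF updates guard denominators at 1e-12; an all-zero primary mode raises
  a degenerate-decomposition error.
* Tie-breaks: channel selection prefers lower channel indices; `argmax`
  over mode intensities takes the first maximum.
* RMSE-loss gradient at exactly zero loss is defined as zero.
* Seeds: every public entry point takes an explicit seed; cohort generation
  spawns per-subject seed sequences, and `RunConfig` derives per-stage
  seeds from one top-level seed via SHA-256.

## Known limitations

* The LSTM reads the last timestep of the final layer; with ~500-step
  windows the practical receptive field is shaped by training, and very
  small calibration sets (a handful of windows) can plateau before the
  forget gates learn to integrate long spans.
* The deviation score conflates all sources of mismatch (pathology, poor
  channel selection, electrode placement); it is an abnormality index, not
  a diagnosis.
* Synthetic pathologies are caricatures calibrated to reproduce the
  qualitative group-level directions (patient > control; deviation
  increasing with severity; improvement under reduced severity), not any
  quantitative clinical effect size.
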