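# Methods

## Pipeline

A trial is a fixed-rate (200 Hz) triaxial acceleration recording in g,
labeled fall or ADL by its activity code (F-codes vs D-codes). The
pipeline maps a trial to a scalar score and thresholds it:

    trace -> [Butterworth low-pass] -> feature series C_i[k] -> max -> score
    score > threshold  =>  fall

Sensitivity SE = TP/(TP+FN), specificity SP = TN/(TN+FP) and accuracy
AC = (SE+SP)/2 are computed per held-out fold of a class-stratified
10-fold cross-validation; summaries are mean ± sample std (ddof = 1)
across folds. The arithmetic-mean accuracy makes unbalanced fall/ADL
counts comparable.

### ADC conversion

Raw counts convert to physical units by the two's-complement full-scale
mapping `units = counts * (2*range) / 2**bits` (±16 g over 13 bits:
1/256 g per count). This is the only linear mapping consistent with a
symmetric full-scale span.

### Filtering

4th-order IIR Butterworth low-pass, 5 Hz cutoff, designed as cascaded
second-order sections and applied per axis as a single causal forward
pass with zero initial state. Causal (not zero-phase two-pass) filtering
matches an online embedded detector; the group delay is accepted. The
step response settles below 1e-6 after ~1.1 s; windowed features absorb
the warm-up through their own valid-index rule (first complete window),
with no additional trimming.

### Features

Dynamic features use trailing windows of Nv samples advanced one sample
at a time; defaults are Nv = 1 s, except 0.5 s for C10, C11 and C14.
Integrals are trapezoid over the window. Conventions that were genuinely
open, with the choice made here (alternates stay available as flags):

- **C3** — per-axis peak-to-peak range over the window, combined as a
  Euclidean norm (`c3_variant="magnitude"` gives the range of the
  magnitude signal instead).
- **C4** — kept exactly as printed, `atan2(sqrt(ax²+az²), -ay)`: quiet
  standing reads π. The sign convention is preserved rather than
  "corrected".
- **C5** — standard deviation over the window of the instantaneous
  trunk-tilt angle `atan2(sqrt(ax²+az²), ay)`.
- **C6** — dot product of the mean horizontal (ax, az) vectors over the
  previous and current adjacent windows; it therefore needs 2·Nv samples
  and is valid from k = 2·Nv − 1 (all other windowed features from
  k = Nv − 1).
- **C7** — norm of the full 3-axis difference a[k] − a[k−Nv+1] divided
  by the window time span (`c7_variant="horizontal"` restricts to x, z).
- **C10/C11** — per-axis |a| integrals with dt = 1/fs, normalized by
  N = Nv (units g·s per sample).
- **C12/C13** — magnitude integrals over the sample index (dn = 1,
  units g·samples), as printed, unnormalized. Note these integrate the
  gravity component too, unlike the gravity-removed signal-magnitude-area
  tradition; a sustained lying posture contributes ≈ Nv − 1 g·samples.
- **C14** — 1/N-normalized norm of the horizontal dt-integrals
  (`c14_normalize=False` gives the physical velocity reading).
- Standard deviations are population (divide by N): windows are
  fixed-length signal statistics, not samples from a larger population.

Rolling statistics are computed with O(n) cumulative sums (globally
centred for conditioning) and O(n) min/max filters; tests pin them to a
naive per-window recomputation at 1e-9 relative tolerance.

### Thresholds

The trial statistic is the maximum of the feature series — the statistic
consistent with online threshold-crossing detection and with
per-activity maxima analyses. Decision rule: fall iff score strictly
exceeds the threshold (ties → ADL, since the sensitivity-first threshold
sits just below the minimum fall score).

- **T1 (maximum accuracy)** — exhaustive scan over midpoints of
  consecutive distinct sorted training scores plus outer sentinels; AC
  is piecewise constant between scores, so the scan is exact. Ties
  resolve to the highest-SE candidate, then the lowest threshold.
- **T2 (maximum sensitivity)** — min(training fall scores) −
  1e-6 × score spread; training SE = 1 by construction.

Folds stratify by class at the trial level (the protocol's stated
stratification); subject-grouped folds are available via the manifest
for leakage-sensitive use.

## Synthetic data

The generator produces class structure, not biomechanics: parametric
closed forms (sinusoids, raised cosines, half-sine spikes) plus Gaussian
sensor noise (sd 0.02 g) and 13-bit ±16 g quantization. All randomness
comes from one root seed; each trial uses a child seed derived by trial
index, so datasets are reproducible and order-independent.

Waveforms (defaults in parentheses; every range is drawn uniformly
per trial):

- **Postures** — constant gravity vector: standing (0, 1, 0); lying
  supine (0, 0, 1), prone (0, 0, −1), lateral (±1, 0, 0).
- **Gait** — gravity + fundamental-plus-second-harmonic sinusoid,
  vertical-dominant with a 0.2–0.5 horizontal share: walk 1.4–2.2 Hz at
  0.10–0.30 g, jog 2.4–3.4 Hz at 0.40–0.80 g, consistent with waist
  accelerometry of level walking and jogging.
- **Sit** — raised-cosine transient (capped at 2 g) over 1–2 s.
- **Jump** — near-zero-magnitude flight of 0.15–0.30 s, then a landing
  half-sine spike of 1.5–3 g, mostly vertical.
- **Fall** — pre-fall activity (walk/jog/stand/sit, 5–8 s), then a
  critical phase of 0.3–0.5 s: gravity magnitude ramps down to a drawn
  free-fall dip level (0–0.3 g), followed by a 60 ms impact spike of
  2.5–9 g oriented by fall direction (forward +z, backward −z, lateral
  ±x) whose peak sample has exactly the drawn magnitude (before noise
  and quantization); then a slow 1–2 s settling rotation into the lying
  posture. Waist-impact peaks of hard falls on firm surfaces span
  roughly 2.5–10 g in the fall-biomechanics literature; the settling
  time reflects that bodies do not rotate into their rest posture within
  the critical phase. ADL and fall durations follow the recording
  protocol (falls 15 s; walking/jogging 100 s; sit/jump 12 s).
- **Elderly cohort** — one multiplicative factor (default 0.7) on every
  dynamic (non-gravity) component, modeling the lower movement
  amplitudes of older participants as a pure amplitude shift. The 0.7
  default is a free parameter exposed in the config.

### What the generator does and does not emulate

It reproduces the statistical contrasts the threshold analysis needs:
high-impact falls vs periodic/transient ADLs, overlap between vigorous
ADLs and weak falls, an amplitude-shifted cohort, sensor noise and
quantization. It does **not** include trunk-tilt or lying ADLs (lying in
bed, bending, car transfer), per-subject anthropometry, real fall
kinematics, or gyroscope signals (emitted as zeros). Consequences worth
knowing:

- Because only falls end lying, orientation-plateau features (C2's 1 g
  lying floor; C12/C13's gravity integral) separate classes partly
  through posture alone, an unscaled signal. Their cross-validated
  accuracies are therefore optimistic relative to real recordings, and
  their sensitivity does not respond to the elderly amplitude scaling —
  the cohort-transfer sensitivity drop manifests in the amplitude-driven
  features (C3, C8, C9), while the downward threshold shift appears in
  all of them.
- Passing tests show the pipeline is correct and that known directional
  effects (filter behavior, cohort shift, T1/T2 trade-off) are
  reproduced; they do not certify performance numbers on real data.

## Experiment sizes and numerics

Experiments and the acceptance script use 200 ADL + 100 fall trials per
cohort at protocol durations (~2.6 M samples per cohort) — large enough
for stable fold metrics, small enough for interactive runs. Degenerate
inputs are errors, not silent defaults: empty feature series, one-class
training sets, folds larger than a class, and metrics with an empty
denominator class all raise. Thresholds are finite by construction;
equal-score ties classify as ADL everywhere.

## Known limitations

- Real-recording headline numbers (e.g. per-feature accuracies and
  printed threshold values) require the external dataset; the package
  reproduces the pipeline and its qualitative behavior, not those
  numbers.
- The printed formulas for C3, C5, C6, C7 and C14 in the source tables
  are typographically ambiguous; the interpretations above are
  documented choices, each with the alternate reading behind a flag.
- The 11 Hz minimum-sampling-rate observation for filtered features is
  discussed here only: the package performs no resampling.
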