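# Methods

## Problem setting

Depth of anesthesia is a latent sedation state inferred from the EEG. As
propofol deepens sedation the EEG becomes slower and more regular: slow-band
power rises, fast-band power falls, and complexity measures (entropies)
decrease. Bedside monitors condense this into a 0–100 index (100 = awake).
The package implements (a) the classical single-channel indices used for
this purpose, (b) a protocol for comparing candidate indices against a
reference depth series by correlation, and (c) a small convolutional
regressor that fuses all indices plus demographics into a learned depth
estimate, evaluated per anesthesia phase.

## Signal model and preprocessing

Input is single-channel EEG in microvolts. Defaults: sampling rate 125 Hz,
epoch length 500 samples (4 s, the typical monitor update cadence),
band-pass 0.5–47 Hz (Butterworth order 4, applied forward–backward so epoch
timestamps stay aligned). The band covers every spectral feature used
downstream while excluding mains interference; all three values are
configurable, and none is claimed to be the only defensible choice — 4 s
epochs at 125 Hz simply make the canonical N = 500 entropy window an
integral number of seconds. Epochs are non-overlapping by default.

NaN samples are rejected at ingestion. No artifact rejection beyond the
band-pass is attempted (EMG, electrocautery and movement artifacts in real
recordings are out of scope).

## Per-epoch indices

- **Sample entropy** (m = 2, r = 0.2 × epoch SD, N = 500): Chebyshev
  distance, self-matches excluded (the Richman–Moorman convention). Both
  template lengths are counted over the same N − m start points so the
  ratio is a conditional probability. When either count is zero the value
  is undefined (NaN) rather than infinite.
- **Permutation entropy** (m = 4, τ = 1): ordinal patterns by stable
  argsort (ties broken by position), Shannon entropy normalized by
  log(m!), so the value lies in [0, 1] regardless of log base. The sign is
  chosen so the result is nonnegative.
- **Wavelet entropy** (db4, 5 levels): Shannon entropy (natural log) of
  relative scale energies over the 5 detail scales plus the final
  approximation (J = 6 scales, so S ∈ [0, log 6]). The decomposition uses
  periodization mode, which keeps the transform orthogonal: scale energies
  then partition signal energy exactly and the relative energies sum to 1
  to machine precision.
- **Band ratios**: log10 power ratios on Welch PSDs. The (β−α) ratio uses
  the 6–12 / 11–21 Hz bands as published even though the β ratio uses
  12–21 Hz; the 12–21 variant is selectable (`SpectralBands.bma_den`).
  A zero denominator yields NaN, not an exception, because a silent band
  in one epoch should not abort a batch run.
- **MPF / SEF95**: 50% / 95% quantiles of the cumulative PSD on
  (0, 47] Hz, linearly interpolated between bins.
- **Surrogates**: ApEn, SFS and SpEn are named in the monitoring
  literature without public defining formulas. They are implemented as
  documented stand-ins — standard approximate entropy (self-matches
  included), log10 of broadband (0.5–47 Hz) over fast-band (40–47 Hz)
  power, and the Shannon entropy of the normalized PSD on (0, 47] Hz —
  and flagged `surrogate=True` in the schema so downstream users can
  exclude them.

PSD estimation uses Welch (Hann window, segment length min(N, 256), 50%
overlap). Oracle tests recompute band powers with an independently written
Welch; the estimator choice cancels in ratios only to the extent both bands
use the same estimator, which they do.

### Indicator schema

The regressor needs 48 indicators per epoch. The named indices above give
11; the remainder is filled with quantities a practitioner would recognize:
log and relative power in six sub-bands (delta through gamma), extra
permutation-entropy orders (3, 5, 6), SampEn at m = 3, the six wavelet
relative energies, SEF90, peak frequency, spectral centroid and bandwidth,
Hjorth activity/mobility/complexity, zero-crossing rate, RMS amplitude,
line length and kurtosis — 44 EEG indicators plus height, weight, age and
sex. The order is fixed by `feature_schema` and shared by feature tables
and sample images. Undefined values (flat epochs, empty bands) are imputed
with the per-subject column median, 0 if a column is entirely undefined, so
tables carry no NaN.

## Sample images and splits

The 48 indicators of 12 consecutive epochs are concatenated oldest-first in
schema order into a 576-vector and reshaped row-major to 24×24. The
regression target is the reference depth at the window's **final** epoch —
a causal choice matching the monitoring use case. Features are z-scored per
indicator with statistics from the training subjects only; the same
statistics are applied to validation and test (leakage guard). Splits are
always by subject; the published cohort proportions 61/16/16 of 93 are
scaled to smaller cohorts, and the full 61/16/16 split is exercised
directly on 93 subject ids.

Whether the published 576-vector spans 12 periods or repeats indicators
within one period is not stated in the source material; the 12-period
reading is this package's declared default (periods_per_sample is
configurable subject to indicators × periods = 576).

## The regressor

Layer stack (one 1×24×24 input):

| layer | kernel | stride | pad | output |
|---|---|---|---|---|
| conv1 + ReLU | 3×3 | 1 | 1 | 16 × 24×24 |
| max-pool | 2×2 | 2 | – | 16 × 12×12 |
| conv2 + ReLU | 3×3 | 1 | 1 | 32 × 12×12 |
| max-pool | 2×2 | 2 | – | 32 × 6×6 |
| conv3 + ReLU | 3×3 | 1 | 1 | 64 × 6×6 |
| max-pool | 2×2 | 2 | – | 64 × 3×3 |
| self-attention | – | – | – | 64 tokens × 9 |
| flatten | – | – | – | 576 |
| residual FC | – | – | – | 576 |
| dense + sigmoid×100 | – | – | – | 1 |

The published layer table stops after the third pool and resumes at the
output layer; the intermediate block here — attention over the 64
three-by-three maps treated as 9-d tokens, then one residual fully
connected block — is this package's design choice, and both blocks can be
disabled (`attention=False`, `residual=False`). Attention is the standard
scaled dot-product form `softmax(QKᵀ/√d_k)V` (d_k = 9). The residual block
is `H(x) = x + W₂ relu(W₁x + b₁) + b₂` with W₂ initialized near zero so
the block starts close to the identity.

The head squashes a linear score through sigmoid×100, guaranteeing
predictions in [0, 100]. A softmax-over-depth-bins head (51 bins,
cross-entropy loss, prediction = expectation over bin centers) is provided
as an alternative for users who want a distributional output.

Training: mean-squared error, plain SGD at learning rate 0.01, minibatch
32, all randomness from one seed (bit-reproducible). One addition to plain
SGD: gradient global-norm clipping at 10. On the 0–100 target scale the
first few batches otherwise produce steps large enough to saturate the
sigmoid head; clipping bounds the step without changing the steady-state
dynamics. Validation accuracy (fraction of predictions within ±10 depth
units — "accuracy" for a regression needs a tolerance, and ±10 is roughly
the width of a clinical sedation band) and RMSE are checkpointed every 30
iterations. `train_model` runs subject-level k-fold cross-validation
(default 5) with a (periods × iterations-per-period) schedule, e.g. 3×57 =
171 iterations.

Everything is implemented directly in numpy with hand-written backward
passes; gradients are verified against central finite differences in the
test suite.

### Autoencoder pretraining

A linear autoencoder (encoder/decoder weight pair) trained by alternating
least squares is provided for optional dimensionality analysis of the
576-d samples. Each ALS step solves one factor exactly, so the
reconstruction error is monotonically non-increasing; on data lying exactly
in a k-dim subspace with code_dim = k it reaches machine-precision
reconstruction. It is not wired into the default training path — whether
pretraining was part of the original training recipe is unknown, and the
regressor trains fine without it.

## Evaluation

R² = 1 − SSE/SST, RMSE = √(Σ(obs−pred)²/n), MAPE = mean |obs−pred|/obs ×
100, and accuracy-within-±10, each reported per phase (induction /
maintenance / recovery) and overall. The RMSE formula sometimes printed in
this literature, Σ(eᵢ−ē)/n with no square or root, is identically zero for
any residual vector; the standard definition is used. R² of a
low-variance segment (the maintenance plateau) is routinely near or below
zero even when absolute errors are small — RMSE and accuracy are the
informative columns there. Overall SSE equals the sum of per-phase SSE,
which the tests assert in place of any (false) claim that overall R² lies
between the per-phase values.

## Synthetic cohorts

The generator emulates the *structure* the method needs, not propofol
pharmacology:

- latent depth: sigmoid fall (awake ≈ 92 → deep ≈ 32) over the induction
  phase, plateau with slow sinusoidal wander (±3) over maintenance,
  sigmoid rise over recovery; default 120 s per phase;
- EEG: three unit-variance band-limited Gaussian components (0.5–4, 6–12,
  15–42 Hz). Log10 gains of the slow and fast components are linear in
  depth with opposite signs (total swing 1.6 decades across the full
  depth range) — the simplest monotone spectral link consistent with how
  the band ratios are used clinically;
- regularity: the fast component is smoothed by a time-varying one-pole
  filter whose coefficient grows as depth falls (0.85 at maximum depth),
  lowering sample/permutation entropy at depth;
- reference series: latent depth + Gaussian observation noise (SD 3),
  clipped to [0, 100] — standing in for the monitor output being
  regressed;
- demographics: uniform draws within the published cohort ranges (height
  158–180 cm, weight 54–93 kg, age 22–83 yr, male fraction 0.73).

What the generator does **not** model: burst suppression at very deep
anesthesia, EMG and electrocautery artifacts, inter-subject spectral
variability beyond the seed, drug PK/PD dynamics, and any nonmonotone
depth–spectrum relationships. Consequently, passing pipeline tests show
the machinery is correct and the learning problem is solvable when the
monotone spectral contract holds; they do not certify clinical
performance, and the published clinical correlation/accuracy tables are
deliberately not reproduced.

Default problem sizes (12 subjects for pipeline runs, 120 s per phase,
171 training iterations) were chosen so a full end-to-end run completes in
a few minutes on a single CPU while leaving comfortable statistical margin
on the pipeline's standing property (held-out R² ≥ 0.7 and the trained
model out-ranking every single index in mean |COR|).

## Numerical choices and degenerate inputs

- Correlation of a constant series is NaN (undefined), never ±1.
- Correlation-band boundaries (0.8 / 0.5 / 0.3) assign to the lower band.
- Feature/reference alignment is a nearest-timestamp join; subjects whose
  worst gap exceeds a tolerance (default 2 s) are skipped with a warning.
- Sample-entropy and permutation-entropy ties: Chebyshev comparisons use
  ≤ r; ordinal ties break by position (stable sort).
- Epoch windows that do not fill N samples are discarded, never padded.
- The EDF writer quantizes to 16 bits over the per-file physical range;
  round-trip error is bounded by (range / 65535)/2.

## Known limitations

- The 44-indicator EEG schema beyond the 11 named indices is a curated
  default, not a canonical list; results depend on it only through the
  regressor, which is retrained per cohort anyway.
- The attention/residual placement between pool-3 and the output is one
  of several defensible readings of the architecture; both blocks are
  switchable for ablation.
- Training uses plain SGD by design fidelity; convergence on hard real
  cohorts would likely benefit from momentum or Adam, which are
  deliberately not provided.
- The synthetic generator's monotone depth–spectrum link makes the
  learning problem easier than clinical data; reported synthetic metrics
  overstate what any method would achieve on real recordings.
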