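# Methods

This note records the models, conventions and numerical choices behind the
package, the places where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real recordings.

## Containers and conventions

Epochs are trials × channels × samples arrays sampled at `fs` (512 Hz by
default) with sample 0 at `t_start_ms` (−100 ms), so sample *k* lies at
`t_start + k/fs·1000` ms and a −100…+700 ms epoch holds
`round(0.8·fs) = 410` samples. Two window conventions coexist deliberately:

* **half-open `[start, end)`** for baseline windows and the sliding decoding
  windows — a 40 ms window at 512 Hz holds `floor(0.040·fs) = 20` samples;
* **inclusive endpoints** for ERP component windows (peaks "from 50 to
  150 ms") and for channel-wise temporal-decoding periods, where a
  `d`-ms period holds `floor(d·fs/1000)+1` samples (31 samples for
  80–140 ms at 512 Hz).

On-disk epochs are a raw float64 payload plus a JSON sidecar; round trips
are bit-exact, and a missing/inconsistent sidecar is a format error rather
than a guess.

## Ratings and labels

Each image is rated twice per dimension on a 1–9 scale. The two
presentations are combined by the arithmetic mean rounded half-up — the
combination rule was an open choice; the mean is deterministic, order-free
and unbiased. Combined ratings map to three increments (1–3 → low/present,
4–5 → medium/intermediate, 6–9 → high/future). Increments are coded 1/2/3
as the SVR regression target, and planted effects scale with
`increment − 2`, making "medium" the neutral level. A participant ×
dimension with fewer than two distinct increments, or with fewer than
`min_trials = 16` trials in its smallest increment (the smallest retained
count in comparable studies), is excluded for that dimension.

## Montage

The 64-channel 10-10 montage is constructed geometrically on an idealized
unit sphere rather than embedded as a numeric table: Cz at the apex, the
equator through Fpz/T8/Oz/T7, 22.5° per 10% arc step, and interior
electrodes (F3, CP1, …) on equal-arc subdivisions of the circle through
their row anchors (F7–Fz–F8). P9/P10/Iz sit 22.5° below the equator. The
construction is deterministic, left-right mirror-symmetric, and puts every
electrode exactly on the unit sphere — which is what the CSD operator
actually needs; no claim is made that it reproduces any manufacturer's
digitized positions.

## Current source density

The surface Laplacian uses the spherical-spline formulation: kernels
`g`/`h` as Legendre series with exponents `m` and `m−1`, evaluated by
Clenshaw recurrence (`numpy.polynomial.legendre`); spline coefficients from
the regularized, zero-sum-constrained solve `(G+λI)c + c₀1 = v, Σc = 0`;
CSD = `H c / r²` in µV/cm². Defaults m = 4, λ = 1e-5, N = 50 Legendre
terms, head radius 10 cm — the de-facto standard parameterization; the
N = 50 series tail (reported per operator build) is ~5e-10. The operator is
a fixed channels × channels matrix: linear, annihilates constants (hence
reference-free), permutation-equivariant, and shrinks to zero as λ → ∞.

Validation uses the Laplace–Beltrami eigenfunction property: a degree-l
surface harmonic must map to `l(l+1)/r²` times itself. On a full-sphere
64-point Fibonacci montage the relative error at the defaults is ~3.8%
(≤ 5%). On the scalp montage the property holds to ~1.4% at electrodes
above 30° elevation but degrades to ~10% overall because the rim
electrodes sit at the boundary of the sampled cap, where any surface
Laplacian estimate extrapolates — an intrinsic edge effect, not a solver
artifact, and the reason the eigenfunction check is defined on the
full-sphere montage.

## Filters

Zero-phase (bidirectional) IIR: a 50 Hz notch (Q = 35) and, on the
ERP-component path only, a 4th-order 30 Hz Butterworth low-pass (≥ 20 dB
at 60 Hz after bidirectional application). Decoding runs on non-low-passed
CSD epochs. Zero-phase filtering protects component latencies; the exact
orders were open choices and are configurable. Baseline correction and the
filters commute only up to the filters' passband ripple and edge handling
(~1e-5 for unit-amplitude band-limited signals, tested as such); the exact
property is linearity plus unit DC gain, which is tested at 1e-6.

## Decoding

Per window, features are all channel × sample amplitudes (channel-major
order). Each analysis is one fold of a `folds`-fold cross-validation:
trials are partitioned into equal bins anew per repetition, an ε-SVR
(linear kernel, C = 0.1, ε = 0.1 — LIBSVM's `-s 3` default ε; only C was
prescribed) is fit on the training bins and correlated with the truth on
the held-out bin. Design choices made here, all configurable:

* **per-fold r, then Fisher-Z, then average** (rather than pooling
  predictions across folds);
* **feature z-scoring with training-set statistics**, on by default
  (LIBSVM practice varies and the choice was unstated);
* **r := 0 for zero-variance predictions or truths** in a fold — a constant
  predictor carries no label information, and an undefined correlation
  would otherwise poison the average (guarded at relative tolerance 1e-10);
* **null labels permuted afresh per analysis** (per fold × repetition, per
  window, per participant) — the stricter reading of "shuffled labels for
  each participant and each analysis time window";
* **one-sided paired group t-tests** (empirical > null), since the
  hypothesis is above-chance prediction; two-sided available;
* **default span 0–440 ms** (centers 20–420 ms): the sliding analysis is
  described over the first 400 ms but results are also reported at a 420 ms
  window; the span is configurable and the period aggregates (full span,
  centers 20–200 ms, 220–400 ms) keep their stated definitions regardless.

A single master seed fixes balanced selection, fold partitions and label
shuffles; reruns are bit-identical.

Channel-wise temporal decoding takes the *sample-range union* of the
selected windows (not a concatenation of overlapping window vectors) as a
single per-channel feature vector — the union avoids duplicating shared
samples.

## Repeated-measures ANOVA

The one- and two-way fully-within decompositions are computed directly
(each effect against its subject × effect error term). Greenhouse–Geisser
ε is Box's estimate from the double-centered condition covariance, clipped
to `[1/(k−1), 1]`; sphericity is checked per effect with Mauchly's test on
the contrast-projected covariance (first-order χ² approximation), and the
GG-corrected p is adopted when Mauchly rejects at .05 — both raw and
corrected p are always reported. All-equal cells yield F = 0, p = 1 with a
degenerate flag. The implementation is cross-checked against pingouin in
the test suite. Peaks are sample-wise extrema (no interpolation), ties to
the earliest sample; the N2 is measured as a negative peak by symmetry with
the N1, its stated window not repeating the polarity.

## Synthetic data

The generator reproduces the experiment's structure exactly: 24 images ×
3 repetitions × 6 blocks = 432 trials, per-block randomized image order,
and 3/4/5 s jitters as an exact 25/50/25% multiset (shuffled), so the
printed counts are deterministic. Ratings come from latent bivariate
Gaussians with target between-dimension correlation ρ (the shared
image-level component is set to ρ exactly so per-participant sample
correlations center on the target), a participant-agreement share of 0.5,
rank-based discretization to 1–9 (order-preserving, full scale coverage at
≥ 9 images) and ±1 presentation noise at rate 0.3.

Epochs are a deterministic shared ERP template (generic fronto-central
negativity ~110 ms, parietal negativity ~220 ms, broad parietal positivity
~400 ms) plus, per effect, a raised-cosine envelope × Gaussian spatial
profile (normalized to max 1) × `slope · (increment−2)`, plus noise:
spatially correlated 1/f noise (squared-exponential kernel of chordal
distance — positive definite on the sphere, unlike its geodesic variant —
RMS 10 µV), a 50 Hz sinusoid (2 µV, random phase per trial), stereotyped
frontal blinks (Poisson rate 0.1/trial, 80 µV, 300 ms), and an exact
`round(fraction·n)` subset of trials with planted ±300 µV artifacts that
the strict ±200 µV screen must catch. Epoch generation is linear in the
effect slope by construction. Defaults are exercise parameters: the
original recordings' noise spectra and effect sizes are not characterized
anywhere, so slopes are chosen to make decoding succeed clearly at 2× noise
RMS without being trivial.

What the generator does **not** emulate: volume-conducted sources
(no forward model), non-stationary or heavy-tailed noise, eye-movement
residuals after ICA, or inter-individual montage variation. Passing tests
therefore establish the pipeline's statistical behavior (calibration,
recovery, determinism, oracle agreement), not decoding performance on real
EEG.

Stimulus images are 512 × 384 RGB noise fields whose chosen low-level
feature (channel means, ratios, luminance statistics or mean spatial
frequency) is driven to a target correlation with rating-like scores;
uint8 clipping and discretization leave residual noise, so recovered
correlations are compared at generous margins. Mean spatial frequency is
the amplitude-weighted mean radial frequency of the 2-D DFT, DC excluded,
in cycles/pixel (the normalization was unstated; cycles/pixel is the
resolution-free choice). Luminance is Rec. 601 (0.299R + 0.587G + 0.114B);
channel ratios divide channel *means* (0/0 flagged undefined, never
fabricated). The multiple regression uses all 11 predictors by default —
F(11, 12) at 24 images — with a collinearity-pruning option; published df
for this design are inconsistent with 11 predictors, and the package
surfaces rather than imitates that.

## Simulation studies (validation module)

* **Null calibration**: 500 simulated null sessions of 8 participants,
  5 windows, 5 folds × 2 repetitions, 8 posterior channels, 8 trials per
  increment at 256 Hz — sizes chosen so the full study runs in minutes on
  one CPU while still using the complete decode-and-test path. The
  window-wise rejection rate must be 5% ± 2%.
* **Effect recovery**: 10 seeded studies of 6 participants with a
  2×-noise-RMS effect planted at the middle window on two channels;
  requires ≥ 90% detection at overlapping windows, localization within one
  window step, ≤ 10% significant windows far from the effect, and the
  channel map peaking on a planted channel.

## Known limitations

* ICA blink removal is treated as an upstream black box; the screens and
  the blink generator exercise the surrounding logic only.
* The CSD eigenfunction tolerance applies on full-sphere sampling; scalp
  rim electrodes carry irreducible edge error (documented above).
* Group inference is uncorrected across windows by design (window-wise
  tests plus period aggregates); no multiple-comparison correction is
  offered as a contract.
* The montage is idealized; users with digitized positions can supply
  their own `ElectrodeMontage`.
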