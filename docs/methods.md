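# Methods

## Interval consonance model

A two-tone interval with crown-to-root frequency ratio p:q (coprime,
within one octave) shares its first overtone at the p-th partial of the
root and the q-th partial of the crown. The consonance coefficient is
K = 1/(m·n) with (m, n) = (p, q); because K spans three orders of
magnitude across the 13 common intervals, it is expressed on a decibel
scale, Ip = 20·log₁₀(1000·K), which places the unison at 60 dB and the
minor second near 12 dB.

Equal-tempered intervals are irrational (2^(k/12)) and share no partials
exactly, so their index is the just-intonation index of the *similar*
just interval minus a detuning penalty. The deviation δ (integer cents,
computed from the nearest-integer just cents, ties away from zero)
corresponds to a frequency ratio η = 2^(δ/1200); treating the shared
partial as a resonator with quality factor Q, the off-resonance relative
amplitude is

    A = (1 + Q²·(η − 1/η)²)^(−1/2),   −ΔI = 20·log₁₀(A) ≤ 0,

and I = Ip + (−ΔI). The square root in A is the standard second-order
resonance response; the package also exposes a `literal_amplitude` variant
without the root (which exactly doubles the dB penalty) for comparison,
but the default is the resonance form because only it reproduces the
conventional tabulated corrections (−0.22 dB at δ=2, −4.5 dB at δ=12)
within a quarter of a decibel.

Defaults: Q = 100. Just ratios per interval are the conventional ones
(P1 1/1, m2 16/15, M2 9/8, m3 6/5, M3 5/4, P4 4/3, A4 64/45, P5 3/2,
m6 8/5, M6 5/3, m7 16/9, M7 15/8, P8 2/1) and are user-overridable via a
YAML table, since published tabulations of this quantity are not always
internally consistent (two commonly printed rows, M2 and A4, imply
m·n values that match no small-integer ratio). Category letters A–E
("very complete" … "very incomplete" consonance) are a fixed lookup by
interval name — no numeric cut-points on I are defined. All dB math is
kept in full precision; half-up rounding to 2 decimals is applied only
when rendering tables.

## Ratings and reliability

Ratings are a complete subjects × materials × attributes grid of integer
1–5 scores; missing cells are rejected, not imputed. Cronbach's alpha is
computed with subjects as the k "measurement items" and materials as the
averaged-over items:

    α = k/(k−1) · (1 − Σᵢ σᵢ²/σₓ²),

σᵢ² the variance of rater i's scores over materials and σₓ² the variance
of per-material totals. The variance ddof is configurable but
inconsequential: the (N−1)/N factor cancels between numerator and
denominator, so sample and population conventions give identical alpha.
Attributes with α < 0.7 (the conventional floor) are flagged. The
per-material attribute vector F is the plain across-subject mean.

## Matching aggregation

Each subject contributes ranked triples (first/second/third pick) per
interval and polarity (matched / mismatched). Before aggregation, all
records in the color categories with the minimal positive selection count
are removed (ties removed jointly) — a least-frequency outlier rule. Two
degenerate cases skip pruning with a logged warning: a uniform histogram
(removal would be arbitrary or total) and a pruning that would leave a
rank with no survivors, which would make the rank-weighted value
undefined.

The published weighting (3·C₁ + 2·C₂ + C₃)/6 is written for one material
per rank; with many subjects a consensus rule is needed. Default: the
per-rank mean across surviving picks, then the 3:2:1 weights (this
commutes with the single-subject formula); a mode-based consensus
(attribute value of the modal material per rank, lowest id on ties) is
available as an option. Repeated stimulus presentations are recorded
under the same interval id with an `is_repeat` flag and pooled with their
originals by default, which is equivalent to averaging them in before the
per-rank mean.

## Correlation analysis

Each interval class yields a 13-row table pairing I with the 16
aggregated attribute columns; Pearson r with a two-sided t-based p is
computed per column (n = 13). Strength bands on |r|: ≥ 0.8 strong,
[0.5, 0.8) medium, [0.3, 0.5) weak, < 0.3 none. Raw p-values are reported
by default; Benjamini–Hochberg adjustment is strictly opt-in, never
silent. The scatter/fit export emits the 13 points and the OLS line,
not rendered figures.

## Prediction models

Directions: audio (8 attribute means → I) and visual (I → one attribute).
Families and defaults:

- **MLR** — OLS; the standalone `mlr_fit` solves the normal problem by
  least squares with an explicit rank check that names collinear columns.
- **SVR** — RBF kernel exp(−γ‖x−y‖²), γ = 0.01, C = 1.0, ε = 0.1.
- **RF** — 100 bootstrap-bagged regression trees, seeded.
- **BP** — one hidden layer of 4 logistic units, linear output, trained
  with full-batch gradient descent (learning rate 0.05, ≤ 2000 epochs) on
  standardized inputs; standardization is required for stable convergence
  at this width.

Evaluation: 10-fold cross-validation (seeded shuffle, contiguous
near-equal folds, each fold tested once), with the out-of-fold
predictions pooled and scored by Pearson r, MAE and RMSE, after which the
model is refit on all data. r is additionally reported rescaled to [0, 1]
as (r + 1)/2 — an arbitrary but documented convention; the raw r is always
reported alongside. Constant predictions leave r undefined (reported as
null) while MAE/RMSE remain valid. Hyperparameter search is two-stage:
random sampling over the family's ranges (log-uniform across decades),
then a small per-parameter grid bracketing the stage-1 optimum, selecting
on cross-validated r; deterministic under a fixed seed.

Nine previously published linear equations relating piano-interval
consonance to color attributes are bundled verbatim (ids 15–23) as fixed
reference predictors.

## Synthetic-data generator

The generator emulates the study design: 50 three-color materials in 16
categories, 16 rating subjects, 23 matching subjects, 52 stimuli (13
interval relations × piano/violin × harmonic/melodic) plus 12 repeated
presentations.

- **Materials** — category attribute centers ~ U(1.5, 4.5) per attribute;
  material profiles scatter around their center with sd (1 − ρ), clipped
  to [1, 5]; CIELAB triplets are drawn uniformly within gamut and carry no
  perceptual meaning (no claim of colorimetric realism).
- **Ratings** — score = clip(round(true + N(0, (1 − ρ)·σ₀)), 1, 5) with
  σ₀ = 1. The consistency default ρ = 0.8 keeps every attribute's alpha
  comfortably above the 0.7 reliability floor, matching the regime the
  analysis assumes; ρ = 1 makes subjects identical.
- **Matching** — the planted target profile is g_d(I) = 3 + b_d·(I − Ī)
  with slopes b_d = ∓0.03 attribute-units per dB (negative for all
  attributes except pleasure, mirroring the qualitative pattern the
  analysis is designed to detect) for the piano classes and b_d = 0 for
  the violin classes, so violin correlations are null by construction.
  Matched picks are 3 distinct materials drawn with probability
  ∝ exp(−‖F − g‖²/τ), τ = 0.5, ranked by proximity; mismatched picks come
  from the complementary tail (∝ exp(+‖F − g‖²/τ), ranked by remoteness).
  As τ → 0 the rule degenerates to the deterministic extreme-3 choice.
  A per-pick lapse probability of 0.02 substitutes a uniformly random
  material, which injects the rare singleton categories the pruning rule
  removes.

What the generator does *not* emulate: real inter-attribute correlation
structure of color perception, response times, order/fatigue effects, and
any colorimetric link between the CIELAB values and the attribute
profiles. Passing pipeline tests therefore demonstrate correctness of the
computations and recoverability of a planted linear effect at study size —
not claims about human observers. One consequence of the shared 8-dim
choice rule over a finite material pool is that individual attributes can
recover the planted drift with flipped sign (attribute profiles of the 50
materials are spuriously correlated), while the strength of recovery is
robust; tests therefore assert magnitude, and sign only in aggregate.

With 13 points per correlation, a perfect null still yields |r| values on
the scale 1/√12 ≈ 0.29, so null-preservation is asserted statistically
(mean signed r near zero, mean |r| near the null expectation and well
below the planted-effect classes), not as a per-run threshold.

## Problem sizes and determinism

All stochastic components (generator, fold shuffling, forest and network
initialization, hyperparameter sampling) consume explicit seeds and are
bit-reproducible. The bundled multi-seed checks use 6–20 generator seeds
at the full study size (a few seconds per study), which is sufficient to
separate the planted piano effects from the violin null at the asserted
margins.
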