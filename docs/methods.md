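# Methods

## Signal processing

Raw input is one tri-axial series per wrist in units of g (m/s² accepted and
divided by 9.80665 on read), with a constant sampling rate; relative timing
jitter above 1% of the median step is rejected rather than resampled. NaN
samples are rejected by default; an optional repair interpolates gaps up to
0.2 s for device dropouts.

Gravity is removed per axis with a zero-phase (forward–backward) Butterworth
high-pass, order 4, cutoff 0.25 Hz — the standard choice for wrist-worn
accelerometry of voluntary movement: slow postural drift and the static 1 g
offset fall well below 0.25 Hz while gesture content (≈ 1–8 Hz) passes
essentially unattenuated. A filter-free alternative, |‖a‖ − 1 g|, is kept for
cross-checks. The movement-intensity signal is the Euclidean norm of the
filtered axes.

Epochs are half-open windows of 1 s (configurable) cut from each task window;
the trailing partial epoch is dropped rather than padded, which would bias
epoch means. An arm is *active* in an epoch when its mean magnitude reaches
0.01 g. That threshold has to exist for "active second" to be defined; 0.01 g
sits a factor ≈ 3 above the epoch-mean noise floor of a 2 mg-RMS sensor, so
quiet seconds are not promoted to activity by noise alone. All thresholds are
carried in a config object whose fingerprint is stamped into every metric row.

## Gesture measures

Movement bouts are maximal suprathreshold runs of the magnitude signal
(default 0.05 g) lasting ≥ 0.25 s after merging sub-threshold dips shorter
than 0.25 s. The count is threshold-dependent by construction, which is why
the laterality analysis rests on the MMR instead; the defaults are exposed,
not buried.

The per-second log magnitude ratio is computed as log m_np − log m_p (not the
log of the quotient) so that exchanging the arms negates every ratio — and
hence the MMR — *exactly* in floating point. Seconds where only one arm is
active receive ±7, following the capped-ratio convention of bilateral
arm-use accelerometry; bilateral ratios are clipped to the same bound. An MMR
is only reported when at least 10 active seconds exist; otherwise the metric
is flagged missing with a reason, never silently zeroed. Two companion
indices (active-second use ratio; magnitude laterality index in [−1, 1]) are
provided as simple threshold-free alternatives; they are this package's own
stand-ins, not reimplementations of any published variant.

The MMR is computed over all task windows pooled (per-window values are
available through the epoch series). Both a ratio cap and the minimum-epoch
rule are configurable.

## Questionnaire scoring

Functional use: mean PAL item response normalised to [0, 1]; up to 20%
missing items are tolerated (excluded from the mean), more flags the score
missing. Embodiment: arithmetic mean of exactly five −3..+3 ratings; group
boundary strictly at 0 (a score of exactly 0 is neutral/negative). The
daily-use composite averages within-cohort z-scores of wear hours and the PAL
score because the two components have incommensurate units; a rank-based
composite is available, and every Spearman analysis downstream is invariant
to that choice when both components enter monotonically. A degenerate
(zero-variance) component is dropped with a warning. The control item ("it
seems like I have three hands") flags possible non-engagement when its
response exceeds −1.

## Statistics

* **Spearman**: Pearson correlation of mid-ranks; p from the t approximation
  on n − 2 df, exact permutation p available for n ≤ 10.
* **Mann-Whitney U**: U for the first sample with the ½-tie convention
  (U_a + U_b = n₁n₂). The exact null pmf is built by a rank-sum counting
  recursion and cached per (n₁, n₂); it is used whenever n₁n₂ ≤ 400 and the
  pooled data are tie-free (the study-scale groups of 25 and 15 qualify).
  Otherwise a tie-corrected normal approximation without continuity
  correction is used and recorded in the result's options. Two-sided p
  doubles the lower tail of min(U_a, U_b), capped at 1.
* **t tests**: one-sample and paired, two-sided. A zero-variance sample at
  the null mean yields t = 0 with a flag; off the null it is an error.
* **JZS Bayes factor**: the default Bayes factor for a t statistic with a
  Cauchy(0, r) prior on the standardised effect (r = 0.707 by default,
  configurable and recorded — the scale is a modelling choice, not a fact of
  the data), evaluated by adaptive quadrature over the g-prior mixture with
  relative tolerance 10⁻⁸ and verified against an independent fine-grid
  trapezoid integration.
* **2×2 mixed ANOVA**: for a two-level within factor the model decomposes
  exactly into OLS on subject sums (between effect) and subject differences
  (within effect = intercept, interaction = group contrast) with an
  effects-coded group, i.e. the Type III / unweighted-means analysis, each F
  on (1, N − 2) df. A saturated fit returns F = 0 for numerically-zero
  effects rather than 0/0.
* **ANCOVA**: OLS with sum-coded factors and Type III sums of squares
  (statsmodels); per-term F against the residual df.
* **Outliers**: |value − median| > 3 × scaled MAD (1.4826·MAD) flags a value
  for *parametric* analyses only; rank-based tests keep everyone, and every
  exclusion (rule-based or named in config) is logged. With MAD = 0 any
  deviation from the median is flagged.
* Unadjusted p values are primary; an optional Benjamini–Hochberg column can
  be added and is labelled as an extension.

## Synthetic data

**Signal level.** Gesture onsets form a Poisson process (default 20/min per
arm, 300 s at 50 Hz). A burst is a raised-cosine envelope (duration
0.7 ± 0.2 s, ≥ 0.3 s) on a 4 Hz sinusoidal carrier with random phase and
direction, amplitude 0.25 g on the preferred arm times a lognormal per-event
jitter; square bursts are available for threshold tests. With bilateral
coupling c, a fraction c of events recruits both arms *sharing one waveform*
scaled by the per-arm amplitudes, so a coupled second's noise-free magnitude
ratio is exactly k = a_np/a_p and the recoverable MMR is ln k. Signals ride
on a gravity vector plus white noise of 2 mg RMS per axis — a typical
spec-sheet noise density for wrist MEMS accelerometers integrated over
gesture bandwidth. An optional minimum event separation thins onsets so that
detected bout counts can be compared 1:1 against generated counts.

Noise adds a small positive floor to both arms' epoch means, which biases
per-second ratios toward 0; the bias grows as the weaker arm's amplitude
approaches the noise floor (≈ 0.05 absolute at k = 0.25, < 0.03 at k = 0.5,
at the defaults). This is a physical property of magnitude-based laterality
measures, not an implementation artefact, and it is why recovery tolerances
are wider at extreme k.

**Cohort level.** Per-participant traits come from a three-dimensional
Gaussian copula over (MMR, prosthesis-use, embodiment) latents; Spearman
targets are mapped to latent Pearson correlations via r = 2 sin(πρ/6), so
targets are controlled independently of marginal shapes. Defaults mirror the
reference study population: 25 prosthesis users (15 congenital, 10 acquired;
9 cosmetic / 3 mechanical / 13 myoelectric devices) and 15 controls; wear
72.8 ± 29.8 h/week; PAL 0.49 ± 0.21; embodiment 0.75 ± 1.68; MMR
−1.25 ± 1.0 for users versus 0 ± 0.4 for controls (chosen to reproduce the
strong reported group separation); ρ(MMR, use) = 0.55, ρ(use, emb) = 0.53,
ρ(MMR, emb) = 0.37. Wear hours and PAL are clipped linear transforms of a
*single* use latent, so the z-score composite preserves the target rank
correlation with MMR exactly up to clipping; the cost is that the two
components are perfectly rank-correlated with each other, which real
questionnaire data are not — correlation-calibration results therefore
certify the copula and estimator, not component-level measurement noise. An
additive MMR shift by embodiment group is available as a direct
mean-difference mechanism and defaults to 0, the association being carried by
the rank correlations. Movement rates use a shared per-subject propensity
plus arm-specific noise (truncated at 0), with a lower nonpreferred-arm mean
for users only. The synthetic questionnaire item expander writes real-valued
in-range items whose means reproduce the cohort scores exactly.

What the simulations do *not* emulate: arm kinematics and orientation change,
speech-correlated burst timing, postural drift, device clock skew between
wrists, and item-level response noise. Passing recovery tests therefore
demonstrates correctness of the measurement and inference chain under the
stated generative model, not robustness to every property of field data.

## Numerical and design choices

* Epoch windows are half-open [start, start + L) to avoid double-counting
  boundary samples; epoch sample indexing uses a 10⁻⁹-second guard against
  float boundary error.
* Exact U feasibility bound n₁n₂ ≤ 400 keeps the cached pmf small while
  covering the study's group sizes with a wide margin.
* The named-exclusion mechanism reproduces published outlier handling by
  listing participant codes in config rather than hard-coding them.
* Reproduction from the public deposit is a separate opt-in command because
  the deposit's internal layout is not machine-readable a priori; the user
  maps the per-participant values onto documented column names, and the
  command never touches the network.
* Determinism: both generators require a seed and are bit-reproducible;
  pipeline outputs carry a config fingerprint and rerun byte-identically.
* Problem sizes in the shipped acceptance script (20 seeds per laterality
  level, 1000 null replicates, 1000 copula draws, enumeration up to
  n₁ + n₂ = 10) were chosen so the whole recomputation stays in the tens of
  seconds while keeping Monte-Carlo error well inside the stated tolerances.

## Known limitations

* The exact high-pass specification of the original acquisition pipeline is
  not public; the 0.25 Hz order-4 default is an explicit, overridable
  stand-in, and MMR values are comparable across datasets only under a fixed
  filter config (hence the fingerprint).
* The two companion laterality indices are deliberately simple and should not
  be cited as any published measure's definition.
* The mixed ANOVA is specialised to 2×2 designs (its exact decomposition);
  larger factorial designs are out of scope.
* Mann-Whitney p values with heavy ties rely on the asymptotic
  approximation; for tiny tied samples an exact tie-aware enumeration is not
  implemented.
* Video-based gesture coding, gesture classification and stimulus materials
  are out of scope; only the accelerometric laterality channel is modelled.
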