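# Methods

This note documents the models and procedures implemented in `msptirr`,
the parameter choices that matter, what the synthetic data do and do not
emulate, and the numerical decisions a careful user should know about.

## Ordinal patterns and the tie rule

Each delay-embedding window `(x_t, x_{t+tau}, ..., x_{t+(m-1)tau})` is
summarised by its amplitude permutation: element `i` receives the position
it occupies after a stable ascending sort, and every group of exactly equal
elements is collapsed to the group's minimum position.  This is identical
to "min" ranking, `rank_i = 1 + #{j : x_j < x_i}`, which is how it is
implemented (vectorised over all windows).  Two consequences are load-
bearing:

- **Reversal theorem.**  Because a rank depends only on value comparisons,
  reversing the window exactly reverses the rank tuple.  The backward
  pattern `b(pi)` is therefore computed as the tuple reversal of the
  forward pattern — no second scan of the series is needed — and the
  identity is enforced by an exhaustive test over every value tuple of
  length ≤ 4 on a 4-letter alphabet (all tie configurations).
- **Pairwise identity.**  The irreversibility sum over the `V` patterns
  (forward patterns plus backward images of forward patterns) collapses
  algebraically to `sum over unordered {pi, ~pi} pairs of |p(pi) - p(~pi)|`;
  self-reverse patterns (including the all-ties pattern of a constant
  window) contribute nothing.  This puts PTIRR in `[0, 1]` and makes it
  symmetric under time reversal of the series.

The probability of a backward pattern is read off the forward distribution
at the reversed tuple.  A literal backward scan of the series would differ
only through the `O(1/n)` boundary-window discrepancy.

Ties are detected with exact floating-point equality by default; an
optional absolute tolerance (`tie_tol`) exists for coarsely quantized data.
`0 * log 0` is taken as 0 in the entropy.  The entropy uses the natural
logarithm by default, with base-2 and `log(m!)`-normalised variants
available.

One typographical ambiguity in the index's printed definition (whether the
probability difference carries absolute-value bars) is resolved with the
bars: without them the statistic would telescope to near zero and could go
negative, contradicting the index's documented range and monotone behavior.

## Multiscale procedure

Coarse-graining at scale `s` takes non-overlapping `s`-sample window means;
trailing samples beyond `s * floor(l/s)` are discarded.  The embedding
delay applies to the coarse-grained series itself (no additional
scale-dependent stride).  Default analysis grid: scales 1..100, `m = 3`,
`tau = 2` — the values the FNN / C-C selectors typically return for
resting MEG, and small enough that scale-100 coarse series of a 2-minute
1200 Hz recording (1440 samples) still yield well-populated pattern
distributions (6 possible patterns at m = 3).

Subject-level indices are unweighted arithmetic means over channels (or
over a region's channels); group curves are means over subjects with the
standard error across subjects.

**Monotone invariance caveat.**  PE and PTIRR are ordinal, so any strictly
increasing transform of the data leaves the single-scale indices unchanged
exactly.  At scales > 1 this survives only for affine transforms: a
nonlinear monotone map does not commute with the coarse-graining average.
Tests assert exactly that (and nothing stronger).

**Finite-sample floor.**  PTIRR of a finite reversible series is positive
(sampling fluctuations make `|p - p~|` nonzero); the floor grows as coarse
series shorten, roughly like `1/sqrt(floor(l/s))`.  Comparisons between
groups are unaffected (both sit on the same floor), but absolute PTIRR
values at large scales should not be read as evidence of irreversibility
on their own — that is what the surrogate test is for.

## Embedding-parameter selection

`fnn_dimension` implements the Kennel false-nearest-neighbor rule with the
standard thresholds: distance-ratio tolerance 10, attractor-size tolerance
2 (in units of the series SD), and a 1 % false-neighbor cutoff.  Pairs
whose joint distance is below `1e-8` of the series SD are counted as true
neighbors: at machine-precision separations the ratio test compares
rounding noise, not geometry (noise-free periodic signals hit this case).

`cc_delay` implements the correlation-integral (C-C) delay selector:
for each candidate delay `t` the series is split into `t` disjoint
decimated sub-series, `S(m, r, t) = C_m(r) - C_1(r)^m` is computed from
sup-norm correlation sums at radii `{0.5, 1, 1.5, 2} x SD` for
`m = 2..5`, and the chosen delay is the first local minimum of the
radius-spread `dS(t)` averaged over `m`.  Two behaviors worth knowing:

- For band-limited oscillations the first minimum sits near an eighth of
  the dominant period, not the quarter-period familiar from
  autocorrelation or mutual-information selectors — with `m` up to 5 the
  embedding span `(m-1)t` covers a full cycle well before `t = T/4`.  The
  selected delay still scales with the period, which is the property that
  matters for pooling.
- For dependence-free data the `dS` curve is flat at sampling-noise level
  and any numerical dip is meaningless, so a minimum is only accepted when
  the curve's range exceeds 0.02; otherwise the maximum candidate delay is
  returned with a warning flag.

Per-channel choices are pooled by their mode, ties broken toward the
smaller (more conservative) value.  Both selectors are advisory; the
pipeline default stays `m = 3, tau = 2`.

## Preprocessing

All filters are 4th-order Butterworth applied forward-backward
(`sosfiltfilt`), i.e. zero-phase.  This is not cosmetic: a causal filter
has an asymmetric impulse response and would inject temporal asymmetry
into exactly the statistic this package measures.  A test verifies that
filtering a linear Gaussian signal leaves PTIRR at the null level.
Defaults: low-pass 65 Hz, 2 Hz-wide band-stop at 50 Hz, and the five
canonical bands δ 1–4, θ 5–8, α 9–12, β 13–29, γ 30–65 Hz.

CTF-style channel labels (`MLC11`, `MRF25`, `MZO01`, ...) are parsed into
hemisphere (L/R/midline) × region (central, frontal, occipital, parietal,
temporal) cells.  Midline (`Z`) channels take part in whole-head analyses
but are excluded from hemispheric contrasts, whose scheme is strictly
left/right; unparsable labels are reported in an `unassigned` bucket, never
dropped silently.

## Synthetic data

The generator exists so every pipeline stage is testable without access to
clinical recordings.  Each synthetic channel is

    unit-SD oscillatory sum  +  noise_sd x 1/f noise  +  3 x mix x irreversible component,

where the oscillatory sum is Butterworth-filtered white noise per band
(default relative powers δ 1.0, θ 0.7, α 1.5, β 0.6, γ 0.3 — an
alpha-dominant, weak-gamma resting spectrum), the background is spectrally
shaped `1/f` noise at `noise_sd = 0.5` of the oscillatory SD, and the
irreversible component is a fully chaotic logistic orbit (r = 4) linearly
interpolated ×32 in time and standardized.

Design notes:

- The interpolation factor 32 (one map step per ~27 ms at 1200 Hz) keeps
  the component's ordinal asymmetry strong across the analyzed scale
  range; with a small factor the asymmetry would wash out by scale ~10.
- The component enters *additively*.  An amplitude-envelope modulation of
  a sign-symmetric carrier was considered and rejected: sign-flip symmetry
  pairs up most ordinal patterns, so such modulation leaves pattern
  probabilities nearly time-symmetric and produces almost no PTIRR
  contrast.
- The gain of 3 relative to the background gives the `mix in [0, 1]`
  weight its intended meaning — spanning fully reversible to clearly
  irreversible channels.  Ordinal asymmetry of an additive mixture is
  diluted roughly cubically by a reversible background, so with unit gain
  even `mix = 1` would barely move the index.
- Group structure: the two groups differ *only* in their mix weight
  (defaults 0.1 for the patient-like and 0.3 for the control-like group);
  geometry defaults mirror a 19 + 15-subject, 275-channel, 2-minute
  1200 Hz study.

What the generator does **not** emulate: physiological artifacts
(cardiac/ocular), sensor noise correlations across channels, head-position
effects, between-subject spectral variability, and any spatial structure
beyond the channel-label convention.  Passing tests therefore demonstrate
that the estimators and statistics behave correctly on signals with known
reversibility structure — not that the clinical effect itself is
reproduced.

## Cohort statistics

Normality is checked per group with the Lilliefors-corrected
Kolmogorov–Smirnov test (means and variances are estimated from the data);
variance homogeneity with a two-sided F test.  The per-scale comparison is
a two-tailed independent-samples t test using pooled variance when the F
check passes at α = 0.05 and Welch's correction otherwise.  No correction
for multiple testing across scales is applied by default, matching the
reporting convention the pipeline mirrors; a Benjamini–Hochberg helper is
available.  Significance intervals are maximal runs of consecutive scales
with p < 0.05.  The two-way fixed-effects ANOVA (group × band or
group × region at one scale) uses a type-II decomposition; degenerate
designs with zero effect sum-of-squares report F = 0, p = 1.  p-value
curves are reported alongside `log_0.05(p)` (1 at p = 0.05; larger is more
significant).

## Problem sizes in tests and the acceptance script

Null and positive-control checks run at series length 1e5.  The cohort
contrast runs at 10 + 10 subjects × 20 channels × 24 000 samples with
scales 1..20 — large enough that the injected group difference is
detected with margin, small enough to iterate on quickly.  The end-to-end
byte-reproducibility check uses the 19 + 15 group split with 4 channels ×
2 400 samples at 400 Hz.  The t-test calibration uses 1 000 null
replicates at the study's 19/15 group sizes (Monte-Carlo SE ≈ 0.007 on a
0.05 rate, hence the accepted band 0.03–0.07).

## Known limitations

- PTIRR's finite-sample floor makes absolute values at large scales
  length-dependent; compare like with like, or use surrogates.
- The C-C selector's first-minimum rule is noisy on strongly periodic
  lattice-sampled data (resonances between the decimation step and the
  period); the mode across channels is the robust quantity.
- Region mapping relies on the CTF naming convention; other vendors'
  label schemes land in `unassigned` and need a user-supplied map.
- The two-way ANOVA treats subjects' region/band values as independent
  observations within cells, as in the mirrored protocol; it is not a
  repeated-measures model.
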