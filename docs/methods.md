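# Methods

This note documents the models, numerical conventions and design
choices behind `thetamod`: what is computed, under which assumptions,
and what the validation on synthetic cohorts does and does not show.

## 1. The biomarker and its controls

For each video the recording is cut into consecutive, non-overlapping
1-s epochs starting at video onset (trailing partial second dropped).
An epoch belongs to half 1 if its onset precedes the video midpoint,
else half 2 — so a 59.5-s video yields 30 + 29 epochs. The primary
index is the fractional change in frontal theta power between the
halves of the **first** presentation,

    Δθ = (P₂ − P₁) / P₁,

computed per condition (social / non-social video) and collapsed as the
unweighted mean over the conditions that pass quality control; a subject
with usable data in only one condition is retained. Controls reuse the
same index on posterior theta, on upper alpha (8–9 Hz, chosen above the
theta range to avoid spectral leakage from it), and on the count of
clean attended epochs. The between-repetition index applies the same
percent change to whole-presentation frontal theta of showings 1 and 2
of the same video.

**Power scale.** P can be the natural-log band power (default) or the
linear band power (µV²); the scale is one config switch (`mode`). The
index is scale-invariant in linear mode, but not across the log
transform, where it depends on the absolute power unit — both facts are
asserted in the tests, and the end-to-end recovery check runs in both
modes (they recover the programmed coupling equally well). The
first-half baseline covariate used by the repetition analyses follows
the same mode switch, default ln.

## 2. Preprocessing

Fixed stage order, logged: segment → attention gate → artifact
detection → interpolation → average reference → QC. Detection precedes
interpolation, so a repaired channel no longer disqualifies its epoch.

* **Attention gate**: an epoch counts as attended only if it is fully
  contained in a looking-at-screen interval (the strict reading;
  intervals are merged half-open `[onset, onset+duration)` spans).
* **Artifact rules**, per epoch × channel, all thresholds exposed as
  `ArtifactParams` with defaults: |amplitude| > 200 µV; sample-to-sample
  step > 100 µV; peak-to-peak < 0.5 µV (flatline). A channel bad in
  > 30 % of epochs is globally bad. The amplitude/gradient rules are
  even functions of the signal (sign-flip invariant). The exact
  thresholds of the acquisition-software pipeline being emulated are
  not published; these defaults are declared stand-ins, and the analyses
  are designed to be robust to them.
* **Interpolation**: a bad channel is replaced, per epoch, by the mean
  of its non-bad neighbors (neighbor map from the montage file, required
  symmetric). No spherical splines — the synthetic layout carries no
  geometry. A bad channel with no good neighbor leaves the epoch
  unclean.
* **Average reference**: subtract the instantaneous channel mean;
  idempotent, preserves pairwise channel differences.
* **QC**: a (video, presentation) enters analysis only when every half
  has ≥ `min_epochs_per_half` (default 5) clean attended epochs. The
  minimum is a declared stand-in for an unpublished inclusion rule.
* The 0.1–100 Hz acquisition band-pass is treated as a hardware
  property and not re-applied; an optional zero-phase high-pass exists
  for matrix-fallback inputs.

## 3. Spectral estimation

1-s epochs give a 1 Hz-resolution one-sided spectrum at integer bins
0..fs/2, normalized so the bin sum equals the signal's mean square
(variance + DC) — Parseval at analysis scale, exact for `taper="none"`.
The default Hann taper is power-corrected by its mean square (unbiased
for broadband power; slightly redistributes a pure tone across
neighboring bins, which the inclusive band mean absorbs). Band edges
are inclusive: theta = bins {3,4,5,6}, upper alpha = {8,9} — at 1 Hz
resolution the stated integer band edges admit no other consistent
reading.

Aggregation order: mean **linear** power over band bins → channels in a
region → clean attended epochs of a (video, presentation, half); one
natural log at the end. Log-of-mean is stable at low epoch counts; the
linear mean is kept alongside for linear mode. Frontal power is the
unweighted mean of the left and right frontal regions (single-region
fallback with a warning).

## 4. Statistics

All computed from explicit formulas; tail probabilities use the
regularized incomplete beta (t, F) and erfc (z) from `scipy.special`.
scipy.stats / statsmodels / pingouin appear only as independent oracles
in the test suite.

* **Pearson**: t = r√(n−2)/√(1−r²), df = n−2, two-sided; exact
  collinearity short-circuits to p = 0. Pairwise-complete (NaN rows
  dropped per analysis, n reported per result).
* **Partial correlation**: first-order formula for one covariate,
  OLS residualization for more (proven equal in tests); default
  df = n−2−k with an `n-2` convention switch, since published reports
  are ambiguous about which df accompanies a partial r.
* **Steiger Z** for two dependent correlations sharing one variable:
  Fisher z-transforms with the pooled-r̄ covariance term
  ψ = r₁₂(1−2r̄²) − r̄²(1−2r̄²−r₁₂²)/2, s = ψ/(1−r̄²)²,
  Z = (z₁₃−z₂₃)·√((n−3)/(2(1−s))). Reported one-sided from the normal
  upper tail — the convention that reproduces published Z→p pairs for
  this directional band comparison; a two-sided value is also exposed.
  Empirical type-I error at α = 0.05 is verified to sit in [0.04, 0.06]
  over 5,000 null triples (n = 50).
* **2×2×2 within-subject ANOVA** (condition × half × region): each
  1-df effect is the squared paired t on the per-subject ± contrast
  over the 8 cell means; F(1, n−1), partial η² = F/(F+n−1). Listwise
  deletion of incomplete subjects, n logged. Contrasts below machine
  precision (relative to the data scale) are snapped to F = 0.
* **Group ANCOVA**: outcome ~ predictor + group + predictor×group
  (+ covariate), sum-to-zero coding, Type-III F tests (residual-SS
  increase on dropping an effect's columns), partial
  η² = SS_eff/(SS_eff+SS_res); per-group Pearson r reported alongside.
  Exact fits report F = ∞, p = 0; aliased terms raise naming the term.
* No multiple-testing correction anywhere (matching the reporting
  practice the battery mirrors); all tests two-sided except the Steiger
  comparison as above.

`verify_reported` recomputes every published statistic that is a pure
function of other printed numbers and compares at printed precision,
propagating the rounding interval of the printed statistic (a printed
r = 0.39 is any r ∈ [0.385, 0.395]); a row passes when the recomputed
interval overlaps the printed value ± half its last printed digit.
Rows whose printed numbers are mutually inconsistent, or whose df
convention is unstated (partial correlations; ANCOVA η² whose error
term is not recoverable from F and df), are shipped flagged
`derivable = 0` and excluded from the must-pass set; their recomputed
values are still reported.

## 5. The synthetic-cohort generator

Each subject's recording is the sum of:

* **1/f background**: white Gaussian noise spectrally shaped by
  1/f^(β/2) (FFT filter; exact spectral control, seedable), β = 1,
  scaled to 15 µV sd per channel;
* **theta oscillator** at 4.5 Hz, base amplitude 10 µV, channel-weighted
  (left frontal × 1.15, right frontal × 1, posterior × 0.6, central
  × 0.5) and condition-weighted (social × 1.2). During the first
  presentation its amplitude ramps linearly so that the second-half
  mean is (1+g) times the first-half mean: a(t) = 1 + d·t/T with
  d = 4g/(2−g). The second presentation plays at the first
  presentation's *mean* amplitude times the repetition factor
  1 + κ·g + ε (κ = 0.5, sd(ε) = 0.1) — anchoring to the presentation-1
  mean makes the between-repetition power change track the repetition
  factor rather than the ramp shape;
* **alpha oscillator** at 9 Hz, constant 6 µV, posterior-weighted
  (frontal fraction 0.3) — the band-specificity control;
* **artifacts**: Poisson-rate square pulses of ±(3–10)× the 200 µV
  amplitude reference lasting 0.2–1.0 s, plus occasional whole-channel
  flatline spans — exercising all three artifact rules; every injected
  artifact is logged as ground truth;
* **attention**: integer-second on/off chunks (3–8 s) per video, each
  attended with probability `attention_fraction` (default 0.8) —
  aligned to epoch boundaries so the programmed fraction is what the
  full-containment gate sees.

**Latent structure.** The theta growth g is drawn per condition,
iid Normal(0.25, 0.15) truncated at −0.5 (the positive mean reproduces
the group-level half effect; the truncation keeps amplitudes positive).
Independent condition growths are what make the within-video change of
one condition predict the repetition change of the *same* condition but
not of the other — a single shared growth cannot produce that
dissociation. The subject-level growth ḡ (mean of the two) drives
cognition: score = 50 + λ(ḡ − E[ḡ]) + ε with λ = r·σ_score/σ_ḡ and
sd(ε) = σ_score√(1−r²), so corr(score, ḡ) = r and sd(score) = 10 by
construction (`derive_coupling`). Scores are clipped to the t-score
range [20, 80]; at these parameters clipping touches < 0.5 % of draws.
Groups may receive distinct programmed couplings (`group_target_r`) to
emulate outcome-group interactions. Verbal scores use a weaker default
coupling (0.2) than nonverbal (0.4).

**Feature-level mode.** `synth_features_cohort` draws the derived
indices directly from the latents (primary index = ḡ plus Gaussian
measurement noise, default sd 0.05 — an upper bound on the half-power
estimation error the full pipeline shows at default amplitudes), used
for replicate-heavy calibration where only correlation structure
matters. The single end-to-end recovery check and the group-effect
check always run through full signal synthesis.

**What the generator does not emulate**: no head-model/volume
conduction, no blink/ECG artifact morphology, no geodesic electrode
geometry (regions are declared in the montage file), no condition-
specific spatial dissociation of the ramp (posterior theta shares the
growth, so the spatial-specificity *null* of the discovery cohort is
not programmed), and the between-subject variance of theta growth is a
testability choice, not an empirical estimate. Passing recovery tests
therefore validate the pipeline's arithmetic and inference under the
model's assumptions — they are not evidence about real infant EEG.

## 6. Validation problem sizes

Chosen to exercise each claim at stable Monte-Carlo error: parameter
recovery on one full-signal cohort of n = 200 (programmed r = 0.4,
pipeline estimate expected within ±0.1); null-cohort p-uniformity over
200 feature-level replicates of n = 36 (KS test); ANCOVA interaction
power over 100 feature-level replicate cohorts of n = 60 with group
couplings 0.9 vs 0.1 (detection rate ≥ 80 % at α = 0.05); Steiger
calibration over 5,000 null triples of n = 50; the qualitative
condition/region/half ANOVA recovery on full-signal cohorts of n = 36
over three seeds. Monte-Carlo sign and fraction checks in the unit
suite use 100 subjects with 20-s videos — the generator's per-second
structure is duration-invariant, so these checks transfer.

## 7. Known limitations

* EDF output is 16-bit; round-trips are exact only to one quantization
  step of each channel's physical range.
* Neighbor-mean interpolation is cruder than spherical splines; with
  the chain neighbor maps the generator emits, a flatlined channel is
  repaired from two neighbors.
* In ln mode the percent-change index depends on the power unit (µV²);
  comparisons across datasets require a common unit convention.
* The ANOVA's half × region and condition × region interactions are not
  null in the generator (multiplicative amplitude gains interact with
  the noise floor on a log scale), so only the three main effects are
  treated as programmed truth in qualitative recovery checks.
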