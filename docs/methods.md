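# Methods

## Reaction model and signal model

The assay couples two irreversible (pseudo-)first-order steps on a
self-quenched ssDNA reporter: deamination of the single target cytosine at
rate k₁, then endonucleolytic cleavage adjacent to the resulting uridine at
rate k₂, which dequenches the 5′ fluorophore.  Species concentrations
follow the consecutive-reaction solution (`raddkit.models`); near rate
degeneracy (|k₁−k₂| < 10⁻⁶·max(k₁,k₂)) the analytic equal-rate limit
P(t) = A₀(1−(1+kt)e^(−kt)), k = (k₁+k₂)/2, replaces the generic form to
avoid catastrophic cancellation in the (k₂−k₁) denominator.  Cleavage-only
controls (pre-deaminated reporter) skip the first step and follow one-phase
association at k₂.

Assumptions: both steps irreversible and first-order in their substrate; no
product inhibition, photobleaching, or inner-filter effects; deamination
pseudo-first-order in reporter (enzyme concentration enters only through
k₁).  The endonuclease is used far above its apparent K_M (2 µM vs 64 nM, a
31-fold margin), which is what licenses treating cleavage as first-order
and not enzyme-limited.

The fluorescence model maps product to signal linearly:
F(t) = F_bg + (F_max−F_bg)·P(t)/A₀ + transient + noise, where the transient
amp·(1−e^(−t/τ)) reproduces the small settling rise instruments show over
the first minutes of a scan.

## Units

Time is always seconds internally; concentrations µM (µmol L⁻¹), except
inhibitor concentrations in nM, matching field reporting conventions.
Rates are s⁻¹, velocities µM s⁻¹, raw signal RFU.

## Trace processing

* **Background**: the per-timepoint mean of the plate's negative-control
  wells is subtracted from every other well.  Because negatives carry the
  same settling transient, per-point subtraction removes it from samples
  too; a scalar-baseline alternative would not.
* **RFU→µM calibration**: the fluorescence of fully processed reporter
  (fmax) comes from the cleavage-only controls.  Three estimators are
  available: `exp_fit` (plateau of a free one-phase fit; pipeline default),
  `plateau_mean` (mean of the last 10 % of points, ≥ 5), and `max`.  The
  exponential fit is preferred because a 1-h scan at k₂ ≈ 3×10⁻³ s⁻¹ ends
  with ~4×10⁻⁵ of the reporter unprocessed, and that tiny deficit in a tail
  mean propagates threefold into the fitted rate; the fitted plateau has no
  such truncation bias and uses every point.  Controls whose tail still
  rises (extrapolated tail slope > 2 % of the plateau over the scan) are
  flagged.
* **Velocities**: ordinary-least-squares slopes over a sliding window; the
  steepest window wins, ties to the earliest.  Default window 10 points
  (5 min at 30-s scans).  Clipping of converted concentrations above
  1.05·A₀ is logged, never silent.

## Fitting

All fits are unweighted least squares (no weighting scheme is standard for
this assay's reporting), replicates pooled as individual points to
preserve degrees of freedom (averaging-first is available via config).
Rate fits use bounded `least_squares` (bounds 10⁻⁹–10 s⁻¹) with three
log-spaced starts around a half-rise heuristic; tolerances are set to
10⁻¹⁴ because the parameters span decades (rates ~10⁻³ s⁻¹, velocities
~10⁻⁴ µM s⁻¹) and default tolerances stop visibly short on exact data.
Confidence intervals are asymptotic, value ± t(df, 0.975)·SE, truncated at
physical bounds; profile-likelihood intervals are out of scope.

**Two-stage single-turnover procedure.**  Stage 1 estimates k₂ from the
cleavage controls; stage 2 fixes k₂ (and A₀ = 1 after normalisation) and
fits k₁.  Three uncertainty corrections keep the intervals honest, and in
simulation lift empirical 95 %-CI coverage from 0.85 to ≥ 0.95:

1. the stage-1 fit used by the pipeline estimates k₂ and the plateau
   jointly on the background-subtracted controls, so the k₂ SE includes
   the RFU→µM scale uncertainty that a fixed-plateau fit on pre-normalised
   data would ignore;
2. the k₁ SE adds the propagated stage-1 term (∂k₁/∂k₂)²·SE(k₂)², with the
   sensitivity evaluated by refitting at a perturbed k₂;
3. pooled-fit SEs are widened for the background trace shared across
   wells: subtracting one mean-negative trace correlates residuals across
   wells, understating parameter variance by (1 + n_wells/n_neg)/(1 +
   1/n_neg) — a factor √1.5 for the standard 3 + 3 design.

The k₁ label is metadata-driven: with enzyme above both the substrate
concentration and K_M the flag `single_turnover` is set and k₁ reports
k_cat; otherwise it is an observed rate k_obs.

**Michaelis–Menten.**  Velocities from a substrate dilution series are fit
to v = V_max·S/(K_M+S); k_cat = V_max/[E].  For trace-level analysis the
slope window is auto-sized to one third of the scan (40 points at 30-s
scans) and located on the replicate-mean trace, with each replicate's
slope then read on that common window.  Two biases motivate this: taking
each noisy replicate's own maximum window selects positive noise
excursions (at 1 % read noise a 10-point window inflates median K_M error
to ~33 %), and short windows see mostly the lag phase.  With the common
long window, median K_M error stays ≤ 12 % from zero to 5 % read noise.
The residual upward K_M bias (~10 % even noiseless) is intrinsic to
reading slopes off coupled-lag progress curves at these scan rates and is
reported as-is.  Tables with flat velocities are flagged unidentifiable
(K_M CI unbounded); series whose maximum substrate is below K_M/2 raise a
range warning.

**Percent activity and IC50.**  Inhibited-well velocities are expressed as
percent of the mean uninhibited velocity and fit to the variable-slope
logistic with top/bottom fixed at 100/0, in log₁₀-concentration space; the
IC50 CI is back-transformed from the log scale.  The default velocity
metric (`rate_fit`) fits each well's k₁ with the sequential model (k₂ from
the plate's own controls) and uses v = k₁·A₀ — the true initial
deamination velocity.  The raw maximum-slope metric is available but
biased: substrate depletion compresses velocity ratios toward 1, which at
a realistic uninhibited rate (k₁ ≈ 5×10⁻⁴ s⁻¹) inflates the fitted IC50 by
roughly a third.  Fits whose responses do not straddle 50 % are flagged as
extrapolations.

**Screening statistics.**  Sample standard deviations (n−1) throughout,
because plate groups are small (n = 18 here).  S:N defaults to
(μ₊−μ₋)/σ₋ and S:B to μ₊/μ₋; a pooled-SD S:N variant is selectable.

## Synthetic-data generator

The generator encodes the assay's characterisation designs as presets:

* `single_turnover` — 5 µM deaminase over 1 µM reporter, k₁ = 5.5×10⁻³,
  k₂ = 2.97×10⁻³ s⁻¹, N = 3 each of samples, cleavage controls, negatives;
* `mm_series` — half dilution series 16→1 µM reporter, N = 3, with
  pseudo-first-order k₁(S) = V_max/(K_M+S) at K_M = 4.390 µM,
  V_max = 5.1397×10⁻⁴ µM s⁻¹ (100 nM enzyme), so initial velocities follow
  the saturation curve; the fluorescence window scales with reporter load;
* `zprime` — 18 positive + 18 negative wells; positives carry larger
  endpoint scatter (enzyme-bearing wells do in practice), with amplitudes
  chosen to give the strong separation (Z′ ≈ 0.7, S:B ≈ 5) typical of the
  assay;
* `inhibition_series` — 78–620 nM inhibitor against 500 nM deaminase,
  k₁ mapped through Hill occupancy k₁·(1−[I]ⁿ/([I]ⁿ+IC50ⁿ)) with reference
  IC50 = 226.4 nM, n = 1, so the constrained logistic fit round-trips in
  expectation; uninhibited k₁ = 4.8×10⁻⁴ s⁻¹ ≈ k_cat·[E]/(K_M+A₀);
* `lysate_dilution` — dilutions 1×/2×/4× scaling a low lysate-like
  k₁ = 5×10⁻⁴ s⁻¹.

Baseline defaults: F_bg = 2000 RFU, F_max = 10000 RFU per µM reporter,
settling transient 150 RFU with τ = 60 s, homoscedastic Gaussian read
noise of 80 RFU (1 % of the signal window — the equivalent of 0.01 µM),
30-s scans for 1 h.  The true noise structure of plate readers is richer
(gain-dependent, mildly heteroscedastic); a proportional-noise option
exists for robustness checks.  Every well draws from an RNG substream
keyed by (seed, CRC32(well id)), so plate edits never perturb other wells
and runs are bit-reproducible.

What the generator does *not* emulate: enzyme–DNA binding kinetics,
processivity, sequence-context preferences, evaporation or edge effects,
photobleaching.  Passing tests therefore demonstrate correctness of the
analysis chain under the stated model, not robustness to every artefact of
real plates.

## Problem sizes used in validation

Simulation-based checks use 121-point, 9–36-well plates; the coverage
study refits 200 independently seeded plates; recovery medians use 15–40
seeds; the ODE cross-check draws 50 random parameter sets.  These sizes
give stable Monte-Carlo estimates while keeping the full suite around a
quarter of a minute.

## Known limitations

* Asymptotic CIs can undercover for strongly nonlinear parameters at very
  low point counts; the coverage study validates the standard designs only.
* The K_M pipeline bias (~10 %) is documented, not corrected; progress-curve
  fitting of K_M directly would remove it but is deliberately out of scope.
* IC50s from the occupancy model are apparent values; tight-binding
  corrections (inhibitor depletion when IC50 ≈ [E]/2) are not applied.
* Instrument-native export parsing is out of scope; data enter as
  long-format or wide-format CSV.
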