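# Methods

This note records the models, conventions and numerical choices behind
`vocsense`, and what the synthetic experiments do and do not show.

## The instrument model

A chromatogram is a resistance–time trace on a fixed grid of 5040 points at
0.5 s spacing (42 min). Metal-oxide sensors respond to a volatile with a
resistance *drop*; the generator emits already-inverted "response" traces so
that elution peaks are maxima, matching how such chromatograms are plotted.
All locations, widths and retention times are in half-second grid units, and
time indices are 1-based (t = 1…5040); CSV trace columns are zero-padded
(`t0001`…`t5040`) so they sort lexically.

Each simulated trace is the sum of:

- **Baseline** — a per-run level `start_level + N(0, drift_sd)` (default
  100 ± 5 resistance units, floored at 10% of the start level) plus a gentle
  within-run linear slope `N(0, slope_sd)` per grid point (default SD 5e-4).
  Real baselines drift between runs with no obvious functional form; a level
  shift plus slope is the minimal model that the within-profile
  standardization must (and does) remove.
- **Shared peaks** — 16 Gaussian peaks spanning the elution range. A Gaussian
  in the time index is the minimal unimodal shape consistent with the
  described chromatograms. Width grows with retention time,
  `width_sd = 18 + 27·location/5040`, so the full width at 10% of maximum
  (≈4.29·width_sd) runs from ~80 half-seconds early to ~190 late, matching
  the instrument's stated ~100 up to ~200 half-second peak widths. Per-sample
  amplitudes are `amplitude_mean · (1 + 0.15·z)`, truncated at 5% of the mean
  so traces stay positive.
- **The marker peak** — location 3204, width_sd 30, mean amplitude 8. It is
  assigned to an *exact* subset of round(prevalence × n) samples chosen
  without replacement (default 20 of 24 cancer samples, 0 of 74 controls),
  rather than by independent Bernoulli draws, so the generator contract is
  testable deterministically.
- **Secondary group effects** — amplitude shifts added to the cancer group's
  mean amplitude at eight shared peaks (t = 117, 153, 174, 201, 359, 1073,
  1162, 1362). These are *calibration constants*, not physical measurements:
  no amplitude scale for the real between-group differences is available, so
  the defaults (+3.5, −2.9, +4.0, −3.5, +4.4, +3.3, −3.3, +2.9) were fixed
  once so that the end-to-end pipelines reproduce the reference
  leave-one-out error rates (see "What the experiments show" below), and are
  not revisited.
- **Retention-time jitter** — one multiplicative factor per run, uniform on
  [1−j, 1+j] (default j = 0.01), applied to every peak center: the tracked
  peaks of real runs co-fluctuate day to day by about ±1%, consistent with a
  single per-run stretch rather than independent per-peak wander. Jittered
  centers are clipped to the grid so extreme robustness experiments stay
  defined.
- **Noise** — additive iid Gaussian, default SD 0.05 response units.

Calibration runs emulate the daily 50-ppm ethanol standard: a true retention
time `N(329.2, 3.97)` half-seconds, rendered as a peak on the grid and
*recovered by peak detection*, plus a sensitivity draw `N(98.5, 10.6)` (in
percent, clipped into (0, 100) because a resistance-drop sensor cannot exceed
a complete drop) that fixes the (R₀, R_g) resistance pair via
sensitivity = 100·(R₀−R_g)/R₀.

## Preprocessing conventions

- **Standardization** uses the sample SD (n−1 denominator). With 5040 points
  the n vs n−1 difference is negligible, but one convention must be fixed for
  bit-reproducibility. Constant traces are rejected.
- **"Measurable peak"**: a local maximum inside the search window standing at
  least `min_height` above the window's median, with
  `min_height = 3 ×` a robust noise scale (1.4826·MAD of first differences,
  divided by √2 to undo the variance doubling of differencing). The apex
  search runs on a lightly boxcar-smoothed copy of the window (21 points,
  much narrower than the ~100-point peaks): over a 200-point window the
  maximum of raw iid noise routinely reaches 3σ, so an unsmoothed 3σ rule
  would false-positive at a material rate, while smoothing leaves real apex
  locations untouched and makes the detector's agreement with the
  generator's marker assignment exact.
- **Marker window** default (3100, 3300): centered on the marker feature with
  the t = 3204 stepwise point inside, wide enough for ±1% jitter (±32 points
  at that retention time).
- Retention-time stability is summarized per tracked peak as mean, SD and
  max |location − mean|/mean across runs.

## Method 1 — stepwise LDA

Entry criterion: minimize Wilks' Λ of the augmented model, computed
incrementally via rank-one determinant updates (`Λ_{S+j} = Λ_S ·
resid_W(j)/resid_T(j)`), which makes each step a vectorized scan over all
5040 candidates. F-to-enter threshold 3.84 and tolerance floor 0.001 are the
conventional stepwise-discriminant defaults; the tolerance is 1 − R² of the
candidate against the already-entered predictors on the total sample. The
selection cap is min(9, smallest group size). If no candidate clears the
entry threshold the model is empty; an empty discriminant scores zero
everywhere and the tie rule (below) assigns everything to control.

The discriminant is the classical Fisher rule: direction S_W⁻¹(μ₁−μ₀) with
S_W the pooled within-group covariance (n−2 denominator, solved by Cholesky;
a singular S_W raises a multicollinearity error, i.e. the stepwise guard
failed). Priors are equal (0.5/0.5) by default despite the 24/74 imbalance —
proportional priors would depress sensitivity far below the reference
behavior — with proportional priors available by argument. Scores exactly at
the threshold go to control (a probability-zero event on continuous data;
the benign default).

**LOO protocols.** `fixed_features` (default) selects time points once on the
full cohort and refits only the coefficients in each fold, mirroring what
standard stepwise-DA software reports as "cross-validated" results;
`reselect_per_fold` repeats selection inside every fold. The fixed protocol
is optimistic on null data (the selection has seen the held-out sample);
the evaluation suite exercises exactly this distinction: the honest protocol
is verified to sit at binomial chance level on effect-free cohorts.

## Method 2 — PLS-DA

PLS1 on a 0/1 class indicator (control→0, cancer→1), decision threshold 0.5,
ties to control. The −1/+1 coding with midpoint threshold is equivalent
under an affine response map; one convention is fixed. Weight vectors are
unit-norm; only the predictor block is deflated (response deflation is
redundant for a univariate response); columns are centered inside the fit
and no per-column scaling is applied, since profiles are already
standardized within-sample. Factor a of a depth-A fit equals factor a of a
depth-a fit, so the 1–10 factor sweep fits one full-depth model per LOO fold
and truncates, costing one fit per fold instead of ten.

## Evaluation harness

Confusion matrices take cancer as positive; percentages are printed to one
decimal place. The replicate study simulates one cohort per seed and runs
both methods end-to-end (standardize → select/fit → LOO), reporting per-seed
sensitivity/specificity and their median/min/max; it is bit-reproducible
given (config, seed list). Jitter robustness re-runs the study across jitter
levels with all else fixed; "negligible" at ±1% jitter is operationalized as
a ≤5-percentage-point change in median LOO accuracy (no numeric tolerance
exists for the qualitative claim), and 50% jitter is verified to degrade
accuracy.

## Problem sizes

The replicate studies use 20 seeded full-size cohorts (24/74 samples, 5040
points) for the headline medians — enough for a stable median while keeping
a full dual-method study under about a minute. Harness guards (null-effect
chance level, jitter robustness) run on a structurally identical scaled-down
instrument (600-point grid, 12/18 samples, four shared peaks) with 5–20
replicates, since they test harness logic rather than instrument geometry.

## What the experiments show — and what they do not

With the frozen calibration the 20-seed medians are: stepwise-LDA LOO
sensitivity 100% and specificity 100%, and PLS-DA (best of 8–10 factors) LOO
sensitivity ~97.9% and specificity 100% — at or slightly above the reference
rates of 95.8%/93.2% (LDA) and 95.8%/94.6% (PLS-DA). The synthetic control
group is more homogeneous than a real urology-clinic control population
(every control is draws from one shared-peak model; the marker is entirely
absent), so specificity saturates near 100% once the cancer-side effects are
strong enough to recover the non-marker cancer cases. Passing these
experiments therefore shows that the pipelines extract the designed signal
at realistic noise, jitter and drift levels — it does not certify
performance on real patient cohorts, whose control-side heterogeneity,
confounders (smoking, medication, diet) and batch structure the generator
does not emulate.

Other known limitations:

- No alignment/warping correction is applied (by design: ±1% jitter is shown
  to be negligible for these classifiers, and a nominal index t is a column,
  not a compound — the second-model behavior of the stepwise selection
  illustrates that several distinct time-point sets classify equally well).
- The generator does not model sensor aging, temperature-program artifacts,
  adsorption kinetics, or storage/freezing effects.
- Sensitivity draws for calibration runs are clipped into (0, 100): the
  configured Normal(98.5, 10.6) has mass above a complete resistance drop,
  which is unphysical, so the simulated mean sensitivity is slightly below
  98.5 while retention-time recovery is unaffected.
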