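# Methods

## Signal model and units

Dynamic signal is modelled as linear in tissue contrast concentration,
`S(t) = S0 · (1 + gain · C_t(t))`, with a single configurable `gain`
(default 0.45 signal-fraction per mM) shared by the synthetic forward
simulation and the fitting code. No T1 mapping or B1 correction is
attempted: fitting operates on relative enhancement `S/S0 − 1` divided by
the gain, which preserves the identifiability of `K^trans` and `v_e` up to
the gain convention. Absolute `K^trans` values are therefore comparable only
within a fixed gain; all responsiveness statistics are invariant to it
(they standardize each variable before comparison).

`S0` is the mean of the pre-contrast frames (3 on the standard protocol,
2 on LTR), which reduces noise relative to using a single frame. The three
semi-quantitative metrics use the ratio convention `S/S0` — a
non-enhancing voxel has `RE_max = RE_late = 1` — and RER uses
consecutive-frame finite differences with no smoothing, the simplest
reading of "maximum slope". RER estimates depend strongly on the slope
estimator and the temporal resolution, so absolute RER values should not be
compared across implementations; the package documents its estimator and
treats RER as internally consistent only.

## Extended Tofts model and fitting

`C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) e^{−k_ep (t−τ)} dτ`,
`k_ep = K^trans / v_e`. The convolution is evaluated on the AIF's dense
grid (1 s default) with an O(n) exponentially-damped trapezoidal recursion
(quadrature error O(Δt²); verified against the boxcar-AIF closed form to
better than 1e−4 at 0.1 s resolution) and linearly interpolated to the
frame times.

Voxel fits use `scipy.optimize.least_squares` (trust-region reflective,
tolerances 1e−8) with box bounds `K^trans ∈ [0, 5] min⁻¹`,
`v_e ∈ [1e−3, 1]`, `v_p ∈ [0, 0.5]` and a fixed 3×3×2 multi-start grid,
keeping the fit deterministic and robust to local minima. Bolus arrival is
taken from the protocol (contrast is injected between two known frames),
not estimated per voxel. Both the three-parameter extended fit (default)
and a two-parameter fit with `v_p` pinned to zero are available; `v_p` is
fitted but not propagated to the cohort table, which carries the
conventional pair `K^trans`, `v_e`. Non-finite or zero-baseline voxels are
flagged non-evaluable, excluded from ROI medians, and counted in the logs.

Temporal resolution matters: noiseless round trips on the standard protocol
(22 s frames) recover `K^trans` and `v_e` to well under 1% median relative
error, while the LTR protocol (39 s frames) degrades `K^trans` accuracy;
the test suite reports the LTR error but does not assert a bound on it.

## ROI aggregation

Synovial tissue volume is in-mask voxel count × voxel volume (mm³; it is
converted to cm³ only for the volume slope in the association table, the
conventional reporting scale). Parameter maps are summarised by the median
over evaluable in-mask voxels (even counts: mean of the central pair).
Masks are supplied in dynamic-image space; registration between the dynamic
series and a high-resolution anatomical series is out of scope and replaced
by an identity transform. Cohort assembly is complete-case: subjects
missing either visit are dropped with a logged reason, and duplicate
subject-visit records are a hard error.

## Responsiveness statistics

Each of the seven variables (volume, RER, RE_late, RE_max, `v_e`,
`K^trans`, KOOS pain) is z-scored over the pooled baseline + follow-up
sample (2n observations, ddof = 1). Pooling across visits is the
standardization convention that makes the mean within-subject z-change
equal the raw mean change divided by the pooled-sample SD; it reproduces
published standardized-change tables from their per-visit means/SDs
(e.g. −0.75/√((1.37² · 92 + 1.12² · 92 + 0.375² · 186)/185) ≈ −0.58 for
RE_late).

The standardized change is estimated as the type-by-visit interaction
coefficient of a random-effects panel model with parameter-type dummies and
a subject random effect, fitted by Swamy–Arora feasible GLS
(within-residual and between-group variance components, quasi-demeaning,
normal-theory 95% CIs). In a balanced two-visit panel the interaction
design is saturated in the visit-by-type cell means, so the point estimate
equals the mean within-subject z-difference for every value of the
quasi-demeaning parameter — the package asserts this identity against a
direct-mean oracle to 1e−10. The practical consequence: point estimates are
estimator-invariant, and only the CIs depend on the variance components.
Both a pooled fit (all seven types, one random effect per subject; default)
and per-parameter fits are provided; their point estimates coincide by the
same identity.

KOOS pain runs from 100 (no pain) to 0 (extreme pain), so a raw
standardized change of +1.13 means improvement; the report flips its sign
(`orientation = "improvement-negative"`) so all seven variables read
"more negative = stronger response".

Associations are bivariate OLS of ΔKOOS on Δparameter (slope, t-based 95%
CI, two-sided p; no multiple-testing adjustment) plus Pearson's r with a
Fisher-z 95% CI (`tanh(atanh r ± 1.96/√(n−3))`), whose ~95% coverage is
verified by simulation.

## Synthetic cohort generator

The generator emulates the study conditions, not knee anatomy:

* **Protocols**: 18 frames every 22 s with contrast between frames 3 and 4
  (standard), or 12 frames every 39 s with contrast between frames 2 and 3
  (LTR); by default 16/93 of subjects are assigned LTR. Bolus arrival is
  halfway between the last pre- and first post-contrast frame.
* **AIF**: a parametric stand-in for a measured popliteal-artery population
  average — zero before the bolus, linear upslope (8 s) to a 6 mM peak,
  then biexponential washout (70% at 0.02 s⁻¹, 30% at 8e−4 s⁻¹). Real AIF
  shape and units are study-specific; these values are conventions chosen
  to give realistic curve shapes (plateauing enhancement with RE_late near
  RE_max), and the fitting code is exercised against whatever AIF it is
  given.
* **Baseline population**: lognormal between-subject distributions matched
  to observed means/SDs (`K^trans` 0.045 ± 0.033 min⁻¹, `v_e` 0.31 ± 0.22,
  volume 9601 ± 5251 mm³), KOOS baseline normal 46.75 ± 14.40 clipped to
  [0, 100], baseline signal 100 with Gaussian noise SD 2 (≈2%), and 10%
  lognormal within-ROI parameter jitter.
* **Treatment effect**: multiplicative follow-up ratios matched to the
  observed mean reductions (`K^trans` ×0.64, `v_e` ×0.71, volume ×0.85)
  with subject-level lognormal heterogeneity (SD 0.15 on the log ratio),
  capped at 1 so no subject worsens under an active treatment; the cap
  introduces a ≲1% downward bias in the mean ratio, accepted in exchange
  for the monotone-response invariant.
* **Pain link**: ΔKOOS = 22.93 + 19.8 · (ρ·z + √(1−ρ²)·ε) with z the
  cohort-standardized true RE_late change and ρ = −0.27, giving a
  population correlation of ρ between pain change and enhancement change.
  Follow-up KOOS is clipped to [0, 100]; the clip attenuates the sample
  correlation by well under 0.03 at the default moments.
* **Exact-moment mode**: per visit and variable, standard-normal draws are
  affinely rescaled so the sample mean and SD (ddof = 1) equal the targets
  to machine precision. Balanced-panel statistics computed from such a
  cohort are deterministic functions of the moment targets — the route by
  which published summary tables are reconstructed. Visits are drawn
  independently, so only statistics that depend on per-visit moments (not
  on the baseline–follow-up covariance, e.g. not the raw-change CI width)
  are pinned down.
* **Determinism**: a master seed fans out to per-subject child seeds via
  `SeedSequence.spawn`, so enlarging the cohort leaves earlier subjects'
  kinetics unchanged (the cohort-level pain pass does re-draw).

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: anatomy, partial-volume and registration
error, motion, coil inhomogeneity, synovial-fluid contamination of late
frames, Rician (rather than Gaussian) magnitude noise, and any deviation of
real tissue from extended-Tofts kinetics. Conclusions supported by the
tests are about the correctness of the computations, not about scanner
data.

## Numerical reconstruction notes

Reconstructing standardized changes from *printed, rounded* summary moments
reproduces published values to two decimals for six of the seven variables
(volume −0.30, RE_late −0.58, RE_max −0.62, `v_e` −0.39, `K^trans` −0.51,
KOOS −1.13). RER reconstructs to −0.60 against a published −0.61: its
moments (0.048/0.030 → 0.032/0.020) are printed with fewer significant
digits relative to their size, and the rounding residue is visible in the
second decimal. RER is therefore excluded from the exact reconstruction
targets and checked at the value the rounded inputs actually imply.

## Problem sizes in the test suite

The suite exercises voxel fitting on hundreds of voxels (200-voxel
noiseless recovery sweeps, 40-voxel noise ladders) and runs the full
image-based pipeline on 2-subject cohorts with ~9-voxel masks on 8×8×2
grids — sizes chosen so the whole suite runs in a few minutes while still
covering every stage end to end. Statistical calibration uses 2000
simulated null cohorts of n = 93 (CI coverage) and a single n = 5000 cohort
(correlation targeting). Cohort-level statistics are cheap and are tested
at the study scale (n = 93) directly.
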