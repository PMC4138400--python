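# Methods

## The assessment and its score

A subject squeezes a spring-loaded handgrip so that a cursor, driven by grip
force, follows a sinusoidal target scrolling across a screen. Force is
normalised to the subject's maximum voluntary contraction (MVC), so the
target spans 0–100 %MVC with its peak equal to the measured MVC. A trial
lasts 45 s; each visit comprises three trials.

The performance score is the mean absolute error (MAE) between target and
response in %MVC,

    MAE = (1/N) Σ_i |response_i − target_i|,

taken on the force axis at matched times: the display drives time externally,
so the error has no horizontal component. The three trial MAEs of a visit are
averaged into the visit score. Lower is better.

**Target shape.** The rendered target is the offset sinusoid
v(t) = 50·(1 − cos 2πt/T). The offset form is forced by physics (grip force
cannot be negative) and by the normalisation (peak = MVC). The period T
(default 9 s) and sample rate (default 50 Hz) are display configuration, not
physiological constants; both are arguments of `generate_target`. No onset
trimming is applied by default — whether the first seconds of a trial should
be discarded as reaction time is an open protocol question, so trimming is
left to the caller.

**Device calibration.** The device holds three of five springs (constants
0.38, 0.88, 1.94, 5.10, 10.70 lbs/inch) acting in parallel, so constants add.
`select_springs` enumerates all C(5,3) = 10 subsets and picks the one whose
resistance at full grasp — (Σ constants) × grip displacement — lies in the
70–80 % band of the subject's MVC, closest to the 0.75 midpoint; ties break
toward the stiffer set so the choice is deterministic. Grip displacement at
full grasp is a free parameter (default 1.0 inch): only the product
constant × displacement enters the band rule. If no subset reaches the band
the nearest subset is returned with an `out_of_band` flag rather than an
error, since a usable calibration is still needed at the extremes of grip
strength.

## Disability index

The Oswestry Disability Index (ODI) is a ten-item activities-of-daily-living
questionnaire, each item scored 0–5 with higher meaning more impaired. The
index is the mean of the answered items rescaled to [0, 1]:
Σ scores / (5 × n answered). Missing items are excluded from numerator and
denominator alike — the standard ODI renormalisation; with all ten items this
is the familiar sum/50. Patients with a 3-month post-operative index ≤ 0.6
are classed *functional*, the rest *nonfunctional*; the boundary is
inclusive.

## Cohort analysis

`CohortAnalysis(dataset).fit()` runs, in a fixed order:

1. **Scoring and classification.** Visit MAEs; functional status from the
   last patient visit's ODI.
2. **Group summaries.** Mean ± SD of the visit MAE for controls at first and
   last visit and patients pre-/post-operatively, with the post-operative
   group split by functional status.
3. **Percent improvement.** The raw change is (MAE_post − MAE_pre)/MAE_pre,
   negative when the error drops. Because group tables conventionally report
   a drop as positive "% improvement", the reported quantity is the negated
   formula (`improvement_magnitude`); both are available. Each patient
   subgroup's improvements are compared with the controls' by a two-sample
   t-test — Welch's unequal-variance form by default, since the groups'
   spreads differ severalfold (a pooled-variance variant is available behind
   a flag). Tests are unpaired: each contrast compares two distinct groups.
4. **Correlation.** All (subject, visit) pairs carrying both measures are
   pooled — with the default schedule that is the patients' pre and 3-month
   visits, n = 22 — and the tracking MAE, divided by 100 onto the ODI's
   [0, 1] scale, is correlated with the ODI (Pearson r, two-sided p from the
   t-distribution on n − 2 df).
5. **Influence screening.** The MAE~ODI simple regression (MAE regressed on
   ODI) is screened with Cook's distance. The distance is computed by literal
   leave-one-out refitting — d_i = Σ_j (ŷ_j − ŷ_{j(−i)})² / ((k+1)s²) with
   k = 1 fitted slope and s the residual RMSE — and cross-asserted against
   the closed form e_i²h_ii/((k+1)s²(1−h_ii)²) at every call; points with
   d_i ≥ 4/(n−(k+1)) are flagged. A single screening pass is the default
   (matching the one-shot use of the rule in practice); the pass count is
   configurable. The correlation is then recomputed without flagged points.
6. **Agreement.** Bland–Altman on the same pooled pairs in the direction
   MAE_fraction − ODI: bias = mean difference, limits of agreement
   bias ± 1.96·SD, bias CI = bias ± 1.96·SD/√n. The normal 1.96 multiplier is
   the default for the CI; a t-quantile variant is available. The identity
   loa_upper − loa_lower = 3.92·SD holds exactly by construction.
7. **Improvement correlation.** Across patients, percent improvement of the
   tracking score against percent improvement of the ODI, with and without
   subjects owning a flagged pooled point.

Missing timepoints yield absent report fields, never failures.

## Synthetic cohorts

No subject-level recordings of this assessment are publicly deposited, so
the package ships a generative simulator whose *structure* mirrors the study
design and whose defaults are calibrated to the published group summaries.

Each subject carries a latent impairment θ ≥ 0, drawn from a normal
distribution truncated at 0 (per group), an MVC, and a motor delay τ
(~60 ± 20 ms). A trial's response is the target delayed by τ plus AR(1)
noise:

    eps_i = φ·eps_{i−1} + innov_i,  innov ~ N(0, sd²),
    sd = (σ0 + σ1·θ) · λ^s,

clipped to the physical range [0, 120] %MVC (responses above the calibration
MVC are transiently possible; negative force is not). φ = 0.6 gives the
serially correlated tracking error real traces show; the AR(1) start is drawn
from the stationary distribution. s counts learning sessions completed before
the visit and λ = 0.865 shrinks the noise geometrically — motor learning.
Sessions are a per-visit schedule rather than a raw visit count: controls
(0, 1, 2) across their three visits; patients (0, 0.2, 0.4, 1.2, 2.0) across
pre, 24 h, 48 h, 2-week and 3-month visits. The fractional values encode that
consolidation tracks spaced practice over calendar time, so the two acute
in-hospital retests contribute little; with integer per-visit learning the
patients would out-learn the controls by schedule length alone, which the
observed improvements contradict.

Surgery multiplies a responder's θ by (1 − 0.25); a non-responder's θ grows
by (1 + 0.75), modelling the declining phenotype. The responder probability
defaults to 0.64 (≈ 7 of 11). Perceived disability is coupled to impairment
through a latent index clip(0.15 + 0.18·θ + N(0, 0.08²), 0, 1), discretised
to round(50·index) points spread deterministically over the ten items (each
capped at 5, remainder from item 1), so re-scoring the items recovers the
index to within 0.01. Surveys are attached at the patients' pre and 3-month
visits, giving the pooled n = 22 correlation structure.

**Calibration.** σ0 = 4.81 and σ1 = 4.0 %MVC, the group θ distributions
(controls: mean 1.0, SD 0.47; patients: half-normal with scale 2.4) and
λ = 0.865 were fixed once by solving the empirical linear map from innovation
SD to expected visit MAE so that the simulated group means land on the
published summaries: control first visit ≈ 8.1 %MVC (SD ≈ 1.6), control last
≈ 6.2, patient pre-op ≈ 11.2. The patient spread was deliberately kept to a
clean half-normal rather than matching the published patient SD exactly —
reproducing both the printed mean and SD forces a degenerate, effectively
exponential truncated normal. Calibration constants live only in
`SimulationConfig`; no logic hard-codes them.

**What the simulator does not emulate.** Within-subject day-to-day
variability beyond trial noise (so simulated percent-improvement spreads are
narrower than observed); any clinical dynamics at the acute timepoints;
fatigue within a session; the negative MAE–ODI correlation reported in some
cohorts (here both scales worsen with θ, so their simulated correlation is
positive — the analysis code makes no assumption either way); and the
published nonfunctional group's mean *decline* (threshold classification
reassigns improved high-impairment responders into the simulated
nonfunctional group, pulling its mean improvement slightly positive).
Passing tests therefore demonstrate correctness of the scoring and analysis
machinery and the qualitative group structure, not subject-level realism.

## Numerical choices

- Visit aggregation warns (does not fail) below three trials, so incomplete
  real-world visits remain scoreable; an empty visit is an error.
- MAE inputs must be NaN-free; no silent dropping.
- Cook's distance raises if the leave-one-out and closed-form routes ever
  disagree beyond 1e-8 relative / 1e-10 absolute; a perfect fit (s = 0)
  returns all-zero distances.
- The outlier threshold comparison is inclusive (≥), matching the rule's
  statement.
- Pearson and the t-tests are delegated to scipy.stats behind this package's
  interfaces; the regression, Cook's distance, screening rule, percent
  improvement and Bland–Altman are implemented here and are cross-checked in
  the tests against independent oracles (statsmodels influence measures,
  textbook formulas).
- Reproducibility: one `SeedSequence` per cohort, spawned into independent
  per-subject streams; identical config + seed gives byte-identical outputs.

## Problem sizes in the test suite

Unit tests run on scaled-down trials (9 s at 25 Hz) and small cohorts;
whole-pipeline checks use the full study geometry (18 controls, 11 patients,
45 s × 50 Hz trials) across 50 replicate seeds, which completes in seconds.
The acceptance script simulates one full default cohort per invocation.
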