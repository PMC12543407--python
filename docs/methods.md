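# Methods

## Model

The package implements a time-shift (self-modelling registration) model of
dementia progression. All participants are assumed to follow a single mean
CDR-SB trajectory `m` up to a subject-specific time shift δ:

    y_ij = m(age_ij + δ_i) + ε_ij,      FDI_ij = age_ij + δ_i.

`m` is a three-parameter logistic `m(t) = C / (1 + exp(−k (t − t0)))` with
the ceiling fixed at the CDR-SB maximum C = 18. The logistic is a design
choice: it is monotone, bounded by the valid score range, and reproduces the
qualitative shape of observed mean trajectories (flat below an FDI of ~75, a
sharp rise between 75 and 100). The curve family is recorded in the model
file so alternatives can be added without breaking serialization.

A shift-only random effect is the minimal structure consistent with mapping
chronological age onto a common disease timescale; per-subject progression
rates (slopes) are deliberately out of scope.

## Estimation

Alternating penalized least squares:

1. initialize all δ_i = 0;
2. fit (k, t0) to the pooled points (age_ij + δ_i, y_ij) by nonlinear least
   squares (`scipy.optimize.least_squares`, trust-region reflective, warm
   started from the previous iterate);
3. update each δ_i by minimizing Σ_j (y_ij − m(age_ij + δ_i))² + λ δ_i²
   over δ ∈ [−30, 30] years: a 0.25-year grid search followed by bounded
   scalar refinement (tolerance 1e-3) around the grid optimum;
4. repeat until the largest shift update is below 0.01 years and the
   relative curve-parameter change is below 1e-4, or 100 iterations
   (non-convergence is returned, flagged, not raised).

The ridge penalty (λ = 1e-3 by default, configurable) is a lightweight
stand-in for Gaussian random-effect shrinkage in a nonlinear mixed-effects
fit. It also resolves the translation gauge: the model is invariant to
shifting all δ and t0 together, and the ridge pins this freedom by shrinking
shifts toward zero over the whole cohort — the same convention by which
mixed-effects software anchors random effects at zero mean, keeping the FDI
scale age-like. A hard re-centering of the shifts (subtracting their mean
with a compensating t0 adjustment) was evaluated and rejected: whether a
shift is identifiable is itself informative (participants observed in the
rising region have systematically late shifts), so re-centering on them
translates the whole scale by several years. Note that predictions θ − δ
are invariant to this gauge choice; only the interpretation of FDI values
against chronological age depends on it.

### Identifiability

A trajectory that stays in the flat region of the curve (e.g. all scores 0)
constrains δ only to a half-line, not a point. A shift is flagged
`identifiable = False` when the unpenalized SSE profile is flat over the
whole grid (range < 1e-6), or when the near-minimum set of shifts — within
`4 · SSE_min / (n − 1)` of the minimum, roughly a 2σ move of one residual —
spans more than 1 year. "Identifiable" therefore means the data pin the
shift to sub-year precision; on the default synthetic cohort this subset
shows shift errors with SD ≈ 0.4 years. Unidentifiable shifts are still
reported (the ridge pulls them toward the least-penalized feasible value)
and still contribute censoring times downstream, but are flagged.

## Thresholds

Onset events are placed at the FDI of the first visit with a qualifying
diagnosis (clinician label when present; CDR-SB staging — CU < 0.5, MCI
0.5–4.5, AD > 4.5 — as fallback). Participants already at or past the
endpoint at their first visit are excluded as prevalent cases rather than
modelled with delayed entry; participants who never qualify are
right-censored at their last visit. Direct CU→AD converters count as MCI
events at the AD visit (MCI onset is latent but no later than AD onset);
excluding them instead is a config option.

Survival is estimated by the Kaplan-Meier product-limit estimator
(`lifelines`), events before censorings at tied times, log-log 95%
confidence limits. The threshold θ is the first event time at which S ≤ 0.5
— no interpolation, since KM is a step function. Stratified thresholds
(sex, comorbidities) repeat this per stratum; strata under 20 participants
(configurable) are reported undefined rather than extrapolated.

The packaged default model carries the published thresholds (overall MCI 79
/ AD 85; AD 84.7 male / 85.5 female; per-comorbidity disease /
disease-free values). The original mean-curve coefficients are not public:
the packaged curve is reconstructed by solving m(79) = 0.5 and m(85) = 4.5
(giving k = ln(35/3)/6 ≈ 0.4095, t0 ≈ 87.68), and its provenance metadata
says so explicitly.

## Prediction and evaluation

Predicted onset age for endpoint e is θ_e − δ, with δ estimated against the
model's curve. Predictions in the past are flagged, never clamped, because
downstream uses (e.g. trial enrichment) need the raw value. Evaluation uses
only visits strictly before the observed onset (at least 2 required),
preventing post-onset leakage; an onset is considered observed only if it
falls within the participant's follow-up window. Errors are signed
predicted − observed; MAE and RMSE carry 95% percentile-bootstrap intervals
(B = 1000, seeded) — a method choice, since no interval method is canonical
for these metrics.

## Synthetic cohorts

The generator draws, per participant: shift δ* ~ Normal(0, 6 y); baseline
age ~ Normal(72, 7) truncated to [60, 95] (matching observational Alzheimer
cohort enrolment); follow-up ~ Uniform(3, 10) years with visits every 1.5
years; observed score = clamp(round-to-0.5(m*(age + δ*) + Normal(0, 0.5)),
0, 18). Diagnosis labels are the latent (noise-free) stage at each visit,
optionally delayed by one visit with a configurable probability to emulate
late clinical recognition. Ground-truth onset ages are the exact solutions
of the latent score crossing the staging cuts, so the estimand is separated
from measurement error — the default calibration puts every true onset at
FDI 79 (MCI) and 85 (AD). Optional covariate effects move a stratum's
conversion FDIs additively; they act on the conversion points rather than
the trajectory shape, because a trajectory-level shift would be absorbed by
alignment and leave no recoverable stratum difference.

"Noise-free" in tests means noise SD 0 *and* grid rounding off: rounding is
part of observation noise, and sub-quarter-year recovery statements are
only meaningful without it.

What the generator does not emulate: attrition by death, non-Alzheimer
etiologies, amyloid status, irregular visit schedules, rater disagreement,
and any misspecification of the single-curve assumption itself. Passing
recovery tests therefore demonstrates internal consistency of the
estimation machinery, not performance on real cohort data.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use cohorts of n = 500 with ~4–7
visits each; the alternating fit converges in ~20 iterations (a few seconds
on one CPU). Shift bounds ±30 years, grid 0.25 years, refinement tolerance
1e-3, curve fit warm-started between iterations. Degenerate inputs raise
typed errors: flat binned data ("no rising signal"), fewer than 3 usable
bins, fewer than 2 scored visits, survival curves that never reach the onset
probability ("threshold undefined" — never extrapolated).

## Known limitations

- The alternating ridge-penalized fit is a pragmatic realization of a
  nonlinear mixed-effects model, not a marginal-likelihood estimator; shrink
  strength does not adapt to the residual noise level, so shifts of subjects
  observed only in the deep tail of the curve are slightly over-shrunk.
- The FDI origin (gauge) is pinned by shrinkage, not externally anchored;
  comparing absolute FDI values across models fitted to different cohorts is
  only meaningful up to a translation.
- Thresholds inherit the visit-schedule discretization: an onset is recorded
  at the first qualifying visit, up to one visit interval after the true
  crossing, which biases fitted thresholds slightly late (~half the visit
  interval under the default cadence).
- The MMSE pathway (30 − MMSE through the same machinery, ceiling 30) is
  wired in but ships no MMSE staging cuts; users must supply their own.
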