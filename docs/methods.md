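# Methods

This note records the statistical procedures the package implements,
the defaults it ships, and the design choices made where more than one
reasonable implementation exists.

## Detection procedure

Detection operates per participant on the weekly LSAS series, treating
weeks as 1-based consecutive integers. An interval (n, n+1) is a
*candidate* only if both endpoint weeks are observed and each flanking
window — weeks n−2..n and n+1..n+3, truncated at the trajectory edges —
retains at least `min_window = 2` observed values. Consequently week 1
is never a pre-gain week (its pre-window holds a single value), and an
interval spanning an unobserved week is never tested; nothing is
imputed.

The three criteria:

* **Criterion 1** (absolute): drop ≥ `cutoff` (default 12 LSAS points).
  Treated as *inclusive* at the boundary. The relative criterion is
  stated as "at least 25%", which is inclusive; we adopt the same
  convention for the absolute cutoff for internal consistency, since a
  12.0-point drop is exactly the minimum reliable change the cutoff
  encodes.
* **Criterion 2** (relative): drop ≥ `pct · x_n` (default 0.25),
  inclusive. A pre-gain score of 0 admits no positive drop and fails.
* **Criterion 3** (stability): `mean(pre) − mean(post) >
  t_crit(n_pre, n_post) · s_pooled`, *strict*, with
  `s_pooled = sqrt((s²_pre + s²_post)/2)` using sample (n−1) SDs.
  `t_crit` is the two-sided `1 − α/2` Student-t quantile with
  `df = n_pre + n_post − 2` (α = 0.05): 2.776 for (3,3) windows —
  conventionally printed 2.78 — 3.182 for (2,3)/(3,2) and 4.303 for
  (2,2). Deriving the missing-data multipliers as t quantiles
  reproduces the full-window constant exactly and is monotonically more
  stringent as observations are lost, which is the property the
  adjustment exists to provide. When both windows have zero variance
  the right-hand side is zero and any positive mean difference passes.

**Reversal**: a gain is reversed at the first later week whose score
reaches `x_{n+1} + 0.5 · magnitude`, inclusive. **Primary gain**:
largest magnitude, ties to the earliest week. **Occurrence rate**:
percentage of analysed participants with ≥1 gain, rounded half away
from zero. Magnitude statistics and the pre-gain-week histogram pool
*all* detected gains, not only primaries; overlapping qualifying
intervals are counted as separate gains.

The inclusion rule drops participants with fewer than 8 observed weekly
LSAS values (configurable); the count is of observed LSAS
administrations, not weeks on treatment.

## Mixed models

Both model families are random-intercept linear mixed models estimated
by maximum likelihood (statsmodels `MixedLM`).

*Outcome model*: endpoint LSAS on `time (post, follow-up) × gain status
+ baseline LSAS (centred)`, random intercept per participant.
The interaction makes the per-timepoint group comparison estimable; the
reported quantity is the covariate-adjusted (no-gain − gain) difference
at each timepoint. If the data are degenerate (residual variance
numerically zero) the fixed effects are taken from the exact OLS
solution, which the mixed model collapses to in that limit.

*Process models*: each around-gain measure on the six-level timepoint
factor, random intercept per participant, missing rows dropped. The
five consecutive contrasts (later minus earlier, so drops are negative)
are Wald tests with a residual between-within df approximation
(`n_obs − n_fixed-effect columns`) — exact for balanced complete
panels, mildly conservative otherwise. Bonferroni correction uses
factor 5 *within* each measure, matching the per-measure organisation
of the contrast table; the correction family is a design choice, and
the factor is exposed as an argument.

*Effect sizes*: Cohen's *d* = |contrast| / pooled raw sample SD of the
two cells being compared (pooled with n−1 weights). A model-based
standardiser (residual SD) was the alternative; the raw-score version
was chosen because it is interpretable on the instrument's published
scale and computable from reported cell summaries. With zero dispersion
*d* is undefined and reported as NaN.

## Synthetic cohorts

The generator's defaults encode the study conditions the analyses
assume:

| parameter | default | rationale |
|---|---|---|
| participants | 146 | analysed-sample size |
| gain prevalence | 0.39 | participant-level occurrence |
| P(second gain) | 13/57 | two-gain subset among gainers |
| baseline LSAS (gain / no-gain) | N(85.74, 21.35) / N(80.12, 18.88), truncated 35–140 | group baselines |
| duration | round N(14.53, 3.33), clipped 8–30 weeks | treatment-length distribution |
| gradual slope (gain / no-gain) | 3.0 / 2.1 LSAS/week | reconciles baselines with endpoint cell means net of the step gain |
| AR(1) noise | ρ = 0.3, innovation SD 2.5 | week-to-week fluctuation small enough that spurious qualifying intervals are rare |
| missingness | 8% MCAR, never at week 1 or an injected gain's weeks n, n+1; ≥8 observed LSAS enforced | no missingness mechanism is assumed |
| step magnitude | 9 + Gamma(mean 10.8, matching SD), i.e. mean 19.8 / SD 12.5 above a floor of 9 | see below |
| pre-gain-week weights | bimodal, peaks at weeks 2 (0.30) and 6 (0.22) | qualitative histogram shape; the heights are free parameters |
| reversal rate | 0 | reversals are rare; an explicit switch injects a decaying rebound that crosses the 50% threshold |

**Magnitude calibration.** The target distribution for detected gains
is mean 25.29, SD 11.27 — but a normal with those moments puts ~12% of
its mass below the 12-point cutoff, which qualifying gains cannot have.
The generator therefore draws the injected step from a floor-plus-gamma
family (hard floor, right skew) and was calibrated once so that the
*certified realised* interval drops — injected step plus the week's
gradual improvement plus noise, conditioned on passing all three
criteria — average ≈25.0–25.7 with SD ≈11, stable across seeds. Weeks
are drawn feasibility-aware: a magnitude is only placed where the 25%
criterion is attainable given the expected symptom level (small gains
land late, where scores are lower — the same mechanism that produces
small qualifying gains in real data).

**Certification.** After noise, integer rounding and missingness, each
trajectory is scanned by a brute-force checker (independent of the
detection module) and resampled until its qualifying intervals are
exactly the injected set. Ground truth is therefore exact by
construction: on generated cohorts the detector owes 100% sensitivity
and zero false positives, and any deviation is a detector bug, not
simulation noise. The replication cohort fixes the per-participant
subsets (89 / 44×1 / 13×2), so its occurrence rate (39%) and total gain
count (70) hold for any seed.

**Process coupling.** Process measures are level + participant
intercept − weekly slope + Gaussian noise, integer-rounded and clipped
to their scales, with gain-locked drops: SCQ frequency −5.81 at
(n−1→n) and −8.64 at (n→n+1); SCQ belief −194.65 and both attention
items −0.83/−0.86 at the gain interval; PHQ-9 none. Between/within SDs
(e.g. 5/6 for SCQ frequency) were chosen so the implied raw-scale
effect sizes sit near 0.7 and 1.05 for the two frequency contrasts and
the remaining contrasts stay null.

**What the generator does not emulate:** informative missingness or
dropout, therapist or site effects, floor effects other than hard
clipping, reversal prevalence, and any causal linkage between the
process drops and the symptom drop (they are co-timed by construction).
Passing tests on these cohorts demonstrates that the pipeline recovers
known structure under the stated noise model — not that the clinical
findings themselves generalise.

## Simulation studies in the test suite

* *Oracle equivalence*: the detector matches an independently coded
  brute-force checker (t quantiles obtained by inverting the
  incomplete-beta CDF) interval-by-interval on 10,000 random short
  trajectories with missing weeks.
* *Outcome-model recovery*: 500 replicates at n = 146 with a true
  25-point post-intervention difference, residual SD 15 and intercept
  SD 8: mean estimate within Monte-Carlo error of 25, ~95% Wald
  coverage; 500 null replicates keep the type-I error inside [3%, 7%].
* *Process-pattern recovery*: 200 replicates at n = 57 with the default
  frequency coupling: both injected contrasts Bonferroni-significant in
  >80% of replicates, the three non-injected ones in <10%.

Problem sizes (10,000 trajectories, 500/200 replicates, cohorts of
1,000) were chosen to make Monte-Carlo error small relative to each
assertion's tolerance while keeping the default suite fast.

## Known limitations

* Contrast p-values use the residual-df approximation rather than
  Satterthwaite/Kenward-Roger, which statsmodels does not provide for
  `MixedLM`; with ≥57 participants the difference is negligible.
* The outcome model assumes a common residual variance across the two
  timepoints.
* "Post-intervention" defaults to the last observed weekly LSAS when no
  explicit endpoint column is supplied; studies with a distinct
  end-of-treatment assessment should provide endpoints explicitly.
* The ≥8-datapoint inclusion rule counts LSAS administrations only; if
  a study's minimum-dose rule counts any measure, filter upstream.
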