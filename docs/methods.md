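# Methods

## Journey model

A patient's journey is modelled as an alternating sequence of contacts
and no-contact (N) sojourns.  The contact-type sequence is treated as an
embedded Markov chain over {I, O, E}: the estimated transition
probability is the likelihood of the *next* contact being of a given
type conditional on the previous contact's type, not a per-unit-time
transition rate.  Estimation pools consecutive type pairs over all
patients in scope, so patients with longer journeys carry
proportionally more weight; this pooled estimator is the one under
which per-group matrices and the AP matrix are consistent (AP pair
counts are exactly the sum of group pair counts).  Rows with no
observed departures are reported as undefined (NA), never as zeros —
an observed 0% (e.g. a group that never chains two emergency
presentations) is a different statement from "no data".

Journey construction sorts each patient's events by start time;
simultaneous events break ties as E before I before O (emergency
presentations clinically precede the admissions they trigger) and then
by encounter id, making the journey invariant to input order.  Gaps are
`next.start − this.end` in fractional days, clamped at zero when
contacts overlap — the transition is retained, the negative gap is not.
The gap after the final observed contact is censored and excluded from
all waiting-time statistics; including it would mix window truncation
into the N-state sojourn law.  The time unit is fractional days
throughout.

Outpatient appointments carry only a start time in costing extracts, so
every O contact is assigned a nominal duration, default 1 hour = 1/24
day (configurable via `JourneyConfig.outpatient_duration_days`).  The
convention matters less for the O row itself than for preventing the N
state from silently absorbing outpatient time.

Age stratification uses age at first recorded contact with a cutoff of
65 years (`age_cutoff_years`): strictly below is Young, at or above is
Old.  The cutoff is both near the cohort's median age at first contact
and the Australian retirement age.

## Statistical tests

Contact-mix differences are tested with Pearson's chi-squared on the
type × group count table (no continuity correction), df = (r−1)(c−1),
overall and for each of the six unordered group pairs.  Pairwise
p-values are reported raw — no multiplicity correction — with
significance flags at 1% and 10%, the two levels used when reading the
pattern.  Within a pairwise slice, a contact type unobserved in both
groups is dropped before testing (it carries no information for that
contrast); the strict API-level test still raises on degenerate
margins.

Waiting times (step durations, "in contact", and gaps labelled by the
previous contact type, "between contacts") are analysed with an OLS
regression on treatment-coded contact type, group, and their
interaction.  F-tests are hierarchical model comparisons: the
interaction against the main-effects model, and the group main effect
against the contact-type-only model.  If the interaction's p-value is
at least `alpha_drop` (default 0.05 — the drop rule's level is a
convention, stated nowhere more precisely than "not significant"), the
final model is the main-effects fit and the interaction fields are
absent from the result.  With large, near-balanced data the choice of
sums-of-squares convention is immaterial to conclusions.  Observations
are treated as independent: the model carries no per-patient random
effect, mirroring the original regression specification; repeated gaps
from one patient are correlated in truth, so p-values on real data are
anti-conservative.  This is a known limitation, not an accident.
Waiting times enter untransformed.

Degenerate inputs are handled explicitly: an all-constant response
yields F = 0, p = 1 (rather than 0/0); an interaction made inestimable
by empty cells is dropped with a warning; fewer than two groups is an
error; a single contact type reduces the model to a group-only fit.

## Synthetic cohort generator

The generator emulates the statistical structure the estimators assume
— a semi-Markov journey process — with known ground truth:

* per group: an initial contact-type distribution, a 3×3 row-stochastic
  transition matrix, and per-previous-type gap laws;
* per contact type: a duration law (I and E lognormal, O fixed).

Each patient draws an initial type and a start time uniform in the
first 30 days of the window (the real distribution of journey starts is
unknown; this is a declared convention), then alternates
duration → gap → next type until the next contact would start after the
window's end.  Durations and gaps are drawn independently of the next
state, matching the estimators' conditioning on the *previous* type
only.  Timestamps are floored to minute precision on emission
(sub-minute rounding is negligible against day-scale statistics).
Generated patients never overlap their own events; overlap handling in
journey construction is exercised by hand-built fixtures instead.  All
draws flow from one `numpy` generator seeded from the config, so output
is a pure function of the configuration.

Defaults are the published cohort's conditions: group sizes
127/130/81/55 (MY/MO/FY/FO), the published per-group transition rows
(renormalised to sum to 1 at machine precision) and per-group mean gaps;
durations use the pooled published means because the duration law is
specified per type.  Where only a mean is published, lognormal laws use
coefficient of variation 1 (sd = mean) — right-skewed, as waiting times
are, and fully determined by the published mean.  The initial-type
distribution is each group's published contact-type mix.  Ages are
drawn uniform within class (Young 20–64, Old 65–90); only the binary
class is used downstream.

What the generator does **not** emulate: calendar structure (weekday
clinics), patient entry/exit within the window (every simulated patient
spans the full two years, so simulated volumes are ~220 contacts per
patient versus the published average of ~131 — recovery tests therefore
compare against the configured truth, not published volumes), dropout
or death, within-patient correlation beyond first-order type
dependence, and costs.  Passing recovery tests shows the estimators are
consistent under the assumed process, not that real journeys follow it.

## Validation strategy and problem sizes

* Exactly recomputable published results: the chi-squared statistic
  (923.56, df 6) and the pairwise significance pattern from the
  published count table; the average/proportion cells that are ratios
  of published counts.  One published average cell (FO inpatient)
  disagrees with its own inputs by 0.09 — an apparent typo in the
  source table — and several proportion cells differ from the count
  ratios by 0.01 from rounding provenance; only self-consistent cells
  are asserted.  The published ANOVA F values and the transition/time
  tables require the raw hospital events and are used only to
  parameterise the generator.
* Parameter recovery: a default-scale cohort (393 patients, two-year
  window, ~85k events, fixed seed) must recover every transition cell
  within 3 binomial standard errors and every gap mean within 3
  standard errors.  A 3-SE criterion over ~50 cells has a ~10% chance
  of one random exceedance under an arbitrary seed; the suite pins one
  seed.
* Oracle equivalence: chi-squared and ANOVA F statistics match
  independent brute-force implementations (explicit cell sums; one-hot
  design matrices + lstsq residual sums of squares) on 20 randomized
  fixtures each, to 1e-8 relative.
* Calibration: under a no-group-effect lognormal record generator
  (50 records per group × type cell, CV 1), the group F-test at
  α = 0.05 rejects in 3–7% of 1000 replicates.  The cell size is large
  enough for the F-test's normality assumption to bite only mildly
  despite lognormal errors.

Simulation sizes in the test suite (small cohorts of 10–50 patients per
group over 60–400-day windows for structural checks, full scale only
for the recovery check) keep the whole suite under a minute while
leaving every statistical tolerance at its stated value.

## Pipeline conventions

Rendered tables follow the published layout: columns AP, MY, MO, FY,
FO; counts as integers, averages and percentages to two decimals, times
to four; undefined cells as NA.  Internal values keep full precision.
The run manifest records the package version, seed, config hash and row
counts; rerunning with the same configuration reproduces every output
byte for byte.
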