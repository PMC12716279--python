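# Methods

## The model and its assumptions

`hearspan` implements an incidence-based multistate life table on a
discrete-time Markov chain over five states — healthy (H), hearing loss (L),
dementia (D), comorbidity (C), death (X) — and forty single-year ages 60–99.
The central assumptions are:

* **Markov in (age, state).**  Transition probabilities depend on current
  age and state only, not on duration of illness or past trajectory.
* **Irreversibility.**  An acquired condition is never lost; death is
  absorbing.  The allowed-move mask is enforced end to end: panel
  validation rejects forbidden moves, estimated and parametric surfaces are
  zero outside it.
* **Annual snapshots.**  The state attached to a calendar-year record is
  the state on record at year end, so onset during year y appears as a
  changed state at record y+1, and each pair of consecutive records is one
  observed transition.  Competing events within a year (e.g. onset versus
  death) are resolved by a single multinomial draw over the full
  destination row; there is no intra-year ordering.
* **Synthetic-cohort interpretation.**  Probabilities are period estimates;
  expectancies and risks describe a hypothetical cohort exposed at every
  age to the period's transition probabilities, not any real cohort's
  future.
* **Truncation at 99.**  The chain is truncated after the age-99 occupancy;
  years lived beyond 99 are discarded, which slightly lowers life
  expectancy relative to an open-ended life table.  The analytic closure
  (death at the end of the age range) lives in the estimated surface's
  age-99 row; simulated panels simply censor after the age-99 record, so
  panel ages never exceed 99.

## Estimation

Transitions are tabulated over consecutive-record pairs within persons,
stratified by sex and education (either dimension may be pooled).
Probabilities are row proportions — no smoothing, no parametric hazard, no
covariate adjustment — which is appropriate for full-population register
data and keeps every downstream quantity a deterministic function of the
panel.  A censored final record contributes exposure to no pair.  Rows with
zero exposure default to `carry_identity` (stay probability 1, logged) so
small panels run end to end; a strict `fail` mode raises instead.

Starting-distribution weights are the shares of living-state person-years
at ages in the half-open window [60, 65).  Person-years rather than persons
are used, consistent with period tabulation, and the window excludes exact
age 65; both choices are configurable.

## Expectancies and risks

Occupancy probabilities are computed twice, by design: a forward recursion
through the matrices P(x), and the fundamental matrix N = (I − Ũ)⁻¹ of the
transient supermatrix Ũ (160 × 160; blocks map age x living states to age
x+1 living states, so Ũ is nilpotent and the inverse exists).  The
recursion is the reference implementation; the fundamental matrix is kept
because it is the canonical construction in the multistate literature, and
the equality of the two paths (to 1e-10) is a standing test.

Conditional expectancies subtract a half-year correction of 0.5 from the
origin state's occupancy sum — equivalently from the total — before the
starting weights are applied.  The mid-interval sentence this implements is
ambiguous between an origin-state and a per-transition correction; the
origin-state reading is used because it matches the standard mid-interval
convention, keeps LE(60|i) = Σ_j e_j(60|i) an exact identity, and applies
"before the weights" as stated.  With it, a forced one-year occupancy gives
e = 0.5 and a deathless chain gives 39.5 years.

Lifetime risk is strict first passage: the destination state's rows are
replaced by self-loops and the absorbed mass is read at the horizon (99
lifetime, 80 partial, inclusive of the age-80 observation).  Moving H → C
directly therefore does not count toward the dementia risk; a variant
accepting a set of destinations (e.g. {D, C}, "any dementia") is exposed
for sensitivity analyses.  Unreachable pairs (L → D and the
like) are exactly zero.

## Uncertainty

The bootstrap resamples whole person trajectories.  Because recomputing
every statistic on thousands of full-population resamples is wasteful, the
interval *length* is estimated on one f-fraction subsample (default 5%) —
B = 200 with-replacement resamples of the subsample, 2.5th–97.5th
percentile spread — then rescaled by √f (1/√20 at f = 0.05) and placed
symmetrically around the full-panel point estimate.  Percentile lengths
were chosen over normal-approximation lengths as the more assumption-free
reading of "interval length"; the subsample is drawn once and shared by all
statistics so comparisons share their resampling noise.  Every statistic is
recomputed end to end (weights, surfaces, expectancies, risks) per
resample, so all estimation noise propagates.  Determinism given a seed is
part of the contract.

## The synthetic register

The generator emulates the structure of annual administrative registers:
staggered entry over an 11-year window (front-loaded first year for the
prevalent pool, uniform thereafter), entry ages 60–99 with exponentially
declining weights, sex and education strata, left truncation, and right
censoring at period end.  Its truth surface is Gompertz mortality
q(x) = a·e^{b(x−60)} with state multipliers (r_H = r_L = 1.0,
r_D = r_C = 2.2), sex multipliers (1.25 male / 0.8 female) and education
multipliers (1.15 / 1.0 / 0.85), plus logistic-in-age incidence curves per
admissible onset move.  Defaults (a = 0.009, b = 0.085, and curve levels /
slopes in `build_default_spec`) are calibrated qualitatively, not fitted:
they reproduce the orderings that define the study conditions — hearing
loss carries no excess mortality; incidence into comorbidity from hearing
loss exceeds healthy→dementia and dementia→comorbidity incidence at every
age; women have lower mortality, higher dementia incidence and lower
hearing-loss incidence — and magnitudes in the right range (male life
expectancy at 60 near 20 years, female near 23.5, lifetime hearing-loss
risk near 22%).  Entry-state weights reproduce the observed near-age-60
composition (men 92.5% H / 5.8% L, women 93.2% / 5.7%, remainder split
D : C by the entry shares).

What the generator does **not** emulate: diagnosis-level events (ICD/ATC
codes and their case definitions), duration dependence, secular trends
within the window, age-varying entry-state prevalence, migration, and any
intervention effects.  Passing recovery tests therefore demonstrates that
the pipeline correctly inverts the discrete-time model it assumes — not
that the model captures every feature of real register data.

A closed-cohort microsimulation (`microsimulate_summaries`) shares the
generator's draw semantics but starts everyone at exact age 60 with no
truncation or censoring.  It is the independent oracle: at 10⁶
trajectories its Monte-Carlo error is a few thousandths of a year for
expectancies and a few ten-thousandths for risks, comfortably inside the
0.05-year / 0.005-probability acceptance tolerances.

## Numerical choices

* Row-stochasticity is validated at 1e-9; the two occupancy algorithms must
  agree to 1e-10; closed-form checks hold to 1e-12.
* The fundamental matrix is obtained by a dense linear solve (160 × 160 is
  trivial); no explicit inverse is required by any contract.
* Candidate row overflow in the parametric surface (off-diagonal mass > 1)
  raises by default (`cap="error"`) to keep truth surfaces honest; a
  proportional-rescale option exists for stress tests and deliberately
  extreme parameter sets.
* Probabilities and expectancies are kept in full double precision
  internally; output CSVs use a 10-significant-digit format so identical
  runs are byte-identical, and the risk tables carry a percent column
  rounded to one decimal.
* Pooled strata ("all") in the parametric surface use baseline curves
  (multiplier 1.0); a pooled *empirical* stratum is a genuine mixture over
  education, which is why parameter-recovery checks compare concrete
  (sex, education) strata and aggregate afterwards.

## Problem sizes

Validation uses 10⁶ microsimulated trajectories per (sex, origin) cell for
oracle equivalence, a 500,000-person panel for parameter recovery (every
well-exposed cell within 5 binomial standard errors; implied per-sex life
expectancy within 0.1 years), 25k/100k-person panels for the bootstrap
root-n and subsample-rescaling checks, and 50 random mask-respecting
surfaces for algorithm equivalence.  `scripts/acceptance.py` uses a
250,000-person register, at which size the bootstrap CI for overall life
expectancy is ≈ 0.16 years — small relative to every reported contrast.

## Known limitations

* No duration dependence or cohort trends; the Markov-in-(age, state)
  assumption is untestable from within the model.
* The pooled-sex stratum mixes male and female dynamics into one chain;
  it is reported for convenience, not as a structural model.
* `carry_identity` can bias high-age expectancies upward in very small
  panels (survivors parked in their state); use `fail` mode or pool strata
  when exposures are thin.
* The subsample-rescaled bootstrap assumes √n scaling of the interval
  length; for statistics with heavy-tailed influence this shortcut can
  misstate the length, which is why the full-resample (f = 1) path is kept.
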