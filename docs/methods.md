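# Methods

## The multi-state model

The subject-level process is a continuous-time jump process on eight states
on an age axis: employment (1), sick leave (2), vocational rehabilitation
(3), medical rehabilitation (4), time-limited disability benefits (5),
disability benefits (6), emigrated (7) and dead (8, absorbing). Employment
is defined negatively — any time not covered by a registered episode — so
it also absorbs education and (historically low) unemployment. For
restricted means and regression models states 3–5 are merged into a single
*time limited benefits* state; occupation curves can be produced on either
space (`StateSpace.merge_map` controls the projection).

Observation is limited to a calendar window (1992–2008 by default) for
cohorts born 1950–1980, with follow-up starting no earlier than age 20.
This yields *delayed entry* (a man born in 1950 is first seen at age 42, in
whatever state he then occupies) and administrative right-censoring, both
handled through the risk sets: `Y_j(t)` counts only persons currently
under observation and in state `j`, with the left-limit convention that a
person leaving `j` at `t` is still in `j`'s risk set at `t`. Time is
continuous fractional years; intervals are half-open `[start, end)`.

## Counting process construction

`episodes_to_process` fills employment into every gap, emits one event per
spell junction, and merges same-state adjacencies into one unbroken at-risk
interval. Same-state re-episodes (a new grant of the same benefit, which
real registries record in bulk) are kept in the *event stream* so the
transition-count table reproduces registry bookkeeping, but they carry no
intensity: a `j→j` hazard is undefined and the estimators use only `j≠k`
events. For every person the intervals tile the observation window exactly
(up to the death age), asserted to 1e-9 years in the tests.

Transition types observed fewer than `min_count = 10` times are removed.
The interrupted spell is *not* re-censored at the removed event: it
continues through the destination spell as if the transition had not
happened, with follow-on events re-attributed to the continuing state.
Re-attributed events that become same-state merge their spells; ones whose
re-attributed type is itself sub-threshold are suppressed too, so no
surviving event carries a sub-threshold type. The one place the
"no re-censoring" rule cannot apply is a removed *terminal* transition
into death: there is no observation afterwards, so the spell is closed as
censored at that age. Counts are tabulated once, before removal; the
filter is a single pass (iterating tabulation and removal would make the
result depend on processing order for no practical gain — removed types
have at most nine events by definition).

## Estimators

Nelson–Aalen increments are `n_jk(T_s)/Y_j(T_s)` with variance increments
`n_jk/Y_j²`, ties aggregated at each distinct event time. Aalen–Johansen
applies one factor `I + ΔĤ(T_s)` per distinct time (simultaneous events
across origin states share a factor), with the diagonal set to minus the
row sum; a factor with a negative diagonal — more simultaneous exits than
persons at risk — is rejected as a tie-handling violation. On a two-state
alive→dead reduction this product limit is algebraically identical to
1 − Kaplan–Meier under the same tie handling; the suite asserts agreement
with the lifelines implementation to 1e-12.

Occupation curves are stored as right-continuous step functions evaluated
at every event time (a requested grid only adds breakpoints for export,
never changes values), and restricted means are exact step-function
integrals — there is no quadrature error, and `Σ_k Ê_k = t1 − t0` holds to
machine precision, which the report generator enforces before writing any
table. The product-limit step assumes the process is Markov given the
covariate group; occupation probabilities are known to be more robust to
Markov violations than the conditional transition probabilities, which is
one reason the package reports them rather than `P̂_jk` panels.

## Simulation-based intervals

Inference replicates the estimated increments `B = 1000` times with
independent Gaussian noise of variance `n_jk/Y_j²` (independent across
transition types and event times), pushes each replicate through the same
product-limit propagation, and takes empirical percentiles (a
normal-theory variant from the replicate SD is available). The point
estimate is always the unperturbed one, and percentile endpoints are
anchored so the point estimate lies inside its own interval.

Negative perturbed increments are **allowed** by default. Clipping them at
zero looks attractive (every replicate stays a valid intensity set) but is
quantifiably harmful: a single-event increment has noise SD equal to the
increment itself, so the clip cuts the lower tail at exactly −1 SD
regardless of cohort size, shrinking the replicate SD by ~18% and pushing
nominal 95% intervals to ~87–90% empirical coverage. Measured here on
constant-intensity cohorts against matrix-exponential truth, the
untruncated intervals achieve 95.0% coverage over 200 replicates while the
truncated variant sits below 90%. The replicates are an inferential
device, not estimates, so per-draw validity is not required;
`truncate=True` restores the clipped variant for comparison.

## Discrete-time hazard model

For each outcome state a person-year panel holds one row per whole year of
age inside the observation window, with indicator 1 if the person occupies
the outcome state at any point of that year (occupancy, not first entry:
transient states recur). Death is absorbing: the death-outcome indicator
stays 1 through the window end, while other outcomes' panels stop after
the year containing the death; years spent entirely emigrated are excluded
from other outcomes' risk rows. Persons missing the IQ or mental-health
classification are dropped from the panels (they still contribute to all
non-parametric estimates).

The marginal model `log(−log(1 − Q_ji)) = α_j + βᵀZ_i` has one intercept
per year of age and group × period contrast columns (period = before/after
age 35, the cut-off of the Norwegian targeted young-disability benefit),
within a single model per outcome so one working-correlation estimate
serves both periods. Fitting is GEE (statsmodels) with an AR(1) working
correlation — the yearly indicators are balanced in time — and the
sandwich covariance is always used for the reported Wald CIs and p-values
(exponentiated to HRR scale). Under an independence working correlation
the estimating equations coincide with a pooled one-row-per-observation
cloglog GLM; the suite asserts that equivalence to 1e-6 as an oracle
check. A group × period cell with no events admits no finite estimate
(complete separation); such cells are dropped from the design, recorded on
the fit, and reported as non-estimable (NaN) rows rather than failing the
whole outcome model.

## Synthetic cohort generator

Each person draws a birth year uniformly on 1950–1980 and a covariate
group, then follows a continuous-time Markov chain from age 20 in
employment using exponential competing risks, with piecewise-constant
baseline intensities on two age bands ([20, 35) and [35, ∞) — the minimal
structure supporting the before/after-35 contrast) scaled multiplicatively
per group and destination state. The chain is simulated from age 20 even
for cohorts observed later so the state at delayed entry has the correct
marginal distribution; the emitted episode table contains only the
windowed, non-employment part of the path, exactly as a registry extract
would. Persons dead before their window opens are dropped.

Default calibration is ordinal/structural, anchored to the published
cohort tabulations: group prevalences reproduce the published marginals
(6.6% low IQ among scored, 5.55% with mental problems, 14.2% problems
within the low-IQ group); disability/benefit/mortality/emigration effects
take the published before/after-35 magnitudes (e.g. ~14-fold disability
entry for low IQ with mental problems, protective high IQ, ~2.5-fold
emigration for high IQ); baseline rates echo the relative magnitudes of
the published transition-count table (heavy employment↔sick-leave cycling,
rehabilitation feeding disability, near-absorbing disability, return
migration allowed). Mental-health and physical scores are missing for
birth years before 1961, mimicking the pre-1980 change of the grading
system (and reproducing roughly a third of the cohort missing); IQ is
missing completely at random at 6%. No attempt is made to match the
published estimates numerically — the generator is the truth source for
parameter-recovery and consistency tests, not a reproduction of the data.

What the generator does *not* emulate: non-Markov duration dependence
(real benefit trajectories remember how long a spell has lasted), seasonal
and calendar-period effects, covariate measurement error, and clustering
of transitions (e.g. yearly benefit renewals). Passing tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness of the scientific conclusions to their
violation.

## Problem sizes and numerical choices

Tests run at the smallest sizes that make their assertions sharp:
machine-precision oracles at n=500, structural invariants at n=2000,
consistency against matrix-exponential truth at n=5000 within 3 estimated
SEs, HRR recovery over 40 replicates of n=1200 within 3 Monte-Carlo SEs
of the replicate mean, and interval coverage over 200 replicates of n=220
with B=400 draws (B=1000 remains the library default; percentile
endpoints at B=400 are already stable relative to the acceptance band).
Tolerances: row-stochasticity and occupation normalization 1e-10,
restricted-mean conservation 1e-8, tiling 1e-9 years, oracle equalities
1e-12 (product limit vs Kaplan–Meier) and 1e-6 (GEE vs GLM, solver
tolerance). Tie-breaks: events at one time are one product factor;
delayed entry at exactly an event time excludes the person from that
time's risk set (`entry < t ≤ exit`). Degenerate inputs — empty event
lists, zero-variance perturbations, persons observed less than one whole
year, windows of zero length — are either well-defined limits (identity
matrices, zero-width intervals) or explicit errors, as exercised in the
unit tests.

## Known limitations

* The Markov assumption is untested on real data; landmark or
  sub-sampling estimators for non-Markov processes are out of scope.
* The discrete-time model targets marginal occupancy, so fitted HRRs equal
  generating intensity ratios only when the outcome is entered through
  effect-scaled paths and exits are rare (near-absorbing states such as
  disability); for heavily recurrent outcomes the HRR is an
  occupancy-odds contrast, not an entry-intensity ratio, and pathway
  amplification can push it above the direct effect.
* Perturbation draws are independent across transition types and times;
  covariance between increments sharing a risk set is ignored (first-order
  adequate, as the coverage study shows, but not exact).
* Episode tables above a few hundred thousand rows are processed in
  per-person Python loops; the design favours auditability over raw speed.
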