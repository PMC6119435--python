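# Methods

## The decision problem

IRIS (Identification and Referral to Improve Safety) is a UK primary-care
training and advocacy programme for domestic violence and abuse (DVA).
General-practice teams are trained to recognise signs of abuse and refer
women to a named advocate educator; the programme is commissioned per site
and its cost is spread over every woman aged 16+ registered at a trained
practice.  The question this package answers is whether commissioning IRIS
is good value for money compared with usual care, measured as incremental
cost per quality-adjusted life-year (QALY) and as net monetary benefit
(NMB) at the NICE willingness-to-pay threshold of £20 000 per QALY.

## Model structure

A deterministic Markov cohort model with five states in fixed order
`[N, U, A, I, D]`:

| code | state | utility (QALY-weight/yr) | per-cycle cost |
|------|-------|--------------------------|----------------|
| N | not abused | 0.85 | 0 |
| U | abused, not identified | 0.63 | £2043 |
| A | abused, identified, seeing advocate educator | 0.65 | £2043 × weight (1.0) |
| I | abused, identified, not seeing advocate educator | 0.63 | £2043 × weight (1.0) |
| D | dead | 0 | 0 |

Cycles are 6 months (the typical duration of advocacy contact); the
horizon is 20 cycles (10 years); costs are 2015/16 GBP; costs and QALYs
are discounted at 3.5% a year.  Transitions follow a sparse graph: N can
only become U or die; U can recover to N, be identified (into A or I) or
die; identified women can only stay, recover to N, or die; D is absorbing.
The two arms (usual care vs IRIS) share every transition except the U-row
identification probabilities, which is where the intervention acts.  The
per-cycle programme cost (£0.46 = £272 613 per 6 months / 595 902
registered women) is charged for every living woman in the intervention
arm, and a one-time onward-referral cost (£312) is charged per entrant to
the seeing-advocate state.

Rows of the transition matrix are always stored and rebuilt as exit
probabilities with the stay probability as their complement, so rows sum
to 1 exactly.

## Reading the published U row (`stay_mode`)

The published input table is internally inconsistent for the
abused-but-not-identified row: the printed stay probabilities (0.9444
control, 0.9419 intervention) do not equal the complement of the printed
exits (0.94126, 0.92796).  The gap matters: the printed *exits* imply an
identification gap between arms of 0.0133 per cycle, while the printed
*stays* imply 0.0025 — a five-fold difference that propagates directly
into every incremental result.

Three readings are implemented:

* `printed_stay` (default) — the printed stay, recovery (U→N 0.0500) and
  death (U→D 0.00554) are taken as authoritative and the identification
  exits are rescaled so the row closes exactly on the printed stay,
  preserving the printed A:I ratio and each member's printed coefficient
  of variation.  Effective identification mass: 0.00006 (control),
  0.00256 (intervention).
* `complement` — the printed exits verbatim; stay is their complement.
* `printed_renormalized` — printed stay and exits, row divided by its sum.

The default was chosen because it is the only reading that reproduces the
published pooled results (verified by the acceptance tests): under it the
control arm accrues £4430/6.670 and the intervention arm £4423/6.671 per
woman, and the one-way variation of the control recovery probability over
0.049–0.051 swings the NMB from +£89 to −£37, all within the published
figures' tolerance; under `complement` the incremental results come out
three to five times too favourable to the intervention (e.g. NMB ≈ £173).
No claim is made that either reading reproduces the original authors'
unpublished code — only their published outputs.

## Accrual and discounting (`accrual`)

Occupancy-based streams (state costs, QALYs, programme cost) support two
conventions:

* `cycle_start` (default) — membership counted at the beginning of each of
  the 20 cycles, discounted at the cycle-start time point.  This is the
  convention that reproduces the published totals to the pound.
* `trapezoid` — the textbook half-cycle correction: weights ½, 1, …, 1, ½
  over the 21 time points.  It shifts totals by about −2.5% and the
  incremental results by under £1.

One-time referral costs are discounted at the end-of-cycle time point at
which the entrant arrives, under both conventions.  Entrants are
transitions landing in a state during a cycle; the initial stock at t = 0
is not charged (toggle `charge_initial_advocates`; the difference is
312 × 0.00051 ≈ £0.16).

## Perspectives and the NHS cost share

The societal perspective counts the full £2043 per-cycle abuse cost (NHS,
lost output, justice and personal costs).  The NHS perspective scales only
that state-cost stream by `nhs_cost_share`; programme and referral costs
are NHS-borne and enter in full.  No NHS share of the abuse cost is
published.  The default (0.27807) is back-derived in closed form from the
published control-arm NHS total (£1232) — the NHS cost is affine in the
share, so the solve is exact (`derive_nhs_cost_share`).  Because the share
is fitted to the same table it would be compared against, NHS-perspective
results are excluded from the acceptance surface and the share is exposed
as an overridable config field.

## Calibration

The incidence (N→U) and recovery (U→N) probabilities were originally
derived by running the chain to its long-run state and matching the
not-abused share to the observed 17% prevalence of DVA among women
consulting in general practice.  With an absorbing death state the
unconditioned chain drains to all-dead, so "long run" is interpreted as
the quasi-stationary distribution: iterate, renormalising mass among
living states, up to 3000 cycles (tolerance 1e−12 on the iterate).

Matching one target with two free probabilities is under-determined; the
solver holds recovery fixed at its tabulated 0.0500 and bisects on
incidence (the not-abused share is strictly decreasing in it), tolerance
1e−6 on the achieved fraction, at most 100 iterations
(`solve_for="recovery"` performs the converse).  The solved incidence
(≈ 0.0103) does not equal the tabulated 0.0037 — with the tabulated values
the long-run not-abused share is ≈ 93%, not 83%.  This inconsistency is in
the source inputs; base-case economics therefore use the tabulated
transition probabilities as printed, and calibration results are reported
separately.

## Uncertainty analysis

**Distribution fitting.**  Each tabulated input carries a base value,
95% limits and a family.  Method of moments treats the base as the mean
and (high − low)/3.92 as the standard deviation: beta for probabilities
and utilities, gamma for costs and cost weights, uniform for the starting
split, point masses for degenerate specs.  Transition-row members (the
"Dirichlet" family) are fitted per element as betas and each drawn row is
re-closed through the stay complement; a draw whose exits reach 1 is
rescaled to 0.999 of its sum and logged in the draw audit (never observed
at the shipped limits).  A `true_dirichlet` mode instead draws whole rows
from a Dirichlet whose single concentration is least-squares fitted to the
per-member limits; the tabulated limits are mutually consistent with one
concentration per row (≈ 7000 for the U row), so the two modes have
near-identical marginals.

**One-way sensitivity (tornado).**  Each parameter is set to its lower and
upper limit with everything else at base and the societal NMB at £20 000
recorded.  Variation items mirror the printed table layout: rows printed
once (the N, A, I rows) are varied in both arms simultaneously — varying
one arm's copy of a natural-history quantity would manufacture large
artificial spans — while the U row, printed per arm, is varied per arm.
Explicit per-parameter override ranges are supported (the published
univariate analysis varies the control recovery over 0.049–0.051 rather
than its tabulated limits).  Limits that break row feasibility are
flagged, not clamped.

**Probabilistic sensitivity (PSA).**  1000 joint draws (seeded,
reproducible bit-for-bit), each run through both arms under the societal
perspective.  Parameters are drawn independently, with one deliberate
exception: transition probabilities whose uncertainty specification is
printed identically in both arms (natural recovery U→N, mortality U→D,
and the arm-unlabelled N/A/I rows) are treated as arm-invariant
natural-history quantities and receive a single draw per simulation — the
programme changes identification, not biology.  Drawing them independently
per arm (`psa_independent_arms=True`) doubles the spread of the
incremental results and pushes the dominated fraction to ~28%.  Under the
default the model yields roughly 70% of simulations cost-effective at
£20 000, ~41% dominant and ~14% dominated, against the published
61%/35%/18%; the published uncertainty intervals are not internally
consistent with the published univariate slopes and tabulated limits (see
the acceptance notes), so no sampling scheme reproduces all published PSA
figures simultaneously, and the cost-effective fraction sits above the
published value under either scheme choice.

Summaries: dominance fractions by strict quadrant counts; the
cost-effectiveness acceptability curve (CEAC) is the fraction of draws
with positive NMB over a £0–£50 000 grid in £1000 steps; uncertainty
intervals are empirical 2.5th/97.5th percentiles under the
linear-interpolation convention (for samples 1…1000: 25.975, 975.025).

## Synthetic data

`random_parameter_set` draws structurally valid parameter sets — exit rows
respecting the model's sparsity with total exit probability below a cap
(default 0.3), utilities in a configurable range, non-negative costs,
coherent low ≤ base ≤ high limits — deterministically from a seed.  It
emulates the *schema* of the real inputs, not their joint distribution:
passing property tests demonstrates probability conservation, absorbing
death, accounting identities and serialisation round trips, not that any
particular clinical parameterisation is realistic.  `toy_models` ships
miniature chains with closed-form answers (geometric death, symmetric
switching, a two-state detailed-balance chain for the calibration solver,
equal-arms and zero-cost economies).

## Numerical choices and edge cases

* State order frozen as `[N, U, A, I, D]` in every matrix, trace and report.
* Rows are validated to sum to 1 within 1e−12; traces conserve mass within
  1e−10 over the horizon.
* ICER reported as a number only when incremental cost and QALYs are
  strictly same-signed; dominance sign patterns get a label; ΔQALY = 0
  leaves the ICER undefined while the NMB is still computed.
* Reported tables round costs to whole pounds and QALYs to 3 decimals;
  all internal arithmetic is unrounded.
* The default RNG seed (20180829) is fixed and documented so shipped
  results are reproducible; the command-line PSA requires an explicit seed.
* Monetary columns are labelled "GBP 2015/16" to prevent silent unit drift.

## Limitations

* Site-level analyses are out of scope (site-specific inputs are not
  published); only the pooled national parameter set ships.
* No effects on children, no time-varying transition probabilities, no age
  structure, no parameter correlations beyond the arm-invariance rule, no
  EVPI/EVSI.
* The three structural ambiguities above (U-row stay inconsistency,
  under-determined calibration, unprinted NHS share) mean the package
  reproduces the published deterministic results within a few pounds, not
  to the penny, and the PSA cost-effective fraction lands about 10 points
  above the published one.
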