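# Methods

## Scope and data model

`careflow` analyses the care pathway of a stepped-care psychological-
therapies service as an operational process.  The unit of analysis is the
*referral* (case); its *events* are time-stamped movements into pathway
stages (referral receipt, waiting lists, assessment, step-2/step-3
treatments, discharge).  Alongside the movements sit three linked tables:
per-case attributes (age, gender, presenting problem, referral source,
deprivation decile, prior referrals), appointment records with attendance
and treatment flags, and per-session outcome-measure scores with an
above-caseness flag.  All five are plain CSV with documented headers; a
minimal XES export is provided for interoperability with other
process-mining tools.

The recorded per-case entry order (`source_order`) is treated as the
authoritative event sequence.  Timestamps are repaired *to* that order —
the pipeline never re-sorts events by timestamp, because the failure mode
being corrected is a mistyped date, not a misordered record.

## Timestamp repair (LOCF)

An event violates order when its timestamp precedes the running maximum of
earlier timestamps in its case.  Repair replaces each violating timestamp
with that running maximum (last observation carried forward).  Properties:
the repaired log is non-decreasing per case; the procedure is idempotent;
only violating events are touched, and each keeps its recorded value in
`original_timestamp`.  The adjustment report gives |repaired − recorded| in
weeks (days/7, reported to 1 dp) and adjustment counts, each summarised
per event and per case, both over all units (zeros included) and over
adjusted units only.  Because adjustments are typically a small minority of
events, the all-events median adjustment is structurally 0 — a useful check
that repair did not distort the bulk of the log.  Ties (equal consecutive
timestamps) are permitted: same-day movements are real.

Only LOCF is implemented, behind a strategy enum; repair using *following*
events would need assumptions about which neighbour is trustworthy that the
data cannot support.

## Abstraction

Raw stage vocabularies are noisy.  An abstraction spec declares, in order:

1. **rename** — map stage-name variants to canonical labels;
2. **collapse** — replace each maximal run of *consecutive* events in one
   subprocess by a single event named after the subprocess.  The collapsed
   event carries the run's **first** timestamp: treatment start defines the
   stage entry, so the duration to the next stage spans the whole
   subprocess.  (Keeping the last timestamp instead would fold treatment
   duration into the preceding wait; either is defensible, this choice is
   fixed and documented.)
3. **exclude** — drop administrative stages.  Exclusion runs *after*
   collapsing so an administrative event cannot split a subprocess run in
   two and artificially multiply routes.
4. **coverage filter** — rank distinct routes by descending case count
   (ties broken lexicographically for determinism) and keep cases on the
   top routes until the cumulative retained fraction first reaches the
   coverage level, including the crossing route.

Level A (process-map view) keeps individual treatment stages and drops
waiting lists; level B (route-analysis view) pools treatments into
step-level subprocesses and *keeps* waiting lists, which is what makes
waiting-list attrition visible as a route feature.  The packaged A/B specs
target the synthetic stage vocabulary; real services configure their own
YAML — stage mappings are service-specific and are deliberately not
inferred from data.

## Process map

The directly-follows graph counts, for every ordered stage pair, the
consecutive event pairs across cases.  Edge statistics: traversal count,
distinct case count, branching probability, and transition-duration
median/IQR in weeks (linear-interpolation quantiles, so printed numbers are
bit-reproducible across implementations).  Node statistics: case count,
traversal count, and stage duration (entry to next event; terminal events
contribute none).  Branching probabilities use traversals and treat
end-of-trace as an implicit sink, so outgoing probabilities (plus the
end-of-trace share) sum to 1.  Repeat visits contribute one traversal each
but one distinct case.

The bottleneck score of an edge is distinct cases × median transition
duration — "many patients, long wait".  Edges at or above the chosen
quantile of all scores (default 0.99) are flagged; zero-score edges never
are.  The flag set is invariant under uniform rescaling of durations.
Semantic markers derive from stage roles: waitlist→discharge edges are
attrition (discharge before the intended care), step2→step3 edges are
step-ups.  DOT export is deterministic (sorted nodes and edges).

## Route analysis

Routes are enumerated on the level-B log, ranked by case count with
lexicographic tie-breaks.  Per-route timing gives each stage position's
median duration and the *total wait*: per case, the sum of durations spent
in waitlist-role stages; per route, the median over its cases
(median-of-sums — the stacked per-stage medians are also exported for
plotting, but comparisons use the median-of-sums because it is a statement
about patients, not about stages).  Outcome bins partition each route's
cases: not-completed, recovered, not-recovered, not-at-caseness (first
score below threshold), unknown (completer without outcome data).

Classification: stepped care requires step-2 treatment followed later by
step-3 *treatment*; treatment at one step only gives step2_only/step3_only
(a case stepped up but discharged from the step-3 waiting list is
step2_only — it was treated at step 2 only); a route ending waitlist →
discharge with no treatment is attrition at that list; the remainder are
no-treatment.  "Common" stepped-care cases are those on stepped-care routes
within the top-N cut (N = 10 by default); stepped-care cases on less common
routes are reported separately, and the overall stepped-care rate is their
sum over all referrals (2 dp).

The wait-comparison table pairs, per step, the most common treated route's
total-wait median with its waiting-list-attrition counterpart (difference,
1 dp) and reports the step3/step2 treated ratio (1 dp); missing
counterparts are omitted with a note.

## Cohort metrics

Every calculator returns numerator and denominator with the rate.
Completion: cases with ≥2 attended treatment appointments over all cases
(appointments with a missing attendance flag are removed first; assessment
appointments never count).  Recovery: among completers with outcome data
who started above the caseness threshold, the fraction below threshold at
the last score; data completeness and the not-at-caseness count are
reported alongside rather than folded into the denominator.  Percentages
are rounded half-even by exact decimal arithmetic to 2 dp (1 dp for the
imputation rate), matching the precision service reports print.

The flow breakdown is computed on a waitlist-retaining map so that triage
discharge and waiting-list attrition are separable: "immediate discharge"
pools referrals discharged straight from referral with those discharged off
the assessment waiting list (on a map whose waitlists are excluded the two
are indistinguishable anyway); per-step triage denominators count a
stepped-up case at both steps, matching how services tally per-step
referral volumes.

## Synthetic generator

The generator emulates the structural features of a two-site stepped-care
service that the pipeline consumes; it is not a clinical simulator.  Per
case it draws: a referral date uniform over a two-year inclusion window;
categorical routing at seven decision points (post-referral,
assessment-waitlist, triage, each treatment waitlist, each treatment, with
step-up from step 2); waiting times per transition from log-normal
distributions parameterised by median (weeks) and log-SD — right-skewed,
median well below the mean, as service waiting times are; session counts
(shifted Poisson) and inter-session gaps; Bernoulli attendance with a small
missing-flag rate; outcome scores anchored at a pre-score (normal, mean 16,
SD 5 on a 0–40-style scale, caseness threshold 10) and a last score
realised from a per-route recovery probability.  Waiting-list attrition
branches draw from distributions with *longer* medians than the treated
branches — a modelling choice that makes the "discharged patients waited
longer" signal reproducible by construction, not an empirical claim.
Raw stage names include outdated variants, an administrative step-change
event, and a discharge-planning stage so that every abstraction operation
has real work to do.

Timestamp corruption back-dates each non-first event independently with
probability `corruption_rate` by a draw from a magnitude distribution
(weeks); an order violation results whenever the draw exceeds the gap to
the running maximum.  True timestamps, true routes, and per-case
completion/recovery are retained as ground truth for the test oracles.

The packaged profiles describe a larger site (`site_a`: 45,401 referrals,
longer waits, heavier attrition, ~1.9% back-dated events with ~2.3-week
offsets) and a smaller one (`site_b`: 12,590 referrals, shorter waits, a
higher triage-discharge rate, 7.2% back-dated events with ~0.5-week
offsets).  Their routing probabilities and wait medians were chosen once so
the abstracted flows sit near the rates a large service of this kind
reports (≈34% discharged before assessment, ≈21% triage discharge,
≈24%/32% step-2/step-3 waiting-list attrition, ≈3–4% stepped care, ≈40%
completion, ≈48–52% recovery, ≈10–12% missed appointments, step-2 vs
attrition total-wait medians ≈13 vs ≈21 weeks, step-3 ≈34 vs ≈42, a
step3/step2 ratio ≈2.6).  What the generator does **not** emulate: seasonal
and pandemic-era referral dynamics, re-referrals, therapist-level effects,
correlated attendance, multi-instrument outcome measures, and any
geography.  Passing tests therefore demonstrate the pipeline's
correctness on logs with these structural properties, not the clinical
realism of any particular service.

## Numerical and degenerate-input choices

Quantiles everywhere are linear-interpolation; durations are float weeks
(days/7); zero-duration transitions are allowed.  Empty logs yield empty
maps and empty route lists; a zero denominator raises (or returns an
undefined marker for recovery, where an all-below-caseness cohort is a
legitimate state).  Route and DOT orderings are fully deterministic.
Percentage rounding is half-even on exact decimals, never on binary floats.

## Problem sizes used in checks

The packaged test-suite fixtures use 1,500–5,000-case synthetic logs for
parameter-recovery checks (binomial 3-SE bounds at n = 5,000) and a
25,000-case log (~120k events) for the repair-at-scale check; the
acceptance script runs both packaged profiles at full size (45,401 and
12,590 cases).  These sizes make sampling error small relative to the
tested tolerances while keeping a full run in the low tens of seconds.

## Known limitations

- Stage-role maps and abstraction specs for real services are user
  configuration; nothing is learned from data.
- LOCF is the only repair strategy; bidirectional repair is future work.
- No statistical testing of the wait-vs-attrition association is included;
  the package computes the descriptive comparison only.
- The deprivation decile is carried as an opaque attribute; deriving it
  from geography is out of scope.
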