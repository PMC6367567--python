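# Methods

## Event model

An observation session is a time-ordered stream of coded hand actions for
one birth attendant. Timestamps are real-valued seconds from session start:
the recording instrument logs absolute clock times, but every downstream
rule depends only on ordering and gaps, so relative seconds avoid timezone
and clock-drift concerns. Each action code carries one of six dispositions
(aseptic procedure, patient-zone action, recontaminating touch,
out-of-workflow activity, hygiene action, session marker) in a shipped,
editable plain-text taxonomy. The vocabulary is the package's canonical one;
observers' tools differ, so unknown codes are either rejected (strict mode)
or conservatively kept as out-of-workflow activities, which end delivery
flows and open new opportunities rather than silently extending a flow.

When several actions share one timestamp, hygiene actions and procedures are
ordered before touches, then patient-zone actions, then out-of-workflow
activities (stable by entry order within a class). Down-ranking rather than
deleting lower-priority simultaneous actions accepts some loss of ordering
information without changing recontamination tallies.

## Segmentation

A delivery flow is a maximal run of aseptic procedures interleaved only with
patient-zone actions and — once the flow has started — glove changes and
rinsing with water, which delivery guidelines permit mid-flow (e.g. a glove
change before cord cutting) without a new hand-hygiene opportunity. Before
the first procedure those same glove actions belong to the pre-flow window.
Each flow is exactly one opportunity; its window runs from the previous
boundary (session start, previous flow's end, or the last out-of-workflow
action) to the first procedure.

Boundary semantics decided here, where the rules left room:

* A recontaminating touch before any procedure stays in the window (it
  informs the avoidance behaviors); after a flow has started it terminates
  the flow — it is not exclusive to the patient zone — and becomes the first
  action of the next window.
* A hand rub/wash during a flow likewise terminates it and is credited to
  the next window: washing entails leaving the patient zone, and the most
  recent wash is what protects the next procedure.
* Actions between a flow's last procedure and its terminating action belong
  to the flow; the next window opens at the terminator itself.
* An out-of-workflow action resets the window: hygiene performed before it
  does not carry over (WHO Moment 2 requires hygiene after the last
  out-of-workflow activity).

**Censoring.** Only a session's first opportunity can be censored: its
window may be truncated by the start of observation. The published analysis
never quantifies "too close to the start", so two criteria are implemented
and combined by disjunction: observed lead time below `min_lead_seconds`
(default 60 s, configurable, echoed in the report), or glove state unknown
with no hygiene action observed. Observer markers (`session_start_bare`,
`session_start_gloved`) can resolve the initial glove state.

**Inconsistency.** Duplicate rub/wash records at one instant that disagree
on soap use or technique (the observers' tool can emit both "soap used" and
"soap not seen") flag the opportunity inconsistent; such opportunities are
excluded from every denominator and counted in the run report.

## Behavior classification

Behavior 1 is performed when the window contains a hand rub, or a hand wash
with soap seen or presumed (a wash with soap positively not used is
rinsing). Behavior 3 requires at least one glove don flagged as a *new*
glove: re-donning a used glove is recorded under the suboptimal pattern
`other`, since the contrast of interest is new gloves versus gloves carried
over from a previous delivery flow. Behaviors 2 and 4 are contingent
(applicable only when 1 and 3, respectively, are performed).

Interval anchoring with multiple events: the LAST rub/wash and the LAST don
anchor the avoidance intervals — the most favorable reading, since the most
recent hygiene is what protects the procedure. Behavior 2's interval ends at
the FIRST don after the last wash (gloves shield the hands thereafter) or at
flow start if no don follows; Behavior 4's interval ends at flow start. The
same intervals define the surface tallies, so a touch is attributed to
exactly one phase.

Rub/wash duration is the gap from the action to the next recorded action
(the instrument logs starts only), compared against the 10 s guideline;
technique comes from the observer's flag on the last rub/wash.

The nine sequences are the 3 × 3 contingent combinations in the order
(1) P P P P, (2) P P P N, (3) P P N –, (4) P N P P, (5) P N P N,
(6) P N N –, (7) N – P P, (8) N – P N, (9) N – N –.

## Statistics

* **Proportions.** Compliance k/n with Clopper–Pearson intervals by default
  (Wilson selectable). The published intervals match cluster-naive exact
  binomial intervals to rounding, and no clustering adjustment is described,
  so none is applied; the report metadata flags this. CI endpoints are
  descriptive output, not validated quantities.
* **ICC.** Random-intercept logistic model per behavior, attendants as
  clusters, restricted to attendants with ≥ 5 applicable opportunities
  (configurable; an all-attendant sensitivity fit is also reported). The
  marginal likelihood uses adaptive Gauss–Hermite quadrature written in this
  package: per-cluster posterior modes by Newton iteration, 21 nodes scaled
  by the curvature at the mode, optimized over (β₀, log σ) by Nelder–Mead.
  Doubling the order changes the log-likelihood by < 1e-6 on the test suite,
  and the fit matches an independent Monte-Carlo integration of the same
  integrand to < 1e-3. ICC = σ²ᵤ/(σ²ᵤ + π²/3); confidence intervals by
  seeded percentile parametric bootstrap (resimulate from the fit, refit;
  B = 500 by default, ≥ 100 enforced). When all outcomes are identical the
  variance is reported as 0 with the intercept at a ±10 logit cap and a
  warning.
* **Kappa.** Cohen's kappa from the 2 × 2 agreement table; degenerate
  marginals (chance agreement 1) leave kappa undefined rather than 0.
* **Sample size.** n = floor(deff · z² p(1−p)/d²) with the exact normal
  quantile (1.959964…). Floor is the only rounding that reproduces the
  conventional printed value 768 from 768.29 at p = 0.10, d = 0.03,
  deff = 2.

## Synthetic data

The stochastic generator draws one random intercept per attendant and
behavior on the log-odds scale, samples each opportunity's four behaviors
contingently, and then emits raw actions realizing exactly that profile
(wash/don events, zero-truncated-Poisson recontaminating touches with
surfaces drawn from per-phase category mixes, a procedure, out-of-workflow
boundaries). Defaults emulate the study conditions: 10 facilities, ~100
attendants, baseline log-odds at the logits of the observed compliance
rates, intercept SDs implying the published ICCs, touch rates matching means
of 1.3 and 1.5 per failure, 14% censoring and 0.7% inconsistency. Timestamps
are schematic (fixed gaps chosen to clear the duration and censoring
thresholds); labor physiology, timing realism and observer fatigue are not
modeled. Passing tests therefore validate the rules and estimators, not the
ecological realism of event timing.

The canonical fixture is fully deterministic (no randomness) and emits
sessions whose pipeline output reproduces every published marginal: 914
candidates, 127 censored (realized as first-of-session opportunities with
truncated windows), 6 inconsistent (conflicting soap records), 781
analyzable with sequence counts (75, 52, 5, 35, 21, 4, 194, 115, 280), 154
reused-glove opportunities within Sequence 9, 78/60 and 275/188
touches/failures with the published per-surface splits, 59/192 adequate
technique, 12/192 hand rubs, across 104 attendants, 10 facilities and 336
sessions with 65 attendants at ≥ 5 opportunities. The per-sequence
allocation is *derived*: the published marginals (behavior totals 192 and
492, their union 501, avoidance failures 60 and 188 with overlap 21,
sequences 1 and 9) pin the nine cells down, and
`hhflow.synth.verify_fixture_marginals()` checks the whole constraint system
before the fixture is built. The true opportunity-level joint distribution
of the study is not public; the fixture is a feasible reconstruction, and
only matched marginals are asserted anywhere. Touches are spread across
failure opportunities as evenly as the totals allow, so dispersion
statistics (SD, range) are narrower than the published ones; means are
exact. One derived consequence: Sequence 9 is 280/781 = 35.85% of
opportunities, which rounds to 35.9% at one decimal.

Within each fixture session, opportunities with glove donning are emitted
before reused-glove opportunities (so carried-over gloves exist) and
bare-hand opportunities last (with a glove removal inserted when needed);
an observer marker fixes the initial glove state. This ordering is a
presentation choice with no effect on any marginal.

## Numerical and reporting conventions

Percentages print to one decimal, rounded half up (`Decimal`); exact
fractions are retained in the JSON report. The pipeline is deterministic
given input and configuration; all randomness (simulator, bootstrap) sits
behind one explicit seed. The acceptance script runs the fixture pipeline at
desk scale (914 opportunities, ~4,000 actions, seconds on one CPU); the
estimator-validation tests use 10,000 random streams for segmentation,
10,000 simulated opportunities for rate consistency, and 20 seeds × 200
attendants × 20 opportunities for ICC recovery — sizes at which Monte-Carlo
error is comfortably inside the asserted tolerances.

## Known limitations

* The fixture's joint distribution beyond the matched marginals is
  conjectural; per-attendant and per-facility allocations are schematic.
* No cluster-robust or design-effect adjustment of compliance intervals; no
  multi-predictor models (the published models are univariate).
* The patient zone is encoded in the action vocabulary, as in the observers'
  precoded tool; no spatial inference is attempted.
* Observer-agreement kappa operates on externally supplied rating tables;
  the package does not model rater error in streams.
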