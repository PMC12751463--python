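# Methods

This note documents the model implemented by `diagcea`, the conventions
that were genuinely open when the package was designed, and what the
shipped simulations do and do not show.

## Tree model

A diagnostic workflow is a rooted tree of `decision`, `action`, `result`
and `exit` nodes with per-edge transition probabilities. Conventions:

* **Exit is its own node kind.** An exit could be viewed as a terminal
  action, but leaf identification and outcome-state extraction need the
  distinction, so it is explicit. Every leaf must be an exit.
* **Trivial nodes are representable, not required.** A decision with a
  single child (probability 1) is legal — builders keep such nodes when
  the consult fee is genuinely incurred (e.g. the final "stop testing"
  consult) and splice them out when it is not.
* **Result nodes route deterministically**: at most one child, probability
  exactly 1. Result values are strictly dichotomous; a quantitative test
  must be encoded as a thresholded 0/1 result, and validation rejects
  anything else with an explicit message rather than guessing a threshold.
* **Probability sums** (per parent, and over all root-to-leaf paths) are
  checked to an absolute tolerance of 1e-9. Nothing is ever silently
  renormalized on load; only the random-tree generator normalizes its own
  draws.
* Tree files are JSON with an explicit edge list (not nesting) so that
  parameter templates can be patched in place; times are stored in weeks
  and converted to years (÷52) only inside the QALY arithmetic.

## Expected cost

Costs accumulate by post-order rollback: `E(C_i+) = C_i + Σ P_ij·E(C_j+)`,
leaves contributing their base cost. The implementation is an explicit
iterative stack (no recursion-depth limit), touches each node exactly once
(O(N), verifiable via `visit_log`), never mutates the input tree, and
returns the full per-node map so trees can be annotated, not just priced
at the root. Result and exit nodes default to cost 0 but honor nonzero
values (e.g. an exit consult fee). An independent brute-force oracle
(probability-weighted path costs over an exhaustive path enumeration) is
part of the public API and the test suite compares the two on hundreds of
random trees.

## Effectiveness

Each exit yields an outcome state `(O, TAT)`; QALYs over a horizon `x` are
`TAT·U(S_0) + (x − TAT)·E[U(S)]`, with `E[U(S)]` the PPV- or NPV-weighted
mix of the true/false outcome utilities. Choices made here:

* **Last-test accuracy.** A pathway that ran several tests scores its
  final result with the *last* test's sensitivity/specificity only.
  Composing accuracy across tiers would require joint distributions of
  test errors that are essentially never published; the approximation is
  deliberate and documented rather than hidden.
* **Direct predictive values.** AI classifiers are often characterized by
  a published precision with no underlying Se/Sp pair; the registry
  accepts `PredictiveValues(ppv, npv)` wherever a `TestPerformance` is
  expected. Gold-standard tests use `ppv = npv = 1`.
* **TAT beyond the horizon is an error**, not a clamp. Silent clamping
  hides mis-specified trees; the caller must choose a sensible horizon.
* **Utility bounds** are validated: `u_tp > u_fp`, positive-state
  utilities in [0, 1], `u_fn` in [−1, 0] (a missed diagnosis may be scored
  worse than death).
* **Ratio aggregation.** Monte Carlo summaries support both the mean of
  per-replicate ratios (default, and what the shipped summaries report)
  and the ratio of expectations; the mode is recorded in every output.

## Unresolved exits (the CMA+GP scenario)

The CMA+GP strategy terminates after a negative gene panel even though a
definitive third-tier exome test exists and would, at its marginal yield,
diagnose roughly a third of those patients. Scoring that exit like an
ordinary negative (NPV-weighted) would make the cheapest, least conclusive
workflow also look the most cost-effective, inverting the qualitative
ranking this class of analyses reports. The shipped scenario therefore
scores that exit as a *missed diagnosis*: its expected utility is the
(sampled) false-negative utility `U_FN`. The mechanism is a general one —
`outcome_states` accepts per-exit utility overrides — so users who prefer
the NPV convention can pass empty overrides and get it.

## The undiagnosed-state utility U(S_0)

`U(S_0)` enters every QALY through the turnaround term but is not an
externally reported quantity. It was fixed once, by a one-dimensional
sweep (`calibrate_undiagnosed_utility`, grid 0.50–0.96 in steps of 0.02,
1000 common-draw replicates) scoring each candidate against published
cost-per-QALY summary statistics for the five DD&MCA strategies; the value
minimizing the worst relative deviation of the five means is
`U_UNDIAGNOSED_DEFAULT = 0.74`, and it is shared across all scenarios. No
single value reproduces every published mean to better than ~11% — the
scenario-1 mean is highly sensitive to U(S_0) because its penalized
unresolved exit puts a heavy right tail on the ratio — but the qualitative
structure (ordering of the four expert strategies, AI-delegated ≈ ES-only)
is stable across the whole plausible range and across seeds. The sweep
function is exported so users can recalibrate against their own
institutional summaries.

## Parameter presets

* `table1` — DD&MCA point estimates: consult fee $174.28 and 4 weeks; CMA
  $871.39, 2 weeks, yield 154/1536; GP $1600 (midpoint of the reported
  $1450–1750 range), 4 weeks, yield 24/113; ES $4847.47, 8 weeks, tier
  yields 27/73, 0.35, 228/692; Se/Sp pairs 0.9068/0.9440 (CMA),
  0.8960/0.9250 (GP), 0.9593/0.9933 (ES); AI precision 0.87; prevalence
  0.1665; utility midpoints 0.85/0.95/0.75/−0.25.
* `table3` — the PSA distributions: lognormal(6.8628, 0.3) for CMA cost
  (mean ≈ $1000), gamma(4, 1211.8675) for ES cost (mean $4847.47),
  uniform turnaround windows (1–3, 2–6, 4–12 weeks), beta yields, uniform
  utilities, AI precision uniform(0.1, 0.9). The GP cost defaults to
  lognormal(log 1600 − 0.08, 0.4), whose mean ($1600) is consistent with
  the quoted price range; an alternative parameterization sometimes quoted
  for this distribution, lognormal(3.1241, 0.4), has a median near $23 —
  three orders of magnitude off — and is preserved only as the
  `gp_cost="printed"` variant for traceability. Lognormal parameters are
  (meanlog, sdlog) and gamma is (shape, scale); the gamma convention is
  pinned down by shape×scale = 4×1211.8675 = 4847.47 matching the ES point
  cost.
* `table5` — SHD constants: ECG $708 (immediate), echocardiography $1852
  (2 weeks), cardiologist consult $174.28 (4 weeks), AI prediction free
  and instantaneous, routing rate 0.27, precision 0.74, prevalence 0.41.
  The AI's NPV is not reported; its default derives from the reported
  constants as `1 − (p − rate·precision)/(1 − rate) ≈ 0.712`, and it is an
  ordinary parameter users can override.

Within the DD&MCA trees, every genuine expert decision (including the
final decision before an undiagnosed exit) carries the consult fee and
4-week consult time; exits and results carry 0/0. On the AI-automated
branch no consult fee or time is incurred anywhere downstream of the AI
node — automated ordering needs no human intervention — while the expert
fallback branch keeps them. AI action nodes cost $0 and take 0 weeks by
default, overridable.

## PSA and simulation sizes

Parameters are drawn in alphabetical order of name from a seeded
generator, so draw streams are bit-reproducible and independent of spec
listing order. Scenario comparisons default to common random numbers
(shared draws), which removes draw noise from between-scenario contrasts;
independent streams are a flag away. Replicates with non-positive expected
QALY are recorded as invalid and excluded (with a count) rather than
resampled, keeping the draw stream seed-stable. Summaries report the n−1
standard deviation and the 95% CI of the mean (±1.96·sd/√n); a constructed
sample with a published mean and SD reproduces the corresponding published
interval to the printed precision, which is how this interval convention
was identified. The shipped studies use 1000 replicates and a 1-year
horizon — matching the reference analyses and comfortably converged for
the reported contrasts (the SE of a scenario mean scales as 1/√n, which
the test suite checks empirically at 250 vs 1000 replicates). Turnaround
windows ("between 1 and 3 weeks") are sampled as continuous uniforms;
granularity finer than that is not specified anywhere and integer-week
sampling changes nothing material.

## What the synthetic trees do and do not show

`random_tree` generates alternating decision→action→result layers with
random costs, turnarounds and normalized probabilities. It exists to
property-test the engine (oracle equivalence, monotonicity, linearity,
single-visit traversal) across thousands of shapes — it does not emulate
clinical realism (no correlation between cost and yield, no shared tests
across branches). Passing those tests demonstrates the *arithmetic* is
right on arbitrary trees; the clinical plausibility of any conclusion
rests entirely on the scenario parameters, which is why every shipped
number is traceable to a preset.

## Known limitations

* No cost discounting, no payer/patient cost split, no post-diagnostic
  disease course (a Markov extension would be needed for lifetime
  horizons).
* Accuracy is not composed across test tiers (see above).
* Trees only — no DAGs with shared subtrees.
* Continuous test results are rejected rather than modelled.
* The DD&MCA reproduction depends on two conventions (unresolved-exit
  scoring and U(S_0)) that the reference summaries do not pin down;
  both are explicit, documented switches rather than baked-in constants.
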