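# diagcea

Cost-effectiveness analysis of multi-tier diagnostic workflows, modelled as
decision trees — with support for AI-delegated test ordering and Monte
Carlo probabilistic sensitivity analysis.

## Who this is for

Rare-disease diagnosis rarely ends after one test: patients move through
tiers (a first-line screen, then progressively broader or more expensive
tests), each step adding cost and waiting time. Health-economic
evaluations that score one test in isolation miss this sequential
structure, and population-level models cannot say what a workflow is worth
*for a particular patient* — especially once an AI model starts deciding
which test to order. `diagcea` is a small library (plus a CLI) for
modelling such workflows explicitly and comparing them on cost per
quality-adjusted life year (QALY).

## The model

A diagnostic process is a rooted tree `T = (N, E)` of typed nodes —
**decision** (a clinician chooses the next step; carries a consult fee
`C_E` and consult time), **action** (a test is run; carries its cost and
turnaround time), **result** (a dichotomous outcome `Y ∈ {0, 1}`) and
**exit** (the process ends). Each edge carries a transition probability
`P_ij`; the probabilities out of every node sum to 1. Decision→action
probabilities encode protocol (0/1) or empirical test-selection rates;
action→result probabilities are diagnostic yields.

**Expected cost** rolls back from the leaves in one post-order pass, O(N):

```
E(C_i+) = C_i                              if i is a leaf
E(C_i+) = C_i + Σ_j P_ij · E(C_j+)         otherwise
```

**Effectiveness** attaches an *outcome state* `S_i = (O_i, TAT_i)` to each
exit: the last result value on the pathway and the accumulated turnaround
time. Over a horizon of `x` years,

```
QALY_i(x) = TAT_i · U(S_0) + (x − TAT_i) · E[U(S_i)]

E[U(S_i)] = PPV·U_TP + (1 − PPV)·U_FP     if O_i = 1
E[U(S_i)] = NPV·U_TN + (1 − NPV)·U_FN     if O_i = 0
```

where `U(S_0)` is the utility of the undiagnosed state and PPV/NPV come
from the final test's sensitivity/specificity and the disease prevalence
(`PPV = Se·p / (Se·p + (1−Sp)(1−p))`, analogously NPV). The strategy's
expected QALY is the probability-weighted average over outcome states, and
**cost per QALY** = expected cost / expected QALY.

**AI delegation** replaces an expert decision node by an AI action whose
score `r` is compared to a threshold `r*`: at or above it, the favoured
test is ordered automatically (no consult fees; its positive-result
probability becomes the AI's precision), below it the case falls back to
an expert decision. **PSA** samples every uncertain parameter from its
declared distribution (lognormal/gamma/beta/uniform), rebuilds the tree
per replicate, and summarizes the cost-per-QALY distribution.

Two case studies ship as ready-made scenarios: four genetic-testing
strategies (plus an AI-delegated variant) for developmental delay and
multiple congenital anomalies — chromosomal microarray (CMA), gene panel
(GP) and exome sequencing (ES) in different tier orders — and a structural
heart disease workflow where an AI reads an ECG and decides whether to
order echocardiography.

## Worked example

Deterministic evaluation of the ES-only strategy at the shipped point
estimates:

```sh
$ diagcea cea --scenario dd_mca_s4
{
  "cost_per_qaly": 5789.40142641201,
  "expected_cost": 5021.75,
  "expected_qaly": 0.8674040077943321,
  ...
}
```

The expected cost is one consult fee plus the exome test
(174.28 + 4847.47 = 5021.75 USD). Both outcome states wait 12 weeks
(4 consult + 8 test), so 0.2308 years of the 1-year horizon are lived at
the undiagnosed-state utility; a positive exome result (probability
0.370, the first-tier yield) is then worth `PPV·U_TP + (1−PPV)·U_FP` ≈
0.847 per year, a negative one ≈ 0.940. The ratio, ~5 789 USD per QALY, is
the strategy's cost-effectiveness score.

The same strategy under parameter uncertainty (1000 replicates):

```sh
$ diagcea psa dd_mca_s4 --n 1000 --seed 7
...
  "summary": {
    "mean": 5870.908376283154,
    "median": 5354.9013203619925,
    "sd": 2855.3585861656425,
    "ci95_low": 5693.931417574643,
    "ci95_high": 6047.885334991665,
    ...
  }
```

Comparing all five DD&MCA scenarios on shared draws
(`diagcea compare dd_mca_s1 dd_mca_s2 dd_mca_s3 dd_mca_s4 dd_mca_ai`)
reproduces the study's qualitative ranking: CMA+GP is the least
cost-effective (its unresolved negative exits are scored as missed
diagnoses), each added or earlier exome tier improves the ratio, and the
AI-delegated workflow matches ES-only while deferring the expensive test
where the AI predicts the cheaper panel will succeed. A precision sweep
(`diagcea sweep dd_mca_ai --param ai_precision --bins 0.1,0.3,0.5,0.7,0.9`)
shows its cost per QALY falling monotonically as AI precision rises.

The same machinery is available as a library — see
`diagcea.build_scenario`, `diagcea.evaluate`, `diagcea.run_psa` — and
works on arbitrary user trees written as JSON files (`diagcea validate`,
`diagcea cost`, `diagcea delegate`).

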