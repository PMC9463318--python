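# Methods

## The decision model

A clinical decision model (CDM) here is a discrete Bayesian network: a DAG
over categorical variables with a conditional probability table (CPT) per
node.  Variables carry a role — `diagnostic` (observed inputs),
`intermediate` (derived clinical summaries), `target` (therapy-eligibility
nodes).  State order is semantic: MAP ties resolve to the first declared
state, and for therapy nodes the first state is the eligible/positive one
used for ROC scoring; Boolean nodes are exactly `[true, false]`.

Inference is exact.  `infer_posterior` runs variable elimination with a
greedy min-degree ordering; since the result is exact, the ordering affects
speed only.  `enumerate_posterior` is the brute-force oracle (sum of the
chain-rule joint over all completions) and the two must agree to 1e-9
wherever enumeration is feasible — this equivalence is asserted on hundreds
of randomized networks in the test suite.  Evidence with probability zero
raises an explicit error rather than returning a silent uniform: a silent
fallback would corrupt validation counts.

CPT rows must sum to 1 within 1e-9; at model load, rows off by at most 1e-6
are renormalised, anything worse is rejected.

## Parameter learning

CPTs are estimated in closed form from complete records with Dirichlet
pseudocount smoothing, `(n_rs + α) / (n_r + αK)`, default `α = 1`.  The
complete-data assumption matches the intended workflow (one fully coded row
per patient); missing cells are rejected, not imputed, so EM is
unnecessary.  With `α = 0` an unobserved parent configuration yields a
uniform row; either way, under-coverage is surfaced by `fit_report`, which
returns per-variable fractions of parent configurations observed at least
once.  This "density of information" is the central small-data diagnostic:
the packaged first-draft model has therapy nodes with 96–640 parent
configurations, which a 94-record cohort cannot populate.

## Abstraction operators

Each operator transforms model and dataset together and records an
`AbstractionStep` with before/after free-parameter counts
(`(|states|−1)·Π|parent states|` per node).

* **merge_states** — partition a variable's states into labelled groups;
  dataset cells are remapped and, by default, all affected CPTs are
  re-learned from the remapped data (merging then learning is exactly
  learning on the remapped dataset).  Without data, tables are aggregated
  analytically: child columns are summed within groups (exact), parent rows
  are pooled by unweighted averaging (exact only for equiprobable merged
  configurations — hence re-learning is the default).
* **condense_variables** — replace several source variables by one derived
  summary via a total mapping over source-state tuples.  The derived node
  takes an explicit (possibly empty) parent list, and children of any
  source are rewired to depend on the derived node.  The rewiring is a
  deliberate design choice: a condensed summary *replaces* its sources in
  the graph, so downstream conditionals survive and are re-learned; without
  it, condensing e.g. resectability would orphan the surgery node.
* **binarize_target** — the two-group special case of merging, producing a
  Boolean `[true, false]` variable.
* **resolve_transitivity** — independence of causal influence between
  target families: for distinct targets X ≠ Y, every edge from a parent of
  X to a parent of Y is removed.  Idempotent, never adds edges; children
  losing parents get uniform rows pending re-learning.  Under the
  evaluation protocol (all non-targets observed) this step cannot change
  target posteriors; it only removes parameters.
* **compile_noisy_or / apply_noisy_or** — leaky noisy-OR:
  `P(true | x) = 1 − (1−leak)·Π_{i:x_i}(1−p_i)` compiled into a full CPT
  over `2^n` rows; `n+1` numbers replace an exponential table.

Recipes (ordered step lists) serialize to YAML and replay deterministically,
so the whole v1→v2→v3 simplification is a reproducible artefact rather than
an anecdote.

## Evaluation protocol

Tenfold cross-validation with shuffled round-robin fold assignment (sizes
differ by at most one; a stratified assignment is available but off by
default).  Per fold, CPTs are learned on the other nine folds; each
held-out patient's targets are predicted from evidence on **all non-target
variables** — therapy nodes are never evidence for one another, matching
clinical use where no decision is known in advance.  Correctness is MAP
state versus recorded state (the 0.5-threshold rule for Boolean targets);
accuracy is micro-averaged: pooled correct (patient, target) pairs over
`n_records × n_targets`.  Per target, the posterior of the positive state
is pooled across folds into an ROC curve (thresholds at the distinct
scores, ties grouped); AUC is the trapezoidal area and equals the
tie-corrected concordance `P(s⁺>s⁻) + ½P(tie)`, an identity the tests
verify against the Mann–Whitney statistic.  A target with one observed
class gets a flagged undefined AUC with class counts rather than an
arbitrary number.  Accuracies and AUCs are reported to 3 decimals.

## The synthetic cohort and what it does (not) show

Real treatment records are hospital data and are not shipped.  The
generator emulates their statistical shape: 23 root diagnostic variables
(TNM-2017-style T/N/M with 8 nodal states, p16 status, Karnofsky bands
k100–k30, infiltration flags, comorbidity, lifestyle and symptom
variables) with fixed realistic marginals; 7 deterministic intermediates
(a stylized stage grouping, resectability, nodal-disease class, general
condition, treatment tolerance, prognosis, functional-limitation risk); and
7 therapy nodes labelled by deterministic guideline-style eligibility rules
(e.g. surgery eligible iff the primary is resectable and general condition
is not poor; primary radiotherapy iff unresectable with adequate treatment
tolerance).  Defaults mirror the emulated study: 94 patients, a 5%
label-noise probability that a recorded therapy label deviates from its
rule value (flipped to a uniformly chosen other state), and exactly two
primary-radiotherapy positives, enforced by patching sampled rows (patches
are recorded on the returned truth object; pure rejection cannot guarantee
exact counts at n = 94).

What passing tests show: the workflow's algebra is correct, and the
qualitative small-data phenomenon is real — an over-detailed model loses
accuracy to unobserved configurations and recovers it under abstraction.
What they do not show: clinical fidelity of the joint distribution beyond
the documented constraints, survival or HPV-epidemiology realism, or the
exact accuracy values of any particular hospital cohort.

## The packaged model versions

* **v1** (37 variables, 109 states, 3108 free parameters): therapy nodes
  hang on the raw high-arity variables — deliberately, since the detailed
  first draft is the failure case under study.
* **v1→v2 recipe** (clinical clustering): 8 nodal states to a
  resectable/unresectable dichotomy; resectability + carotid infiltration
  condensed to one observed summary; the two side-specific neck-dissection
  nodes condensed to one (five therapy nodes remain); organ comorbidities
  condensed to a burden flag; Karnofsky to three bands; stage to three
  strata.
* **v2→v3 recipe** (canonical models): stage, Karnofsky, T-extent, general
  condition binarized into risk flags; surgery and neck dissection condensed
  into a Boolean `surgery_feasible`; remaining therapy nodes binarized
  (`true` = eligible); prognosis condensed to a directly observed summary
  (once stage is binary its conditional is an irreducible mixture and it
  carries no decision information through parents); transitivity resolved
  between the four target families; best supportive care re-parameterized
  as a leaky noisy-OR of advanced stage and poor general condition (links
  0.90/0.95, leak 0.02 — palliative care essentially only via those
  causes).  Best supportive care exists in all versions and is excluded
  from every evaluation.

v1 validation uses five targets (the contralateral neck-dissection node is
excluded), giving the 94×5 = 470 denominator; v2 likewise 470; v3 has
94×4 = 376.

Fixture CPTs: v1 carries the generator's diagnostic layer and uniform
therapy tables (parameters are the learner's job).  v2/v3 tables are
empirical conditionals from a fixed-seed calibration cohort (n = 2000)
with *marginal back-off* for configurations absent from it — the ICI
restructuring decouples parents, so configurations impossible in coupled
data become reachable when sampling the fixture, and a concentrated
back-off row is the realistic generating behaviour there.  The v3 therapy
tables are written analytically from the eligibility rules with a 2%
residual deviation rate.  A consequence worth knowing: rows of the v3
fixture that are reachable only at low probability are near-deterministic,
which is what makes parameter recovery from finite samples well-posed at
the tested precision.

## Numerical choices and edge cases

* MAP ties: first declared state wins (deterministic, documented).
* Impossible evidence: hard error end to end.
* Learning: `α = 1` default; `α = 0` uses uniform fallback rows and flags
  them; results never depend on the exact α in the tests' assertions.
* Fold assignment, sampling and noise all derive from a single integer
  seed; reports are reproducible bit-for-bit from
  (dataset, structure, k, seed, α).
* Problem sizes used in the shipped checks: 94-record cohorts for the
  pipeline demonstrations, 10,000-record ancestral samples for parameter
  recovery, 200 randomized networks (≤6 nodes, ≤4 states) for the
  inference-oracle equivalence — sizes at which the brute-force oracle is
  itself trustworthy.

## Known limitations

* The staging, resectability and eligibility rules are stylized teaching
  rules, not clinical staging logic; do not reuse them for care decisions.
* Condensed summaries become (optionally parentless) observed nodes; the
  package does not model them as latent.
* XDSL support is export-only (no submodels, no layout); round-tripping
  through the external modeller is out of scope.
* No approximate inference: networks whose elimination width defeats exact
  inference are out of scope by design.
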