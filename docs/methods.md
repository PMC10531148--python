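# Methods

## The decision problem

One row of the visit table is one clinic visit: cognitive assessments
(MMSE, ADAS13, RAVLT immediate/learning, CDRSB, MoCA), an FDG-PET
metabolic ratio, age, diagnosis (CN/MCI/AD), hypertension and depression
flags, and the medications recorded at that visit. The package treats the
sequence of visits as a logged tabular MDP episode: the state is a
discretized disease stage, the action is the medication class recorded at
the earlier visit of each consecutive pair (it labels the interval that
follows), and the reward is the raw MMSE difference to the next visit —
no per-interval time normalization, even when visit gaps differ. Records
end at the last visit with no terminal bonus; the value beyond the record
is zero. The discount is γ = 0.3 throughout, so the effective horizon is
short (γ⁴ < 0.01) and the return is dominated by the next one or two
intervals.

## State discretization

Ordinary least squares regresses MMSE on the candidate assessments;
features with p < 0.05 enter a CART regression tree (squared error,
maximum depth 6) whose minimum leaf size equals the occupancy threshold
(default 50 visits). Leaves are the discrete states, numbered depth-first.
Split intervals are left-open/right-closed, `(a, b]`: a value exactly on a
threshold belongs to the lower leaf. Visits falling into a pruned-leaf
region are "unassigned" and any transition touching them is dropped from
the MDP data. Constant or exactly collinear candidates are excluded before
the fit with a logged warning. The tree fit is deterministic for fixed
data and settings; equal-gain split ties are resolved by the CART
implementation's deterministic internal order.

A published per-cohort rule set ships as a verbatim CSV fixture (13
whole-data states, 9 AD states, and the hypertension/depression blocks).
The fixture deliberately preserves two anomalies in its source table — one
state label appears twice in the depression block, and one
hypertension-block state overlaps two earlier ones — and the loader
reports both on the returned model instead of silently resolving them;
assignment is first-match.

## Policies and solvers

All policies are rows π(a|s) over the six classes. Every solver obeys a
*support restriction*: greedy improvement ranks only actions observed at a
state in the training log, and a state with no observed action falls back
to NO_DRUGS. This avoids fabricating dynamics for unobserved pairs; it
also means the learned policies are only defined relative to what
clinicians actually tried.

- **Policy iteration** — exact evaluation (direct linear solve
  `v = (I − γP_π)⁻¹ r_π` up to 200 states, power iteration to 1e-8
  beyond) alternating with greedy improvement until the policy is stable.
  Ties break to the lowest action index.
- **Q-learning** — tabular replay of the logged transitions: Q starts at
  zero and each pass sweeps all transitions in a fresh seeded random
  order with `Q(s,a) += α (r + γ max_{a'∈observed(s')} Q(s',a') − Q(s,a))`,
  α = 0.05, 50 passes by default. The last transition of a trajectory
  targets the raw reward (episode end, value 0); a `bootstrap_terminals`
  flag instead bootstraps through it, appropriate when trajectories are
  truncations of a continuing process (used in the solver-consistency
  tests on continuing random MDPs). With a fixed α on stochastic logs the
  Q-table fluctuates around the empirical fixed point rather than
  converging exactly; on deterministic replayed logs it converges
  geometrically, which is what the consistency oracle exploits.
- **Clinician policy** — one evaluation + one improvement cycle on the
  empirical transition model, starting from the behavior policy (the
  per-state empirical prescribing frequencies). A data-driven proxy: with
  abundant data it coincides with policy iteration's fixed point wherever
  the behavior policy is already near-greedy.
- **Zero / random** — one-hot NO_DRUGS everywhere; uniform 1/6 everywhere.

## Off-policy evaluation

Step-WIS (per-decision weighted importance sampling): for trajectory i at
step t the cumulative ratio is w_{i,t} = Π_{u≤t} π(a_u|s_u)/π_b(a_u|s_u),
and the value estimate is Σ_t γ^t Σ_i ŵ_{i,t} r_{i,t} with ŵ normalized
across trajectories at each step. A trajectory shorter than t keeps its
final cumulative weight with zero reward; this carrying convention is what
makes the estimator collapse exactly to the empirical mean discounted
return when target = behavior even with variable-length records, which is
the identity the tests pin down. A step whose normalizer is zero (the
target has no support on any logged prefix) contributes zero and is
flagged. Trajectory-wise WIS and plain IS are available behind an
`estimator` flag; ratios can optionally be clipped. The behavior policy
used for evaluation is always the empirical policy of the evaluation log
itself, which guarantees the support precondition. Deterministic targets
are one-hot rows; their estimates rest on the (typically few) logged
trajectories whose prefix matches the target exactly, which is the
familiar variance cost of WIS with deterministic policies.

## The experimental harness

Each experiment splits patients (not visits) 60/20/20 into
train/validation/test. The state tree and empirical MDP come from the
training split. Q-learning is trained over 50 seeded repetitions and the
repetition with the best validation step-WIS value is kept; policy
iteration is deterministic and trained once. All five policies are scored
on 100 bootstrap resamples of the test patients; resamples are shared
across policies, so comparisons are paired. Pairwise significance uses
Welch's unequal-variance t-test (a flag restores the pooled-variance
version). All randomness descends from one master seed through labelled
streams, and repeated runs write byte-identical result tables.

The data-size sweep (driver 04) fits the state space once on the full
training split and holds it fixed while the solvers are retrained on
100/80/50/30% subsamples, and all fractions share one bootstrap stream.
Varying only the training data — not the state definition — isolates the
data-volume effect and makes the per-fraction distributions directly
comparable; refitting the tree per fraction would confound shrinking data
with a changing abstraction.

## The synthetic cohort

Real AD registry exports are access-controlled, so the cohort is simulated
from an explicit ground-truth MDP with (by default) five latent severity
stages. Each stage has a characteristic assessment profile (MMSE means
29/25/20/14/6 with matching ADAS13, RAVLT, CDRSB, MoCA and FDG profiles);
scores are emitted as Gaussians around the stage mean, truncated to
instrument ranges and rounded to instrument granularity (integers for the
cognitive batteries, half points for CDRSB, continuous FDG). Each stage
has one clearly best medication class — ChEIs while mild, memantine or
the combination once moderate/severe — under which patients mostly hold
steady with a real chance of improving a stage; under any other class,
and especially under no treatment, decline to the next stage dominates.
The per-(stage, action) expected MMSE change is derived from the
transition tensor and the MMSE emission profile, so observed rewards are
consistent with the latent dynamics by construction, and the exactly
optimal policy (via exact policy iteration on the latent MDP) is known.
The resulting per-stage best-action value gaps at γ = 0.3 are 1.9–3.9
MMSE points.

The behavior policy is a softmax over stage-dependent logits
(temperature 1): watchful waiting and supplements dominate while mild,
AD-specific drugs grow with severity, and every class keeps positive
probability at every stage — full support is what makes the behavior
policy estimable and the WIS weights well-defined. Visits are six-monthly;
the visit count is uniform on [2, 15] (no informative dropout); ages start
uniform in [55, 88] and advance with the calendar; hypertension and
depression are patient-level Bernoulli flags (prevalences 0.40 and 0.30)
that do not enter the dynamics; score cells are missing completely at
random at rate 0.05, except MMSE at baseline, which is never missing.
Seeding is hierarchical — the global seed plus the patient index seeds
each patient's stream — so patient k's record is byte-identical whatever
the cohort size.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: informative dropout and visit irregularity;
comorbidity-dependent dynamics or prescribing (the flags are decorative,
so the five analysis cohorts share one data-generating process and —
because the synthetic behavior policy prescribes AD drugs at least
occasionally at every stage — nearly every simulated patient qualifies
for the AD cohort, unlike a real registry with a large cognitively-normal
stratum); confounding by unobserved severity (the behavior policy
conditions only on the latent stage the state tree is designed to
recover, so the no-unmeasured-confounders assumption of off-policy
evaluation holds by construction); measurement drift, practice effects
and floor/ceiling dynamics of real instruments beyond simple truncation.
One floor-effect artifact of the truncated design is worth noting: the
most severe stage cannot decline further, so patients with low MMSE can
show less negative observed rewards than milder patients, and the
JR/SR caseload stratification need not order the strata the way real
junior/senior caseloads would.

## Recovery analyses and granularity

The end-to-end recovery test generates 2000-patient cohorts, fits the full
pipeline, and asks whether each solver's action matches the true optimal
action of the latent stage, mapping every tree state to its modal latent
stage among training visits. For this analysis the occupancy threshold is
200 rather than 50: with ~12 000 visits and a depth-6 tree, a 50-visit
minimum admits noise splits whose boundary leaves mix adjacent stages, and
a mixed leaf's empirical-MDP optimum can legitimately differ from its
modal stage's optimum — a property of the abstraction, not a solver
error. At a 200-visit minimum the leaves align with the five stages and
both solvers recover ≥ 95% of states (median over seeds). The
state-count sweep (driver 06) explores the same granularity trade-off on
the reward scale.

## Numerical conventions

- Gamma must lie in [0, 1); alpha in (0, 1); violations raise domain
  errors rather than clamping.
- Transition rows are validated to sum to 1 within 1e-12; policy rows
  likewise.
- All argmax tie-breaks resolve to the lowest action index, so NO_DRUGS
  wins full ties by construction.
- Empty states: behavior rows default to uniform; greedy policies fall
  back to NO_DRUGS; policy evaluation treats them as absorbing with zero
  reward.
- Degenerate inputs (fewer visits than the occupancy threshold, empty
  eligibility output, empty cohorts or strata in sweeps) degrade to
  logged warnings and single-state models or skipped sweep levels, never
  silent wrong answers.
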