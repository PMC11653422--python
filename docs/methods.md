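# Methods

This note documents the models, the tunable parameters and their defaults,
the synthetic-data design, numerical choices, and known limitations of
`citutor`. It is the companion to the API documentation; nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Learner model

The learner model is a discrete Bayesian network over 12 ternary nodes
(states low/med/high, embedded numerically as 0/0.5/1). Seven observable
variables — sound perception, sound categorization, consonant and vowel
differentiation, word differentiation, word identification, sentence
identification — carry the evidence from task results. Four subcompetencies
(nonlexical, phoneme, word, sentence understanding) aggregate them, and a
single sink node `hearing` aggregates the subcompetencies. Sound perception
additionally parents sound categorization, so a perception result propagates
into the categorization belief. The topology is config-overridable
(`build_default_network(config)`), since any fixed competency graph is a
clinical simplification.

**CPTs.** The design constraint is symmetry: a child depends on each parent
identically. We therefore generate every row from the *mean* m of the
parents' numeric states, linearly interpolated between the one-hot
distributions (m ≤ 0.5: between one-hot low and one-hot med; m ≥ 0.5: between
one-hot med and one-hot high) and smoothed with ε:

    row = (1 − 3ε)·B(m) + ε        ε = 0.05 by default, ε ∈ [0, 1/3)

ε = 0 gives intuitive deterministic endpoints (all parents high ⇒ child high);
ε = 1/3 would erase all parent information. 0.05 keeps rows informative while
preventing zero-probability states from hard-locking inference.

**Evidence.** Task results never clamp a node. Each node holds a virtual
evidence vector (a soft likelihood, uniform ⇔ uninformative) multiplied into
the joint. A result on observable v mixes its evidence toward one-hot
high/low:

    e_v ← normalize(clamp(λ_min, (1 − δ_eff)·e_v + δ_eff·target))
    δ_eff = δ0·(0.5 + d)  if correct,   δ0·(1.5 − d)  if incorrect,  clamped to [0, 0.2]

with task difficulty d. The weighting encodes that a correct answer on a hard
task is stronger evidence of high competence, and an incorrect answer on an
easy task stronger evidence of low competence. δ0 = 0.08 by default ("slight"
changes: roughly 12 consistent results to traverse most of the belief range);
the floor λ_min = 0.01 keeps states from becoming absorbing. Virtual evidence
is legal on any node, which is how stereotype profiles initialize latent
nodes too.

**Inference** is exact: posterior marginals are computed by tensor
contraction of all CPT and evidence factors along a cached greedy elimination
path (`numpy.einsum`). With ≤ 12 ternary nodes exactness is cheap (~2 ms);
the test suite checks agreement with brute-force joint-state enumeration to
1e-9 (in practice ~1e-16).

**Cold start.** Seven stereotype profiles P1…P7 ladder every observable's
evidence from (0.8, 0.15, 0.05) to (0.05, 0.15, 0.8) in equal steps of 0.125,
so profile k implies a mean competence scalar of 0.125·k. A 10-task
introductory chapter (each type at mid difficulty, three seeded extras) maps
observed accuracy to the profile with the nearest implied scalar; ties go to
the lower profile. The ladder and the accuracy rule are this package's
choices — deployed systems use clinician-defined profiles, which are not
public.

## Task bank

Assets are sounds, words, or sentences with difficulty metadata in [0, 1]:
loudness, recurrence (familiarity), concreteness, plus a phonetic code.
Similarity between same-type assets is 1 − (Levenshtein distance / max code
length). Candidate difficulty per task type:

| type  | difficulty of a candidate |
|-------|---------------------------|
| SP/SC | mean(1−loudness, 1−recurrence, 1−concreteness) of the key |
| CD/VD/WD | similarity(key, distractor) on different-trials; 1−recurrence(key) on same-trials |
| WI/SI | 0.6·mean distractor similarity + 0.4·(1−recurrence of key) |

Background noise adds +0.15 (capped at 1) and is switched on when the target
difficulty exceeds 0.7. These per-type formulas are documented stand-ins for
production selection-parameter tables that are not public; every weight is a
module constant. Same/different trials for CD/VD/WD are balanced 0.5/0.5,
seeded; SP trials are silent with probability 0.5 (so "No" can be correct),
and a silence trial inherits the difficulty of the sound that would have been
played — the simplest rule consistent with difficulty-matched selection.

The fixture generator emulates a realistic annotated pool (default n = 1053):
~40% sounds, ~40% words, ~20% sentences; the three difficulty features are
i.i.d. uniform on [0, 1]; syllable counts span 1–8; phonetic codes are built
from a small synthetic syllable inventory so pairwise similarity spans
[0, 1]; sounds carry 1–2 category tags from a fixed set of six so
categorization tasks are constructible. The codes are synthetic strings — no
grapheme-to-phoneme conversion, no audio. What passing tests show is that the
*algorithms* behave correctly on pools with this structure; they say nothing
about the psychometric validity of any real asset annotation.

## Tutor

Task-type utility is U(t) = w_rep·rep + w_weak·weak + w_streak·streak with
defaults 0.5/0.3/0.2: repetition dominates (prevents fixation on one type),
weakness adds a minor focus on weak competencies, streak breaks long
monotonous runs. rep(t) = 1 − count(t in last 30 results)/30;
weak(t) = 1 − posterior scalar of t's observable; streak(t) = 1 −
min(L, 5)/5 with L the trailing same-outcome run among type-t results. Ties
break in canonical order SP, SC, CD, VD, WD, WI, SI — determinism over
randomness, for testability.

Target difficulty is the posterior scalar of the chosen type's observable
(0·p_low + 0.5·p_med + 1·p_high). Task selection enumerates candidates —
fully for single-asset types; key/distractor combinations are combinatorial,
so CD/VD/WD pairs and WI/SI triples are drawn as a seeded sample capped at
M = 500 — excludes keys used in the last K = 10 tasks, and returns the
candidate minimizing |difficulty − target| (ties: smaller asset id). The
sampling cap trades an exactly-nearest candidate for bounded latency; with
M = 500 the gap to the true nearest difficulty is negligible relative to the
pool's difficulty grid.

## Learner simulation

Agents hold one static latent ability θ ∈ [0, 1] per observable and answer
with the guessing-floored logistic (3-parameter IRT form)

    P(correct) = g + (1 − g − s)·σ(a·(θ − d)),   g = 1/#options

with slip s = 0.05 and discrimination a = 8 (σ spans most of its range over
|θ − d| ≈ 0.5). Abilities are static within a session: the training period is
short and within-period learning unquantified, so estimated-competence drift
reflects the tutoring loop, not the agent. Cohorts draw per-observable
abilities i.i.d. uniform on [0.1, 0.9] by default; per-agent seeds are
spawned from the master seed via `numpy.random.SeedSequence`, making logs
bit-reproducible. The closed loop per task: recommend → sample correctness →
update the answered observable → infer → log a competence snapshot. With
cold start enabled, the 10-task introductory chapter only selects the
starting profile and is not part of the returned log, so trajectories start
at the profile values.

A structural property of this model worth knowing: for the five 2-option
task types the guessing floor puts P(correct) ≥ 0.5 at every difficulty, and
under the difficulty-weighted update the expected evidence drift is
proportional to 2p + d − 1.5 — strictly positive whenever the served
difficulty exceeds 0.5. Those observables' estimates therefore trend toward
"high" for *any* ability level, only at ability-dependent speed; the
4-option types (WI/SI), whose floor is 0.25, have a stable ability-dependent
equilibrium and recover ability rankings much more sharply. Consequences:
ability recovery through the aggregate hearing node is diluted (rank
correlations around 0.6–0.7 for a 23-agent, 250-task cohort, as
`scripts/acceptance.py` reports), and at 250 tasks the 2-option nodes are
still mid-transit, so late-session movement of the hearing scalar remains
comparable to early movement. Both are consequences of combining a
floor-type response model with sign-free difficulty weighting, not of any
particular parameter setting.

## Evaluation

Descriptives report exact integer counts and per-learner means/medians/SDs;
error proportions are reported both pooled and as the mean of per-learner
proportions (they differ whenever learners complete different task counts,
and published summaries mix the two conventions). Analyses truncate each
learner to the first `max_tasks` = 250 results.

The χ² goodness-of-fit statistic is Σ(O−E)²/E with df = cells − 1 (6 for the
seven types), p from the χ² upper tail. Group comparisons use Kruskal–Wallis
(tie-corrected, via scipy) followed by Dunn z-tests on mean ranks with the
tie-corrected pooled variance and Holm step-down adjustment over all 21
pairs of 7 groups; results are summarized as a compact letter display via
the insertion algorithm (groups sharing a letter do not differ at α).
All-identical pooled values raise a degenerate-data error rather than a
meaningless statistic.

Competence trajectories are smoothed with a centered moving average
(default window 5, shrinking at the edges) — a deliberately dependency-light
substitute for spline/GAM smoothing, which these analyses use only
descriptively — and convergence is quantified as the mean |Δ| over the first
versus last quartile of task indices (series of length ≥ 8).

## Numerical and interface choices

- Belief vectors must sum to 1 within 1e-9; every operation renormalizes.
- All ties break deterministically (task-type order, then asset id; lower
  profile index), so `recommend`, sessions, and the pipeline are pure
  functions of their seeds; event logs are written with sorted JSON keys and
  compare byte-identical across runs.
- Network state serializes to JSON with full float precision (`repr`
  round-trip), so save/load reproduces evidence bitwise.
- The pipeline (`run_pipeline`) writes pool CSV, per-agent state JSON, JSONL
  logs, a report JSON, and a manifest recording the seed and effective
  config. Pseudonyms are opaque generated strings; no identifying data
  exists anywhere in the system.
- Problem sizes in the test suite and acceptance script (23 × 250 and
  20 × 100 simulated sessions, 100 random evidence configurations for the
  inference oracle) were chosen as the smallest sizes that exercise the
  cohort-level statistics meaningfully.

## Limitations

- No audio, no German lexicon: phonetic codes and labels are synthetic, and
  similarity is plain edit distance, not a perceptual metric.
- The response model ignores fatigue, motivation, and learning within the
  training period; abilities are static unless configured otherwise.
- CPTs are fixed by the symmetry kernel; no learning of CPTs from data, no
  continuous-state or time-sliced (dynamic) network variants.
- The compact-letter display is the standard insertion algorithm without
  letter-minimization heuristics; for 7 groups this is exact enough.
- The simulator is a study tool, not a clinical claim: passing its tests
  shows the adaptive loop behaves as designed under the stated response
  model, not that real CI recipients behave like the agents.
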