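# citutor

An intelligent tutoring system for **adaptive auditory training of cochlear
implant (CI) recipients**, implemented as a tested Python library with a small
CLI. After implantation, CI recipients must relearn spoken-language
comprehension; self-directed computer-based training works best when task type
and difficulty track the learner's current skill. `citutor` provides the three
parts of such a system, plus the synthetic learners and statistics needed to
study it without patient data:

- a **Bayesian-network learner model** over three-state competencies
  (low/medium/high) with virtual-evidence updates and exact inference,
- a **utility-based tutor** that picks the next task type, derives a target
  difficulty, and assembles the closest-matching single-choice task from an
  annotated pool of sound/word/sentence assets,
- an **agent-based simulator** of CI recipients (IRT-style response model) and
  an **evaluation pipeline** (descriptives, χ² goodness of fit,
  Kruskal–Wallis + Dunn/Holm with compact letter display, competence-trajectory
  gradient analysis) over JSONL event logs.

## The model

The learner model is a 12-node discrete Bayesian network. Seven *observable
variables* — one per task type: sound perception (SP), sound categorization
(SC), consonant/vowel differentiation (CD/VD), word differentiation (WD), word
identification (WI), sentence identification (SI) — feed four latent
subcompetencies (nonlexical, phoneme, word, and sentence understanding), which
feed the overall competence *hearing*. Every node has states
{low, med, high} ↦ {0, 0.5, 1}. CPTs are "evenly distributed": a child's row
depends only on the mean m of its parents' numeric states, interpolated
between one-hot state distributions and smoothed by ε:

    row = (1 − 3ε) · B(m) + ε,   B(m) linear between δ_low, δ_med, δ_high

Each task result nudges the answered observable's virtual evidence e_v toward
high (correct) or low (incorrect),

    e_v ← normalize(max((1 − δ_eff) e_v + δ_eff · target, λ_min)),
    δ_eff = δ0 (0.5 + d) if correct, δ0 (1.5 − d) if incorrect,

with task difficulty d ∈ [0, 1], and exact inference propagates the change.
The tutor scores the seven types with U(t) = 0.5·repetition + 0.3·weakness +
0.2·streak, uses the chosen type's posterior scalar as target difficulty, and
serves the candidate task minimizing |difficulty − target|. Synthetic learners
answer with P(correct) = g + (1 − g − s)·σ(a(θ − d)), where g is the guessing
floor (1/#options), s the slip rate, and θ the latent ability.

## Worked example

```python
from citutor import (build_default_network, generate_fixture_pool,
                     infer_marginals, recommend, update_observable)
from citutor.network import TYPE_OBSERVABLE

pool = generate_fixture_pool(1053, seed=1)     # synthetic annotated asset pool
net = build_default_network()                  # fresh learner model
task = recommend(net, pool, history=[], seed=7)
print("recommended:", task.task_type, "difficulty=%.3f" % task.difficulty,
      "options=%s" % (task.options,))

net = update_observable(net, TYPE_OBSERVABLE[task.task_type], correct=True,
                        task_difficulty=task.difficulty)
m = infer_marginals(net)
print("P(sound_perception) = %s" % m["sound_perception"].as_array().round(3))
print("P(hearing)          = %s" % m["hearing"].as_array().round(3))
print("hearing scalar      = %.3f" % m["hearing"].scalar())
```

prints

```
recommended: SP difficulty=0.500 options=('Yes', 'No')
P(sound_perception) = [0.307 0.307 0.387]
P(hearing)          = [0.169 0.649 0.182]
hearing scalar      = 0.507
```

With no history every task type has equal utility and the tie breaks to SP;
the uniform belief maps to target difficulty 0.5. One correct answer at
d = 0.5 shifts the perception posterior toward "high" (0.387), and inference
lifts the overall hearing estimate slightly above neutral (0.507).

The same loop is available from the shell:

```sh
citutor init-fixtures --n 1053 --seed 1 --out pool.csv
citutor simulate --agents 23 --tasks 100 --seed 7 --pool pool.csv --out logs/
citutor evaluate --logs logs/ --max-tasks 250 --out report.json
```

`report.json` contains the cohort summary, the task-type χ² test, the
Kruskal–Wallis/Dunn letters for type and error proportions, and per-learner
early/late trajectory gradients.

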