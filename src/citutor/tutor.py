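"""Utility-based task recommendation.

Each new task is created in three steps.  First the task *type* is chosen by
scoring all seven types with a weighted sum of three criteria — repetition
(types seen rarely in the recent window score higher), weakness (types whose
observable variable is believed weak score higher), and streak (types on a
long run of identical outcomes score lower) — and taking the argmax.  Second,
the *target difficulty* is the scalar competence of the chosen type's
observable under the current posterior.  Third, candidate key/distractor
combinations from the asset pool are scored and the one whose difficulty is
closest to the target wins.

Ties are always broken deterministically: task types in canonical order
(SP, SC, CD, VD, WD, WI, SI), assets by id.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .beliefs import BeliefVector
from .errors import ContractError, EmptyPoolError, NodeLookupError
from .network import (
    TASK_TYPES,
    TYPE_OBSERVABLE,
    CompetenceProfile,
    CompetencyNetwork,
    belief_to_difficulty,
    infer_marginals,
)
from .task_bank import (
    DISTRACTOR_COUNT,
    TASK_ASSET_TYPE,
    AssetPool,
    SoundAsset,
    TaskSpec,
    build_task,
    candidate_difficulty,
)


@dataclass(frozen=True)
class TutorConfig:
    """Tunable parameters of the recommender.

    The weights sum to 1; repetition dominates so no single type can be
    drilled exclusively, with a minor focus on the weaker competencies.
    """

    w_rep: float = 0.5
    w_weak: float = 0.3
    w_streak: float = 0.2
    streak_cap: int = 5
    recent_k: int = 10
    sample_m: int = 500
    noise_threshold: float = 0.7
    window: int = 30

    def __post_init__(self) -> None:
        if min(self.w_rep, self.w_weak, self.w_streak) < 0:
            raise ContractError("utility weights must be non-negative")
        if abs(self.w_rep + self.w_weak + self.w_streak - 1.0) > 1e-9:
            raise ContractError("utility weights must sum to 1")
        if self.window < 1 or self.streak_cap < 1:
            raise ContractError("window and streak_cap must be >= 1")


@dataclass
class HistoryWindow:
    """Ordered task results with the recency window used for scoring."""

    results: list = field(default_factory=list)
    window: int = 30


def _results(history) -> Sequence:
    return history.results if isinstance(history, HistoryWindow) else history


# -- the three criteria ----------------------------------------------------

def repetition_score(history, task_type: str, window: int = 30) -> float:
    """1 − (share of the last ``window`` tasks that had this type)."""
    recent = list(_results(history))[-window:]
    count = sum(1 for r in recent if r.task_type == task_type)
    return 1.0 - count / window


def weakness_score(marginals: Mapping[str, BeliefVector], task_type: str) -> float:
    """1 − scalar competence of the type's observable: weak types score high."""
    if task_type not in TYPE_OBSERVABLE:
        raise NodeLookupError(f"no observable mapped to task type {task_type!r}")
    node = TYPE_OBSERVABLE[task_type]
    if node not in marginals:
        raise NodeLookupError(f"marginals lack node {node!r}")
    return 1.0 - belief_to_difficulty(marginals[node])


def streak_score(history, task_type: str, streak_cap: int = 5) -> float:
    """1 − min(L, cap)/cap where L is the trailing same-outcome run length."""
    outcomes = [r.correct for r in _results(history) if r.task_type == task_type]
    run = 0
    for outcome in reversed(outcomes):
        if run == 0 or outcome == last:
            run += 1
            last = outcome
        else:
            break
    return 1.0 - min(run, streak_cap) / streak_cap


def utility_scores(
    marginals: Mapping[str, BeliefVector], history, cfg: TutorConfig
) -> dict[str, float]:
    """Weighted utility of every task type."""
    return {
        t: cfg.w_rep * repetition_score(history, t, cfg.window)
        + cfg.w_weak * weakness_score(marginals, t)
        + cfg.w_streak * streak_score(history, t, cfg.streak_cap)
        for t in TASK_TYPES
    }


def select_task_type(
    net: CompetencyNetwork,
    history,
    cfg: TutorConfig | None = None,
    marginals: Mapping[str, BeliefVector] | None = None,
) -> str:
    """Argmax utility; ties resolved in canonical task-type order."""
    cfg = cfg or TutorConfig()
    if marginals is None:
        marginals = infer_marginals(net)
    scores = utility_scores(marginals, history, cfg)
    return max(TASK_TYPES, key=lambda t: (scores[t], -TASK_TYPES.index(t)))


def target_difficulty(
    net: CompetencyNetwork,
    task_type: str,
    marginals: Mapping[str, BeliefVector] | None = None,
) -> float:
    """Scalar competence of the type's observable under the posterior."""
    if task_type not in TYPE_OBSERVABLE:
        raise NodeLookupError(f"no observable mapped to task type {task_type!r}")
    if marginals is None:
        marginals = infer_marginals(net)
    return belief_to_difficulty(marginals[TYPE_OBSERVABLE[task_type]])


# -- candidate enumeration and selection -----------------------------------

@dataclass(frozen=True)
class _Candidate:
    key: SoundAsset
    distractors: tuple[SoundAsset, ...]
    same_trial: bool
    difficulty: float


def _enumerate_candidates(
    pool: AssetPool,
    task_type: str,
    noise: bool,
    excluded: frozenset[str],
    cfg: TutorConfig,
    rng: np.random.Generator,
) -> list[_Candidate]:
    assets = [a for a in pool.by_type[TASK_ASSET_TYPE[task_type]] if a.id not in excluded]
    cands: list[_Candidate] = []
    if task_type in ("SP", "SC"):
        if task_type == "SC":
            assets = [a for a in assets if a.categories]
        for a in assets:
            cands.append(
                _Candidate(a, (), False, candidate_difficulty(task_type, a, (), False, noise))
            )
    elif task_type in ("CD", "VD", "WD"):
        for a in assets:  # same-trials: fully enumerated
            cands.append(
                _Candidate(a, (), True, candidate_difficulty(task_type, a, (), True, noise))
            )
        # different-trials are combinatorial; draw a seeded sample of pairs
        if len(assets) >= 2:
            n_pairs = min(cfg.sample_m, len(assets) * (len(assets) - 1))
            for _ in range(n_pairs):
                i, j = rng.choice(len(assets), size=2, replace=False)
                key, dis = assets[i], assets[j]
                cands.append(
                    _Candidate(
                        key,
                        (dis,),
                        False,
                        candidate_difficulty(task_type, key, (dis,), False, noise),
                    )
                )
    else:  # WI / SI: seeded sample of key + 3 distinct distractors
        k = DISTRACTOR_COUNT[task_type]
        if len(assets) >= k + 1:
            for _ in range(cfg.sample_m):
                picks = rng.choice(len(assets), size=k + 1, replace=False)
                key = assets[picks[0]]
                dis = tuple(assets[i] for i in picks[1:])
                cands.append(
                    _Candidate(
                        key, dis, False, candidate_difficulty(task_type, key, dis, False, noise)
                    )
                )
    return cands


def select_task(
    pool: AssetPool,
    task_type: str,
    target: float,
    history,
    cfg: TutorConfig | None = None,
    seed: int | None = None,
) -> TaskSpec:
    """Pick the candidate whose difficulty is nearest the target.

    Keys used within the last ``recent_k`` tasks are excluded; exact
    difficulty ties go to the smaller key id.  Background noise is switched
    on when the target exceeds the noise threshold.
    """
    cfg = cfg or TutorConfig()
    rng = np.random.default_rng(seed)
    noise = target > cfg.noise_threshold
    recent = list(_results(history))[-cfg.recent_k:]
    excluded = frozenset(r.key_id for r in recent if getattr(r, "key_id", None))
    cands = _enumerate_candidates(pool, task_type, noise, excluded, cfg, rng)
    if not cands:
        raise EmptyPoolError(f"no eligible candidate for task type {task_type}")
    best = min(cands, key=lambda c: (abs(c.difficulty - target), c.key.id))
    build_seed = int(rng.integers(2**31))
    if task_type == "SP":
        silence = bool(rng.random() < 0.5)
        return build_task(task_type, best.key, seed=build_seed, noise=noise, silence=silence)
    if task_type == "SC":
        key_tags = sorted(best.key.categories)
        other_tags = sorted(
            {t for a in pool.by_type["sound"] for t in a.categories} - best.key.categories
        )
        if other_tags and (not key_tags or rng.random() < 0.5):
            category = str(rng.choice(other_tags))
        else:
            category = str(rng.choice(key_tags))
        return build_task(task_type, best.key, seed=build_seed, noise=noise, category=category)
    return build_task(
        task_type,
        best.key,
        best.distractors,
        same_trial=best.same_trial,
        noise=noise,
        seed=build_seed,
    )


def recommend(
    net: CompetencyNetwork,
    pool: AssetPool,
    history,
    cfg: TutorConfig | None = None,
    seed: int | None = None,
    marginals: Mapping[str, BeliefVector] | None = None,
) -> TaskSpec:
    """Full three-step recommendation: type → target difficulty → task."""
    cfg = cfg or TutorConfig()
    if marginals is None:
        marginals = infer_marginals(net)
    task_type = select_task_type(net, history, cfg, marginals=marginals)
    target = target_difficulty(net, task_type, marginals=marginals)
    return select_task(pool, task_type, target, history, cfg, seed=seed)


# -- cold start ------------------------------------------------------------

def initial_chapter_types(seed: int | None = None) -> list[str]:
    """Task-type mix of the 10-task introductory chapter.

    All seven types appear once; three extras are drawn seeded; the order is
    a seeded shuffle.
    """
    rng = np.random.default_rng(seed)
    types = list(TASK_TYPES) + [str(t) for t in rng.choice(TASK_TYPES, size=3, replace=False)]
    rng.shuffle(types)
    return types


def run_initial_analysis(
    results: Sequence, profiles: Sequence[CompetenceProfile]
) -> CompetenceProfile:
    """Map the 10-task introductory-chapter accuracy to the nearest profile.

    The learner's accuracy is matched against each profile's mean implied
    competence scalar; exact ties go to the lower-indexed profile.
    """
    results = list(_results(results))
    if len(results) != 10:
        raise ContractError(f"initial analysis needs exactly 10 results, got {len(results)}")
    if len(profiles) != 7:
        raise ContractError(f"initial analysis needs exactly 7 profiles, got {len(profiles)}")
    accuracy = sum(1 for r in results if r.correct) / len(results)
    return min(profiles, key=lambda p: (abs(p.mean_scalar() - accuracy),))
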