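"""Synthetic cochlear-implant-recipient agents and closed-loop simulation.

Agents answer single-choice tasks through a guessing-floored logistic
response curve (a 3-parameter IRT-style model): with ability θ for the
task's observable, difficulty d, discrimination a, slip s and guessing floor
g = 1/#options,

    P(correct) = g + (1 − g − s) · logistic(a · (θ − d)).

Abilities are static within a session — the study period is short and the
training effect unquantified — so any drift in the *estimated* competence
reflects the tutoring loop, not the agent.  Sessions close the loop:
recommend a task, sample correctness, update the answered observable's
evidence, infer, repeat, logging a competence snapshot after every task.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import ContractError, NodeLookupError
from .network import (
    DEFAULT_DELTA0,
    TYPE_OBSERVABLE,
    CompetenceProfile,
    CompetencyNetwork,
    apply_profile,
    default_profiles,
    infer_marginals,
    update_observable,
)
from .task_bank import AssetPool, TaskSpec
from .tutor import (
    TutorConfig,
    initial_chapter_types,
    recommend,
    run_initial_analysis,
    select_task,
)


@dataclass(frozen=True)
class LearnerAgent:
    """Synthetic recipient with one latent ability per observable variable."""

    pseudonym: str
    theta: Mapping[str, float]
    slip: float = 0.05
    discrimination: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for node, v in self.theta.items():
            if not (0.0 <= v <= 1.0):
                raise ContractError(f"ability for {node!r} outside [0, 1]: {v}")
        if not (0.0 <= self.slip <= 0.3):
            raise ContractError(f"slip {self.slip!r} outside [0, 0.3]")
        if self.discrimination <= 0:
            raise ContractError("discrimination must be positive")

    def mean_theta(self) -> float:
        return float(np.mean(list(self.theta.values())))


@dataclass(frozen=True)
class TaskResult:
    """One answered task, as recorded in the event log."""

    pseudonym: str
    index: int
    task_type: str
    difficulty: float
    correct: bool
    key_id: str | None = None
    snapshot: Mapping[str, float] | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.snapshot is not None:
            d["snapshot"] = dict(self.snapshot)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskResult":
        return cls(
            pseudonym=d["pseudonym"],
            index=int(d["index"]),
            task_type=d["task_type"],
            difficulty=float(d["difficulty"]),
            correct=bool(d["correct"]),
            key_id=d.get("key_id"),
            snapshot=d.get("snapshot"),
        )


def p_correct(agent: LearnerAgent, task: TaskSpec) -> float:
    """Probability the agent answers the task correctly."""
    node = TYPE_OBSERVABLE[task.task_type]
    if node not in agent.theta:
        raise NodeLookupError(f"agent {agent.pseudonym!r} lacks ability for {node!r}")
    g = 1.0 / len(task.options)
    theta = agent.theta[node]
    return float(
        g + (1 - g - agent.slip) * expit(agent.discrimination * (theta - task.difficulty))
    )


def _snapshot(marginals) -> dict[str, float]:
    return {name: b.scalar() for name, b in marginals.items()}


def run_cold_start(
    agent: LearnerAgent,
    pool: AssetPool,
    cfg: TutorConfig,
    rng: np.random.Generator,
    profiles: Sequence[CompetenceProfile] | None = None,
) -> CompetenceProfile:
    """Play the 10-task introductory chapter and pick the nearest profile.

    All tasks are drawn at mid difficulty (0.5) with an empty history, one
    per type plus three seeded extras.
    """
    profiles = list(profiles) if profiles is not None else default_profiles()
    types = initial_chapter_types(int(rng.integers(2**31)))
    results = []
    for i, t in enumerate(types):
        task = select_task(pool, t, 0.5, [], cfg, seed=int(rng.integers(2**31)))
        correct = bool(rng.random() < p_correct(agent, task))
        results.append(
            TaskResult(agent.pseudonym, i, t, task.difficulty, correct, task.key_id)
        )
    return run_initial_analysis(results, profiles)


def simulate_session(
    agent: LearnerAgent,
    net: CompetencyNetwork,
    pool: AssetPool,
    cfg: TutorConfig | None = None,
    n_tasks: int = 100,
    seed: int | None = None,
    delta0: float = DEFAULT_DELTA0,
    cold_start: bool = False,
    profiles: Sequence[CompetenceProfile] | None = None,
) -> tuple[list[TaskResult], CompetencyNetwork]:
    """Closed training loop: recommend → answer → update → infer → log.

    With ``cold_start`` the 10-task introductory chapter is played first and
    only sets the starting profile; the returned log holds exactly
    ``n_tasks`` records, each with a post-update competence snapshot.
    """
    if n_tasks < 1:
        raise ContractError("n_tasks must be >= 1")
    cfg = cfg or TutorConfig()
    rng = np.random.default_rng(seed)
    if cold_start:
        profile = run_cold_start(agent, pool, cfg, rng, profiles)
        net = apply_profile(net, profile)
    log: list[TaskResult] = []
    marginals = infer_marginals(net)
    for i in range(n_tasks):
        task = recommend(net, pool, log, cfg, seed=int(rng.integers(2**31)),
                         marginals=marginals)
        correct = bool(rng.random() < p_correct(agent, task))
        net = update_observable(
            net, TYPE_OBSERVABLE[task.task_type], correct, task.difficulty, delta0
        )
        marginals = infer_marginals(net)
        log.append(
            TaskResult(
                pseudonym=agent.pseudonym,
                index=i,
                task_type=task.task_type,
                difficulty=task.difficulty,
                correct=correct,
                key_id=task.key_id,
                snapshot=_snapshot(marginals),
            )
        )
    return log, net


# -- cohorts ---------------------------------------------------------------

DEFAULT_ABILITY_SPEC = {"kind": "uniform", "low": 0.1, "high": 0.9}


def draw_agents(
    n_agents: int,
    ability_spec: Mapping | None,
    master_seed: int,
    observables: Sequence[str] = tuple(TYPE_OBSERVABLE.values()),
    slip: float = 0.05,
    discrimination: float = 8.0,
) -> list[LearnerAgent]:
    """Draw agents with per-observable abilities from the spec.

    ``{"kind": "uniform", "low": .., "high": ..}`` draws each observable's
    ability independently; ``{"kind": "constant", "value": ..}`` fixes all.
    Per-agent seeds are spawned from the master seed (SeedSequence).
    """
    spec = dict(ability_spec) if ability_spec else dict(DEFAULT_ABILITY_SPEC)
    kind = spec.get("kind")
    if kind not in ("uniform", "constant"):
        raise ContractError(f"unknown ability spec kind {kind!r}")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_agents)
    agents = []
    for i, child in enumerate(children):
        agent_seed = int(child.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(agent_seed)
        if kind == "uniform":
            low, high = float(spec.get("low", 0.1)), float(spec.get("high", 0.9))
            if not (0 <= low <= high <= 1):
                raise ContractError(f"bad uniform ability bounds ({low}, {high})")
            theta = {obs: float(rng.uniform(low, high)) for obs in observables}
        else:
            v = float(spec.get("value", 0.5))
            if not (0 <= v <= 1):
                raise ContractError(f"constant ability {v} outside [0, 1]")
            theta = {obs: v for obs in observables}
        agents.append(
            LearnerAgent(
                pseudonym=f"agent-{i:03d}",
                theta=theta,
                slip=slip,
                discrimination=discrimination,
                rng_seed=agent_seed,
            )
        )
    return agents


@dataclass
class CohortResult:
    """Logs plus the agents and final networks behind them."""

    logs: list[list[TaskResult]]
    agents: list[LearnerAgent]
    networks: list[CompetencyNetwork] = field(default_factory=list)


def simulate_cohort(
    n_agents: int,
    ability_spec: Mapping | None = None,
    n_tasks: int = 100,
    master_seed: int = 0,
    pool: AssetPool | None = None,
    net: CompetencyNetwork | None = None,
    cfg: TutorConfig | None = None,
    delta0: float = DEFAULT_DELTA0,
    cold_start: bool = True,
) -> CohortResult:
    """Simulate independent sessions for a cohort of synthetic recipients."""
    if n_agents < 1:
        raise ContractError("n_agents must be >= 1")
    from .network import build_default_network
    from .task_bank import generate_fixture_pool

    if pool is None:
        pool = generate_fixture_pool(1053, seed=master_seed % 2**31)
    base_net = net if net is not None else build_default_network()
    agents = draw_agents(n_agents, ability_spec, master_seed)
    logs, nets = [], []
    for agent in agents:
        log, final = simulate_session(
            agent,
            base_net,
            pool,
            cfg,
            n_tasks=n_tasks,
            seed=agent.rng_seed,
            delta0=delta0,
            cold_start=cold_start,
        )
        logs.append(log)
        nets.append(final)
    return CohortResult(logs=logs, agents=agents, networks=nets)
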