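"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` describes one reproducible experiment: where the asset
pool comes from (a manifest on disk or a generated fixture), the tutor
parameters, the simulated cohort, the evaluation options, and a master seed.
``run_pipeline`` executes fixtures → simulation → evaluation and writes every
artifact (pool CSV, per-agent state JSON, event logs JSONL, report JSON) plus
a run manifest under the output directory.
"""
from __future__ import annotations

import json
import pathlib
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigValidationError
from . import evaluation
from .network import build_default_network, save_state
from .simulator import simulate_cohort
from .task_bank import generate_fixture_pool, load_pool, write_pool
from .tutor import TutorConfig


class FixtureSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = Field(default=1053, ge=50)


class TutorSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    w_rep: float = Field(default=0.5, ge=0)
    w_weak: float = Field(default=0.3, ge=0)
    w_streak: float = Field(default=0.2, ge=0)
    streak_cap: int = Field(default=5, ge=1)
    recent_k: int = Field(default=10, ge=0)
    sample_m: int = Field(default=500, ge=1)
    noise_threshold: float = Field(default=0.7, ge=0, le=1)
    window: int = Field(default=30, ge=1)

    def to_tutor_config(self) -> TutorConfig:
        return TutorConfig(**self.model_dump())


class AbilitySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "uniform"
    low: float = Field(default=0.1, ge=0, le=1)
    high: float = Field(default=0.9, ge=0, le=1)
    value: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self):
        if self.kind not in ("uniform", "constant"):
            raise ValueError(f"unknown ability kind {self.kind!r}")
        if self.kind == "uniform" and self.low > self.high:
            raise ValueError("ability low must be <= high")
        return self


class SimulationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_agents: int = Field(default=23, ge=1)
    n_tasks: int = Field(default=100, ge=1)
    delta0: float = Field(default=0.08, gt=0, le=0.2)
    cold_start: bool = True
    ability: AbilitySpec = AbilitySpec()


class EvaluationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_tasks: int = Field(default=250, ge=1)
    node: str = "hearing"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    smoothing_window: int = Field(default=5, ge=1)


class RunConfig(BaseModel):
    """Fully validated configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int
    outdir: str = "runs/demo"
    pool: str | None = None  # manifest path; None -> generate a fixture pool
    network: str | None = None  # network config path; None -> default topology
    fixture: FixtureSpec = FixtureSpec()
    tutor: TutorSettings = TutorSettings()
    simulation: SimulationSpec = SimulationSpec()
    evaluation: EvaluationSpec = EvaluationSpec()

    @model_validator(mode="after")
    def _paths_resolve(self):
        for label, path in (("pool", self.pool), ("network", self.network)):
            if path is not None and not pathlib.Path(path).exists():
                raise ValueError(f"{label} path {path!r} does not exist")
        return self


def validate_config(source: str | Mapping[str, Any], strict: bool = True) -> RunConfig:
    """Parse and validate a YAML/JSON config text, mapping, or file path.

    In strict mode unknown keys are errors; in lax mode they are dropped with
    a flagged warning.  The error message lists every violation.
    """
    if isinstance(source, Mapping):
        data: Any = dict(source)
    else:
        text = source
        p = pathlib.Path(str(source))
        if len(str(source)) < 4096 and p.suffix in (".yaml", ".yml", ".json") and p.exists():
            text = p.read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigValidationError(f"config is not valid YAML/JSON: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigValidationError("config must be a mapping of options")
    if not strict:
        import warnings

        known = set(RunConfig.model_fields)
        extras = [k for k in data if k not in known]
        if extras:
            warnings.warn(f"ignoring unknown config keys (lax mode): {extras}")
        data = {k: v for k, v in data.items() if k in known}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(x) for x in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigValidationError(
            "invalid run configuration:\n" + "\n".join(lines)
        ) from exc


def effective_config(cfg: RunConfig) -> dict:
    """The fully-defaulted configuration as a plain mapping (re-validatable)."""
    return cfg.model_dump()


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute fixtures → simulation → evaluation; return artifact paths.

    Every stage failure is re-raised annotated with the stage name.
    """
    outdir = pathlib.Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "fixtures"
    try:
        if cfg.pool is not None:
            pool = load_pool(cfg.pool)
        else:
            pool = generate_fixture_pool(cfg.fixture.n, seed=cfg.seed)
        pool_path = outdir / "pool.csv"
        write_pool(pool, pool_path)
        artifacts["pool"] = str(pool_path)

        if cfg.network is not None:
            net_cfg = yaml.safe_load(pathlib.Path(cfg.network).read_text())
            net = build_default_network(net_cfg)
        else:
            net = build_default_network()

        stage = "simulation"
        sim = cfg.simulation
        cohort = simulate_cohort(
            n_agents=sim.n_agents,
            ability_spec=sim.ability.model_dump(),
            n_tasks=sim.n_tasks,
            master_seed=cfg.seed,
            pool=pool,
            net=net,
            cfg=cfg.tutor.to_tutor_config(),
            delta0=sim.delta0,
            cold_start=sim.cold_start,
        )
        logdir = outdir / "logs"
        logdir.mkdir(exist_ok=True)
        statedir = outdir / "states"
        statedir.mkdir(exist_ok=True)
        for agent, log, final_net in zip(cohort.agents, cohort.logs, cohort.networks):
            evaluation.write_log(log, logdir / f"{agent.pseudonym}.jsonl")
            (statedir / f"{agent.pseudonym}.json").write_text(save_state(final_net))
        artifacts["logs"] = str(logdir)
        artifacts["states"] = str(statedir)

        stage = "evaluation"
        report = build_report(
            cohort.logs,
            max_tasks=cfg.evaluation.max_tasks,
            node=cfg.evaluation.node,
            alpha=cfg.evaluation.alpha,
        )
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        artifacts["report"] = str(report_path)

        manifest = {
            "seed": cfg.seed,
            "effective_config": effective_config(cfg),
            "artifacts": artifacts,
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        artifacts["manifest"] = str(manifest_path)
        return artifacts
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc


def build_report(
    logs,
    max_tasks: int = 250,
    node: str = "hearing",
    alpha: float = 0.05,
) -> dict:
    """Assemble the evaluation report: descriptives, tests, letters, gradients."""
    from .network import TASK_TYPES

    summary = evaluation.descriptive_stats(logs, max_tasks=max_tasks)
    counts = evaluation.task_type_counts(logs, max_tasks=max_tasks)
    stat, df, p = evaluation.chi_square_gof([counts[t] for t in TASK_TYPES])

    # per-learner task-type proportions -> 7 groups for the rank tests
    proportions: dict[str, list[float]] = {t: [] for t in TASK_TYPES}
    error_rates: dict[str, list[float]] = {t: [] for t in TASK_TYPES}
    for log in logs:
        log = log[:max_tasks]
        if not log:
            continue
        n = len(log)
        for t in TASK_TYPES:
            of_type = [r for r in log if r.task_type == t]
            proportions[t].append(len(of_type) / n)
            if of_type:
                error_rates[t].append(
                    sum(1 for r in of_type if not r.correct) / len(of_type)
                )
    report: dict = {
        "summary": summary.to_dict(),
        "task_type_counts": counts,
        "chi_square_gof": {"statistic": stat, "df": df, "p": p},
    }
    try:
        groups = [proportions[t] for t in TASK_TYPES]
        h, kw_p = evaluation.kruskal_wallis(groups)
        pairwise = evaluation.dunn_holm(groups, alpha=alpha)
        letters = evaluation.compact_letters(pairwise, len(TASK_TYPES), alpha=alpha)
        report["type_proportions"] = {
            "kruskal_wallis": {"H": h, "p": kw_p},
            "letters": dict(zip(TASK_TYPES, letters)),
        }
    except evaluation.DegenerateDataError:
        report["type_proportions"] = None
    try:
        groups = [error_rates[t] for t in TASK_TYPES]
        h, kw_p = evaluation.kruskal_wallis(groups)
        pairwise = evaluation.dunn_holm(groups, alpha=alpha)
        letters = evaluation.compact_letters(pairwise, len(TASK_TYPES), alpha=alpha)
        report["error_proportions"] = {
            "kruskal_wallis": {"H": h, "p": kw_p},
            "letters": dict(zip(TASK_TYPES, letters)),
        }
    except (evaluation.DegenerateDataError, evaluation.ContractError):
        report["error_proportions"] = None

    series = evaluation.trajectories(logs, node=node, max_tasks=max_tasks)
    gradients = []
    for s in series:
        try:
            early, late = evaluation.convergence_gradient(s)
        except evaluation.ContractError:
            continue
        gradients.append(
            {"pseudonym": s.pseudonym, "early_slope": early, "late_slope": late}
        )
    if gradients:
        frac = sum(1 for g in gradients if g["early_slope"] > g["late_slope"]) / len(
            gradients
        )
    else:
        frac = None
    report["trajectories"] = {
        "node": node,
        "gradients": gradients,
        "fraction_early_faster": frac,
    }
    return report
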