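"""Statistical evaluation of training event logs.

Mirrors the study pipeline on JSONL event logs: descriptive statistics of
task counts and correctness, a chi-square goodness-of-fit test of the
recommended task-type distribution against uniformity, Kruskal-Wallis with
Dunn post-hoc tests (Holm-adjusted) summarized as a compact letter display,
and a competence-trajectory convergence analysis.  The trajectory analysis
uses centered moving-average smoothing with early/late-quartile gradient
comparison — a dependency-light, testable substitute for the purely
descriptive spline smoother; it captures the same qualitative question,
whether competencies move faster early in training than late.

Per the study's truncation rule, analyses consider at most the first 250
tasks of each learner (``max_tasks``).
"""
from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, DegenerateDataError, LogParseError
from .network import TASK_TYPES
from .simulator import TaskResult

DEFAULT_MAX_TASKS = 250


def _truncate(logs: Sequence[Sequence[TaskResult]], max_tasks: int | None):
    if max_tasks is None:
        return [list(log) for log in logs]
    return [list(log)[:max_tasks] for log in logs]


# -- descriptive statistics ------------------------------------------------

@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level descriptive statistics of task results."""

    n_learners: int
    total_tasks: int
    total_correct: int
    total_incorrect: int
    per_learner_tasks: Mapping[str, int]
    per_learner_correct: Mapping[str, int]
    per_learner_incorrect: Mapping[str, int]
    mean_tasks: float
    median_tasks: float
    sd_tasks: float
    mean_correct: float
    median_correct: float
    mean_incorrect: float
    median_incorrect: float
    pooled_error_rate: float
    mean_error_rate: float

    def to_dict(self) -> dict:
        return {
            "n_learners": self.n_learners,
            "total_tasks": self.total_tasks,
            "total_correct": self.total_correct,
            "total_incorrect": self.total_incorrect,
            "mean_tasks": self.mean_tasks,
            "median_tasks": self.median_tasks,
            "sd_tasks": self.sd_tasks,
            "mean_correct": self.mean_correct,
            "median_correct": self.median_correct,
            "mean_incorrect": self.mean_incorrect,
            "median_incorrect": self.median_incorrect,
            "pooled_error_rate": self.pooled_error_rate,
            "mean_error_rate": self.mean_error_rate,
        }


def descriptive_stats(
    logs: Sequence[Sequence[TaskResult]], max_tasks: int | None = DEFAULT_MAX_TASKS
) -> CohortSummary:
    """Counts, means, medians and SDs of per-learner task results.

    The error proportion is reported both pooled (total incorrect over total
    tasks) and as the mean of per-learner proportions; the two differ
    whenever learners complete different numbers of tasks.
    """
    logs = _truncate(logs, max_tasks)
    if not logs or all(len(log) == 0 for log in logs):
        raise ContractError("descriptive_stats needs at least one non-empty log")
    tasks, correct, incorrect, rates = {}, {}, {}, []
    for log in logs:
        if not log:
            continue
        p = log[0].pseudonym
        n = len(log)
        c = sum(1 for r in log if r.correct)
        tasks[p] = tasks.get(p, 0) + n
        correct[p] = correct.get(p, 0) + c
        incorrect[p] = incorrect.get(p, 0) + (n - c)
    for p in tasks:
        rates.append(incorrect[p] / tasks[p])
    n_arr = np.array(list(tasks.values()), dtype=float)
    c_arr = np.array(list(correct.values()), dtype=float)
    i_arr = np.array(list(incorrect.values()), dtype=float)
    return CohortSummary(
        n_learners=len(tasks),
        total_tasks=int(n_arr.sum()),
        total_correct=int(c_arr.sum()),
        total_incorrect=int(i_arr.sum()),
        per_learner_tasks=dict(tasks),
        per_learner_correct=dict(correct),
        per_learner_incorrect=dict(incorrect),
        mean_tasks=float(n_arr.mean()),
        median_tasks=float(np.median(n_arr)),
        sd_tasks=float(n_arr.std(ddof=1)) if len(n_arr) > 1 else 0.0,
        mean_correct=float(c_arr.mean()),
        median_correct=float(np.median(c_arr)),
        mean_incorrect=float(i_arr.mean()),
        median_incorrect=float(np.median(i_arr)),
        pooled_error_rate=float(i_arr.sum() / n_arr.sum()),
        mean_error_rate=float(np.mean(rates)),
    )


# -- task-type distribution ------------------------------------------------

def task_type_counts(
    logs: Sequence[Sequence[TaskResult]], max_tasks: int | None = DEFAULT_MAX_TASKS
) -> dict[str, int]:
    """Pooled count of recommended tasks per task type."""
    counts = {t: 0 for t in TASK_TYPES}
    for log in _truncate(logs, max_tasks):
        for r in log:
            counts[r.task_type] += 1
    return counts


def chi_square_gof(
    observed: Sequence[float], expected: Sequence[float] | None = None
) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit: Σ(O−E)²/E with df = cells − 1.

    ``expected=None`` tests against the uniform distribution.
    """
    obs = np.asarray(observed, dtype=float)
    if expected is None:
        exp = np.full(len(obs), obs.sum() / len(obs))
    else:
        exp = np.asarray(expected, dtype=float)
    if (exp <= 0).any():
        raise ContractError("chi-square expected counts must all be positive")
    if len(obs) != len(exp):
        raise ContractError("observed and expected must have the same length")
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


# -- rank-based group comparisons ------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its p-value."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ContractError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all pooled values identical; tie correction undefined")
    h, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(h), float(p)


def dunn_holm(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> dict[tuple[int, int], float]:
    """Dunn pairwise z-tests on mean ranks with Holm step-down adjustment.

    Returns Holm-adjusted two-sided p-values for every pair (i, j), i < j.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ContractError("dunn_holm needs >= 2 non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all pooled values identical")
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for arr in arrays:
        mean_ranks.append(ranks[start : start + len(arr)].mean())
        sizes.append(len(arr))
        start += len(arr)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs, raw = [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            pairs.append((i, j))
            raw.append(2 * stats.norm.sf(abs(z)))
    _, adjusted, _, _ = multipletests(raw, alpha=alpha, method="holm")
    return {pair: float(p) for pair, p in zip(pairs, adjusted)}


def compact_letters(
    pairwise_p: Mapping[tuple[int, int], float], n_groups: int, alpha: float = 0.05
) -> list[str]:
    """Compact letter display: groups sharing a letter do not differ.

    Insertion algorithm: start with one letter covering every group; each
    significant pair splits the letters that still join it; redundant
    (subset) letters are absorbed.
    """
    letters: list[set[int]] = [set(range(n_groups))]
    for (i, j), p in sorted(pairwise_p.items()):
        if p >= alpha:
            continue
        new: list[set[int]] = []
        for s in letters:
            if i in s and j in s:
                new.append(s - {j})
                new.append(s - {i})
            else:
                new.append(s)
        # drop empty, duplicate, and subset letters
        uniq: list[set[int]] = []
        for s in new:
            if s and s not in uniq:
                uniq.append(s)
        letters = [s for s in uniq if not any(s < t for t in uniq)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned = [""] * n_groups
    for idx, s in enumerate(letters):
        for g in sorted(s):
            assigned[g] += alphabet[idx]
    return assigned


# -- trajectories ----------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySeries:
    """Per-learner competence scalars of one node over task indices."""

    pseudonym: str
    node: str
    indices: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ContractError("trajectory indices must be strictly increasing")
        if any(not (0 <= v <= 1) for v in self.values):
            raise ContractError("trajectory values must lie in [0, 1]")


def trajectories(
    logs: Sequence[Sequence[TaskResult]],
    node: str = "hearing",
    max_tasks: int | None = DEFAULT_MAX_TASKS,
) -> list[TrajectorySeries]:
    """Extract each learner's estimated-competence series for one node."""
    out = []
    for log in _truncate(logs, max_tasks):
        pts = [(r.index, r.snapshot[node]) for r in log if r.snapshot and node in r.snapshot]
        if pts:
            out.append(
                TrajectorySeries(
                    pseudonym=log[0].pseudonym,
                    node=node,
                    indices=tuple(i for i, _ in pts),
                    values=tuple(v for _, v in pts),
                )
            )
    return out


def smooth(series: TrajectorySeries, window: int = 5) -> TrajectorySeries:
    """Centered moving average with shrinking edge windows."""
    if window < 1:
        raise ContractError("smoothing window must be >= 1")
    vals = np.asarray(series.values, dtype=float)
    half = window // 2
    smoothed = [
        float(vals[max(0, i - half) : i + half + 1].mean()) for i in range(len(vals))
    ]
    return TrajectorySeries(series.pseudonym, series.node, series.indices, tuple(smoothed))


def convergence_gradient(series: TrajectorySeries) -> tuple[float, float]:
    """Mean |Δ| over the first vs the last quartile of the series.

    A larger early slope means the model updated the competence faster at
    the start of training than at the end.
    """
    vals = np.asarray(series.values, dtype=float)
    if len(vals) < 8:
        raise ContractError("gradient comparison needs a series of length >= 8")
    diffs = np.abs(np.diff(vals))
    q = len(diffs) // 4
    q = max(q, 1)
    return float(diffs[:q].mean()), float(diffs[-q:].mean())


# -- event-log I/O ---------------------------------------------------------

def write_log(results: Sequence[TaskResult], path) -> None:
    """Write one TaskResult per line (JSONL, sorted keys for determinism)."""
    with open(path, "w") as fh:
        for r in results:
            fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")


def read_log(path) -> list[TaskResult]:
    """Read a JSONL event log; malformed lines are reported with line numbers."""
    results = []
    text = pathlib.Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            results.append(TaskResult.from_dict(json.loads(line)))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise LogParseError(f"{path}: line {lineno}: {exc}") from exc
    if not results:
        warnings.warn(f"event log {path} is empty")
    return results


def group_by_learner(results: Sequence[TaskResult]) -> list[list[TaskResult]]:
    """Split a mixed log into per-learner logs (insertion order preserved)."""
    grouped: dict[str, list[TaskResult]] = {}
    for r in results:
        grouped.setdefault(r.pseudonym, []).append(r)
    return list(grouped.values())
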