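"""Bayesian-network learner model for auditory competencies.

The learner model is a small discrete Bayesian network whose nodes all share
the three states low/medium/high.  Seven *observable variables* — one per
single-choice task type — feed four latent subcompetencies (nonlexical,
phoneme, word, and sentence understanding), which in turn feed the overall
competence ``hearing``.  Task results never set a node to a hard state;
instead each node carries a *virtual evidence* vector that is multiplied into
the joint distribution, and a correct/incorrect answer nudges the evidence of
the answered observable toward high/low.  Exact inference then propagates the
nudge to the related competencies.

Conditional probability tables are "evenly distributed": a child's CPT row
depends only on the *mean* numeric value of its parent states, interpolated
between the one-hot state distributions and smoothed by ``epsilon``.  The CPT
is therefore invariant under any permutation of the parents — phoneme
understanding depends on vowel differentiation exactly as it depends on
consonant differentiation.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .beliefs import (
    EVIDENCE_FLOOR,
    STATE_INDEX,
    STATE_VALUES,
    BeliefVector,
    normalize_floored,
)
from .errors import (
    ContractError,
    DegenerateEvidenceError,
    NetworkValidationError,
    NodeLookupError,
    StateParseError,
)

LAYERS = ("observable", "subcompetency", "root")

#: Canonical task-type order (also the tie-break order of the tutor).
TASK_TYPES = ("SP", "SC", "CD", "VD", "WD", "WI", "SI")

#: Observable node behind each task type.
TYPE_OBSERVABLE = {
    "SP": "sound_perception",
    "SC": "sound_categorization",
    "CD": "consonant_differentiation",
    "VD": "vowel_differentiation",
    "WD": "word_differentiation",
    "WI": "word_identification",
    "SI": "sentence_identification",
}
OBSERVABLE_TYPE = {v: k for k, v in TYPE_OBSERVABLE.items()}

DEFAULT_EPSILON = 0.05
DEFAULT_DELTA0 = 0.08


@dataclass(frozen=True)
class CompetencyNode:
    """One node of the learner model."""

    name: str
    layer: str
    parents: tuple[str, ...] = ()
    task_type: str | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise NetworkValidationError(
                f"node {self.name!r}: unknown layer {self.layer!r} (expected one of {LAYERS})"
            )
        if self.layer == "observable" and self.task_type is None:
            raise NetworkValidationError(f"observable node {self.name!r} lacks a task_type")
        if self.layer != "observable" and self.task_type is not None:
            raise NetworkValidationError(
                f"non-observable node {self.name!r} must not carry a task_type"
            )


def cpt_row(parent_states: Sequence[str | int], epsilon: float = DEFAULT_EPSILON) -> BeliefVector:
    """CPT row for a child given its parents' states.

    With numeric parent values v_i in {0, 0.5, 1} and m = mean(v_i), the base
    row interpolates linearly between one-hot low and one-hot medium for
    m <= 0.5, and between one-hot medium and one-hot high for m >= 0.5; the
    result is then smoothed: row = (1 - 3·epsilon)·base + epsilon.
    """
    if len(parent_states) == 0:
        raise ContractError("cpt_row needs at least one parent state; roots have no CPT rows")
    if not (0 <= epsilon < 1 / 3):
        raise ContractError(f"epsilon {epsilon!r} outside [0, 1/3)")
    idx = []
    for s in parent_states:
        if isinstance(s, str):
            if s not in STATE_INDEX:
                raise ContractError(f"unknown state {s!r}")
            idx.append(STATE_INDEX[s])
        else:
            if s not in (0, 1, 2):
                raise ContractError(f"state index {s!r} outside 0..2")
            idx.append(int(s))
    m = float(np.mean(STATE_VALUES[idx]))
    if m <= 0.5:
        base = np.array([1 - 2 * m, 2 * m, 0.0])
    else:
        base = np.array([0.0, 2 - 2 * m, 2 * m - 1])
    row = (1 - 3 * epsilon) * base + epsilon
    return BeliefVector.from_array(row)


def _build_cpt(n_parents: int, epsilon: float) -> np.ndarray:
    """Dense CPT, axes = parents (in order) then child, each of length 3."""
    cpt = np.empty((3,) * (n_parents + 1))
    for combo in itertools.product(range(3), repeat=n_parents):
        cpt[combo] = cpt_row(list(combo), epsilon).as_array()
    return cpt


class CompetencyNetwork:
    """DAG of competency nodes with CPTs and per-node virtual evidence.

    Roots have a uniform prior; every node's evidence vector (default
    uniform, i.e. uninformative) multiplies into the joint.
    """

    def __init__(
        self,
        nodes: Sequence[CompetencyNode],
        epsilon: float = DEFAULT_EPSILON,
        evidence: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        if not (0 <= epsilon < 1 / 3):
            raise NetworkValidationError(f"epsilon {epsilon!r} outside [0, 1/3)")
        self.epsilon = float(epsilon)
        self.nodes: dict[str, CompetencyNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise NetworkValidationError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node in self.nodes.values():
            for p in node.parents:
                if p not in self.nodes:
                    raise NetworkValidationError(
                        f"node {node.name!r} references unknown parent {p!r}"
                    )
                g.add_edge(p, node.name)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            arcs = " -> ".join(a for a, _ in cycle) + " -> " + cycle[-1][1]
            raise NetworkValidationError(f"graph contains a cycle: {arcs}")
        self.graph = g
        # Stable topological order: ties broken by insertion order, for determinism.
        insertion = {n: i for i, n in enumerate(self.nodes)}
        self.order: list[str] = list(nx.lexicographical_topological_sort(g, key=insertion.get))
        self.cpts: dict[str, np.ndarray] = {
            name: _build_cpt(len(node.parents), self.epsilon)
            for name, node in self.nodes.items()
            if node.parents
        }
        self.evidence: dict[str, np.ndarray] = {}
        for name in self.nodes:
            if evidence is not None and name in evidence:
                vec = np.asarray(evidence[name], dtype=float)
                if vec.shape != (3,) or (vec < 0).any():
                    raise NetworkValidationError(f"bad evidence vector for {name!r}")
                self.evidence[name] = vec.copy()
            else:
                self.evidence[name] = np.full(3, 1 / 3)
        # contraction plan for inference, built lazily and shared by copies
        self._plan: dict | None = None

    # -- structure helpers -------------------------------------------------
    @property
    def observables(self) -> list[str]:
        return [n for n in self.nodes if self.nodes[n].layer == "observable"]

    def observable_for(self, task_type: str) -> str:
        for name, node in self.nodes.items():
            if node.task_type == task_type:
                return name
        raise NodeLookupError(f"no observable node for task type {task_type!r}")

    def copy(self) -> "CompetencyNetwork":
        clone = object.__new__(CompetencyNetwork)
        clone.epsilon = self.epsilon
        clone.nodes = self.nodes
        clone.graph = self.graph
        clone.order = self.order
        clone.cpts = self.cpts
        clone.evidence = {k: v.copy() for k, v in self.evidence.items()}
        clone._plan = self._plan
        return clone


def build_default_network(
    config: Mapping | None = None, epsilon: float = DEFAULT_EPSILON
) -> CompetencyNetwork:
    """Build the default learner model, or one described by ``config``.

    The default DAG has the seven observables, the four understanding
    subcompetencies, and the overall competence ``hearing`` as the single
    sink.  Sound perception additionally feeds sound categorization, which is
    why a good result on a perception task raises the categorization belief.
    """
    if config is not None:
        return _network_from_config(config)
    nodes = [
        CompetencyNode("sound_perception", "observable", (), "SP"),
        CompetencyNode("sound_categorization", "observable", ("sound_perception",), "SC"),
        CompetencyNode("consonant_differentiation", "observable", (), "CD"),
        CompetencyNode("vowel_differentiation", "observable", (), "VD"),
        CompetencyNode("word_differentiation", "observable", (), "WD"),
        CompetencyNode("word_identification", "observable", (), "WI"),
        CompetencyNode("sentence_identification", "observable", (), "SI"),
        CompetencyNode(
            "nonlexical_understanding",
            "subcompetency",
            ("sound_perception", "sound_categorization"),
        ),
        CompetencyNode(
            "phoneme_understanding",
            "subcompetency",
            ("consonant_differentiation", "vowel_differentiation"),
        ),
        CompetencyNode(
            "word_understanding",
            "subcompetency",
            ("word_differentiation", "word_identification"),
        ),
        CompetencyNode("sentence_understanding", "subcompetency", ("sentence_identification",)),
        CompetencyNode(
            "hearing",
            "root",
            (
                "nonlexical_understanding",
                "phoneme_understanding",
                "word_understanding",
                "sentence_understanding",
            ),
        ),
    ]
    return CompetencyNetwork(nodes, epsilon=epsilon)


def _network_from_config(config: Mapping) -> CompetencyNetwork:
    if "nodes" not in config:
        raise NetworkValidationError("network config lacks a 'nodes' list")
    nodes = []
    for entry in config["nodes"]:
        try:
            nodes.append(
                CompetencyNode(
                    name=entry["name"],
                    layer=entry["layer"],
                    parents=tuple(entry.get("parents", ())),
                    task_type=entry.get("task_type"),
                )
            )
        except KeyError as exc:
            raise NetworkValidationError(f"node entry {entry!r} lacks key {exc}") from exc
    return CompetencyNetwork(nodes, epsilon=float(config.get("epsilon", DEFAULT_EPSILON)))


# -- inference -------------------------------------------------------------

_EINSUM_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _einsum_plan(net: CompetencyNetwork) -> dict[str, tuple[str, list]]:
    """Per-node einsum expression and contraction path (structure-cached).

    The operand list interleaves evidence vectors and CPTs; the path is an
    elimination order found once per topology and reused, so each marginal is
    a variable-elimination contraction rather than a full-joint product.
    """
    axis = {n: i for i, n in enumerate(net.order)}
    subs = []
    shapes = []
    for name in net.order:
        node = net.nodes[name]
        subs.append(_EINSUM_LETTERS[axis[name]])
        shapes.append((3,))
        if node.parents:
            subs.append(
                "".join(_EINSUM_LETTERS[axis[p]] for p in node.parents)
                + _EINSUM_LETTERS[axis[name]]
            )
            shapes.append((3,) * (len(node.parents) + 1))
    plan = {}
    dummies = [np.empty(s) for s in shapes]
    for name in net.order:
        expr = ",".join(subs) + "->" + _EINSUM_LETTERS[axis[name]]
        path = np.einsum_path(expr, *dummies, optimize="greedy")[0]
        plan[name] = (expr, path)
    return plan


def infer_marginals(net: CompetencyNetwork) -> dict[str, BeliefVector]:
    """Exact posterior marginals of every node.

    Factorization: P(x) ∝ Π_node CPT(x_node | parents) · Π_node ev_node(x_node),
    with uniform priors at the roots.  Marginals are computed by exact tensor
    contraction (variable elimination along a cached greedy path); the
    network is small enough that this is exact to machine precision.
    """
    for name, ev in net.evidence.items():
        if not np.any(ev > 0):
            raise DegenerateEvidenceError(f"evidence vector of {name!r} is all zero")
    if net._plan is None:
        net._plan = _einsum_plan(net)
    operands = []
    for name in net.order:
        operands.append(net.evidence[name])
        if net.nodes[name].parents:
            operands.append(net.cpts[name])
    out: dict[str, BeliefVector] = {}
    for name in net.nodes:
        expr, path = net._plan[name]
        marg = np.einsum(expr, *operands, optimize=path)
        z = marg.sum()
        if z <= 0:
            raise DegenerateEvidenceError("joint distribution has zero mass")
        out[name] = BeliefVector.from_array(marg / z)
    return out


# -- evidence updates ------------------------------------------------------

def update_observable(
    net: CompetencyNetwork,
    observable: str,
    correct: bool,
    task_difficulty: float,
    delta0: float = DEFAULT_DELTA0,
) -> CompetencyNetwork:
    """Nudge an observable's evidence toward high (correct) or low (incorrect).

    The effective rate is difficulty-weighted: a correct answer on a hard task
    is stronger evidence of high competence (δ_eff = δ0·(0.5+d)), an incorrect
    answer on an easy task stronger evidence of low competence
    (δ_eff = δ0·(1.5−d)); δ_eff is clamped to [0, 0.2].  Only the named node's
    evidence changes; a new network is returned.
    """
    if observable not in net.nodes:
        raise NodeLookupError(f"unknown node {observable!r}")
    if net.nodes[observable].layer != "observable":
        raise NodeLookupError(f"node {observable!r} is not an observable variable")
    if not (0 < delta0 <= 0.2):
        raise ContractError(f"delta0 {delta0!r} outside (0, 0.2]")
    d = float(task_difficulty)
    if not (0 <= d <= 1):
        raise ContractError(f"task difficulty {d!r} outside [0, 1]")
    delta = delta0 * (0.5 + d) if correct else delta0 * (1.5 - d)
    delta = min(max(delta, 0.0), 0.2)
    target = np.array([0.0, 0.0, 1.0]) if correct else np.array([1.0, 0.0, 0.0])
    new = net.copy()
    mixed = (1 - delta) * net.evidence[observable] + delta * target
    new.evidence[observable] = normalize_floored(mixed, EVIDENCE_FLOOR)
    return new


def belief_to_difficulty(b: BeliefVector) -> float:
    """Normalized scalar competence: 0·p_low + 0.5·p_med + 1·p_high."""
    return b.scalar()


# -- stereotype profiles ---------------------------------------------------

@dataclass(frozen=True)
class CompetenceProfile:
    """Preconfigured evidence presets used for cold-start initialization."""

    name: str
    evidence_presets: Mapping[str, BeliefVector] = field(default_factory=dict)

    def mean_scalar(self) -> float:
        """Mean implied competence over the preset nodes (0.5 if empty)."""
        if not self.evidence_presets:
            return 0.5
        return float(np.mean([b.scalar() for b in self.evidence_presets.values()]))


def default_profiles() -> list[CompetenceProfile]:
    """The default ladder of 7 profiles, P1 (all low) … P7 (all high).

    Each grades every observable's evidence from (0.8, 0.15, 0.05) to
    (0.05, 0.15, 0.8) in equal steps of 0.125.
    """
    profiles = []
    for k in range(7):
        p_low = 0.8 - 0.125 * k
        p_high = 0.05 + 0.125 * k
        vec = BeliefVector(p_low, 1.0 - p_low - p_high, p_high)
        presets = {name: vec for name in TYPE_OBSERVABLE.values()}
        profiles.append(CompetenceProfile(f"P{k + 1}", presets))
    return profiles


def apply_profile(net: CompetencyNetwork, profile: CompetenceProfile) -> CompetencyNetwork:
    """Replace evidence of the profile's preset nodes; others untouched."""
    new = net.copy()
    for name, belief in profile.evidence_presets.items():
        if name not in net.nodes:
            raise NodeLookupError(f"profile {profile.name!r} references unknown node {name!r}")
        new.evidence[name] = belief.as_array()
    return new


# -- serialization ---------------------------------------------------------

def save_state(net: CompetencyNetwork) -> str:
    """Serialize topology, epsilon, and all evidence vectors to JSON text."""
    payload = {
        "epsilon": net.epsilon,
        "nodes": [
            {
                "name": n.name,
                "layer": n.layer,
                "parents": list(n.parents),
                "task_type": n.task_type,
                "evidence": [float(x) for x in net.evidence[n.name]],
            }
            for n in net.nodes.values()
        ],
    }
    return json.dumps(payload, indent=2)


def load_state(text: str) -> CompetencyNetwork:
    """Inverse of :func:`save_state`; round-trips evidence bit-comparably."""
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StateParseError(
            f"malformed network state at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(payload, dict) or "nodes" not in payload:
        raise StateParseError("network state lacks a 'nodes' list")
    nodes = []
    evidence = {}
    for entry in payload["nodes"]:
        try:
            nodes.append(
                CompetencyNode(
                    name=entry["name"],
                    layer=entry["layer"],
                    parents=tuple(entry["parents"]),
                    task_type=entry.get("task_type"),
                )
            )
            evidence[entry["name"]] = np.array(entry["evidence"], dtype=float)
        except KeyError as exc:
            raise StateParseError(f"node entry lacks key {exc}") from exc
    return CompetencyNetwork(nodes, epsilon=float(payload.get("epsilon", DEFAULT_EPSILON)),
                             evidence=evidence)
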