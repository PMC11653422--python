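"""Three-state belief distributions over competency levels.

Every competency node in the learner model — observable variables as well as
latent subcompetencies — carries a categorical distribution over the ordered
states ``low < medium < high``.  The numeric embedding low→0, medium→0.5,
high→1 turns a belief into a scalar competence estimate, which doubles as the
target task difficulty.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError

#: Ordered state labels.
STATES = ("low", "med", "high")
STATE_INDEX = {"low": 0, "med": 1, "high": 2}
#: Numeric embedding of the three states (order-preserving, unit range).
STATE_VALUES = np.array([0.0, 0.5, 1.0])
#: Floor applied to evidence components after every update; keeps states
#: from becoming absorbing.
EVIDENCE_FLOOR = 0.01

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class BeliefVector:
    """Probability distribution over the states (low, medium, high)."""

    p_low: float
    p_med: float
    p_high: float

    def __post_init__(self) -> None:
        arr = (self.p_low, self.p_med, self.p_high)
        for p in arr:
            if not (-_SUM_TOL <= p <= 1 + _SUM_TOL):
                raise ContractError(f"belief component {p!r} outside [0, 1]")
        if abs(sum(arr) - 1.0) > _SUM_TOL:
            raise ContractError(f"belief components {arr} do not sum to 1")

    @classmethod
    def from_array(cls, arr) -> "BeliefVector":
        a = np.asarray(arr, dtype=float)
        if a.shape != (3,):
            raise ContractError(f"belief vector needs 3 components, got shape {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))

    @classmethod
    def uniform(cls) -> "BeliefVector":
        return cls(1 / 3, 1 / 3, 1 / 3)

    def as_array(self) -> np.ndarray:
        return np.array([self.p_low, self.p_med, self.p_high])

    def scalar(self) -> float:
        """Expected competence under the numeric state embedding."""
        return float(STATE_VALUES @ self.as_array())


def normalize_floored(arr: np.ndarray, floor: float = EVIDENCE_FLOOR) -> np.ndarray:
    """Clamp components to ``floor`` from below, then renormalize to sum 1."""
    clamped = np.maximum(np.asarray(arr, dtype=float), floor)
    return clamped / clamped.sum()
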