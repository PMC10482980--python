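"""The multinomial cooperation-and-punishment model.

Two processing trees describe a round of a Prisoner's Dilemma with a costly
punishment option, one tree per partner behavior (defecting / cooperating).
Five probabilities generate the eight observable categories:

``C``
    probability that the participant cooperates (shared by both trees, since
    decisions are simultaneous and therefore independent of the partner's);
``P_Moral``
    punishment of a defecting partner by a cooperating participant;
``P_Hypocritical``
    punishment of a defecting partner by a defecting participant;
``P_Antisocial``
    punishment of a cooperating partner by a defecting participant;
``b``
    an unspecific punishment bias that can produce punishment on every path
    on which no outcome-specific punishment process fired.

Defecting-partner tree:

====================  =============================================
category              probability
====================  =============================================
cooperate, punished   C * (P_Moral + (1 - P_Moral) * b)
cooperate, not        C * (1 - P_Moral) * (1 - b)
defect, punished      (1 - C) * (P_Hypocritical + (1 - P_Hypocritical) * b)
defect, not           (1 - C) * (1 - P_Hypocritical) * (1 - b)
====================  =============================================

Cooperating-partner tree: mutual cooperation gives no specific reason to
punish, so only the bias operates (``C * b`` / ``C * (1 - b)``); unilateral
participant defection may trigger antisocial punishment, with the analogous
``(1 - C) * (P_Antisocial + (1 - P_Antisocial) * b)`` split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .game import CATEGORIES, CATEGORY_INDEX, Decision, ResponseCategory

__all__ = [
    "PARAM_NAMES",
    "N_CATEGORIES",
    "DEFECT_TREE",
    "COOP_TREE",
    "ParameterVector",
    "FrequencyTable",
    "category_probabilities",
    "probability_jacobian",
    "log_likelihood",
    "expected_counts",
]

#: Model parameters in canonical order.
PARAM_NAMES = ("C", "P_Moral", "P_Hypocritical", "P_Antisocial", "b")

N_CATEGORIES = 8
#: Indices of the defecting-partner tree in canonical category order.
DEFECT_TREE = np.arange(0, 4)
#: Indices of the cooperating-partner tree.
COOP_TREE = np.arange(4, 8)


@dataclass(frozen=True)
class ParameterVector:
    """The five branch probabilities, each in [0, 1]."""

    c: float
    p_moral: float
    p_hypocritical: float
    p_antisocial: float
    b: float

    def __post_init__(self) -> None:
        for name, value in zip(PARAM_NAMES, self.to_array()):
            if not (0.0 <= value <= 1.0) or not np.isfinite(value):
                raise ValueError(f"parameter {name} must lie in [0, 1], got {value}")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.c, self.p_moral, self.p_hypocritical, self.p_antisocial, self.b],
            dtype=float,
        )

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ParameterVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise ValueError("expected 5 parameter values")
        return cls(*values.tolist())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.to_array().tolist()))


class FrequencyTable:
    """Counts of the 8 response categories for one group.

    Counts are stored in the canonical category order of
    :data:`punishmpt.game.CATEGORIES` (defecting-partner tree first,
    cooperate choice first, punished first).
    """

    __slots__ = ("counts",)

    def __init__(self, counts) -> None:
        arr = np.asarray(counts)
        if arr.shape != (N_CATEGORIES,):
            raise ValueError(f"expected {N_CATEGORIES} counts, got shape {arr.shape}")
        if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        self.counts = arr.astype(np.int64)

    @classmethod
    def from_mapping(cls, counts: Mapping[ResponseCategory, int]) -> "FrequencyTable":
        arr = np.zeros(N_CATEGORIES, dtype=np.int64)
        for cat, n in counts.items():
            arr[CATEGORY_INDEX[cat]] = n
        return cls(arr)

    @property
    def n_defect_tree(self) -> int:
        """Test trials with a defecting partner."""
        return int(self.counts[DEFECT_TREE].sum())

    @property
    def n_coop_tree(self) -> int:
        """Test trials with a cooperating partner."""
        return int(self.counts[COOP_TREE].sum())

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, cat: ResponseCategory) -> int:
        return int(self.counts[CATEGORY_INDEX[cat]])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FrequencyTable) and bool(
            np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"FrequencyTable({self.counts.tolist()})"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "partner": [c.partner_behavior.value for c in CATEGORIES],
                "participant": [c.participant_behavior.value for c in CATEGORIES],
                "punished": [int(c.punished) for c in CATEGORIES],
                "count": self.counts,
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        """8-row CSV (partner, participant, punished, count); round-trips losslessly."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "FrequencyTable":
        df = pd.read_csv(path, dtype={"partner": str, "participant": str})
        arr = np.zeros(N_CATEGORIES, dtype=np.int64)
        for row in df.itertuples(index=False):
            cat = ResponseCategory(
                Decision(row.partner), Decision(row.participant), bool(row.punished)
            )
            arr[CATEGORY_INDEX[cat]] = int(row.count)
        return cls(arr)


def _theta_array(theta) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        return theta.to_array()
    arr = np.asarray(theta, dtype=float)
    if arr.shape != (5,):
        raise ValueError("expected a ParameterVector or 5 values")
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError("all parameters must lie in [0, 1]")
    return arr


def category_probabilities(theta) -> np.ndarray:
    """The 8 category probabilities in canonical order.

    Each tree's four probabilities sum to one by construction.
    """
    c, pm, ph, pa, b = _theta_array(theta)
    return np.array(
        [
            c * (pm + (1 - pm) * b),
            c * (1 - pm) * (1 - b),
            (1 - c) * (ph + (1 - ph) * b),
            (1 - c) * (1 - ph) * (1 - b),
            c * b,
            c * (1 - b),
            (1 - c) * (pa + (1 - pa) * b),
            (1 - c) * (1 - pa) * (1 - b),
        ]
    )


def probability_jacobian(theta) -> np.ndarray:
    """(8, 5) matrix of partial derivatives of the category probabilities.

    Columns follow :data:`PARAM_NAMES`; used for gradients and for the
    expected Fisher information.
    """
    c, pm, ph, pa, b = _theta_array(theta)
    J = np.zeros((N_CATEGORIES, 5))
    # defect-partner tree, cooperate branch
    J[0] = [pm + (1 - pm) * b, c * (1 - b), 0, 0, c * (1 - pm)]
    J[1] = [(1 - pm) * (1 - b), -c * (1 - b), 0, 0, -c * (1 - pm)]
    # defect-partner tree, defect branch
    J[2] = [-(ph + (1 - ph) * b), 0, (1 - c) * (1 - b), 0, (1 - c) * (1 - ph)]
    J[3] = [-(1 - ph) * (1 - b), 0, -(1 - c) * (1 - b), 0, -(1 - c) * (1 - ph)]
    # coop-partner tree, cooperate branch (bias only)
    J[4] = [b, 0, 0, 0, c]
    J[5] = [1 - b, 0, 0, 0, -c]
    # coop-partner tree, defect branch
    J[6] = [-(pa + (1 - pa) * b), 0, 0, (1 - c) * (1 - b), (1 - c) * (1 - pa)]
    J[7] = [-(1 - pa) * (1 - b), 0, 0, -(1 - c) * (1 - b), -(1 - c) * (1 - pa)]
    return J


def log_likelihood(theta, table: FrequencyTable) -> float:
    """Multinomial log-likelihood ``sum count * ln(prob)`` over the 8 categories.

    Zero counts contribute exactly 0 regardless of the probability; the result
    is ``-inf`` only when a category with a positive count has probability 0.
    """
    p = category_probabilities(theta)
    counts = table.counts
    pos = counts > 0
    if np.any(p[pos] == 0):
        return -np.inf
    return float(np.sum(counts[pos] * np.log(p[pos])))


def expected_counts(theta, n_defect_tree: int, n_coop_tree: int) -> np.ndarray:
    """Expected category counts for given tree totals (probability x total)."""
    if n_defect_tree < 0 or n_coop_tree < 0:
        raise ValueError("tree totals must be non-negative")
    p = category_probabilities(theta)
    totals = np.array([n_defect_tree] * 4 + [n_coop_tree] * 4, dtype=float)
    return p * totals
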