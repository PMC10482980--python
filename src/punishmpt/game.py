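"""Prisoner's Dilemma payoff rules and costly-punishment economics.

A simultaneous one-shot Prisoner's Dilemma: each player either cooperates by
investing a fixed amount into a joint account or defects by investing nothing.
A bonus proportional to the joint investment is added and the account is split
evenly, so defection strictly dominates while mutual cooperation beats mutual
defection.  After each round the participant may pay 1 unit to deduct
``punishment_ratio`` units from the partner (costly punishment).

This module also maps a single trial to one of the eight observable response
categories (partner behavior x participant behavior x punished-or-not) that
the multinomial model in :mod:`punishmpt.model` is defined over.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "Decision",
    "Phase",
    "PayoffRules",
    "EXP1_RULES",
    "EXP2_RULES",
    "TrialRecord",
    "ResponseCategory",
    "CATEGORIES",
    "CATEGORY_INDEX",
    "TRIAL_LOG_COLUMNS",
    "round_payoff",
    "punishment_effect",
    "categorize_trial",
    "settle_round",
    "running_balance",
    "read_trial_log",
    "write_trial_log",
]


class Decision(str, Enum):
    """A player's choice in one round: cooperate (invest) or defect (keep)."""

    COOPERATE = "C"
    DEFECT = "D"


class Phase(str, Enum):
    """Trial phase; only test-phase trials enter the statistical model."""

    TRAINING = "training"
    TEST = "test"


@dataclass(frozen=True)
class PayoffRules:
    """Economic parameters of the game, in integer minor currency units.

    Parameters
    ----------
    investment_on_cooperate
        Units a cooperating player pays into the joint account (default 30).
    bonus_fraction
        Fraction of the joint investment added as a bonus before the even
        split (default 1/3, held as an exact ``Fraction``).
    punishment_ratio
        Units removed from the partner per unit invested in punishment
        (default 10, the 1:10 ratio).
    max_punishment_investment
        Cap on the punishment investment: 9 for the cents variant, 3 for the
        points variant.
    endowment
        Starting account balance (400 cents or 100 points).
    """

    investment_on_cooperate: int = 30
    bonus_fraction: Fraction = Fraction(1, 3)
    punishment_ratio: int = 10
    max_punishment_investment: int = 9
    endowment: int = 400

    def __post_init__(self) -> None:
        if self.investment_on_cooperate <= 0:
            raise ValueError("investment_on_cooperate must be positive")
        if not (0 < self.bonus_fraction < 1):
            raise ValueError("bonus_fraction must lie strictly in (0, 1)")
        if self.punishment_ratio <= 0:
            raise ValueError("punishment_ratio must be positive")
        if self.max_punishment_investment <= 0:
            raise ValueError("max_punishment_investment must be positive")
        if self.endowment <= 0:
            raise ValueError("endowment must be positive")


#: Cents variant: punish with up to 9 cents, endowment 400 cents.
EXP1_RULES = PayoffRules()
#: Points variant: punish with up to 3 points, endowment 100 points.
EXP2_RULES = PayoffRules(max_punishment_investment=3, endowment=100)


@dataclass(frozen=True)
class TrialRecord:
    """One game round as it appears in a trial log."""

    participant_id: str
    group_label: str
    trial_index: int
    phase: Phase
    partner_behavior: Decision
    participant_behavior: Decision
    punishment_investment: int

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index must be a positive integer")
        if self.punishment_investment < 0:
            raise ValueError("punishment_investment must be non-negative")


@dataclass(frozen=True)
class ResponseCategory:
    """One of the 8 observable outcome categories of a test trial."""

    partner_behavior: Decision
    participant_behavior: Decision
    punished: bool

    def __str__(self) -> str:  # e.g. "D/C/punished"
        return (
            f"{self.partner_behavior.value}/{self.participant_behavior.value}/"
            f"{'punished' if self.punished else 'not_punished'}"
        )


def _categories() -> tuple[ResponseCategory, ...]:
    # Canonical order: defecting-partner tree first, cooperate choice first,
    # punished first.  Serialized tables rely on this order being stable.
    cats = []
    for partner in (Decision.DEFECT, Decision.COOPERATE):
        for participant in (Decision.COOPERATE, Decision.DEFECT):
            for punished in (True, False):
                cats.append(ResponseCategory(partner, participant, punished))
    return tuple(cats)


#: The 8 categories in canonical (serialization) order.
CATEGORIES: tuple[ResponseCategory, ...] = _categories()
#: Category -> position in :data:`CATEGORIES`.
CATEGORY_INDEX: dict[ResponseCategory, int] = {c: i for i, c in enumerate(CATEGORIES)}


def round_payoff(
    d_self: Decision, d_partner: Decision, rules: PayoffRules = EXP1_RULES
) -> tuple[float, float]:
    """Net gain (self, partner) from one round, before any punishment.

    Each cooperator invests ``investment_on_cooperate``; a bonus of
    ``bonus_fraction`` times the joint investment is added and the resulting
    account is split evenly.  The net gain is the half-share minus the own
    investment, so with the default rules mutual cooperation yields +10 each,
    unilateral defection +20 to the defector and -10 to the cooperator, and
    mutual defection 0.
    """
    inv_self = rules.investment_on_cooperate if d_self is Decision.COOPERATE else 0
    inv_partner = rules.investment_on_cooperate if d_partner is Decision.COOPERATE else 0
    pot = Fraction(inv_self + inv_partner)
    share = (pot + Fraction(rules.bonus_fraction) * pot) / 2
    return float(share - inv_self), float(share - inv_partner)


def punishment_effect(invest: int, rules: PayoffRules = EXP1_RULES) -> int:
    """Units deducted from the partner for a punishment investment.

    Raises
    ------
    ValueError
        If ``invest`` is negative or exceeds ``rules.max_punishment_investment``.
    """
    if not (0 <= invest <= rules.max_punishment_investment):
        raise ValueError(
            f"punishment investment must be between 0 and "
            f"{rules.max_punishment_investment}, got {invest}"
        )
    return rules.punishment_ratio * invest


def categorize_trial(t: TrialRecord) -> ResponseCategory:
    """Map a test-phase trial to its response category.

    Punishment is binarized (any positive investment counts as punished); the
    magnitude of the investment does not enter the multinomial model.

    Raises
    ------
    ValueError
        For training-phase trials, which never enter the model.
    """
    if t.phase is not Phase.TEST:
        raise ValueError(
            f"only test-phase trials are categorized; trial {t.trial_index} of "
            f"participant {t.participant_id!r} is a {t.phase.value} trial"
        )
    return ResponseCategory(
        partner_behavior=t.partner_behavior,
        participant_behavior=t.participant_behavior,
        punished=t.punishment_investment > 0,
    )


def settle_round(
    d_self: Decision,
    d_partner: Decision,
    punish_invest_self: int = 0,
    punish_invest_partner: int = 0,
    rules: PayoffRules = EXP1_RULES,
) -> tuple[float, float]:
    """Net balance change (self, partner) for a full round including punishment.

    Each punisher pays their investment; the punished side loses
    ``punishment_ratio`` times the amount invested against them.  Bookkeeping
    only — punishment magnitudes never feed the statistical model.
    """
    gain_self, gain_partner = round_payoff(d_self, d_partner, rules)
    fine_to_partner = punishment_effect(punish_invest_self, rules)
    fine_to_self = punishment_effect(punish_invest_partner, rules)
    return (
        gain_self - punish_invest_self - fine_to_self,
        gain_partner - punish_invest_partner - fine_to_partner,
    )


def running_balance(
    deltas: Iterable[float], rules: PayoffRules = EXP1_RULES
) -> list[float]:
    """Account trajectory starting from the endowment, one entry per round."""
    balance = float(rules.endowment)
    out = []
    for d in deltas:
        balance += d
        out.append(balance)
    return out


#: Canonical trial-log CSV header.
TRIAL_LOG_COLUMNS = (
    "participant_id",
    "group",
    "trial",
    "phase",
    "partner",
    "participant",
    "punish_invest",
)


def write_trial_log(trials: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trial log in the canonical CSV dialect (see TRIAL_LOG_COLUMNS)."""
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    trials.loc[:, TRIAL_LOG_COLUMNS].to_csv(path, index=False)


def read_trial_log(path: Union[str, Path]) -> pd.DataFrame:
    """Read a canonical trial-log CSV written by :func:`write_trial_log`."""
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "group": str,
            "trial": int,
            "phase": str,
            "partner": str,
            "participant": str,
            "punish_invest": int,
        },
    )
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    return df
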