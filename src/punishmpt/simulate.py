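"""Trial-level simulation of the Prisoner's Dilemma with costly punishment.

The generator reproduces the study's structure: each participant plays 26
rounds against preprogrammed partners (the first 6 are training trials), half
of the partners cooperate and half defect, trials appear in random order, and
each round ends with a punishment decision.  Participant behavior follows the
cooperation-and-punishment model exactly: cooperate with probability C, then
traverse the matching punishment branch (outcome-specific parameter first,
then the unspecific bias b).  A punished trial gets an investment drawn
uniformly from 1..max_punishment_investment; the magnitude matters only for
payoff bookkeeping, never for the statistical model.

Randomness is keyed per (seed, group, participant), so enlarging a group
leaves the trials of earlier participants untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .game import EXP1_RULES, Decision, PayoffRules, Phase, TRIAL_LOG_COLUMNS
from .inference import FitOptions, ModelSpec, _maximize
from .model import PARAM_NAMES, FrequencyTable, ParameterVector

__all__ = [
    "GroupDesign",
    "Schedule",
    "RecoveryReport",
    "simulate_trials",
    "write_manifest",
    "parameter_recovery",
]


@dataclass(frozen=True)
class GroupDesign:
    """One between-subjects condition: label, generating parameters, size."""

    label: str
    theta: ParameterVector
    n_participants: int

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")


@dataclass(frozen=True)
class Schedule:
    """Trial schedule per participant.

    Defaults follow the study: 6 training trials then 20 test trials, with
    the test phase split 10 defecting / 10 cooperating partners (the 26-trial
    session has 13 partners of each kind overall; training takes 3 of each).
    """

    n_training: int = 6
    n_test_defect: int = 10
    n_test_coop: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_training < 0:
            raise ValueError("n_training must be non-negative")
        if self.n_test_defect < 1 or self.n_test_coop < 1:
            raise ValueError("each test tree needs at least one trial")

    @property
    def n_trials(self) -> int:
        return self.n_training + self.n_test_defect + self.n_test_coop


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery summary across simulation replicates."""

    theta_true: ParameterVector
    n_participants: int
    n_replicates: int
    bias: dict[str, float]
    rmse: dict[str, float]
    coverage: dict[str, float]
    n_nonconverged: int
    estimates: pd.DataFrame = field(repr=False, compare=False)


_PUNISH_PARAM_OF_PAIR = {
    # (partner, participant) -> outcome-specific punishment parameter index
    (Decision.DEFECT, Decision.COOPERATE): 1,  # moral
    (Decision.DEFECT, Decision.DEFECT): 2,  # hypocritical
    (Decision.COOPERATE, Decision.DEFECT): 3,  # antisocial
    (Decision.COOPERATE, Decision.COOPERATE): None,  # bias only
}


def _participant_frame(
    rng: np.random.Generator,
    theta: np.ndarray,
    schedule: Schedule,
    rules: PayoffRules,
    punish_back: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Partner behavior, own behavior, punishment investment, phase flags."""
    c, pm, ph, pa, b = theta
    n_tr = schedule.n_training
    # training partners: half defect, half cooperate (extra trial defects)
    tr_defect = (n_tr + 1) // 2
    training = np.array([1] * tr_defect + [0] * (n_tr - tr_defect), dtype=bool)
    rng.shuffle(training)
    test = np.array(
        [1] * schedule.n_test_defect + [0] * schedule.n_test_coop, dtype=bool
    )
    rng.shuffle(test)
    partner_defects = np.concatenate([training, test])
    n = partner_defects.size

    self_cooperates = rng.random(n) < c
    specific_p = np.where(
        self_cooperates,
        np.where(partner_defects, pm, 0.0),  # moral / bias-only
        np.where(partner_defects, ph, pa),  # hypocritical / antisocial
    )
    u_specific = rng.random(n)
    u_bias = rng.random(n)
    punished = (u_specific < specific_p) | (u_bias < b)
    invest = np.where(
        punished, rng.integers(1, rules.max_punishment_investment + 1, size=n), 0
    )
    if punish_back:
        # partners punish unilateral participant defection (payoff realism
        # only; never enters the frequency tables)
        unilateral_defect = ~self_cooperates & ~partner_defects
        partner_invest = np.where(
            unilateral_defect,
            rng.integers(1, rules.max_punishment_investment + 1, size=n),
            0,
        )
    else:
        partner_invest = np.zeros(n, dtype=int)
    phase_is_training = np.arange(n) < n_tr
    return partner_defects, self_cooperates, invest, partner_invest, phase_is_training


def simulate_trials(
    designs: Sequence[GroupDesign],
    schedule: Schedule = Schedule(),
    rules: PayoffRules = EXP1_RULES,
    punish_back: bool = False,
) -> pd.DataFrame:
    """Simulate trial logs for a set of group designs.

    Returns a DataFrame in the canonical trial-log dialect
    (:data:`punishmpt.game.TRIAL_LOG_COLUMNS`), fully reproducible from
    ``schedule.seed``.
    """
    frames = []
    for g_idx, design in enumerate(designs):
        theta = design.theta.to_array()
        for p_idx in range(design.n_participants):
            rng = np.random.default_rng([schedule.seed, g_idx, p_idx])
            (
                partner_defects,
                self_coop,
                invest,
                partner_invest,
                is_training,
            ) = _participant_frame(rng, theta, schedule, rules, punish_back)
            n = partner_defects.size
            frame = pd.DataFrame(
                {
                    "participant_id": f"{design.label}-{p_idx:04d}",
                    "group": design.label,
                    "trial": np.arange(1, n + 1),
                    "phase": np.where(
                        is_training, Phase.TRAINING.value, Phase.TEST.value
                    ),
                    "partner": np.where(
                        partner_defects, Decision.DEFECT.value, Decision.COOPERATE.value
                    ),
                    "participant": np.where(
                        self_coop, Decision.COOPERATE.value, Decision.DEFECT.value
                    ),
                    "punish_invest": invest.astype(int),
                }
            )
            if punish_back:
                frame["partner_punish_invest"] = partner_invest.astype(int)
            frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    cols = list(TRIAL_LOG_COLUMNS) + (
        ["partner_punish_invest"] if punish_back else []
    )
    return out.loc[:, cols]


def write_manifest(
    path: Union[str, Path],
    designs: Sequence[GroupDesign],
    schedule: Schedule,
    rules: PayoffRules = EXP1_RULES,
) -> None:
    """Record the generating design next to a simulated trial log."""
    manifest = {
        "designs": [
            {
                "label": d.label,
                "theta": d.theta.as_dict(),
                "n_participants": d.n_participants,
            }
            for d in designs
        ],
        "schedule": {
            "n_training": schedule.n_training,
            "n_test_defect": schedule.n_test_defect,
            "n_test_coop": schedule.n_test_coop,
            "seed": schedule.seed,
        },
        "rules": {
            "investment_on_cooperate": rules.investment_on_cooperate,
            "bonus_fraction": str(rules.bonus_fraction),
            "punishment_ratio": rules.punishment_ratio,
            "max_punishment_investment": rules.max_punishment_investment,
            "endowment": rules.endowment,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def _aggregate_single(trials: pd.DataFrame, label: str) -> FrequencyTable:
    from .pipeline import aggregate  # deferred to avoid an import cycle

    return aggregate(trials)[label]


def parameter_recovery(
    theta_true: ParameterVector,
    n_participants: int,
    n_replicates: int,
    schedule: Schedule = Schedule(),
    options: FitOptions = FitOptions(),
    confidence: float = 0.95,
) -> RecoveryReport:
    """Simulate -> aggregate -> fit, replicated; summarize estimation quality.

    For each replicate a single group is simulated under ``theta_true``,
    aggregated to a frequency table and fitted without constraints.  The
    report gives per-parameter bias, root-mean-square error, and coverage of
    nominal Wald intervals (coverage is computed over replicates with a
    defined standard error for that parameter).  Non-converged replicates are
    counted, not hidden.
    """
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + confidence / 2))
    spec = ModelSpec(groups=("sim",))
    rows = []
    n_nonconverged = 0
    for rep in range(n_replicates):
        rep_schedule = Schedule(
            n_training=schedule.n_training,
            n_test_defect=schedule.n_test_defect,
            n_test_coop=schedule.n_test_coop,
            seed=int(np.random.default_rng([schedule.seed, rep]).integers(2**31)),
        )
        trials = simulate_trials(
            [GroupDesign("sim", theta_true, n_participants)], rep_schedule
        )
        table = _aggregate_single(trials, "sim")
        result = _maximize(spec, {"sim": table}, options)
        if not result.converged:
            n_nonconverged += 1
        est = result.estimates["sim"].as_dict()
        ses = result.standard_errors["sim"]
        for name, true_val in zip(PARAM_NAMES, theta_true.to_array()):
            se = ses[name]
            covered = (
                abs(est[name] - true_val) <= z * se if np.isfinite(se) else np.nan
            )
            rows.append(
                {
                    "replicate": rep,
                    "parameter": name,
                    "true": true_val,
                    "estimate": est[name],
                    "se": se,
                    "covered": covered,
                }
            )
    df = pd.DataFrame(rows)
    bias, rmse, coverage = {}, {}, {}
    for name in PARAM_NAMES:
        sub = df[df["parameter"] == name]
        err = sub["estimate"] - sub["true"]
        bias[name] = float(err.mean())
        rmse[name] = float(np.sqrt(np.mean(err**2)))
        cov = sub["covered"].dropna()
        coverage[name] = float(cov.mean()) if len(cov) else float("nan")
    return RecoveryReport(
        theta_true=theta_true,
        n_participants=n_participants,
        n_replicates=n_replicates,
        bias=bias,
        rmse=rmse,
        coverage=coverage,
        n_nonconverged=n_nonconverged,
        estimates=df,
    )
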