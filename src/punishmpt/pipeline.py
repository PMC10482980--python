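"""End-to-end analysis: trial logs -> frequency tables -> fits and tests.

A trial log (canonical CSV or any dialect described by a
:class:`ColumnMapping`) is aggregated into one 8-category frequency table per
group, a base model with one instance per group is fitted, and a battery of
nested equality tests — one per (parameter, group subset) comparison — is
run.  Human-readable output follows the conventional reporting style
("ΔG²(1) = 5.11, p = 0.024, w = 0.04") with round-half-up rounding and
"< 0.01" / "< 0.001" rendering for positive values that would display as
zero; the JSON report keeps full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .game import CATEGORY_INDEX, Decision, Phase, ResponseCategory, read_trial_log
from .inference import (
    EqualityConstraint,
    FitOptions,
    FitResult,
    ModelSpec,
    TestResult,
    fit,
    nested_test,
)
from .model import N_CATEGORIES, PARAM_NAMES, FrequencyTable

__all__ = [
    "ColumnMapping",
    "AnalysisConfig",
    "AnalysisReport",
    "aggregate",
    "run_full_analysis",
    "default_battery",
    "round_half_up",
    "format_value",
    "format_test_line",
]


@dataclass(frozen=True)
class ColumnMapping:
    """Maps a trial-log dialect onto the canonical columns and value codes.

    ``*_codes`` map raw cell values to canonical ones: decisions to "C"/"D"
    and phases to "training"/"test".
    """

    participant_id: str = "participant_id"
    group: str = "group"
    trial: str = "trial"
    phase: str = "phase"
    partner: str = "partner"
    participant: str = "participant"
    punish_invest: str = "punish_invest"
    decision_codes: Mapping[str, str] = field(
        default_factory=lambda: {"C": "C", "D": "D"}
    )
    phase_codes: Mapping[str, str] = field(
        default_factory=lambda: {"training": "training", "test": "test"}
    )

    @property
    def columns(self) -> dict[str, str]:
        return {
            "participant_id": self.participant_id,
            "group": self.group,
            "trial": self.trial,
            "phase": self.phase,
            "partner": self.partner,
            "participant": self.participant,
            "punish_invest": self.punish_invest,
        }


def _decode(series: pd.Series, codes: Mapping[str, str], what: str) -> pd.Series:
    decoded = series.astype(str).map(dict(codes))
    bad = decoded.isna()
    if bad.any():
        rows = series.index[bad].tolist()[:10]
        values = sorted(series[bad].astype(str).unique().tolist())
        raise ValueError(
            f"unknown {what} codes {values} (rows {rows}); "
            f"extend the column mapping's {what} codes"
        )
    return decoded


def aggregate(
    trials: pd.DataFrame, mapping: ColumnMapping = ColumnMapping()
) -> dict[str, FrequencyTable]:
    """Count the 8 response categories per group from a trial log.

    Training trials are excluded; punishment is binarized (investment > 0).

    Raises
    ------
    ValueError
        On missing columns, unknown value codes, duplicate (participant,
        trial) keys, or a log without test-phase trials — each with row-level
        diagnostics.
    """
    missing = [c for c in mapping.columns.values() if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    df = trials.rename(
        columns={raw: canon for canon, raw in mapping.columns.items()}
    ).copy()

    dup = df.duplicated(subset=["participant_id", "trial"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["participant_id", "trial"]]
            .drop_duplicates()
            .head(10)
            .to_records(index=False)
            .tolist()
        )
        raise ValueError(f"duplicate (participant, trial) keys, e.g. {keys}")

    df["phase"] = _decode(df["phase"], mapping.phase_codes, "phase")
    df["partner"] = _decode(df["partner"], mapping.decision_codes, "decision")
    df["participant"] = _decode(df["participant"], mapping.decision_codes, "decision")

    test = df[df["phase"] == Phase.TEST.value]
    if test.empty:
        raise ValueError("trial log contains no test-phase trials")

    tables: dict[str, FrequencyTable] = {}
    for group, sub in test.groupby("group", sort=False):
        counts = np.zeros(N_CATEGORIES, dtype=np.int64)
        idx = [
            CATEGORY_INDEX[
                ResponseCategory(
                    Decision(row.partner), Decision(row.participant), row.punish_invest > 0
                )
            ]
            for row in sub.itertuples(index=False)
        ]
        np.add.at(counts, idx, 1)
        tables[str(group)] = FrequencyTable(counts)
    return tables


def default_battery(groups: Sequence[str]) -> tuple[tuple[str, tuple[str, ...]], ...]:
    """The study's test battery: every parameter, every pair of groups.

    With two groups this is the five pairwise comparisons; with more groups,
    all pairwise comparisons per parameter.
    """
    battery = []
    for name in PARAM_NAMES:
        if len(groups) == 2:
            battery.append((name, tuple(groups)))
        else:
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    battery.append((name, (groups[i], groups[j])))
    return tuple(battery)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce an analysis run."""

    input_paths: tuple[str, ...]
    groups: tuple[str, ...]
    battery: tuple[tuple[str, tuple[str, ...]], ...]
    mapping: ColumnMapping = ColumnMapping()
    alpha: float = 0.05
    seed: int = 0
    output_dir: Optional[str] = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "input_paths": list(self.input_paths),
                "groups": list(self.groups),
                "battery": [[p, list(g)] for p, g in self.battery],
                "columns": self.mapping.columns,
                "decision_codes": dict(self.mapping.decision_codes),
                "phase_codes": dict(self.mapping.phase_codes),
                "alpha": self.alpha,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class AnalysisReport:
    """Base fit, the battery of nested tests, and provenance."""

    base: FitResult
    tests: dict[str, TestResult]
    config: AnalysisConfig
    provenance: dict[str, str]

    def estimates_table(self) -> pd.DataFrame:
        return self.base.summary()

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "base": {
                "g_squared": self.base.g_squared,
                "df": self.base.df,
                "p_value": self.base.p_value,
                "log_likelihood": self.base.log_likelihood,
                "converged": self.base.converged,
                "n_total": self.base.n_total,
                "estimates": {
                    g: th.as_dict() for g, th in self.base.estimates.items()
                },
                "standard_errors": {
                    g: {k: _json_float(v) for k, v in se.items()}
                    for g, se in self.base.standard_errors.items()
                },
            },
            "tests": {
                label: {
                    "delta_g_squared": t.delta_g_squared,
                    "df": t.df,
                    "p_value": t.p_value,
                    "w": t.w,
                }
                for label, t in self.tests.items()
            },
        }
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        lines = [
            f"Base model: {format_fit_line(self.base)}",
            "",
            "Parameter estimates (SE):",
        ]
        for group, theta in self.base.estimates.items():
            parts = []
            for name, est in theta.as_dict().items():
                se = self.base.standard_errors[group][name]
                se_txt = f"{se:.3f}" if np.isfinite(se) else "undef."
                parts.append(f"{name} = {est:.3f} ({se_txt})")
            lines.append(f"  {group}: " + ", ".join(parts))
        lines += ["", "Nested tests:"]
        for label, t in self.tests.items():
            lines.append(f"  {label}: {format_test_line(t)}")
        return "\n".join(lines) + "\n"


def _json_float(x: float) -> Optional[float]:
    return float(x) if np.isfinite(x) else None


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.035 -> 0.04 at two digits), unlike banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_value(x: float, ndigits: int) -> str:
    """Render a non-negative statistic, using "< bound" when it would show 0."""
    bound = 10.0 ** (-ndigits)
    rounded = round_half_up(x, ndigits)
    if x > 0 and rounded < bound:
        return f"< {bound:.{ndigits}f}"
    return f"{rounded:.{ndigits}f}"


def format_fit_line(result: FitResult) -> str:
    p = format_value(result.p_value, 3)
    p_txt = p if p.startswith("<") else f"= {p}"
    return f"G²({result.df}) = {round_half_up(result.g_squared, 2):.2f}, p {p_txt}"


def format_test_line(t: TestResult) -> str:
    p = format_value(t.p_value, 3)
    p_txt = p if p.startswith("<") else f"= {p}"
    w = format_value(t.w, 2)
    w_txt = w if w.startswith("<") else f"= {w}"
    return (
        f"ΔG²({t.df}) = {round_half_up(t.delta_g_squared, 2):.2f}, "
        f"p {p_txt}, w {w_txt}"
    )


def run_full_analysis(
    config: AnalysisConfig,
    trials: Optional[pd.DataFrame] = None,
    options: Optional[FitOptions] = None,
) -> AnalysisReport:
    """Run the full analysis: aggregate, base fit, battery of nested tests.

    ``trials`` may be passed directly (e.g. from :func:`simulate_trials`);
    otherwise the configured input paths are read and concatenated.
    """
    if options is None:
        options = FitOptions(seed=config.seed)
    if trials is None:
        if not config.input_paths:
            raise ValueError("config has no input paths and no trials were passed")
        trials = pd.concat(
            [read_trial_log(p) for p in config.input_paths], ignore_index=True
        )
    try:
        tables = aggregate(trials, config.mapping)
    except ValueError as err:
        raise ValueError(f"[aggregate] {err}") from err

    unknown = set(config.groups) - set(tables)
    if unknown:
        raise ValueError(f"[aggregate] configured groups not in the data: {unknown}")
    tables = {g: tables[g] for g in config.groups}  # fixed group order

    spec = ModelSpec(groups=tuple(config.groups))
    try:
        base = fit(spec, tables, options)
    except Exception as err:
        raise RuntimeError(f"[fit] {err}") from err

    tests: dict[str, TestResult] = {}
    for parameter, subset in config.battery:
        label = f"{parameter}: {' vs '.join(subset)}"
        try:
            tests[label] = nested_test(
                spec, tables, EqualityConstraint(parameter, tuple(subset)), options
            )
        except Exception as err:
            raise RuntimeError(f"[test {label}] {err}") from err

    provenance = {
        "config_hash": config.config_hash(),
        "seed": str(config.seed),
        "software_version": __version__,
    }
    return AnalysisReport(base=base, tests=tests, config=config, provenance=provenance)
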