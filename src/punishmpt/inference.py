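"""Multi-group maximum-likelihood estimation and likelihood-ratio testing.

One instance of the cooperation-and-punishment model is fitted per
experimental group; cross-group equality constraints collapse a parameter to
a single free value shared by the constrained groups.  Goodness of fit is the
likelihood-ratio statistic G² = 2 Σ obs·ln(obs/exp), asymptotically central
chi-square with df = 6·(number of groups) − (number of free parameters)
(each group contributes two multinomial trees with three independent
categories each).  Hypotheses about parameters are tested by adding an
equality constraint and referring ΔG² = G²(restricted) − G²(base) to a
chi-square distribution; the accompanying effect size is Cohen's
w = sqrt(ΔG² / N), with N the total number of test decisions across all
groups of the fitted model.

Optimization runs on the log-odds scale (boundary-safe) with analytic
gradients and a fixed number of seeded random restarts, so results are
deterministic given the options.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .model import (
    PARAM_NAMES,
    FrequencyTable,
    ParameterVector,
    category_probabilities,
    expected_counts,
    probability_jacobian,
)

__all__ = [
    "EqualityConstraint",
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "TestResult",
    "CooperationPunishmentMLE",
    "fit",
    "nested_test",
    "effect_size_w",
    "standard_errors",
]

_EXPECTED_FLOOR = 1e-12  # floor for expected counts / probabilities inside logs
_BOUNDARY_TOL = 1e-6  # estimates closer than this to 0/1 count as boundary


@dataclass(frozen=True)
class EqualityConstraint:
    """Equate one model parameter across two or more groups."""

    parameter: str
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; expected one of {PARAM_NAMES}"
            )
        if len(self.groups) < 2:
            raise ValueError("an equality constraint needs at least two groups")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("constraint groups must be distinct")
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass(frozen=True)
class ModelSpec:
    """Groups to fit (one model instance each) plus equality constraints."""

    groups: tuple[str, ...]
    constraints: tuple[EqualityConstraint, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "constraints", tuple(self.constraints))
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if not self.groups:
            raise ValueError("at least one group is required")
        for con in self.constraints:
            unknown = set(con.groups) - set(self.groups)
            if unknown:
                raise ValueError(f"constraint references unknown groups: {unknown}")

    def with_constraint(self, constraint: EqualityConstraint) -> "ModelSpec":
        return replace(self, constraints=self.constraints + (constraint,))


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings; identical options + data give bit-identical results."""

    n_restarts: int = 10
    tol: float = 1e-10
    seed: int = 0
    max_iter: int = 1000


@dataclass(frozen=True)
class FitResult:
    """Multi-group ML fit: estimates, standard errors, and goodness of fit."""

    estimates: dict[str, ParameterVector]
    standard_errors: dict[str, dict[str, float]]
    g_squared: float
    df: int
    p_value: float
    log_likelihood: float
    converged: bool
    n_total: int
    n_free: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for group, theta in self.estimates.items():
            for name, est in theta.as_dict().items():
                rows.append(
                    {
                        "group": group,
                        "parameter": name,
                        "estimate": est,
                        "se": self.standard_errors[group][name],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TestResult:
    """Nested likelihood-ratio test of an equality constraint."""

    delta_g_squared: float
    df: int
    p_value: float
    w: float
    base: FitResult = field(repr=False, compare=False)
    restricted: FitResult = field(repr=False, compare=False)


def effect_size_w(delta_g_squared: float, n_total: int) -> float:
    """Cohen's w = sqrt(ΔG² / N) for a chi-square-family test.

    ``n_total`` is the total number of observations entering the fitted model
    (participants × test decisions, summed over all groups).
    """
    if delta_g_squared < 0:
        raise ValueError("delta_g_squared must be non-negative")
    if n_total <= 0:
        raise ValueError("n_total must be a positive count of observations")
    return float(np.sqrt(delta_g_squared / n_total))


# ---------------------------------------------------------------------------
# parameter indexing: (group, parameter) cells -> free parameter indices
# ---------------------------------------------------------------------------


def _free_index(spec: ModelSpec) -> tuple[np.ndarray, int]:
    """Map the (n_groups, 5) parameter cells onto free-parameter indices.

    Equality constraints are merged with union-find, so overlapping
    constraints on the same parameter chain correctly.
    """
    n_groups = len(spec.groups)
    group_pos = {g: i for i, g in enumerate(spec.groups)}
    parent = list(range(n_groups * 5))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for con in spec.constraints:
        p = PARAM_NAMES.index(con.parameter)
        cells = [group_pos[g] * 5 + p for g in con.groups]
        root = find(cells[0])
        for cell in cells[1:]:
            parent[find(cell)] = root

    labels: dict[int, int] = {}
    index = np.empty(n_groups * 5, dtype=int)
    for cell in range(n_groups * 5):
        root = find(cell)
        if root not in labels:
            labels[root] = len(labels)
        index[cell] = labels[root]
    return index.reshape(n_groups, 5), len(labels)


def _tree_totals(table: FrequencyTable) -> np.ndarray:
    return np.array(
        [table.n_defect_tree] * 4 + [table.n_coop_tree] * 4, dtype=float
    )


def _neg_loglik_and_grad(
    eta: np.ndarray,
    index: np.ndarray,
    counts: np.ndarray,  # (n_groups, 8)
) -> tuple[float, np.ndarray]:
    theta_free = expit(eta)
    nll = 0.0
    grad = np.zeros_like(eta)
    dtheta_deta = theta_free * (1.0 - theta_free)
    for g in range(counts.shape[0]):
        th = theta_free[index[g]]
        p = category_probabilities(th)
        J = probability_jacobian(th)
        pc = np.maximum(p, _EXPECTED_FLOOR)
        nll -= float(np.sum(counts[g] * np.log(pc)))
        g_theta = J.T @ (counts[g] / pc)  # d loglik / d theta_g
        np.add.at(grad, index[g], -g_theta * dtheta_deta[index[g]])
    return nll, grad


def _neg_loglik_and_grad_theta(
    theta_free: np.ndarray,
    index: np.ndarray,
    counts: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Objective on the probability scale, for the bounded polish stage."""
    nll = 0.0
    grad = np.zeros_like(theta_free)
    for g in range(counts.shape[0]):
        th = theta_free[index[g]]
        p = category_probabilities(th)
        J = probability_jacobian(th)
        pc = np.maximum(p, _EXPECTED_FLOOR)
        nll -= float(np.sum(counts[g] * np.log(pc)))
        np.add.at(grad, index[g], -(J.T @ (counts[g] / pc)))
    return nll, grad


def _g_squared(
    theta_free: np.ndarray, index: np.ndarray, tables: Sequence[FrequencyTable]
) -> float:
    g2 = 0.0
    for g, table in enumerate(tables):
        exp = expected_counts(theta_free[index[g]], table.n_defect_tree, table.n_coop_tree)
        obs = table.counts.astype(float)
        pos = obs > 0
        g2 += 2.0 * float(
            np.sum(obs[pos] * np.log(obs[pos] / np.maximum(exp[pos], _EXPECTED_FLOOR)))
        )
    return g2


def _expected_information(
    theta_free: np.ndarray, index: np.ndarray, tables: Sequence[FrequencyTable]
) -> np.ndarray:
    """Expected Fisher information of the free parameters (probability scale)."""
    n_free = theta_free.size
    info = np.zeros((n_free, n_free))
    for g, table in enumerate(tables):
        th = theta_free[index[g]]
        p = np.maximum(category_probabilities(th), _EXPECTED_FLOOR)
        J = probability_jacobian(th)
        weights = _tree_totals(table) / p
        A = J.T @ (weights[:, None] * J)  # (5, 5) per-group information
        idx = index[g]
        info[np.ix_(idx, idx)] += A
    return info


def _maximize(
    spec: ModelSpec,
    tables: Mapping[str, FrequencyTable],
    options: FitOptions,
) -> FitResult:
    missing = [g for g in spec.groups if g not in tables]
    if missing:
        raise ValueError(f"no frequency table for groups: {missing}")
    table_seq = [tables[g] for g in spec.groups]
    for g, table in zip(spec.groups, table_seq):
        if table.n_defect_tree == 0 or table.n_coop_tree == 0:
            raise ValueError(
                f"group {g!r} has an empty tree "
                f"(defect={table.n_defect_tree}, coop={table.n_coop_tree})"
            )

    index, n_free = _free_index(spec)
    counts = np.stack([t.counts.astype(float) for t in table_seq])

    rng = np.random.default_rng(options.seed)
    starts = [np.full(n_free, 0.5)]
    starts += [rng.uniform(0.05, 0.95, size=n_free) for _ in range(options.n_restarts)]

    best = None
    any_success = False
    for start in starts:
        res = optimize.minimize(
            _neg_loglik_and_grad,
            logit(start),
            args=(index, counts),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": options.max_iter,
                # ftol is relative in L-BFGS-B; scale down so the absolute
                # log-likelihood resolution stays near options.tol
                "ftol": options.tol * 1e-2,
                "gtol": 1e-10,
            },
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    # bounded polish on the probability scale: the log-odds search cannot
    # land exactly on a boundary maximum, the projected step can
    polish = optimize.minimize(
        _neg_loglik_and_grad_theta,
        expit(best.x),
        args=(index, counts),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * n_free,
        # run essentially to gradient convergence: the polish must traverse
        # the shallow ridges that couple the bias with the punishment rates
        options={"maxiter": options.max_iter, "ftol": 1e-16, "gtol": 1e-12},
    )
    if polish.fun <= best.fun:
        theta_free = polish.x
        fun = polish.fun
    else:
        theta_free = expit(best.x)
        fun = best.fun
    loglik = -float(fun)
    g2 = max(_g_squared(theta_free, index, table_seq), 0.0)
    df = 6 * len(spec.groups) - n_free
    p_value = float(chi2.sf(g2, df)) if df > 0 else 1.0

    estimates = {
        g: ParameterVector.from_array(np.clip(theta_free[index[i]], 0.0, 1.0))
        for i, g in enumerate(spec.groups)
    }
    ses = _standard_errors_from_free(theta_free, index, table_seq, spec)
    n_total = int(sum(t.n_total for t in table_seq))
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        g_squared=g2,
        df=df,
        p_value=p_value,
        log_likelihood=loglik,
        converged=any_success,
        n_total=n_total,
        n_free=n_free,
    )


def _standard_errors_from_free(
    theta_free: np.ndarray,
    index: np.ndarray,
    table_seq: Sequence[FrequencyTable],
    spec: ModelSpec,
) -> dict[str, dict[str, float]]:
    interior = (theta_free > _BOUNDARY_TOL) & (theta_free < 1 - _BOUNDARY_TOL)
    se_free = np.full(theta_free.size, np.nan)
    if np.all(interior):
        info = _expected_information(theta_free, index, table_seq)
        try:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)
            with np.errstate(invalid="ignore"):
                se_free = np.where(diag >= 0, np.sqrt(np.abs(diag)), np.nan)
        except np.linalg.LinAlgError:
            pass
    elif np.any(interior):
        # boundary parameters get undefined SEs; the interior block is inverted
        sub = np.flatnonzero(interior)
        info = _expected_information(theta_free, index, table_seq)
        try:
            cov = np.linalg.inv(info[np.ix_(sub, sub)])
            se_free[sub] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            pass
    out: dict[str, dict[str, float]] = {}
    for i, g in enumerate(spec.groups):
        out[g] = {
            name: float(se_free[index[i, j]]) for j, name in enumerate(PARAM_NAMES)
        }
    return out


class CooperationPunishmentMLE(BaseEstimator):
    """Maximum-likelihood estimator for the cooperation-and-punishment model.

    Fits one model instance per group by maximizing the summed multinomial
    log-likelihood on the log-odds scale, with seeded random restarts.

    Parameters
    ----------
    constraints
        Cross-group equality constraints, as ``EqualityConstraint`` objects or
        ``(parameter, (group, ...))`` tuples.
    n_restarts
        Random restarts after the central start (default 10).
    tol
        Convergence tolerance on the log-likelihood (default 1e-10).
    random_state
        Seed for the restart draws; fits are deterministic given it.
    max_iter
        Iteration cap per optimizer run.

    Attributes
    ----------
    estimates_ : dict[str, ParameterVector]
        Per-group parameter estimates.
    standard_errors_ : dict[str, dict[str, float]]
        Expected-information standard errors (NaN at boundary estimates).
    g_squared_, df_, p_value_ : float, int, float
        Goodness of fit against the saturated model.
    log_likelihood_ : float
    converged_ : bool
    n_total_ : int
        Total test decisions across groups.
    result_ : FitResult

    Examples
    --------
    >>> from punishmpt.model import FrequencyTable
    >>> tab = FrequencyTable([30, 10, 20, 20, 20, 20, 20, 20])
    >>> est = CooperationPunishmentMLE().fit({"control": tab})
    >>> round(est.estimates_["control"].c, 3)
    0.5
    """

    def __init__(
        self,
        constraints: Sequence = (),
        n_restarts: int = 10,
        tol: float = 1e-10,
        random_state: int = 0,
        max_iter: int = 1000,
    ) -> None:
        self.constraints = constraints
        self.n_restarts = n_restarts
        self.tol = tol
        self.random_state = random_state
        self.max_iter = max_iter

    def _canonical_constraints(self) -> tuple[EqualityConstraint, ...]:
        out = []
        for con in self.constraints:
            if isinstance(con, EqualityConstraint):
                out.append(con)
            else:
                parameter, groups = con
                out.append(EqualityConstraint(parameter, tuple(groups)))
        return tuple(out)

    def fit(self, X: Mapping[str, FrequencyTable], y=None) -> "CooperationPunishmentMLE":
        """Fit from a mapping of group label to :class:`FrequencyTable`.

        Group order follows the mapping's insertion order.
        """
        if not isinstance(X, Mapping):
            raise TypeError(
                "X must be a mapping {group label: FrequencyTable}; aggregate "
                "trial logs first with punishmpt.pipeline.aggregate"
            )
        spec = ModelSpec(groups=tuple(X.keys()), constraints=self._canonical_constraints())
        options = FitOptions(
            n_restarts=self.n_restarts,
            tol=self.tol,
            seed=self.random_state,
            max_iter=self.max_iter,
        )
        result = _maximize(spec, X, options)
        self.spec_ = spec
        self.result_ = result
        self.estimates_ = result.estimates
        self.standard_errors_ = result.standard_errors
        self.g_squared_ = result.g_squared
        self.df_ = result.df
        self.p_value_ = result.p_value
        self.log_likelihood_ = result.log_likelihood
        self.converged_ = result.converged
        self.n_total_ = result.n_total
        self.n_free_ = result.n_free
        return self

    def score(self, X: Mapping[str, FrequencyTable], y=None) -> float:
        """Summed multinomial log-likelihood of ``X`` under the fitted parameters."""
        from .model import log_likelihood as _ll

        return float(
            sum(_ll(self.estimates_[g], table) for g, table in X.items())
        )

    def expected_counts(self, X: Mapping[str, FrequencyTable]) -> dict[str, np.ndarray]:
        """Per-group expected category counts at the fitted parameters."""
        return {
            g: expected_counts(
                self.estimates_[g], table.n_defect_tree, table.n_coop_tree
            )
            for g, table in X.items()
        }


def fit(
    spec: ModelSpec,
    tables: Mapping[str, FrequencyTable],
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit the model for a :class:`ModelSpec`; thin wrapper over the estimator."""
    return _maximize(spec, tables, options)


def nested_test(
    spec: ModelSpec,
    tables: Mapping[str, FrequencyTable],
    added_constraint: EqualityConstraint,
    options: FitOptions = FitOptions(),
) -> TestResult:
    """Likelihood-ratio test of one added equality constraint.

    ΔG² = G²(restricted) − G²(base) is referred to a central chi-square with
    df equal to the number of parameters the constraint removes; small
    negative ΔG² from optimizer noise is clipped to zero.
    """
    base = _maximize(spec, tables, options)
    restricted = _maximize(spec.with_constraint(added_constraint), tables, options)
    if restricted.n_free >= base.n_free:
        raise ValueError("added constraint does not restrict the model")
    delta = restricted.g_squared - base.g_squared
    if delta < -1e-6:
        raise RuntimeError(
            f"restricted model fit better than the base model (ΔG² = {delta:.3g}); "
            "optimization likely failed, rerun with more restarts"
        )
    delta = max(delta, 0.0)
    df = base.n_free - restricted.n_free
    p_value = float(chi2.sf(delta, df))
    w = effect_size_w(delta, base.n_total)
    return TestResult(
        delta_g_squared=delta, df=df, p_value=p_value, w=w, base=base, restricted=restricted
    )


def standard_errors(
    theta_hat: Mapping[str, ParameterVector],
    tables: Mapping[str, FrequencyTable],
    spec: ModelSpec,
) -> dict[str, dict[str, float]]:
    """Expected-information standard errors at given per-group estimates.

    Boundary estimates (within 1e-6 of 0 or 1) get NaN: the Wald approximation
    is undefined there.
    """
    index, n_free = _free_index(spec)
    theta_free = np.empty(n_free)
    for i, g in enumerate(spec.groups):
        theta_free[index[i]] = theta_hat[g].to_array()
    table_seq = [tables[g] for g in spec.groups]
    return _standard_errors_from_free(theta_free, index, table_seq, spec)
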