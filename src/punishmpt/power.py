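"""Chi-square power analysis for likelihood-ratio (ΔG²) tests.

Under an alternative with effect size w (Cohen), a chi-square-family test on
N observations has noncentrality λ = w²·N.  Power is the upper-tail mass of
the noncentral chi-square(df, λ) beyond the central critical value at α.
N counts observations, i.e. participants × test decisions per participant
(20 by default), not participants.

Three entry points mirror the standard G*Power modes: achieved power,
sensitivity (minimal detectable w at fixed N), and a-priori (minimal
participant count for a target power).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2, ncx2

__all__ = ["PowerSpec", "chi2_power", "sensitivity_w", "a_priori_n"]


@dataclass(frozen=True)
class PowerSpec:
    """A fully specified chi-square power problem."""

    alpha: float
    df: int
    w: float
    n_obs: int
    power: float

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must lie in (0, 1)")
        if self.df < 1:
            raise ValueError("df must be a positive integer")
        if self.w < 0:
            raise ValueError("w must be non-negative")
        if self.n_obs < 1:
            raise ValueError("n_obs must be at least 1")


def chi2_power(w: float, n_obs: float, df: int = 1, alpha: float = 0.05) -> float:
    """Achieved power of a chi-square test with effect size ``w`` on ``n_obs``.

    With w = 0 the noncentral distribution collapses to the central one and
    the power equals the nominal level α exactly.
    """
    if w < 0:
        raise ValueError("w must be non-negative")
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    if df < 1:
        raise ValueError("df must be a positive integer")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    lam = w * w * n_obs
    if lam == 0.0:
        return float(alpha)
    crit = chi2.ppf(1.0 - alpha, df)
    return float(ncx2.sf(crit, df, lam))


def sensitivity_w(
    target_power: float, n_obs: float, df: int = 1, alpha: float = 0.05
) -> float:
    """Minimal detectable effect size w at fixed sample size.

    Solves ``chi2_power(w, n_obs, df, alpha) = target_power`` by bisection on
    w in [0, 1] to an absolute tolerance of 1e-8.
    """
    if not (alpha < target_power < 1):
        raise ValueError("target_power must lie in (alpha, 1)")
    lo, hi = 0.0, 1.0
    if chi2_power(hi, n_obs, df, alpha) < target_power:
        raise ValueError(
            f"target power {target_power} is unreachable with n_obs={n_obs} "
            "even at w = 1; increase the sample size"
        )
    while hi - lo > 1e-8:
        mid = 0.5 * (lo + hi)
        if chi2_power(mid, n_obs, df, alpha) < target_power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def a_priori_n(
    w: float,
    target_power: float,
    decisions_per_participant: int = 20,
    df: int = 1,
    alpha: float = 0.05,
) -> int:
    """Smallest participant count reaching the target power.

    Each participant contributes ``decisions_per_participant`` observations to
    the noncentrality λ = w²·(n × decisions).  The integer search brackets by
    doubling, then scans linearly near the bracket.
    """
    if w <= 0:
        raise ValueError("w must be strictly positive for an a-priori analysis")
    if decisions_per_participant < 1:
        raise ValueError("decisions_per_participant must be at least 1")
    if not (alpha < target_power < 1):
        raise ValueError("target_power must lie in (alpha, 1)")

    def achieved(n: int) -> float:
        return chi2_power(w, n * decisions_per_participant, df, alpha)

    hi = 1
    while achieved(hi) < target_power:
        hi *= 2
        if hi > 10**9:
            raise ValueError("required sample size exceeds 1e9 participants")
    lo = hi // 2 if hi > 1 else 0
    # narrow the bracket, then scan the last stretch linearly
    while hi - lo > 64:
        mid = (lo + hi) // 2
        if achieved(mid) < target_power:
            lo = mid
        else:
            hi = mid
    n = lo + 1
    while achieved(n) < target_power:
        n += 1
    return n
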