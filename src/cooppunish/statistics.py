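"""Chi-square p-values, Cohen's w, and power/sensitivity for G² tests.

The effect-size and power conventions match standard power-analysis software
for chi-square tests: ``w = sqrt(statistic / N)`` and noncentrality
``λ = N·w²``.  N is the *total decision count* entering the test —
participants times analysed trials — not the number of participants; this is
the convention under which the effect sizes of restriction tests on pooled
multinomial counts are on Cohen's scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize, stats


@dataclass(frozen=True)
class PowerQuery:
    """One power or sensitivity query for a chi-square-distributed test.

    Attributes
    ----------
    n_observations : int
        Total decision count N entering the statistic (participants × trials).
    df : int
        Degrees of freedom of the test (1 for a single equality restriction).
    alpha : float
        Significance level.
    w : float, optional
        Cohen's effect size (for :func:`power`).
    power : float, optional
        Target power 1 − β (for :func:`sensitivity_w`).
    """

    n_observations: int
    df: int = 1
    alpha: float = 0.05
    w: float | None = None
    power: float | None = None

    def __post_init__(self) -> None:
        if self.n_observations <= 0:
            raise ValueError("n_observations must be positive")
        if self.df < 1:
            raise ValueError("df must be at least 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.w is not None and self.w < 0:
            raise ValueError("w must be non-negative")
        if self.power is not None and not (0 < self.power < 1):
            raise ValueError("target power must lie in (0, 1)")


def chi_square_p(statistic: float, df: int) -> float:
    """Survival function of the central chi-square: P(X² ≥ statistic)."""
    if statistic < 0:
        raise ValueError(f"chi-square statistic must be ≥ 0, got {statistic}")
    if df < 1:
        raise ValueError(f"df must be ≥ 1, got {df}")
    return float(stats.chi2.sf(statistic, df))


def cohens_w(statistic: float, n_observations: float) -> float:
    """Cohen's w effect size: sqrt(statistic / N).

    N is the total observation count the statistic was computed over (here,
    total decisions = participants × analysed trials).
    """
    if statistic < 0:
        raise ValueError(f"statistic must be ≥ 0, got {statistic}")
    if n_observations <= 0:
        raise ValueError(f"n_observations must be positive, got {n_observations}")
    return math.sqrt(statistic / n_observations)


def power(query: PowerQuery) -> float:
    """Achieved power of a chi-square test at effect size w.

    ``1 − F_ncx2(q; df, λ)`` with ``q`` the central (1 − α) quantile and
    noncentrality ``λ = N·w²``.  At w = 0 this reduces to α.
    """
    if query.w is None:
        raise ValueError("PowerQuery.w is required for a power computation")
    q = stats.chi2.ppf(1 - query.alpha, query.df)
    lam = query.n_observations * query.w**2
    if lam == 0:
        return query.alpha
    return float(stats.ncx2.sf(q, query.df, lam))


def sensitivity_w(query: PowerQuery) -> float:
    """Minimal detectable effect size w reaching the target power.

    Solves ``power(w) = target`` by bracketing; exact 0 when the target
    equals α (the null effect).  Raises if the target power is unreachable
    at any finite w (it is not, for valid inputs, but the guard documents
    the contract).
    """
    if query.power is None:
        raise ValueError("PowerQuery.power is required for a sensitivity analysis")
    target = query.power
    if target <= query.alpha:
        return 0.0

    def gap(w: float) -> float:
        return power(PowerQuery(query.n_observations, query.df, query.alpha, w=w)) - target

    hi = 0.1
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise ValueError(
                f"target power {target} unreachable at N={query.n_observations}"
            )
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-12, rtol=8.9e-16))
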