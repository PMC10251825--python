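"""Statistical power for binary-outcome MR designs and multiple-testing control.

The power computation is the standard noncentrality calculation for an
instrumental-variable test of a binary outcome (the approach used by the
mRnd calculator), reproduced here so the pipeline has no web dependency:
with outcome sample size N, exposure variance explained by the instruments
R²(xz), case fraction K, and target odds ratio OR,

    b   = K (OR / (1 + K (OR - 1)) - 1)
    v   = (K (1 - K) - b²) / (N R²)
    NCP = b² / v

and the power is the upper-tail probability of a noncentral chi-square
(1 df, NCP) beyond the central chi-square critical value at 1 - α.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import DomainError

__all__ = ["PowerInput", "mr_power_binary", "bonferroni_threshold", "bonferroni_flags"]


@dataclass(frozen=True)
class PowerInput:
    """Inputs to the binary-outcome MR power computation."""

    n: int
    r2_xz: float
    k_case: float
    or_target: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DomainError("n must be positive")
        if not 0 < self.r2_xz < 1:
            raise DomainError("r2_xz must be in (0, 1)")
        if not 0 < self.k_case < 1:
            raise DomainError("k_case must be in (0, 1)")
        if not self.or_target > 0:
            raise DomainError("or_target must be > 0")
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must be in (0, 1)")


def mr_power_binary(p: PowerInput) -> float:
    """Power of a two-sided MR test of a binary outcome at level alpha.

    Returns exactly ``alpha`` when ``or_target`` is 1 (zero noncentrality).
    """
    b = p.k_case * (p.or_target / (1.0 + p.k_case * (p.or_target - 1.0)) - 1.0)
    v = (p.k_case * (1.0 - p.k_case) - b * b) / (p.n * p.r2_xz)
    if v <= 0:
        raise DomainError("degenerate parameterization: nonpositive variance")
    if b == 0.0:
        return float(p.alpha)
    ncp = b * b / v
    crit = stats.chi2.isf(p.alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    if m < 1:
        raise DomainError("m must be a positive integer")
    return alpha / m


def bonferroni_flags(pvals, alpha: float, m: int):
    """Boolean flags: p strictly below the Bonferroni threshold alpha / m."""
    import numpy as np

    thr = bonferroni_threshold(alpha, m)
    return np.asarray(pvals, dtype=float) < thr
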