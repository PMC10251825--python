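"""Causal-effect estimators and diagnostics for two-sample MR.

Each method is a scikit-learn-style estimator: construct with
hyperparameters, call :meth:`fit` on a harmonized instrument table, and
read fitted attributes (``beta_``, ``se_``, ``ci_low_``, ``pvalue_``, ...).
``fit`` accepts a :class:`~mrscreen.harmonize.HarmonizedInstrumentSet`, a
DataFrame with ``beta_x``/``se_x``/``beta_y``/``se_y`` columns, or an
(n_snp, 4) array in that column order.

Methods
-------
WaldRatio
    Single-instrument ratio estimate beta_y / beta_x with first-order SE.
IVW
    Inverse-variance-weighted estimate: the weighted zero-intercept
    regression of outcome on exposure effects with weights se_y^-2,
    equivalently the inverse-variance meta-analysis of per-instrument Wald
    ratios. Fixed or multiplicative random effects (SE inflated by
    max(1, sqrt(Q / (J - 1)))).
MREgger
    Weighted regression with a free intercept after orienting exposure
    effects non-negative; the slope estimates the causal effect under
    InSIDE and the intercept the average directional pleiotropy.
WeightedMedian
    Median of the inverse-variance-weighted empirical distribution of
    per-instrument ratios; consistent when valid instruments carry over
    half the weight. SE by seeded parametric bootstrap.
WeightedMode
    Mode of a kernel-smoothed weighted density of per-instrument ratios
    (modified-Silverman bandwidth); consistent when the largest group of
    instruments sharing a ratio is valid. SE by seeded parametric bootstrap.

Cochran's Q heterogeneity and the Egger intercept test are exposed both as
fitted attributes and through :func:`cochran_q` / :func:`egger`.
Module-level functions (:func:`wald_ratio`, :func:`ivw`, ...) are thin
wrappers returning :class:`MREstimate` records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateModelError,
    DomainError,
    EmptyDatasetError,
    InsufficientInstrumentsError,
)

__all__ = [
    "MREstimate",
    "DiagnosticsResult",
    "WaldRatio",
    "IVW",
    "MREgger",
    "WeightedMedian",
    "WeightedMode",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "weighted_median",
    "weighted_mode",
    "estimate_all",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds scale plus OR scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))


@dataclass(frozen=True)
class DiagnosticsResult:
    """Cochran's Q heterogeneity and MR-Egger intercept (pleiotropy) tests."""

    q: float
    q_df: int
    q_pval: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    @property
    def heterogeneous(self) -> bool:
        """True iff the Q test rejects at the 0.05 level."""
        return self.q_pval <= 0.05


def _as_effects(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coerce input to (beta_x, se_x, beta_y, se_y) float arrays."""
    if hasattr(X, "to_frame") and hasattr(X, "instruments"):  # HarmonizedInstrumentSet
        X = X.to_frame()
    if isinstance(X, pd.DataFrame):
        arr = X[["beta_x", "se_x", "beta_y", "se_y"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("expected an (n_snp, 4) array of beta_x, se_x, beta_y, se_y")
    if arr.shape[0] == 0:
        raise EmptyDatasetError("empty harmonized instrument set")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in harmonized effects")
    if np.any(arr[:, 1] <= 0) or np.any(arr[:, 3] <= 0):
        raise ValueError("standard errors must be > 0")
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


class _BaseMR(BaseEstimator):
    """Shared fit plumbing and normal/t inference for MR estimators."""

    method_name: str = ""
    min_snp: int = 1

    def _finalize(self, beta: float, se: float, n_snp: int, df: int | None = None) -> None:
        self.beta_ = float(beta)
        self.se_ = float(se)
        self.n_snp_ = int(n_snp)
        self.ci_low_ = self.beta_ - _Z95 * self.se_
        self.ci_high_ = self.beta_ + _Z95 * self.se_
        if se > 0:
            t = beta / se
            if df is None:
                self.pvalue_ = float(2.0 * stats.norm.sf(abs(t)))
            else:
                self.pvalue_ = float(2.0 * stats.t.sf(abs(t), df))
        else:
            self.pvalue_ = 0.0 if beta != 0 else 1.0

    def _check_size(self, n: int) -> None:
        if n < self.min_snp:
            raise InsufficientInstrumentsError(
                f"{self.method_name} requires at least {self.min_snp} instruments, got {n}"
                + (" (use WaldRatio for a single instrument)" if self.min_snp == 2 else "")
            )

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method=self.method_name,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            pval=self.pvalue_,
            n_snp=self.n_snp_,
        )


class WaldRatio(_BaseMR):
    """Single-instrument causal estimate beta_y / beta_x.

    The SE is the first-order (no-measurement-error) approximation
    se_y / abs(beta_x); inference is normal.
    """

    method_name = "wald_ratio"
    min_snp = 1

    def fit(self, X, y=None):
        bx, sx, by, sy = _as_effects(X)
        if bx.shape[0] != 1:
            raise InsufficientInstrumentsError(
                f"wald_ratio is defined for exactly one instrument, got {bx.shape[0]}"
            )
        if bx[0] == 0:
            raise DomainError("wald_ratio undefined for beta_x = 0")
        self._finalize(by[0] / bx[0], sy[0] / abs(bx[0]), 1)
        return self


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect IVW beta, its SE, and Cochran's Q."""
    w = sy**-2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise DegenerateModelError("all exposure effects are zero")
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


class IVW(_BaseMR):
    """Inverse-variance-weighted estimator.

    Parameters
    ----------
    effects_model : {"multiplicative_random", "fixed"}
        Fixed effects use SE = (sum w beta_x^2)^(-1/2); multiplicative
        random effects inflate it by max(1, sqrt(Q / (J - 1))) so that
        between-instrument heterogeneity widens the interval but can never
        tighten it.

    Fitted attributes include ``q_``, ``q_df_``, ``q_pvalue_``.
    """

    method_name = "ivw"
    min_snp = 2

    def __init__(self, effects_model: str = "multiplicative_random"):
        self.effects_model = effects_model

    def fit(self, X, y=None):
        if self.effects_model not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown effects_model {self.effects_model!r}")
        bx, sx, by, sy = _as_effects(X)
        self._check_size(bx.shape[0])
        n = bx.shape[0]
        beta, se_fixed, q = _ivw_core(bx, by, sy)
        self.q_ = q
        self.q_df_ = n - 1
        self.q_pvalue_ = float(stats.chi2.sf(q, n - 1))
        se = se_fixed
        if self.effects_model == "multiplicative_random":
            se *= max(1.0, np.sqrt(q / (n - 1)))
        self._finalize(beta, se, n)
        self.method_name = (
            "ivw_fixed" if self.effects_model == "fixed" else "ivw_mre"
        )
        return self


class MREgger(_BaseMR):
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Pairs are oriented so beta_x >= 0 (both betas negated where beta_x is
    negative), then beta_y is regressed on beta_x with weights se_y^-2.
    The residual dispersion used for standard errors is floored at 1 (an
    underdispersed fit must not shrink the interval below the fixed-effect
    one); p-values use the t distribution with J - 2 df.

    Fitted attributes: ``beta_`` (slope), ``intercept_``, ``intercept_se_``,
    ``intercept_pvalue_``, ``scale_`` (floored dispersion).
    """

    method_name = "egger"
    min_snp = 3

    def fit(self, X, y=None):
        bx, sx, by, sy = _as_effects(X)
        n = bx.shape[0]
        self._check_size(n)
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        if np.ptp(bx) == 0:
            raise DegenerateModelError("constant exposure effects: Egger slope unidentified")
        w = sy**-2.0
        design = sm.add_constant(bx)
        fit = sm.WLS(by, design, weights=w).fit()
        scale = float(fit.scale)  # weighted RSS / (J - 2)
        self.scale_ = max(1.0, scale)
        cov = np.asarray(fit.normalized_cov_params) * self.scale_
        se_int, se_slope = np.sqrt(np.diag(cov))
        intercept, slope = fit.params
        df = n - 2
        self._finalize(slope, se_slope, n, df=df)
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_int)
        self.intercept_pvalue_ = float(2.0 * stats.t.sf(abs(intercept / se_int), df))
        return self

    def intercept_test(self) -> DiagnosticsResult:
        """Egger intercept (directional pleiotropy) test as a diagnostics record."""
        return DiagnosticsResult(
            q=float("nan"), q_df=self.n_snp_ - 1, q_pval=float("nan"),
            egger_intercept=self.intercept_,
            egger_intercept_se=self.intercept_se_,
            egger_intercept_pval=self.intercept_pvalue_,
        )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Median of the weighted empirical CDF with linear interpolation."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5, side="right")) - 1
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    spread_candidates = [s for s in (sd, mad) if s > 0]
    if not spread_candidates:
        return 0.0
    return factor * 0.9 * min(spread_candidates) * ratios.size ** (-0.2)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                         bandwidth_factor: float, grid_size: int = 512) -> float:
    h = _mode_bandwidth(ratios, bandwidth_factor)
    lo, hi = float(ratios.min()), float(ratios.max())
    if h == 0.0 or lo == hi:
        # all ratios (effectively) identical: the mode is the common ratio
        return float(np.average(ratios, weights=weights))
    grid = np.linspace(lo, hi, grid_size)
    dens = (weights[None, :] * stats.norm.pdf((grid[:, None] - ratios[None, :]) / h)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


class _RatioBootstrapMR(_BaseMR):
    """Shared machinery for ratio-based estimators with bootstrap SEs.

    The parametric bootstrap perturbs each per-instrument ratio with its
    first-order (delta-method) SE se_y / |beta_x| and re-evaluates the point
    estimator; weights are held fixed. ``n_boot = 0`` skips the bootstrap
    (SE, CI and p become NaN), useful for pure point-estimate studies.
    """

    min_snp = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def _point(self, ratios: np.ndarray, weights: np.ndarray) -> float:
        raise NotImplementedError

    def fit(self, X, y=None):
        bx, sx, by, sy = _as_effects(X)
        n = bx.shape[0]
        self._check_size(n)
        if np.any(bx == 0):
            raise DomainError("per-instrument ratios undefined for beta_x = 0")
        ratios = by / bx
        ratio_se = sy / np.abs(bx)
        weights = (bx / sy) ** 2
        point = self._point(ratios, weights)
        if self.n_boot > 0:
            rng = np.random.default_rng(self.seed)
            draws = ratios[None, :] + ratio_se[None, :] * rng.standard_normal((self.n_boot, n))
            boots = np.array([self._point(d, weights) for d in draws])
            se = float(np.std(boots, ddof=1))
        else:
            se = float("nan")
        self._finalize(point, se, n)
        if not np.isfinite(se):
            self.pvalue_ = float("nan")
        return self


class WeightedMedian(_RatioBootstrapMR):
    """Weighted-median estimator over per-instrument Wald ratios.

    Weights are (beta_x / se_y)^2, i.e. inverse variances of the ratios to
    first order; the estimate interpolates the weighted empirical CDF at
    one half. Consistent when valid instruments carry > 50% of the weight.
    """

    method_name = "weighted_median"

    def _point(self, ratios, weights):
        return _weighted_median_point(ratios, weights)


class WeightedMode(_RatioBootstrapMR):
    """Weighted-mode estimator over per-instrument Wald ratios.

    A Gaussian-kernel weighted density of the ratios is evaluated on a
    512-point grid spanning their range; the estimate is the argmax. The
    bandwidth is modified-Silverman, bandwidth_factor * 0.9 *
    min(sd, 1.4826 * MAD) * J^(-1/5).
    """

    method_name = "weighted_mode"

    def __init__(self, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0):
        super().__init__(n_boot=n_boot, seed=seed)
        self.bandwidth_factor = bandwidth_factor

    def _point(self, ratios, weights):
        return _weighted_mode_point(ratios, weights, self.bandwidth_factor)


# ---------------------------------------------------------------------------
# functional wrappers


def wald_ratio(h) -> MREstimate:
    """Wald ratio estimate for a single harmonized instrument.

    Accepts a HarmonizedInstrument, a 1-row table, or a length-4 sequence.
    """
    if hasattr(h, "beta_x"):
        X = np.array([[h.beta_x, h.se_x, h.beta_y, h.se_y]])
    elif isinstance(h, pd.DataFrame) or (hasattr(h, "to_frame") and hasattr(h, "instruments")):
        X = h
    else:
        X = np.asarray(h, dtype=float).reshape(1, 4)
    return WaldRatio().fit(X).to_estimate()


def ivw(hs, effects_model: str = "multiplicative_random") -> MREstimate:
    """IVW causal estimate (multiplicative random effects by default)."""
    return IVW(effects_model=effects_model).fit(hs).to_estimate()


def cochran_q(hs, beta_ivw: float | None = None) -> DiagnosticsResult:
    """Cochran's Q heterogeneity test about the (fixed-effect) IVW estimate.

    Q = sum w_j (beta_y_j - beta * beta_x_j)^2 with w_j = se_y_j^-2;
    p is upper-tail chi-square on J - 1 df. ``beta_ivw`` overrides the
    internally computed fixed-effect estimate when supplied.
    """
    bx, sx, by, sy = _as_effects(hs)
    n = bx.shape[0]
    if n < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires at least 2 instruments")
    if beta_ivw is None:
        beta_ivw, _, _ = _ivw_core(bx, by, sy)
    w = sy**-2
    q = float(np.sum(w * (by - beta_ivw * bx) ** 2))
    return DiagnosticsResult(q=q, q_df=n - 1, q_pval=float(stats.chi2.sf(q, n - 1)))


def egger(hs) -> tuple[MREstimate, DiagnosticsResult]:
    """MR-Egger slope estimate plus the intercept (pleiotropy) test."""
    est = MREgger().fit(hs)
    return est.to_estimate(), est.intercept_test()


def weighted_median(hs, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    return WeightedMedian(n_boot=n_boot, seed=seed).fit(hs).to_estimate()


def weighted_mode(hs, bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MREstimate:
    return WeightedMode(bandwidth_factor=bandwidth_factor, n_boot=n_boot,
                        seed=seed).fit(hs).to_estimate()


def estimate_all(hs, seed: int = 0, n_boot: int = 1000,
                 effects_model: str = "multiplicative_random",
                 ) -> tuple[list[MREstimate], DiagnosticsResult | None]:
    """Run every applicable method on a harmonized set.

    Dispatch follows instrument count: one instrument gives the Wald ratio
    only; two give IVW plus Cochran's Q; three or more add MR-Egger (with
    the intercept test), weighted median and weighted mode.
    """
    bx, sx, by, sy = _as_effects(hs)
    n = bx.shape[0]
    X = np.column_stack([bx, sx, by, sy])
    if n == 1:
        return [wald_ratio(X[0])], None
    ivw_fit = IVW(effects_model=effects_model).fit(X)
    estimates = [ivw_fit.to_estimate()]
    diag = DiagnosticsResult(q=ivw_fit.q_, q_df=ivw_fit.q_df_, q_pval=ivw_fit.q_pvalue_)
    if n >= 3:
        egger_fit = MREgger().fit(X)
        estimates.append(egger_fit.to_estimate())
        estimates.append(weighted_median(X, n_boot=n_boot, seed=seed))
        estimates.append(weighted_mode(X, n_boot=n_boot, seed=seed))
        diag = DiagnosticsResult(
            q=diag.q, q_df=diag.q_df, q_pval=diag.q_pval,
            egger_intercept=egger_fit.intercept_,
            egger_intercept_se=egger_fit.intercept_se_,
            egger_intercept_pval=egger_fit.intercept_pvalue_,
        )
    return estimates, diag
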