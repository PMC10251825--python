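"""Reference simulation studies: the package's standing evaluation suite.

Each function runs a self-contained Monte-Carlo study of one statistical
property of the pipeline — estimator recovery, test calibration, robustness
under pleiotropy, heterogeneity calibration, and the null multi-exposure
screen — at fixed scenario configurations, and returns summary metrics.
The scenarios are documented in the methods note; the test suite asserts
their expected outcomes and the reproduction script reports their numbers.

All randomness derives from an explicit ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .estimators import IVW, MREgger, WeightedMedian
from .simulate import SimulationConfig, harmonized_truth_set, make_screen_fixture, simulate_two_sample
from .pipeline import screen_datasets

__all__ = [
    "recovery_study",
    "type1_study",
    "robustness_study",
    "heterogeneity_study",
    "null_screen_study",
]

#: study conditions shared by the simulation studies: 100 instruments,
#: exposure GWAS of 50,000, outcome GWAS of 100,000 with a rare-disease
#: case fraction; palindromic variants disabled so the instrument count
#: is exactly J in every replicate (the palindromic path has its own tests)
_BASE = dict(n_snp=100, n_exposure=50_000, n_outcome=100_000,
             palindromic_fraction=0.0)


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _replicates(cfg_kwargs: dict, seed: int, n_reps: int):
    for s in _sub_seeds(seed, n_reps):
        cfg = SimulationConfig(seed=int(s), **cfg_kwargs)
        exp, out, _, truth = simulate_two_sample(cfg)
        yield harmonized_truth_set(exp, out, truth)


def recovery_study(seed: int = 0, n_reps: int = 200, true_beta: float = 0.2) -> dict:
    """IVW bias and 95% CI coverage under a true causal effect, no pleiotropy."""
    betas, covered = [], 0
    for hs in _replicates({**_BASE, "true_beta": true_beta}, seed, n_reps):
        fit = IVW().fit(hs)
        betas.append(fit.beta_)
        covered += fit.ci_low_ <= true_beta <= fit.ci_high_
    betas = np.asarray(betas)
    mc_se = float(betas.std(ddof=1) / np.sqrt(n_reps))
    return dict(
        n_reps=n_reps,
        true_beta=true_beta,
        mean_estimate=float(betas.mean()),
        mean_bias=float(betas.mean() - true_beta),
        mc_se=mc_se,
        coverage=covered / n_reps,
    )


def type1_study(seed: int = 0, n_reps: int = 500) -> dict:
    """Rejection rates at alpha = 0.05 under the null with balanced pleiotropy.

    Balanced zero-mean pleiotropy on every instrument, scaled to be
    comparable to the outcome-side SE so heterogeneity is genuinely present;
    the multiplicative-random-effects IVW test and the Egger intercept test
    should both stay near nominal level.
    """
    cfg = {**_BASE, "true_beta": 0.0, "pleiotropy_mode": "balanced",
           "invalid_fraction": 1.0, "pleiotropy_sd": 0.1}
    rej_ivw = rej_egger_int = 0
    for hs in _replicates(cfg, seed, n_reps):
        rej_ivw += IVW().fit(hs).pvalue_ <= 0.05
        rej_egger_int += MREgger().fit(hs).intercept_pvalue_ <= 0.05
    lo, hi = (np.array(stats.binom.interval(0.95, n_reps, 0.05)) / n_reps)
    return dict(
        n_reps=n_reps,
        ivw_rejection_rate=rej_ivw / n_reps,
        egger_intercept_rejection_rate=rej_egger_int / n_reps,
        binomial_low=float(lo),
        binomial_high=float(hi),
    )


def robustness_study(seed: int = 0, n_reps: int = 200, true_beta: float = 0.2) -> dict:
    """Estimator bias under directional pleiotropy on 40% of instruments.

    Run in the NOME regime (exposure effects measured in 2,000,000 people,
    balanced outcome) so that exposure-side regression dilution does not
    confound the comparison: the weighted median should be less biased than
    fixed-effect IVW, and the Egger slope unbiased (InSIDE holds).
    """
    cfg = {**_BASE, "true_beta": true_beta, "pleiotropy_mode": "directional",
           "invalid_fraction": 0.4, "pleiotropy_mean": 0.02, "pleiotropy_sd": 0.01,
           "n_exposure": 2_000_000, "outcome_case_fraction": 0.5}
    wm, ivw_fixed, egger_slope = [], [], []
    for hs in _replicates(cfg, seed, n_reps):
        wm.append(WeightedMedian(n_boot=0).fit(hs).beta_)
        ivw_fixed.append(IVW(effects_model="fixed").fit(hs).beta_)
        egger_slope.append(MREgger().fit(hs).beta_)
    wm, ivw_fixed, egger_slope = map(np.asarray, (wm, ivw_fixed, egger_slope))
    return dict(
        n_reps=n_reps,
        true_beta=true_beta,
        weighted_median_abs_bias=float(abs(wm.mean() - true_beta)),
        ivw_fixed_abs_bias=float(abs(ivw_fixed.mean() - true_beta)),
        egger_slope_mean_error=float(egger_slope.mean() - true_beta),
        egger_slope_mc_se=float(egger_slope.std(ddof=1) / np.sqrt(n_reps)),
    )


def heterogeneity_study(seed: int = 0, n_reps: int = 500, true_beta: float = 0.2) -> dict:
    """Cochran's Q calibration on homogeneous (pleiotropy-free) data.

    Q/(J-1) should average 1 and the Q p-values should be uniform.
    """
    q_over_df, pvals = [], []
    for hs in _replicates({**_BASE, "true_beta": true_beta}, seed, n_reps):
        fit = IVW().fit(hs)
        q_over_df.append(fit.q_ / fit.q_df_)
        pvals.append(fit.q_pvalue_)
    q_over_df = np.asarray(q_over_df)
    ks = stats.kstest(pvals, "uniform")
    return dict(
        n_reps=n_reps,
        mean_q_over_df=float(q_over_df.mean()),
        mc_se=float(q_over_df.std(ddof=1) / np.sqrt(n_reps)),
        ks_pvalue=float(ks.pvalue),
    )


def null_screen_study(seed: int = 0, n_exposures: int = 187) -> dict:
    """An all-null multi-exposure screen with Bonferroni correction.

    Mirrors a phenome-scale cytokine screen: every exposure has zero causal
    effect, so nominal p < 0.05 counts should be binomial and nothing should
    survive correction at alpha / m.
    """
    fixture = make_screen_fixture(n_exposures, seed=seed, true_beta=0.0)
    result = screen_datasets(
        fixture.exposures, fixture.outcome, fixture.panel,
        n_boot=200, seed=seed + 1,
    )
    primary = result.forest[result.forest["method"].isin(["ivw_mre", "wald_ratio"])]
    n_tested = int(primary["exposure"].nunique())
    n_nominal = int((primary["pval"] < 0.05).sum())
    n_bonferroni = int(primary["bonferroni_significant"].sum())
    lo, hi = stats.binom.interval(0.95, n_tested, 0.05)
    return dict(
        n_exposures=n_exposures,
        n_tested=n_tested,
        n_nominal_significant=n_nominal,
        n_bonferroni_significant=n_bonferroni,
        binomial_low=int(lo),
        binomial_high=int(hi),
        bonferroni_threshold=0.05 / n_tested if n_tested else float("nan"),
    )
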