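"""MR estimators against independent algebraic, grid, and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrscreen import (
    IVW,
    DomainError,
    InsufficientInstrumentsError,
    MREgger,
    WeightedMedian,
    WeightedMode,
    cochran_q,
    egger,
    estimate_all,
    ivw,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import random_effects_frame


def frame(bx, sy, by, sx=None):
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sx = np.full_like(bx, 0.01, dtype=float) if sx is None else np.asarray(sx)
    return pd.DataFrame(dict(beta_x=bx, se_x=sx, beta_y=by, se_y=sy))


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,beta,se",
        [(0.1, 0.05, 0.02, 0.5, 0.2), (0.1, 0.0, 0.02, 0.0, 0.2),
         (-0.1, 0.05, 0.02, -0.5, 0.2)],
    )
    def test_direct_arithmetic(self, bx, by, sy, beta, se):
        est = wald_ratio([bx, 0.01, by, sy])
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)
        if by == 0:
            assert est.or_value == pytest.approx(1.0)

    def test_zero_exposure_effect_is_undefined(self):
        with pytest.raises(DomainError):
            wald_ratio([0.0, 0.01, 0.05, 0.02])


class TestIVW:
    def test_duplicated_instrument_equals_wald(self):
        X = frame([0.1, 0.1], [0.02, 0.02], [0.05, 0.05])
        assert ivw(X).beta == pytest.approx(0.5)

    def test_two_instrument_meta_analysis_oracle(self):
        # hand-combined inverse-variance meta-analysis of the Wald ratios
        bx = np.array([0.1, 0.2])
        by = np.array([0.04, 0.12])  # ratios 0.4 and 0.6
        sy = np.array([0.02, 0.03])
        ratios = by / bx
        w = (bx / sy) ** 2
        expected = np.sum(w * ratios) / np.sum(w)
        est = ivw(frame(bx, sy, by), effects_model="fixed")
        assert 0.4 < est.beta < 0.6
        assert est.beta == pytest.approx(expected, abs=1e-12)
        assert est.se == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)

    def test_null_outcome_gives_or_one(self):
        est = ivw(frame([0.1, 0.2, 0.15], [0.02, 0.02, 0.02], [0.0, 0.0, 0.0]))
        assert est.beta == 0.0 and est.or_value == 1.0

    def test_fixed_equals_wald_meta_on_random_sets(self, rng):
        for _ in range(20):
            df = random_effects_frame(rng, int(rng.integers(2, 30)))
            bx, by, sy = df["beta_x"].values, df["beta_y"].values, df["se_y"].values
            w = (bx / sy) ** 2
            expected = np.sum(w * (by / bx)) / np.sum(w)
            assert ivw(df, effects_model="fixed").beta == pytest.approx(expected, abs=1e-10)

    def test_mre_se_never_below_fixed(self, rng):
        df = random_effects_frame(rng, 15)
        assert ivw(df).se >= ivw(df, effects_model="fixed").se

    def test_single_instrument_directs_to_wald(self):
        with pytest.raises(InsufficientInstrumentsError, match="WaldRatio"):
            ivw(frame([0.1], [0.02], [0.05]))


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        X = frame([0.1, 0.2, 0.3], [0.02, 0.02, 0.02], [0.05, 0.10, 0.15])
        d = cochran_q(X)
        assert d.q == pytest.approx(0.0, abs=1e-20)
        assert d.q_pval == pytest.approx(1.0)
        assert d.q_df == 2
        assert not d.heterogeneous

    def test_direct_summation_oracle(self, rng):
        df = random_effects_frame(rng, 10)
        bx, by, sy = df["beta_x"].values, df["beta_y"].values, df["se_y"].values
        beta = ivw(df, effects_model="fixed").beta
        expected = sum(
            (by[j] - beta * bx[j]) ** 2 / sy[j] ** 2 for j in range(10)
        )
        assert cochran_q(df).q == pytest.approx(expected, abs=1e-10)

    def test_chi_square_calibration(self, rng):
        # homogeneous sets: Q/(J-1) should average 1 over replicates
        reps, J, beta = 200, 12, 0.3
        qs = []
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.15, J)
            sy = rng.uniform(0.01, 0.05, J)
            by = beta * bx + sy * rng.standard_normal(J)
            qs.append(cochran_q(frame(bx, sy, by)).q / (J - 1))
        mc_se = np.std(qs) / np.sqrt(reps)
        assert np.mean(qs) == pytest.approx(1.0, abs=3 * mc_se)


class TestMREgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.02 + 0.5 * bx
        fit = MREgger().fit(frame(bx, [0.02, 0.02, 0.02, 0.02], by))
        assert fit.beta_ == pytest.approx(0.5, abs=1e-10)
        assert fit.intercept_ == pytest.approx(0.02, abs=1e-10)
        assert fit.scale_ == 1.0  # residual dispersion at its floor

    def test_normal_equations_oracle(self, rng):
        df = random_effects_frame(rng, 10)
        bx, by, sy = df["beta_x"].values.copy(), df["beta_y"].values.copy(), df["se_y"].values
        sign = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * sign, by * sign
        w = sy**-2.0
        # hand-rolled weighted normal equations
        X = np.column_stack([np.ones_like(bxo), bxo])
        XtWX = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(XtWX, X.T @ (w * byo))
        resid = byo - X @ coef
        scale = max(1.0, float(np.sum(w * resid**2) / (len(bx) - 2)))
        cov = np.linalg.inv(XtWX) * scale
        fit = MREgger().fit(df)
        assert fit.intercept_ == pytest.approx(coef[0], abs=1e-10)
        assert fit.beta_ == pytest.approx(coef[1], abs=1e-10)
        assert fit.intercept_se_ == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)
        assert fit.se_ == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_intercept_test_calibrated_under_balanced_pleiotropy(self, rng):
        reps, J = 300, 25
        rejections = 0
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.15, J)
            sy = rng.uniform(0.02, 0.05, J)
            alpha = rng.normal(0.0, 0.03, J)  # zero-mean pleiotropy
            by = 0.2 * bx + alpha + sy * rng.standard_normal(J)
            fit = MREgger().fit(frame(bx, sy, by))
            rejections += fit.intercept_pvalue_ <= 0.05
        rate = rejections / reps
        lo, hi = stats.binom.interval(0.999, reps, 0.05)
        assert lo / reps <= rate <= hi / reps

    def test_degenerate_regressor_rejected(self):
        from mrscreen import DegenerateModelError

        X = frame([0.1, 0.1, 0.1], [0.02, 0.02, 0.02], [0.05, 0.04, 0.06])
        with pytest.raises(DegenerateModelError):
            MREgger().fit(X)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        X = frame([0.1, 0.1, 0.1], [0.02, 0.02, 0.02], [0.1, 0.2, 0.3])
        est = weighted_median(X, n_boot=50, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_grid_oracle(self, rng):
        df = random_effects_frame(rng, 5)
        bx, by, sy = df["beta_x"].values, df["beta_y"].values, df["se_y"].values
        ratios, w = by / bx, (bx / sy) ** 2
        order = np.argsort(ratios)
        r, wn = ratios[order], w[order] / w.sum()
        s = np.cumsum(wn) - wn / 2
        grid = np.linspace(r[0], r[-1], 100_001)
        cdf = np.interp(grid, r, s)
        oracle = grid[np.argmin(np.abs(cdf - 0.5))]
        est = weighted_median(df, n_boot=0)
        assert est.beta == pytest.approx(oracle, abs=(r[-1] - r[0]) / 100_000 + 1e-12)

    def test_majority_valid_beats_fixed_ivw_under_pleiotropy(self, rng):
        # 10 valid instruments (true beta 0.3) + 4 with strong directional
        # pleiotropy: the median stays near truth, fixed IVW is dragged away
        bx = rng.uniform(0.08, 0.15, 14)
        sy = np.full(14, 0.01)
        by = 0.3 * bx + sy * rng.standard_normal(14)
        by[10:] += 0.05  # directional pleiotropy
        X = frame(bx, sy, by)
        wm = weighted_median(X, n_boot=500, seed=7)
        fixed = ivw(X, effects_model="fixed")
        assert abs(wm.beta - 0.3) <= 2 * wm.se
        assert abs(fixed.beta - 0.3) > abs(wm.beta - 0.3)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(frame([0.1, 0.2], [0.02, 0.02], [0.05, 0.1]))


class TestWeightedMode:
    def test_point_mass_returns_common_ratio(self):
        X = frame([0.1, 0.2, 0.3], [0.02, 0.02, 0.02], [0.07, 0.14, 0.21])
        est = weighted_mode(X, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.7)
        assert np.isfinite(est.se)  # SE still comes from the bootstrap

    def test_bimodal_picks_larger_mode(self, rng):
        ratios = np.concatenate([rng.normal(0.0, 0.01, 7), rng.normal(0.8, 0.01, 3)])
        bx = np.full(10, 0.1)
        X = frame(bx, np.full(10, 0.01), ratios * bx)
        est = weighted_mode(X, n_boot=0)
        assert abs(est.beta) < 0.1

    def test_refinement_oracle(self, rng):
        from mrscreen.estimators import _mode_bandwidth

        df = random_effects_frame(rng, 8)
        bx, by, sy = df["beta_x"].values, df["beta_y"].values, df["se_y"].values
        ratios, w = by / bx, (bx / sy) ** 2
        h = _mode_bandwidth(ratios, 1.0)
        fine = np.linspace(ratios.min(), ratios.max(), 5120)
        dens = (w[None, :] * stats.norm.pdf((fine[:, None] - ratios[None, :]) / h)).sum(1)
        oracle = fine[np.argmax(dens)]
        est = weighted_mode(df, n_boot=0)
        coarse_step = (ratios.max() - ratios.min()) / 511
        assert abs(est.beta - oracle) <= coarse_step


class TestEstimateAll:
    def test_single_instrument_dispatches_to_wald(self):
        ests, diag = estimate_all(frame([0.1], [0.02], [0.05]))
        assert [e.method for e in ests] == ["wald_ratio"]
        assert diag is None

    def test_two_instruments_give_ivw_and_q(self):
        ests, diag = estimate_all(frame([0.1, 0.2], [0.02, 0.02], [0.05, 0.1]))
        assert [e.method for e in ests] == ["ivw_mre"]
        assert diag is not None and diag.q_df == 1
        assert diag.egger_intercept is None

    def test_three_instruments_give_all_methods(self, rng):
        df = random_effects_frame(rng, 3)
        ests, diag = estimate_all(df, seed=5, n_boot=100)
        assert [e.method for e in ests] == [
            "ivw_mre", "egger", "weighted_median", "weighted_mode"
        ]
        assert all(e.n_snp == 3 for e in ests)
        assert diag.egger_intercept is not None

    def test_same_seed_bit_identical(self, rng):
        df = random_effects_frame(rng, 6)
        a, _ = estimate_all(df, seed=42, n_boot=200)
        b, _ = estimate_all(df, seed=42, n_boot=200)
        assert [(e.beta, e.se, e.pval) for e in a] == [(e.beta, e.se, e.pval) for e in b]

    def test_empty_set_is_explicit_error(self):
        from mrscreen import EmptyDatasetError

        with pytest.raises(EmptyDatasetError):
            estimate_all(frame([], [], []))


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_outcome_scaling_scales_estimates(self, rng, c):
        df = random_effects_frame(rng, 12)
        scaled = df.copy()
        scaled["beta_y"] *= c
        scaled["se_y"] *= c
        for est_cls, kw in [
            (IVW, dict(effects_model="fixed")),
            (IVW, dict()),
            (MREgger, dict()),
            (WeightedMedian, dict(n_boot=200, seed=3)),
            (WeightedMode, dict(n_boot=200, seed=3)),
        ]:
            base = est_cls(**kw).fit(df)
            scal = est_cls(**kw).fit(scaled)
            assert scal.beta_ == pytest.approx(c * base.beta_, rel=1e-9), est_cls
            assert scal.se_ == pytest.approx(c * base.se_, rel=1e-9), est_cls


class TestCIAndOR:
    def test_ci_brackets_beta_and_or_is_exp(self, rng):
        df = random_effects_frame(rng, 8)
        ests, _ = estimate_all(df, seed=1, n_boot=100)
        for e in ests:
            assert e.ci_low <= e.beta <= e.ci_high
            assert e.or_value == pytest.approx(np.exp(e.beta))
            assert e.or_low == pytest.approx(np.exp(e.ci_low))
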