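"""MR estimators against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidmr import mr
from lipidmr.exceptions import (
    CollinearityError,
    InsufficientInstrumentsError,
    UndefinedStatisticError,
    ValidationError,
)


def wls_oracle(X, y, w):
    """Brute-force weighted normal equations with t-based inference."""
    W = np.diag(w)
    XtWX = X.T @ W @ X
    coef = np.linalg.solve(XtWX, X.T @ W @ y)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = (resid * w) @ resid / dof
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    p = 2 * stats.t.sf(np.abs(coef / se), dof)
    return coef, se, p


def random_instance(rng, n=None):
    n = n or int(rng.integers(4, 40))
    bx = rng.normal(0, 0.1, n)
    bx[bx == 0] = 0.05
    by = rng.normal(0, 0.05, n)
    sy = rng.uniform(0.005, 0.05, n)
    return bx, by, sy


class TestIvw:
    def test_single_snp_is_wald_ratio(self):
        est = mr.ivw([0.5], [0.25], [0.01])
        assert est.beta == pytest.approx(0.5)

    def test_constant_ratio_recovered_for_any_weights(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.1, 0.5, 10)
        est = mr.ivw(bx, 0.37 * bx, rng.uniform(0.01, 0.1, 10))
        assert est.beta == pytest.approx(0.37, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            bx, by, sy = random_instance(rng)
            est = mr.ivw(bx, by, sy)
            coef, se, p = wls_oracle(bx[:, None], by, 1 / sy**2)
            assert est.beta == pytest.approx(coef[0], abs=1e-10)
            assert est.se == pytest.approx(se[0], abs=1e-10)
            assert est.p == pytest.approx(p[0], abs=1e-10)

    def test_all_zero_bx_unidentifiable(self):
        with pytest.raises(UndefinedStatisticError):
            mr.ivw([0.0, 0.0], [0.1, 0.2], [0.01, 0.01])

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr.ivw([], [], [])


class TestEgger:
    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.1 + 0.4 * bx
        slope, intercept = mr.mr_egger(bx, by, np.full(3, 0.01))
        assert slope.beta == pytest.approx(0.4, abs=1e-12)
        assert intercept.beta == pytest.approx(0.1, abs=1e-12)

    def test_constant_shift_moves_intercept_only(self):
        rng = np.random.default_rng(2)
        bx, by, sy = random_instance(rng, n=15)
        bx = np.abs(bx)  # already oriented so the shift stays a shift
        s0, i0 = mr.mr_egger(bx, by, sy)
        s1, i1 = mr.mr_egger(bx, by + 0.05, sy)
        assert s1.beta == pytest.approx(s0.beta, abs=1e-12)
        assert i1.beta == pytest.approx(i0.beta + 0.05, abs=1e-12)

    def test_matches_oracle_after_orientation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            bx, by, sy = random_instance(rng)
            slope, intercept = mr.mr_egger(bx, by, sy)
            sign = np.where(bx < 0, -1.0, 1.0)
            X = np.column_stack([np.ones_like(bx), bx * sign])
            coef, se, p = wls_oracle(X, by * sign, 1 / sy**2)
            assert slope.beta == pytest.approx(coef[1], abs=1e-10)
            assert slope.se == pytest.approx(se[1], abs=1e-10)
            assert intercept.beta == pytest.approx(coef[0], abs=1e-10)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr.mr_egger([0.1, 0.2], [0.1, 0.2], [0.01, 0.01])


class TestMedians:
    def test_odd_count_middle_ratio(self):
        est = mr.simple_median([1.0, 1.0, 1.0], [0.1, 0.5, 0.9], n_boot=100)
        assert est.beta == pytest.approx(0.5)

    def test_even_count_midpoint(self):
        est = mr.simple_median([1, 1, 1, 1], [0.2, 0.4, 0.1, 0.9], n_boot=100)
        assert est.beta == pytest.approx(0.3)

    def test_zero_bx_ratio_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            mr.simple_median([0.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_weighted_equals_simple_under_equal_weights(self):
        rng = np.random.default_rng(4)
        for n in (3, 4, 7, 10):
            bx = np.full(n, 0.2)
            by = rng.normal(0, 0.05, n)
            simple = mr.simple_median(bx, by, n_boot=50)
            weighted = mr.weighted_median(bx, by, np.full(n, 0.01), n_boot=50)
            assert weighted.beta == pytest.approx(simple.beta, abs=1e-12)

    def test_dominant_weight_returns_its_ratio(self):
        # the middle-sorted SNP holds half the total weight, flanked evenly
        bx = np.array([0.1, 0.2, 0.1])
        sy = np.array([0.1, 0.2 / np.sqrt(2), 0.1])  # weights 1, 2, 1
        by = np.array([0.01, 0.1, 0.07])  # ratios 0.1, 0.5, 0.7
        weights = (bx / sy) ** 2
        assert weights[1] / weights.sum() == pytest.approx(0.5)
        est = mr.weighted_median(bx, by, sy, n_boot=50)
        assert est.beta == pytest.approx(0.5)

    def test_weighted_median_matches_interpolation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            bx, by, sy = random_instance(rng)
            est = mr.weighted_median(bx, by, sy, n_boot=10)
            ratios = by / bx
            w = (bx / sy) ** 2
            order = np.argsort(ratios)
            r, wq = ratios[order], w[order]
            cum = (np.cumsum(wq) - 0.5 * wq) / wq.sum()
            expect = float(np.interp(0.5, cum, r))
            if cum[0] >= 0.5:
                expect = r[0]
            assert est.beta == pytest.approx(expect, abs=1e-12)

    def test_bootstrap_se_stable_across_seeds(self):
        rng = np.random.default_rng(6)
        bx, by, sy = random_instance(rng, n=25)
        ses = [
            mr.simple_median(bx, by, n_boot=10_000, seed=s).se for s in (1, 2, 3)
        ]
        assert max(ses) / min(ses) < 1.10


class TestSignFlipInvariance:
    def test_all_estimators_invariant_to_instrument_reorientation(self):
        rng = np.random.default_rng(7)
        bx, by, sy = random_instance(rng, n=12)
        flip = rng.random(12) < 0.5
        fx, fy = np.where(flip, -bx, bx), np.where(flip, -by, by)
        assert mr.ivw(fx, fy, sy).beta == pytest.approx(mr.ivw(bx, by, sy).beta, abs=1e-12)
        assert mr.mr_egger(fx, fy, sy)[0].beta == pytest.approx(
            mr.mr_egger(bx, by, sy)[0].beta, abs=1e-12
        )
        assert mr.simple_median(fx, fy, n_boot=10).beta == pytest.approx(
            mr.simple_median(bx, by, n_boot=10).beta, abs=1e-12
        )
        assert mr.weighted_median(fx, fy, sy, n_boot=10).beta == pytest.approx(
            mr.weighted_median(bx, by, sy, n_boot=10).beta, abs=1e-12
        )


def beta_frame(bx_cols, by, sy):
    df = pd.DataFrame({f"beta_{k}": v for k, v in bx_cols.items()})
    df["beta_cad"] = by
    df["se_cad"] = sy
    return df


class TestMvmr:
    def test_single_exposure_reduces_to_ivw(self):
        rng = np.random.default_rng(8)
        bx, by, sy = random_instance(rng, n=20)
        table = beta_frame({"ldl": bx}, by, sy)
        est = mr.mvmr(table, exposures=["ldl"]).estimates[0]
        ref = mr.ivw(bx, by, sy)
        assert est.beta == pytest.approx(ref.beta, abs=1e-12)
        assert est.se == pytest.approx(ref.se, abs=1e-12)
        assert est.p == pytest.approx(ref.p, abs=1e-12)

    def test_orthogonal_exposures_decouple(self):
        # block design: each exposure nonzero on its own SNPs, equal weights
        n = 12
        bx = {x: np.zeros(n) for x in ("ldl", "hdl", "tg")}
        rng = np.random.default_rng(9)
        by = np.zeros(n)
        sy = np.full(n, 0.01)
        for i, x in enumerate(("ldl", "hdl", "tg")):
            block = slice(4 * i, 4 * i + 4)
            vals = rng.uniform(0.1, 0.3, 4)
            bx[x][block] = vals
            by[block] = (0.5 - 0.2 * i) * vals
        table = beta_frame(bx, by, sy)
        result = mr.mvmr(table)
        for i, est in enumerate(result.estimates):
            own = mr.ivw(bx[est.exposure][4 * i : 4 * i + 4], by[4 * i : 4 * i + 4],
                         sy[4 * i : 4 * i + 4])
            assert est.beta == pytest.approx(own.beta, abs=1e-10)

    def test_matches_multivariate_oracle(self):
        rng = np.random.default_rng(10)
        n = 30
        X = rng.normal(0, 0.1, (n, 3))
        y = X @ [0.4, -0.3, 0.1] + rng.normal(0, 0.01, n)
        sy = rng.uniform(0.005, 0.02, n)
        table = beta_frame({"ldl": X[:, 0], "hdl": X[:, 1], "tg": X[:, 2]}, y, sy)
        result = mr.mvmr(table)
        coef, se, p = wls_oracle(X, y, 1 / sy**2)
        for i, est in enumerate(result.estimates):
            assert est.beta == pytest.approx(coef[i], abs=1e-10)
            assert est.se == pytest.approx(se[i], abs=1e-10)
            assert est.p == pytest.approx(p[i], abs=1e-10)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(11)
        v = rng.normal(0, 0.1, 10)
        table = beta_frame({"ldl": v, "hdl": 2 * v, "tg": rng.normal(0, 0.1, 10)},
                           rng.normal(0, 0.1, 10), np.full(10, 0.01))
        with pytest.raises(CollinearityError, match="ldl"):
            mr.mvmr(table)

    def test_too_few_snps_rejected(self):
        table = beta_frame(
            {"ldl": [0.1] * 3, "hdl": [0.2, 0.1, 0.3], "tg": [0.3, 0.2, 0.1]},
            [0.1] * 3,
            [0.01] * 3,
        )
        with pytest.raises(InsufficientInstrumentsError):
            mr.mvmr(table)


class TestOrCi:
    def test_null_effect_symmetric_interval(self):
        or_, lo, hi = mr.to_or_ci(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_lipid_effect_sizes_on_or_scale(self):
        # per-SD log-odds effects of 0.396 and -0.315 map to OR ~1.486 / ~0.729
        # (reference values are printed at 3 decimals from unrounded betas)
        assert mr.to_or_ci(0.396, 0.03)[0] == pytest.approx(1.486, abs=1e-3)
        assert mr.to_or_ci(-0.315, 0.03)[0] == pytest.approx(0.729, abs=1e-3)

    def test_interval_ordering_invariant(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            or_, lo, hi = mr.to_or_ci(rng.normal(), rng.uniform(0, 0.5))
            assert lo <= or_ <= hi


class TestRSquared:
    def test_equal_class_means_give_zero(self):
        betas = [0.1, 0.3, 0.1, 0.3]
        r2 = mr.r_squared(betas, ["A", "A", "C", "C"], ["G", "G", "T", "T"])
        assert r2 == pytest.approx(0.0)

    def test_one_beta_per_class_gives_one(self):
        r2 = mr.r_squared([0.1, 0.5], ["A", "C"], ["G", "T"])
        assert r2 == pytest.approx(1.0)

    def test_matches_anova_decomposition(self):
        rng = np.random.default_rng(13)
        pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
        for _ in range(20):
            n = int(rng.integers(5, 40))
            pick = rng.integers(0, 4, n)
            a1 = [pairs[i][0] for i in pick]
            a2 = [pairs[i][1] for i in pick]
            betas = rng.normal(0, 1, n)
            if len(set(pick)) < 2:
                continue
            r2 = mr.r_squared(betas, a1, a2)
            # independent one-way ANOVA sums of squares
            groups = {}
            for b, key in zip(betas, pick):
                groups.setdefault(key, []).append(b)
            grand = betas.mean()
            ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups.values())
            ss_total = ((betas - grand) ** 2).sum()
            assert r2 == pytest.approx(ss_between / ss_total, abs=1e-12)
            assert 0.0 <= r2 <= 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            mr.r_squared([0.1, 0.2], ["A", "A"], ["G", "G"])
        with pytest.raises(UndefinedStatisticError):
            mr.r_squared([0.1, 0.1], ["A", "C"], ["G", "T"])
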