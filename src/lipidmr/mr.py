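"""Mendelian-randomization estimators.

All estimators operate on harmonized summary statistics: per-SNP exposure
effects ``bx`` (per 1 SD of the lipid trait), outcome effects ``by`` (log
odds of CAD) and outcome standard errors ``sy``.

* ``ivw`` — inverse-variance-weighted estimator: the slope of the
  no-intercept regression of ``by`` on ``bx`` with weights ``1/sy**2``.
* ``mr_egger`` — the same weighted regression with an intercept, each SNP
  first oriented so ``bx >= 0``; a non-zero intercept signals directional
  (unbalanced) pleiotropy and the slope is the pleiotropy-adjusted effect.
* ``simple_median`` / ``weighted_median`` — the (weighted) median of the
  per-SNP Wald ratios ``by/bx``; robust to up to half the instruments (or
  half the weight) being invalid.  Median standard errors come from a
  seeded bootstrap because no closed form exists.
* ``mvmr`` — multivariable MR: joint weighted regression of the outcome
  betas on all three exposures' betas, separating each lipid's direct
  effect from effects channelled through the co-associated lipids.

Weighted fits use :mod:`statsmodels` WLS; p-values are two-sided from the
t distribution with ``n_snps - k`` degrees of freedom.  Effects are
reported on the log-odds scale and as odds ratios per 1 SD of exposure
with 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    CollinearityError,
    InsufficientInstrumentsError,
    UndefinedStatisticError,
    ValidationError,
)
from .gwas_io import EXPOSURES

_Z95 = 1.959964


@dataclass
class MrEstimate:
    """One causal-effect estimate.

    ``beta`` is the effect on CAD log odds per 1 SD of the exposure;
    ``or_`` = exp(beta) with a 95% CI on the odds-ratio scale.
    """

    method: str
    exposure: str
    beta: float
    se: float
    p: float
    or_: float
    ci_low: float
    ci_high: float
    n_snps: int

    @classmethod
    def from_beta_se(
        cls, method: str, exposure: str, beta: float, se: float, p: float, n_snps: int
    ) -> "MrEstimate":
        or_, lo, hi = to_or_ci(beta, se) if np.isfinite(se) else (np.exp(beta), np.nan, np.nan)
        return cls(
            method=method,
            exposure=exposure,
            beta=float(beta),
            se=float(se),
            p=float(p),
            or_=or_,
            ci_low=lo,
            ci_high=hi,
            n_snps=int(n_snps),
        )


@dataclass
class MrResultSet:
    """A collection of estimates plus provenance of the input they came from."""

    estimates: list[MrEstimate] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": e.method,
                "exposure": e.exposure,
                "n_snps": e.n_snps,
                "beta": e.beta,
                "se": e.se,
                "p": e.p,
                "or": e.or_,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows)

    def get(self, method: str, exposure: str) -> MrEstimate:
        for e in self.estimates:
            if e.method == method and e.exposure == exposure:
                return e
        raise KeyError((method, exposure))


def to_or_ci(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio and 95% CI from a log-odds effect and its SE."""
    if se < 0 or not np.isfinite(se):
        raise UndefinedStatisticError(f"se must be finite and >= 0, got {se}")
    or_ = float(np.exp(beta))
    return or_, float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))


def _as_arrays(*arrays):
    out = [np.asarray(a, dtype=float) for a in arrays]
    n = {a.shape for a in out}
    if len(n) != 1 or out[0].ndim != 1:
        raise ValidationError("bx, by, sy must be 1-d arrays of equal length")
    return out


def ivw(bx, by, sy, exposure: str = "") -> MrEstimate:
    """Inverse-variance-weighted estimate (no-intercept weighted regression).

    With a single SNP the slope reduces to the Wald ratio ``by/bx`` (SE and
    p are then undefined).

    Raises
    ------
    InsufficientInstrumentsError
        With zero SNPs.
    UndefinedStatisticError
        If every ``bx`` is zero (slope unidentifiable).
    """
    bx, by, sy = _as_arrays(bx, by, sy)
    if len(bx) < 1:
        raise InsufficientInstrumentsError("IVW requires at least 1 SNP")
    if np.all(bx == 0.0):
        raise UndefinedStatisticError("all exposure betas are zero; IVW slope unidentifiable")
    if np.any(sy <= 0.0):
        raise ValidationError("outcome SEs must be positive")
    if len(bx) == 1:  # Wald ratio; no residual degrees of freedom
        return MrEstimate.from_beta_se(
            "ivw", exposure, by[0] / bx[0], np.nan, np.nan, 1
        )
    fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
    return MrEstimate.from_beta_se(
        "ivw", exposure, fit.params[0], fit.bse[0], fit.pvalues[0], len(bx)
    )


def mr_egger(bx, by, sy, exposure: str = "") -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger regression: weighted fit with an intercept after orienting
    every SNP so its exposure beta is non-negative.

    Returns ``(slope, intercept)`` estimates.  A non-zero intercept is
    evidence of unbalanced (directional) pleiotropy; the slope remains a
    consistent causal estimate under the InSIDE assumption.

    Raises
    ------
    InsufficientInstrumentsError
        With fewer than 3 SNPs.
    """
    bx, by, sy = _as_arrays(bx, by, sy)
    if len(bx) < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 SNPs")
    sign = np.where(bx < 0.0, -1.0, 1.0)
    fit = sm.WLS(by * sign, sm.add_constant(bx * sign), weights=1.0 / sy**2).fit()
    slope = MrEstimate.from_beta_se(
        "egger", exposure, fit.params[1], fit.bse[1], fit.pvalues[1], len(bx)
    )
    intercept = MrEstimate.from_beta_se(
        "egger_intercept", exposure, fit.params[0], fit.bse[0], fit.pvalues[0], len(bx)
    )
    return slope, intercept


def _check_ratio_inputs(bx, by):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    if len(bx) < 3:
        raise InsufficientInstrumentsError("median estimators require at least 3 SNPs")
    if np.any(bx == 0.0):
        raise UndefinedStatisticError("Wald ratio undefined for bx == 0")
    return bx, by


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at the 50% weight point.

    The k-th sorted ratio sits at standardized cumulative weight
    ``(S_k - w_k/2) / S_total``; the estimate interpolates linearly where
    that function crosses one half.  Under equal weights this equals the
    ordinary median, including the midpoint convention for even counts.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(estimator, n: int, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    values = np.array([estimator(row) for row in idx])
    return float(np.std(values, ddof=1))


def simple_median(bx, by, n_boot: int = 10_000, seed: int = 0, exposure: str = "") -> MrEstimate:
    """Median of the per-SNP Wald ratios ``by/bx``.

    Even instrument counts use the midpoint of the two central ratios.
    The SE is the standard deviation of ``n_boot`` nonparametric bootstrap
    medians (resampling SNPs, seeded); p is the two-sided normal tail of
    ``beta/se``.
    """
    bx, by = _check_ratio_inputs(bx, by)
    ratios = by / bx
    beta = float(np.median(ratios))
    se = _bootstrap_se(lambda idx: np.median(ratios[idx]), len(ratios), n_boot, seed)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else np.nan
    return MrEstimate.from_beta_se("simple_median", exposure, beta, se, p, len(bx))


def weighted_median(
    bx, by, sy, n_boot: int = 10_000, seed: int = 0, exposure: str = ""
) -> MrEstimate:
    """Weighted median of the Wald ratios, weights ``(bx/sy)**2``.

    The weight is the inverse of the first-order variance of the ratio, so
    precisely estimated instruments pull the median toward themselves.
    Reduces to :func:`simple_median` under equal weights.
    """
    bx, by = _check_ratio_inputs(bx, by)
    sy = np.asarray(sy, dtype=float)
    if np.any(sy <= 0.0):
        raise ValidationError("outcome SEs must be positive")
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median(ratios, weights)
    se = _bootstrap_se(
        lambda idx: _weighted_median(ratios[idx], weights[idx]), len(ratios), n_boot, seed
    )
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else np.nan
    return MrEstimate.from_beta_se("weighted_median", exposure, beta, se, p, len(bx))


def mvmr(
    beta_table: pd.DataFrame,
    exposures: Sequence[str] = EXPOSURES,
    weighted: bool = True,
    intercept: bool = False,
) -> MrResultSet:
    """Multivariable MR of CAD log odds on all exposures' betas jointly.

    The default convention is weighted (``1/se_cad**2``) with no
    intercept, which makes the single-exposure case collapse exactly to
    :func:`ivw`; ``weighted``/``intercept`` expose the alternative
    conventions.  Per-exposure p-values are t-tests with
    ``n_snps - k`` degrees of freedom.

    Raises
    ------
    InsufficientInstrumentsError
        With fewer than 4 SNPs.
    CollinearityError
        If the exposure design matrix is rank deficient.
    """
    exposures = list(exposures)
    if len(beta_table) < 4:
        raise InsufficientInstrumentsError("MVMR requires at least 4 SNPs")
    X = beta_table[[f"beta_{x}" for x in exposures]].to_numpy(dtype=float)
    y = beta_table["beta_cad"].to_numpy(dtype=float)
    sy = beta_table["se_cad"].to_numpy(dtype=float)
    if np.any(~np.isfinite(sy)) or np.any(sy <= 0.0):
        raise ValidationError("se_cad must be finite and positive for MVMR weights")

    design = sm.add_constant(X) if intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            f"rank-deficient design over exposures {exposures}; "
            "drop or merge collinear exposures"
        )
    weights = 1.0 / sy**2 if weighted else np.ones_like(sy)
    fit = sm.WLS(y, design, weights=weights).fit()

    offset = 1 if intercept else 0
    result = MrResultSet(
        provenance={
            "method": "mvmr",
            "weighted": weighted,
            "intercept": intercept,
            "n_snps": len(beta_table),
        }
    )
    for i, x in enumerate(exposures):
        result.estimates.append(
            MrEstimate.from_beta_se(
                "mvmr", x, fit.params[offset + i], fit.bse[offset + i],
                fit.pvalues[offset + i], len(beta_table),
            )
        )
    return result


def single_variable_suite(
    beta_table: pd.DataFrame,
    exposure: str,
    p_threshold: float | None = 5e-08,
    n_boot: int = 10_000,
    seed: int = 0,
) -> MrResultSet:
    """Run IVW, Egger and both medians for one exposure.

    Instruments are the SNPs associated with the exposure at
    ``p_threshold`` (all SNPs when ``None``), mirroring how a
    single-variable analysis picks its instrument subset from a selected
    set.
    """
    sub = beta_table
    if p_threshold is not None:
        sub = beta_table.loc[beta_table[f"p_{exposure}"] <= p_threshold]
    bx = sub[f"beta_{exposure}"].to_numpy(dtype=float)
    by = sub["beta_cad"].to_numpy(dtype=float)
    sy = sub["se_cad"].to_numpy(dtype=float)
    result = MrResultSet(provenance={"exposure": exposure, "n_snps": len(sub)})
    result.estimates.append(ivw(bx, by, sy, exposure=exposure))
    slope, icept = mr_egger(bx, by, sy, exposure=exposure)
    result.estimates.extend([slope, icept])
    result.estimates.append(simple_median(bx, by, n_boot=n_boot, seed=seed, exposure=exposure))
    result.estimates.append(
        weighted_median(bx, by, sy, n_boot=n_boot, seed=seed, exposure=exposure)
    )
    return result


def r_squared(betas, a1, a2) -> float:
    """Genotype-class share of effect-size variance for one exposure.

    SNPs are grouped by their (unordered) allele pair; the statistic is
    the between-class variance of the betas (class means weighted by class
    size) over the total variance — the one-way ANOVA decomposition, so
    the value lies in [0, 1].

    Raises
    ------
    ValidationError
        With fewer than 2 distinct allele-pair classes.
    UndefinedStatisticError
        If the total variance is zero.
    """
    betas = np.asarray(betas, dtype=float)
    pairs = ["/".join(sorted((str(x), str(y)))) for x, y in zip(a1, a2, strict=True)]
    if len(betas) != len(pairs):
        raise ValidationError("betas and allele pairs must align")
    frame = pd.DataFrame({"beta": betas, "pair": pairs})
    if frame["pair"].nunique() < 2:
        raise ValidationError("need >= 2 distinct genotype classes")
    grand = frame["beta"].mean()
    v_t = float(np.mean((frame["beta"] - grand) ** 2))
    if v_t == 0.0:
        raise UndefinedStatisticError("total variance of betas is zero")
    means = frame.groupby("pair")["beta"].transform("mean")
    v_g = float(np.mean((means - grand) ** 2))
    return v_g / v_t
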