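"""Two-sample MR causal-effect estimators.

Implements the estimator suite over harmonized per-variant effect pairs
(bx, sex) on the exposure and (by, sey) on the outcome:

* Wald ratio (single instrument), first- or second-order delta-method se;
* inverse-variance weighted (IVW) combination, fixed-effect or multiplicative
  random-effects, with the weights w_j = bx_j^2 / sey_j^2 convention;
* generalized IVW for correlated instruments via GLS with Omega = D rho D;
* MR-Egger regression (intercept indexes directional pleiotropy);
* weighted median (consistent with up to half the weight on invalid
  instruments), bootstrap se;
* Cochran's Q heterogeneity statistic.

All p-values are two-sided normal. Estimates for case-control outcomes live
on the log-odds scale until :func:`to_odds_ratio` exponentiates them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

Z95 = stats.norm.ppf(0.975)


class EstimatorError(ValueError):
    pass


@dataclass
class MREstimate:
    """One method's causal estimate.

    ``beta`` is per exposure-unit increase unless ``orientation`` is
    "drug-action", in which case it reads as the effect of pharmacological
    modulation of the target. ``scale`` is "linear" or "log-odds".
    """

    method: str
    beta: float
    se: float
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    pvalue: float = field(init=False)
    n_iv: int = 1
    f_stat: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    scale: str = "linear"
    orientation: str = "biomarker-increase"

    def __post_init__(self) -> None:
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se
        self.pvalue = (
            float(2.0 * stats.norm.sf(abs(self.beta) / self.se))
            if self.se > 0
            else (1.0 if self.beta == 0 else 0.0)
        )

    def with_heterogeneity(self, q: float, df: int) -> "MREstimate":
        self.q_stat, self.q_df = float(q), int(df)
        self.q_pvalue = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
        return self


@dataclass
class EggerResult(MREstimate):
    intercept: float = 0.0
    intercept_se: float = float("nan")
    intercept_pvalue: float = float("nan")


def _as_arrays(*cols):
    out = [np.asarray(c, dtype=float) for c in cols]
    n = {a.shape for a in out}
    if len(n) != 1:
        raise EstimatorError("instrument arrays must share a length")
    return out


def wald_ratio(
    bx: float, sex: float, by: float, sey: float, second_order: bool = False
) -> MREstimate:
    """Single-instrument causal estimate by/bx.

    First-order delta-method se is sey/|bx|; the second-order option adds the
    exposure-uncertainty term: se^2 = sey^2/bx^2 + by^2 sex^2 / bx^4.
    """
    if bx == 0:
        raise EstimatorError("Wald ratio undefined for bx = 0")
    beta = by / bx
    var = (sey / bx) ** 2
    if second_order:
        var += (by**2) * (sex**2) / bx**4
    return MREstimate(method="wald_ratio", beta=float(beta), se=float(np.sqrt(var)))


def cochran_q(bx, sex, by, sey, beta_ivw: float) -> tuple[float, int, float]:
    """Heterogeneity of per-instrument ratios around an IVW estimate.

    Q = sum w_j (by_j/bx_j - beta_ivw)^2 with w_j = bx_j^2/sey_j^2,
    chi-square with n_iv - 1 df.
    """
    bx, sex, by, sey = _as_arrays(bx, sex, by, sey)
    w = bx**2 / sey**2
    q = float(np.sum(w * (by / bx - beta_ivw) ** 2))
    df = len(bx) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, p


def ivw(bx, sex, by, sey, random_effects: bool | str = "auto") -> MREstimate:
    """Inverse-variance weighted estimate.

    beta = sum(bx by / sey^2) / sum(bx^2 / sey^2); fixed-effect
    se = sum(bx^2/sey^2)^(-1/2). ``random_effects`` True multiplies the se by
    sqrt(max(1, Q/df)) (multiplicative random effects); "auto" (the default
    primary analysis) escalates only when Q/df > 1.
    """
    bx, sex, by, sey = _as_arrays(bx, sex, by, sey)
    if len(bx) < 1:
        raise EstimatorError("IVW requires at least one instrument")
    w = bx**2 / sey**2
    beta = float(np.sum(bx * by / sey**2) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    n_iv = len(bx)
    q, df, _ = cochran_q(bx, sex, by, sey, beta)
    dispersion = q / df if df > 0 else 1.0
    method = "ivw_fe"
    if random_effects is True or (random_effects == "auto" and dispersion > 1.0):
        se *= np.sqrt(max(1.0, dispersion))
        method = "ivw_mre"
    est = MREstimate(method=method, beta=beta, se=se, n_iv=n_iv)
    if df > 0:
        est.with_heterogeneity(q, df)
    return est


def ivw_correlated(bx, sex, by, sey, rho: np.ndarray, ridge: float = 0.0) -> MREstimate:
    """Generalized IVW for LD-correlated instruments.

    GLS with Omega = D rho D (D = diag(sey)):
    beta = (bx' Omega^-1 bx)^-1 bx' Omega^-1 by, se = (bx' Omega^-1 bx)^(-1/2).
    ``ridge`` adds lambda to the correlation diagonal for near-singular rho.
    """
    bx, sex, by, sey = _as_arrays(bx, sex, by, sey)
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (len(bx), len(bx)):
        raise EstimatorError("correlation matrix does not match instruments")
    if ridge:
        rho = rho + ridge * np.eye(len(bx))
    omega = np.outer(sey, sey) * rho
    try:
        c, low = (np.linalg.cholesky(omega), True)
    except np.linalg.LinAlgError as exc:
        raise EstimatorError(
            "instrument covariance numerically singular; pass ridge=1e-6"
        ) from exc
    from scipy.linalg import cho_solve

    oi_bx = cho_solve((c, low), bx)
    prec = float(bx @ oi_bx)
    if prec <= 0:
        raise EstimatorError("degenerate exposure effects")
    beta = float(bx @ cho_solve((c, low), by)) / prec
    return MREstimate(
        method="ivw_correlated", beta=beta, se=prec**-0.5, n_iv=len(bx)
    )


def egger(bx, sex, by, sey) -> EggerResult:
    """MR-Egger: weighted regression of by on bx with an intercept.

    Rows are flipped so bx >= 0 (the method's orientation convention), then
    by is regressed on bx with weights 1/sey^2. The slope is the causal
    estimate; the intercept tests directional pleiotropy. Standard errors use
    the residual dispersion floored at 1 (multiplicative random effects).
    """
    bx, sex, by, sey = _as_arrays(bx, sex, by, sey)
    n = len(bx)
    if n < 3:
        raise EstimatorError("MR-Egger requires three or more instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise EstimatorError("collinear design: all |bx| equal")
    import statsmodels.api as sm

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sey**2).fit()
    scale_mult = max(1.0, fit.scale) / fit.scale  # floor dispersion at 1
    se_int, se_slope = np.sqrt(np.diag(fit.cov_params()) * scale_mult)
    res = EggerResult(
        method="egger",
        beta=float(fit.params[1]),
        se=float(se_slope),
        n_iv=n,
        intercept=float(fit.params[0]),
        intercept_se=float(se_int),
    )
    res.intercept_pvalue = float(
        2.0 * stats.norm.sf(abs(res.intercept) / res.intercept_se)
        if res.intercept_se > 0
        else 1.0
    )
    q = float(np.sum((by - fit.fittedvalues) ** 2 / sey**2))
    res.with_heterogeneity(q, n - 2)
    res.q_df = n - 2
    return res


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w  # mid-cumulative weight per ordered ratio
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5))
    # linear interpolation between the bracketing ordered ratios
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(
    bx, sex, by, sey, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap se.

    Ratio estimates by_j/bx_j are ordered; inverse-variance weights
    w_j = bx_j^2/sey_j^2 are normalized, and the estimate interpolates where
    the mid-cumulative weight crosses 0.5. Consistent when instruments
    carrying up to half the weight are invalid (50% breakdown).
    """
    bx, sex, by, sey = _as_arrays(bx, sex, by, sey)
    n = len(bx)
    if n < 3:
        raise EstimatorError("weighted median requires three or more instruments")
    ratios = by / bx
    weights = bx**2 / sey**2
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sex)
        by_b = rng.normal(by, sey)
        ok = bx_b != 0
        boots[b] = _weighted_median_point(
            by_b[ok] / bx_b[ok], bx_b[ok] ** 2 / sey[ok] ** 2
        )
    return MREstimate(
        method="weighted_median", beta=point, se=float(boots.std(ddof=1)), n_iv=n
    )


def f_statistic(bx, sex) -> tuple[np.ndarray, float, bool]:
    """Per-variant F_j = (bx_j/sex_j)^2, summary F = mean, weak flag if < 10."""
    bx, sex = _as_arrays(bx, sex)
    f = (bx / sex) ** 2
    summary = float(f.mean())
    return f, summary, summary < 10.0


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Exponentiate a log-odds-scale estimate to an odds ratio.

    Returns a copy with beta/CI exponentiated and scale "odds-ratio";
    the p-value is unchanged. Linear-scale traits cannot be exponentiated.
    """
    if est.scale != "log-odds":
        raise EstimatorError("odds ratios only defined for log-odds estimates")
    out = copy.copy(est)
    out.beta = float(np.exp(est.beta))
    out.ci_low = float(np.exp(est.ci_low))
    out.ci_high = float(np.exp(est.ci_high))
    out.pvalue = est.pvalue
    out.scale = "odds-ratio"
    return out
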