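"""Overall and difference-in-fit measures for covariance-structure models.

Implements the standard toolkit used to judge longitudinal factor models and
their invariance restrictions: the chi-square test of exact fit, RMSEA with a
90% noncentral-chi-square confidence interval and the conventional close/
reasonable-fit labels, CFI/TLI against the independence baseline, and the
information criteria ECVI/AIC/BIC, plus nested-model comparisons via the
chi-square difference test and the delta-CFI > 0.01 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .estimation import FittedModel, independence_fit

__all__ = [
    "FitIndexSet",
    "ComparisonResult",
    "overall_fit",
    "compare_nested",
    "rmsea_label",
    "cfi_label",
]

RMSEA_CLOSE = 0.05
RMSEA_REASONABLE = 0.08
CFI_GOOD = 0.95
DELTA_CFI_RULE = 0.01


def rmsea_label(rmsea: float | None) -> str:
    """Conventional RMSEA verdict: < .05 'close', < .08 'reasonable' (strict)."""
    if rmsea is None or not np.isfinite(rmsea):
        return "not applicable"
    if rmsea < RMSEA_CLOSE:
        return "close"
    if rmsea < RMSEA_REASONABLE:
        return "reasonable"
    return "poor"


def cfi_label(cfi: float) -> str:
    """Conventional CFI verdict: > .95 'good' (strict)."""
    return "good" if cfi > CFI_GOOD else "poor"


@dataclass
class FitIndexSet:
    """Overall goodness-of-fit summary for one fitted model."""

    chi_square: float
    df: int
    p_exact: float
    rmsea: float | None
    rmsea_ci: tuple[float, float] | None
    rmsea_verdict: str
    cfi: float
    tli: float
    ecvi: float
    aic: float
    bic: float
    cfi_verdict: str
    n: int
    n_params: int

    def to_dict(self) -> dict:
        d = {
            "chi_square": self.chi_square,
            "df": self.df,
            "p_exact": self.p_exact,
            "rmsea": self.rmsea,
            "rmsea_ci_90": list(self.rmsea_ci) if self.rmsea_ci else None,
            "rmsea_verdict": self.rmsea_verdict,
            "cfi": self.cfi,
            "tli": self.tli,
            "ecvi": self.ecvi,
            "aic": self.aic,
            "bic": self.bic,
            "cfi_verdict": self.cfi_verdict,
            "n": self.n,
            "n_params": self.n_params,
        }
        return d


def _ncp_ci(chi2: float, df: int, level: float = 0.90) -> tuple[float, float]:
    """Invert the noncentral chi-square CDF for the noncentrality interval."""
    alpha = (1.0 - level) / 2.0

    def solve(target: float) -> float:
        # find ncp with ncx2.cdf(chi2, df, ncp) == target; cdf decreases in ncp
        if stats.chi2.cdf(chi2, df) < target:
            return 0.0
        hi = max(4.0 * chi2, 10.0)
        while stats.ncx2.cdf(chi2, df, hi) > target and hi < 1e8:
            hi *= 4.0
        return float(optimize.brentq(
            lambda nc: stats.ncx2.cdf(chi2, df, nc) - target, 0.0, hi, xtol=1e-8
        ))

    return solve(1.0 - alpha), solve(alpha)


def overall_fit(fitted: FittedModel, baseline: FittedModel | None = None) -> FitIndexSet:
    """Compute the overall fit-index set for one converged fit.

    ``baseline`` is the independence model (free variances and means, all
    covariances zero) used by the comparative indices; it is computed in
    closed form from the sample moments when not supplied.
    """
    if not fitted.converged:
        raise ValueError("fit indices require a converged model")
    if baseline is None:
        baseline = independence_fit(fitted.moments)
    n = fitted.n
    chi2, df = fitted.chi_square, fitted.df
    q = fitted.n_params
    p_exact = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df > 0:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        lo, hi = _ncp_ci(chi2, df)
        ci = (
            float(np.sqrt(lo / (df * (n - 1)))),
            float(np.sqrt(hi / (df * (n - 1)))),
        )
    else:
        rmsea, ci = None, None
    num = max(chi2 - df, 0.0)
    den = max(baseline.chi_square - baseline.df, 0.0)
    cfi = 1.0 if num == 0.0 else (0.0 if den == 0.0 else 1.0 - num / den)
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df > 0 and baseline.df > 0 and baseline.chi_square > baseline.df:
        tli = float(
            (baseline.chi_square / baseline.df - chi2 / df)
            / (baseline.chi_square / baseline.df - 1.0)
        )
    else:
        tli = 1.0
    ecvi = (chi2 + 2.0 * q) / (n - 1)
    aic = chi2 + 2.0 * q
    bic = chi2 + q * np.log(n)
    return FitIndexSet(
        chi_square=chi2, df=df, p_exact=p_exact,
        rmsea=rmsea, rmsea_ci=ci, rmsea_verdict=rmsea_label(rmsea),
        cfi=cfi, tli=tli, ecvi=float(ecvi), aic=float(aic), bic=float(bic),
        cfi_verdict=cfi_label(cfi), n=n, n_params=q,
    )


@dataclass
class ComparisonResult:
    """Difference in fit between two nested models on the same moments.

    Sign conventions: ``delta_chi_square`` and ``delta_df`` are
    more-restricted minus less-restricted; ``delta_cfi`` is less minus more
    (positive values mean the restrictions cost fit); ``delta_ecvi`` and
    ``delta_aic`` are positive when they favour the less-restricted model.
    """

    delta_chi_square: float
    delta_df: int
    p_delta: float
    delta_cfi: float
    delta_ecvi: float
    delta_aic: float
    alpha: float
    significant: bool
    cfi_rule_reject: bool
    verdict: str

    def to_dict(self) -> dict:
        return {
            "delta_chi_square": self.delta_chi_square,
            "delta_df": self.delta_df,
            "p_delta": self.p_delta,
            "delta_cfi": self.delta_cfi,
            "delta_ecvi": self.delta_ecvi,
            "delta_aic": self.delta_aic,
            "alpha": self.alpha,
            "significant": self.significant,
            "cfi_rule_reject": self.cfi_rule_reject,
            "verdict": self.verdict,
        }


def compare_nested(
    less_restricted: FittedModel,
    more_restricted: FittedModel,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Likelihood-ratio and descriptive comparison of two nested fits.

    The more-restricted model must have strictly more degrees of freedom and
    both fits must be to the same sample moments.  A significant chi-square
    difference (or a clamped-CFI difference above 0.01) argues against the
    restrictions.
    """
    a, b = less_restricted, more_restricted
    if a.n != b.n or not np.allclose(a.moments.S, b.moments.S):
        raise ValueError("models were fitted to different sample moments")
    ddf = b.df - a.df
    if ddf <= 0:
        raise ValueError(
            f"models are not properly nested: delta df = {ddf} (must be > 0)"
        )
    dchi = b.chi_square - a.chi_square
    if dchi < -1e-6 * max(1.0, a.chi_square):
        raise ValueError(
            "more restricted model fits better than less restricted model; "
            "fits are inconsistent (non-convergence?)"
        )
    dchi = max(dchi, 0.0)
    p = float(stats.chi2.sf(dchi, ddf))
    base = independence_fit(a.moments)
    fia = overall_fit(a, base)
    fib = overall_fit(b, base)
    delta_cfi = fia.cfi - fib.cfi
    delta_ecvi = fib.ecvi - fia.ecvi
    delta_aic = fib.aic - fia.aic
    significant = p < alpha
    cfi_reject = delta_cfi > DELTA_CFI_RULE
    verdict = "reject more restricted" if significant else "retain more restricted"
    return ComparisonResult(
        delta_chi_square=float(dchi), delta_df=int(ddf), p_delta=p,
        delta_cfi=float(delta_cfi), delta_ecvi=float(delta_ecvi),
        delta_aic=float(delta_aic), alpha=alpha, significant=significant,
        cfi_rule_reject=cfi_reject, verdict=verdict,
    )
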