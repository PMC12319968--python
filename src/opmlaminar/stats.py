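"""Summary statistics for classification sweeps.

Exact two-sided binomial tests against 50% chance (classification accuracy
and pial bias), exact McNemar tests for paired comparisons of analyses or
conditions, and logistic regressions of accuracy/bias on ordered condition
levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "binomial_two_sided",
    "mcnemar_exact",
    "logistic_fit",
    "LogisticFit",
]


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (sum of outcomes no more probable
    than the observed one)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def mcnemar_exact(b_discordant: int, c_discordant: int) -> float:
    """Exact McNemar test on the two discordant-pair counts.

    p = min(1, 2 P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    with no discordant pairs the test is vacuous and p = 1.
    """
    b, c = int(b_discordant), int(c_discordant)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * sps.binom.cdf(min(b, c), n, 0.5)))


@dataclass
class LogisticFit:
    beta: float  # slope on the (optionally standardised) level index
    se: float
    wald_p: float
    intercept: float
    converged: bool
    separated: bool


def logistic_fit(
    outcome: np.ndarray,
    predictor: np.ndarray,
    standardise: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic slope of a binary outcome on ordered
    condition levels, with a Wald p-value.

    Perfect separation (or a constant outcome) is flagged rather than
    raised; the reported slope is then the last iterate and the p-value is
    not meaningful.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and predictor must have equal length")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two predictor levels")
    if standardise:
        x = (x - x.mean()) / x.std()
    design = sm.add_constant(x)
    separated = bool(y.min() == y.max())
    converged = False
    beta = se = wald_p = np.nan
    intercept = np.nan
    if not separated:
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200, tol=1e-8)
            intercept, beta = fit.params
            se = fit.bse[1]
            wald_p = fit.pvalues[1]
            converged = bool(fit.mle_retvals.get("converged", False))
            # huge |beta| with exploding SE signals separation
            separated = not np.isfinite(se) or (abs(beta) > 25 and se > 1e3)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True
    return LogisticFit(
        beta=float(beta),
        se=float(se),
        wald_p=float(wald_p),
        intercept=float(intercept),
        converged=converged,
        separated=separated,
    )
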