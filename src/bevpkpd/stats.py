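"""Model-comparison statistics: Wald, likelihood-ratio, AIC/BIC, %RSE."""

from __future__ import annotations

import warnings

from scipy import stats as sps

#: chi-square(1) critical value at 5%: a -2LL drop above this is significant
LRT_CRITICAL_1DF = float(sps.chi2.ppf(0.95, 1))


def wald_test(coefficient: float, se: float) -> tuple[float, float]:
    """Two-sided Wald test of a coefficient against zero: (z, p)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = coefficient / se
    return z, 2.0 * sps.norm.sf(abs(z))


def lrt(minus2ll_reduced: float, minus2ll_full: float, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio test for nested models: (drop, p).

    ``drop`` is the -2LL reduction of the full vs reduced model; negative
    drops (possible with Monte-Carlo likelihoods) yield p = 1 with a warning.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    drop = minus2ll_reduced - minus2ll_full
    if drop < 0:
        warnings.warn("negative -2LL drop: full model fits worse than reduced")
        return drop, 1.0
    return drop, float(sps.chi2.sf(drop, df))


def information_criteria(minus2ll: float, k: int, n: int) -> tuple[float, float]:
    """(AIC, BIC) from -2LL with k parameters and n subjects."""
    import numpy as np
    if k < 0 or n < 1:
        raise ValueError("need k >= 0 and n >= 1")
    return minus2ll + 2.0 * k, minus2ll + k * float(np.log(n))


def relative_standard_error(estimate: float, se: float) -> float:
    """%RSE = 100*SE/|estimate|; 0 for a fixed parameter (SE = 0)."""
    if se == 0:
        return 0.0
    if estimate == 0:
        raise ValueError("%RSE undefined for a zero estimate with nonzero SE")
    return 100.0 * se / abs(estimate)
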