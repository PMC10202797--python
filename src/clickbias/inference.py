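"""Auxiliary statistics: two-sample KS comparison and equivalence testing.

The KS test compares the distributions of positive vs negative word
proportions across headlines.  The equivalence test implements the
pre-declared null-region rule: an effect whose confidence interval lies
entirely inside (−0.001, 0.001) is taken as evidence for a null effect;
otherwise the result is inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_EQUIVALENCE_BOUNDS = (-0.001, 0.001)


@dataclass(frozen=True)
class KsResult:
    statistic: float
    p_value: float


@dataclass(frozen=True)
class EquivalenceResult:
    estimate: float
    se: float
    bounds: tuple[float, float]
    level: float
    ci: tuple[float, float]
    verdict: str  # "null-supported" | "inconclusive"
    tost_p: float


def ks_two_sample(a, b) -> KsResult:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p value).

    D is the supremum of the absolute difference between the two
    empirical CDFs; the p value uses the asymptotic two-sample KS
    distribution (appropriate for the tens of thousands of headlines in
    a real archive).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KsResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def equivalence_test(
    estimate: float,
    se: float,
    bounds: tuple[float, float] = DEFAULT_EQUIVALENCE_BOUNDS,
    level: float = 0.99,
) -> EquivalenceResult:
    """Equivalence verdict by CI containment, with a TOST p value.

    The verdict is ``null-supported`` iff the Wald CI at ``level`` is
    fully contained in the open interval ``bounds``.  The TOST p value —
    the larger of the two one-sided normal p values against the bounds —
    is reported alongside but does not drive the verdict (the
    pre-declared rule is the CI containment).
    """
    lower, upper = bounds
    if not (se > 0):
        raise ValueError("SE must be positive")
    if not lower < upper:
        raise ValueError("equivalence bounds must satisfy lower < upper")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    crit = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    ci = (estimate - crit * se, estimate + crit * se)
    contained = lower < ci[0] and ci[1] < upper
    # TOST: H0 is estimate <= lower OR estimate >= upper
    p_low = stats.norm.sf((estimate - lower) / se)   # test against the lower bound
    p_high = stats.norm.cdf((estimate - upper) / se)  # test against the upper bound
    tost_p = float(max(p_low, p_high))
    return EquivalenceResult(
        estimate=float(estimate),
        se=float(se),
        bounds=(float(lower), float(upper)),
        level=float(level),
        ci=(float(ci[0]), float(ci[1])),
        verdict="null-supported" if contained else "inconclusive",
        tost_p=tost_p,
    )
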