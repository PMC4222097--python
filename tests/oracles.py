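"""Independent stdlib-only reference implementations used as test oracles.

Deliberately scipy-free: the normal CDF/quantile are built on math.erfc
plus bisection, and the chi-square upper tail uses the closed-form series
valid for even degrees of freedom, so these provide a genuinely
independent check of the package's distribution arithmetic.
"""

from __future__ import annotations

import math


def norm_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def norm_sf(x: float) -> float:
    return 0.5 * math.erfc(x / math.sqrt(2.0))


def norm_isf(p: float) -> float:
    """Upper-tail normal quantile by bisection (valid for p in (0, 1))."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if norm_sf(mid) > p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def chi2_sf_even(x: float, dof: int) -> float:
    """Chi-square upper tail, closed form for even dof:
    sf(x, 2k) = exp(-x/2) * sum_{i<k} (x/2)^i / i!   (computed in log space)."""
    assert dof % 2 == 0 and dof > 0
    k = dof // 2
    if x <= 0:
        return 1.0
    half = x / 2.0
    terms = [math.exp(-half + i * math.log(half) - math.lgamma(i + 1)) for i in range(k)]
    return min(1.0, math.fsum(terms))


def stouffer_oracle(p_ones: list[float], directions: list[int], sqrt_n: bool = True):
    """Signed Z-transform combination built purely on the stdlib oracle."""
    z = [norm_isf(p) * d for p, d in zip(p_ones, directions)]
    n = len(z)
    zs = math.fsum(z) / (math.sqrt(n) if sqrt_n else n)
    return zs, 2.0 * norm_sf(abs(zs))


def fisher_oracle(p_ones: list[float]):
    chi2 = -2.0 * math.fsum(math.log(p) for p in p_ones)
    return chi2, chi2_sf_even(chi2, 2 * len(p_ones))
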