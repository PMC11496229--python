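"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's own code paths: exact rational
arithmetic for the smoothed probabilities, and direct series summation for
the Poisson tail.
"""

from fractions import Fraction
from math import exp, log


def iota_oracle(a: int, b: int, c: int, d: int, alpha: float = 0.5) -> float:
    """Plug-in evaluation of the implication index from first principles."""
    al = Fraction(alpha).limit_denominator(10**6)
    n = a + b + c + d
    denom = n + 4 * al
    p11 = (a + al) / denom
    p10 = (b + al) / denom
    p01 = (c + al) / denom
    p00 = (d + al) / denom
    p1_ = p11 + p10
    p0_ = p01 + p00
    p_1 = p11 + p01
    p_0 = p10 + p00
    direct = (p11 * p_0) / (p10 * p_1)
    contra = (p00 * p1_) / (p10 * p0_)
    return 0.5 * (log(direct) + log(contra))


def poisson_tail_oracle(b: int, lam: float) -> float:
    """P(N >= b) for N ~ Poisson(lam) by direct summation of the pmf."""
    if b <= 0:
        return 1.0
    term = exp(-lam)
    cdf = 0.0
    for k in range(b):
        cdf += term
        term *= lam / (k + 1)
    return 1.0 - cdf


def gras_oracle(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    lam = (a + b) * (b + d) / n
    return poisson_tail_oracle(b, lam)
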