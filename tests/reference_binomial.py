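"""Exact-rational enumeration oracle for the two-tailed binomial test.

Probabilities are computed as Fractions, so outcome-likelihood
comparisons are exact and the minimum-likelihood two-tailed sum carries
no floating-point ambiguity.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def enumerate_two_tailed(k: int, n: int, p0: Fraction) -> float:
    """Sum of Pr(j) over all outcomes j with Pr(j) <= Pr(k), exactly."""
    q0 = 1 - p0
    pmf = [comb(n, j) * p0 ** j * q0 ** (n - j) for j in range(n + 1)]
    observed = pmf[k]
    total = sum(p for p in pmf if p <= observed)
    return float(min(total, Fraction(1)))
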